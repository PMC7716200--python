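"""Pedigree and genomic BLUP.

Implements the animal model y = X beta + Z u + e with var(u) = K sigma_g2
(K a pedigree A, genomic G, or stabilized G* relationship matrix) and
var(e) = I sigma_e2.  Breeding values solve Henderson's mixed-model
equations; variance components come from EM-REML with an optional
average-information acceleration.  The numerator relationship matrix uses
the tabular method with inbreeding; G follows VanRaden: centered genotype
cross-products over 2*sum(p_i*(1-p_i)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .errors import ConfigurationError, LpevalError, PedigreeError
from .types import GenotypeMatrix, MISSING

UNKNOWN_PARENT = "0"
VARIANCE_FLOOR = 1e-10


@dataclass
class MixedModelData:
    """Everything a single-trait animal model needs."""

    y: np.ndarray                 # (n,)
    X: np.ndarray                 # (n, p) fixed-effect incidence
    Z: np.ndarray                 # (n, q) animal incidence
    K: np.ndarray                 # (q, q) relationship matrix
    sigma_g2: float | None = None
    sigma_e2: float | None = None
    animal_ids: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.K = np.asarray(self.K, dtype=float)
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise LpevalError("rows of y, X, Z must agree")
        if self.Z.shape[1] != self.K.shape[0] or self.K.shape[0] != self.K.shape[1]:
            raise LpevalError("Z columns must match the dimension of K")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise LpevalError("K must be symmetric")


@dataclass
class VarianceEstimates:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    n_records: int
    converged: bool
    iterations: int
    loglik_trace: list = field(default_factory=list)


@dataclass
class BreedingValues:
    animal_ids: np.ndarray
    values: np.ndarray
    reliability: np.ndarray | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.animal_ids)


def _topological_order(animal, sire, dam):
    """Indices in an order where parents precede offspring; cycles raise."""
    index = {a: i for i, a in enumerate(animal)}
    n = len(animal)
    state = np.zeros(n, dtype=np.int8)  # 0 new, 1 visiting, 2 done
    order = []

    def parents(i):
        out = []
        for p in (sire[i], dam[i]):
            if p != UNKNOWN_PARENT and p in index:
                out.append(index[p])
        return out

    for start in range(n):
        if state[start]:
            continue
        stack = [(start, iter(parents(start)))]
        state[start] = 1
        path = [animal[start]]
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if state[p] == 1:
                    cycle = path[path.index(animal[p]):] + [animal[p]]
                    raise PedigreeError(f"pedigree cycle: {' -> '.join(cycle)}")
                if state[p] == 0:
                    state[p] = 1
                    path.append(animal[p])
                    stack.append((p, iter(parents(p))))
                    advanced = True
                    break
            if not advanced:
                state[node] = 2
                order.append(node)
                stack.pop()
                if path and path[-1] == animal[node]:
                    path.pop()
    return order


def build_A(pedigree: pd.DataFrame):
    """Numerator relationship matrix by the tabular method, with inbreeding.

    ``pedigree`` needs columns animal, sire, dam ("0" = unknown); parents
    without their own row are treated as unknown, i.e. unrelated founders.
    Returns (A, animal_ids) with rows in the pedigree's input order.
    """
    for col in ("animal", "sire", "dam"):
        if col not in pedigree.columns:
            raise PedigreeError(f"pedigree missing column '{col}'")
    animal = pedigree["animal"].astype(str).to_list()
    sire = pedigree["sire"].astype(str).to_list()
    dam = pedigree["dam"].astype(str).to_list()
    if len(set(animal)) != len(animal):
        raise PedigreeError("duplicate animal ids in pedigree")

    order = _topological_order(animal, sire, dam)
    pos = {orig: k for k, orig in enumerate(order)}  # original index -> topo position
    index = {a: i for i, a in enumerate(animal)}
    n = len(animal)

    a = np.zeros((n, n))  # in topo coordinates
    for k, orig in enumerate(order):
        s = index.get(sire[orig]) if sire[orig] != UNKNOWN_PARENT else None
        d = index.get(dam[orig]) if dam[orig] != UNKNOWN_PARENT else None
        ks = pos[s] if s is not None else None
        kd = pos[d] if d is not None else None
        f = a[ks, kd] if (ks is not None and kd is not None) else 0.0
        a[k, k] = 1.0 + 0.5 * f
        if k:
            rel = np.zeros(k)
            if ks is not None:
                rel += a[:k, ks]
            if kd is not None:
                rel += a[:k, kd]
            a[k, :k] = a[:k, k] = 0.5 * rel

    perm = np.array([pos[i] for i in range(n)])
    A = a[np.ix_(perm, perm)]
    return A, np.array(animal, dtype=object)


@dataclass
class GenomicRelationship:
    """G with the pieces (freqs, divisor) the backsolve step needs."""

    G: np.ndarray
    freqs: np.ndarray
    divisor: float               # k = 2 * sum(p_i * (1 - p_i))
    n_missing_imputed: int = 0


def build_G(
    M,
    freqs: np.ndarray | None = None,
    center: bool = True,
    max_missing: float = 0.05,
) -> GenomicRelationship:
    """VanRaden genomic relationship matrix.

    ``M`` is a GenotypeMatrix or a raw (animals x variants) 0/1/2 array
    (-1 missing).  Missing genotypes are imputed to 2*p_i (count logged);
    animals missing more than ``max_missing`` of their sites are rejected.
    ``center=False`` reproduces the literal uncentered cross-product.
    """
    g = (M.genotypes if isinstance(M, GenotypeMatrix) else np.asarray(M)).astype(float)
    missing = g == MISSING
    bad = missing.mean(axis=1) > max_missing
    if bad.any():
        raise LpevalError(f"{int(bad.sum())} animals missing > {max_missing:.0%} of sites")
    if freqs is None:
        with np.errstate(invalid="ignore"):
            obs_n = (~missing).sum(axis=0)
            freqs = np.where(obs_n > 0, np.where(missing, 0, g).sum(axis=0) / (2.0 * np.maximum(obs_n, 1)), 0.5)
    freqs = np.asarray(freqs, dtype=float)
    n_imputed = int(missing.sum())
    g = np.where(missing, 2.0 * freqs, g)
    k = 2.0 * float(np.sum(freqs * (1.0 - freqs)))
    if k <= 0:
        raise LpevalError("all variants monomorphic: zero divisor for G")
    z = g - 2.0 * freqs if center else g
    return GenomicRelationship(G=(z @ z.T) / k, freqs=freqs, divisor=k, n_missing_imputed=n_imputed)


def stabilize_G(G: np.ndarray) -> np.ndarray:
    """G* = 0.99 G + 0.01 I."""
    G = np.asarray(G, dtype=float)
    return 0.99 * G + 0.01 * np.eye(G.shape[0])


def _solve_mme(y, X, Z, K, sigma_g2, sigma_e2):
    lam = sigma_e2 / sigma_g2
    try:
        kinv = sla.cho_solve(sla.cho_factor(K), np.eye(K.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise LpevalError(
            "relationship matrix is not invertible; apply stabilize_G first"
        ) from exc
    p = X.shape[1]
    q = Z.shape[1]
    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Z + lam * kinv
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(C, rhs)
    return sol[:p], sol[p:], C, kinv


def fit_blup(data: MixedModelData):
    """Solve Henderson's MME; returns (beta_hat, BreedingValues)."""
    if data.sigma_g2 is None or data.sigma_e2 is None:
        raise LpevalError("variance components required; run reml() first")
    beta, u, _, _ = _solve_mme(data.y, data.X, data.Z, data.K, data.sigma_g2, data.sigma_e2)
    ids = data.animal_ids if data.animal_ids is not None else np.arange(len(u))
    return beta, BreedingValues(animal_ids=np.asarray(ids, dtype=object), values=u)


def _reml_loglik(y, X, Z, K, sg2, se2):
    """Restricted log-likelihood, computed directly from V (up to a constant)."""
    n = len(y)
    V = sg2 * (Z @ K @ Z.T) + se2 * np.eye(n)
    cf = sla.cho_factor(V)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    vinv_x = sla.cho_solve(cf, X)
    xtvx = X.T @ vinv_x
    sign, logdet_xvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        raise LpevalError("X'V^-1X not positive definite; is X full rank?")
    vinv_y = sla.cho_solve(cf, y)
    beta = np.linalg.solve(xtvx, vinv_x.T @ y)
    py = vinv_y - vinv_x @ beta
    return -0.5 * (logdet_v + logdet_xvx + float(y @ py)), py, cf, vinv_x, xtvx


def _reml_eigen(y, X, K, method, max_iter, tol, start, n_em_warmup):
    """REML for Z = I via one eigendecomposition of K; O(n p^2) per iteration.

    Uses the gradient form of the EM update
    sigma_new^2 = sigma^2 + (sigma^4/n) (y'P Vi P y - tr(P Vi)),
    identical to the MME-based EM step, and the same AI acceleration rule
    as the general path.
    """
    n = len(y)
    p_rank = int(np.linalg.matrix_rank(X))
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    def core(sg2, se2):
        w = sg2 * d + se2
        xw = Xt / w[:, None]
        xtvx = Xt.T @ xw
        sign, logdet_xvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise LpevalError("X'V^-1X not positive definite; is X full rank?")
        beta = np.linalg.solve(xtvx, xw.T @ yt)
        a = yt / w - xw @ beta          # rotated P y
        ll = -0.5 * (np.sum(np.log(w)) + logdet_xvx + float(yt @ a))
        return w, xw, xtvx, a, ll

    def p_apply(vec, w, xw, xtvx):
        return vec / w - xw @ np.linalg.solve(xtvx, xw.T @ vec)

    def traces(w, xw, xtvx):
        xtvx_inv = np.linalg.inv(xtvx)
        m = xw.T * d  # p x n
        tr_pk = float(np.sum(d / w) - np.sum((m @ xw) * xtvx_inv))
        tr_p = float(np.sum(1.0 / w) - np.sum((xw.T @ xw) * xtvx_inv))
        return tr_pk, tr_p

    vy = float(np.var(y))
    sg2, se2 = (start if start is not None else (0.5 * vy, 0.5 * vy))
    sg2, se2 = max(sg2, VARIANCE_FLOOR), max(se2, VARIANCE_FLOOR)
    w, xw, xtvx, a, ll = core(sg2, se2)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tr_pk, tr_p = traces(w, xw, xtvx)
        ypkpy = float(np.sum(d * a * a))
        yppy = float(a @ a)
        sg2_em = sg2 + (sg2**2 / n) * (ypkpy - tr_pk)
        se2_em = se2 + (se2**2 / n) * (yppy - tr_p)
        cand = (max(sg2_em, VARIANCE_FLOOR), max(se2_em, VARIANCE_FLOOR))

        if method == "ai" and it > n_em_warmup:
            pda = p_apply(d * a, w, xw, xtvx)
            pa = p_apply(a, w, xw, xtvx)
            score = np.array([-0.5 * (tr_pk - ypkpy), -0.5 * (tr_p - yppy)])
            ai_mat = 0.5 * np.array(
                [
                    [float((d * a) @ pda), float((d * a) @ pa)],
                    [float(a @ pda), float(a @ pa)],
                ]
            )
            try:
                step = np.linalg.solve(ai_mat, score)
                for _ in range(10):  # halve the step until inside the space
                    ai_cand = (sg2 + step[0], se2 + step[1])
                    if ai_cand[0] > 0 and ai_cand[1] > 0:
                        ll_ai = core(*ai_cand)[-1]
                        if ll_ai >= trace[-1] - 1e-10:
                            cand = ai_cand
                            break
                    step = step / 2.0
            except np.linalg.LinAlgError:
                pass

        rel_change = max(
            abs(cand[0] - sg2) / max(sg2, VARIANCE_FLOOR),
            abs(cand[1] - se2) / max(se2, VARIANCE_FLOOR),
        )
        sg2, se2 = cand
        w, xw, xtvx, a, ll = core(sg2, se2)
        trace.append(ll)
        ll_change = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
        if rel_change < tol or ll_change < 1e-12 or sg2 / (sg2 + se2) < 1e-7:
            converged = True
            break

    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations", stacklevel=3)

    # information-based SE for h2 at the solution
    se_h2 = float("nan")
    try:
        tr_pk, tr_p = traces(w, xw, xtvx)
        pda = p_apply(d * a, w, xw, xtvx)
        pa = p_apply(a, w, xw, xtvx)
        ai_mat = 0.5 * np.array(
            [
                [float((d * a) @ pda), float((d * a) @ pa)],
                [float(a @ pda), float(a @ pa)],
            ]
        )
        cov = np.linalg.inv(ai_mat)
        tot = sg2 + se2
        grad = np.array([se2, -sg2]) / tot**2
        var_h2 = float(grad @ cov @ grad)
        if var_h2 >= 0:
            se_h2 = float(np.sqrt(var_h2))
    except np.linalg.LinAlgError:
        pass

    return VarianceEstimates(
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        h2=float(sg2 / (sg2 + se2)),
        se_h2=se_h2,
        n_records=n,
        converged=converged,
        iterations=it,
        loglik_trace=trace,
    )


def reml(
    data: MixedModelData,
    method: str = "ai",
    max_iter: int = 500,
    tol: float = 1e-8,
    start: tuple | None = None,
    n_em_warmup: int = 3,
) -> VarianceEstimates:
    """EM-REML with optional average-information acceleration.

    ``method='em'`` runs pure EM (monotone in the restricted likelihood);
    ``'ai'`` switches to AI steps after ``n_em_warmup`` EM iterations,
    falling back to EM whenever an AI step leaves the parameter space or
    lowers the likelihood.  Non-convergence returns converged=False with a
    warning rather than raising.
    """
    y, X, Z, K = data.y, data.X, data.Z, data.K
    n = len(y)
    p = int(np.linalg.matrix_rank(X))
    q = K.shape[0]
    if n <= X.shape[1] + 1:
        raise LpevalError("need more records than fixed effects + 1")
    if method not in ("em", "ai"):
        raise ConfigurationError("method", "must be 'em' or 'ai'")

    if Z.shape[0] == Z.shape[1] and np.array_equal(Z, np.eye(n)):
        return _reml_eigen(y, X, K, method, max_iter, tol, start, n_em_warmup)

    vy = float(np.var(y))
    sg2, se2 = (start if start is not None else (0.5 * vy, 0.5 * vy))
    sg2 = max(sg2, VARIANCE_FLOOR)
    se2 = max(se2, VARIANCE_FLOOR)

    zkz = Z @ K @ Z.T
    trace = []
    converged = False
    it = 0
    ll, *_ = _reml_loglik(y, X, Z, K, sg2, se2)
    trace.append(ll)
    ai_mat = None

    for it in range(1, max_iter + 1):
        use_ai = method == "ai" and it > n_em_warmup

        # EM step quantities from the MME
        beta, u, C, kinv = _solve_mme(y, X, Z, K, sg2, se2)
        cinv = np.linalg.inv(C)
        cuu = cinv[X.shape[1]:, X.shape[1]:]
        sg2_em = (u @ kinv @ u + se2 * np.trace(kinv @ cuu)) / q
        se2_em = (y @ y - beta @ (X.T @ y) - u @ (Z.T @ y)) / (n - p)
        cand = (max(sg2_em, VARIANCE_FLOOR), max(se2_em, VARIANCE_FLOOR))

        if use_ai:
            _, py, cf, vinv_x, xtvx = _reml_loglik(y, X, Z, K, sg2, se2)
            vinv = sla.cho_solve(cf, np.eye(n))
            P = vinv - vinv_x @ np.linalg.solve(xtvx, vinv_x.T)
            dg_py = zkz @ py
            score = np.array(
                [
                    -0.5 * (np.sum(P * zkz) - py @ dg_py),
                    -0.5 * (np.trace(P) - py @ py),
                ]
            )
            ai_mat = 0.5 * np.array(
                [
                    [dg_py @ P @ dg_py, dg_py @ P @ py],
                    [py @ P @ dg_py, py @ P @ py],
                ]
            )
            try:
                step = np.linalg.solve(ai_mat, score)
                for _ in range(10):
                    ai_cand = (sg2 + step[0], se2 + step[1])
                    if ai_cand[0] > 0 and ai_cand[1] > 0:
                        ll_ai, *_ = _reml_loglik(y, X, Z, K, *ai_cand)
                        if ll_ai >= trace[-1] - 1e-10:
                            cand = ai_cand
                            break
                    step = step / 2.0
            except np.linalg.LinAlgError:
                pass

        rel_change = max(
            abs(cand[0] - sg2) / max(sg2, VARIANCE_FLOOR),
            abs(cand[1] - se2) / max(se2, VARIANCE_FLOOR),
        )
        sg2, se2 = cand
        ll, *_ = _reml_loglik(y, X, Z, K, sg2, se2)
        trace.append(ll)
        ll_change = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
        if rel_change < tol or ll_change < 1e-12 or sg2 / (sg2 + se2) < 1e-7:
            converged = True
            break

    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations", stacklevel=2)

    h2 = sg2 / (sg2 + se2)
    se_h2 = float("nan")
    try:
        _, py, cf, vinv_x, xtvx = _reml_loglik(y, X, Z, K, sg2, se2)
        vinv = sla.cho_solve(cf, np.eye(n))
        P = vinv - vinv_x @ np.linalg.solve(xtvx, vinv_x.T)
        dg_py = zkz @ py
        ai_mat = 0.5 * np.array(
            [
                [dg_py @ P @ dg_py, dg_py @ P @ py],
                [py @ P @ dg_py, py @ P @ py],
            ]
        )
        cov = np.linalg.inv(ai_mat)
        tot = sg2 + se2
        grad = np.array([se2, -sg2]) / tot**2
        var_h2 = float(grad @ cov @ grad)
        if var_h2 >= 0:
            se_h2 = float(np.sqrt(var_h2))
    except (np.linalg.LinAlgError, LpevalError):
        pass

    return VarianceEstimates(
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        h2=float(h2),
        se_h2=se_h2,
        n_records=n,
        converged=converged,
        iterations=it,
        loglik_trace=trace,
    )


def project_pwg(ages, weights, wean_age: float):
    """Average daily gain from a per-animal quadratic weight-on-age fit.

    Fits w(t) = a + b t + c t^2 by least squares and returns
    (w(wean_age + 160) - w(wean_age)) / 160.
    """
    ages = np.asarray(ages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ages.shape != weights.shape:
        raise LpevalError("ages and weights must have the same length")
    if ages.size < 3:
        raise LpevalError("need at least 3 weight records for a quadratic fit")
    if np.unique(ages).size < 3:
        raise LpevalError("degenerate design: need 3 distinct ages")
    coeffs = np.polynomial.polynomial.polyfit(ages, weights, 2)
    w = np.polynomial.polynomial.Polynomial(coeffs)
    return float((w(wean_age + 160.0) - w(wean_age)) / 160.0)
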