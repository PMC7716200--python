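"""Diploid Li–Stephens imputation by forward–backward.

The hidden state at each site is an ordered pair of panel haplotypes.  Each
haplotype of the pair switches independently between sites: it stays with
probability 1 - s and otherwise jumps uniformly over the panel, with
s = 1 - exp(-rho * distance).  Emission sums, over the genotype implied by
the copied pair (each allele flipped with probability ``mismatch_rate``),
the per-site genotype likelihood.  The factorized transition keeps the
forward/backward updates at O(K^2) per site.

Posteriors are collapsed to the genotype triple (RR, RA, AA) per site and
renormalized.  A numba-compiled core is used when numba is importable; a
vectorized numpy implementation gives identical results otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ConfigurationError
from .types import HaplotypePanel, ReadPileup

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

DEFAULT_GPMAX_THRESHOLD = 0.9


@dataclass
class ImputationConfig:
    """Parameters of the haplotype-copying model.

    switch_rate is the per-bp rate rho in s = 1 - exp(-rho * d);
    mismatch_rate is the per-allele copying-error probability; max_panel
    caps the number of panel haplotypes used per target (closest by shared
    rare alleles).
    """

    switch_rate: float = 1e-6
    mismatch_rate: float = 1e-3
    max_panel: int = 100

    def validate(self) -> None:
        if self.switch_rate <= 0:
            raise ConfigurationError("switch_rate", "must be > 0")
        if not 0.0 < self.mismatch_rate < 1.0:
            raise ConfigurationError("mismatch_rate", "must be in (0, 1)")
        if self.max_panel < 2:
            raise ConfigurationError("max_panel", "must be >= 2")


@dataclass
class SitePosteriors:
    """Per-site genotype posteriors for one target individual."""

    gp: np.ndarray          # (n_sites, 3) posterior (RR, RA, AA), rows sum to 1
    gp_max: np.ndarray
    dosage: np.ndarray      # gp[:,1] + 2*gp[:,2]
    hard_call: np.ndarray   # argmax genotype, ties to the lowest index
    passed: np.ndarray      # gp_max > threshold
    positions: np.ndarray
    threshold: float = DEFAULT_GPMAX_THRESHOLD


def _pattern_tables(mu: float):
    """Coefficients P(genotype g | copied pair (a1, a2)) as three 2x2 tables."""
    pa = np.array([mu, 1.0 - mu])           # P(allele = 1 | panel allele a)
    p1 = pa[:, None]
    p2 = pa[None, :]
    q0 = (1 - p1) * (1 - p2)
    q1 = (1 - p1) * p2 + p1 * (1 - p2)
    q2 = p1 * p2
    return q0, q1, q2


def _fb_numpy(H: np.ndarray, L: np.ndarray, switch: np.ndarray, mu: float) -> np.ndarray:
    K, V = H.shape
    q0, q1, q2 = _pattern_tables(mu)
    e2 = (
        L[:, 0, None, None] * q0
        + L[:, 1, None, None] * q1
        + L[:, 2, None, None] * q2
    )  # (V, 2, 2)

    ind = np.zeros((V, K, 2))
    ind[np.arange(V)[:, None], np.arange(K)[None, :], H.T] = 1.0

    F = np.empty((V, K, K))
    a = H[:, 0]
    f = e2[0][a[:, None], a[None, :]]
    f /= f.sum()
    F[0] = f
    for t in range(1, V):
        s = switch[t]
        c1 = (1 - s) ** 2
        c2 = (1 - s) * s / K
        c3 = (s / K) ** 2
        r = f.sum(axis=1)
        c = f.sum(axis=0)
        a = H[:, t]
        em = e2[t][a[:, None], a[None, :]]
        f = (c1 * f + c2 * (r[:, None] + c[None, :]) + c3) * em
        f /= f.sum()
        F[t] = f

    gp = np.empty((V, 3))
    b = np.full((K, K), 1.0 / (K * K))
    for t in range(V - 1, -1, -1):
        fb = F[t] * b
        w = ind[t].T @ fb @ ind[t]  # pattern-summed posterior mass (2x2)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(e2[t] > 0, w / e2[t], 0.0)
        g = np.array(
            [(w * q0).sum() * L[t, 0], (w * q1).sum() * L[t, 1], (w * q2).sum() * L[t, 2]]
        )
        gp[t] = g / g.sum()
        if t > 0:
            s = switch[t]
            c1 = (1 - s) ** 2
            c2 = (1 - s) * s / K
            c3 = (s / K) ** 2
            a = H[:, t]
            g_mat = e2[t][a[:, None], a[None, :]] * b
            gr = g_mat.sum(axis=1)
            gc = g_mat.sum(axis=0)
            b = c1 * g_mat + c2 * (gr[:, None] + gc[None, :]) + c3 * g_mat.sum()
            b /= b.sum()
    return gp


if _HAVE_NUMBA:

    @njit(cache=True)
    def _fb_numba(H, L, switch, mu):  # pragma: no cover - mirrors _fb_numpy
        K, V = H.shape
        pa = np.empty(2)
        pa[0] = mu
        pa[1] = 1.0 - mu
        q0 = np.empty((2, 2))
        q1 = np.empty((2, 2))
        q2 = np.empty((2, 2))
        for a1 in range(2):
            for a2 in range(2):
                p1 = pa[a1]
                p2 = pa[a2]
                q0[a1, a2] = (1 - p1) * (1 - p2)
                q1[a1, a2] = (1 - p1) * p2 + p1 * (1 - p2)
                q2[a1, a2] = p1 * p2
        e2 = np.empty((V, 2, 2))
        for t in range(V):
            for a1 in range(2):
                for a2 in range(2):
                    e2[t, a1, a2] = (
                        L[t, 0] * q0[a1, a2] + L[t, 1] * q1[a1, a2] + L[t, 2] * q2[a1, a2]
                    )

        F = np.empty((V, K, K))
        tot = 0.0
        for k in range(K):
            for l in range(K):
                val = e2[0, H[k, 0], H[l, 0]]
                F[0, k, l] = val
                tot += val
        for k in range(K):
            for l in range(K):
                F[0, k, l] /= tot

        R = np.empty(K)
        C = np.empty(K)
        for t in range(1, V):
            s = switch[t]
            c1 = (1 - s) ** 2
            c2 = (1 - s) * s / K
            c3 = (s / K) ** 2
            for k in range(K):
                rk = 0.0
                for l in range(K):
                    rk += F[t - 1, k, l]
                R[k] = rk
            for l in range(K):
                cl = 0.0
                for k in range(K):
                    cl += F[t - 1, k, l]
                C[l] = cl
            tot = 0.0
            for k in range(K):
                hk = H[k, t]
                for l in range(K):
                    val = (c1 * F[t - 1, k, l] + c2 * (R[k] + C[l]) + c3) * e2[t, hk, H[l, t]]
                    F[t, k, l] = val
                    tot += val
            for k in range(K):
                for l in range(K):
                    F[t, k, l] /= tot

        gp = np.empty((V, 3))
        b = np.full((K, K), 1.0 / (K * K))
        G = np.empty((K, K))
        W = np.empty((2, 2))
        for t in range(V - 1, -1, -1):
            W[0, 0] = 0.0
            W[0, 1] = 0.0
            W[1, 0] = 0.0
            W[1, 1] = 0.0
            for k in range(K):
                hk = H[k, t]
                for l in range(K):
                    W[hk, H[l, t]] += F[t, k, l] * b[k, l]
            g0 = 0.0
            g1 = 0.0
            g2 = 0.0
            for a1 in range(2):
                for a2 in range(2):
                    if e2[t, a1, a2] > 0.0:
                        w = W[a1, a2] / e2[t, a1, a2]
                        g0 += w * q0[a1, a2]
                        g1 += w * q1[a1, a2]
                        g2 += w * q2[a1, a2]
            g0 *= L[t, 0]
            g1 *= L[t, 1]
            g2 *= L[t, 2]
            tot = g0 + g1 + g2
            gp[t, 0] = g0 / tot
            gp[t, 1] = g1 / tot
            gp[t, 2] = g2 / tot
            if t > 0:
                s = switch[t]
                c1 = (1 - s) ** 2
                c2 = (1 - s) * s / K
                c3 = (s / K) ** 2
                for k in range(K):
                    hk = H[k, t]
                    for l in range(K):
                        G[k, l] = e2[t, hk, H[l, t]] * b[k, l]
                sg = 0.0
                for k in range(K):
                    rk = 0.0
                    for l in range(K):
                        rk += G[k, l]
                    R[k] = rk
                    sg += rk
                for l in range(K):
                    cl = 0.0
                    for k in range(K):
                        cl += G[k, l]
                    C[l] = cl
                tot = 0.0
                for k in range(K):
                    for l in range(K):
                        val = c1 * G[k, l] + c2 * (R[k] + C[l]) + c3 * sg
                        b[k, l] = val
                        tot += val
                for k in range(K):
                    for l in range(K):
                        b[k, l] /= tot
        return gp


def _forward_backward(H, L, switch, mu, use_numba=True):
    H = np.ascontiguousarray(H, dtype=np.uint8)
    L = np.ascontiguousarray(L, dtype=np.float64)
    switch = np.ascontiguousarray(switch, dtype=np.float64)
    if _HAVE_NUMBA and use_numba:
        return _fb_numba(H, L, switch, float(mu))
    return _fb_numpy(H, L, switch, float(mu))


def select_haplotypes(panel: HaplotypePanel, likelihoods: np.ndarray, max_panel: int) -> np.ndarray:
    """Indices of the panel haplotypes closest to the read evidence.

    Sites whose likelihoods favor one homozygote provide an evidence
    allele; haplotypes carrying it score the allele's rarity weight
    -log(freq).  The top ``max_panel`` scorers are kept (stable order).
    """
    K = panel.n_haplotypes
    if K <= max_panel:
        return np.arange(K)
    l_rr, l_aa = likelihoods[:, 0], likelihoods[:, 2]
    informative = l_rr != l_aa
    evidence = (l_aa > l_rr).astype(np.uint8)
    freq = panel.alt_frequencies()
    allele_freq = np.where(evidence == 1, freq, 1.0 - freq)
    w = -np.log(np.clip(allele_freq, 1.0 / (2 * K), None)) * informative
    match = panel.alleles == evidence[None, :]
    scores = (match * w[None, :]).sum(axis=1)
    order = np.argsort(-scores, kind="stable")[:max_panel]
    return np.sort(order)


def call_genotypes(gp: np.ndarray, threshold: float = DEFAULT_GPMAX_THRESHOLD):
    """Hard calls (argmax, ties to the lowest genotype index) and pass flags."""
    gp = np.asarray(gp, dtype=float)
    hard = np.argmax(gp, axis=-1).astype(np.int8)
    gp_max = gp.max(axis=-1)
    return hard, gp_max > threshold


def impute_sample(
    positions: np.ndarray,
    likelihoods: np.ndarray,
    panel: HaplotypePanel,
    cfg: ImputationConfig | None = None,
    threshold: float = DEFAULT_GPMAX_THRESHOLD,
    use_numba: bool = True,
) -> SitePosteriors:
    """Impute one target's genotype posteriors against the phased panel.

    ``likelihoods`` is (n_sites, 3) in RR, RA, AA order, position-matched
    1:1 with the panel variants (checked; misalignment raises
    :class:`AlignmentError` naming the first offending position).
    """
    cfg = cfg or ImputationConfig()
    cfg.validate()
    positions = np.asarray(positions)
    likelihoods = np.asarray(likelihoods, dtype=float)
    panel_pos = panel.positions
    if len(positions) != len(panel_pos):
        raise AlignmentError(
            f"{len(positions)} likelihood sites vs {len(panel_pos)} panel variants"
        )
    mismatched = np.flatnonzero(positions != panel_pos)
    if mismatched.size:
        i = mismatched[0]
        raise AlignmentError(
            f"site {i}: likelihood position {positions[i]} != panel position {panel_pos[i]}"
        )
    if likelihoods.shape != (len(positions), 3):
        raise AlignmentError("likelihoods must be (n_sites, 3)")

    keep = select_haplotypes(panel, likelihoods, cfg.max_panel)
    H = panel.alleles[keep]

    d = np.diff(panel_pos.astype(float), prepend=panel_pos[0])
    switch = 1.0 - np.exp(-cfg.switch_rate * d)
    switch[0] = 0.0

    gp = _forward_backward(H, likelihoods, switch, cfg.mismatch_rate, use_numba=use_numba)
    hard, passed = call_genotypes(gp, threshold)
    return SitePosteriors(
        gp=gp,
        gp_max=gp.max(axis=1),
        dosage=gp[:, 1] + 2.0 * gp[:, 2],
        hard_call=hard,
        passed=passed,
        positions=panel_pos.copy(),
        threshold=threshold,
    )


def impute_pileup(
    pileup: ReadPileup,
    panel: HaplotypePanel,
    cfg: ImputationConfig | None = None,
    base_error: float = 0.01,
    threshold: float = DEFAULT_GPMAX_THRESHOLD,
) -> dict:
    """Impute every library in a pileup; returns {animal_id: SitePosteriors}."""
    from .lowpass import likelihood_matrix

    out = {}
    positions = pileup.variants["pos"].to_numpy()
    for i, animal in enumerate(pileup.animal_ids):
        lik = likelihood_matrix(pileup.ref_counts[i], pileup.alt_counts[i], base_error)
        out[animal] = impute_sample(positions, lik, panel, cfg, threshold)
    return out
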