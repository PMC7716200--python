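"""Per-variant effects backsolved from genomic breeding values.

The textbook backsolve alpha = M'[MM']^-1 u is singular for centered M, so
the default route is the equivalent well-conditioned form
alpha = Z' (G*)^-1 u / k with Z the centered genotypes, k the G divisor and
G* the stabilized relationship matrix from the GBLUP fit.  A literal
pseudoinverse mode is kept for oracle tests.  Molecular breeding values are
centered target genotypes times the effects, using the training
frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .errors import ConfigurationError, LpevalError
from .gblup import (
    BreedingValues,
    GenomicRelationship,
    MixedModelData,
    build_G,
    fit_blup,
    reml,
    stabilize_G,
)
from .types import GenotypeMatrix, MISSING


@dataclass
class MarkerEffects:
    alpha: np.ndarray            # per-variant effect
    variant_ids: np.ndarray
    freqs: np.ndarray            # training allele frequencies
    divisor: float               # k = 2 * sum(p_i (1 - p_i))


@dataclass
class MBVTable:
    """Molecular breeding values, one row per (animal, variant set, source)."""

    table: pd.DataFrame          # columns: animal, mbv, variant_set, source

    def values_for(self, variant_set: str, source: str) -> pd.Series:
        t = self.table
        sel = t[(t["variant_set"] == variant_set) & (t["source"] == source)]
        return pd.Series(sel["mbv"].to_numpy(), index=sel["animal"].to_numpy())


def _variant_ids(gm: GenotypeMatrix) -> np.ndarray:
    v = gm.variants
    return (v["chrom"].astype(str) + ":" + v["pos"].astype(str)).to_numpy()


def _centered(gm: GenotypeMatrix, freqs: np.ndarray) -> np.ndarray:
    g = gm.genotypes.astype(float)
    g = np.where(gm.genotypes == MISSING, 2.0 * freqs, g)
    return g - 2.0 * freqs


def backsolve_effects(
    M_train: GenotypeMatrix,
    u_hat: BreedingValues | np.ndarray,
    freqs: np.ndarray | None = None,
    stabilized: bool = True,
    exact: bool = False,
) -> MarkerEffects:
    """Solve per-variant effects from training breeding values.

    Default: alpha = Z'(G*)^-1 u / k.  ``stabilized=False`` uses plain G
    (requires full rank).  ``exact=True`` evaluates the literal
    M'[MM']^-1 u with a pseudoinverse instead.
    """
    u = u_hat.values if isinstance(u_hat, BreedingValues) else np.asarray(u_hat, dtype=float)
    if len(u) != M_train.n_animals:
        raise LpevalError("u_hat length must equal training animals")
    rel = build_G(M_train, freqs=freqs)
    z = _centered(M_train, rel.freqs)
    if exact:
        alpha = z.T @ np.linalg.pinv(z @ z.T) @ u
    else:
        gmat = stabilize_G(rel.G) if stabilized else rel.G
        try:
            ginv_u = sla.cho_solve(sla.cho_factor(gmat), u)
        except np.linalg.LinAlgError as exc:
            raise LpevalError("G not invertible; use stabilized=True") from exc
        alpha = z.T @ ginv_u / rel.divisor
    return MarkerEffects(
        alpha=alpha,
        variant_ids=_variant_ids(M_train),
        freqs=rel.freqs,
        divisor=rel.divisor,
    )


def predict_mbv(
    Ms: GenotypeMatrix,
    effects: MarkerEffects,
    variant_set: str = "default",
    source: str = "default",
) -> MBVTable:
    """MBV = centered target genotypes times backsolved effects.

    Target variants are matched to effect variant ids; effect variants the
    targets lack are dropped with a logged count, and fewer than 50%
    matched is an error.
    """
    target_ids = _variant_ids(Ms)
    pos = {v: i for i, v in enumerate(target_ids)}
    keep_eff = np.array([i for i, v in enumerate(effects.variant_ids) if v in pos])
    if keep_eff.size < 0.5 * len(effects.variant_ids):
        raise LpevalError(
            f"only {keep_eff.size}/{len(effects.variant_ids)} effect variants present in targets"
        )
    n_dropped = len(effects.variant_ids) - keep_eff.size
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} effect variants absent from targets", stacklevel=2)
    col = np.array([pos[effects.variant_ids[i]] for i in keep_eff])
    sub = Ms.subset(variant_idx=col)
    z = _centered(sub, effects.freqs[keep_eff])
    mbv = z @ effects.alpha[keep_eff]
    table = pd.DataFrame(
        {
            "animal": Ms.animal_ids,
            "mbv": mbv,
            "variant_set": variant_set,
            "source": source,
        }
    )
    return MBVTable(table=table)


def predict_mbv_from_dosage(
    dosage: np.ndarray,
    variant_ids: np.ndarray,
    effects: MarkerEffects,
) -> np.ndarray:
    """MBV from imputed dosages instead of hard calls.

    ``dosage`` is (n_animals, n_variants) expected alt-allele counts aligned
    with ``variant_ids``; centering uses the training frequencies, exactly
    as :func:`predict_mbv` does for 0/1/2 genotypes.
    """
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    pos = {v: i for i, v in enumerate(variant_ids)}
    keep_eff = np.array([i for i, v in enumerate(effects.variant_ids) if v in pos])
    if keep_eff.size < 0.5 * len(effects.variant_ids):
        raise LpevalError("fewer than half of the effect variants present in dosages")
    col = np.array([pos[effects.variant_ids[i]] for i in keep_eff])
    z = dosage[:, col] - 2.0 * effects.freqs[keep_eff]
    return z @ effects.alpha[keep_eff]


def permutation_select(
    M: GenotypeMatrix,
    y: np.ndarray,
    X: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
    n_perm: int = 100,
    n_keep: int = 10,
    percentile: float = 99.0,
    seed: int = 0,
) -> np.ndarray:
    """Variant subset whose observed |alpha| most exceeds its permutation null.

    The null refits breeding values after jointly permuting the phenotype
    and fixed-effect rows against the genotyped animals, backsolves, and
    takes the per-variant ``percentile`` of |alpha| over permutations.
    Returns the indices (into M's variants) of the top ``n_keep`` variants
    by exceedance, ties broken by observed |alpha| then variant order.
    """
    eligible = np.nan_to_num(M.maf()) > 0
    if n_keep > int(eligible.sum()):
        raise ConfigurationError("n_keep", "more variants requested than polymorphic variants available")
    if n_perm < 1:
        raise ConfigurationError("n_perm", "must be >= 1")
    rng = np.random.default_rng([int(seed), 808])
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X = X[:, np.abs(X).sum(axis=0) > 0]  # drop empty factor levels
    rel = build_G(M)
    gstar = stabilize_G(rel.G)
    z = _centered(M, rel.freqs)
    n = len(y)
    Zinc = np.eye(n)
    data = MixedModelData(y=y, X=X, Z=Zinc, K=gstar, sigma_g2=sigma_g2, sigma_e2=sigma_e2)
    _, bv = fit_blup(data)
    ginv = sla.cho_solve(sla.cho_factor(gstar), np.eye(n))

    def alphas(u):
        return z.T @ (ginv @ u) / rel.divisor

    alpha_obs = np.abs(alphas(bv.values))

    # the coefficient matrix is unchanged under permutation, only the RHS
    # moves; precompute the pieces of the MME solve
    lam = sigma_e2 / sigma_g2
    p = X.shape[1]
    C = np.empty((p + n, p + n))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T
    C[p:, :p] = X
    C[p:, p:] = np.eye(n) + lam * ginv
    lu = sla.lu_factor(C)

    null = np.empty((n_perm, M.n_variants))
    for j in range(n_perm):
        perm = rng.permutation(n)
        yp = y[perm]
        rhs = np.concatenate([X[perm].T @ yp, yp])
        u_p = sla.lu_solve(lu, rhs)[p:]
        null[j] = np.abs(alphas(u_p))
    q = np.percentile(null, percentile, axis=0)
    exceed = np.where(eligible, alpha_obs - q, -np.inf)
    order = np.lexsort((np.arange(M.n_variants), -alpha_obs, -exceed))
    return np.sort(order[:n_keep])


def leave_out_validate(
    M_all: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    X_columns: list,
    pedigree: pd.DataFrame,
    holdout_ids,
    variant_sets: dict,
    holdout_sources: dict,
    variances: tuple | None = None,
    estimate_variances: bool = False,
) -> pd.DataFrame:
    """Train effects without the holdouts, predict their MBV from each
    genotype source, and correlate with pedigree EBV and full-data GEBV.

    ``variant_sets`` maps set name -> variant indices into M_all;
    ``holdout_sources`` maps source name -> GenotypeMatrix of holdout
    genotypes on M_all's variants.  Returns a tidy grid with one row per
    (variant set, source, reference prediction).
    """
    from .gblup import build_A

    pheno = phenotypes.set_index("animal")
    holdout_ids = np.asarray(holdout_ids, dtype=object)
    all_ids = M_all.animal_ids
    is_hold = np.isin(all_ids, holdout_ids)
    train_idx = np.flatnonzero(~is_hold)

    y_all = pheno.loc[all_ids, "y"].to_numpy(dtype=float)
    X_all = _design_from_factors(pheno.loc[all_ids], X_columns)

    if variances is None:
        rel_all = build_G(M_all)
        data0 = MixedModelData(
            y=y_all, X=X_all, Z=np.eye(len(all_ids)), K=stabilize_G(rel_all.G)
        )
        est = reml(data0, method="ai")
        sg2, se2 = est.sigma_g2, est.sigma_e2
    else:
        sg2, se2 = variances

    # reference predictions on the full data
    A, ped_ids = build_A(pedigree)
    ped_pos = {a: i for i, a in enumerate(ped_ids)}
    in_ped = [a in ped_pos for a in all_ids]
    if not all(in_ped):
        raise LpevalError("all genotyped animals must appear in the pedigree")
    Z_ped = np.zeros((len(all_ids), len(ped_ids)))
    for r, a in enumerate(all_ids):
        Z_ped[r, ped_pos[a]] = 1.0
    _, ebv = fit_blup(
        MixedModelData(y=y_all, X=X_all, Z=Z_ped, K=A, sigma_g2=sg2, sigma_e2=se2,
                       animal_ids=ped_ids)
    )
    ebv_hold = ebv.as_series().loc[holdout_ids].to_numpy()

    rel_all = build_G(M_all)
    _, gebv = fit_blup(
        MixedModelData(
            y=y_all, X=X_all, Z=np.eye(len(all_ids)), K=stabilize_G(rel_all.G),
            sigma_g2=sg2, sigma_e2=se2, animal_ids=all_ids,
        )
    )
    gebv_hold = gebv.as_series().loc[holdout_ids].to_numpy()

    rows = []
    n_h = len(holdout_ids)
    maf_train = M_all.subset(animal_idx=train_idx).maf()
    for set_name, var_idx in variant_sets.items():
        var_idx = np.asarray(var_idx)
        poly = var_idx[np.nan_to_num(maf_train[var_idx]) > 0]
        if poly.size < var_idx.size:
            warnings.warn(
                f"set '{set_name}': dropped {var_idx.size - poly.size} variants "
                "monomorphic in the training animals",
                stacklevel=2,
            )
        if poly.size == 0:
            raise LpevalError(f"variant set '{set_name}' has no polymorphic training variants")
        var_idx = poly
        m_train = M_all.subset(animal_idx=train_idx, variant_idx=var_idx)
        rel = build_G(m_train)
        X_tr = X_all[train_idx]
        # a factor level absent from the training subset leaves a zero column
        X_tr = X_tr[:, np.abs(X_tr).sum(axis=0) > 0]
        data = MixedModelData(
            y=y_all[train_idx],
            X=X_tr,
            Z=np.eye(train_idx.size),
            K=stabilize_G(rel.G),
            sigma_g2=sg2,
            sigma_e2=se2,
            animal_ids=all_ids[train_idx],
        )
        if estimate_variances:
            est = reml(data, method="ai")
            data.sigma_g2, data.sigma_e2 = est.sigma_g2, est.sigma_e2
        _, u_train = fit_blup(data)
        eff = backsolve_effects(m_train, u_train, stabilized=True)
        for source, gm in holdout_sources.items():
            gm_set = gm.subset(variant_idx=np.asarray(var_idx))
            mbv = predict_mbv(gm_set, eff, variant_set=set_name, source=source)
            vals = mbv.values_for(set_name, source).loc[holdout_ids].to_numpy()
            for ref_name, ref in (("pedigree_ebv", ebv_hold), ("gebv", gebv_hold)):
                r = float(np.corrcoef(vals, ref)[0, 1])
                se = float(np.sqrt((1 - r**2) / (n_h - 2))) if n_h > 2 else float("nan")
                rows.append(
                    {
                        "variant_set": set_name,
                        "source": source,
                        "reference": ref_name,
                        "r": r,
                        "se": se,
                        "n": n_h,
                    }
                )
    return pd.DataFrame(rows)


def _design_from_factors(pheno: pd.DataFrame, factor_columns: list) -> np.ndarray:
    """Fixed-effect design: intercept plus dummy columns, first level of
    each factor constrained to zero."""
    n = len(pheno)
    cols = [np.ones((n, 1))]
    for col in factor_columns:
        levels = pd.Categorical(pheno[col])
        for lev in levels.categories[1:]:
            cols.append((levels == lev).astype(float).reshape(-1, 1))
    return np.hstack(cols)
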