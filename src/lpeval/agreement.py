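"""Imputation quality metrics.

Call confidence (CC) is the phred-scaled mean error probability over
uncertain calls: cc = mean(-10*log10(1 - gp_max)) over sites with
gp_max < 1 after rounding to 4 decimals (the precision genotype
probabilities carry in a VCF).  A library with no uncertain calls gets the
cap (100 phred).

Agreement between two call sets is reported both as a Pearson correlation
of 0/1/2 codes and as concordance (fraction of identical calls), overall
and stratified into half-open (lo, hi] minor-allele-frequency bins of
width 0.01 computed from the comparator matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LpevalError
from .types import GenotypeMatrix, HaplotypePanel, MISSING

CC_CAP = 100.0
GP_DECIMALS = 4


@dataclass
class AgreementReport:
    """Bundle of the per-library and per-variant agreement statistics."""

    cc: pd.Series                      # per-library call confidence (phred)
    pass_rate_by_library: pd.Series
    pass_rate_by_variant: pd.Series
    window_low_pass: pd.DataFrame
    r_overall: pd.Series               # per-library genotype correlation
    concordance_overall: pd.Series
    by_maf_bin: pd.DataFrame

    def to_json_summary(self) -> dict:
        return {
            "mean_cc": float(self.cc.mean()),
            "mean_pass_rate_by_library": float(self.pass_rate_by_library.mean()),
            "mean_r": float(self.r_overall.mean(skipna=True)),
            "mean_concordance": float(self.concordance_overall.mean()),
        }


def call_confidence(gp_max: np.ndarray, cap: float = CC_CAP, decimals: int = GP_DECIMALS) -> float:
    """Phred CC over uncertain calls; ``cap`` when every call is certain.

    gp_max is rounded to the VCF's probability precision first, so
    e.g. 0.99996 counts as a certain call.
    """
    g = np.round(np.asarray(gp_max, dtype=float), decimals)
    if g.size == 0:
        raise LpevalError("call_confidence needs at least one site")
    uncertain = g < 1.0
    if not uncertain.any():
        return float(cap)
    return float(np.mean(-10.0 * np.log10(1.0 - g[uncertain])))


def genotype_agreement(a: np.ndarray, b: np.ndarray):
    """(r, concordance, n_shared) between two 0/1/2 call vectors.

    Missing calls (-1) on either side are dropped.  r is NaN when fewer
    than 2 shared sites remain or either vector is constant; concordance is
    computed whenever at least one shared site exists.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    shared = (a != MISSING) & (b != MISSING)
    n = int(shared.sum())
    if n == 0:
        return float("nan"), float("nan"), 0
    x = a[shared].astype(float)
    y = b[shared].astype(float)
    concordance = float(np.mean(x == y))
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), concordance, n
    r = float(np.corrcoef(x, y)[0, 1])
    return r, concordance, n


def _per_variant_agreement(calls: GenotypeMatrix, truth: GenotypeMatrix):
    """Per-variant correlation and concordance across libraries."""
    c = calls.genotypes.astype(float)
    t = truth.genotypes.astype(float)
    obs = (calls.genotypes != MISSING) & (truth.genotypes != MISSING)
    n = obs.sum(axis=0)
    cm = np.where(obs, c, np.nan)
    tm = np.where(obs, t, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mc = np.nanmean(np.where(obs, c, np.nan), axis=0)
        mt = np.nanmean(np.where(obs, t, np.nan), axis=0)
        dc = np.where(obs, c - mc, 0.0)
        dt = np.where(obs, t - mt, 0.0)
        cov = (dc * dt).sum(axis=0)
        vc = (dc**2).sum(axis=0)
        vt = (dt**2).sum(axis=0)
        r = np.where((vc > 0) & (vt > 0), cov / np.sqrt(vc * vt), np.nan)
        conc = np.where(n > 0, ((cm == tm) & obs).sum(axis=0) / np.maximum(n, 1), np.nan)
    return r, conc, n


def maf_binned_agreement(
    calls: GenotypeMatrix,
    truth: GenotypeMatrix,
    bin_width: float = 0.01,
    min_compared: int = 35,
) -> pd.DataFrame:
    """Mean per-variant r and concordance within comparator-MAF bins.

    MAF comes from the comparator (truth) matrix; variants with fewer than
    ``min_compared`` shared non-missing calls are dropped.  Bins are
    half-open (lo, hi] covering (0, 0.5]; empty bins are kept and flagged.
    """
    if calls.genotypes.shape != truth.genotypes.shape:
        raise LpevalError("calls and truth matrices must have the same shape")
    r, conc, n = _per_variant_agreement(calls, truth)
    maf = truth.maf()
    keep = n >= min_compared
    n_bins = int(round(0.5 / bin_width))
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    # half-open (lo, hi]: maf exactly on an edge belongs to the lower bin
    bin_idx = np.searchsorted(edges, maf, side="left") - 1
    rows = []
    for b in range(n_bins):
        in_bin = keep & (bin_idx == b) & (maf > 0)
        rr = r[in_bin]
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_variants": int(in_bin.sum()),
                "mean_r": float(np.nanmean(rr)) if in_bin.any() and not np.isnan(rr).all() else float("nan"),
                "mean_concordance": float(np.nanmean(conc[in_bin])) if in_bin.any() else float("nan"),
                "empty": bool(~in_bin.any()),
            }
        )
    return pd.DataFrame(rows)


def window_pass_rates(
    pass_flags: np.ndarray,
    variant_table: pd.DataFrame,
    window: int = 1_000_000,
    rate_threshold: float = 0.95,
) -> pd.DataFrame:
    """Per 1-Mb window: fraction of variants with across-library pass rate
    below ``rate_threshold``, plus the mean inter-variant spacing.

    ``pass_flags`` is (n_libraries, n_variants) boolean (or an already
    reduced per-variant pass-rate vector).  Window k spans
    [k*window + 1, (k+1)*window].
    """
    flags = np.asarray(pass_flags)
    rate = flags.mean(axis=0) if flags.ndim == 2 else flags.astype(float)
    pos = variant_table["pos"].to_numpy()
    chrom = variant_table["chrom"].to_numpy()
    win = (pos - 1) // window
    rows = []
    for ch in pd.unique(chrom):
        on_ch = chrom == ch
        for k in np.unique(win[on_ch]):
            m = on_ch & (win == k)
            p = np.sort(pos[m])
            rows.append(
                {
                    "chrom": ch,
                    "window": int(k),
                    "start": int(k * window + 1),
                    "end": int((k + 1) * window),
                    "n_variants": int(m.sum()),
                    "frac_low_pass": float(np.mean(rate[m] < rate_threshold)),
                    "mean_spacing": float(np.mean(np.diff(p))) if p.size > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def verify_identity(
    imputed: GenotypeMatrix,
    comparator: GenotypeMatrix,
    min_concordance: float = 0.9,
) -> pd.DataFrame:
    """Best-concordance comparator sample per imputed library.

    A library is flagged when its best match is not its declared identity
    or the best concordance falls below ``min_concordance``.
    """
    rows = []
    for i, lib in enumerate(imputed.animal_ids):
        best_id, best_c = None, -1.0
        for j, cand in enumerate(comparator.animal_ids):
            _, c, n = genotype_agreement(imputed.genotypes[i], comparator.genotypes[j])
            if n > 0 and c > best_c:
                best_id, best_c = cand, c
        rows.append(
            {
                "library": lib,
                "best_match": best_id,
                "best_concordance": best_c,
                "flagged": bool(best_id != lib or best_c < min_concordance),
            }
        )
    return pd.DataFrame(rows)


def panel_pca(
    panel: HaplotypePanel,
    n_snps: int = 150_000,
    maf_min: float = 0.05,
    seed: int = 0,
    n_components: int = 10,
):
    """Centered PCA of panel haplotypes on a random common-SNP subset.

    Returns (scores, explained_fractions, snp_indices): scores is
    (n_haplotypes, n_components), explained fractions relative to the
    total variance of the subset matrix.
    """
    rng = np.random.default_rng([int(seed), 707])
    freq = panel.alt_frequencies()
    maf = np.minimum(freq, 1 - freq)
    eligible = np.flatnonzero(maf > maf_min)
    if eligible.size == 0:
        raise LpevalError(f"no variants with MAF > {maf_min}")
    take = min(n_snps, eligible.size)
    snp_idx = np.sort(rng.choice(eligible, size=take, replace=False))
    x = panel.alleles[:, snp_idx].astype(float)
    x -= x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n_components = min(n_components, s.size)
    scores = u[:, :n_components] * s[:n_components]
    total = float((s**2).sum())
    evf = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return scores, evf, snp_idx


def filter_genotypes(
    gm: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.005,
):
    """Call-rate and MAF filtering, one pass each in the order
    variants, animals, variants, then the MAF cut (thresholds exclusive:
    kept when strictly above).  Returns (filtered, removal_log)."""
    removal_log = {}
    out = gm
    v_keep = np.flatnonzero(out.call_rate_by_variant() > call_rate_min)
    removal_log["variants_call_rate_pass1"] = out.n_variants - v_keep.size
    out = out.subset(variant_idx=v_keep)

    a_keep = np.flatnonzero(out.call_rate_by_animal() > call_rate_min)
    removal_log["animals_call_rate"] = out.n_animals - a_keep.size
    out = out.subset(animal_idx=a_keep)

    v_keep = np.flatnonzero(out.call_rate_by_variant() > call_rate_min)
    removal_log["variants_call_rate_pass2"] = out.n_variants - v_keep.size
    out = out.subset(variant_idx=v_keep)

    maf = out.maf()
    v_keep = np.flatnonzero(np.nan_to_num(maf) > maf_min)
    removal_log["variants_maf"] = out.n_variants - v_keep.size
    out = out.subset(variant_idx=v_keep)
    return out, removal_log


def build_report(
    posteriors: dict,
    calls: GenotypeMatrix,
    truth: GenotypeMatrix,
    variant_table: pd.DataFrame,
    min_compared: int = 1,
    window: int = 1_000_000,
    bin_width: float = 0.01,
    pass_rate_threshold: float = 0.95,
) -> AgreementReport:
    """Assemble the full AgreementReport for a set of imputed libraries."""
    libs = list(posteriors)
    cc = pd.Series({a: call_confidence(posteriors[a].gp_max) for a in libs})
    pass_mat = np.stack([posteriors[a].passed for a in libs])
    pass_by_lib = pd.Series(pass_mat.mean(axis=1), index=libs)
    pass_by_var = pd.Series(pass_mat.mean(axis=0))
    window_df = window_pass_rates(
        pass_mat, variant_table, window=window, rate_threshold=pass_rate_threshold
    )
    r, conc = {}, {}
    for i, a in enumerate(libs):
        ri, ci, _ = genotype_agreement(calls.genotypes[i], truth.genotypes[i])
        r[a], conc[a] = ri, ci
    by_bin = maf_binned_agreement(calls, truth, bin_width=bin_width, min_compared=min_compared)
    return AgreementReport(
        cc=cc,
        pass_rate_by_library=pass_by_lib,
        pass_rate_by_variant=pass_by_var,
        window_low_pass=window_df,
        r_overall=pd.Series(r),
        concordance_overall=pd.Series(conc),
        by_maf_bin=by_bin,
    )
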