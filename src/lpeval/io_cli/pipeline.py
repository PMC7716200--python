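"""End-to-end pipeline: simulate -> downsample -> impute -> qc -> gblup ->
validate.

Stages communicate only through declared file artifacts under the output
directory, every stage appends its seeds and row counts to manifest.json,
and reruns with the same config are byte-identical (no timestamps are
written).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .. import agreement as agr
from .. import effects as eff
from .. import gblup
from ..errors import LpevalError
from ..impute import ImputationConfig, SitePosteriors, impute_sample
from ..lowpass import downsample_reads, likelihood_matrix
from ..simdata import (
    SimConfig,
    _STAGE_SALT,
    simulate_individuals,
    simulate_panel,
    simulate_phenotypes,
    simulate_reads,
)
from ..types import GenotypeMatrix, MISSING
from .config import RunConfig
from .tables import read_genotype_csv, read_pileup_tsv, write_genotype_csv, write_pileup_tsv
from .vcfio import read_panel_vcf, read_vcf, write_imputed_vcf, write_panel_vcf

log = logging.getLogger("lpeval")

STAGES = ("simulate", "downsample", "impute", "qc", "gblup", "validate")


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _update_manifest(out: Path, stage: str, info: dict) -> None:
    path = out / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["stages"][stage] = info
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    sim = cfg.sim
    panel = simulate_panel(sim)
    pedigree, truth = simulate_individuals(panel, sim)
    phenos = simulate_phenotypes(truth, sim)
    pileup = simulate_reads(truth, sim)

    write_panel_vcf(panel, out / "panel.vcf")
    pedigree.to_csv(out / "pedigree.csv", index=False)
    phenos.table.to_csv(out / "phenotypes.csv", index=False)
    write_genotype_csv(truth.true_genotypes, out / "truth_genotypes.csv")
    truth_df = pd.DataFrame(
        {
            "animal": truth.animal_ids,
            "true_bv": truth.true_breeding_values,
            "is_target": truth.is_target,
        }
    )
    pd.concat([truth_df, truth.breed_fraction.reset_index(drop=True)], axis=1).to_csv(
        out / "truth_animals.csv", index=False
    )
    pd.DataFrame(
        {
            "variant_index": truth.qtl_indices,
            "effect": truth.qtl_effects,
            "center_freq": truth.qtl_center_freqs,
        }
    ).to_csv(out / "truth_qtl.csv", index=False)
    write_pileup_tsv(pileup, out / "pileup.tsv")
    _update_manifest(
        out,
        "simulate",
        {
            "seed": cfg.seed,
            "stage_salts": dict(_STAGE_SALT),
            "n_panel_haplotypes": panel.n_haplotypes,
            "n_variants": panel.n_variants,
            "n_animals": len(truth.animal_ids),
            "n_targets": int(truth.is_target.sum()),
        },
    )


def stage_downsample(cfg: RunConfig, out: Path) -> None:
    panel = read_panel_vcf(out / "panel.vcf")
    pileup = read_pileup_tsv(out / "pileup.tsv", panel.variants)
    if cfg.downsample.enabled:
        thinned = downsample_reads(
            pileup,
            fraction=cfg.downsample.fraction,
            target_mean_depth=cfg.downsample.target_mean_depth,
            seed=cfg.seed,
        )
    else:
        thinned = pileup
    write_pileup_tsv(thinned, out / "downsampled.tsv")
    _update_manifest(
        out,
        "downsample",
        {
            "enabled": cfg.downsample.enabled,
            "mean_depth_in": pileup.mean_depth(),
            "mean_depth_out": thinned.mean_depth(),
        },
    )


def _truth_posteriors(g_row: np.ndarray, positions: np.ndarray) -> SitePosteriors:
    """One-hot posteriors for truth substitution when imputation is disabled."""
    v = len(g_row)
    gp = np.zeros((v, 3))
    gp[np.arange(v), g_row] = 1.0
    return SitePosteriors(
        gp=gp,
        gp_max=np.ones(v),
        dosage=g_row.astype(float),
        hard_call=g_row.astype(np.int8),
        passed=np.ones(v, dtype=bool),
        positions=positions,
    )


def stage_impute(cfg: RunConfig, out: Path) -> None:
    panel = read_panel_vcf(out / "panel.vcf")
    pileup = read_pileup_tsv(out / "downsampled.tsv", panel.variants)
    imp_dir = out / "imputed"
    imp_dir.mkdir(exist_ok=True)
    icfg = ImputationConfig(
        switch_rate=cfg.impute.switch_rate,
        mismatch_rate=cfg.impute.mismatch_rate,
        max_panel=cfg.impute.max_panel,
    )
    positions = panel.positions
    if cfg.impute.enabled:
        for i, animal in enumerate(pileup.animal_ids):
            lik = likelihood_matrix(
                pileup.ref_counts[i], pileup.alt_counts[i], cfg.impute.base_error
            )
            post = impute_sample(positions, lik, panel, icfg, threshold=cfg.impute.gpmax_threshold)
            write_imputed_vcf(imp_dir / f"{animal}.vcf", str(animal), panel.variants, post)
            log.info("imputed %s", animal)
    else:
        truth_gm = read_genotype_csv(out / "truth_genotypes.csv")
        for animal in pileup.animal_ids:
            post = _truth_posteriors(truth_gm.row(animal), positions)
            write_imputed_vcf(imp_dir / f"{animal}.vcf", str(animal), panel.variants, post)
    _update_manifest(
        out,
        "impute",
        {
            "enabled": cfg.impute.enabled,
            "n_libraries": len(pileup.animal_ids),
            "gpmax_threshold": cfg.impute.gpmax_threshold,
        },
    )


def _load_imputed(out: Path, animals) -> dict:
    posts = {}
    for animal in animals:
        data = read_vcf(out / "imputed" / f"{animal}.vcf")
        gp = np.round(data.gp[0], 4)
        passed = data.ft[0] == "PASS" if data.ft is not None else np.ones(len(gp), dtype=bool)
        posts[animal] = SitePosteriors(
            gp=gp,
            gp_max=gp.max(axis=1),
            dosage=data.dosage[0],
            hard_call=data.genotypes.genotypes[0],
            passed=passed,
            positions=data.genotypes.variants["pos"].to_numpy(),
        )
    return posts


def _calls_matrix(posts: dict, variants: pd.DataFrame, mask_failed: bool = True) -> GenotypeMatrix:
    animals = list(posts)
    calls = np.stack([posts[a].hard_call for a in animals]).astype(np.int8)
    if mask_failed:
        passed = np.stack([posts[a].passed for a in animals])
        calls = np.where(passed, calls, MISSING).astype(np.int8)
    return GenotypeMatrix(calls, np.array(animals, dtype=object), variants)


def stage_qc(cfg: RunConfig, out: Path) -> None:
    panel = read_panel_vcf(out / "panel.vcf")
    truth_all = read_genotype_csv(out / "truth_genotypes.csv")
    animals_df = pd.read_csv(out / "truth_animals.csv")
    targets = animals_df.loc[animals_df["is_target"], "animal"].to_numpy(dtype=object)
    posts = _load_imputed(out, targets)
    target_rows = [np.flatnonzero(truth_all.animal_ids == a)[0] for a in targets]
    truth_gm = truth_all.subset(animal_idx=np.array(target_rows))
    calls = _calls_matrix(posts, panel.variants)

    report = agr.build_report(
        posts,
        calls,
        truth_gm,
        panel.variants,
        min_compared=cfg.agreement.min_compared,
        window=cfg.agreement.window,
        bin_width=cfg.agreement.maf_bin,
        pass_rate_threshold=cfg.agreement.pass_rate_threshold,
    )
    qc_dir = out / "agreement"
    qc_dir.mkdir(exist_ok=True)
    pd.DataFrame(
        {
            "library": report.cc.index,
            "cc": report.cc.to_numpy(),
            "pass_rate": report.pass_rate_by_library.to_numpy(),
            "r": report.r_overall.to_numpy(),
            "concordance": report.concordance_overall.to_numpy(),
        }
    ).to_csv(qc_dir / "per_library.csv", index=False)
    report.window_low_pass.to_csv(qc_dir / "window_pass_rates.csv", index=False)
    report.by_maf_bin.to_csv(qc_dir / "maf_bins.csv", index=False)
    agr.verify_identity(calls, truth_gm).to_csv(qc_dir / "identity.csv", index=False)
    scores, evf, _ = agr.panel_pca(panel, seed=cfg.seed)
    pca_df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    pca_df.insert(0, "pop", panel.pop_labels)
    pca_df.to_csv(qc_dir / "panel_pca.csv", index=False)
    (qc_dir / "summary.json").write_text(
        json.dumps(report.to_json_summary(), indent=2, sort_keys=True) + "\n"
    )
    _update_manifest(out, "qc", report.to_json_summary())


def _design(pheno: pd.DataFrame) -> np.ndarray:
    factor_cols = [c for c in pheno.columns if c.startswith("cg")]
    return eff._design_from_factors(pheno, factor_cols)


def stage_gblup(cfg: RunConfig, out: Path) -> None:
    pedigree = pd.read_csv(out / "pedigree.csv", dtype=str)
    pheno = pd.read_csv(out / "phenotypes.csv")
    truth_all = read_genotype_csv(out / "truth_genotypes.csv")

    pheno = pheno.set_index("animal").loc[truth_all.animal_ids].reset_index()
    y = pheno["y"].to_numpy(dtype=float)
    X = _design(pheno)
    n = len(y)

    A, ped_ids = gblup.build_A(pedigree)
    # records are in pedigree order here by construction
    data_a = gblup.MixedModelData(y=y, X=X, Z=np.eye(n), K=A, animal_ids=ped_ids)
    est_a = gblup.reml(data_a, method=cfg.gblup.reml_method)
    data_a.sigma_g2, data_a.sigma_e2 = est_a.sigma_g2, est_a.sigma_e2
    _, ebv = gblup.fit_blup(data_a)

    rel = gblup.build_G(truth_all)
    gstar = gblup.stabilize_G(rel.G)
    data_g = gblup.MixedModelData(
        y=y, X=X, Z=np.eye(n), K=gstar, animal_ids=truth_all.animal_ids
    )
    est_g = gblup.reml(data_g, method=cfg.gblup.reml_method)
    data_g.sigma_g2, data_g.sigma_e2 = est_g.sigma_g2, est_g.sigma_e2
    _, gebv = gblup.fit_blup(data_g)

    gdir = out / "gblup"
    gdir.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "relationship": name,
                "sigma_g2": e.sigma_g2,
                "sigma_e2": e.sigma_e2,
                "h2": e.h2,
                "se_h2": e.se_h2,
                "n": e.n_records,
                "converged": e.converged,
                "iterations": e.iterations,
            }
            for name, e in (("A", est_a), ("Gstar", est_g))
        ]
    ).to_csv(gdir / "variances.csv", index=False)
    pd.DataFrame(
        {"animal": ebv.animal_ids, "ebv": ebv.values, "gebv": gebv.as_series().loc[ebv.animal_ids].to_numpy()}
    ).to_csv(gdir / "breeding_values.csv", index=False)
    _update_manifest(
        out,
        "gblup",
        {"h2_A": est_a.h2, "h2_Gstar": est_g.h2, "n_records": n},
    )


def stage_validate(cfg: RunConfig, out: Path) -> None:
    pedigree = pd.read_csv(out / "pedigree.csv", dtype=str)
    pheno = pd.read_csv(out / "phenotypes.csv")
    truth_all = read_genotype_csv(out / "truth_genotypes.csv")
    animals_df = pd.read_csv(out / "truth_animals.csv")
    targets = animals_df.loc[animals_df["is_target"], "animal"].to_numpy(dtype=object)
    variances = pd.read_csv(out / "gblup" / "variances.csv")
    row = variances.loc[variances["relationship"] == "Gstar"].iloc[0]
    sg2, se2 = float(row["sigma_g2"]), float(row["sigma_e2"])

    posts = _load_imputed(out, targets)
    lowpass_gm = _calls_matrix(posts, truth_all.variants)

    # trait-specific subset by permutation on the training animals
    is_hold = np.isin(truth_all.animal_ids, targets)
    train_idx = np.flatnonzero(~is_hold)
    pheno_idx = pheno.set_index("animal").loc[truth_all.animal_ids]
    y = pheno_idx["y"].to_numpy(dtype=float)
    X = _design(pheno_idx.reset_index())
    m_train = truth_all.subset(animal_idx=train_idx)
    selected = eff.permutation_select(
        m_train,
        y[train_idx],
        X[train_idx],
        sigma_g2=sg2,
        sigma_e2=se2,
        n_perm=cfg.effects.n_perm,
        n_keep=cfg.effects.n_keep,
        percentile=cfg.effects.percentile,
        seed=cfg.seed,
    )
    rng = np.random.default_rng([cfg.seed, _STAGE_SALT["effects"], 1])
    random_set = np.sort(
        rng.choice(truth_all.n_variants, size=min(cfg.effects.random_subset_size, truth_all.n_variants), replace=False)
    )
    variant_sets = {
        "all": np.arange(truth_all.n_variants),
        "selected": selected,
        "random": random_set,
    }
    target_rows = [np.flatnonzero(truth_all.animal_ids == a)[0] for a in targets]
    holdout_sources = {
        "array": truth_all.subset(animal_idx=np.array(target_rows)),
        "lowpass": lowpass_gm,
    }
    factor_cols = [c for c in pheno.columns if c.startswith("cg")]
    grid = eff.leave_out_validate(
        truth_all,
        pheno,
        factor_cols,
        pedigree,
        targets,
        variant_sets,
        holdout_sources,
        variances=(sg2, se2),
    )
    grid.to_csv(out / "validation_grid.csv", index=False)
    pd.DataFrame({"variant_index": selected}).to_csv(out / "selected_variants.csv", index=False)
    _update_manifest(
        out,
        "validate",
        {"n_holdouts": len(targets), "n_selected": int(len(selected))},
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "downsample": stage_downsample,
    "impute": stage_impute,
    "qc": stage_qc,
    "gblup": stage_gblup,
    "validate": stage_validate,
}


def run_pipeline(cfg: RunConfig, outdir, stages=STAGES) -> Path:
    """Run the requested stages in order; any failure halts with the stage
    name while earlier artifacts persist."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    _update_manifest(out, "config", {"hash": _config_hash(cfg), "seed": cfg.seed})
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise LpevalError(f"unknown stage {stage!r}")
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            raise LpevalError(f"stage '{stage}' failed: {exc}") from exc
    return out
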