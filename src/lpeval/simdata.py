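"""Synthetic data generation with known truth.

Produces every input the downstream pipeline needs: a multi-population
phased haplotype panel, pedigreed individuals whose chromosomes are
recombinant mosaics of panel haplotypes, additive phenotypes with
configurable heritability and fixed effects, and per-site read counts at a
configurable mean coverage.

Population structure follows a Balding–Nichols drift model: each
population's allele frequencies are Beta draws around shared ancestral
frequencies, with a single divergence parameter (Fst-like) controlling how
far the populations drift apart.  All randomness flows from one master
seed; each stage derives its own child generator deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import GenotypeMatrix, HaplotypePanel, ReadPileup

# fixed per-stage salts so child seeds are reproducible and independent
_STAGE_SALT = {
    "panel": 101,
    "individuals": 202,
    "phenotypes": 303,
    "reads": 404,
    "downsample": 505,
    "impute": 606,
    "agreement": 707,
    "effects": 808,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child generator for a named pipeline stage."""
    if stage not in _STAGE_SALT:
        raise ConfigurationError("stage", f"unknown stage name {stage!r}")
    return np.random.default_rng([int(seed), _STAGE_SALT[stage]])


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator."""

    n_panel_haplotypes: int = 200
    n_variants: int = 2000
    chromosome_length: int = 10_000_000
    n_populations: int = 2
    divergence: float = 0.1          # Balding-Nichols Fst-like drift
    recomb_rate: float = 1e-7        # per-bp crossover probability
    n_target_animals: int = 50
    pedigree_depth: int = 2          # generations, founders included
    n_qtl: int = 50
    h2_true: float = 0.5
    fixed_effect_levels: Sequence[int] = (3,)
    coverage: float = 1.0            # mean sequencing depth (X)
    base_error: float = 0.01         # per-read base error
    seed: int = 0
    founders_from_panel: bool = False  # copy panel haplotype pairs verbatim into founders

    def validate(self) -> None:
        if self.n_panel_haplotypes < 2:
            raise ConfigurationError("n_panel_haplotypes", "need at least 2 haplotypes")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants", "need at least 1 variant")
        if self.chromosome_length < self.n_variants:
            raise ConfigurationError("chromosome_length", "shorter than the variant count")
        if self.n_populations < 1:
            raise ConfigurationError("n_populations", "need at least 1 population")
        if not 0.0 <= self.divergence < 1.0:
            raise ConfigurationError("divergence", "must be in [0, 1)")
        if self.recomb_rate < 0:
            raise ConfigurationError("recomb_rate", "must be non-negative")
        if self.n_target_animals < 1:
            raise ConfigurationError("n_target_animals", "need at least 1 animal")
        if self.pedigree_depth < 1:
            raise ConfigurationError("pedigree_depth", "must be >= 1")
        if self.pedigree_depth > 1 and self.n_target_animals < 2:
            raise ConfigurationError("n_target_animals", "need >= 2 per generation to draw parents")
        if not 0 <= self.n_qtl <= self.n_variants:
            raise ConfigurationError("n_qtl", "must be between 0 and n_variants")
        if not 0.0 < self.h2_true < 1.0:
            raise ConfigurationError("h2_true", "must be in the open interval (0, 1)")
        for k in self.fixed_effect_levels:
            if k < 1:
                raise ConfigurationError("fixed_effect_levels", "every factor needs >= 1 level")
        if self.coverage < 0:
            raise ConfigurationError("coverage", "must be non-negative")
        if not 0.0 <= self.base_error < 0.5:
            raise ConfigurationError("base_error", "must be in [0, 0.5)")


@dataclass
class TruthSet:
    """Ground truth for recovery tests.

    ``true_breeding_values`` is exactly the centered QTL genotypes times
    ``qtl_effects`` — reproducible from the stored pieces bit for bit.
    """

    true_genotypes: GenotypeMatrix
    true_haplotypes: np.ndarray          # (n_animals, 2, n_variants)
    true_breeding_values: np.ndarray     # (n_animals,)
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    qtl_center_freqs: np.ndarray         # frequencies used to center QTL genotypes
    breed_fraction: pd.DataFrame         # animals x populations genome proportions
    is_target: np.ndarray                # bool, final-generation animals

    @property
    def animal_ids(self) -> np.ndarray:
        return self.true_genotypes.animal_ids

    def target_ids(self) -> np.ndarray:
        return self.animal_ids[self.is_target]

    def recompute_breeding_values(self) -> np.ndarray:
        g = self.true_genotypes.genotypes[:, self.qtl_indices].astype(float)
        return (g - 2.0 * self.qtl_center_freqs) @ self.qtl_effects


@dataclass
class PhenotypeSet:
    """Simulated phenotypes plus the generating parameters."""

    table: pd.DataFrame                  # animal, y, one column per fixed factor
    true_beta: dict
    sigma_g2: float
    sigma_e2: float


def simulate_panel(cfg: SimConfig) -> HaplotypePanel:
    """Draw a multi-population phased reference panel.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each population's
    frequencies are Balding–Nichols Beta draws with parameter
    ``cfg.divergence``, and haplotypes are independent Bernoulli draws from
    their population's frequencies.
    """
    cfg.validate()
    rng = stage_rng(cfg.seed, "panel")
    v = cfg.n_variants
    ancestral = rng.uniform(0.05, 0.95, size=v)

    f = cfg.divergence
    pop_freqs = []
    for _ in range(cfg.n_populations):
        if f <= 0:
            pop_freqs.append(ancestral.copy())
        else:
            a = ancestral * (1.0 - f) / f
            b = (1.0 - ancestral) * (1.0 - f) / f
            pop_freqs.append(rng.beta(a, b))

    # split haplotypes across populations as evenly as possible
    sizes = np.full(cfg.n_populations, cfg.n_panel_haplotypes // cfg.n_populations)
    sizes[: cfg.n_panel_haplotypes % cfg.n_populations] += 1

    alleles = np.empty((cfg.n_panel_haplotypes, v), dtype=np.uint8)
    labels = np.empty(cfg.n_panel_haplotypes, dtype=object)
    row = 0
    for p, (n_h, freqs) in enumerate(zip(sizes, pop_freqs)):
        alleles[row : row + n_h] = rng.random((n_h, v)) < freqs
        labels[row : row + n_h] = f"pop{p + 1}"
        row += n_h

    positions = np.sort(rng.choice(cfg.chromosome_length, size=v, replace=False)) + 1
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=v)
    ref = bases[ref_i]
    alt = bases[(ref_i + rng.integers(1, 4, size=v)) % 4]
    variants = pd.DataFrame(
        {"chrom": "1", "pos": positions.astype(np.int64), "ref": ref, "alt": alt}
    )
    return HaplotypePanel(alleles, variants, labels)


def _crossover_segments(rng, positions, chrom_length, rate):
    """Segment index per variant after Poisson crossovers; returns (seg_idx, n_segments)."""
    n_cross = rng.poisson(rate * chrom_length)
    if n_cross == 0:
        return np.zeros(len(positions), dtype=np.int64), 1
    breakpoints = np.sort(rng.uniform(1.0, chrom_length, size=n_cross))
    return np.searchsorted(breakpoints, positions), n_cross + 1


def _mosaic_haplotype(rng, panel, cfg):
    """One founder haplotype: a crossover mosaic of random panel haplotypes."""
    seg, n_seg = _crossover_segments(
        rng, panel.positions, cfg.chromosome_length, cfg.recomb_rate
    )
    sources = rng.integers(0, panel.n_haplotypes, size=n_seg)
    src = sources[seg]
    return panel.alleles[src, np.arange(panel.n_variants)], src


def _gamete(rng, hap_pair, anc_pair, positions, cfg):
    """One transmitted gamete: Poisson crossovers between a parent's two haplotypes."""
    seg, _ = _crossover_segments(rng, positions, cfg.chromosome_length, cfg.recomb_rate)
    which = (rng.integers(0, 2) + seg) % 2
    idx = np.arange(len(positions))
    return hap_pair[which, idx], anc_pair[which, idx]


def simulate_individuals(panel: HaplotypePanel, cfg: SimConfig):
    """Build a pedigree of panel-mosaic individuals and the matching TruthSet.

    Founders' chromosomes are recombinant mosaics of panel haplotypes;
    later generations inherit recombinant gametes from their parents.  Each
    generation holds ``cfg.n_target_animals`` animals and the final
    generation is flagged as the sequencing targets.

    Returns ``(pedigree, truth)`` where the pedigree table has columns
    animal, sire, dam (``"0"`` = unknown) and generation, topologically
    ordered.
    """
    cfg.validate()
    if panel.n_variants < 1 or panel.n_haplotypes < 2:
        raise ConfigurationError("panel", "panel must be non-empty")
    rng = stage_rng(cfg.seed, "individuals")

    n_per_gen = cfg.n_target_animals
    n_total = n_per_gen * cfg.pedigree_depth
    v = panel.n_variants
    positions = panel.positions

    pops = pd.unique(panel.pop_labels)
    pop_index = {p: i for i, p in enumerate(pops)}
    hap_pop = np.array([pop_index[p] for p in panel.pop_labels])

    haps = np.zeros((n_total, 2, v), dtype=np.uint8)
    anc = np.zeros((n_total, 2, v), dtype=np.int16)   # source population per allele
    animal, sire, dam, generation, sex = [], [], [], [], []

    idx = 0
    gen_rows: list[np.ndarray] = []
    for g in range(cfg.pedigree_depth):
        rows = np.arange(idx, idx + n_per_gen)
        gen_rows.append(rows)
        for i in rows:
            aid = f"A{i + 1:06d}"
            animal.append(aid)
            generation.append(g)
            sex.append("M" if i % 2 == 0 else "F")
            if g == 0:
                sire.append("0")
                dam.append("0")
                if cfg.founders_from_panel:
                    h = rng.integers(0, panel.n_haplotypes // 2)
                    for j, hap_i in enumerate((2 * h, 2 * h + 1)):
                        haps[i, j] = panel.alleles[hap_i]
                        anc[i, j] = hap_pop[hap_i]
                else:
                    for j in range(2):
                        haps[i, j], src = _mosaic_haplotype(rng, panel, cfg)
                        anc[i, j] = hap_pop[src]
            else:
                prev = gen_rows[g - 1]
                males = prev[prev % 2 == 0]
                females = prev[prev % 2 == 1]
                s = int(rng.choice(males))
                d = int(rng.choice(females))
                sire.append(animal[s])
                dam.append(animal[d])
                haps[i, 0], anc[i, 0] = _gamete(rng, haps[s], anc[s], positions, cfg)
                haps[i, 1], anc[i, 1] = _gamete(rng, haps[d], anc[d], positions, cfg)
        idx += n_per_gen

    pedigree = pd.DataFrame(
        {"animal": animal, "sire": sire, "dam": dam, "generation": generation, "sex": sex}
    )

    genotypes = GenotypeMatrix(
        haps.sum(axis=1).astype(np.int8), np.array(animal, dtype=object), panel.variants
    )

    frac = np.zeros((n_total, len(pops)))
    for p in range(len(pops)):
        frac[:, p] = (anc == p).mean(axis=(1, 2))
    breed_fraction = pd.DataFrame(frac, index=animal, columns=list(pops))

    # QTL: panel variants with MAF > 0.01, additive N(0,1) effects rescaled
    # so the realized genetic variance equals h2_true
    panel_p = panel.alt_frequencies()
    panel_maf = np.minimum(panel_p, 1 - panel_p)
    eligible = np.flatnonzero(panel_maf > 0.01)
    n_qtl = min(cfg.n_qtl, eligible.size)
    qtl_idx = np.sort(rng.choice(eligible, size=n_qtl, replace=False)) if n_qtl else np.array([], dtype=int)
    effects = rng.normal(size=n_qtl)
    g_qtl = genotypes.genotypes[:, qtl_idx].astype(float)
    center_p = g_qtl.mean(axis=0) / 2.0 if n_qtl else np.array([])
    u = (g_qtl - 2.0 * center_p) @ effects if n_qtl else np.zeros(n_total)
    var_u = float(np.var(u))
    if var_u > 0:
        scale = np.sqrt(cfg.h2_true / var_u)
        effects = effects * scale
        u = (g_qtl - 2.0 * center_p) @ effects

    is_target = np.zeros(n_total, dtype=bool)
    is_target[gen_rows[-1]] = True

    truth = TruthSet(
        true_genotypes=genotypes,
        true_haplotypes=haps,
        true_breeding_values=u,
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        qtl_center_freqs=center_p,
        breed_fraction=breed_fraction,
        is_target=is_target,
    )
    return pedigree, truth


def simulate_phenotypes(truth: TruthSet, cfg: SimConfig) -> PhenotypeSet:
    """y = X beta + u_true + e with residual variance set from the realized
    genetic variance so that h2 equals ``cfg.h2_true``."""
    cfg.validate()
    rng = stage_rng(cfg.seed, "phenotypes")
    n = len(truth.animal_ids)
    u = truth.true_breeding_values

    table = pd.DataFrame({"animal": truth.animal_ids})
    fixed = np.zeros(n)
    true_beta = {}
    for j, n_levels in enumerate(cfg.fixed_effect_levels):
        name = f"cg{j + 1}"
        levels = rng.integers(0, n_levels, size=n)
        beta = np.concatenate([[0.0], rng.normal(size=n_levels - 1)])
        fixed += beta[levels]
        table[name] = levels
        true_beta[name] = beta

    var_u = float(np.var(u))
    sigma_e2 = var_u * (1.0 - cfg.h2_true) / cfg.h2_true if var_u > 0 else 1.0
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    table["y"] = fixed + u + e
    return PhenotypeSet(table=table, true_beta=true_beta, sigma_g2=var_u, sigma_e2=sigma_e2)


def simulate_reads(truth: TruthSet, cfg: SimConfig, animal_ids=None) -> ReadPileup:
    """Poisson depth, per-read base error; counts only (no read strings).

    By default reads are generated for the target (final-generation)
    animals, mirroring sequencing a terminal cohort.
    """
    cfg.validate()
    rng = stage_rng(cfg.seed, "reads")
    if animal_ids is None:
        animal_ids = truth.target_ids()
    animal_ids = np.asarray(animal_ids, dtype=object)
    rows = [np.flatnonzero(truth.animal_ids == a)[0] for a in animal_ids]
    g = truth.true_genotypes.genotypes[rows, :].astype(float)

    depth = rng.poisson(cfg.coverage, size=g.shape)
    eps = cfg.base_error
    p_alt = (g / 2.0) * (1.0 - eps) + (1.0 - g / 2.0) * eps
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    return ReadPileup(ref, alt, animal_ids, truth.true_genotypes.variants)
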