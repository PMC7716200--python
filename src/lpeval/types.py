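"""Core data containers shared across pipeline stages.

A :class:`HaplotypePanel` is the hidden-state space for imputation: a
haplotypes x variants binary matrix plus variant coordinates and a
population label per haplotype.  A :class:`GenotypeMatrix` holds 0/1/2
alt-allele counts (``-1`` for missing) for animals x variants, and a
:class:`ReadPileup` holds per-animal, per-site ref/alt read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LpevalError

MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


def _as_variant_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise LpevalError(f"variant table missing columns: {missing}")
    return df.reset_index(drop=True)


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes with coordinates and population labels."""

    alleles: np.ndarray          # (n_haplotypes, n_variants) values in {0, 1}
    variants: pd.DataFrame       # columns: chrom, pos (1-based), ref, alt
    pop_labels: np.ndarray       # (n_haplotypes,) population / breed strings

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.variants = _as_variant_table(self.variants)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        self.validate()

    def validate(self) -> None:
        if self.alleles.ndim != 2:
            raise LpevalError("panel alleles must be a 2-D matrix")
        if self.n_haplotypes < 2:
            raise LpevalError("panel needs at least 2 haplotypes")
        if self.alleles.shape[1] != len(self.variants):
            raise LpevalError("allele matrix and variant table disagree on variant count")
        if len(self.pop_labels) != self.n_haplotypes:
            raise LpevalError("pop_labels length != haplotype count")
        if not np.isin(self.alleles, (0, 1)).all():
            raise LpevalError("panel alleles must be biallelic 0/1")
        pos = self.variants["pos"].to_numpy()
        for chrom in self.variants["chrom"].unique():
            p = pos[self.variants["chrom"].to_numpy() == chrom]
            if not (np.diff(p) > 0).all():
                raise LpevalError(f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def alt_frequencies(self) -> np.ndarray:
        """Empirical alt-allele frequency per variant across the panel."""
        return self.alleles.mean(axis=0)


@dataclass
class GenotypeMatrix:
    """Animals x variants alt-allele counts; ``-1`` encodes a missing call."""

    genotypes: np.ndarray        # (n_animals, n_variants) int8 in {-1, 0, 1, 2}
    animal_ids: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.variants = _as_variant_table(self.variants)
        if self.genotypes.ndim != 2:
            raise LpevalError("genotypes must be a 2-D matrix")
        if self.genotypes.shape != (len(self.animal_ids), len(self.variants)):
            raise LpevalError("genotype matrix shape does not match ids / variant table")
        if not np.isin(self.genotypes, (MISSING, 0, 1, 2)).all():
            raise LpevalError("genotypes must be in {-1, 0, 1, 2}")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def observed_mask(self) -> np.ndarray:
        return self.genotypes != MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls (NaN if none)."""
        obs = self.observed_mask()
        n = obs.sum(axis=0).astype(float)
        g = np.where(obs, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, g / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def call_rate_by_animal(self) -> np.ndarray:
        return self.observed_mask().mean(axis=1)

    def call_rate_by_variant(self) -> np.ndarray:
        return self.observed_mask().mean(axis=0)

    def subset(self, animal_idx=None, variant_idx=None) -> "GenotypeMatrix":
        g, ids, var = self.genotypes, self.animal_ids, self.variants
        if animal_idx is not None:
            g, ids = g[animal_idx, :], ids[animal_idx]
        if variant_idx is not None:
            g = g[:, variant_idx]
            var = var.iloc[np.atleast_1d(variant_idx)].reset_index(drop=True)
        return GenotypeMatrix(g.copy(), ids.copy(), var)

    def row(self, animal_id) -> np.ndarray:
        idx = np.flatnonzero(self.animal_ids == animal_id)
        if idx.size != 1:
            raise LpevalError(f"animal {animal_id!r} not found exactly once")
        return self.genotypes[idx[0]]


@dataclass
class ReadPileup:
    """Per animal x site reference / alternate read counts."""

    ref_counts: np.ndarray       # (n_animals, n_variants) non-negative ints
    alt_counts: np.ndarray
    animal_ids: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self):
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int32)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int32)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.variants = _as_variant_table(self.variants)
        if self.ref_counts.shape != self.alt_counts.shape:
            raise LpevalError("ref/alt count shapes differ")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise LpevalError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    def mean_depth(self) -> float:
        return float(self.depth.mean())
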