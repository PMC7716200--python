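"""Plain-text table artifacts: pileup TSV, pedigree/phenotype/genotype CSVs.

All CSVs are headered, comma-delimited UTF-8.  The pileup TSV is long
format with columns animal, chrom, pos, ref_count, alt_count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..types import GenotypeMatrix, ReadPileup


def write_pileup_tsv(pileup: ReadPileup, path) -> None:
    n_a, n_v = pileup.ref_counts.shape
    df = pd.DataFrame(
        {
            "animal": np.repeat(pileup.animal_ids, n_v),
            "chrom": np.tile(pileup.variants["chrom"].to_numpy(), n_a),
            "pos": np.tile(pileup.variants["pos"].to_numpy(), n_a),
            "ref_count": pileup.ref_counts.ravel(),
            "alt_count": pileup.alt_counts.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path, variants: pd.DataFrame) -> ReadPileup:
    """Rebuild the pileup against a known variant table (ref/alt bases are
    not stored in the TSV)."""
    df = pd.read_csv(path, sep="\t")
    animals = pd.unique(df["animal"])
    n_v = len(variants)
    pos_index = {(c, p): i for i, (c, p) in enumerate(zip(variants["chrom"].astype(str), variants["pos"]))}
    ref = np.zeros((len(animals), n_v), dtype=np.int32)
    alt = np.zeros((len(animals), n_v), dtype=np.int32)
    a_index = {a: i for i, a in enumerate(animals)}
    rows = df["animal"].map(a_index).to_numpy()
    cols = [pos_index[(str(c), p)] for c, p in zip(df["chrom"], df["pos"])]
    ref[rows, cols] = df["ref_count"].to_numpy()
    alt[rows, cols] = df["alt_count"].to_numpy()
    return ReadPileup(ref, alt, np.array(animals, dtype=object), variants)


def write_genotype_csv(gm: GenotypeMatrix, path) -> None:
    """Wide CSV: one row per animal, one ``chrom:pos`` column per variant."""
    cols = gm.variants["chrom"].astype(str) + ":" + gm.variants["pos"].astype(str)
    df = pd.DataFrame(gm.genotypes, columns=cols)
    df.insert(0, "animal", gm.animal_ids)
    df.to_csv(path, index=False)


def read_genotype_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    animals = df["animal"].to_numpy(dtype=object)
    var_cols = [c for c in df.columns if c != "animal"]
    chrom = [c.split(":")[0] for c in var_cols]
    pos = [int(c.split(":")[1]) for c in var_cols]
    variants = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "N", "alt": "N"})
    return GenotypeMatrix(df[var_cols].to_numpy(dtype=np.int8), animals, variants)
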