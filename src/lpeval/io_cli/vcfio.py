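"""VCF reading and writing.

Reading uses cyvcf2; only bi-allelic SNP records are loaded, indels and
multi-allelic records are skipped with a count.  Genotype probabilities are
serialized with 4 decimals (numpy's round-half-to-even), the precision the
agreement module's certain-call rule keys off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ..errors import VcfParseError
from ..types import GenotypeMatrix, HaplotypePanel, MISSING

_GP_FMT = "{:.4f}"


@dataclass
class VcfData:
    """Everything read from a VCF: hard genotypes plus GP/DS when present."""

    genotypes: GenotypeMatrix
    gp: np.ndarray | None            # (n_samples, n_variants, 3)
    dosage: np.ndarray | None
    phased: np.ndarray | None        # (n_samples, n_variants, 2) haplotype alleles
    ft: np.ndarray | None            # per-call filter strings
    n_skipped: int


def _format_field(rec, key):
    try:
        return rec.format(key)
    except KeyError:  # field absent from the header
        return None


def read_vcf(path) -> VcfData:
    """Load bi-allelic SNPs; multi-allelic and indel records are skipped."""
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot open {path}: {exc}") from exc
    samples = np.array(vcf.samples, dtype=object)
    chroms, poss, refs, alts = [], [], [], []
    gts, gps, dss, haps, fts = [], [], [], [], []
    n_skipped = 0
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                n_skipped += 1
                continue
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(rec.ALT[0])
            g = np.array([row[:2] for row in rec.genotypes], dtype=np.int16)
            gt = np.where((g < 0).any(axis=1), MISSING, g.clip(0).sum(axis=1))
            gts.append(gt.astype(np.int8))
            haps.append(g)
            gp = _format_field(rec, "GP")
            gps.append(None if gp is None else np.asarray(gp, dtype=float))
            ds = _format_field(rec, "DS")
            dss.append(None if ds is None else np.asarray(ds, dtype=float).ravel())
            ft = _format_field(rec, "FT")
            fts.append(None if ft is None else np.asarray(ft, dtype=object).ravel())
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed record #{record_no}: {exc}") from exc
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    genotypes = GenotypeMatrix(
        np.array(gts, dtype=np.int8).T if gts else np.zeros((len(samples), 0), dtype=np.int8),
        samples,
        variants,
    )
    gp = None
    if gps and all(g is not None for g in gps):
        gp = np.stack(gps, axis=1)  # (n_samples, n_variants, 3)
    ds = None
    if dss and all(d is not None for d in dss):
        ds = np.stack(dss, axis=1)
    phased = np.stack(haps, axis=1) if haps else None
    ft = None
    if fts and all(f is not None for f in fts):
        ft = np.stack(fts, axis=1)
    return VcfData(
        genotypes=genotypes, gp=gp, dosage=ds, phased=phased, ft=ft, n_skipped=n_skipped
    )


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Phased diploid VCF pairing consecutive haplotypes; the population
    label is encoded in the sample name as ``<pop>__S<k>``."""
    if panel.n_haplotypes % 2:
        raise VcfParseError("panel haplotype count must be even for diploid VCF output")
    n_samples = panel.n_haplotypes // 2
    names = [f"{panel.pop_labels[2 * i]}__S{i + 1}" for i in range(n_samples)]
    contigs = {
        str(c): int(panel.variants.loc[panel.variants["chrom"] == c, "pos"].max())
        for c in panel.variants["chrom"].unique()
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        a = panel.alleles
        for v in range(panel.n_variants):
            row = panel.variants.iloc[v]
            cells = "\t".join(f"{a[2 * i, v]}|{a[2 * i + 1, v]}" for i in range(n_samples))
            fh.write(
                f"{row['chrom']}\t{row['pos']}\tv{v + 1}\t{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t{cells}\n"
            )


def read_panel_vcf(path) -> HaplotypePanel:
    """Inverse of :func:`write_panel_vcf`."""
    data = read_vcf(path)
    if data.phased is None:
        raise VcfParseError("panel VCF has no genotypes")
    if (data.phased < 0).any():
        raise VcfParseError("panel VCF contains missing genotypes")
    n_samples, n_var, _ = data.phased.shape
    alleles = data.phased.transpose(0, 2, 1).reshape(2 * n_samples, n_var).astype(np.uint8)
    labels = np.empty(2 * n_samples, dtype=object)
    for i, s in enumerate(data.genotypes.animal_ids):
        pop = str(s).split("__")[0] if "__" in str(s) else "NA"
        labels[2 * i] = labels[2 * i + 1] = pop
    return HaplotypePanel(alleles, data.genotypes.variants, labels)


def write_imputed_vcf(path, sample_id: str, variants: pd.DataFrame, posteriors) -> None:
    """Single-sample VCF with GT (hard call), GP (4 decimals, RR,RA,AA
    order), DS (dosage) and FT (PASS / LOWGP)."""
    gp = np.round(posteriors.gp, 4)
    ds = np.round(posteriors.dosage, 4)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    contigs = {
        str(c): int(variants.loc[variants["chrom"] == c, "pos"].max())
        for c in variants["chrom"].unique()
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities RR,RA,AA">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt-allele dosage">\n')
        fh.write('##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-call filter">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for v in range(len(variants)):
            row = variants.iloc[v]
            gp_s = ",".join(_GP_FMT.format(x) for x in gp[v])
            ft = "PASS" if posteriors.passed[v] else "LOWGP"
            fh.write(
                f"{row['chrom']}\t{row['pos']}\tv{v + 1}\t{row['ref']}\t{row['alt']}\t.\t.\t.\t"
                f"GT:GP:DS:FT\t{gt_strings[int(posteriors.hard_call[v])]}:{gp_s}:{_GP_FMT.format(ds[v])}:{ft}\n"
            )
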