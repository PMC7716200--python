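# lpeval

Evaluate genotype imputation from low-pass sequencing for genomic
prediction, end to end on synthetic data with known truth.

The pipeline mirrors a standard livestock workflow:

1. **simdata** — simulate a multi-population phased haplotype reference
   panel (Balding–Nichols drift between populations), pedigreed individuals
   whose chromosomes are recombinant mosaics of panel haplotypes, additive
   phenotypes with configurable heritability and fixed effects, and
   sequencing read counts at a configurable mean coverage.
2. **lowpass** — binomial downsampling of read counts and standard
   biallelic genotype likelihoods.
3. **impute** — a diploid Li–Stephens haplotype-copying HMM
   (forward–backward, factorized transitions, O(sites × K²)) producing
   per-site genotype probabilities (GP), GP_max, dosages and hard calls
   with a GP_max > 0.9 pass rule.
4. **agreement** — phred-scaled call confidence (CC = mean
   −10·log10(1−GP_max) over uncertain calls), correlation/concordance
   against comparator genotypes overall and within 0.01-MAF bins, per-1-Mb
   window pass rates, library identity verification and panel PCA.
5. **gblup** — pedigree (tabular A with inbreeding) and genomic (VanRaden
   G, stabilized G\* = 0.99G + 0.01I) BLUP via Henderson's mixed-model
   equations, EM/AI-REML variance components, and a quadratic
   weight-on-age projection for average daily gain.
6. **effects** — marker effects backsolved from genomic breeding values,
   molecular breeding values (MBV) for held-out animals from either true
   or imputed genotypes, permutation-based variant subset selection, and a
   leave-out validation grid.
7. **io_cli** — VCF (GT/GP/DS/FT) and CSV/TSV artifacts, strict YAML
   configuration, and the orchestrating CLI.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance properties (HMM oracle
against exhaustive path enumeration, Hardy–Weinberg no-data limit,
coverage monotonicity, CC behavior, MME/GLS oracle, REML recovery,
backsolve identities, MBV source invariance, null-subset control, A-matrix
exactness, end-to-end determinism).

## CLI

```sh
lpeval run --config cfg.yaml --seed 1 --out outdir      # full pipeline
lpeval simulate --out outdir                            # single stage
lpeval qc --out outdir --gpmax-threshold 0.9 --maf-bin 0.01
lpeval --version
```

Stages communicate only through files under `--out` (panel VCF, pedigree /
phenotype / genotype CSVs, pileup TSV, per-library imputed VCFs, agreement
CSVs, validation grid); `manifest.json` records seeds and counts, and
reruns with the same config are byte-identical.

A minimal config file:

```yaml
seed: 1
sim:
  n_panel_haplotypes: 200
  n_variants: 5000
  chromosome_length: 50000000
  n_target_animals: 50
  coverage: 1.0
impute:
  gpmax_threshold: 0.9
```

Unknown keys are rejected; omitted sections take their defaults.

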