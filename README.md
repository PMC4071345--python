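# bsamap

Asymmetric, single-bulk bulk-segregant analysis (BSA) of pooled RNA-seq
allele counts, for mapping a recessive resistance locus from a backcross
design — plus the companion analyses such a mapping study needs.

In this design an F1 is backcrossed to the resistant parent and the offspring
are selected at a diagnostic dose, so only homozygous-resistant survivors
enter the sequenced bulk. Because only one bulk extreme is available,
evidence of linkage comes from each marker's deviation toward fixation of
the resistant-parent allele, not from a two-bulk frequency difference.

## What it does

- **simdata** — seeded synthetic data: a genome map of SNP markers grouped
  into unigenes, BC1 meiosis (Haldane, no interference), survival selection
  at a recessive locus with configurable penetrance, pooled read counts
  (negative-binomial coverage, optional allele-specific-expression bias),
  zero-coverage deletion footprints, and directional homology hit tables.
- **genetics** — the monogenic recessive penetrance model: genotype
  distributions per cross, expected mortalities, the expected 75% resistant
  genome background of selected BC1 survivors, and exact binomial
  consistency tests of observed bulk mortalities.
- **variants** — variant-table parsing (long-format TSV or minimal VCF v4.2
  with per-sample AD), informative-SNP calling with bulk allele frequencies,
  deletion-footprint scanning over coverage tracks, and protein-level
  deletion arithmetic (in-frame / frameshift, amino acids removed).
- **bsa** — the per-unigene fixation index (fraction of informative SNPs
  with the resistant-parent allele above 0.95 frequency in the bulk),
  reciprocal-best-hit ortholog anchoring onto a reference genome,
  overlapping 3-ortholog rolling windows, and candidate-region calling
  above a 0.60 window-mean threshold, with a Manhattan-style plot.
- **txfilter** — RPKM, the four-criterion disjunctive unigene filter
  (CDS | homolog | >0.25 RPKM | >500 bp) and longest-per-cluster
  representative selection.
- **binding** — one-site homologous-competition radioligand binding:
  model, weighted nonlinear fit of (Kd, Rt, nonspecific slope) with
  asymptotic standard errors, the three-sample dissection of specific
  binding into reversible and irreversible components, and a seeded curve
  simulator for recovery experiments.

## CLI

```sh
bsamap simulate --n-offspring 2000 --coverage 200 --seed 7 --out sim/
bsamap scan --counts sim/counts.tsv --hits-fwd sim/hits_fwd.tsv \
    --hits-rev sim/hits_rev.tsv --genes sim/genes.tsv --out scan/
bsamap pipeline --seed 7 --out run/        # simulate + scan in one go
bsamap genetics                            # expected vs observed mortalities
bsamap filter --annotations annot.tsv --total-mapped 10000000 --out kept.tsv
bsamap binding fit --curve curve.csv --hot 1.0
bsamap binding dissect --total 1000 --nonspecific 200 --irreversible-sample 500
```

All parameters can also come from a YAML config (`--config`); explicit flags
override it. Every output table records its parameters and seed in `#`
header comments, so reruns with the same config are byte-identical.

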