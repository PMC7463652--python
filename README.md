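# matrisome-scan

Pan-cancer analysis of copy-number alterations (CNAs) and somatic mutations
in the **matrisome** — the ~1000 genes encoding extracellular-matrix (ECM)
and ECM-associated proteins — compared against the rest of the genome.

Matrisome genes are systematically long, heavily amplified or deleted in
solid tumors, and accumulate coding mutations whose burden can predict
patient survival. This package provides the statistical machinery of such a
screen as a tested, reusable Python library, for computational cancer
biologists working with TCGA-style inputs (GISTIC-thresholded gene-level CNA
calls, log2(norm+1) expression, MC3-style MAF mutation tables, clinical
tables with overall survival):

* **CNA frequencies** — per (tumor, gene) percentage of samples altered,
  binned into quartile classes (Q0 = 0%, then (0,25], (25,50], (50,75],
  (75,100]), with a two-sided chi-square comparison of the matrisome and
  non-matrisome bin distributions;
* **CNA → expression** — carriers vs non-carriers on the back-transformed
  linear scale; an effect is called when the fold ratio is ≥ 1.5 or ≤ 0.5;
* **mutation burden** — per-gene mutations per bp (count / gene length),
  compared by a two-sided Mann–Whitney U test and by randomization nulls
  drawing ~33%, size-matched and length-matched non-matrisome gene sets;
* **hotspots & spectra** — identical mutations recurring in ≥ 5 patients per
  tumor type in ≥ 2 tumor types; transition/transversion and
  mutation-type composition;
* **protein domains** — interval mapping of coding mutations onto
  amino-acid domain coordinates, per-tumor top-k domain ranking, and
  PolyPhen impact tabulation;
* **survival screen** — per tumor and gene (≥ 10 mutation carriers), a
  Kaplan–Meier log-rank test and a Cox proportional-hazards fit adjusted for
  age, gender and ethnicity; only genes significant (p < 0.05) and
  direction-concordant in *both* analyses are reported, with
  `os_difference = −β̂` (negative = carriers fare worse);
* **synthetic cohorts** — a generator producing TCGA-like cohorts with
  planted ground truth (length disparity, CNA enrichment, expression
  coupling, length-proportional Poisson mutations, planted hazards), so
  every stage can be validated against known effects.

## Worked example

`examples/` contains one short script per capability. For instance, the
length-normalized burden analysis on a default synthetic cohort
(`python examples/04_mutation_burden.py`) prints:

```
mutated genes: 96 matrisome, 699 non-matrisome
global Mann-Whitney: U=52274, p=7.05e-19
frac33          set_size= 230 fraction_significant=1.000 empirical_p=0.0010 direction=higher
size_matched    set_size=  96 fraction_significant=1.000 empirical_p=0.0010 direction=higher
length_matched  set_size=  96 fraction_significant=1.000 empirical_p=0.0010 direction=higher

hotspots (>=5 patients in >=2 tumor types): 0
```

The cohort plants a 2× matrisome mutation-rate multiplier; the per-bp burden
of matrisome genes beats every one of 1000 random non-matrisome gene sets in
all three schemes (`fraction_significant = 1`), including the sets composed
only of genes longer than the mean matrisome gene — i.e. the signal is not a
gene-length artifact. The survival example
(`python examples/06_survival_screen.py`) recovers a planted log-hazard
ratio of +1.0 as `os_difference = −1.23` with both p-values < 1e-14.

A thin CLI wraps the same functions:

```bash
matrisome-scan simulate --seed 1 --out cohort/
matrisome-scan run --config run.yaml      # matrisome-scan init-config writes one
```

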