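# Methods

This note documents the statistical procedures implemented in
`matrisome_scan`, the synthetic-cohort generator used to validate them, the
numerical conventions, and the design choices that were genuinely open.

## Analysis procedures

### CNA frequency binning and comparison

For each tumor type and gene, the CNA frequency is the percentage of that
tumor's samples with a qualifying GISTIC-thresholded call (direction `any`
means call ≠ 0; `gain`, `loss`, `high_amp` (+2), `low_amp` (+1), `homo_del`
(−2), `single_del` (−1) restrict it). Frequencies are binned as

    Q0: pct = 0      Q1: 0 < pct ≤ 25     Q2: 25 < pct ≤ 50
    Q3: 50 < pct ≤ 75                     Q4: 75 < pct ≤ 100

The half-open edges make the bins a partition of [0, 100]: integer
presentations of these ranges ("0–25%", "26–50%") leave real-valued
frequencies between 25 and 26 undefined, so the left-open convention is used
throughout and 25.0 falls in Q1. Matrisome vs non-matrisome bin
distributions are compared per tumor with Pearson's chi-square on the 2×5
gene-count table, no continuity correction, all-zero bins dropped; a table
degenerating to a single occupied bin yields χ² = 0, p = 1.

### CNA → expression effects

Expression matrices are log2(norm + 1); fold ratios are computed on the
back-transformed linear scale (2^v − 1) because "50% higher expression" is a
linear-scale statement. Carriers default to any nonzero call (gains and
losses pooled; a direction flag is exposed for sensitivity analysis). Gene ×
tumor pairs need ≥ 3 carriers and ≥ 3 non-carriers — a minimum that prevents
single-sample fold artifacts — and a positive non-carrier mean. Effect
boundaries (fold ≥ 1.5 → up, ≤ 0.5 → down) are inclusive, with a 1e-9
tolerance absorbing the log/exp round trip.

### Length-normalized mutation burden

Burden = mutation count / gene length (per bp), computed per tumor or
pan-cancer. By default only mutated genes enter the matrisome-vs-rest
comparisons; unmutated genes can be included with a flag (the conditioning
this introduces is discussed under *Null simulation design*). The global
test is a two-sided Mann–Whitney U without continuity correction — exact for
small tie-free groups, tie-corrected normal approximation otherwise, so
identical groups give p = 1.

The randomization suite redraws non-matrisome comparison sets per
repetition (default 1000):

1. `frac33` — ⌊0.33 × pool⌋ genes of the non-matrisome pool;
2. `size_matched` — sets the size of the mutated matrisome set;
3. `length_matched` — same size, drawn only from non-matrisome genes longer
   than the mean matrisome gene length (the set size for this scheme is not
   independently defined anywhere, so it reuses the size-matched count).

Each repetition records a two-sided MWU p-value and the set median. Two
summaries are reported: `fraction_significant` (share of repetitions with
p < α *and* the matrisome median above the set median — the analogue of
"1000/1000 tests significant") and `empirical_p`, the add-one-smoothed rank
of the matrisome median among set medians, (k+1)/(n+1). The two are not
interchangeable: the per-repetition MWU is a calibrated test, so
`fraction_significant` has controlled type-I behavior, whereas `empirical_p`
ranks a statistic that is *not* exchangeable with the resampled ones (the
matrisome group differs in size from a frac33 set, and subsample medians
from a finite pool are shrunk relative to a fresh group's median). Its null
distribution is therefore U-shaped rather than uniform and its tails exceed
α in every scheme geometry; it should be read as an effect-location summary,
not as a p-value. This is a property of the statistic's definition, not of
the implementation.

### Recurrence and hotspots

Mutation identity is the genomic substitution (gene, chrom, pos, ref, alt) —
the strictest defensible key; protein-change keying (gene, protein position,
alt) is available as an option. Patients are counted distinctly (a patient
with the same substitution recorded twice counts once). A hotspot is a key
with ≥ 5 distinct patients per tumor type in ≥ 2 tumor types; both
thresholds are sharp and configurable.

### Substitution spectra and composition

Only single-base A/C/G/T pairs are SNVs; A↔G and C↔T are transitions, the
remaining eight ordered pairs transversions. Composition tables report
variant-class counts and proportions per tumor × matrisome category, with
transitions + transversions = SNV count as a conservation invariant.

### Domain mapping and impact

A mutation maps to a domain iff it is in the same gene and
aa_start ≤ protein_pos ≤ aa_end (1-based inclusive amino-acid coordinates).
Mutations without protein positions (UTR, splice site, intron) are
unmappable by construction; overlapping intervals each receive the mutation.
Domain frequency is normalized by the tumor's total mapped mutations (the
natural per-tumor share); a raw count and a per-amino-acid rate over the
domain's annotated extent are also emitted, since no length normalization is
implied by a ranking of most-mutated domains. Ranking ties are broken
lexicographically. PolyPhen labels are consumed, never computed; the impact
test is a 2×2 chi-square of damaging (possibly + probably) vs not against
matrisome status.

### Survival screen

Per tumor, genes with ≥ 10 carriers are tested univariately (Kaplan–Meier
curves, two-group log-rank) and multivariately (Cox proportional hazards
with age, gender and ethnicity; categorical covariates one-hot encoded
against their most frequent level; Efron tie handling via lifelines;
patients missing a covariate are dropped from the Cox fit only). The
log-rank requires ≥ 1 event overall and both groups nonempty — a single
event-free group is complete separation, the strongest possible signal, not
a degenerate case. A gene is reported when both p-values are < 0.05 *and*
the univariate direction (sign of the restricted-mean survival difference,
carriers minus non-carriers) matches the sign of `os_difference = −β̂`.
Raw p-values are used for filtering, matching the screen's reporting rule; a
Benjamini–Hochberg column is emitted for reference only. The published "OS
Difference" column has no stated definition or units; −β̂ reproduces its sign
semantics (negative = worse survival for carriers) and its published
magnitudes should not be treated as numeric ground truth. The domain-level
screen reuses the same engine with carrier = any mutation mapping to the
domain name.

### Cohort summary and purity

A patient counts toward the matrisome-CNA column iff ≥ 1 matrisome gene has
a nonzero call, and toward the mutation column iff they carry ≥ 1 matrisome
mutation. Percentages round half-up to integers (773/1236 → 63%). Purity
confounding is assessed per tumor by a GLM of per-patient alteration counts
on the consensus purity estimate (CPE); the default family is Gaussian on
log1p(count) — counts are overdispersed and the log link on raw Poisson
counts is fragile at zero — with Poisson and negative-binomial selectable.
Tumors need ≥ 10 CPE measurements and non-constant CPE.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, with
every draw descending from one integer seed (identical config ⇒
byte-identical cohort). Defaults and their rationale:

| parameter | default | why |
|---|---|---|
| `n_genes`, `frac_matrisome` | 1000, 0.10 | desk-scale universe; ~100 matrisome genes keeps every group comparison well-populated |
| `category_weights` | 44/195/35/171/238/344 ÷ 1027 | the six matrisome categories in their human-matrisome proportions |
| `length_params` | core 6000 bp (σ=0.8), associated 4500 (0.8), rest 3000 (1.0), log-normal medians | matrisome genes are markedly longer than the genome background; this disparity is what burden normalization and the length-matched null exist to control |
| `cna_rate`, `matrisome_cna_multiplier` | 0.20, 2.0 | gene-level GISTIC-thresholded call frequencies in real pan-cancer data sit in the tens of percent (arm-level events cover many genes at once), populating bins up to Q2–Q3; at a few percent every gene would sit in Q1 and the binned comparison would carry no information |
| `cna_state_weights` | uniform over {−2,−1,1,2} | the empirical state mix is not published; uniform and configurable |
| `expr_coupled_genes`, `expr_effect`, `expr_noise_sd` | 20, 2.0, 0.5 (log2) | a 2-fold planted effect against ~0.5 log2 units of sample-level noise is a realistic, recoverable coupling |
| `mutation_rate_per_bp` | 3e-6 per sample | ~3 mutations/Mb, a typical solid-tumor somatic rate |
| `matrisome_mut_multiplier` | 2.0 | a clear planted enrichment for power checks |
| `variant_class_weights` | missense 0.50, silent 0.25, remainder spread over nonsense/splice/indel/UTR/intron classes | matches the observed dominance of missense (~50%) and silent (~25%) mutations |
| `transition_prob` | 0.70 | transitions are ~70% of SNVs in most tumor types |
| `polyphen_weights` | benign 0.40 / possibly 0.25 / probably 0.35 | drawn for missense only; non-missense records are "unknown" |
| `baseline_hazard` | 1/36 months⁻¹ | median OS ≈ 25 months, the scale of pan-cancer KM plots |
| `censor_rate` | 0.5 | half the observations censored, typical of OS endpoints |

Mechanics worth knowing: protein positions are uniform on
[1, length/3] (codon approximation; real CDS structure is not modelled —
adequate for interval-mapping tests); UTR/splice/intron mutations get no
protein position and are unmappable by construction; indel alleles are
anchored (ref "AT" / alt "A" style); survival times are exponential with
per-sample hazard = baseline × exp(Σ planted log-HR × carrier status), and a
censored observation is uniform on (0, T); gender/ethnicity are 2- and
4-level categoricals with fixed frequencies and no planted effect; tumor
types are assigned round-robin from the 14 solid-tumor codes.

What the generator does **not** emulate: trinucleotide mutational
signatures, CNA–mutation linkage at the same locus, subclonal structure,
batch effects, or covariate-dependent hazards. Passing tests therefore
demonstrate that the machinery recovers planted effects of the assumed form,
not that real tumor data satisfy those assumptions.

## Simulation designs used in validation

Problem sizes were chosen so the whole validation stack runs on a single
CPU in minutes.

* **Null (type-I) cohorts** use multipliers of 1 *and* equal, nearly
  constant gene lengths (median 3000 bp, σ = 0.05) with a mutation rate
  (3e-5/bp, 40 samples) high enough that essentially every gene is mutated.
  Two confounders are thereby removed by design: conditioning on "mutated"
  (which inflates the conditional burden of short genes) and the
  length-stratum mismatch between the matrisome group and length-matched
  sets. On these exchangeable cohorts the matrisome median is typical of
  random-set medians (empirical_p mean ≈ 0.5), the bin-comparison
  false-positive rate is ≈ 4%, and the survival screen's concordant-report
  rate is ≈ 2% — but the empirical_p tail mass still exceeds 5% for the
  reasons given above (U-shaped null), which the validation suite reports
  honestly rather than hiding. 200 null cohorts of 240 genes × 40 samples
  (60 randomization repetitions each) and 200 survival cohorts of 10 genes ×
  120 samples are used.
* **Power cohorts**: multiplier 3, 400 genes × 100 samples, 20 replicates —
  all three randomization schemes reject in every replicate.
* **Cox recovery**: one tumor of 500 samples, one planted gene with ~30%
  carriers; log-HRs of ±{0.5, 1, 1.5} are recovered with |mean bias| < 0.1
  over repeated cohorts.
* **Expression recovery**: the default config; planted 2-fold coupled genes
  are recovered by the 50% rule with sensitivity ≥ 0.9 and a false-flag rate
  ≤ 0.05 per record.

## Numerical conventions and edge cases

* Genomic coordinates 1-based inclusive (MAF convention); amino-acid
  coordinates 1-based inclusive.
* Readers reject, never repair: out-of-range CNA calls (with row/column
  named), duplicate identifiers, ref = alt, category/division mismatches.
  Unknown MAF variant classifications map to `other` with a logged count.
  Missing values are forbidden in CNA matrices and treated as absent in
  expression matrices.
* Matrices never encode tumor type; sample→tumor assignment lives only in
  the clinical table.
* Result tables are written with fixed column order and stated sort keys, so
  identical runs are byte-identical (the manifest's timestamps excepted).
* Cox fits that fail to converge, separate, or see no events are skipped and
  logged, never silently reported.

## Known limitations

* Gene length is the annotated transcript length supplied in the annotation;
  no transcript-selection policy is imposed.
* The symbol-level merge of a curated matrisome list with a genome-wide
  table is exact-match; unmatched symbols are dropped and logged, so a few
  genes can be lost exactly as symbol mismatches lose them in practice.
* `empirical_p` from the randomization suite is an effect summary, not a
  calibrated p-value (see above); use `fraction_significant` or the global
  MWU for inference.
* The survival screen tests marginal carrier effects gene by gene; it does
  not model gene–gene correlation or multiple testing beyond the reference
  FDR column.
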