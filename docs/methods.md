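# Methods

## Model and assumptions

The pipeline asks, per patient and per pathway, whether the patient carries
more qualifying variants in a pathway's genes than a large population
reference would predict. It assumes:

* variants are annotated upstream (gene symbol, exonic consequence class,
  reference-population allele frequency, CADD, a 0–10
  deleteriousness-predictor consensus) and left-aligned, so variant identity
  is exact `(chrom, pos, ref, alt)` equality;
* the reference provides, per pathway, a count of variants of the tier's
  consequence classes and a grand total; counts are treated as fixed, not as
  a sample (the reference is orders of magnitude larger than one exome);
* variants are exchangeable within a patient's qualifying set — the Fisher
  test conditions on the patient's total and the reference total and
  compares in-pathway proportions through the hypergeometric distribution.

### The 2×2 construction

Rows are {in pathway, outside pathway}; columns are {patient, reference}.
The test is one-sided (*greater*) because the scientific question is an
*increased* burden; a two-sided option exists
(`alternative="two-sided"`). The p-value is the upper hypergeometric tail
computed with `scipy.stats.hypergeom.sf`, which is a numerically stable
log-space evaluation; a test asserts agreement with exact rational
enumeration on every table with total ≤ 60 to 1e-10.

### Multiplicity

Benjamini–Hochberg is applied per patient across that patient's tested
pathways (only pathways with ≥1 patient variant are tested; all-zero tables
carry no information and would only dilute the FDR). The per-patient scope
matches an analysis performed individually per exome; a `global` scope
pooling all (patient, pathway) tests is available. Significance is
`q < alpha`, default `alpha = 0.05`.

### Exclusivity and trace-back

A pathway is exclusive to a group when significant in ≥1 of its patients and
0 of the other group's. No minimum-support threshold beyond 1 is imposed by
default because single-supporter pathways are meaningful at these cohort
sizes; `min_patients` raises the bar. Trace-back takes, per signature row,
the union over supporting patients of their tier-qualifying variants inside
the pathway's genes, distinct by site; totals are distinct variants and
distinct genes across the signature.

### Noncentered PCA

The patients × variants 0/1 (or 0/1/2 dosage) matrix is column-scaled by the
root mean square about zero, `sqrt(sum(x^2)/(n-1))`, *without*
mean-centering — for sparse presence data the origin (no variant) is the
natural reference point, and this matches the convention of R's
`prcomp(center = FALSE, scale. = TRUE)`. All-zero columns cannot be scaled
and are dropped with a warning. The scaled matrix is decomposed by SVD,
equivalent to eigen-decomposition of the uncentered cross-product (a test
checks this equivalence and exact reconstruction). Component signs are fixed
by making each component's largest-magnitude loading positive. All
`min(n_patients, n_variants)` components are kept and reported with
explained-variance fractions.

The outlier rule flags patients whose Euclidean distance from the score
centroid exceeds `median + 3 × 1.4826 × MAD` of the distances. It is a
declared convention: robust, scale-free, and conservative when the MAD is
zero (only strictly larger distances can flag).

## Variant tiers

The two tiers are configurable in `TierConfig`; the defaults are declared
assumptions, since report tables in this field print tier membership but not
cutoffs:

| parameter | default | meaning |
|---|---|---|
| `functional_consequences` | frameshift ins/del, stopgain, stoploss, splicing | protein-truncating-style classes |
| `impact_consequences` | nonsynonymous SNV | missense class |
| `min_cadd` | 10.0 | CADD phred floor for impact tier (≈ top 10% deleterious) |
| `min_impact_score` | 1 | ≥1 predictor votes deleterious (0–10 consensus scale) |
| `rare_af_max` | 0.01 | strict AF ceiling for "rare" |
| `treat_missing_af_as_rare` | true | absent from reference ⇒ novel ⇒ rare |

Tier consequence sets must be disjoint, so no variant is ever in both tiers.
The rarity filter is **not** applied to the reference side of the 2×2 —
rarity is defined relative to that same reference, and filtering the
reference by its own frequencies would be circular; `apply_rarity_filter`
switches this.

## Clinical grouping

Phases: *early* = during treatment; *acute* = (0, 6] months after the end of
radiotherapy; *late* = beyond 6 months. The severe group (STox) is defined
by ≥1 pulmonary event (cough, dyspnea, fibrosis, pneumonitis, thromboembolic
event) of grade ≥3 in any phase, using the maximum grade across phases;
grades 4–5 qualify by the same rule even where a cohort happens to contain
only grade-3 events. Summary tables report, per term, grade-band (1–2 vs ≥3;
fracture and thromboembolic events as single unbanded rows, mirroring the
usual clinical layout) and phase, the count and the integer percentage
`round(100·count/n_total)` rounded half away from zero.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets, not real
exomes. Defaults (chosen once, with an analytical power check that the
fold-5 signal is detectable at these sizes):

| parameter | default | emulates |
|---|---|---|
| `n_patients` / `n_stox` | 49 / 9 | the cohort split of a severe-toxicity study |
| `n_genes`, `n_pathways`, `genes_per_pathway` | 400, 20, 20 | a disjoint pathway partition at desk scale |
| `background_rate` | 0.05 /gene/patient/tier | ~20 qualifying variants per tier per exome |
| `signal_pathways`, `signal_group`, `signal_fold` | first 2 pathways, STox, 5 | the group-specific burden excess |
| `ref_variants_per_gene` | 4.0 /tier | a reference ~80× denser than one exome |
| `reference_n` | 1000 | nominal reference sample count (AF floor 1/2000) |
| `rare_af_max` | 0.01 | the rarity ceiling |

Per-gene, per-patient qualifying counts are Poisson; allele frequencies are
Beta(0.3, 8) (skewed rare), floored at one allele in `2·reference_n`.
Patients draw variants from fixed per-gene site pools (6 per gene per tier),
so variants recur across patients — needed by the shared-variant and PCA
stages. Qualifying variants are rare or novel by construction; synonymous
and common noise variants are added at `noise_rate`. Toxicity events give
every severe patient ≥1 grade-3 pulmonary event and cap everyone else's
pulmonary events at grade 2, with optional non-pulmonary grade-3 noise in
both groups; every patient emits ≥1 event so the grouping rule can recover
labels exactly. Each generation step derives an independent RNG substream
from `(seed, step)`, and identical configs give byte-identical output files.

What the simulator does **not** model — and what passing tests therefore do
not show about real data: linkage between variants, realistic human AF
spectra and site-frequency structure, annotation error, caller error
profiles, population stratification, or any genotype→toxicity causal link
(the signal fold is a simulation knob, not an estimate).

## Numerical and degenerate-input choices

* Fisher p is clipped to [0, 1]; `a = 0` returns exactly 1 (whole-tail).
* Odds ratio `(a·d)/(b·c)` reports `inf` on a zero denominator.
* BH uses `statsmodels`' `fdr_bh`, test-verified against a hand step-up
  oracle; empty p-vectors return empty.
* A patient with zero qualifying variants yields an empty result list; a
  reference with total 0 is an error.
* `rare_af_max` is a strict inequality, so `ref_af == rare_af_max` is common.
* Unknown consequence strings map to `other` with a logged warning; unknown
  toxicity terms are errors naming the term.
* GMT duplicate pathway ids are errors; duplicate genes within a set are
  deduplicated. Gene identifiers are opaque strings (symbols or numeric ids).
* Signature rows order by first supporting patient (cohort order), then
  pathway id; rendered patient ids use the `x<ID>` report style.

## Problem sizes

The default test suite runs the enrichment sweep exhaustively over all 2×2
tables with total ≤ 60, the null-calibration check over 50 seeded cohorts at
default sizes, and signal recovery over 20 seeds — about a minute end to end
on one core. These sizes give stable verdicts for the properties checked
(FDR calibration within 1.5× nominal, ≥80% signal recovery at fold 5);
larger sweeps change nothing qualitatively.

## Known limitations

* Gene–pathway membership is binary; no weighting by gene length or
  mutational target size, so long genes inflate pathway counts in both the
  patient and the reference columns (the comparison is still fair, but power
  varies across pathways).
* The Fisher test treats the reference counts as fixed truth; uncertainty in
  the reference is ignored.
* Per-patient FDR does not control the group-level error of the exclusivity
  step; exclusive pathways supported by a single patient are hypotheses, not
  confirmations.
* The impact-tier score cutoffs are conventions; sensitivity to them should
  be explored with `TierConfig` on real data.
* No covariate adjustment (age, dosimetry, smoking) anywhere in the
  pipeline.
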