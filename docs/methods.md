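# Methods

## Scope and data model

`varmedal` prioritizes germline single-nucleotide variants and small indels
from per-patient VCFs over a configurable cancer-gene panel.  The unit of
computation is the *variant record*: one (chrom, pos, ref, alt) change in one
patient, with per-allele read depths and a genotype.  Coordinates are
1-based, VCF-style (indels carry an anchor base), on a single assumed
assembly (hg19); there is no liftover, no BAM handling, and no variant
calling — the pipeline starts where a caller ends.  Multi-allelic sites are
split into one record per alternate allele, with depths taken per allele
from the AD field (an RO/AO pair is accepted as fallback); records without
usable depths are flagged and bypass depth filters rather than aborting a
cohort run.  Consequences (frameshift, nonsense, splice, missense, in-frame
indel, …) are consumed from the input annotation: rebuilding a
variant-effect predictor is explicitly out of scope, which keeps the
pipeline testable without transcript databases.  Genotypes on chrX are
treated as diploid heterozygous; the pipeline was designed around an
all-female cohort and makes no hemizygosity adjustment.

## Filters

Two read-support stages with deliberately literal boundary semantics:

| rule | comparator | boundary behaviour |
|---|---|---|
| total depth | exclude < 10 | exactly 10 passes |
| ABHet = r/(r+a), het only | exclude < 0.2 or > 0.8 | 0.2 and 0.8 pass |
| popmax AF | keep < 0.01 | exactly 0.01 excluded |
| alternate reads | exclude < 10 | exactly 10 passes |
| minor allelic fraction, het only | exclude < 0.25 | exactly 0.25 passes |
| post: total reads | exclude < 20 | exactly 20 passes |
| post: VAF | exclude < 0.25 | exactly 0.25 passes |

The minor allelic fraction is min(VAF, 1−VAF); like ABHet it is only
meaningful for heterozygotes and is skipped for homozygous-alt records.  A
variant absent from the population-frequency table is treated as never
observed (popmax 0).  The alt-read ≥ 10 rule and the later ≥ 20-total-read
rule are kept as separate sequential stages; the second is applied after
classification, to Gold/Silver candidates.  Filters are idempotent, and
raising any threshold can only shrink the passing set — both are enforced as
property tests.

## Medal rules

Classification is a pure function of an *evidence bundle* (consequence, gene
attributes, assertions, somatic match, population frequency, in-silico
prediction), so it is deterministic and insensitive to assertion ordering.
Precedence is Gold > Silver > Bronze > Unknown; the first tier whose
conditions hold wins, and the fired rules are recorded per call for
auditing.

* **Gold** = (truncating ∨ pathogenic assertion) ∧ disease-associated gene
  (LoF mechanism ∨ tumor suppressor) ∧ (star-rated pathogenic assertion with
  ≥ 2 stars ∨ pathogenic assertion from a specialty source).  The specialty
  source tags (IARC-TP53, ASU-TERT, ARUP-RET, BIC, PCFP, COSMIC) are
  configuration, not hard-coded clients.
* **Silver** = ¬Gold ∧ (in-frame indel ∨ truncation in a non-tumor-suppressor
  gene ∨ damaging-predicted missense) ∧ ≥ 1 assertion from any configured
  source.  Silver calls are subsequently *refined*: retained only when the
  identical change is catalogued Gold or Silver in the somatic catalogue.
* **Bronze** = predicted tolerated in silico with no pathogenic assertion.
  The tolerated/damaging flag is consumed as input evidence; the package
  performs no SIFT/PolyPhen-style scoring.

Only rules that are publicly documented are implemented; the original
annotation engine has additional unpublished branches, and no fidelity
beyond the documented behaviour is claimed.  An exhaustive acceptance test
compares the classifier against an independently enumerated truth table over
~2,600 evidence combinations.

### C-terminal caution and pLI triage

Truncations near the protein end often escape nonsense-mediated decay and
may be functionally attenuated.  A call is caution-flagged when the
truncated fraction aa_position / protein_size, rounded half-up to two
decimals, is ≥ 0.90, or when the annotation marks the variant in the final
coding exon (the final-exon route is what flags N-terminal FLG truncations).
Known limitation: the fraction rule is not a perfect reconstruction of the
upstream tool's unpublished criterion — it recovers all seven curated
caution genes but also flags two near-terminal truncations (BRCA2 at 90.1%,
POLQ at 92.1%) that the curated table does not mark.  No monotone threshold
can separate those from the flagged 89.9% NSD1 truncation, so the rule is
kept as specified; the flag is informational and affects no count.

pLI tiers follow the gnomAD guidance: ≥ 0.9 high LoF intolerance, 0.5–0.9
intermediate, < 0.5 low, absent when the gene has no pLI.

## Cohort curation

Curation codifies the manual review that followed classification:

* **Mapping artifacts** — a position is removed when ≥ `min_patients`
  (default 3) carriers show ≥ 2 distinct alternate alleles and every carrier
  has fewer alternate than reference reads.  The motivating real case had 6
  carriers; 3 is the smallest count at which "varied genotypes" is
  observable, and the threshold is configurable.
* **Common variants** — a position carried by ≥ 100% of the roster (the
  literal "present in all patients"; the fraction is configurable) is
  removed as a population variant that slipped past the frequency filter.

The cohort roster is passed explicitly so carrier fractions are computed
against the full cohort, not just patients surviving to the Gold set.
Summaries deduplicate variants by (chrom, pos, ref, alt): a variant recurring
in two patients counts once at variant level, twice at occurrence level,
which is how a 50-row table yields 49 unique variants.  Carrier frequency is
carriers / n_patients (not alleles / 2n); patient fractions round half-up to
whole percent and carrier frequencies to one decimal, matching the reporting
style of the source table.

## Statistics

Association and survival methods are standard and are delegated to standard
implementations behind the package's interfaces: the logistic model is a
binomial GLM fitted by iteratively reweighted least squares (statsmodels;
coefficient tolerance 1e-8, ≤ 100 iterations), with Wald 95% intervals on
exp(coef), dummy-coded subtype against the largest category, separation
reported as an error naming the covariate, and rank-deficient designs
rejected.  2×2 odds ratios use the cross-product with a Woolf CI and a
Haldane–Anscombe 0.5 correction for empty cells.  Kaplan–Meier curves and
the two-group log-rank test come from lifelines; the log-rank statistic is
cross-checked in tests against a hand-rolled hypergeometric O/E computation
and a 10,000-draw permutation null implemented independently in numpy.
Cox regression and covariate-adjusted survival curves are deliberately not
provided.

## Synthetic cohorts

The generator's defaults are the emulated study conditions: 115 patients, an
862-gene panel built as a 712 + 723 union with 573 shared symbols, 49
Gold-like planted variants (~28% of carriers receive two), 106 Silver-like,
2 artifact positions, 1 cohort-wide variant, plus low-quality and off-panel
background records.  Depths follow a negative-binomial model with mean 40
(the magnitude of the curated table's depth pairs) and heterozygous alternate
fractions a symmetric Beta centred at 0.5; planted true variants are
rejection-sampled to pass the read filters, so filter losses come only from
the background records.  Carrier status shifts covariates by the configured
odds multipliers — defaults 3.21 (family history), 3.74 (age < 30), 1.19 per
BMI unit, anchored to the magnitudes reported for the original cohort — and
scales the event hazard by 2.5 against a 0.0019/month baseline with uniform
48–73-month censoring.  Binary covariates are drawn conditionally on carrier
status so that the carrier/non-carrier odds ratio equals the target; BMI is
shifted by sd² · ln(OR) under equal variances, the Gaussian equivalent.

What the simulation does *not* model: linkage and haplotype structure,
read-level errors (no FASTQ/BAM), multi-transcript effects, correlated
covariates, and ambiguous evidence.  A clean pass of the recovery tests
therefore demonstrates that the pipeline implements its rules exactly — not
that the rules themselves would achieve perfect precision on real exomes,
where evidence is noisier and artifacts less stylized.

## Problem sizes and numerical choices

Tests run the generator at 30–115 patients and statistics at n = 600–2,000
with 10–25 replicates; the acceptance script uses a 115-patient pipeline
cohort, 10 × 2,000 patients for odds-ratio recovery, and n = 600 for the
log-rank check — sizes chosen so the whole suite completes in seconds while
keeping Monte-Carlo error well inside the asserted tolerances.  Percent
values use half-up rounding (not banker's) to match the source table's
reporting.  Ties in survival times have probability zero under the
continuous simulation; the log-rank implementation handles them via the
standard hypergeometric variance.  All randomness flows from
`numpy.random.default_rng(seed)`; no global state is touched, and equal
seeds give byte-identical cohort directories.

## Known limitations

* The cohort-scale funnel counts of the original study (≈1.19 M raw calls,
  350 K filtered, 6,496 in-panel) and its fitted odds ratios and survival
  percentages are not recomputable: the underlying patient-level data are
  not deposited.  These analyses are validated by parameter recovery on
  synthetic cohorts only.
* The medal rule set reproduces the documented behaviour of the upstream
  annotation engine, not its full unpublished decision tree.
* One canonical transcript per gene; splice-variant residue indices are used
  as annotated, with exon codes kept as opaque text.
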