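# Methods

This note documents the models, parameter choices and numerical decisions
behind `ctcdiv`, and what the simulation-based tests do and do not establish.

## Inputs and genotype filtering

The pipeline consumes post-calling artifacts: per-patient VCFs with `DP`
(total depth) and `AD` (ref,alt depths) FORMAT fields and `GENE`/`CSQCLASS`
INFO keys; tab-separated copy-number segment tables (`chrom start end event`,
1-based inclusive, events in {neutral, gain, loss, loh}); a per-patient
fraction of mutated microsatellites; a clinical table; a driver-gene list with
a coordinate table; and a capture BED (0-based half-open) whose total length
defines the exome footprint. Variant calling, annotation, segmentation and
MSI estimation themselves are out of scope.

Genotype filter semantics are deliberately literal: a call is kept iff
total ≥ 10 **and** alt ≥ 2 **and** VAF > 0.075. The boundaries matter —
total = 10 and alt = 2 pass, VAF = 0.075 fails. Multi-allelic records are
split into one call per alternate allele with per-allele AD, since VAF is a
per-allele quantity. Records without a `GENE` key are kept with an empty gene
(they still count toward MB and MATH); records without `CSQCLASS` are treated
as silent, which is conservative for driver-gene metrics; both are counted
and logged. The filter applies identically to SNVs and indels.

## Diversity metrics

- **MB** counts SNVs only (a substitution with single-base ref and alt),
  divided by the capture size in Mb.
- **PAG** divides aberrant segment length by the *patient's own* total
  segmented length, not a genome-build constant: segmentation output covers
  the callable genome, and a fixed denominator would silently deflate PAG
  when coverage is incomplete. No segments yields a missing value, never 0.
  PAG is invariant to splitting segments into contiguous sub-segments of the
  same event class.
- **MATH** is `100 · s · median(|VAF_i − median(VAF)|) / median(VAF)` over
  SNV+indel VAFs, after requiring ≥ 25 total and ≥ 5 alternate reads (the
  depth filter is configurable and switched off for panel scoring). The MAD
  scale factor `s` defaults to 1.4826 — the normal-consistency constant used
  by the original MATH definition, making scores comparable to published
  values — with `s = 1` available for the raw-MAD reading; both settings are
  oracle-tested. At least 3 qualifying variants are required (the smallest
  set with a non-degenerate MAD); fewer yields a missing value that
  propagates (the patient drops out of MATH-based survival models, with a
  logged reason). MATH is scale-free: rescaling all VAFs by c ∈ (0,1] leaves
  it unchanged.
- **CRC-mut** counts non-silent SNVs+indels in driver genes; gene symbols are
  matched case-insensitively after whitespace stripping.
- **CRC-CNA** counts aberrant-segment × driver-gene *pairs* (a gene overlapped
  by two aberrant segments contributes 2); the alternative — unique genes —
  is not what "number of CNAs overlapping driver genes" most naturally means,
  and pair counting preserves information about fragmented events. Overlap is
  any non-empty intersection of 1-based inclusive intervals.
- **Gene status** is computed at driver genes non-silently mutated in
  ≥ 4 patients (configurable). The inclusive "at least four" reading is used;
  the exclusive "more than four" reading is available via `min_patients=5`.
- **MSI** is strict: fraction > 0.30 ⇒ MSI, else MSS. All survival analyses
  run on the MSS subset only.

## Survival procedure

The two-group log-rank statistic is computed from risk-set tabulation
(observed minus expected group-1 events over distinct event times, with the
hypergeometric variance), implemented as a vectorised grid so the cutoff scan
evaluates every candidate split in one pass; it is cross-checked against an
independently coded tabulation oracle and against lifelines. Kaplan–Meier
estimation (Greenwood-based bands; median = earliest time the curve reaches
0.5) and Cox partial-likelihood maximisation use lifelines; ties are handled
by the Efron approximation, the default of the R `survival` package this
class of analysis is usually run in.

Optimal cutoffs: candidates are midpoints between consecutive distinct
observed values (midpoints avoid the ambiguity of placing the threshold on an
observed value); candidates leaving either group below 10% of the cohort are
excluded; the minimum-log-rank-p candidate wins, ties going to the candidate
nearest the marker median, then to the smaller cutoff. The scan is
permutation-invariant and matches an exhaustive brute-force oracle exactly.

The staged screen fits one univariate Cox model per metric form — continuous
metrics raw and as their optimal-cutoff Low/High split (High = 1), gene
status and sex as intrinsic binaries with unmutated/female as reference
(coded 0) — and selects forms with p ≤ 0.1, preferring the continuous form
when both pass. No multiple-testing correction is applied (the report
records the number of tests); patients missing a metric are dropped per
model. The selected set enters one multivariate Cox fit; KM curves and
median OS are reported per stratum of the selected (or display-dichotomized)
variables.

**The minimum-p caveat.** Minimum-p dichotomization is strongly
anti-conservative: in the calibration experiment a null marker's
"optimal-cutoff" split rejects at nominal 0.05 in ~43% of replicates, and at
the screening level ~100 candidate cutoffs push a null metric's binary form
past p ≤ 0.1 in half the replicates at n = 100. Two consequences are
documented by the test suite rather than hidden: (i) optimal-cutoff p-values
are not face-value p-values; (ii) because each selected binary is *fitted to
the same survival outcome*, spuriously selected binaries are correlated with
any true effect and dilute it in the multivariate model — at n = 100 with a
planted hazard of 3.5 on the high-diversity stratum, the MATH metric is
selected in ~96% of replicates but its multivariate term reaches p < 0.05 in
only ~60%, a property of the procedure itself, not of the estimators (each
of which is independently calibrated and oracle-verified).

## Gene panels

Frequency panels collect genes whose total variant-record count across
patients is strictly above a threshold (records, not patient–gene pairs —
matching a "sorted by mutation counts" construction; all consequence classes
count, with a non-silent-only switch available). Panel MATH reuses the MATH
routine with the depth filter off, since panels retain too few variants to
afford discarding any; < 3 panel variants yields a missing value. Concordance
with exome-wide MATH is an OLS fit (R², slope-test p). Panel↔survival
association reuses the survival module (continuous and optimal-cutoff binary
forms). A panel built from the most frequently mutated genes of the *same*
cohort whose survival it is then tested against inherits an ascertainment
bias; its prognostic value must be validated on an independent cohort.

## The synthetic cohort generator

The generator defines the conditions everything is tested under.

Per patient: the number of clones K is uniform on `n_clones_range` (default
1–4); the clonal cluster sits at VAF 0.40, subclones uniform on (0.08, 0.30);
each variant belongs to the clonal cluster with probability 0.5, else to a
random subclone. Total depth is negative binomial (mean 80, size 4 — a
standard overdispersed sequencing model), alternate counts binomial at the
clone VAF, so VAF noise shrinks with depth; in the single-clone,
infinite-depth limit MATH → 0. Variant counts per patient are uniform on
350–1250 with 65% indels, emulating the indel-heavy per-patient counts of
WGA-amplified CTC pools. Passenger genes follow a long-tailed landscape (two
tiers of frequently hit genes over an 18,000-gene background) so that
frequency panels at the > 15 / > 10 thresholds have realistic sizes (tens of
genes). Driver mutations are per-gene Bernoulli events (APC 0.70, TP53 0.65,
KRAS 0.45, … BCL9L 0.30) forced non-silent, placed within a deterministic
synthetic coordinate table so CNA overlap needs no external annotation.
Segments tile the 22 autosomes (GRCh38 lengths); the per-patient aberrant
rate is Beta-distributed around 0.12 to give realistic inter-patient PAG
spread. The MSI fraction exceeds 0.30 with probability 1/29. Age is
N(66.28, 16.33²) truncated to [18, 95]; sex is female with probability 0.345;
lines of treatment are Poisson(2).

Survival is exponential with
`log h = log h₀ + β_MATH·I(high) + Σ_g β_g·I(g mutated) + β_age·(age − 66.28)`,
where the *high-diversity stratum* is generative — K ≥ 3 clones — so
recovery experiments never depend on an estimated MATH cutoff. Defaults:
h₀ = log 2 / 30 per month, β_MATH = log 3.5, β_BCL9L = log 6.0,
β_age = log 1.07 per year. Censoring is an independent uniform draw on
(0, 100 months) applied with probability 0.3, plus administrative censoring
at 100 months — the simplest non-informative mechanism.

Randomness: one root seed, split into counter-based per-patient substreams
(`default_rng([seed, index])`), so cohorts are byte-reproducible and
individual patients reproducible under reordering.

**What the generator does not emulate.** Real CTC pools pass through
whole-genome amplification, which distorts the joint VAF distribution
(allelic dropout, locus-specific amplification bias); the clone-mixture model
here is an assumption, not a fit to pooled-cell data. Mutational signatures,
CTC capture efficiency, tumor purity/ploidy and within-gene variant hotspots
are not modelled. With all planted hazards active the cohort's overall
median OS is shorter than typical mCRC cohorts (the age effect compounds the
stratum and gene effects); rates and calibration properties, not absolute
survival times, are the quantities the tests rely on. Passing tests
establish that the *pipeline* is correct and calibrated under these
conditions, not that the biological conclusions transfer to any particular
real cohort.

## Problem sizes

The simulation experiments use sizes chosen to pin down each property while
keeping the suite fast: 1,000 random patients for metric-oracle equivalence;
1,000 replicates for log-rank calibration; 500 for cutoff-inflation and
planted-null cohort calibration; 200 replicates of n = 300 for Cox recovery
and CI coverage; 100 replicate cohorts of n = 100 patients (150–400 variants
each) for end-to-end power and screen specificity. The power experiments use
a lighter variant count than the cohort default since MATH stabilises well
below 150 variants and the power is driven by the clone structure, not the
variant count.
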