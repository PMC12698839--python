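# ctcdiv — genomic diversity of CTC pools and overall survival in mCRC

`ctcdiv` implements, as a tested and reusable pipeline, an analysis linking the
genomic diversity of circulating-tumor-cell (CTC) pools to overall survival (OS)
in metastatic colorectal cancer (mCRC). CTC pools sampled from a blood draw
carry a mixture of tumor subclones; the dispersion of somatic variant allele
frequencies (VAFs) in the pool summarises how heterogeneous that mixture is,
and the hypothesis under study is that more heterogeneous pools predict worse
survival.

The pipeline starts from the outputs of somatic variant calling (per-patient
VCFs, copy-number segment tables, microsatellite-instability fractions, a
clinical table) and runs:

1. **Genotype filtering** — calls with < 10 total reads, < 2 alternate reads,
   or VAF ≤ 0.075 are treated as missing and dropped.
2. **Diversity metrics** per patient:
   - mutational burden `MB = #SNVs / Mb of captured exome`;
   - proportion of aberrant genome `PAG` (fraction of the segmented autosomal
     genome under gain/loss/LOH);
   - mutant-allele tumor heterogeneity
     `MATH = 100 · MAD(VAF) / median(VAF)` over SNV+indel VAFs at sites with
     ≥ 25 total and ≥ 5 alternate reads;
   - counts of non-silent driver-gene mutations (CRC-mut) and of
     aberrant-segment × driver-gene overlaps (CRC-CNA);
   - mutated/unmutated status at recurrently hit driver genes.
3. **MSI classification** — > 30% mutated microsatellites ⇒ MSI; all survival
   analyses are restricted to microsatellite-stable (MSS) patients.
4. **Survival modelling** — each continuous metric is dichotomized at the
   *optimal cutoff* (the split minimising the log-rank p-value); metrics with
   univariate Cox p ≤ 0.1 (continuous preferred over binary when both pass)
   enter a multivariate Cox proportional-hazards model; Kaplan–Meier curves
   and median OS are reported per stratum.
5. **Gene panels** — frequency-based panels (genes with > 15 / > 10 mutations
   across the cohort) re-score MATH without read-count filters as a low-cost
   surrogate for exome-wide MATH.

Because the analysis is defined on post-calling inputs, the package ships a
first-class synthetic cohort generator (`ctcdiv.simulate`) that emulates the
statistical structure these analyses assume — clonal + subclonal VAF clusters,
negative-binomial read depths, segment-level CNA events, an MSI fraction, and
exponential survival under a proportional-hazards model with planted effects —
so every stage can be exercised and calibrated end to end.

## Worked example

The numbered scripts under `analysis/` run the full study on the reference
synthetic cohort (29 patients, seed 1):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_diversity_metrics.py
python analysis/03_survival_analysis.py
python analysis/04_gene_panels.py
python analysis/05_calibration.py
```

`02_diversity_metrics.py` prints, for this cohort:

```
metrics for 29 patients -> results/metrics.tsv
  MSS: 29  (MSI excluded from survival analyses)
  MB   [SNVs/Mb]: 0.97-3.79
  PAG           : 0.000-0.447
  MATH          : 12.1-68.2
  recurrent driver genes (>=4 patients): 9
```

i.e. per-patient mutational burden spans ~1–4 SNVs/Mb, up to ~45% of the
segmented genome is copy-number aberrant, and MATH spans 12–68 (higher = more
dispersed VAFs = more subclonal structure). `03_survival_analysis.py` then
screens every metric (continuous and optimal-cutoff binary forms), fits the
multivariate model on the selected set and reports hazard ratios with 95%
confidence intervals — e.g. for this cohort age is selected continuously
(HR 1.06 per year, p = 0.005) — and median OS per stratum.
`05_calibration.py` quantifies the statistical behaviour of the machinery:

```
log-rank null rejection at alpha=0.05: 0.050 (nominal 0.05, 500 reps)
optimal-cutoff null rejection at nominal 0.05: 0.427
Cox recovery of planted HR 3.6 (n=300/rep): mean HR 3.58
planted HR 3.5, n=100: MATH selected 30/30; multivariate p<0.05 21/30
```

The 0.427 line is worth pausing on: choosing the cutoff that minimises the
log-rank p-value inflates the null rejection rate roughly eight-fold, so
"optimal cutoff" p-values must never be read at face value (see
`docs/methods.md`).

As a command-line tool the same stages are available as
`ctcdiv simulate|validate-inputs|metrics|survival|panels|run-all`.

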