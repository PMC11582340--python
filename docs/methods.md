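# Methods

## Scope and data model

The pipeline starts at classified cell coordinates: upstream image
analysis (staining, segmentation, supervised cell classification) is
out of scope and assumed done. A cohort consists of

- **cell tables** — one row per detected cell with case id, core id,
  region (tumor center / invasive margin), marker (CD3 / CD8),
  coordinates in µm and a three-valued class (tumor / immune / other).
  Coordinates are continuous, origin at the core-disc center; cores are
  discs of radius 500 µm by default (1-mm TMA punches). Cells slightly
  outside the disc are kept — detection exports are noisy at the punch
  boundary — and only flagged beyond a configurable tolerance
  (default 10 µm).
- **clinical tables** — one row per case: treatment (nRT = no
  preoperative radiotherapy, SRT = short-course radiotherapy,
  CRT = chemoradiotherapy), TNM stage, age-adjusted Charlson
  comorbidity index (CCI) class, sex, resection radicality (R0/R1/R2),
  lymphovascular invasion, tumor regression grade (TRG, fibrosis-based;
  defined only after preoperative therapy), a postoperative-death
  flag, DSS/OS follow-up clocks from surgery, and the CLR follicle
  count with the measured invasive-front length.

Missing categorical values are carried as an explicit `missing` level,
never dropped at read time; each analysis decides complete-case
handling itself. Every filter logs counts removed and retained.

## Spatial statistics

Immune-cell **density** is count over disc area (cells/mm²). The
**G-cross** value at radius r is the empirical fraction of tumor cells
whose nearest immune cell lies within r (ties at exactly r count as
within). We deliberately report the raw empirical fraction without edge
correction: the score is defined operationally as the likelihood that a
tumor cell in the sample has an immune cell within 20 µm, not as an
unbiased estimator of a stationary process property. A border
correction (denominator restricted to tumor cells at least r from the
disc boundary) is available for sensitivity analysis. The
nearest-neighbour search uses vectorized all-pairs distances for small
cores and a k-d tree beyond ~250k candidate pairs; either path must
agree exactly with a brute-force O(n²) oracle, which the tests enforce
on random cores.

Replicate cores of the same case × region × marker pool as total
immune count over total area (density) and as the tumor-cell-count-
weighted mean of per-core fractions (G-cross) — algebraically the
empirical fraction over the union of tumor cells with within-core
neighbour search, so the pooled value remains a fraction. A region with
no tumor cells has an undefined (not zero) G-cross, propagated as a
missing component.

## Scoring

Raw values convert to cohort percentiles *100·midrank/n* (ties get the
mean of their ranks). This convention makes the cohort maximum exactly
100 and distinct values a permutation of {100/n, …, 100}, so the top
bin (>70–100] is reachable; the reference population is the loaded
cohort by default and can be switched to within-treatment. The mean of
the four component percentiles is binned low (0–25] / intermediate
(>25–70] / high (>70–100]; boundaries are inclusive on the low side
(a mean of exactly 25 is low, 70 is intermediate). A score is computed
when at least 3 of 4 components exist (configurable); otherwise it is
missing, and missingness propagates to the immune grade rather than
being imputed.

CLR density is follicle count / front length (follicles/mm); a case is
CLR-high when density **strictly** exceeds the cutoff. The shipped
default cutoff is 0.25 follicles/mm; `roc_cutoff` re-derives it on new
cohorts by maximizing Youden's J over midpoints between adjacent
distinct densities, treating low density as predicting disease-specific
death, ties broken toward the smaller cutoff, with degenerate and
low-separation results flagged. The immune grade is the PS category
plus one if CLR-high (0–3), dichotomized low (0–1) vs high (2–3).

## Cohort statistics

Pearson chi-square without continuity correction (this choice
reproduces the development cohort's printed cross-tab p-values, e.g.
0.404 for sex × treatment and 0.123 for mucinous × treatment, which the
acceptance script recomputes); Spearman correlation on midranks.
Survival analyses keep only R0 resections and exclude immediate
postoperative deaths. Kaplan–Meier survival at a horizon is the
right-continuous step value at the horizon (5 years by default);
group differences use the two-sided log-rank test. The multivariable
Cox model uses Efron tie handling (the common modern default; the
original analyses were run in SPSS whose default is Breslow — with
yearly-scale times and moderate ties the difference is small, and the
choice is fixed here for reproducibility) with Wald 95% intervals and
explicit reference levels: CCI 0–2, female, stage I, immune grade
high, no LVI, CRT, TRG 1; untreated cases enter TRG as grade 1. The
report builders emit a cross-tab table by treatment, a per-stratum
5-year DSS/OS table for the nRT and pooled pRT (= SRT ∪ CRT) groups —
a reporting-level pooling only — and the Cox tables. On very small
cohorts the full covariate set can separate; the report builder then
retries with a mild ridge penalty (0.1) and flags the fit as
penalized. Direct `cox_model` calls never penalize silently.

## Synthetic cohorts

The generator emulates the statistical structure the analysis relies
on, with defaults chosen to echo the development cohort's marginals:

- **Tumor cells**: parent–offspring (Thomas-type) cluster process —
  Poisson parents (8/mm²) uniform on the disc, Poisson(40) offspring
  per parent with Gaussian dispersion σ = 25 µm, clipped to the disc.
  Tumor cells are spatially aggregated; the specific cluster family is
  a modelling convenience, and nothing downstream depends on it beyond
  aggregation.
- **Immune cells**: expected counts per core by marker and treatment
  (CD3 300/140/200 and CD8 150/55/145 for nRT/SRT/CRT), echoing the
  observed ordering of lymphocyte depletion after SRT. A
  Binomial(n, ρ) share is "attracted": placed as Gaussian offsets
  (σ = 10 µm) from uniformly chosen tumor cells; the rest is uniform.
  The per-case attraction fraction ρ ~ U(0.05, 0.9) is the single
  co-localization knob and maps monotonically to G-cross; with ρ = 0
  the immune field is homogeneous Poisson and mean G(20 µm) matches
  the closed form 1 − exp(−λπr²) up to a small (<0.01) edge deficit
  from tumor cells near the disc boundary.
- **CLR**: a two-component density mixture straddling 0.25
  follicles/mm (low: 0.25·Beta(2, 2.5); high: 0.25 + 1.25·Beta(1.5, 3)),
  with treatment-dependent high fractions 0.66/0.56/0.22, front length
  U(10, 40) mm. The integer follicle count is kept on the drawn
  component's side of the threshold, so the component defines the
  case's true CLR class exactly.
- **Covariates**: treatment mix 154:95:97/346 and per-treatment stage,
  CCI, sex, LVI, TRG and radicality probabilities mirroring the
  development cohort's distributions.
- **Outcomes**: exponential baseline (rate 0.033/yr, ≈85% 5-year DSS
  at zero predictor) scaled by exp(linear predictor); the default
  coefficients are the development cohort's multivariable DSS hazard
  ratios, in particular immune-grade-low HR 3.17. The "true" immune
  grade combines the ρ-quantile tercile (boundaries 25/70) with the
  drawn CLR class. Disease death competes with a CCI-graded
  other-cause death (rates 0.010/0.022/0.040 per year); censoring is
  the minimum of a uniform 3–16-year administrative horizon
  (reproducing a recruitment window with median follow-up around
  7 years) and a rare random censoring time. DSS treats other-cause
  death as censoring; OS counts any death.

What the generator does **not** emulate: cell-classification error,
staining artifacts, within-tumor heterogeneity between replicate
cores beyond Poisson noise, non-proportional hazards, or calendar-time
treatment drift. Passing tests therefore demonstrate correctness of
the computational pipeline under its own model assumptions, not
clinical validity on real data. The recovered immune-grade hazard
ratio from pipeline-observed grades is attenuated relative to the true
3.17 (≈2.6 at n = 346) because the observed grade is a noisy
measurement of the generated one; recovery checks therefore fit on the
ground-truth grade, where the multivariable model recovers the
coefficient with ~94% CI coverage across replicates.

## Numerical and design choices

- Distances compare in the squared domain (d² ≤ r²), avoiding square
  roots; the all-pairs oracle used in tests does the same, making the
  equivalence exact in the count domain.
- Percentile definition, boundary inclusivity, strict CLR
  "exceeds", and the midpoint ROC candidate grid are frozen as
  documented above; each has a dedicated boundary test.
- Problem sizes: the packaged test cohort is 40 cases with reduced
  per-core counts (~150–300 cells/core), generated programmatically
  from a frozen config and seed; the analysis drivers use the full
  346-case configuration; parameter-recovery checks use 2000
  covariate-only cases and 50 replicates of 500. These sizes were
  chosen so every statistical check sits at several standard errors
  from its tolerance.
- All randomness derives from a single seed via spawned
  per-case substreams, so cohorts are reproducible case-by-case and
  every pipeline rerun is byte-identical.

## Known limitations

- The G-cross border correction is provided but untested against an
  external spatial-statistics reference beyond its definition.
- The Cox implementation is lifelines' (Efron ties); no
  proportional-hazards diagnostics, competing-risks models or
  multiple-testing corrections are included, matching the scope of the
  original analyses.
- `read_clinical_table` expects canonical level labels (with a small
  alias map); heterogeneous real-world exports may need pre-mapping
  through the format configs.
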