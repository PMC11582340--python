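# immugrade

Immune-contexture scoring and survival analysis for tissue-microarray
(TMA) cell maps, aimed at researchers quantifying the tumor immune
microenvironment of rectal cancer (and colorectal cancer generally)
from classified cell coordinates rather than raw images.

Rectal tumors are commonly treated with preoperative short-course
radiotherapy (SRT) or long-course chemoradiotherapy (CRT) before
surgery, and these treatments reshape the antitumoral immune response.
This package implements the scoring system used to study that question:
starting from per-core cell coordinates (tumor / immune / other cells,
CD3 and CD8 immunohistochemistry, tumor center and invasive margin),
it computes

- **T-cell density score (DS)** — Immunoscore-style: the four raw
  immune-cell densities (CD3 center, CD3 margin, CD8 center, CD8
  margin, cells/mm²) are converted to cohort percentiles
  *p = 100·midrank/n*, averaged, and binned low (0–25], intermediate
  (>25–70], high (>70–100];
- **T-cell proximity score (PS)** — the same construction applied to
  the empirical cross-type nearest-neighbour statistic
  *G*(r) = fraction of tumor cells with at least one immune cell
  within radius r, evaluated at r = 20 µm — a direct measure of
  tumor-cell/T-cell co-localization;
- **CLR density** — Crohn's-like lymphoid reaction follicles per mm of
  invasive front, dichotomized at 0.25 follicles/mm (a cutoff
  originally derived from a ROC curve against disease-specific
  mortality; a Youden-optimal `roc_cutoff` is provided to re-derive it
  on new cohorts);
- **Immune grade (IG)** — PS category (0–2) raised by one when CLR
  density strictly exceeds the cutoff, giving a 0–3 scale dichotomized
  as low (0–1) vs high (2–3);

plus the cohort statistics used to evaluate them: Pearson chi-square
cross-tabs, Spearman correlation, Kaplan–Meier / log-rank survival,
and multivariable Cox proportional-hazards models (Efron ties, explicit
reference levels, survival restricted to R0 resections with immediate
postoperative deaths excluded).

Because patient-level data of this kind cannot be shared, the package
includes a synthetic-cohort generator (`immugrade.synthetic`) producing
clustered tumor-cell point patterns, immune cells with a tunable tumor
attraction fraction, bimodal CLR densities, realistic covariate mixes
and proportional-hazards outcomes, so the entire pipeline is testable
end to end.

## Worked example

```python
from immugrade.pipeline import RunConfig, run_pipeline
from immugrade.synthetic import fixture_config

cfg = RunConfig(synthetic=fixture_config(), seed=7)   # 40-case synthetic cohort
manifest = run_pipeline(cfg, "out")
print(manifest.stage_counts)
```

prints

```
{'simulate': {'cases': 40}, 'read': {'cores': 320, 'cases': 40},
 'validate': {'cases': 40, 'cores': 320, 'cells': {'tumor': 24769, 'immune': 20788, 'other': 32029}},
 'spatial': {'region_measures': 160},
 'score': {'cases': 40, 'missing_ps': 0},
 'stats': {'input': 40, 'removed_not_r0': 5, 'removed_postop_death': 1, 'retained': 34}}
```

i.e. 40 cases were simulated (8 cores each: 2 cores × 2 regions × 2
markers), validated, reduced to 160 case×region×marker measures, scored
(no case lost its proximity score), and filtered to 34 R0 cases without
postoperative death for the survival reports. `out/` then contains
`scores.tsv` (one row per case with raw values, percentiles, DS, PS,
CLR, IG), the three report tables, and `manifest.json` with checksums —
rerunning the same config reproduces identical checksums.

The numbered drivers under `analysis/` run the same steps at full
cohort scale (346 cases): `01_simulate_cohort.py` writes the raw tables
to `scratch/`, `02_spatial_scoring.py` scores the cohort,
`03_cohort_tables.py` builds the cross-tab report, and
`04_survival_models.py` fits the survival models. On the default
configuration the multivariable Cox fit recovers an immune-grade-low
hazard ratio of 2.63 (95% CI 1.80–3.85) for disease-specific survival —
attenuated from the generator's true 3.17 because the pipeline observes
the immune grade through noisy spatial measurements.

A thin CLI mirrors the library: `immugrade simulate|validate|score|stats|run`.

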