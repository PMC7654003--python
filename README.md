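# stageyield

Weighted-growth-stage potato yield estimation from multi-period LAI and
canopy hyperspectral data.

## The problem

Plot-level canopy spectra and leaf area index (LAI) measured at several
growth stages carry strong yield signal, but two obstacles block their joint
use. First, illumination, aerosol and soil-background conditions drift
between measurement dates, so multi-period data are not directly comparable.
Second, the stages contribute unequally to final tuber yield, so pooling
them naively (e.g. in an unweighted multi-period regression) mixes
informative and uninformative dates.

`stageyield` implements the two remedies together:

* **Relative variables.** A reference plot is chosen and its same-stage
  value is subtracted from every plot's LAI, vegetation index (VI) and
  yield (`rLAI = LAI − LAI_ref`, `rVI = VI − VI_ref`,
  `relative yield = yield − yield_ref`). Any confound shared by all plots at
  a stage cancels exactly, while every between-plot difference — and hence
  every correlation, slope and R² within a stage — is preserved.
* **Weighted growth stages.** The season is partitioned with a Slogistic
  dry-matter curve `y = a/(1 + b·e^(−kx))`: the extrema of its second
  derivative at `(ln b ∓ ln(2+√3))/k` delimit the rapid-growth phase that
  anchors the tuber expansion stage (TES), flanked by seeding (SS), tuber
  formation (TFS), starch accumulation (SAS) and harvest (HS) windows.
  Stage weights `w = (w_SS, …, w_HS)` come from three routes: a three-scale
  improved analytic hierarchy process (IAHP, subjective), the entropy
  weight method (EW, objective), and their convex combination
  `W = α·W_IAHP + (1−α)·W_EW` (OCW, default α = 0.7). The yield model is
  then simple linear regression of relative yield on the stage-weighted
  composite `x_p = Σ_t w_t · value(p, t)`, validated by leave-one-out
  cross-validation, with absolute yield recovered as
  `ŷ = slope·x + intercept + yield_ref`.

Six VIs are supported (NDVI, CI_red edge, CI_green, EVI2, NDRE, MTCI),
computed from windowed band means at 550/670/720/800 nm.

Because real campaigns of this kind are rarely public, the package ships a
first-class synthetic trial generator (27 plots in a 3 water × 3 nitrogen ×
3 replicate design, 17-date dry-weight series, per-stage canopy spectra from
tabulated vegetation/soil endmembers, yield coupled predominantly to
mid-season canopy state) so the entire pipeline is testable offline. See
`docs/methods.md` for the model details and the generator's assumptions.

## Worked example

Simulate a trial, partition the season, compute weights, and fit everything:

```console
$ stageyield simulate --seed 42 --out demo
wrote fixture tree to demo

$ stageyield stages --dryweight demo/dryweight.csv
a = 99.0651 g/plant, b = 1314.5056, k = 0.097883 1/day, adjusted R^2 = 0.9939 (n = 17)
rapid phase: day 59.91 to 86.82 (inflection 73.37)
stage ranking: TES > TFS > SAS > HS > SS
  SS: [0.00, 43.00)
  TFS: [43.00, 59.91)
  TES: [59.91, 86.82)
  SAS: [86.82, 105.00)
  HS: [105.00, 117.00)

$ stageyield weights --method iahp
importance totals r = [1.0, 5.0, 9.0, 7.0, 3.0], kappa = 9.0
  SS: 0.0329
  TFS: 0.1296
  TES: 0.5100
  SAS: 0.2638
  HS: 0.0636

$ stageyield report --data demo --out demo_report
reference plot NM-N2-1 (yield 13.200 kg)
stage ranking: TES > TFS > SAS > HS > SS
best model: lai / IAHP (adj R^2 = 0.9748, RMSE = 0.2093)
report written to demo_report
```

Reading the output: the dry-matter curve reaches half its asymptote
(≈ 99 g/plant) on day 73, and its rapid phase (days 60–87) defines the tuber
expansion window — the stage the IAHP matrix weights at 0.51. The report's
`models.csv` holds 16 rows (5 single-stage + 3 weighted models for each of
rCI_red edge and rLAI) with slope, intercept, adjusted R², RMSE, F-test
p-value, and the LOOCV columns (`rmse_cv`, `mre`, per-fold means). On this
trial the weighted rLAI models (adj R² ≈ 0.97) clearly beat the best
single-stage model (TES, adj R² ≈ 0.89), and the mean relative error of the
cross-validated predictions on absolute yields is under 2%.

The same workflow is available as a library:

```python
from stageyield import PipelineConfig, TrialConfig, run_pipeline

report = run_pipeline(PipelineConfig(trial=TrialConfig(seed=42)))
print(report.models[["variable", "weighting", "stage", "adj_r2", "rmse"]])
```

or through sklearn-style estimators (`SlogisticCurve`,
`WeightedStageYieldRegressor`, `StageRelativizer`) that compose with
scikit-learn tooling.

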