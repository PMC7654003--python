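# Methods

This note documents the models behind `stageyield`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Relative variables

All working variables are differences against one reference plot:
`rLAI = LAI − LAI_ref`, `rVI = VI − VI_ref` (per stage, against the
reference's *same-stage* measurement), `relative yield = yield − yield_ref`.
Subtraction of a value shared by all plots at a stage removes stage-level
confounds (illumination, aerosol, background) exactly, and — unlike
ratio-based relative indices — leaves every pairwise difference between
plots, and therefore every within-stage correlation, OLS slope, R² and
RMSE, unchanged. Only intercepts shift, by `yield_ref − slope·VI_ref`.

Two consequences shape the package's diagnostics:

* Within a single stage, relativization is statistically a no-op. Its
  benefit appears only when multi-period data are used *together*, so the
  benefit metric reported by the pipeline is the **pooled multi-period
  correlation**: |Pearson r| between a variable and yield over all
  (plot, stage) rows jointly. Per-stage offsets inflate the between-stage
  variance of absolute variables and attenuate this pooled correlation;
  relative variables are immune.
* Model fits are invariant to *which* plot is the reference as long as the
  fitted plot set is fixed. The default pipeline excludes the reference
  plot from fitting (its relative values are identically zero, and
  leave-one-out then runs K = 26 folds on the 27-plot design); setting
  `exclude_reference=False` fits all plots and makes reports exactly
  reference-invariant.

Reference selection: the paperwork-free default is the agronomically
"normal" treatment (normal moisture × normal nitrogen, replicate 1); a
`median_yield` strategy (lower median, deterministic) is provided for
designs without a designated control.

## Band extraction and vegetation indices

Spectra are two-column ASCII (wavelength nm, reflectance); duplicate
wavelengths are averaged and rows re-sorted on ingestion, reflectance must
lie in [0, 1.5] (whiteboard-relative calibration can exceed 1; negatives are
rejected). Each working band (550, 670, 720, 800 nm) is the arithmetic mean
over a ±2.5 nm window (configurable); a windowed mean is robust to
single-channel noise at sub-nanometre instrument resolution. Indices:
NDVI, CI_red edge = R800/R720 − 1, CI_green = R800/R550 − 1, EVI2,
NDRE, MTCI = (R800 − R720)/(R720 − R670). Zero denominators raise an
undefined-index error rather than returning infinities.

## Slogistic growth curve and stage partition

Dry matter follows `y = a/(1 + b·e^(−kx))` with a > 0 (asymptotic dry
weight, g/plant), b > 0 (shape, dimensionless), k > 0 (rate, 1/day). The
fit is unweighted nonlinear least squares on raw g/plant (simple, and the
fitted adjusted R² on realistic noise is ≈ 0.99, consistent with the
near-0.9-or-better narrative such campaigns report): initialization
`a₀ = 1.05·max(y)`, then `(b₀, k₀)` from ordinary regression of
`ln(a₀/y − 1)` on x, refined by trust-region least squares to relative
tolerance 1e−8. Adjusted R² uses `(n−1)/(n−3)` (three parameters).

Derivatives are analytic: `dy/dx = a·b·k·e^(−kx)/(1 + b·e^(−kx))²`,
maximal at the inflection `x = ln(b)/k` where the rate equals `a·k/4` and
the value equals `a/2`; both are validated against a finite-difference
oracle in the tests. The second derivative has extrema at
`t_low, t_high = (ln b ∓ ln(2+√3))/k`, which delimit the rapidly increasing
phase (width `2·ln(2+√3)/k`; a 26-day rapid phase therefore pins
k = 0.101304/day).

Stage windows: TES is the rapid phase `[t_low, t_high)`; TFS fills from the
end of SS to `t_low`, SAS from `t_high` to a configured harvest onset. The
SS end (first post-emergence measurement, default day 43), harvest onset
(default day 105) and season end (default day 117) are **calendar anchors**
supplied by configuration, not derived from the curve — a growth curve has
no senescence information.

`rank_stages` orders stages by mean growth rate over each window, computed
exactly as `(y(hi) − y(lo))/(hi − lo)` (point rate for degenerate zero-width
windows; ties break toward the later stage). A caveat documented here
deliberately: the TFS and SAS windows flank the rapid phase symmetrically,
so their mean rates are near-tied (within ~7% on the default anchors) and
their curve-derived order is decided by window length alone. An agronomic
judgment that late-season starch accumulation matters more than early tuber
formation is exactly that — a judgment — and belongs in the stage
comparison matrix below, which is where this package encodes it.

## Stage weights

**IAHP.** A 5×5 three-scale comparison matrix A (entries 0/1/2, unit
diagonal, complementary `a_ij + a_ji = 2`) encodes pairwise stage
importance; the built-in default encodes TES > SAS > TFS > HS > SS. The
per-stage importance totals are the **row sums** r of A (row sums reproduce
that ranking; column sums invert it). The judgment matrix stretches total
differences onto a ratio scale,

    b_ij = (r_i − r_j)/(r_max − r_min) · (κ − 1) + 1   for r_i ≥ r_j,
    b_ij = 1 / (|r_i − r_j|/(r_max − r_min) · (κ − 1) + 1)   otherwise,

with κ = r_max/r_min. The quasi-optimal matrix `C* = 10^C` with
`C_ij = (1/5)·Σ_t log10(b_it/b_jt)` is multiplicatively consistent by
construction (`C*_ij·C*_jk = C*_ik`), so no consistency test is needed, its
principal eigenvector equals the normalized geometric row means of B (a
dual-route identity the tests assert), and power iteration (tolerance
1e−12) converges in two effective steps. If all row sums are equal, κ is
undefined and uniform weights are returned with a warning. On the default
matrix the weights are (0.0329, 0.1296, 0.5100, 0.2638, 0.0636); note the
TES component is 0.510039, which rounds to 0.5100 at four decimals.

**EW.** For a plots × stages data matrix G, column shares
`p_ij = g_ij/Σ_i g_ij` give entropies `e_j = −(1/ln n)·Σ p ln p` (with
0·ln 0 := 0), difference coefficients `d_j = (1 − e_j)/(m − Σe)` and weights
`w_j = d_j/Σd`. Relativized variables can be negative, where shares are
undefined, so the default normalization min-max rescales each column to
[1e−6, 1] first; `normalization="none"` is available for nonnegative data
and errors on negatives with a pointer to the shift. The weights are
invariant to positive column rescaling and permutation-equivariant. The
pipeline computes EW from the relativized data matrix of whichever variable
is being modelled.

**OCW.** The distance objective
`R = Σ_m (1 − √((1/5)·Σ_j (w_j − w_j^m)²))` over the two input vectors is
constant along the entire segment between them — the optimum is degenerate,
a fact the tests demonstrate on an α grid at 1e−12 resolution. The package
therefore treats the combination coefficient as an explicit convention,
`W = α·W_IAHP + (1 − α)·W_EW` with default α = 0.7 (subjective share), and
provides `calibrate_alpha` — a least-squares projection of a published
combined vector onto the segment — to recover the convention another study
used. The audit records α and the attained objective value.

## Yield models and validation

Single-stage models regress relative yield on one stage's relative
variable; weighted models regress it on the composite
`x_p = Σ_t w_t·value(p, t)`. Conventions, fixed deliberately and used
everywhere: R² is the squared Pearson correlation; adjusted
R² = 1 − (1 − R²)(n−1)/(n−2); **RMSE divides by n** (not n−2), matching the
cross-validation formula; the F statistic is `R²(n−2)/(1−R²)` with the
p-value from the upper tail of F(1, n−2), and reports carry a "P < 0.001"
threshold flag.

Leave-one-out cross-validation runs K = n folds, each refitting on n−1
points. Reported: the per-fold coefficient means; the mean per-fold
**training** R² (a single held-out point has no R² of its own, so this is
the only coherent reading of a per-fold R²) alongside the squared
correlation of pooled held-out predictions vs observations (both labelled);
the held-out RMSE with 1/K; and the mean relative error computed on
**absolute** yields reconstructed with the reference yield — relative
yields pass through zero, where relative errors diverge. Held-out
predictions equal the hat-matrix closed form `ŷ₍₋ᵢ₎ = yᵢ − eᵢ/(1 − hᵢᵢ)`,
asserted to 1e−10.

Absolute predictions add the reference yield back:
`ŷ = slope·x + intercept + yield_ref`.

The estimator face of the package (`SlogisticCurve`,
`WeightedStageYieldRegressor`, `StageRelativizer`) follows scikit-learn
conventions (get_params/set_params, trailing-underscore fitted attributes,
clone-compatibility) so the models drop into sklearn pipelines; the
module-level functions are thin wrappers over the same code paths.

## Synthetic trial generator

`simulate_trial` emulates a greenhouse water × nitrogen campaign: 27 plots
(3 water levels EM/NM/IM × 3 nitrogen levels N1/N2/N3 × 3 replicates), five
measurement stages at days 43/57/82/99/117 after sowing, and a 17-date
dry-weight series whose base curve (a = 100 g/plant, b = 1627.5,
k = 0.101304/day) has its rapid phase on days 60–86 and inflection on
day 73.

Mechanism per plot p and stage t:

* amplitude `a_p = a·m_water·m_N·e^(ε_p)` with multipliers
  (0.92, 1.00, 0.80) for water, (0.85, 1.00, 1.05) for nitrogen, and 8%
  lognormal replicate scatter — water stress hurts more than excess, and
  half-rate nitrogen costs more than double-rate gains;
* `LAI(p,t) = 0.045·Slogistic(a_p, b, k)(day_t)` times 10% lognormal
  measurement noise (typical of ceptometer LAI under field conditions),
  giving a realistic 0.2–4.5 LAI range over the season;
* canopy reflectance is a Beer–Lambert linear mixture
  `R(λ) = f·R_veg(λ) + (1−f)·R_soil(λ) + δ_t` with cover fraction
  `f = 1 − e^(−0.5·LAI)`, fixed in-repo tabulated endmembers (400–900 nm,
  10 nm table interpolated to a 1 nm grid), per-wavelength Gaussian noise
  (σ = 0.005), and per-stage additive offsets δ_t of ±0.02–0.03 reflectance
  — the minimal shared illumination/background confound that subtraction
  removes. The saturating cover fraction makes NDVI flatten at high LAI
  while red-edge indices stay responsive;
* `yield_p = 4.0 + 3.0·Σ_t w*_t·LAI(p,t) + N(0, 0.25 kg)` with coupling
  weights w* = (0.05, 0.15, 0.45, 0.25, 0.10) peaking at tuber expansion —
  yields land at 8–14 kg/plot with a ~2–3% unexplained residual.

Everything is deterministic given the seed; `ground_truth` returns the
generating parameters for recovery tests, and `write_fixture_tree` writes
the plain-text tree (`plots.csv`, `lai.csv`, `dryweight.csv`,
`spectra/*.txt`, `manifest.csv`, `truth.json`) the CLI consumes.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no radiative-transfer canopy model (the linear
mixture is a caricature of PROSAIL-class physics), no senescence (LAI is
monotone through harvest, whereas real potato canopies wither at HS and
degrade late-season VI quality), no spatial autocorrelation between plots,
no weather-driven phenology, and yield is coupled to the *measured* LAI
trajectory rather than to an underlying physiological state, which makes
the weighted composite the generator's own truth. Results on this
generator demonstrate internal consistency and the direction of the
method's benefits, not field-level accuracy; the real campaign's printed
accuracies are not reproducible from synthetic data and are not targeted.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on 27-plot
trials; replication studies use 100 seeded trials (tests) and 50 seeded
trials (acceptance script), sizes at which the replication rates are stable
to a few percent. Noise-recovery statistics for the growth curve use 100
seeds at 5% multiplicative noise. Under that noise, a and k recover to
~1–4% median relative error and the phase boundaries to ~1 day, but b's
median relative error is ~23%: b enters as `exp(k·t_inflect)`, so k's error
is amplified roughly 60–70-fold in log-space, and the Fisher information at
the true parameters already caps any unbiased estimator at ~17% relative
standard deviation. Pinning b tightly requires either sub-2% dry-weight
noise or reporting the stable reparameterization (t_inflect, k) instead;
the package reports both parameterizations in its outputs.

Other conventions: duplicate wavelengths averaged on read; constant
entropy-weight columns contribute zero weight (uniform fallback with a
warning only when *all* columns are uniform); the lower median breaks even-n
ties in `median_yield` reference selection; IAHP power iteration tolerance
1e−12; curve-fit tolerance 1e−8 with positivity bounds on (a, b, k).
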