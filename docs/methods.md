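# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of the package. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Day length

Day length (sunrise to sunset, hours) is computed from the NOAA
low-precision solar-position algorithm: solar declination from a
three-term Fourier expansion of the fractional year evaluated at local
solar noon, and the sunrise hour angle H from
cos H = (cos z − sin φ sin δ)/(cos φ cos δ) with zenith z = 90.833°
(solar radius + mean refraction). When |cos H| ≥ 1 the routine returns
exactly 24 h (polar day) or 0 h (polar night). Accuracy is a few
minutes — immaterial for a covariate used in hours. The time of day of
sampling is ignored; only the calendar date matters. Hemispheric
antisymmetry (day length at +φ equals that at −φ half a year later)
holds within 0.5 h up to 60° latitude; the mismatch grows to about
0.7 h at 66° because a fixed 182-day shift is not exactly half an
anomalistic year.

## Synthetic data

The generator emulates the two field datasets only through (a) their
published per-column means, SDs and ranges, (b) the stated sampling
design (21 dates × 8 fixed depths, 12 cells lost, for the seasonal
series; 7 stations, 37 casts ≤ 80 m in July–August for the survey), and
(c) qualitative oceanography: a winter mixed layer near −1.7 °C with
summer surface warming, surface freshening by river water, and a summer
near-surface chlorophyll bloom.

Covariates are drawn from smooth depth-and-season profiles plus small
Gaussian jitter and then moment-calibrated: temperature and salinity by
a rank-preserving affine map to the published mean/SD, the positive,
skewed columns (Chl-a, abundances) by a rank-preserving power law
x → C·xᵇ (an affine map of log x), whose exponent b is solved by Brent's
method so the coefficient of variation matches and whose scale C sets
the mean. Day length is computed, never calibrated.

Abundances are `true_response(covariates) × exp(ε)` with
ε ~ N(0, 0.35²). The response surfaces are the latent truth that
model-recovery tests measure against:

* HNA: (0.35 + Gaussian peak in temperature at −0.8 °C, width 1.4 °C) ×
  productivity factor;
* LNA: increasing, saturating in temperature (exp(0.9 tanh(T/2))) ×
  productivity factor;
* V1: exp(−z/70 m) × productivity factor × increasing in day length;
* V2: exp(−z/90 m) × productivity factor × weakly increasing in day
  length.

The productivity factor is exp(g·tanh(log(chl/0.15)/1.5)) — increasing
and *saturating* in Chl-a (g = 1.7 for HNA, 0.7–0.8 otherwise). The
saturation is deliberate: chlorophyll-to-substrate coupling levels off
at bloom concentrations, and a bounded response keeps the surface
well-defined where the spatial survey extends beyond the seasonal
covariate range.

The seasonal table is calibrated to the published seasonal mean and SD
per abundance column; the power-law link (b, C) fitted there defines the
abundance units of the synthetic world. The spatial survey reuses that
same link — both tables sample one response surface — and then applies
only a per-population scale so the spatial means match the published
values exactly. Spatial SDs are consequently emergent, not imposed:
matching them too would require a second, different response surface
for the same populations, which would make cross-dataset evaluation
meaningless. As a result spatial CVs for HNA and V1 deviate from the
published ones by more than 30% at default settings; this is a known,
accepted property of the design.

What passing tests therefore show: the protocol recovers the drivers and
shapes of a *consistent* world whose marginal statistics match the
published tables. What they do not show: performance on real Arctic
data, with its unmodelled structure (advection, ice cover, nutrient
fields, measurement error correlated across depths).

## Networks and training

FFW: ŷ = Σ w⁽ᵒ⁾ⱼ σ(wⱼ·x+bⱼ) + b⁽ᵒ⁾ with bias units in both layers.
RBF: isotropic Gaussian bumps with per-unit width and an output-layer
bias only. Initialisation ties the non-linear parameters to the (scaled)
data range: FFW sigmoid inflection hyperplanes pass through a uniform
random in-range point; RBF centers are uniform in-range with widths
uniform in 0.2–2× the mean per-dimension spread. Linear parameters are
iid Uniform(−1, 1).

Levenberg–Marquardt: δ = −(JᵀJ + μI)⁻¹Jᵀr with analytic Jacobians
(validated against central finite differences to rel. error < 1e-5);
μ starts at 1e-2, is divided by 10 after an accepted step (training SSE
decreased) and multiplied by 10 with a retry otherwise, up to 10 inner
attempts, bounded to [1e-12, 1e12]. Exactly 100 outer iterations
(30 at the reduced scale) are recorded regardless of inner retries.
Early stopping reconstitutes the snapshot at the minimum of
RMSE_train + RMSE_test, ties to the earliest iteration. RBF widths may
change sign during optimisation; they enter the model only squared, so
this is harmless.

## Screening, selection and seeds

All randomness descends from one master seed. Restart i of architecture
s draws its generator from `SeedSequence([master, crc32(s), i])`, so a
phase-2 run with more restarts is a strict superset of phase 1's stream
and can only improve the best-of-restarts RMSE. Candidate enumeration
covers all 25 input subsets of size 1–3 (the published supplement
screened a 7-combination subset that is not listed; enumerating the
superset guarantees coverage), 2–15 hidden units and both families.
Selection keeps, among candidates whose spatial observed-vs-predicted
r² exceeds 0.5, the slope closest to 1, breaking ties by smaller
combined RMSE (the tie-break is this package's choice). If nothing
passes the gate the pipeline records an explicit "no admissible model"
outcome rather than silently picking something.

Scale presets: the full protocol (700 specs × 100/1000 restarts × 100
iterations) is available behind `scale="full"`; the default `ci`
preset — the problem size used throughout the test suite — screens the
generator's true input combination plus a decoy per output with 2 or 4
hidden units, 5 phase-1 and 10 phase-2 restarts and 30 iterations, which
exercises every code path of the full protocol at a few seconds per
output.

## Statistics

`linfit` computes the OLS line with textbook standard errors; r² is the
squared Pearson correlation (cross-checked against statsmodels in the
tests). The t-test against a theoretical slope/intercept uses
t = |b − B|/S_b with n−2 degrees of freedom: the theoretical constant
carries no sampling SD, so the printed two-SD denominator reduces to
S_b. The seasonal/spatial contrast uses the pooled two-sample Student's
t-test (Welch available via `pooled=False`). SMLR is bidirectional
stepwise OLS with entry and removal at p = 0.05 on
log-policy-transformed data (natural log of depth, Chl-a and abundances;
temperature, salinity, day length untransformed); a guard skips
candidates whose SSE improvement is below 1e-12·n·var(y) so an exact fit
does not draw in spurious predictors with 0/0 partial F statistics.
SMLR spatial performance is evaluated after back-transforming
predictions to abundance units, the same scale the network models are
judged on. With forward entry taking the best of four null candidates at
α = 0.05, the null model survives with probability ≈ 0.95⁴ ≈ 0.81 — the
type-I level of min-p stepwise entry, reflected in the test suite's
tolerance.

## Simulation

Grids span the seasonal covariate ranges (temperature −1.8–2.8 °C, day
length 0–24 h, Chl-a 0.01–0.61 µg L⁻¹), with viral models sliced at 5,
50, 100, 150 and 200 m; 50 points per continuous axis at full scale, 15
at the reduced scale. Predictions are inverse-scaled to abundance units
and never clipped: negative values flag covariate regions the model
extrapolates into. A support histogram over the same axes (bin edges at
grid-value midpoints) marks unsupported regions; the fixed-depth
sampling design guarantees empty depth bins between the sampled levels.

## Known limitations

* The published per-model numbers (RMSE, r², slopes of the real field
  fits; SMLR coefficients) are not reproducible without the field data;
  the pipeline reproduces the protocol and its qualitative findings on
  synthetic data only.
* The spatial survey extrapolates beyond the seasonal covariate range
  (chlorophyll especially); trained networks behave reasonably there
  only because both truth and sigmoid/Gaussian units saturate. Real
  extrapolation risk is larger.
* One network output per model; no uncertainty on network predictions
  beyond the evaluation regressions.
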