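# Methods

## The models

**Prevalence.** Population surveys of Raynaud's phenomenon (RP) report the
percentage of the general population affected. The calibration table holds
20 surveys (site, latitude, publication year, sample size, prevalence %).
Each survey is assigned the mean near-surface air temperature of the winter
preceding its publication — Nov 1 of year *Y−1* through Mar 31 of year *Y*
for a study published in *Y* — extracted from gridded daily climate at the
survey city. Prevalence is then regressed on that winter mean:

    p_i = a + b·T_i + e_i,      e_i ~ (0, σ²)

by ordinary least squares (sample-size weights optional, off by default:
the surveys differ enormously in size, but the unweighted fit treats each
*site-climate* observation equally, which is the ecological unit here).
The model is linear on the raw percent scale because the quantity of
interest is an additive change in percentage points per °C; predictions
are clamped to [0, 100]. The downward zero crossing −a/b is the
temperature above which the predicted prevalence is zero. The slope's
p-value uses the t distribution with n−2 df.

Extrapolation from the 20 calibration sites to the rest of the world is
temperature-mediated: every grid cell is predicted from its own local
temperature, so latitude enters only through climate. A direct
prevalence-versus-|latitude| regression is available
(`latitude_fallback_fit`) as a sensitivity path only.

**Severity.** Daily attack counts from pooled n-of-1 diaries (one row per
patient-day with the temperature at the nearest weather station) are
modelled as log-link Poisson:

    attacks_day ~ Poisson(exp(β0 + β_T·T + γ'x))

with exposure fixed at one day per row. The fit is by iteratively
reweighted least squares written in this package: working response
z = η + (y−μ)/μ, weights μ, update β = (X'WX)⁻¹X'Wz, with step halving
whenever a full step would decrease the log-likelihood (this keeps the
recorded likelihood path monotone, which the tests assert). Convergence is
declared when the relative log-likelihood change falls below 1e−8, with a
100-iteration cap after which the fit is returned flagged
`converged=False`. The covariance is the inverse Fisher information X'WX
at the optimum; initialisation is deterministic (intercept = log mean
count, others 0), so fitting involves no randomness. Extra covariates are
a configurable list (default: temperature only) with optional patient
fixed effects; a previously published model can be imported as a
coefficient JSON instead of refitting.

Weekly frequency is 7× the daily rate. Because attacks are empirically not
observed above ≈13 °C, predictions at or above a configurable ceiling
(default 13 °C) are forced to zero after prediction — a post-hoc threshold,
not a model term, since the ceiling is an observation about the data rather
than part of the likelihood. The temperature effect is summarised as the
secant slope of weekly attacks over a range (default 0–13 °C, the span
between freezing and the ceiling), and as its reciprocal: the °C of warming
per one fewer weekly attack. The endpoint predictions include the
threshold, so the default upper endpoint contributes zero attacks.

## Projection

Each scenario (historical baseline plus RCP2.6/4.5/6.0/8.5) is a daily
climate file. The mapped quantity is the mean temperature of a one-week
Christmas window (Dec 22–28, configurable) of the target year — 1999 for
the baseline, 2099 for scenarios. Both response curves are evaluated
cellwise on that field; ocean cells (masked in the land-only inputs) stay
masked throughout. Scenario maps carry exact cellwise deltas against the
baseline, and global summaries are cos(latitude)-weighted means over
unmasked cells (cell areas on a regular grid are proportional to
cos(latitude); the summaries exist for regression testing and reporting,
not as published quantities). Under uniform warming ΔT every unclamped
cell's prevalence delta is exactly b·ΔT, which the tests assert bitwise-
tight.

## Climate I/O choices

Files are CF-convention NetCDF with (time, lat, lon) and a units attribute;
Kelvin is converted to °C at load (all model quantities are Celsius), and
values outside [−90, 60] °C after conversion are rejected as a units
mistake. The time axis must be daily; storage order is normalised to
chronological, making window means invariant to on-disk day order. Window
day counts follow the real calendar: 151 days for a Nov→Mar winter, 152
when it contains a leap February.

Point extraction takes the nearest *unmasked* cell centre by great-circle
distance, searching up to 3 index rings (configurable) around the
index-nearest cell, because coastal cities on land-only grids often sit
over a masked sea cell; exact distance ties break toward smaller |lat|,
then smaller longitude. No interpolation or area averaging is done — one
value per site from one cell. Southern-hemisphere sites use the same
Nov→Mar window by default (mirroring the single calibration convention);
an austral May→Sep window is available via configuration.

## Synthetic data: what it emulates, and what it does not

The generators exist so every stage runs against known ground truth:

- **Climate**: T(lat, day) = equator_temp − gradient·|lat| + seasonal
  cycle + N(0, σ_daily) per day and cell, written as CF NetCDF in Kelvin
  with NaN oceans. Defaults: 36×72 grid (5°), equator 27 °C, gradient
  0.5 °C per degree latitude, seasonal amplitude 8 °C phased so the
  northern-hemisphere minimum falls mid-January (the calibration window
  must be the cold season), daily noise sd 2 °C, land fraction 0.7,
  historical decade 1991–2000 and scenario decade 2091–2100. Scenario
  offsets +1.0/+2.0/+3.0/+4.5 °C for RCP2.6/4.5/6.0/8.5 — representative
  end-of-century land warming spreads. Scenario files reuse the historical
  noise realisation shifted to the scenario decade, so scenario-minus-
  historical differences are exactly the offset.
- **Surveys**: 20 sites at random land cells with latitude in 30–60°N,
  years drawn from the winters the grid covers, prevalence =
  clamp(6.5 − 0.5·winter_mean + N(0, 1), 0, 100); the intercept 6.5 %
  puts the true zero crossing at 13 °C, consistent with the attack
  ceiling. Sample sizes are log-uniform over [67, 4182], the extremes of
  the published surveys.
- **Diaries**: 4 patients × 550 days = 2200 patient-days (the pooled
  n-of-1 series scale), temperatures uniform on (−5, 15) °C, counts
  Poisson with rate exp(0.3 − 0.12·T).

Each generator draws from its own seed-derived stream (SeedSequence with a
per-generator tag), so runs are bit-reproducible and adding one generator
call does not perturb the others.

Deliberately *not* emulated: spatial covariance, weather autocorrelation,
coastlines/orography, survey methodology differences, within-patient
correlation, overdispersion, or treatment effects in the diaries. Passing
tests therefore demonstrate that the pipeline recovers known parameters and
preserves its invariants under clean generative conditions — not that the
fitted values would be unbiased on real surveys (which differ in case
definition and age structure) or real diaries (which are overdispersed and
autocorrelated).

## Numerical choices and degenerate inputs

- OLS/WLS is delegated to a standard linear-model routine; tests verify it
  against the closed-form normal equations at 1e−10 relative.
- The prevalence fit accepts n = 2 records (a line through two points,
  with undefined standard errors at 0 df) and rejects designs where all
  temperatures are identical.
- IRLS rejects rank-deficient designs and all-zero counts (log mean −∞);
  non-convergence returns a flagged fit rather than raising.
- Window means require every calendar day present and report the missing
  dates otherwise; means over permuted storage orders are bit-identical.
- extract_at ties are exact float ties (symmetric grids), broken
  deterministically; the ring-limited search equals exhaustive search
  whenever a land cell exists within the radius.
- The pipeline driver contains no random number generation; rerunning a
  config reproduces byte-identical CSV outputs.

## Problem sizes used in the checks

The test suite runs on grids from 1×1 to 24×24 cells and diaries of
100–2200 days; coverage checks use 100 replicates per model (20-site
tables; 500-day diaries). The acceptance script runs the full default
configuration: 36×72 grid, two decades of daily data, five climate files,
20 surveys, 2200 patient-days.

## Known limitations

- Ecological calibration: the prevalence line is fitted across 20 surveys
  that differ in methodology, era and age range; the model attributes all
  between-site variation to winter temperature.
- A single climate realisation per scenario; no ensemble or uncertainty
  band on the projections.
- The attack ceiling is a hard threshold, producing a discontinuity in
  projected weekly attacks at exactly the threshold temperature.
- Negative predicted prevalence is clamped to zero rather than modelled
  (e.g. via a link function); warm-region predictions are therefore flat
  at zero rather than asymptotic.
- The latitude-only fallback regression shares the linear form and its
  caveats; it exists for sensitivity analysis, not as a recommended path.
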