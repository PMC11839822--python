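# Methods

`eggwdi` estimates withdrawal intervals (WDIs) for drug residues in hen
eggs after extra-label drug use, using the egg yolk as the slow-depleting
marker matrix. The pipeline has five stages: censored residue data
handling, non-compartmental analysis (NCA), per-timepoint summarisation
with Monte Carlo "virtual animal" augmentation, tolerance-limit WDI
estimation, and reporting. A synthetic laying-flock generator provides
data with the statistical structure the analysis assumes, so every stage
is testable end to end.

## Data model and censoring

Concentrations are in ng/g (≡ ppb); pipeline time is in days since the
**final** administered dose (input files carry study days and are shifted
on read). Each measured egg fraction (yolk or white) is one observation
with a censoring state derived from the assay limits: `quantified`
(≥ LLOQ), `below_lloq_above_lod` (in [LOD, LLOQ)) or `below_lod`.
Depletion and WDI work exclude only non-detects (`below_lod`); values
reported between LOD and LLOQ are retained as numbers but flagged, and a
stricter exclude-below-LLOQ policy is available. Default limits are those
of the reference UPLC-fluorescence assay: yolk LOD/LLOQ 0.03/0.075 ng/g,
white 0.01/0.025 ng/g.

Each egg is assigned its single collection time; no yolk-maturation
back-dating is attempted, because the analysis operates on lay-date
profiles.

## Non-compartmental analysis

Per hen, on the post-final-dose yolk series (internal PK time unit:
hours):

* **Cmax/Tmax** read directly off the data, ties to the earliest time.
* **λz** from ordinary least squares of ln C on t over a best-fit terminal
  window: candidates are the last k points after Tmax (Tmax excluded
  unless fewer than three points would remain), k = 3 … all. The window
  maximising adjusted R² wins; windows within 1 × 10⁻⁴ of the best — the
  conventional best-fit tie band — count as tied *provided their residual
  SD is within a factor two of the best's* (adjusted R² alone is
  scale-dependent on data spanning several decades), and ties go to the
  window with more points. Additionally, a window must span at least two
  of its own estimated half-lives (the usual λz reliability criterion);
  if no window does — typically a hen whose record was truncated early —
  the window covering the most half-lives is used. Without the span rule,
  truncated series occasionally yield three-point fits with half-life
  errors of a factor 3–4.
* **t½ = ln 2 / λz**, exactly, for every fit.
* **AUC** by the linear trapezoidal rule over observed points, with the
  tail C_last/λz added for AUC₀₋∞ and the extrapolated percentage
  reported.

Flock summaries are geometric means with (min, max) ranges, the standard
summary for log-normally distributed PK parameters, over hens with a
valid terminal fit.

## Timepoint augmentation

Regulatory tolerance-limit methods expect ≥ 10 residue values per
timepoint; a small flock laying irregularly rarely provides that.
Observations are binned to integer days since the final dose (collection
is daily); bins with at least 5 detectable values are retained; bins up
to and including the peak-mean bin are dropped so the regression sees
only the elimination phase. Each retained timepoint is topped up to
exactly 10 values with draws from Normal(mean, SD) of its observed
values, truncated below at the LOD by rejection sampling. Truncation is a
deliberate choice: sub-LOD values would be excluded downstream anyway, so
the exclusion is implemented at source; with SD = 0 the draws are the
mean itself. Observed values pass through unchanged, and the draw stream
is a pure function of the seed.

## Withdrawal-interval estimators

* **HLM (half-life multiplier)**: 10 × t½, the time for > 99% depletion.
* **Tolerance-limit methods**: OLS of ln C on time over the pooled
  augmented values gives slope b, intercept a, residual SD s on n − 2 df,
  mean time x̄ and Sxx. The upper one-sided (P, 1 − α) tolerance limit at
  time t is

      UTL(t) = a + b·t + K(t)·s,
      K(t)   = q_nct(1 − α; df = n − 2, nc = z_P·√n*(t)) / √n*(t),
      n*(t)  = [1/n + (t − x̄)²/Sxx]⁻¹,

  the noncentral-t formulation of a regression percentile bound with
  pointwise effective sample size. The WDI is the first time UTL(t) falls
  to ln(limit), located by a whole-day scan refined on a 0.01-day grid
  (raw WDIs are conventionally reported to 0.1 day) and rounded **up** to
  the next whole day. The implementation is validated against
  simulation oracles rather than the regulatory binaries: the factor K
  agrees with a 2 × 10⁵-draw pivotal Monte Carlo to < 0.2%, and the
  95/95 limit covers the true 95th percentile in 95% ± 2% of 1,000
  simulated regressions.
* **US-style run**: P = 0.99, 95% confidence, all elimination-phase
  timepoints, limit = assay LOD when no tolerance exists.
* **EU-style run**: P = 0.95, 95% confidence, restricted to the final 7
  timepoints (the EU tool's input cap), limit = 2 × LLOQ when no MRL
  exists (an LOD-based run is also provided for comparison). Data checks
  — lack-of-fit F test of linearity against the per-timepoint-means
  model and Bartlett's variance-homogeneity test, both at α = 0.05 —
  warn in the diagnostics rather than abort; a strict mode promotes them
  to errors. The window policies are separately configurable because the
  window difference, not the percentile, is what can invert the two
  methods' ordering: when late residues hover near the limit with a
  shallow slope, the last-7-timepoints regression extrapolates a flatter
  terminal phase and yields the *longer* interval despite its less
  extreme percentile.
* **PAR**: the provisionally acceptable residue
  ADI × bodyweight × partition fraction / consumption, in µg/kg ≡ ppb;
  with the US egg defaults (5 µg/kg/d, 60 kg, 20%, 0.1 kg/d) this is
  600 ppb.

## Synthetic flock generator

The generator emulates a pilot depletion study: n = 8 older hens, 0.4
mg/kg topical doses on study days 0 and 7, eggs collected at daily checks
for 90 days, with collection for a hen ending if she ceases laying or
after three consecutive eggs below the LOD in both fractions.

* **Kinetics**: yolk concentration is a superposition of Bateman terms
  (first-order absorption ka, elimination ke, ka > ke by construction),
  one per dose, with dose-proportional, time-invariant kinetics — the
  simplest model consistent with a single-peak profile. Population
  geometric mean ke = ln 2 / 9.5 d⁻¹; ka and the amplitude are solved
  numerically so the two-dose curve peaks 6.6 days after the final dose.
  Inter-hen variability is lognormal with geometric SD 1.2 for ka, ke and
  amplitude, chosen to cover the reported per-hen ranges (Cmax 2.5–5.1
  ng/g, t½ 142–297 h); these geometric SDs are assumptions, not
  estimates — the source study reports only ranges.
* **Cmax calibration**: the reported 3.54 ng/g geometric-mean Cmax is an
  *observed maximum* of noisy, discretely sampled eggs, which sits above
  the latent curve's peak. By default the amplitude is therefore scaled
  down by an observation-bias factor — the geometric-mean ratio of
  observed to latent peak over 512 virtual hens drawn from the
  population law with a fixed internal seed — so the simulated flock's
  observed geometric-mean Cmax matches 3.54 ng/g in expectation.
  Calibrating the latent peak itself to 3.54
  (`calibrate_observed_cmax=False`) makes the observed statistic
  overshoot by 25–45%.
* **Laying**: inter-egg gaps are 1 day (hard physiological minimum) plus
  a gamma variate; per-hen mean intervals are spread lognormally
  (geometric SD 1.7) around a flock arithmetic mean of 1.52 days,
  covering the reported per-hen range 1.16–1.83 days, with occasional
  long gaps. One hen (chosen by the seeded RNG) ceases laying at study
  day 47. Eggs are picked up at the next daily check (times ceilinged to
  whole days); the lay clock accumulates continuously so daily pickup
  does not stretch the mean interval.
* **Measurement**: multiplicative mean-one lognormal noise combining the
  assay's intra-assay CV (2.3%) with a biological between-egg CV
  defaulting to 25% — the source data give no between-egg variance, so
  this is an explicit assumption. Egg white is the yolk curve × 0.004,
  putting the white peak at its LOD so only a handful of white records
  are detectable, matching the reference study's ~10 detectable whites
  out of several hundred.

What the generator does **not** emulate: yolk follicle maturation (no
multi-day deposition window, no back-dating), plasma kinetics (none were
measured), assay drift or batch effects, and any seasonal or
health-related laying trends. Tests passing on this generator show the
pipeline's statistics behave correctly under its assumptions — log-linear
depletion with lognormal noise — not that real egg data satisfy those
assumptions.

## Numerical choices and degenerate inputs

* Tolerance-limit crossing search: whole-day bracketing scan over a
  365-day window, then a 0.01-day grid; "no crossing" is an error naming
  the window end.
* s = 0 (no residual scatter) short-circuits the tolerance limit to the
  fitted mean line; the zero-variance WDI equals the analytic
  line-crossing time to 0.01 day.
* Rejection sampling of the truncated normal is guaranteed ≥ 50%
  acceptance because augmentation refuses timepoints whose mean is below
  the LOD.
* Seeds: one pipeline seed fans out as seed + stage index (simulation 0,
  augmentation 1), so stages re-run in isolation reproduce the pipeline;
  all internal RNG is numpy `default_rng` via `SeedSequence`.
* Ceased-lay detection distinguishes a truncated record that ends with
  three consecutive all-below-LOD eggs (collection stopped by the
  depletion rule) from a genuine cease-lay gap.

## Problem sizes in the test suite

The suite simulates flocks of 8 hens (~600 observations each), 200
replicate flocks for the lay-interval calibration check, 200 replicate
single-hen series for λz recovery, 1,000 regression replicates for the
tolerance-limit coverage check and 2 × 10⁵ pivotal draws for the K-factor
oracle; the full suite runs in well under a minute.

## Known limitations

* The regulatory methods are re-implementations of the published
  statistical constructions, not bug-for-bug ports of the agencies'
  programs; on a given dataset small numerical differences from those
  tools are expected.
* The best-fit λz rule, like every automatic window selector, can be
  unstable on short, noisy, truncated series; the span criterion bounds
  but does not eliminate this.
* Left-censoring (excluding non-detects) flattens late-phase slopes
  slightly; recovered half-lives carry a small upward bias (~5% at the
  default noise level), which the reference study's own analysis shares
  by construction.
* No milk/tissue methods, no marker-residue chemistry, no plasma
  compartment.
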