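# Methods

## Study frame and timeline

The package analyzes monthly health-service counts over a 24-month window
split into three regimes: a 15-month pre-pandemic baseline, a 6-month
shock window beginning the month after the baseline ends, and a resumption
period covering the remaining quarter. Months are an abstract 1-based
index (month 1 ≈ January 2019 in the canonical application, so months
16–21 are April–September 2020 and 22–24 the final quarter). Calendars
that shift the declaration month are handled by configuration — e.g. a
14-month baseline moves every boundary one month earlier — never by date
arithmetic.

## The segmented regression

Unit-month totals are modeled by OLS:

    Y_it = b0 + b1 T + b2 X_t + b3 Z + b4 W + b5 S + b6 R + e_it

- `T` — month index (secular trend `b1`).
- `X_t` — 1 during the shock window (`b2` = immediate level change).
- `Z` — months since the shock began, 1..6 within the window, 0 elsewhere
  (`b3` = slope change during the shock).
- `W` — 1 from the resumption quarter onward (`b4` = remaining level gap).
- `S` — three season dummies, `R` — unit dummies (first sorted season and
  unit are reference levels; coefficient values, though not fits or
  effects, depend on this and it is documented for that reason).

**Z in the resumption quarter.** `Z` (and `X`) return to 0 after the
shock window, so `b4` alone measures the gap between the final quarter
and the *continued pre-pandemic trend*. The alternative — letting `Z`
continue to accumulate — would make `b4` a contrast against the
extrapolated shock-window slope instead, which does not correspond to the
"remaining level change" interpretation used for the resumption effect.

The fit uses a QR decomposition; the normal-equations solve exists only
as a test oracle. Rank-deficient designs raise with the offending columns
listed. Unit-months absent after cleaning are dropped (complete-case):
OLS has no missing-data machinery, and imputation is out of scope.

## Cluster-robust small-sample inference

Observations within a unit are serially correlated, so the coefficient
covariance is the clustered sandwich

    V = c (X'X)^-1 [ Σ_g X_g' e_g e_g' X_g ] (X'X)^-1,
    c = [G/(G-1)] · [(n-1)/(n-k)],

with G clusters (units). The finite-sample factor `c` is the default of
the major econometrics packages; `small_sample="cluster"` (G/(G−1) only)
and `"none"` are available for sensitivity. CIs and p values use a
t-distribution with **G−2** degrees of freedom regardless of how many
parameters the unit fixed effects consume — a deliberately conservative
convention for analyses with few sub-national units. With every
observation its own cluster the estimator reduces exactly to HC1.

Monte-Carlo calibration (`rhits.calibration`, 500 replicates, 10 units,
NB noise, immediate drop of 20% of baseline) puts 95% CI coverage for the
shock-level coefficient at ~96–98% and type-I error at ~4% — mildly
conservative, as expected from t(G−2) with 10 clusters.

## Percent-change effects

`percent_change = 100 · b / baseline_mean`, where `baseline_mean` is the
observation-weighted mean unit-month count over baseline months — the
same scale the coefficient is estimated on. CI bounds are divided by the
same fixed denominator and the p value carries over; the baseline mean's
own sampling error is ignored. A `national` mode (mean of national
monthly totals) exists for display next to country-level trend plots; on
balanced panels the two denominators differ exactly by the number of
units, and the percent change differs correspondingly — the unit-month
mode is the default because numerator and denominator then share units.

## Missed care

Counterfactual predictions evaluate the fitted model with `X = Z = W = 0`
while keeping trend, season and unit terms ("what delivery would have
been had the pre-pandemic trend continued, adjusted for seasonality").
Monthly deficit = Σ_units (predicted − observed), restricted to
unit-months with an observed value so the sums are like-for-like;
cumulative missed care sums the deficits over the pandemic window
(months 16–24 by default). Negative totals mean more care was delivered
than predicted and are reported as such. Predictions are not floored at
zero — a strong negative trend could predict negative counts, which are
flagged rather than clipped (clipping would bias deficits downward).

Normalization: per 1,000 annual births with
births = population × CBR / 1,000 (maternal/newborn/child services), or
per 1,000 population (chronic care). Service groups (e.g. antenatal +
delivery + postnatal care) are summed *before* normalization; a group
missing any member indicator is marked excluded rather than partially
summed, keeping grouped rates comparable across runs.

## Data cleaning

Step 1 — completeness: per indicator, keep facilities reporting at least
`min_months_reported` of the study months (default 15 of 24, boundary
inclusive; a reported zero is a report, only an absent/NaN month is not).
This guards against pandemic-era reporting decay masquerading as a
service drop. A sweep utility reruns the pipeline at {12, 15, 18, total}
to show threshold sensitivity.

Step 2 — outliers: per facility×indicator, counts more than `outlier_z`
(default 3.5) sample SDs (ddof = 1) above the facility mean are set to
missing. The mean/SD include the candidate point, and the rule runs in a
single pass by default; an iterated mode (recompute statistics after each
pass until stable) exists behind a flag. Low outliers are kept: a genuine
pandemic collapse looks exactly like a low outlier. Flagging order is
completeness first, then outliers.

**Detection limits.** With k extreme outliers among n points of one
series, the largest attainable z is √((n−1)/k) — about 4.8 for k = 1 and
3.4 for k = 2 at n = 24 — so two or more very large outliers in the same
facility-series mask each other under any threshold ≥3.5, and iteration
cannot help because nothing is flagged on the first pass. The ≥95%
detection guarantee is therefore stated (and tested) for sparse,
one-per-facility contamination; heavily contaminated series are the
completeness filter's problem, not the z-rule's.

The retention audit reports per-indicator cleaned/raw sum ratios and
monthly facility-reporting counts so an over-aggressive configuration is
visible before it biases estimates.

## Synthetic data generator

The generator runs the regression model forward at the facility level:
mu = linear predictor (same codings as the design matrix), counts drawn
as negative binomial with variance `mu(1 + dispersion·mu)` — Poisson-like
as dispersion → 0+ — and `dispersion = 0` meaning *no noise*, counts equal
to the rounded linear predictor. The rounding matters: exact-recovery
tests use integer-valued predictors so rounding is lossless and OLS must
interpolate the truth. A negative mean at any cell is a configuration
error naming the cell; only the final noisy draw is floored at zero.
Aggregating `f` identical-mean facilities multiplies every coefficient by
`f` on the unit scale, which is the estimand the regression sees.

Corruption emulates the two reporting-quality threats the cleaning step
exists for: missing monthly reports (probability optionally multiplied
during pandemic months, emulating reporting decay) and replacement of a
value by `outlier_scale ×` the facility mean. Every altered cell is
logged. Missingness is an absent report (NaN), never a zero.

Defaults across examples and validation studies: 6–10 units, 10–20
facilities per unit, baseline level 100–500 visits/facility-month,
dispersion 0.01–0.05 (coefficient of variation roughly 10–25% at those
levels, typical of monthly facility counts), immediate drops of 10–30% of
baseline, dropout 5–15% with a ×2 pandemic multiplier, 1–2% outlier
contamination at 5× the mean.

**What the generator does not emulate:** care-seeking behavior or
epidemic dynamics (effects are imposed, not mechanistic); facility
heterogeneity within a unit (facilities share a unit's mean); reporting
patterns correlated with service volume; calendar effects beyond the
four-season cycle. Passing tests therefore demonstrate that the
*estimator and pipeline* are correct and calibrated under the assumed
data-generating process, not that the substantive conclusions transfer
to any particular country's data.

## Numerical and design choices

- The noise distribution of RHIS counts is not identified by the analysis
  model (which is OLS on aggregates); negative binomial is a modeling
  convenience chosen for realistic overdispersion, with a *linear* (not
  log) mean so the generating parameters are exactly the OLS estimand.
- Sample SD (ddof = 1) in the outlier rule; outlier statistics include
  the candidate point (no leave-one-out) — the simplest reading, logged.
- Designs are validated by rank before fitting; fewer than 2 units is an
  error (G−2 df impossible), fewer than 3 makes inference impossible.
- Tiny negative variances arising from floating-point on the PSD sandwich
  are clipped to zero; genuinely negative diagonals still raise.
- Validation problem sizes: 50 random panels for oracle equivalence, 500
  replicates for coverage/type-I studies, 10×20×24 for exact recovery —
  the full suite runs in well under a minute on one core.
- Determinism: every random path is driven by `numpy` Generators seeded
  from the run seed via `SeedSequence`; run artifacts contain no
  timestamps, so identical config + seed reproduces files byte-for-byte.

## Known limitations

- No uncertainty intervals on missed-care totals (point estimates only,
  matching the estimand's definition here); no autocorrelation-consistent
  or bootstrap variance alternatives.
- Complete-case unit-months: units whose facility composition changes
  month to month are not re-scaled; the completeness filter is the
  defense against composition drift.
- Coverage indicators (service ÷ target population) are out of scope; the
  pipeline analyzes absolute counts.
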