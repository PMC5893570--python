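# Methods

`burnflow` implements a four-step statistical framework for deciding whether a
wildland fire disturbed a watershed's river flow and for splitting the observed
change into a climate part and a fire part. The package is built around a
synthetic watershed generator with recorded ground truth, so every statistical
property of the framework is testable without proprietary gauge, climate or
burn-severity archives.

## Data model

A watershed record is a daily frame of precipitation P (mm), mean air
temperature T (deg C), daylight hours Hr_day, snow water equivalent SWE (mm)
and area-normalised river flow Q (mm). Analysis operates on calendar-month
aggregates (fluxes summed, states averaged) and on two 60-month windows: the
5 years before and the 5 years from the fire month onward (the fire month
belongs to the post window, because the disturbance hypothesis concerns the
year *following* the fire). Monthly PET is derived from T and Hr_day by
Hamon's formula, PET = 29.8 * Hr_day * e_sat(T)/(T + 273.2) mm/day, with the
Magnus saturation vapor pressure e_sat(T) = 0.6108 exp(17.27 T/(T + 237.3))
kPa; the e_sat form is a pluggable argument since Hamon's method does not fix
it. Window summaries carry mean annual P, PET, SWE and Q, the sample variance
(n-1 denominator) of the 60 monthly precipitation totals (sigma^2_Pm), their
post-minus-pre deltas, and percent deltas relative to the pre window (flagged
undefined, not dropped, when a pre-mean is zero). Annual aggregation uses
consecutive 12-month blocks counted from the fire month rather than water
years; the choice is isolated in `features.annual_records`.

## Step 1 — change point in monthly flow

The change-point model evaluates the Lepage statistic L = U*^2 + M^2 at every
split of the 120-month flow window leaving at least 12 months on each side.
U* is the Mann-Whitney rank-sum statistic in its min form,
U = min(U_S, U_T) with U_S = n_S n_T + n_S(n_S+1)/2 - (rank sum of the first
segment), centred at n_S n_T/2 and scaled by sqrt(n_S n_T (n+1)/12); M is the
Mood scale statistic |M' - mu|/sigma with M' the sum of squared rank
deviations from (n+1)/2 over the first segment, mu = n_S(n^2-1)/12 and
sigma^2 = n_S n_T (n+1)(n^2-4)/180. Standardising the Mann-Whitney component
before squaring is required for L to behave as chi-squared with 2 df under no
change; the min-form U alone is not centred. Ties take mid-ranks; a fully
tied window carries no rank information and reports L = 0 (no detection).

Because the change time is chosen by maximising L over splits, the critical
value h_t is calibrated on the permutation distribution of the *maximum*
split statistic: the pooled ranks are permuted B times (B = 1999 by default)
and h_t is the m-th largest permuted maximum with m = floor(alpha (B+1)),
giving exact level m/(B+1) <= alpha for continuous data. Monte-Carlo checks
in the test-suite confirm a type-I rate of ~0.05 at alpha = 0.05 with
B = 199. The flow-disturbance null is rejected only when a change is detected
*and* the estimated post-change regime begins within twelve months from the
fire month. Monthly flow is analysed raw, without deseasonalisation, which
makes the test conservative against within-year spread; this mirrors how the
statistic is used on gauge records and is one reason step 1 fires less often
than step 2 on identical inputs.

## Step 2 — structural break in the double-mass curve

Cumulative monthly flow is regressed on cumulative monthly precipitation over
the same 120 months. Under a stable water-yield ratio the double-mass curve
is a straight line; the Chow test compares the pooled single-line fit (error
SSE0) against separate pre- and post-fire lines (SSE1, SSE2):

    F = [(SSE0 - (SSE1 + SSE2))/K] / [(SSE1 + SSE2)/(n - 2K)],   K = 2,

referred to F(K, n-2K). The break is *fixed at the fire month*, not searched,
so no maximum-selection correction applies (deliberate contrast with step 1).
Intercepts are included in every segment fit: after accumulation the segments
need not pass through the origin. Segment fits at round-off error (relative
SSE below 1e-12 of the response's centred sum of squares) are treated as
perfect: both-perfect-while-pooled-is-not reports an unambiguous break with
p = 0; an entirely linear curve reports no break. The cumulative coordinates
are serially correlated, which inflates the nominal F under misspecified
errors; the test is applied in the classical form and the caveat is recorded
in the result's notes. Null simulations in the suite draw iid noise around a
straight line in double-mass coordinates, where the p-value is uniform.

## Step 3 — boosted influence and the burned-area threshold

The 5-year change in mean annual flow (dQ, mm) is regressed across
watersheds on the feature families: fire variables (burned-area ratio BAR and
the watershed-area fractions in each burn-severity class, i.e. severity mix
times BAR), watershed geometry (area, perimeter, Gravelius compactness
C = Pm/(2 sqrt(pi A))), topography (elevation, slope), land-cover fractions,
pre-fire climate levels, and 5-year climate deltas. The exact predictor list
is `pipeline.FEATURE_MANIFEST`. Two uniform random probe columns are
appended; a variable counts as influential only when its relative influence
strictly exceeds the larger probe influence — the probes estimate the noise
floor of the importance measure from inside the same fit.

Boosting uses squared-error regression trees (scikit-learn's gradient
boosting) with subsampling (bag fraction 0.5). The tree budget is chosen by
five-fold cross-validation: held-out error is traced along the boosting path,
the model is refit on all cases with the error-minimising iteration count,
and relative influences are that refit's split-improvement importances
normalised to sum to 100. If the cross-validated model never beats the
constant mean predictor, no variable is declared influential regardless of
the importance ranking — otherwise a near-null fit with a handful of trees
would hand arbitrary variables spuriously large shares. Two profiles exist:
the reference configuration (30 000 trees, learning rate 0.001, interaction
depth equal to the number of predictors) and the default desk profile
(600 trees, rate 0.02, 7-split trees) which keeps a full nine-threshold scan
in minutes on one core; the screening behaviour under test does not depend on
the profile.

The threshold scan refits the influence model on nested subsets with an
increasing lower limit on BAR over the grid {1, 10, 15, 16, 17, 18, 19, 20,
25}%, skipping subsets below 20 cases. The critical threshold BAR_t is the
smallest limit at which a moderate- or high-severity variable becomes
influential; the full influence-versus-threshold trajectory is returned so
users can see where severity influence concentrates rather than relying on
the point estimate alone. See "Known limitations" for why the point estimate
is biased low whenever the fire signal is strong.

## Step 4 — climate elasticity and attribution

Four candidate climate-elasticity models predict annual flow anomalies from
annual climate anomalies on *pre-fire* data only: CEM1 uses dP; CEM2 dP and
dPET; CEM3 dP and d(sigma^2_Pm); CEM4 dP and dSWE. Anomalies are year values
minus the pre-fire mean, so the regressions carry no intercept; coefficients
are in mm of flow per unit predictor (absolute, not log-log, so the
attribution identity stays in flow units). Candidates are compared by
BIC = -2 ln(L_k) + k ln(n) with a Gaussian likelihood (variance SSE/n) and
k the number of regression coefficients (the shared variance parameter
cancels from the comparison); ties break toward fewer parameters. With fewer
than 4 pre-fire years only CEM1 is attempted. Significance uses the overall
regression F-test for two-predictor models and a coefficient t-test for CEM1,
both on n - k - 1 residual degrees of freedom — the anomaly form estimates
each variable's mean from the same sample, which costs the extra degree of
freedom; ignoring it demonstrably miscalibrates the null rejection rate.

The chosen model predicts the climate-expected change dQ_clim as the dot
product of its coefficients with the observed 5-year climate deltas, and the
disturbance attributed to fire is the identity dQ_dist = dQ_obs - dQ_clim,
reported in mm/yr and as a percentage of pre-fire mean annual flow
(suppressed with a flag when that mean is not positive). Attribution is
computed for every analysable watershed but marked fire-attributable only
when BAR reaches the working BAR_t *and* a step-2 yield breakpoint was
detected *and* the chosen elasticity model is significant — the same nested
eligibility chain the framework prescribes. Fitting a model on five annual
points is intrinsically unstable; the per-case result retains the full
candidate list, p-values and SSEs so downstream users can judge.

## Synthetic watershed generator

The generator produces the study conditions, not meteorological realism:

* **Occurrence/depth weather.** Wet days are Bernoulli with seasonal
  probability (DJF/MAM/JJA/SON; optional first-order persistence that
  preserves the marginal wet-day frequency); wet-day depths are gamma
  (default mean 7 mm, shape 0.75). Temperature is an annual cosine (default
  mean 8 C, amplitude 11 C, warmest late July) plus Gaussian daily noise
  (sd 3 C); daylight hours are a deterministic cosine around 12 h with a
  latitude-proxy amplitude (default 3 h). Defaults give ~900 mm/yr
  precipitation with interannual CV of ~6% on 5-year means — mid-latitude
  mixed rain/snow conditions.
* **Snow.** A degree-day model (default 2.5 mm/C/day, rain/snow threshold
  0 C): precipitation below the threshold accumulates as SWE; melt is capped
  by the pack. SWE is non-negative and melt never exceeds snowfall.
* **Flow.** Expected annual flow follows a power-law elasticity relation
  about the record-mean climate, Q_y = r P_ref (P_y/P_ref)^eps_P
  (PET_y/PET_ref)^eps_PET with defaults r = 0.4, eps_P = 2.0, eps_PET = -0.6
  (typical gauge-derived values), perturbed by Gaussian annual noise
  (default sd 25 mm) and floored at zero; daily flow distributes the annual
  total along a linear-reservoir routing of rain + melt (storage carry-over
  0.95/day), giving realistic monthly seasonality.
* **Fire.** A fire event carries a date, BAR, and a severity mix over the
  burned area (unburned/underburned, low, moderate, high, increased
  greenness) summing to one; watershed-area class fractions are mix times
  BAR. When BAR reaches the activation threshold (default 19%), flow is
  multiplied by 1 + c * f_mh for the effect duration (default 5 years,
  optional linear decay), with f_mh the moderate+high watershed-area
  fraction and c the enhancement coefficient (default 1.0, i.e. +1% flow
  per percentage point of moderate+high burned area). The pre-multiplier
  series is the exact no-fire counterfactual under the same seed, and the
  true effect (mm/yr and % of pre-fire flow) is stored on the case.
* **Cohorts.** Burned-area ratios are drawn log-uniformly over (0.01, 0.40)
  by default, reproducing the strong right skew of real fire sizes (cohort
  median near 6% BAR); severity mixes are Dirichlet-jittered; watershed
  attributes (area, compactness, elevation, slope, land cover) are sampled
  per case; per-case climate diversity jitters wet-day depth, wetness and
  temperature level so the cohort spans distinct climates. A cohort-wide
  post-fire precipitation factor emulates a climate shift concurrent with
  the fire; it applies to the counterfactual too, so ground truth is
  unaffected — this is the configuration that reproduces climate *masking*
  (positive fire effect inside a negative observed change). All randomness
  descends from one seed via spawned substreams; identical seeds give
  identical cohorts.

What the generator does **not** emulate: spatial rainfall structure, storm
hydrograph dynamics below monthly resolution, vegetation regrowth
trajectories, correlated multi-fire histories, or measurement error in gauge
ratings. Passing tests therefore demonstrate the statistical machinery under
a known, well-behaved data-generating process — not performance on real
gauge records.

## Problem sizes in the verification suite

The suite and the acceptance script scale simulations to single-core
minutes: permutation counts of 199 for Monte-Carlo calibration runs (1999
remains the analysis default), 500-1000 replicates for type-I/power
estimates, cohorts of 120-200 watersheds for recovery experiments, and the
desk boosting profile for all influence fits. Each experiment's size is
stated where it runs.

## Known limitations

* The Chow test inherits the serial correlation of cumulative sums; its
  p-values on real double-mass data are anti-conservative. The decision is
  faithful to the framework's usage and the caveat travels in the result.
* Elasticity models fitted on five annual anomalies have wide sampling
  variance; BIC selection between nested candidates at n = 5 is close to
  noise-driven, and a one-predictor truth is frequently "beaten" by a
  two-predictor candidate that fits noise. Recovery experiments use 10
  pre-fire years where the point is model identification rather than the
  5-year operational setting.
* The BAR_t scan has limited resolution under a threshold-activated effect.
  Systematic simulation (cohorts of 130-200 watersheds; effect strengths
  from +2% to +45% of flow; severity-mix spreads from near-fixed to
  near-uniform; tree depths from stumps to full interaction depth; both the
  desk and a deep reference-like profile) shows that a severity variable's
  influence, relative to the probe floor, is governed by the *number of
  active cases and the effect size* and is nearly invariant to the subset
  lower limit: real split improvements scale with the active count and
  spurious ones with the residual noise, and neither changes when inactive
  cases are added, because the trees isolate the active subpopulation
  anyway. Consequently, when the effect is strong enough to detect at all,
  it is usually already influential in the full cohort, and the
  smallest-threshold rule reports a BAR_t near the bottom of the grid; only
  the disappearance of severity influence above the grid's top (where BAR
  variation vanishes) is sharply localised. Threshold recovery experiments
  therefore measure this bias honestly instead of hiding it; the influence
  trajectory, not the point estimate, is the scan's trustworthy output.
* The fire effect model is multiplicative and constant (or linearly
  decaying) over the effect window; real post-fire responses vary with storm
  sequencing and recovery.
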