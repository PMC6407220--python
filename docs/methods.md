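# Methods

`mealvar` analyzes meal-level variation in energy and macronutrient intake
from repeated 24-h dietary recalls. This note describes the statistical
models, the synthetic cohort the package ships with, the numerical choices,
and the limits of what the synthetic results demonstrate.

## The hierarchical model of intake

One recall day records up to 11 eating occasions; four participant-identified
meals (breakfast, lunch, afternoon snack, dinner) are retained for analysis.
Zero intakes — almost entirely energy-free beverages — are excluded per
outcome and the remaining values are log-transformed (natural log; the base
is irrelevant to every reported statistic, all of which are scale-invariant).

The intercept-only model treats occasions *t* as nested in
participant-by-meal cells *(i, m)* nested in participants *i*:

    log y_imt = mu + u_i + v_im + e_imt
    u_i ~ N(0, s2_P),  v_im ~ N(0, s2_M),  e_imt ~ N(0, s2_e)

The intra-class correlation of a level is its share of the total variance,
e.g. ICC_meal = s2_M / (s2_P + s2_M + s2_e). Level-2 units are
participant-by-meal-type *cells*, not the four meal types as global clusters:
with only four global clusters a random-effect variance is not estimable,
and the cell formulation is what a nested hierarchy of occasions within
meals within participants means operationally.

### Estimation

`fit_three_level` maximizes the profiled Gaussian likelihood. The likelihood
factorizes exactly into (a) within-cell deviations, which depend only on
s2_e, and (b) cell means, whose per-participant covariance is a rank-one
update of a diagonal matrix — so one likelihood evaluation is O(number of
cells) and the fixed intercept is profiled out by GLS in closed form.
Variances are optimized on the log scale (Nelder–Mead, function tolerance
1e-12); each constrained candidate with one or both upper-level components
pinned at zero is also fitted, and the best likelihood wins, with near-ties
resolved toward the boundary (projection to exactly 0, flagged in
`truncated`). Unbalanced cells and single-recall participants are handled by
construction; a participant with one observation still informs the
participant level.

ML is the default. REML is available (`method="reml"`) because for balanced
designs the restricted likelihood reproduces the closed-form nested-ANOVA
method-of-moments estimator (`fit_nested_anova_balanced`), which the test
suite uses as an oracle; ML itself is checked against a brute-force
maximization of the explicit multivariate-normal likelihood and against an
independent mixed-model implementation. For balanced designs ML and the
ANOVA estimator differ by design — ML shrinks the upper-level mean squares
by (G−1)/G — which is why the oracle equivalence is stated for REML.

## Meal-stratified predictor importance

Because no covariate is specific to meal *type*, predictor models are
two-level models stratified by meal: occasions (level 1) within participants
(level 2). For the occasion rows z_it of one meal the package computes the
pooled within-cluster covariance and the moment estimator of the
between-cluster (latent mean) covariance:

    S_PW    = sum_i sum_t (z_it − z̄_i)(z_it − z̄_i)' / (N − G)
    S_B     = sum_i n_i (z̄_i − z̄)(z̄_i − z̄)' / (G − 1)
    Sigma_B = (S_B − S_PW) / c,   c = (N − sum_i n_i² / N) / (G − 1)

This closed-form decomposition (the classical moment estimator used in
multilevel SEM) was chosen over full-information ML because it is exactly
reproducible, consistent for random-intercept models, and fast enough to sit
inside a 1000-replicate bootstrap. Equivalence with full-ML multilevel SEM
software is asymptotic, not exact.

Intake-level covariates (weekend, season, special day, prior interval, place
of meal) enter the within model on S_PW; participant-level covariates (sex,
age, BMI, education, occupation, smoking, physical activity — plus the
misreporting dummies in the sensitivity analysis) enter the between model on
Sigma_B. Each non-reference category of a categorical covariate is its own
dummy predictor (references: home, never smoker, no vocational training, no
job/retired, male, winter, plausible reporter). From a level's covariance
block the package solves the normal equations Sigma_xx b = sigma_xy and
reports

* standardized beta-weight  beta_j = b_j · sd(x_j) / sd(y),
* zero-order correlation    r_j = cov(x_j, y) / (sd(x_j) sd(y)),
* level R² = sum_j beta_j r_j,
* Pratt index  PI_j = beta_j r_j / R².

Standardization uses level-specific SDs — the only choice under which the
level R² decomposes additively as beta'r. Pratt indices sum to 1 by
construction and may be negative (suppression). When a level's R² is below
`min_r2` (default 1e-8) the Pratt vector is flagged undefined rather than
reported. Negative Sigma_B diagonals (sampling noise) are floored at 0 and
the affected variable is excluded from the between model with a warning;
covariates constant within a meal stratum are dropped with a warning. Rows
missing a covariate (e.g. a first occasion's prior interval) are excluded
row-wise. Tables rounded to whole percent may sum to 99–101%; full precision
is retained internally.

## Prior interval

The prior interval of an occasion is the time in hours since the
participant's previous consumed occasion, counting all 11 occasion slots.
The gap crosses midnight only when two recall days are consecutive calendar
days; since recalls fall on randomly chosen, usually non-adjacent days, a
day's first occasion otherwise has no defined interval and its row is
excluded from models that use the covariate. This is a declared policy: the
overnight gap before an isolated recall day is unknowable.

## Cluster bootstrap

All reported statistics get 95% percentile intervals from a cluster
bootstrap: participants are drawn with replacement (G out of G), each draw
carrying all of its occasion rows under a fresh surrogate id. The default is
B = 1000 replicates with 2.5/97.5 empirical percentiles (linear
interpolation between order statistics — the quantile rule is configurable
in principle but this common default is fixed here). Each replicate uses an
independent sub-seed derived from (seed, replicate index), so results are
identical regardless of execution order. Replicates where estimation fails
(singular covariance in a sparse stratum, floored between-variance on the
outcome) are dropped from the percentile pool and counted; more than 50%
failures is a hard error.

## Energy misreporting

Usual energy intake is summarized as the naive mean of daily totals over
recall days (a deliberate, labelled stand-in for usual-intake modelling).
Participants with measured total energy expenditure are classified by
EI/TEE: strictly below 0.81 under-reporting, strictly above 1.19
over-reporting, the closed interval [0.81, 1.19] plausible (the boundary is
measure-zero; assigning it to "plausible" matches the strict inequalities of
the rule). The cutoffs are fixed constants. The sensitivity analysis adds
under/over dummies (reference: plausible) to the between level and restricts
to classifiable participants.

## The synthetic cohort

`SimulationConfig()` defaults describe the study-like conditions: 814
participants, 3 recall days, 11 occasions per day, four analyzed meals,
participant marginals matching a typical older German cohort (50.5% men, age
65.5 ± 8.4 y, BMI 27.5 ± 4.4, smoking 46/43/10%, education 33/23/44%,
occupation 31/8/62%), TEE available for 84% of participants.

Intakes are log-normal:

    log y = mu + mu_m + x'beta_W + w'beta_B + log b_i + u_i + v_im + e_imt

with per-outcome variance components calibrated to the published ICC shares
(energy 0/0.273/0.427, carbohydrate 0.024/0.200/0.576, protein
0/0.282/0.318, fat 0.015/0.165/0.320 for participant/meal-cell/occasion) and
per-outcome zero-injection rates 2.8/2.7/3.3/4.9% (zeros replace the
simulated value exactly, emulating energy-free beverages, independently per
outcome). Meal offsets mu_m default to 0 so the meal-level ICC share equals
s2_M/total exactly in recovery tests; with non-zero offsets the systematic
meal differences load into the estimated meal-level variance of an
intercept-only model, as they would in real data.

Covariate effects default to modest log-scale values in the directions the
study reports (place of meal and weekend dominating the intake level, sex
the participant level), sized so level R² lands in the reported low ranges;
they are package choices, as are the 11 occasion labels and their clock
times (drawn from truncated normals bounded by neighbouring occasions'
midpoints, which guarantees monotone within-day times).

Reporting bias: when TEE is enabled, each participant receives a
multiplicative bias factor b (39.6% under-reporters with b in 0.55–0.78,
52.6% plausible with b in 0.84–1.16, 7.8% over-reporters with b in
1.22–1.55) that multiplies the *reported* intakes, while TEE is the unbiased
requirement EI/b. EI/TEE therefore recovers b exactly, and misreporting is a
genuine between-person signal, which is what makes the sensitivity analysis
informative. A consequence worth stating: with bias enabled the
intercept-only participant-level share rises above the bias-free
calibration by roughly var(log b)/total. The published data show near-zero
participant shares *despite* containing misreporting — a tension a simple
generative model cannot resolve; the parameter-recovery scenarios therefore
disable TEE and recover the bias-free calibration.

### What the generator does not emulate

Food-item composition within meals, energy–macronutrient correlations
(outcomes are drawn independently), nutrient-database structure, realistic
day-total magnitudes (snack occasions share the meal-scale grand mean, so
simulated daily totals overshoot typical cohort means — harmless, since
every reported statistic is scale/location invariant), seasonal eating
patterns, and usual-intake measurement error. Passing recovery tests shows
the estimators are correct under the declared model, not that the model
captures all features of real recall data.

## Problem sizes and numerical conventions

Recovery tests run at the study scale (800 participants × 4 cells × 3
occasions, ~9600 rows; one ML fit takes well under a second). The bootstrap
coverage study is scaled down (200 simulated datasets × B = 200, 40 clusters
each) — percentile-interval coverage for a within-level beta is checked
against a [0.90, 0.99] band. Monte-Carlo-noisy point checks (ICC share
recovery, variance recovery) average a handful of independent replicate
cohorts so the Monte-Carlo SE is small relative to the stated band; the
bands themselves are fixed. Degenerate inputs: constant outcomes return
all-zero variance components; a zero total variance makes ICC shares
undefined (error); a zero level R² makes Pratt indices undefined (error, or
a flag inside the meal-model driver); singular predictor blocks raise an
error naming the collinear predictors.
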