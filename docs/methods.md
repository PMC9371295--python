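# Methods

## The process being modelled

`statelife` analyses a progressive illness-death process with five states:
no complications (1), one (2), two (3), three-or-more (4) — all transient —
and death (5), absorbing. Seven transitions are allowed: one state up from
each transient state (1→2, 2→3, 3→4) and death from any transient state.
Complications are irreversible and accrue one at a time; the model is
Markov on the *age* clock — transition intensities depend on current age
and state, never on sojourn duration. Age 50 is the clock origin and 110
the assumed maximum life span.

## Transition intensities

Every transition has its own Gompertz proportional-hazards intensity

    h(t | x) = rate · exp(shape · t) · exp(x'β),   t = age − 50 in years.

* `rate` (> 0, per year) is the baseline hazard at age 50 for the
  reference profile (male, least-deprived quintile, risk factors at the
  cohort mean).
* `shape` (any real, per year) is the log-hazard slope; `shape → 0`
  degrades to the exponential model, handled by a series expansion below
  |shape| < 1e−8 so the likelihood is smooth through zero.
* `exp(β)` are hazard ratios. Covariate sets: `set1` = sex; `set2` = sex +
  deprivation quintile (indicators `q1..q4` against the least-deprived
  quintile 5); `set3` = `set2` + time-updated, mean-centered risk factors
  (episodes split at measurement times, centering at the analysis-table
  grand mean at fit time).

Episodes are left-truncated at study entry (the likelihood accumulates
hazard only over the observed window) and right-censored at the competing
exit. The competing-risks likelihood factorizes over transitions, so the
seven fits are independent. Estimation is Newton–Raphson on
(shape, log rate, β) with analytic gradient and Hessian, started at the
closed-form exponential solution (shape 0, log rate = log events/person-
time, β = 0) with step halving; a BFGS fallback covers awkward surfaces.
Convergence requires gradient max-norm < 1e−6 and relative log-likelihood
change < 1e−10; the observed information must be positive definite at the
optimum, otherwise the fit is reported as failed rather than silently
returned. Continuous-time likelihood needs no tie correction.

AIC (2k − 2ℓ) compares distributions (Gompertz vs exponential vs Weibull)
and covariate sets per transition; on the synthetic register the Gompertz
wins every death transition, as expected from the generating process.

## Panel construction

Observation time is sliced into 30-day intervals (30/365.25 years); the
final partial slice is kept and its person-time counts. The state of a
slice is the number of complications accrued *at or before its start*, so
an onset becomes visible at the first slice boundary at or after it —
episode times are therefore interval-grouped, and accepted as such. Two
onsets inside one slice surface as a two-state jump; those individuals
are excluded (no ordering is imputed). A death and an onset inside the
same final slice resolve as death from the pre-slice state, one reading
of an ambiguous corner case; it affects a fraction of a percent of
deaths.

The "observable for more than 30 days" entry rule is applied to
*censoring only*: an individual whose record ends by non-death causes
within the first slice is excluded, but an early death is fully observed
and kept. Excluding early deaths would select on outcome; in synthetic
experiments at n = 50,000 it biased high-deprivation life expectancy
upward by 1–2%.

## Occupancy and life expectancy

The Kolmogorov forward system dP/du = P·Q(u) is integrated per start
state with classical RK4 at a fixed 30-day step (matching the panel
resolution) from 50 to 110; the last step is shortened to land exactly on
the horizon. Hazards are smooth, so halving the step changes no entry by
more than 1e−6 (an optional built-in refinement check enforces this).
The solver validates the probability bounds of its output and fails
loudly when fed degenerate intensities (which can arise in bootstrap
replicates of very small cohorts); the bootstrap records and drops such
replicates, aborting if more than 10% fail.

Start-state-specific expectancies are trapezoid integrals of the
occupancy curves over [50, 110], ignoring mass remaining at the horizon
and never counting time in the death state. A left-endpoint rule is
available as a config switch; the two differ by well under one slice of
probability mass. Total LE weights the start-state rows by the baseline
state prevalence `w_j` estimated from an auxiliary sample aged 45–54
(half-open window [45, 55), mean age ≈ 50). Prediction profiles are one
per stratum, with set-3 risk factors at 0 — i.e. the cohort mean.

## Uncertainty

Nonparametric bootstrap at the individual level: cohort and weight sample
are resampled with replacement (all records of an individual move
together), and the *same* pipeline callable that produced the point
estimate is re-run per replicate, weights re-estimated inside. 95%
intervals use the normal approximation from the replicate standard error
(percentile intervals optional); per-replicate seeds derive from
(seed, replicate index), so results are independent of execution order.
Coverage of the normal CIs is itself exercised in the test suite over 100
simulated registers.

## Validation estimators

* **Chiang abridged life table**: 5-year groups from 50–54, open-ended at
  85+; q = n·m/(1 + n(1−a)m) with a = 0.5; the open group closes with
  e = 1/m. Under a constant rate this reproduces e(50) = 1/m exactly.
  The life table is *not* truncated at 110, a known small source of
  disagreement with the multistate estimate.
* **Two-state Gompertz**: all transient states collapsed, one
  left-truncated survival fit, LE = ∫ S(t) dt over [50, 110].

On the default register the three total-LE estimates agree within ~1–2%
per sex. A deliberately misspecified multistate model (exponential
intensities fitted to age-graded mortality on a young-entry cohort) is
flagged by the >5% discrepancy rule, confirming the comparison has teeth.

## The synthetic register

The generator emulates a national diabetes-register cohort: ~8,600
individuals aged 50+ at entry, 6-year administrative window, non-death
dropout as a constant 0.007/yr hazard, 55.3% male, quintile shares
(17.9, 21.4, 21.5, 18.9, 20.4)%. Entry ages follow a truncated normal
(mean 41.4, sd 18.4, truncated to [50, 90]) calibrated to the target
median 59.6 and IQR 54.3–66.9 — the three quantiles are the only
distributional facts available, so the law is identified only up to them.

Sampling is exact in continuous time: per sojourn, one latent waiting
time per allowed exit by closed-form inversion of the Gompertz cumulative
hazard conditional on survival to the current age; the minimum wins;
exact ties (probability zero) resolve in transition-id order. The 30-day
discretization is *not* simulated — it is applied downstream by the panel
builder, so slice-induced double jumps and the exclusion rule are
exercised naturally (≈0.3% of individuals at default intensities).

Baseline states are drawn from an age-band × stratum mix table built by
evolving each stratum complication-free from age 40 under the true
intensities and conditioning on being alive. This makes the
cross-sectional state composition of entrants internally consistent with
the model's own dynamics — period mortality rates and cohort projections
then estimate the same quantity, which is what makes the life-table
triangulation a fair check. The same table defines the exact start-state
weights of the ground-truth oracle (`true_expectancies`), computed as the
band average over [45, 55); sex-level truth is the quintile mixture under
the generating quintile shares.

Default intensities were calibrated once (Nelder–Mead on oracle outputs)
to registry-like conditions: baseline mix ≈ 38/31/22/9% over 0/1/2/3+
complications, total LE(50) ≈ 22 (males) / 25 (females), a ~7–8 year
least-vs-most-deprived LE gap, and a ~2× gradient in years without
complications. Gompertz shapes were fixed a priori at 0.085/yr (death)
and 0.05/yr (onsets) for demographic realism, and death rates are
constrained nondecreasing in state (0.0029, 0.0050, 0.0100, 0.0201 per
year at age 50 for the reference profile) — an unconstrained calibration
can trade these for marginally better target fit, at the cost of a
nonsensical state gradient. The auxiliary weight sample defaults to
20,000 individuals, larger than the cohort, mirroring the design choice
of drawing weights from a wider age band to suppress small-cell noise.

What the generator does **not** emulate: measurement processes behind the
complication definitions (onsets are generated directly as ages),
unobserved heterogeneity/frailty, risk-factor feedback on intensities
beyond a constant individual effect, seasonality or calendar trends, and
informative censoring. Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to violations of
it.

## Problem sizes in the test suite

Closed-form checks run at negligible cost. Simulation-backed checks use:
100,000 trajectories for solver-vs-Monte-Carlo agreement; n = 10,000 for
parameter recovery; n = 20,000 for method triangulation; 100 cohorts of
n = 3,000 with 100 bootstrap replicates each for CI coverage; 20 seeds at
n = 4,000 for sign recovery; n = 100,000 for the collapsible two-state
equivalence, where the argument is asymptotic. These sizes keep every
Monte-Carlo tolerance (3 SEs) meaningfully tight while the whole suite
completes in minutes.

## Known limitations

* Interval grouping at 30 days leaves a small conservative bias in onset
  timing (~15 days late on average); refitting at 2-day slices moves
  stratum LE by well under 1%.
* The exclusion of multi-jump individuals removes the fastest
  progressors; at default intensities the effect is negligible, but it
  grows with onset hazards and slice width.
* Quintile-specific LE at registry scale (n ≈ 10,000) carries ~1.5–2%
  sampling noise; per-quintile point estimates should always be read with
  their bootstrap intervals.
* The two-state and life-table comparators share the cohort's mortality
  data with the multistate model; they are independent *estimators*, not
  independent data.
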