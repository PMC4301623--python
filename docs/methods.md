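# Methods and design notes

This note documents the generative model, the estimation machinery, and the
numerical and design choices behind `stovewedge`, in the spirit of a model
documentation page: what is assumed, what is tunable, and what passing the
test suite does and does not establish.

## Trial structure

The stepped-wedge design is 12 randomization groups of 4 sectors each
(48 sectors; the field study used 51, combined into 12 groups), observed
over 24 monthly periods: 6 pre-installation months, a 12-month wedge in
which one randomly ordered group receives stoves per month, and 6
post-installation months. Sectors are striped onto groups round-robin over
a supplied geographic ordering, mimicking the stratified systematic
assignment used in the field; exact geography is not modelled, so the
ordering is caller-supplied (identity by default).

**Transition coding.** Stove installation in a group takes about a month,
so the installation month itself is ambiguous exposure time. The exposure
indicator codes it unexposed by default; `transition="exposed"` and
`transition="drop"` are available. This choice was genuinely open; excluding
the partially exposed month is the conservative default because
contaminating the exposed category dilutes θ.

**Analysis clustering.** "Village" is ambiguous between sector (48/51
units) and randomization group (12 units). The model's village random
intercept and the default robust-variance clustering use sectors; group-
level aggregation is one keyword away (`cluster_level="group"`).

## Generative outcome model

For child *j* in sector *i* at month *t*:

    logit p_ijt = α₀ + b_i + c_ij + log m(t) + τ(t) + θ·x_it
    b_i ~ N(0, 0.025),   c_ij ~ N(0, 0.10)

- `m(t) = A^sin(2π(t − φ)/12)` is the seasonal rate multiplier with relative
  amplitude A = 1.05 (peak month 3 under the default phase φ = 0). Its
  geometric mean over a cycle is 1, so seasonality preserves the long-run
  average rate. It enters the linear predictor as `log m(t)`, treating rate
  and odds multipliers as interchangeable — an approximation accurate to
  O(p) at the monthly p ≈ 0.08 involved.
- `τ(t)` is the optional "large" secular trend: log(1.5) at month 1
  declining linearly to 0 at month 11.
- Cohorts are Poisson(35) children per sector; each child contributes a
  binary response every month (no dropout — see Limitations).

**Rate calibration.** The intercept α₀ is chosen so that the
population-averaged per-month probability under the null scenario equals
`baseline_rate / 12` (default 1.0 episodes per child-year): α₀ solves

    mean_t E_Z[ expit(α₀ + log m(t) + Z) ] = baseline_rate/12,
    Z ~ N(0, σ²_village + σ²_child),

by 31-node Gauss–Hermite quadrature and Brent root-finding. The naive
`α₀ = logit(1/12)` would overshoot the marginal rate by ≈5% through the
Jensen effect of the random intercepts; the calibrated intercept makes the
simulated annual rate equal the nominal rate to Monte-Carlo error, which the
acceptance checks verify directly.

**Period granularity** is monthly (24 periods). Whether weekly responses
would change the power results can be probed by `periods_per_year`, but
monthly matches the wedge step length and is the default throughout.

## Diary and episode machinery

An ALRI episode is ≥2 consecutive days with fever or fast/difficult
breathing (the two core symptoms), both reported together on at least one
day, at least one core symptom on every non-gap day, and ≥7 symptom-free
days between episodes. The last two clauses are jointly satisfiable only if
symptomatic runs separated by 1–6 clear days are merged into one episode;
the detector does exactly that, retaining interior gap days flagged as such.
"Both symptoms on at least one day" is read as same-day co-occurrence
(`require_cooccurrence=False` gives the weaker each-symptom-some-day
reading). Missing diary days break runs by default; `bridge_missing=k`
permits merging across up to k missing days. Episode duration is calendar
days from first to last symptomatic day.

The diary generator plants episodes that satisfy this definition by
construction and keeps episodes and noise days at least 7 clear days apart,
so the detector's output on generated diaries should equal the ground truth
exactly — a round-trip property the tests assert. Noise days carry a single
core symptom and therefore can never create a false episode; real diaries
will contain messier near-miss patterns than this model produces.

The severity grade applies the age-dependent tachypnea thresholds (RR
strictly >50/min at ≥12 months, strictly >60/min below) plus retractions,
unconsciousness, or crackles, from examinations dated inside the episode;
unexamined episodes are graded non-severe and flagged. Person-time rates
are reported with both denominators (total days, and days excluding episode
days) because the at-risk adjustment is not fixed by the case definition.

## Exposure chain

For each monitored day (deployment window ≥18 h, 10-second samples):
optional pluggable nephelometer correction (applied to raw samples, before
any averaging), 10-minute trimmed means, length-5 running medians, daily
baseline, SIT, SIP/SIC.

Numerical conventions, pinned for reproducibility:

- "3% trimmed" = 3% per tail, `floor(n·0.03)` samples per side (1 of 60),
  always retaining ≥1 sample; a total-6% switch exists (`per_tail=False`).
- Intervals with <75% valid samples are invalid (NaN) and excluded from the
  baseline and SIT.
- Running median of 5 uses shrinking end windows (1, 3, 5, …, 3, 1) so the
  output length equals the input length; NaNs propagate in place and are
  excluded from neighbours' windows.
- Baseline = linear-interpolation 10th percentile of the day's filtered
  values (numpy's default quantile rule).
- SIT uses the strict inequality `filtered > 1.2 × baseline`; with a zero
  baseline every interval with positive filtered value qualifies.
- SIP sums `(unfiltered 10-min average − baseline)` over SIT intervals, in
  concentration·10-min units (also reported as concentration·hours and
  rescaled to a nominal 24 h). The filtered series only *selects* the
  intervals; `use_filtered=True` integrates filtered values instead. The
  sum is not clipped: a pathological trace in which an unfiltered average
  inside SIT dips below baseline could contribute negatively, which is
  reported as-is rather than masked.

The whole chain is scale-equivariant (SIT invariant, SIP homogeneous of
degree 1 in the trace), which the property tests exercise.

The trace generator produces near-rectangular cooking events (2-minute
cosine ramps, default 90 min duration) over a constant or slowly drifting
baseline with multiplicative log-normal noise and optional 1–2-sample
spikes. Events shorter than ~3 filter intervals would be attenuated by the
median filter; real traces have more irregular event shapes and diurnal
baselines than this model.

Before/after stove contrasts (annual, and restricted to ±2 months around
installation) come from a linear mixed model with household random
intercepts, harmonic season terms, and a linear secular-trend term;
households observed on only one side are excluded with a warning.

## Estimation

The analysis model is fitted by maximizing the Laplace-approximated
marginal likelihood, the same approximation family as `lme4::glmer`'s
default. Exploiting the nesting of children within sectors, the penalized
Hessian of the random effects is arrow-shaped within each sector, so the
joint Newton step over (β, b, c) and the Laplace log-determinant cost O(n):

- inner loop: damped Newton (PIRLS) on the penalized deviance, jointly over
  fixed effects and random-effect modes, convergence at relative deviance
  change < 1e-9, max 100 iterations;
- outer loop: Nelder–Mead over (log σ²_village, log σ²_child) of the
  Laplace deviance, warm-starting the inner state, xatol 1e-3, max 200
  iterations; variances are bounded to exp(±16) so boundary (≈0) variance
  fits are handled without reparameterization.

Model-based SEs come from the Schur complement of the joint Hessian
(conditional on the estimated variance parameters, as `glmer` reports).
On a common test panel the implementation agrees with `glmer` on θ to
~3×10⁻⁵ and on its SE to <1%; an adaptive Gauss–Hermite audit path
(15 nodes, single-level models) agrees with the Laplace θ to <0.01.

**Robust variance.** The sandwich estimator aggregates the envelope scores
`X_i'(y_i − p̂_i)` at the chosen cluster level with a G/(G−1) small-sample
factor around the model-based bread. The recorded decision rule: robust SEs
are adopted when they exceed the model-based SE by more than 1.2-fold.
Because the scores are evaluated at the conditional modes, dependence that
a cluster-level intercept can absorb is (correctly) not flagged; the tests
demonstrate detection of genuinely unmodelled dependence via duplicated
observations.

**Testing.** θ is tested by a Wald z against its model-based SE at α = 0.05
two-sided, which is also the rejection rule of the power simulation (the
field analysis may use robust SEs per the decision rule; the choice is a
switch).

**Spline basis.** `s(t, v)` uses the truncated-power natural cubic basis
(linear term + v−1 constrained cubics; interior knots at equally spaced
quantiles of the observed periods, boundary knots at min/max, columns
standardized for conditioning). The basis spans the same space as R's
`ns(t, df=v)` with matching knots; span properties (linear reproduction at
v=2, C² continuity, linearity beyond the boundaries) are tested rather than
basis-coefficient equality. v=1 is rejected; v=0 removes the time function.
A rank check guards against v too large for the observed periods, and the
v-sensitivity sweep reports such cells as NaN with a warning.

## Power and sample size

Each power-grid cell draws `n_sims` fresh replicates (new wedge order,
cohort, panel), fits the model at the scenario's `v_fit`, and reports the
Wald rejection percentage with its binomial Monte-Carlo SE; non-converged
replicates are dropped from the denominator and counted. Seed streams are
keyed by scenario content (θ, trend, v), not grid position, so cell results
are independent of evaluation order. Scaled-down runs are first-class and
carry a scale note in the output.

Problem sizes used by the shipped checks: the design-scale acceptance tests
run 100 replicates per targeted power cell (two no-trend cells), 100
replicates each for type-I error and coverage, and 15 replicates for the
v=0 trend-bias demonstration, with ~40,000 observations per replicate;
calibration checks use ≥2,000 simulated child-years, 5,000 sectors, and
50,000 birthweights.

The closed-form calculators are:

    MDD  = (z_{1−α/2} + z_power) · sd · sqrt(2·DE / n_per_group),
           DE = 1 + (m − 1)·ICC
    LBW power: pooled-variance normal approximation of the two-proportion
           z-test with effective n = n_per_group / DEFF

The study's printed sample-size outputs (57 g and 83 g detectable
differences, 47% and ">80%" low-birthweight power) depend on per-phase
cluster sizes and allocations that are not stated alongside them, so they
are not asserted numerically; the calculators are instead validated against
an independently derived closed-form value (50.5 g for 1,175 per arm, SD
437 g, no clustering) and a binomial simulation of the pooled z-test
(agreement within 2 points). Back-solving the standard formula, the 57 g
phase-1 figure would correspond to roughly 9 weighed births per sector at
ICC 0.03357 — plausible, but not stated, so not assumed.

## Reproducibility

All generators take either a seed or a `numpy.random.Generator`; for a
fixed seed every output is bit-reproducible, and the CLI records seeds, a
config hash, and the package version in a JSON manifest next to each
output set. Files are plain delimited text, ISO-8601 dates, 1-based period
and interval indices.

## Limitations

- The panel generator has full follow-up: no migration, dropout, ageing
  out, or stove-use noncompliance; power estimates are accordingly slightly
  optimistic relative to a field cohort.
- Seasonality-as-odds and the monthly binary response are approximations
  of an underlying episode process; multiple episodes within a month
  collapse to one positive period.
- The robust-variance scores use the conditional-mode envelope
  approximation (log-determinant derivative terms dropped), standard but
  approximate at small cluster counts.
- The nephelometer humidity correction is a pluggable hook (identity by
  default); fitting such a correction from gravimetric co-location data is
  out of scope.
- The exposure contrast model assumes a shared seasonal shape across
  households and linear secular trend.
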