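# Methods

## Data model and conventions

Time is measured in months everywhere. A `SurvivalDataset` holds strictly
positive observation times, 0/1 event indicators and (optionally) calendar
entry times for staggered accrual. Administrative data cuts operate on the
calendar scale: a database lock at calendar time L keeps events observed
before L and censors everyone else at L − entry. Cutting at L₁ and then at
L₀ < L₁ equals cutting once at L₀, which the tests assert.

Kaplan-Meier estimation follows the standard product-limit conventions:
ties are grouped, deaths are processed before censorings at an equal time
(so a patient censored at t is still at risk for a death at t), and the
curve is right-continuous. Point estimates and RMST are only defined
within the observed follow-up; queries beyond it raise rather than
extrapolate — extrapolation is exclusively the fitted models' job.
RMST under the KM curve is the exact area of the step function, not a
quadrature approximation.

## Smoothed hazard diagnostics

The hazard estimator convolves Nelson-Aalen increments d_j/n_j with an
Epanechnikov kernel on a uniform grid of 101 points over [0, max_time].
Within one bandwidth of either end, Mueller boundary kernels (zeroth
moment 1, first moment 0 on the truncated support) replace the symmetric
kernel, which removes the edge bias that would otherwise fake a hazard
decline near the lock date. Defaults: `max_time` should be set to the data
cut's minimum follow-up (beyond it few patients remain at risk and the
estimate is noise); the global bandwidth defaults to `max_time / 8`.
**The bandwidth default is a pragmatic choice** — there is no adaptive or
cross-validated selection — and materially shapes the curve; it is
exposed everywhere and should be varied in any serious application.

Shape classification walks the grid with a hysteresis filter: a new
turning point is only recorded when the curve moves more than
`tolerance × max(hazard)` (default 5%) past the running extremum. Zero
turning points ⇒ constant, one ⇒ monotone, two or more ⇒ non-monotone.
The screening rule maps shapes to rejected families: non-monotone rejects
exponential, Weibull and Gompertz; monotone rejects the exponential;
constant rejects nothing. On genuinely constant-hazard *data* the
finite-sample wiggle can still exceed 5% of the maximum, so the classifier
is a screening aid, not a test; the pipeline's strict mode drops rejected
families, advisory mode fits them anyway and only flags them.

## Standard parametric families

Six families with right-censored log-likelihood
Σ_events log f + Σ_censored log S: exponential (rate), Weibull
(shape, scale), Gompertz (shape ∈ ℝ, rate), lognormal (μ, σ),
log-logistic (shape, scale), and generalized gamma in the Prentice
(μ, σ, Q) parameterisation, which contains the lognormal at Q = 0 and the
Weibull at Q = 1. A negative Gompertz shape gives an improper distribution
with survival plateau exp(rate/shape); all reporting is RMST-based, which
stays finite, so this is allowed.

Fitting maximises the log-likelihood over transformed parameters (log for
positivity-constrained components) with Nelder-Mead followed by BFGS
polish, from method-of-moments style starts plus up to five jittered
restarts drawn from a fixed RNG — the whole schedule is deterministic
given the dataset, and stops early when two starts agree to 1e-6.
Non-convergence is flagged on the returned model, not raised. Maximised
log-likelihoods agree with lifelines to ~1e-8 on simulated data for the
overlapping families, and the Gompertz was verified once against an
independent reference implementation during development.

## Royston-Parmar splines

A natural cubic spline in x = log t models a transform of S:
η(x) = γ₀ + γ₁x + Σ γ_{j+1} v_j(x), with the truncated-cube basis
v_j(x) = (x−k_j)₊³ − λ_j(x−k_min)₊³ − (1−λ_j)(x−k_max)₊³,
λ_j = (k_max−k_j)/(k_max−k_min). η is exactly linear in log t beyond the
boundary knots — that linearity *is* the extrapolation contract of these
models. Scales: log cumulative hazard (S = exp(−e^η)), log cumulative
odds (S = 1/(1+e^η)), and probit (S = Φ(−η)); with no interior knots these
are exactly the Weibull, log-logistic and lognormal, which the tests
exploit as an equivalence oracle (0-knot configurations exist only for
that purpose; analyses use 1-3 interior knots — more tends to be
unstable at trial-sized n).

Boundary knots sit at the extreme log uncensored times; interior knots at
the median / {33⅓, 66⅔} / {25, 50, 75} percentiles of the log uncensored
times (linear-interpolation quantiles) for 1/2/3 knots. The likelihood's
event term involves dη/dx, which is not constrained to be positive:
parameter vectors with a non-positive density at an observed event get a
−∞ log-likelihood (a penalised objective, not a crash), and a fitted model
whose η is non-monotone over the knot span is flagged via `eta_monotone`
but not rejected. Optimisation starts from a least-squares regression of
the transformed KM estimate on the basis, falling back to the mapped
0-knot family fit padded with zeros.

## Scoring, ranking, accuracy

The five statistics are −2LL, AIC = −2LL + 2k,
AICc = AIC + (2k² + 2k)/(n − k − 1), HQC = −2LL + 2k ln ln n and
BIC = −2LL + k ln n; at n = 88 the per-parameter penalties are 2.0, ~3.0
and ~4.5 for AIC, HQC, BIC. −2LL is reported for context only and is
never used to rank non-nested models. Rankings sort ascending with ties
broken by fewer parameters then label, and annotate Δ-to-best with the
Burnham-Anderson (Δ ≤ 2) and Hilbe (Δ ≤ 2.5; Δ ≤ 6 and n ≤ 256) flags.
Scores are displayed to 1 dp; comparisons use full precision.

Prediction accuracy compares each fitted model with the KM curve of its
own cut (at that cut's minimum follow-up by default) and with the latest
cut (anchor and RMST horizon 36 months by default; the paper-style
protocol of mid/max anchors at roughly 6-monthly intervals is available
through the anchor configuration). Differences are model minus KM —
negative means the model underestimates survival — in percentage points
(PE) and months (RMST), rounded to 1 dp. `lifeyear_impact` converts an
RMST difference to life-years (÷12) and QALYs (× utility), to 2 dp.

## Synthetic trial generator

The generator's truth is the mixture S(t) = π S_long(t) + (1−π) S_short(t)
with a Weibull short-term component and a low-rate exponential long-term
component — the simplest shape producing a steep early fall, a
non-monotone hazard and a late plateau. It is deliberately *not* in the
fitted roster (no mixture/cure models are fitted), so every fitted model
is misspecified, as with real data. Calibration minimises squared survival
residuals at the published anchors (12/18/24/30/36 months) plus the
squared RMST(36) residual in survival-equivalent units (/36), by
`scipy.optimize.least_squares` from a fixed multistart grid; it is fully
deterministic. The calibrated default lands at π ≈ 0.316,
Weibull(1.21, 10.0), long-term rate at its 1e-6/month lower bound
(effectively a cured fraction), with anchor residuals ≤ 0.006,
S(36) = 32.2% and RMST(36) = 17.75 months.

Trials draw n = 88 entries uniformly over a 12-month accrual window
(the real accrual schedule is unpublished; 12 months is an assumption),
latent death times by inverse transform from the mixture, and independent
exponential dropout at 0.002/month (small, mimicking sparse
non-administrative censoring). Locks sit at accrual end + 12/18/24/36
months, so each cut guarantees at least that much follow-up per patient;
with uniform accrual the realised minimum follow-up slightly exceeds the
offset (by the gap between the last entry and the accrual end). Runs are
bit-reproducible from the seed.

What the generator does *not* emulate: response/progression intermediate
outcomes, background general-population mortality, calendar-time effects,
informative dropout, or the real trial's tie structure. Tests passing on
this generator therefore demonstrate the pipeline's internal correctness
and the qualitative screening/extrapolation behaviour, not fidelity to any
particular trial's patient-level data (which are not public).

## Numerical choices and problem sizes

Model RMST uses adaptive quadrature (absolute tolerance 1e-6); the
calibration objective uses a fixed 64-point Gauss-Legendre rule for speed
(error ≪ 1e-8 for these smooth mixtures). The generalized gamma switches
to its lognormal limit for |Q| < 1e-8; the Gompertz to its exponential
limit for |shape| < 1e-9 (series expansion of the cumulative hazard).
Simulation-based tests run at deliberately modest sizes chosen to make the
statistical assertions sharp but cheap: 100 seeds at n = 88 for the
screening/accuracy replication, n = 5000 for parameter recovery, n = 10⁴-10⁵
for generator consistency checks.

## Known limitations

- Single-arm data only: no covariates, treatment effects or
  proportional-hazards machinery.
- No interval censoring, left truncation, frailty or Bayesian fitting.
- Greenwood confidence intervals are not produced; uncertainty in the
  IC scores and accuracy differences is not quantified (the method is a
  model-selection protocol, not an inferential procedure).
- The hazard smoother's bandwidth is global and heuristic (see above).
- Mixture-cure, landmark/response-based and relative-survival approaches
  are intentionally out of scope.
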