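# survcuts

Evaluating parametric survival extrapolation across successive
administrative data cuts of a single-arm oncology trial.

## The problem

Health-technology assessment needs lifetime survival estimates long before
a trial's follow-up is complete. The standard practice is to fit parametric
survival models (PSMs) to the observed Kaplan-Meier data and extrapolate.
For immune-checkpoint inhibitors this is treacherous: overall survival
often falls steeply and then plateaus, so the hazard h(t) rises and then
falls, and the constant- or monotone-hazard families (exponential,
Weibull, Gompertz) are structurally wrong. With several pre-planned
database locks from the same trial — data cuts with 12, 18, 24 and 36
months of minimum patient follow-up — one can fit models to an early cut
and score their predictions against the later, more mature cuts.

`survcuts` implements that whole workflow as a library plus CLI:

- **Kaplan-Meier estimation** with point estimates S(t) and restricted
  mean survival time, RMST(τ) = ∫₀^τ S(t) dt (exact step-function area);
- **administrative data cuts**: a database lock at calendar time L turns a
  calendar-anchored cohort into a right-censored dataset with minimum
  follow-up L − (end of accrual);
- **hazard screening**: Epanechnikov-kernel smoothing of the Nelson-Aalen
  increments (with boundary-kernel correction) and a shape classifier that
  rejects families whose functional form the smoothed hazard contradicts;
- **six standard PSMs** — exponential, Weibull, Gompertz, lognormal,
  log-logistic, generalized gamma (μ, σ, Q parameterisation) — fitted by
  right-censored maximum likelihood;
- **Royston-Parmar spline PSMs**: a natural cubic spline in log t models
  log H(t), log odds(t) or −probit S(t) with 1-3 interior knots placed at
  percentiles of the log uncensored survival times;
- **goodness of fit**: −2LL, AIC, AICc, HQC and BIC, with Δ-score rules of
  thumb (Burnham-Anderson Δ ≤ 2 "substantial empirical support"; Hilbe
  Δ ≤ 2.5 / Δ ≤ 6 at n ≤ 256);
- **prediction accuracy**: model-vs-KM survival differences (percentage
  points) and RMST differences (months) against both the fitted cut and
  the latest cut, plus the life-year/QALY conversion of an RMST error;
- **a calibrated synthetic trial generator**: an n = 88 cohort with
  staggered accrual and four locks, whose mixture survivor function is
  least-squares calibrated to published KM anchors
  (S(12)=51.8%, …, S(36)=32.1%; RMST(36)=17.5 months).

## Worked example

```python
import survcuts as sc

# evaluate a synthetic trial (n=88, four data cuts), small model roster
cfg = sc.RunConfig(seed=1, spline_knots=(1,), spline_scales=("odds", "normal"))
bundle = sc.run_evaluation(cfg)

cut = bundle["cuts"]["12mo"]
print("screening:", cut["screening"]["shape"], "->", cut["screening"]["rejected"])
for r in cut["rankings"]["AIC"]:
    print(f"{r['label']:<14} AIC {r['score']:6.1f}  delta {r['delta']:4.1f}  "
          f"support={r['burnham_anderson_support']}")
row = [r for r in bundle["accuracy"]
       if r["cut"] == "12mo" and r["model"] == "1-knot odds"][0]
print("1-knot odds vs latest cut: PE diff", row["pe_diff_latest"],
      "pp; RMST diff", row["rmst_diff_latest"], "months")
print(sc.lifeyear_impact(row["rmst_diff_latest"], utility=0.71))
```

prints

```
screening: non_monotone -> ['exponential', 'gompertz', 'weibull']
loglogistic    AIC  386.5  delta  0.0  support=True
1-knot odds    AIC  388.5  delta  2.0  support=True
1-knot normal  AIC  388.8  delta  2.3  support=False
lognormal      AIC  388.9  delta  2.5  support=False
gengamma       AIC  389.4  delta  3.0  support=False
1-knot odds vs latest cut: PE diff -2.7 pp; RMST diff 0.2 months
(0.02, 0.01)
```

Read: the smoothed hazard of the 12-month cut rises then falls, so the
three monotone-hazard families are screened out before fitting. Among the
survivors the log-logistic has the best AIC, but the 1-knot odds spline is
within 2 points (Δ = 2.0), i.e. it has substantial empirical support and
should not be discarded on AIC alone. Compared with the 36-month cut's KM
curve, that spline misses 36-month survival by −2.7 percentage points and
36-month RMST by +0.2 months — worth +0.02 life-years (+0.01 QALYs at a
utility of 0.71) if carried into an economic model.

The same run is available from the shell:

```sh
survcuts all --seed 1 --out results/run1        # fit, score, plots, summary.md
survcuts simulate --seed 1 --out results/data   # just the synthetic data cuts
```

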