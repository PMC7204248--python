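"""Goodness-of-fit scoring, model ranking, and prediction accuracy.

Five statistics per model, all penalised forms of -2 log L:

    -2LL  = -2 log L
    AIC   = -2LL + 2k
    AICc  = AIC + (2k^2 + 2k) / (n - k - 1)
    HQC   = -2LL + 2k ln(ln n)
    BIC   = -2LL + k ln(n)

At n = 88 the per-parameter penalties are 2.0 (AIC), about 3.0 (HQC) and
about 4.5 (BIC), so the criteria differ only in how hard extra flexibility
is punished.  Ranking annotates each non-best model with its score gap to
the best and the usual rules of thumb: Burnham & Anderson's "substantial
empirical support" at a gap <= 2; Hilbe's "no difference" at <= 2.5 and
"retain unless n > 256" at <= 6.

Prediction accuracy compares a fitted model with the Kaplan-Meier estimate
of the data cut it was fitted to and with the latest available cut, both as
a point estimate of survival at an anchor time (percentage points) and as
restricted mean survival time (months).  Negative differences mean the
model underestimates survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data import StepSurvivalCurve, rmst_km, survival_at
from .parametric import FittedModel, model_rmst, model_survival

__all__ = [
    "ICScores",
    "RankedModel",
    "AccuracyReport",
    "information_criteria",
    "rank_models",
    "prediction_accuracy",
    "lifeyear_impact",
    "CRITERIA",
]

CRITERIA = ("minus2LL", "AIC", "AICc", "HQC", "BIC")


@dataclass(frozen=True)
class ICScores:
    minus2LL: float
    AIC: float
    AICc: float
    HQC: float
    BIC: float
    k: int
    n: int

    def score(self, criterion: str) -> float:
        if criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {criterion!r}")
        return getattr(self, criterion)


@dataclass(frozen=True)
class RankedModel:
    label: str
    score: float
    k: int
    rank: int
    delta: float
    burnham_anderson_support: bool
    hilbe_no_difference: bool
    hilbe_retain_small_n: bool


@dataclass(frozen=True)
class AccuracyReport:
    model: str
    pe_diff_fitted: float
    pe_diff_latest: float
    rmst_diff_fitted: float
    rmst_diff_latest: float
    anchor_fitted: float
    anchor_latest: float
    tau_latest: float


def information_criteria(loglik: float, k: int, n: int) -> ICScores:
    """The five goodness-of-fit statistics from a maximised log-likelihood."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if n <= k + 1:
        raise ValueError(f"AICc undefined: need n > k + 1, got n={n}, k={k}")
    if n <= math.e:
        raise ValueError(f"HQC undefined: need n > e, got n={n}")
    minus2ll = -2.0 * loglik
    aic = minus2ll + 2.0 * k
    aicc = aic + (2.0 * k * k + 2.0 * k) / (n - k - 1)
    hqc = minus2ll + 2.0 * k * math.log(math.log(n))
    bic = minus2ll + k * math.log(n)
    return ICScores(minus2LL=minus2ll, AIC=aic, AICc=aicc, HQC=hqc, BIC=bic, k=k, n=n)


def rank_models(
    scores: list[tuple[str, ICScores]], criterion: str
) -> list[RankedModel]:
    """Ascending ranking under one criterion with score-gap rules of thumb.

    Ties are broken by fewer parameters, then label.  All models must share
    the same n (scores on different sample sizes are not comparable).
    """
    if len(scores) < 2:
        raise ValueError("ranking needs at least 2 models")
    ns = {s.n for _, s in scores}
    if len(ns) > 1:
        raise ValueError(f"models fitted to different sample sizes are not comparable: {ns}")
    n = ns.pop()
    ordered = sorted(scores, key=lambda it: (it[1].score(criterion), it[1].k, it[0]))
    best = ordered[0][1].score(criterion)
    out = []
    for rank, (label, sc) in enumerate(ordered, start=1):
        delta = sc.score(criterion) - best
        out.append(
            RankedModel(
                label=label,
                score=sc.score(criterion),
                k=sc.k,
                rank=rank,
                delta=delta,
                burnham_anderson_support=delta <= 2.0,
                hilbe_no_difference=delta <= 2.5,
                hilbe_retain_small_n=(delta <= 6.0 and n <= 256),
            )
        )
    return out


def prediction_accuracy(
    m: FittedModel,
    km_fitted: StepSurvivalCurve,
    km_latest: StepSurvivalCurve,
    anchor_fitted: float,
    anchor_latest: float,
    tau_latest: float | None = None,
) -> AccuracyReport:
    """Model-vs-KM accuracy against the fitted cut and the latest cut.

    Point-estimate differences are 100*(S_model - S_KM) at the anchor times,
    in percentage points; RMST differences are model RMST minus KM RMST over
    [0, anchor_fitted] and [0, tau_latest] respectively, in months.  All four
    are rounded to 1 decimal place, matching the reporting convention.
    """
    if tau_latest is None:
        tau_latest = anchor_latest
    pe_f = 100.0 * (model_survival(m, anchor_fitted) - survival_at(km_fitted, anchor_fitted))
    pe_l = 100.0 * (model_survival(m, anchor_latest) - survival_at(km_latest, anchor_latest))
    rm_f = model_rmst(m, anchor_fitted) - rmst_km(km_fitted, anchor_fitted)
    rm_l = model_rmst(m, tau_latest) - rmst_km(km_latest, tau_latest)
    return AccuracyReport(
        model=m.name,
        pe_diff_fitted=round(pe_f, 1),
        pe_diff_latest=round(pe_l, 1),
        rmst_diff_fitted=round(rm_f, 1),
        rmst_diff_latest=round(rm_l, 1),
        anchor_fitted=anchor_fitted,
        anchor_latest=anchor_latest,
        tau_latest=tau_latest,
    )


def lifeyear_impact(rmst_diff_months: float, utility: float) -> tuple[float, float]:
    """Convert an RMST difference to (life-years, QALYs), each rounded to 2 dp.

    QALYs are utility-weighted life-years; utility must lie in [0, 1].
    """
    if not 0.0 <= utility <= 1.0:
        raise ValueError(f"utility must be in [0, 1], got {utility}")
    life_years = rmst_diff_months / 12.0
    qalys = utility * life_years
    return round(life_years, 2), round(qalys, 2)
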