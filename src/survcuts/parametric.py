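"""Maximum-likelihood fitting of standard parametric survival models to
right-censored data, and survival / RMST evaluation of fitted models.

The right-censored log-likelihood is

    l(theta) = sum_{events} log f(t_i; theta) + sum_{censored} log S(t_i; theta).

Optimisation is quasi-Newton on transformed parameters (log transform for
positivity-constrained components), started from method-of-moments style
heuristics with a fixed, deterministic schedule of jittered restarts, so a
fit is fully reproducible from the dataset alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

from . import families
from .data import SurvivalDataset

__all__ = ["FittedModel", "loglik", "fit_mle", "model_survival", "model_hazard", "model_rmst"]

_PENALTY = -1e10


class FitError(ValueError):
    """The dataset cannot support the requested fit."""


@dataclass(frozen=True)
class FittedModel:
    """A fitted parametric survival model (standard family or spline).

    ``k`` is the number of estimated parameters, ``loglik`` the maximised
    right-censored log-likelihood.  Spline models additionally record the
    transformation ``scale`` (hazard / odds / normal) and the log-time
    ``knots`` (boundary + interior, ascending).
    """

    family: str
    params: tuple
    k: int
    loglik: float
    n: int
    scale: str | None = None
    knots: tuple | None = None
    converged: bool = True
    label: str = ""

    @property
    def name(self) -> str:
        if self.family == "spline":
            m = len(self.knots) - 2
            return f"{m}-knot {self.scale}"
        return self.family

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "scale": self.scale,
            "params": list(self.params),
            "k": self.k,
            "loglik": self.loglik,
            "n": self.n,
            "knots": list(self.knots) if self.knots is not None else None,
            "converged": self.converged,
            "label": self.label,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def loglik(family: str, params, ds: SurvivalDataset) -> float:
    """Right-censored log-likelihood of a standard family on a dataset."""
    t = ds.times_array()
    e = ds.events_array()
    lp = families.logpdf(family, params, t)
    ls = families.logsf(family, params, t)
    contrib = np.where(e == 1, lp, ls)
    if not np.all(np.isfinite(contrib)):
        return -np.inf
    return float(contrib.sum())


# ---------------------------------------------------------------------------
# parameter transforms: optimisation runs on an unconstrained scale


_LOG_MASK = {
    "exponential": (True,),
    "weibull": (True, True),
    "gompertz": (False, True),
    "lognormal": (False, True),
    "loglogistic": (True, True),
    "gengamma": (False, True, False),
}


def _to_unconstrained(family, params):
    return np.array(
        [np.log(p) if lg else p for p, lg in zip(params, _LOG_MASK[family])]
    )


def _from_unconstrained(family, x):
    return np.array([np.exp(v) if lg else v for v, lg in zip(x, _LOG_MASK[family])])


def _starting_values(family: str, ds: SurvivalDataset) -> np.ndarray:
    """Method-of-moments style starting heuristics on the natural scale."""
    t = ds.times_array()
    d = max(ds.n_events, 1)
    total_time = t.sum()
    rate = d / total_time
    lt = np.log(ds.uncensored_times()) if ds.n_events else np.log(t)
    mu, sd = float(np.mean(lt)), float(np.std(lt))
    sd = max(sd, 0.2)
    if family == "exponential":
        return np.array([rate])
    if family == "weibull":
        # log of a Weibull is Gumbel: sd = pi/(shape*sqrt(6))
        shape = np.pi / (sd * np.sqrt(6.0))
        scale = np.exp(mu + np.euler_gamma * sd)
        return np.array([shape, scale])
    if family == "gompertz":
        return np.array([0.01, rate])
    if family == "lognormal":
        return np.array([mu, sd])
    if family == "loglogistic":
        return np.array([np.pi / (sd * np.sqrt(3.0)), np.exp(mu)])
    if family == "gengamma":
        return np.array([mu, sd, 0.5])
    raise ValueError(f"unknown family {family!r}")


def _maximise(nll, x0: np.ndarray, n_restarts: int = 5):
    """Deterministic multistart quasi-Newton maximisation.

    Restarts jitter the start with a fixed RNG so the whole schedule is a
    pure function of x0.
    """
    rng = np.random.default_rng(12345)
    best = None
    starts = [x0] + [x0 + rng.normal(scale=0.4, size=x0.size) for _ in range(n_restarts)]
    for s in starts:
        res = optimize.minimize(nll, s, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        res2 = optimize.minimize(nll, res.x, method="BFGS",
                                 options={"gtol": 1e-8, "maxiter": 500})
        cand = res2 if res2.fun <= res.fun else res
        if best is None or cand.fun < best.fun - 1e-10:
            best = cand
        # stop early once two independent starts agree to tight tolerance
        if s is not starts[0] and abs(cand.fun - best.fun) < 1e-6:
            break
    return best


def fit_mle(family: str, ds: SurvivalDataset, label: str | None = None) -> FittedModel:
    """Fit a standard parametric family by maximum likelihood.

    Non-convergence is flagged on the returned model rather than raised;
    a dataset with zero events cannot identify any family and raises.
    """
    if family not in families.FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if ds.n_events == 0:
        raise FitError("cannot fit a parametric model to a dataset with no events")

    def nll(x):
        try:
            p = _from_unconstrained(family, x)
            ll = loglik(family, p, ds)
        except (families.ParameterDomainError, FloatingPointError):
            return -_PENALTY
        if not np.isfinite(ll):
            return -_PENALTY
        return -ll

    x0 = _to_unconstrained(family, _starting_values(family, ds))
    res = _maximise(nll, x0)
    params = _from_unconstrained(family, res.x)
    ll = -res.fun
    converged = bool(np.isfinite(ll)) and ll > _PENALTY / 2
    return FittedModel(
        family=family,
        params=tuple(float(p) for p in params),
        k=families.N_PARAMS[family],
        loglik=float(ll),
        n=ds.n,
        converged=converged,
        label=label if label is not None else ds.label,
    )


def model_survival(m: FittedModel, t) -> np.ndarray | float:
    """S(t) of a fitted model, defined for every t >= 0 (the extrapolation surface)."""
    if m.family == "spline":
        from .splines import spline_survival_model

        return spline_survival_model(m, t)
    out = families.sf(m.family, m.params, t)
    return float(out) if np.isscalar(t) else out


def model_hazard(m: FittedModel, t) -> np.ndarray | float:
    if m.family == "spline":
        from .splines import spline_hazard_model

        return spline_hazard_model(m, t)
    out = families.hazard(m.family, m.params, t)
    return float(out) if np.isscalar(t) else out


def model_rmst(m: FittedModel, tau: float) -> float:
    """Restricted mean survival time: integral of S over [0, tau] by adaptive quadrature."""
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    if tau == 0:
        return 0.0
    val, err = integrate.quad(
        lambda t: model_survival(m, float(t)), 0.0, tau, epsabs=1e-6, limit=200
    )
    if not np.isfinite(val):
        raise ArithmeticError("non-finite survival encountered during RMST quadrature")
    return float(val)
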