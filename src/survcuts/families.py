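"""Standard parametric survival families: log-density, log-survival, survival.

All families are parameterised on their natural scale (rates, shapes and
scales strictly positive where the distribution requires it):

=============  ==========================  =========================================
family         params                      survivor function S(t)
=============  ==========================  =========================================
exponential    (rate,)                     exp(-rate*t)
weibull        (shape, scale)              exp(-(t/scale)^shape)
gompertz       (shape, rate)               exp(-(rate/shape)*(exp(shape*t)-1))
lognormal      (mu, sigma)                 1 - Phi((log t - mu)/sigma)
loglogistic    (shape, scale)              1/(1 + (t/scale)^shape)
gengamma       (mu, sigma, Q)              Prentice parameterisation (see below)
=============  ==========================  =========================================

The generalised gamma uses the (mu, sigma, Q) parameterisation of Prentice:
with w = (log t - mu)/sigma and gamma = Q^-2, the variate u = gamma*exp(Q*w)
is Gamma(gamma, 1).  Q -> 0 recovers the lognormal, Q = 1 the Weibull, and
Q = sigma the ordinary gamma.  The Gompertz shape may be any real number; a
negative shape gives an improper distribution with survival plateau
exp(rate/shape), which is the standard convention for this family.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.stats import norm

FAMILIES = ("exponential", "weibull", "gompertz", "lognormal", "loglogistic", "gengamma")

#: number of parameters per family
N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gengamma": 3,
}

# Gompertz shape below this magnitude is treated as the exponential limit.
_GOMPERTZ_EPS = 1e-9
# |Q| below this is treated as the lognormal limit of the gengamma.
_GENGAMMA_Q_EPS = 1e-8


class ParameterDomainError(ValueError):
    """Raised when a parameter vector lies outside the family's domain."""


def _check(family: str, params) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if params.shape != (N_PARAMS[family],):
        raise ParameterDomainError(
            f"{family} expects {N_PARAMS[family]} parameters, got {params.shape}"
        )
    if not np.all(np.isfinite(params)):
        raise ParameterDomainError(f"{family}: non-finite parameters {params}")
    positive = {
        "exponential": [0],
        "weibull": [0, 1],
        "gompertz": [1],  # shape may be negative
        "lognormal": [1],
        "loglogistic": [0, 1],
        "gengamma": [1],
    }[family]
    for i in positive:
        if params[i] <= 0:
            raise ParameterDomainError(
                f"{family}: parameter {i} must be positive, got {params[i]}"
            )
    return params


def _gompertz_cumhaz(a: float, b: float, t: np.ndarray) -> np.ndarray:
    # H(t) = (b/a)(e^{at}-1); series expansion avoids 0/0 at the exponential limit
    if abs(a) < _GOMPERTZ_EPS:
        return b * t * (1.0 + a * t / 2.0)
    return (b / a) * np.expm1(a * t)


def logsf(family: str, params, t) -> np.ndarray:
    """log S(t) for the family, elementwise over t > 0."""
    p = _check(family, params)
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        if family == "exponential":
            return -p[0] * t
        if family == "weibull":
            k, lam = p
            return -((t / lam) ** k)
        if family == "gompertz":
            a, b = p
            return -_gompertz_cumhaz(a, b, t)
        if family == "lognormal":
            mu, sigma = p
            return norm.logsf(np.log(t), mu, sigma)
        if family == "loglogistic":
            k, lam = p
            return -np.log1p((t / lam) ** k)
        # gengamma
        mu, sigma, q = p
        if abs(q) < _GENGAMMA_Q_EPS:
            return norm.logsf(np.log(t), mu, sigma)
        gam = q ** -2
        w = (np.log(t) - mu) / sigma
        u = gam * np.exp(q * w)
        s = special.gammaincc(gam, u) if q > 0 else special.gammainc(gam, u)
        return np.log(np.clip(s, 1e-320, 1.0))


def logpdf(family: str, params, t) -> np.ndarray:
    """log f(t) for the family, elementwise over t > 0."""
    p = _check(family, params)
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if family == "exponential":
            return np.log(p[0]) - p[0] * t
        if family == "weibull":
            k, lam = p
            z = t / lam
            return np.log(k / lam) + (k - 1.0) * np.log(z) - z ** k
        if family == "gompertz":
            a, b = p
            return np.log(b) + a * t - _gompertz_cumhaz(a, b, t)
        if family == "lognormal":
            mu, sigma = p
            return norm.logpdf(np.log(t), mu, sigma) - np.log(t)
        if family == "loglogistic":
            k, lam = p
            z = (t / lam) ** k
            return np.log(k / lam) + (k - 1.0) * np.log(t / lam) - 2.0 * np.log1p(z)
        mu, sigma, q = p
        if abs(q) < _GENGAMMA_Q_EPS:
            return norm.logpdf(np.log(t), mu, sigma) - np.log(t)
        gam = q ** -2
        w = (np.log(t) - mu) / sigma
        return (
            np.log(abs(q))
            + gam * np.log(gam)
            + gam * q * w
            - gam * np.exp(q * w)
            - special.gammaln(gam)
            - np.log(sigma)
            - np.log(t)
        )


def sf(family: str, params, t) -> np.ndarray:
    """Survivor function S(t); S(0) = 1 by convention for every family."""
    t = np.asarray(t, dtype=float)
    out = np.exp(logsf(family, params, np.where(t > 0, t, 1.0)))
    return np.where(t > 0, out, 1.0)


def hazard(family: str, params, t) -> np.ndarray:
    """Instantaneous hazard f(t)/S(t)."""
    return np.exp(logpdf(family, params, t) - logsf(family, params, t))
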