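"""Royston-Parmar flexible parametric survival models.

A natural cubic spline in x = log t models a transformation of the survivor
function:

    eta(x) = gamma_0 + gamma_1 x + sum_j gamma_{j+1} v_j(x)

with basis functions built from truncated cubes around interior knots k_j
and boundary knots k_min < k_max,

    v_j(x) = (x - k_j)_+^3 - lam_j (x - k_min)_+^3 - (1 - lam_j)(x - k_max)_+^3,
    lam_j = (k_max - k_j) / (k_max - k_min),

which makes eta linear in x outside the boundary knots (the natural-spline
extrapolation contract).  Three transformation scales are supported, each
reducing to a standard two-parameter family when there are no interior
knots:

    hazard:  log H(t)            = eta  ->  S = exp(-exp(eta))   (Weibull at m=0)
    odds:    log[(1-S)/S]        = eta  ->  S = 1/(1+exp(eta))   (log-logistic at m=0)
    normal:  -probit(S)          = eta  ->  S = Phi(-eta)        (lognormal at m=0)

Interior knots sit at quantiles of the log uncensored survival times
(median for 1 knot; 33.3/66.7 for 2; 25/50/75 for 3), boundary knots at the
extreme log uncensored times.  The density needed for the event
contributions of the right-censored log-likelihood involves d eta/dx, which
the model does not constrain to be positive; parameter vectors that make
the density negative anywhere at an observed event are handled with a
penalised objective during fitting, and a fitted model whose eta is
non-monotone over the observed range is flagged, not rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .data import SurvivalDataset, km_estimate
from .parametric import FittedModel, FitError, _maximise, fit_mle

__all__ = [
    "SplineSpec",
    "place_knots",
    "spline_basis",
    "spline_survival",
    "fit_spline",
    "spline_loglik",
]

SCALES = ("hazard", "odds", "normal")

#: the two-parameter family each scale extends at zero interior knots
SCALE_FAMILY = {"hazard": "weibull", "odds": "loglogistic", "normal": "lognormal"}


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a Royston-Parmar spline on one transformation scale."""

    transform_scale: str
    interior_knots: tuple
    boundary_knots: tuple

    def __post_init__(self):
        if self.transform_scale not in SCALES:
            raise ValueError(f"unknown scale {self.transform_scale!r}")
        lo, hi = self.boundary_knots
        ks = (lo, *self.interior_knots, hi)
        if any(a >= b for a, b in zip(ks, ks[1:])):
            raise ValueError(f"knots must be strictly ascending, got {ks}")

    @property
    def n_interior(self) -> int:
        return len(self.interior_knots)

    @property
    def all_knots(self) -> tuple:
        return (self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1])


def place_knots(ds: SurvivalDataset, n_interior: int) -> tuple:
    """Knot locations from the log uncensored survival times.

    Returns (interior_knots, boundary_knots) in log-time.  Boundary knots sit
    at the extreme log uncensored times; interior knots at the
    {50} / {33.3, 66.7} / {25, 50, 75} percentiles (linear-interpolation
    quantiles) for 1 / 2 / 3 interior knots.
    """
    if n_interior not in (0, 1, 2, 3):
        raise ValueError("n_interior must be in {0, 1, 2, 3}")
    lt = np.log(ds.uncensored_times())
    if np.unique(lt).size < n_interior + 2:
        raise FitError(
            f"need at least {n_interior + 2} distinct uncensored times for "
            f"{n_interior} interior knots, have {np.unique(lt).size}"
        )
    boundary = (float(lt.min()), float(lt.max()))
    if n_interior == 0:
        return (), boundary
    probs = {1: [50.0], 2: [100 / 3, 200 / 3], 3: [25.0, 50.0, 75.0]}[n_interior]
    interior = tuple(float(np.percentile(lt, p)) for p in probs)
    return interior, boundary


def spline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Natural cubic spline basis (1, x, v_1(x), ..., v_m(x)); rows follow x."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kmin, kmax = spec.boundary_knots
    cols = [np.ones_like(x), x]
    span = kmax - kmin
    for kj in spec.interior_knots:
        lam = (kmax - kj) / span
        v = (
            np.clip(x - kj, 0, None) ** 3
            - lam * np.clip(x - kmin, 0, None) ** 3
            - (1 - lam) * np.clip(x - kmax, 0, None) ** 3
        )
        cols.append(v)
    return np.column_stack(cols)


def _basis_deriv(x, spec: SplineSpec) -> np.ndarray:
    """d/dx of the basis, same layout as :func:`spline_basis`."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kmin, kmax = spec.boundary_knots
    cols = [np.zeros_like(x), np.ones_like(x)]
    span = kmax - kmin
    for kj in spec.interior_knots:
        lam = (kmax - kj) / span
        dv = (
            3 * np.clip(x - kj, 0, None) ** 2
            - 3 * lam * np.clip(x - kmin, 0, None) ** 2
            - 3 * (1 - lam) * np.clip(x - kmax, 0, None) ** 2
        )
        cols.append(dv)
    return np.column_stack(cols)


def _eta(gamma, spec, x):
    return spline_basis(x, spec) @ np.asarray(gamma, dtype=float)


def _surv_from_eta(scale: str, eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        if scale == "hazard":
            return np.exp(-np.exp(eta))
        if scale == "odds":
            return 1.0 / (1.0 + np.exp(eta))
        return norm.sf(eta)  # Phi(-eta)


def spline_survival(scale: str, gamma, spec: SplineSpec, t) -> np.ndarray | float:
    """Survivor function of the spline model at time t > 0 (S(0+) = 1)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.ones_like(t_arr)
    pos = t_arr > 0
    eta = _eta(gamma, spec, np.log(t_arr[pos]))
    out[pos] = _surv_from_eta(scale, eta)
    return float(out[0]) if np.isscalar(t) else out


def spline_loglik(scale: str, gamma, spec: SplineSpec, ds: SurvivalDataset) -> float:
    """Right-censored log-likelihood; -inf if the density is non-positive at any event."""
    t = ds.times_array()
    e = ds.events_array() == 1
    x = np.log(t)
    eta = _eta(gamma, spec, x)
    deta = _basis_deriv(x, spec) @ np.asarray(gamma, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if scale == "hazard":
            log_s = -np.exp(eta)
            log_f = eta + np.log(deta) - x + log_s
        elif scale == "odds":
            log_s = -np.logaddexp(0.0, eta)
            log_f = eta + np.log(deta) - x + 2.0 * log_s
        else:
            log_s = norm.logsf(eta)
            log_f = norm.logpdf(eta) + np.log(deta) - x
    contrib = np.where(e, log_f, log_s)
    if not np.all(np.isfinite(contrib)):
        return -np.inf
    return float(contrib.sum())


def _initial_gamma(scale: str, spec: SplineSpec, ds: SurvivalDataset) -> np.ndarray:
    """Initialise gamma by regressing the transformed KM estimate on the basis.

    Falls back to the 0-knot standard-family fit (mapped into gamma, padded
    with zeros) when the regression is degenerate.
    """
    km = km_estimate(ds)
    t = np.asarray(km.event_times)
    s = np.asarray(km.survival)
    keep = (s > 1e-8) & (s < 1 - 1e-8)
    m = spec.n_interior
    if keep.sum() >= m + 2:
        x = np.log(t[keep])
        sv = s[keep]
        if scale == "hazard":
            z = np.log(-np.log(sv))
        elif scale == "odds":
            z = np.log((1 - sv) / sv)
        else:
            z = -norm.ppf(sv)
        basis = spline_basis(x, spec)
        gamma, *_ = np.linalg.lstsq(basis, z, rcond=None)
        if np.all(np.isfinite(gamma)) and gamma[1] > 0:
            return gamma
    base = fit_mle(SCALE_FAMILY[scale], ds)
    gamma = np.zeros(m + 2)
    if scale == "hazard":
        shape, lam = base.params
        gamma[0], gamma[1] = -shape * np.log(lam), shape
    elif scale == "odds":
        shape, lam = base.params
        gamma[0], gamma[1] = -shape * np.log(lam), shape
    else:
        mu, sigma = base.params
        gamma[0], gamma[1] = -mu / sigma, 1.0 / sigma
    return gamma


def fit_spline(
    scale: str,
    n_interior: int,
    ds: SurvivalDataset,
    label: str | None = None,
) -> FittedModel:
    """Fit a Royston-Parmar spline model by maximum likelihood.

    The returned model records k = n_interior + 2 parameters and the full
    (boundary + interior) log-time knot vector.  ``converged`` is False if
    optimisation failed; a non-monotone fitted eta over the observed
    log-time range sets ``converged`` True but is reported via
    :func:`eta_monotone` (flag, not rejection).
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    interior, boundary = place_knots(ds, n_interior)
    spec = SplineSpec(scale, interior, boundary)

    def nll(gamma):
        ll = spline_loglik(scale, gamma, spec, ds)
        return 1e10 if not np.isfinite(ll) else -ll

    g0 = _initial_gamma(scale, spec, ds)
    res = _maximise(nll, np.asarray(g0, dtype=float))
    ll = -res.fun
    converged = bool(np.isfinite(ll)) and ll > -1e9
    return FittedModel(
        family="spline",
        params=tuple(float(g) for g in res.x),
        k=n_interior + 2,
        loglik=float(ll),
        n=ds.n,
        scale=scale,
        knots=spec.all_knots,
        converged=converged,
        label=label if label is not None else ds.label,
    )


def _spec_of(m: FittedModel) -> SplineSpec:
    return SplineSpec(m.scale, tuple(m.knots[1:-1]), (m.knots[0], m.knots[-1]))


def spline_survival_model(m: FittedModel, t):
    return spline_survival(m.scale, m.params, _spec_of(m), t)


def spline_hazard_model(m: FittedModel, t):
    spec = _spec_of(m)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    x = np.log(t_arr)
    gamma = np.asarray(m.params)
    eta = _eta(gamma, spec, x)
    deta = _basis_deriv(x, spec) @ gamma
    s = _surv_from_eta(m.scale, eta)
    with np.errstate(over="ignore"):
        if m.scale == "hazard":
            h = deta / t_arr * np.exp(eta)
        elif m.scale == "odds":
            h = deta / t_arr * np.exp(eta) / (1.0 + np.exp(eta))
        else:
            h = norm.pdf(eta) * deta / t_arr / np.clip(s, 1e-320, None)
    return float(h[0]) if np.isscalar(t) else h


def eta_monotone(m: FittedModel, n_grid: int = 200) -> bool:
    """True if d eta/dx >= 0 across the observed log-time range (knot span)."""
    spec = _spec_of(m)
    x = np.linspace(m.knots[0], m.knots[-1], n_grid)
    deta = _basis_deriv(x, spec) @ np.asarray(m.params)
    return bool(np.all(deta >= 0))
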