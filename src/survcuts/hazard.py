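"""Kernel-smoothed hazard estimation and hazard-shape model screening.

The estimator convolves the increments of the Nelson-Aalen cumulative hazard
with an Epanechnikov kernel,

    h_hat(t) = sum_j K_b(t, t_j) * d_j / n_j,

where d_j deaths out of n_j at risk occur at event time t_j and b is a
global bandwidth.  Within b of 0 or of ``max_time`` the symmetric kernel
would lose mass and bias the estimate downwards, so the Mueller boundary
kernels for the Epanechnikov family are used there: for q = t/b in [0, 1)
and u = (t - s)/b restricted to [-1, q],

    K_q(u) = 12 (1 + u) / (1 + q)^4 * [ u (1 - 2q) + (3q^2 - 2q + 1)/2 ],

which integrates to one with vanishing first moment on the truncated
support (mirrored at the right boundary).

The screening rule turns the smoothed curve into a shape label and a list of
parametric families whose hazard cannot take that shape: a non-monotone
(rise-and-fall) hazard rules out the constant-hazard exponential and the
monotone-hazard Weibull and Gompertz; a monotone hazard rules out only the
exponential; a constant hazard rules out nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset

__all__ = ["HazardCurve", "HazardShape", "smoothed_hazard", "classify_hazard_shape"]

#: families whose functional form a given shape label contradicts
REJECTION_RULE = {
    "constant": frozenset(),
    "monotone_increasing": frozenset({"exponential"}),
    "monotone_decreasing": frozenset({"exponential"}),
    "non_monotone": frozenset({"exponential", "weibull", "gompertz"}),
}


class DiagnosticError(ValueError):
    """The data cannot support a hazard diagnostic."""


@dataclass(frozen=True)
class HazardCurve:
    grid: tuple
    hazard: tuple
    bandwidth: float
    max_time: float

    def __post_init__(self):
        h = np.asarray(self.hazard, dtype=float)
        if not np.all(np.isfinite(h)) or np.any(h < 0):
            raise DiagnosticError("hazard values must be finite and non-negative")


@dataclass(frozen=True)
class HazardShape:
    label: str
    rejected_families: frozenset


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    out = 0.75 * (1.0 - u ** 2)
    return np.where(np.abs(u) <= 1.0, out, 0.0)


def _boundary_kernel(u: np.ndarray, q: float) -> np.ndarray:
    """Mueller boundary Epanechnikov kernel on support u in [-1, q], q in [0, 1)."""
    out = (
        12.0
        * (1.0 + u)
        / (1.0 + q) ** 4
        * (u * (1.0 - 2.0 * q) + (3.0 * q ** 2 - 2.0 * q + 1.0) / 2.0)
    )
    return np.where((u >= -1.0) & (u <= q), out, 0.0)


def smoothed_hazard(
    ds: SurvivalDataset,
    bandwidth: float | None = None,
    max_time: float | None = None,
    grid_size: int = 101,
) -> HazardCurve:
    """Kernel-smoothed hazard on a uniform grid over [0, max_time].

    ``bandwidth`` defaults to max_time / 8 (a global bandwidth; there is no
    local adaptation).  ``max_time`` defaults to the maximum follow-up but
    should normally be set to the data cut's minimum follow-up, beyond which
    few patients remain at risk and the estimate is unstable.
    """
    if ds.n_events < 2:
        raise DiagnosticError("smoothed hazard needs at least 2 events")
    if max_time is None:
        max_time = ds.max_follow_up
    if max_time > ds.max_follow_up + 1e-12:
        raise DiagnosticError(
            f"max_time={max_time} exceeds the maximum follow-up {ds.max_follow_up}"
        )
    if bandwidth is None:
        bandwidth = max_time / 8.0
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if grid_size < 3:
        raise ValueError("grid_size must be at least 3")

    # Nelson-Aalen increments d_j / n_j at distinct event times
    t = ds.times_array()
    e = ds.events_array()
    order = np.lexsort((1 - e, t))
    t, e = t[order], e[order]
    n = t.size
    ev_times, increments = [], []
    i = 0
    while i < n:
        ti = t[i]
        d = 0
        j = i
        while j < n and t[j] == ti:
            if e[j] == 1:
                d += 1
            j += 1
        if d > 0:
            risk = n - i
            ev_times.append(ti)
            increments.append(d / risk)
        i = j
    ev_times = np.asarray(ev_times)
    increments = np.asarray(increments)

    grid = np.linspace(0.0, max_time, grid_size)
    b = float(bandwidth)
    haz = np.empty_like(grid)
    for gi, tt in enumerate(grid):
        u = (tt - ev_times) / b
        if tt < b:
            w = _boundary_kernel(u, tt / b)
        elif tt > max_time - b:
            w = _boundary_kernel(-u, (max_time - tt) / b)
        else:
            w = _epanechnikov(u)
        haz[gi] = np.dot(w, increments) / b
    haz = np.maximum(haz, 0.0)  # boundary kernels can dip marginally below zero
    return HazardCurve(tuple(grid), tuple(haz), b, float(max_time))


def classify_hazard_shape(curve: HazardCurve, tolerance: float = 0.05) -> HazardShape:
    """Label the hazard's shape from its turning points.

    Direction changes smaller than ``tolerance`` times the curve's maximum
    are treated as noise (hysteresis filter), so small wiggles do not count
    as turning points.
    """
    h = np.asarray(curve.hazard, dtype=float)
    if h.size < 3:
        raise DiagnosticError("need at least 3 grid points to classify a shape")
    hmax = h.max()
    if hmax <= 0:
        raise DiagnosticError("degenerate flat-zero hazard curve")
    thr = tolerance * hmax

    pattern = []
    direction = 0
    ext = h[0]
    for v in h[1:]:
        if direction == 0:
            if v > ext + thr:
                direction = 1
                pattern.append(1)
                ext = v
            elif v < ext - thr:
                direction = -1
                pattern.append(-1)
                ext = v
        elif direction == 1:
            if v > ext:
                ext = v
            elif v < ext - thr:
                direction = -1
                pattern.append(-1)
                ext = v
        else:
            if v < ext:
                ext = v
            elif v > ext + thr:
                direction = 1
                pattern.append(1)
                ext = v

    if not pattern:
        label = "constant"
    elif len(pattern) == 1:
        label = "monotone_increasing" if pattern[0] == 1 else "monotone_decreasing"
    else:
        label = "non_monotone"
    return HazardShape(label=label, rejected_families=REJECTION_RULE[label])
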