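"""Right-censored survival datasets, administrative data cuts, and the
Kaplan-Meier product-limit estimator with RMST and point-estimate readout.

Time is measured in months throughout.  A dataset may optionally carry
calendar entry times (staggered accrual); in that case the ``time`` field of
each record is interpreted on the calendar scale so that an administrative
data cut (database lock) can be applied with :func:`apply_data_cut`, after
which times are again relative to each patient's entry.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SurvivalDataset",
    "DataCutSpec",
    "StepSurvivalCurve",
    "read_dataset",
    "apply_data_cut",
    "km_estimate",
    "survival_at",
    "rmst_km",
    "write_km_curve",
]


class FormatError(ValueError):
    """A required column is missing or the file cannot be parsed."""


class ValidationError(ValueError):
    """A record violates the dataset invariants."""


class OutOfSupportError(ValueError):
    """A nonparametric quantity was requested beyond the observed follow-up."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored observations, optionally anchored to calendar time.

    times
        Observation times, strictly positive, in months.
    events
        1 for an observed death, 0 for censoring.
    entries
        Optional calendar entry (accrual) times in months; either absent or
        present for every patient.
    """

    times: tuple
    events: tuple
    entries: tuple | None = None
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events)
        if t.size == 0:
            raise ValidationError("dataset must contain at least one record")
        if t.size != e.size:
            raise ValidationError("times and events differ in length")
        for i, ti in enumerate(t):
            if not np.isfinite(ti) or ti <= 0:
                raise ValidationError(f"row {i}: time must be positive and finite, got {ti}")
        if not np.isin(e, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(e, (0, 1)))[0])
            raise ValidationError(f"row {bad}: event must be 0 or 1, got {e[bad]}")
        if self.entries is not None:
            ent = np.asarray(self.entries, dtype=float)
            if ent.size != t.size:
                raise ValidationError("entries must be present for every patient or absent")
            if np.any(ent < 0) or not np.all(np.isfinite(ent)):
                raise ValidationError("entry times must be finite and non-negative")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "events", tuple(int(x) for x in e))
        if self.entries is not None:
            object.__setattr__(self, "entries", tuple(float(x) for x in self.entries))

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(sum(self.events))

    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def events_array(self) -> np.ndarray:
        return np.asarray(self.events, dtype=int)

    def uncensored_times(self) -> np.ndarray:
        t = self.times_array()
        return t[self.events_array() == 1]

    @property
    def max_follow_up(self) -> float:
        return float(max(self.times))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            if self.entries is not None:
                w.writerow(["time", "event", "entry"])
                w.writerows(zip(self.times, self.events, self.entries))
            else:
                w.writerow(["time", "event"])
                w.writerows(zip(self.times, self.events))


@dataclass(frozen=True)
class DataCutSpec:
    """An administrative database lock at a fixed calendar time."""

    lock_time: float
    label: str = ""

    def __post_init__(self):
        if not np.isfinite(self.lock_time) or self.lock_time <= 0:
            raise ValidationError(f"lock_time must be positive, got {self.lock_time}")


@dataclass(frozen=True)
class StepSurvivalCurve:
    """Kaplan-Meier product-limit estimate as a right-continuous step function."""

    event_times: tuple
    survival: tuple
    at_risk: tuple
    max_follow_up: float
    label: str = ""

    def __post_init__(self):
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.any(np.diff(s) > 1e-12) or s[0] > 1.0 + 1e-12):
            raise ValidationError("survival must be non-increasing and start at <= 1")


def read_dataset(
    path,
    column_map: Mapping[str, str] | None = None,
    label: str = "",
) -> SurvivalDataset:
    """Read a survival dataset from a headed CSV file.

    ``column_map`` maps the canonical names ``time``, ``event`` and
    (optionally) ``entry`` to the column names used in the file; by default
    the canonical names themselves are expected.  Row order is preserved.
    """
    cmap = {"time": "time", "event": "event", "entry": "entry"}
    if column_map:
        cmap.update(column_map)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        for key in ("time", "event"):
            if cmap[key] not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {cmap[key]!r}")
        has_entry = cmap["entry"] in reader.fieldnames
        times, events, entries = [], [], []
        for i, row in enumerate(reader):
            try:
                t = float(row[cmap["time"]])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"row {i}: unparseable time {row[cmap['time']]!r}") from exc
            if not np.isfinite(t) or t <= 0:
                raise ValidationError(f"row {i}: time must be positive, got {t}")
            try:
                e = int(float(row[cmap["event"]]))
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"row {i}: unparseable event {row[cmap['event']]!r}") from exc
            if e not in (0, 1):
                raise ValidationError(f"row {i}: event must be 0 or 1, got {e}")
            times.append(t)
            events.append(e)
            if has_entry:
                entries.append(float(row[cmap["entry"]]))
    return SurvivalDataset(
        times=tuple(times),
        events=tuple(events),
        entries=tuple(entries) if has_entry else None,
        label=label,
    )


def apply_data_cut(ds: SurvivalDataset, cut: DataCutSpec) -> SurvivalDataset:
    """Administratively censor a calendar-anchored dataset at a database lock.

    The input must carry calendar entry times, with ``times`` on the calendar
    scale (entry + follow-up).  Patients whose event or censoring falls
    before the lock are kept as observed; everyone still under observation at
    the lock is censored there.  The returned dataset is on the
    time-since-entry scale with no entries.
    """
    if ds.entries is None:
        raise ValidationError("apply_data_cut requires calendar entry times")
    lock = float(cut.lock_time)
    times, events = [], []
    for t_cal, e, entry in zip(ds.times, ds.events, ds.entries):
        if entry >= lock:
            raise ValidationError(
                f"lock at {lock} precedes entry {entry}: patient not yet enrolled"
            )
        if t_cal < lock:
            times.append(t_cal - entry)
            events.append(e)
        else:
            times.append(lock - entry)
            events.append(0)
    return SurvivalDataset(tuple(times), tuple(events), None, label=cut.label or ds.label)


def km_estimate(ds: SurvivalDataset) -> StepSurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Ties are grouped; censorings at an event time are processed after the
    events (standard convention), i.e. a patient censored at t is still at
    risk for a death at t.
    """
    t = ds.times_array()
    e = ds.events_array()
    order = np.lexsort((1 - e, t))  # events before censorings at equal times
    t, e = t[order], e[order]
    n = t.size
    event_times, surv, at_risk = [], [], []
    s = 1.0
    i = 0
    while i < n:
        ti = t[i]
        d = 0
        c = 0
        while i < n and t[i] == ti:
            if e[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            risk = n - (i - d - c)  # patients with time >= ti
            event_times.append(ti)
            at_risk.append(risk)
            s *= 1.0 - d / risk
            surv.append(s)
    return StepSurvivalCurve(
        event_times=tuple(event_times),
        survival=tuple(surv),
        at_risk=tuple(at_risk),
        max_follow_up=float(t[-1]),
        label=ds.label,
    )


def survival_at(curve: StepSurvivalCurve, t: float) -> float:
    """Right-continuous KM survival at time t within the observed follow-up."""
    if t < 0:
        raise OutOfSupportError(f"t must be non-negative, got {t}")
    if t > curve.max_follow_up:
        raise OutOfSupportError(
            f"t={t} exceeds the observed follow-up {curve.max_follow_up}; "
            "the product-limit estimate is undefined there"
        )
    times = np.asarray(curve.event_times)
    idx = np.searchsorted(times, t, side="right")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


def rmst_km(curve: StepSurvivalCurve, tau: float) -> float:
    """Restricted mean survival time: exact area under the KM step function on [0, tau]."""
    if tau < 0:
        raise OutOfSupportError(f"tau must be non-negative, got {tau}")
    if tau > curve.max_follow_up:
        raise OutOfSupportError(
            f"tau={tau} exceeds the observed follow-up {curve.max_follow_up}"
        )
    knots = [0.0]
    values = []
    s = 1.0
    for ti, si in zip(curve.event_times, curve.survival):
        if ti >= tau:
            break
        knots.append(ti)
        values.append(s)
        s = si
    knots.append(tau)
    values.append(s)
    widths = np.diff(knots)
    return float(np.dot(widths, values))


def write_km_curve(curve: StepSurvivalCurve, csv_path=None, json_path=None) -> None:
    """Export a KM curve as CSV (time, survival, at_risk) and/or a JSON summary."""
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "survival", "at_risk"])
            w.writerows(zip(curve.event_times, curve.survival, curve.at_risk))
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "label": curve.label,
                    "max_follow_up": curve.max_follow_up,
                    "event_times": list(curve.event_times),
                    "survival": list(curve.survival),
                    "at_risk": list(curve.at_risk),
                },
                fh,
                indent=2,
            )
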