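"""Weighted weighted average aggregation over sensor groups.

Each sensor contributes the product of (i) its distance from its
setpoint or reference value, (ii) a static scaling weight, and (iii) a
binary critical-range gate that opens only when the raw distance reaches
the sensor's critical distance.  The group score is the mean of these
terms over the group's active sensors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import AlertSeries, BatchRun, Channel
from .errors import GroupUnavailableError, ParameterError, ValidationError

DISTANCE_MODES = ("relative", "raw")

#: a reference value: either a constant or a stepwise schedule of
#: (start_day, value) pairs, the first of which must start at day 0
ReferenceSchedule = float | Sequence[tuple[float, float]]


def reference_at(reference: ReferenceSchedule, time_days) -> np.ndarray | float:
    """Evaluate a constant or stepwise reference at the given time(s)."""
    t = np.asarray(time_days, dtype=float)
    if np.isscalar(reference) or isinstance(reference, (int, float)):
        out = np.full(t.shape, float(reference))
        return float(out) if t.ndim == 0 else out
    pairs = sorted((float(s), float(v)) for s, v in reference)
    if not pairs:
        raise ValidationError("empty reference schedule")
    starts = np.array([p[0] for p in pairs])
    values = np.array([p[1] for p in pairs])
    if starts[0] > 0:
        raise ValidationError("reference schedule must start at day 0")
    idx = np.searchsorted(starts, t, side="right") - 1
    out = values[idx]
    return float(out) if t.ndim == 0 else out


class SensorGroup(str, enum.Enum):
    SP = "SP"  # sensors driven towards a setpoint
    NSP = "NSP"  # sensors judged against a historical reference value


@dataclass
class SensorSpec:
    """Aggregation parameters for one channel."""

    channel: Channel
    reference: ReferenceSchedule
    scaling_weight: float
    critical_distance: float
    group: SensorGroup

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.group = SensorGroup(self.group)
        if not 0 < self.scaling_weight <= 1:
            raise ValidationError("scaling_weight must lie in (0, 1]")
        if self.critical_distance <= 0:
            raise ValidationError("critical_distance must be positive")

    def reference_at(self, time_days):
        return reference_at(self.reference, time_days)


def critical_weight(spec: SensorSpec, value: float, time_days: float = 0.0) -> int:
    """Binary gate: 1 when the raw distance reaches the critical distance."""
    ref = spec.reference_at(time_days)
    return int(abs(value - ref) >= spec.critical_distance)


def sensor_distance(
    spec: SensorSpec,
    value,
    time_days=0.0,
    mode: str = "relative",
):
    """Distance term for one sensor.

    ``relative`` divides the raw distance by |reference| so that channels
    on very different scales are comparable; a zero reference falls back
    to the raw distance.
    """
    if mode not in DISTANCE_MODES:
        raise ParameterError(f"distance mode must be one of {DISTANCE_MODES}")
    ref = spec.reference_at(time_days)
    d = np.abs(np.asarray(value, dtype=float) - ref)
    if mode == "raw":
        return d if d.ndim else float(d)
    denom = np.abs(np.asarray(ref, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(denom > 0, d / denom, d)
    return rel if rel.ndim else float(rel)


@dataclass
class WwaScore:
    """Group score at one time point with its per-sensor term breakdown."""

    time_days: float
    score: float
    contributing: dict[Channel, float] = field(default_factory=dict)


def wwa_score(
    values: Mapping[Channel | str, float],
    specs: Sequence[SensorSpec],
    group: SensorGroup | str,
    time_days: float = 0.0,
    distance_mode: str = "relative",
) -> WwaScore:
    """Aggregate one group's sensors at a single time point.

    ``values`` maps channels to readings; sensors absent from the map or
    carrying NaN are treated as inactive and drop out of the mean.
    """
    group = SensorGroup(group)
    vals = {Channel(k): v for k, v in values.items()}
    terms: dict[Channel, float] = {}
    for spec in specs:
        if spec.group != group:
            continue
        v = vals.get(spec.channel)
        if v is None or not np.isfinite(v):
            continue
        w = critical_weight(spec, v, time_days)
        s = sensor_distance(spec, v, time_days, distance_mode)
        terms[spec.channel] = s * spec.scaling_weight * w
    if not terms:
        raise GroupUnavailableError(f"no active sensors in group {group.value}")
    score = float(sum(terms.values()) / len(terms))
    return WwaScore(time_days=time_days, score=score, contributing=terms)


def wwa_series(
    run: BatchRun,
    specs: Sequence[SensorSpec],
    group: SensorGroup | str,
    distance_mode: str = "relative",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised group score over a whole run.

    Returns (scores, n_active); the score is NaN wherever no group
    sensor is active.  Raises if the group never has an active sensor.
    """
    group = SensorGroup(group)
    t = run.time_days
    term_rows = []
    active_rows = []
    for spec in specs:
        if spec.group != group or spec.channel not in run.channels:
            continue
        cs = run.channels[spec.channel]
        ref = spec.reference_at(t)
        raw = np.abs(cs.values - ref)
        gate = (raw >= spec.critical_distance).astype(float)
        s = sensor_distance(spec, cs.values, t, distance_mode)
        term = s * spec.scaling_weight * gate
        act = np.isfinite(cs.values)
        term_rows.append(np.where(act, term, 0.0))
        active_rows.append(act)
    if not term_rows:
        raise GroupUnavailableError(f"no sensors available for group {group.value}")
    terms = np.vstack(term_rows)
    n_active = np.vstack(active_rows).sum(axis=0)
    if not n_active.any():
        raise GroupUnavailableError(f"group {group.value} has no active samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(n_active > 0, terms.sum(axis=0) / n_active, np.nan)
    return scores, n_active


def wwa_alert(
    time_days: np.ndarray,
    scores: np.ndarray,
    threshold: float,
    name: str = "WWA",
) -> AlertSeries:
    """Alert where the group score strictly exceeds the threshold."""
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    with np.errstate(invalid="ignore"):
        alert = np.isfinite(scores) & (scores > threshold)
    return AlertSeries(name, time_days, scores, alert.astype(int))


def wwa_sensor(
    run: BatchRun,
    specs: Sequence[SensorSpec],
    group: SensorGroup | str,
    threshold: float,
    distance_mode: str = "relative",
) -> AlertSeries:
    group = SensorGroup(group)
    scores, _ = wwa_series(run, specs, group, distance_mode)
    return wwa_alert(run.time_days, scores, threshold, name=f"WWA_{group.value}")
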