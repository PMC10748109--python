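"""Consensus fusion of the six smart-sensor alert streams.

Alert streams are stacked into a binary matrix; a consensus event is a
(merged) interval where the simultaneous-alert count reaches a quorum.
The coincidence summary cross-tabulates, per sensor and per run, how
many consensus events each sensor's own alerts coincided with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlertSeries
from .errors import ParameterError, ValidationError

SENSOR_COLUMNS = ("SDI", "Boll_Glucose", "Boll_Lactate", "WWA_SP", "WWA_NSP", "Fuzzy")


@dataclass
class AlertMatrix:
    """Per-timestamp 0/1 alerts for each smart sensor on a common grid."""

    time_days: np.ndarray
    alerts: pd.DataFrame

    def __post_init__(self) -> None:
        self.time_days = np.asarray(self.time_days, dtype=float)
        if len(self.alerts) != self.time_days.size:
            raise ValidationError("alert matrix rows must match the time grid")
        values = self.alerts.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("alert matrix entries must be 0 or 1")
        self.alerts = self.alerts.astype(int)

    @classmethod
    def from_alert_series(cls, series: Sequence[AlertSeries]) -> "AlertMatrix":
        if not series:
            raise ValidationError("need at least one alert series")
        t = series[0].time_days
        for s in series[1:]:
            if s.time_days.shape != t.shape or not np.allclose(s.time_days, t):
                raise ValidationError("alert series must share one time grid")
        frame = pd.DataFrame({s.name: s.alert for s in series})
        return cls(time_days=t, alerts=frame)

    @property
    def sensors(self) -> list[str]:
        return list(self.alerts.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.alerts.copy()
        out.insert(0, "time_days", self.time_days)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AlertMatrix":
        if "time_days" not in frame.columns:
            raise ValidationError("alert matrix table must have a time_days column")
        t = frame["time_days"].to_numpy(dtype=float)
        return cls(time_days=t, alerts=frame.drop(columns=["time_days"]))


def count_simultaneous(matrix: AlertMatrix) -> np.ndarray:
    """Number of sensors alerting at each timestamp."""
    return matrix.alerts.to_numpy().sum(axis=1)


@dataclass(frozen=True)
class ConsensusEvent:
    start_days: float
    end_days: float
    peak_count: int


def detect_events(
    counts: np.ndarray,
    time_days: np.ndarray,
    min_sensors: int = 3,
    merge_gap_minutes: float = 30.0,
    min_duration_minutes: float = 0.0,
) -> list[ConsensusEvent]:
    """Maximal above-quorum intervals, merged across short gaps.

    Two intervals separated by strictly less than the merge gap are
    reported as one event.  ``min_duration_minutes`` optionally drops
    events shorter than the given duration (default keeps everything,
    including single-sample events of zero duration).
    """
    if min_sensors < 1:
        raise ParameterError("min_sensors must be >= 1")
    counts = np.asarray(counts)
    time_days = np.asarray(time_days, dtype=float)
    above = counts >= min_sensors
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2] - 1  # inclusive sample indices

    gap_days = merge_gap_minutes / 1440.0
    merged: list[list[int]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if time_days[s] - time_days[merged[-1][1]] < gap_days:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    min_dur_days = min_duration_minutes / 1440.0
    for s, e in merged:
        start_t, end_t = float(time_days[s]), float(time_days[e])
        if end_t - start_t < min_dur_days:
            continue
        peak = int(counts[s : e + 1].max())
        events.append(ConsensusEvent(start_t, end_t, peak))
    return events


def coincidence(events: Sequence[ConsensusEvent], matrix: AlertMatrix) -> dict[str, int]:
    """Per sensor, how many events contain at least one of its alert samples."""
    t = matrix.time_days
    detected = {name: 0 for name in matrix.sensors}
    for ev in events:
        in_event = (t >= ev.start_days) & (t <= ev.end_days)
        for name in matrix.sensors:
            if matrix.alerts[name].to_numpy()[in_event].any():
                detected[name] += 1
    return detected


def events_to_frame(events: Sequence[ConsensusEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_days": [e.start_days for e in events],
            "end_days": [e.end_days for e in events],
            "peak_count": [e.peak_count for e in events],
        }
    )


def _ratio(num: int, den: int, places: str = "0.01") -> Decimal:
    """Half-up rounded ratio of two integers."""
    if den == 0:
        raise ValidationError("ratio denominator is zero")
    return (Decimal(num) / Decimal(den)).quantize(Decimal(places), rounding=ROUND_HALF_UP)


@dataclass
class CoincidenceTable:
    """Detected/undetected consensus-event counts with derived percentages.

    Undetected fractions are rounded half-up to two decimals before the
    complement percentages are formed, matching how the printed summary
    tables are derived.
    """

    runs: list[str]
    sensors: list[str]
    totals: list[int]
    detected: dict[str, list[int]]
    undetected: dict[str, list[int]] = field(init=False)
    total_events: int = field(init=False)

    def __post_init__(self) -> None:
        n_runs = len(self.runs)
        if len(self.totals) != n_runs:
            raise ValidationError("totals must have one entry per run")
        for name in self.sensors:
            det = self.detected.get(name)
            if det is None or len(det) != n_runs:
                raise ValidationError(f"detected counts malformed for sensor {name}")
            for d, tot in zip(det, self.totals):
                if not 0 <= d <= tot:
                    raise ValidationError(
                        f"sensor {name}: detected count {d} outside [0, {tot}]"
                    )
        self.total_events = int(sum(self.totals))
        self.undetected = {
            name: [tot - d for d, tot in zip(self.detected[name], self.totals)]
            for name in self.sensors
        }

    # --- per-sensor summary -------------------------------------------------

    def sensor_undetected_total(self, name: str) -> int:
        return int(sum(self.undetected[name]))

    def sensor_undetected_fraction(self, name: str) -> Decimal:
        return _ratio(self.sensor_undetected_total(name), self.total_events)

    def sensor_consensus_percent(self, name: str) -> float:
        return float(100 * (1 - self.sensor_undetected_fraction(name)))

    @property
    def sensor_average_percent(self) -> float:
        total = sum(
            Decimal(str(self.sensor_consensus_percent(n))) for n in self.sensors
        )
        avg = (total / len(self.sensors)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        return float(avg)

    # --- per-run summary ----------------------------------------------------

    def run_undetected_total(self, run_index: int) -> int:
        return int(sum(self.undetected[name][run_index] for name in self.sensors))

    @property
    def grand_undetected_total(self) -> int:
        return int(sum(self.run_undetected_total(i) for i in range(len(self.runs))))

    def run_undetected_fraction(self, run_index: int) -> Decimal:
        return _ratio(self.run_undetected_total(run_index), self.grand_undetected_total)

    def run_consensus_percent(self, run_index: int) -> float:
        return float(100 * (1 - self.run_undetected_fraction(run_index)))

    @property
    def run_consensus_percents(self) -> list[float]:
        return [self.run_consensus_percent(i) for i in range(len(self.runs))]

    @property
    def run_average_percent(self) -> float:
        total = sum(Decimal(str(p)) for p in self.run_consensus_percents)
        avg = (total / len(self.runs)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        return float(avg)

    # --- export ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Undetected-count table with the marginal sums and fractions."""
        rows: dict[str, list] = {"row": [], **{r: [] for r in self.runs}}
        rows["sum_b"] = []
        rows["pct_b"] = []

        rows["row"].append("total_consensus_events")
        for r, tot in zip(self.runs, self.totals):
            rows[r].append(tot)
        rows["sum_b"].append(self.total_events)
        rows["pct_b"].append(1.0)

        for name in self.sensors:
            rows["row"].append(name)
            for r, u in zip(self.runs, self.undetected[name]):
                rows[r].append(u)
            rows["sum_b"].append(self.sensor_undetected_total(name))
            rows["pct_b"].append(float(self.sensor_undetected_fraction(name)))

        rows["row"].append("sum_s")
        for i, r in enumerate(self.runs):
            rows[r].append(self.run_undetected_total(i))
        rows["sum_b"].append(self.grand_undetected_total)
        rows["pct_b"].append(float("nan"))

        rows["row"].append("pct_s")
        for i, r in enumerate(self.runs):
            rows[r].append(float(self.run_undetected_fraction(i)))
        rows["sum_b"].append(float("nan"))
        rows["pct_b"].append(float("nan"))
        return pd.DataFrame(rows)

    def to_summary_dict(self) -> dict:
        return {
            "per_sensor_consensus_percent": {
                name: self.sensor_consensus_percent(name) for name in self.sensors
            },
            "sensor_average_percent": self.sensor_average_percent,
            "per_run_consensus_percent": dict(zip(self.runs, self.run_consensus_percents)),
            "run_average_percent": self.run_average_percent,
            "run_min_percent": min(self.run_consensus_percents),
            "run_max_percent": max(self.run_consensus_percents),
            "total_consensus_events": self.total_events,
            "grand_undetected_total": self.grand_undetected_total,
        }


def summarize(
    totals: Sequence[int],
    detected: Mapping[str, Sequence[int]],
    runs: Sequence[str] | None = None,
    sensors: Sequence[str] | None = None,
) -> CoincidenceTable:
    """Build the coincidence summary from per-run totals and detected counts."""
    runs = list(runs) if runs is not None else [f"run{i + 1}" for i in range(len(totals))]
    sensors = list(sensors) if sensors is not None else list(detected.keys())
    return CoincidenceTable(
        runs=runs,
        sensors=sensors,
        totals=[int(t) for t in totals],
        detected={name: [int(d) for d in detected[name]] for name in sensors},
    )
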