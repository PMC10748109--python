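"""Batch-run data model, rolling-window statistics and CSV plumbing.

A :class:`BatchRun` bundles the eight monitored channels of one
cell-expansion run on a common, uniformly sampled time grid.  Time is
stored in days (matching how runs are plotted) while sampling intervals
are given in seconds; the conversion is exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ChannelUnavailableError, GridError, ParameterError, ValidationError

DAY_SECONDS = 86400.0

#: relative tolerance for grid-uniformity checks
GRID_RTOL = 1e-6


class Channel(str, enum.Enum):
    """The eight monitored hard-sensor channels."""

    T = "T"
    DO = "DO"
    PH = "pH"
    GASFL = "GasFL"
    GLU = "Glu"
    LAC = "Lac"
    O2 = "O2"
    CO2 = "CO2"


#: canonical column order used by the batch-run CSV format
CHANNEL_ORDER: tuple[Channel, ...] = (
    Channel.T,
    Channel.DO,
    Channel.PH,
    Channel.GASFL,
    Channel.GLU,
    Channel.LAC,
    Channel.O2,
    Channel.CO2,
)

CHANNEL_UNITS: dict[Channel, str] = {
    Channel.T: "degC",
    Channel.DO: "% a.s.",
    Channel.PH: "-",
    Channel.GASFL: "mL/min",
    Channel.GLU: "mM",
    Channel.LAC: "mM",
    Channel.O2: "%",
    Channel.CO2: "%",
}


def _check_grid(time_days: np.ndarray) -> float:
    """Validate a strictly increasing uniform grid; return step in days."""
    if time_days.ndim != 1 or time_days.size < 1:
        raise GridError("time axis must be a non-empty 1-D array")
    if time_days.size == 1:
        return 0.0
    dt = np.diff(time_days)
    if not (dt > 0).all():
        raise GridError("timestamps must be strictly increasing")
    step = float(np.median(dt))
    if not np.allclose(dt, step, rtol=GRID_RTOL, atol=step * GRID_RTOL):
        raise GridError("timestamps must be uniformly spaced")
    return step


@dataclass
class ChannelSeries:
    """One channel of a batch run on a uniform time grid.

    ``active`` is a per-sample mask: inactive samples carry NaN in
    ``values``.  A channel that never reports (e.g. a disconnected
    exhaust sensor) is simply all-inactive.
    """

    channel: Channel
    time_days: np.ndarray
    values: np.ndarray
    active: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.time_days = np.asarray(self.time_days, dtype=float)
        self.values = np.asarray(self.values, dtype=float).copy()
        _check_grid(self.time_days)
        if self.values.shape != self.time_days.shape:
            raise ValidationError("values and time_days must have the same shape")
        if self.active is None:
            self.active = np.isfinite(self.values)
        else:
            self.active = np.asarray(self.active, dtype=bool).copy()
            if self.active.shape != self.time_days.shape:
                raise ValidationError("active mask must match the time grid")
        if not np.isfinite(self.values[self.active]).all():
            raise ValidationError(
                f"channel {self.channel.value}: non-finite value in active samples"
            )
        self.values[~self.active] = np.nan

    def __len__(self) -> int:
        return self.time_days.size

    @property
    def interval_seconds(self) -> float:
        if len(self) < 2:
            raise GridError("interval undefined for a single-sample series")
        return float(self.time_days[1] - self.time_days[0]) * DAY_SECONDS

    @property
    def is_active(self) -> bool:
        """True if the channel reports at least one sample."""
        return bool(self.active.any())

    def shifted(self, offset: float) -> "ChannelSeries":
        return replace(self, values=self.values + offset, active=self.active.copy())

    def scaled(self, factor: float) -> "ChannelSeries":
        return replace(self, values=self.values * factor, active=self.active.copy())


@dataclass
class BatchRun:
    """All eight channels of one expansion run on a shared grid."""

    run_id: str
    channels: dict[Channel, ChannelSeries]
    sample_interval: float  # seconds
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValidationError("sample_interval must be positive")
        self.channels = {Channel(k): v for k, v in self.channels.items()}
        grids = [cs.time_days for cs in self.channels.values()]
        if not grids:
            raise ValidationError("a batch run needs at least one channel")
        ref = grids[0]
        for g in grids[1:]:
            if g.shape != ref.shape or not np.allclose(g, ref, rtol=GRID_RTOL, atol=0):
                raise GridError("all channels must share identical timestamps")
        if ref.size >= 2:
            step_s = float(ref[1] - ref[0]) * DAY_SECONDS
            if not np.isclose(step_s, self.sample_interval, rtol=GRID_RTOL):
                raise GridError(
                    f"sample_interval {self.sample_interval}s does not match the "
                    f"grid step {step_s}s"
                )

    @property
    def time_days(self) -> np.ndarray:
        return next(iter(self.channels.values())).time_days

    @property
    def n_samples(self) -> int:
        return self.time_days.size

    def channel(self, channel: Channel | str) -> ChannelSeries:
        channel = Channel(channel)
        if channel not in self.channels:
            raise ChannelUnavailableError(f"channel {channel.value} not in run {self.run_id}")
        return self.channels[channel]

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"time_days": self.time_days}
        for ch in CHANNEL_ORDER:
            if ch in self.channels:
                data[ch.value] = self.channels[ch].values
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        run_id: str = "run",
        metadata: dict | None = None,
    ) -> "BatchRun":
        if "time_days" not in frame.columns:
            raise ValidationError("batch-run table must have a time_days column")
        t = frame["time_days"].to_numpy(dtype=float)
        step = _check_grid(t)
        channels: dict[Channel, ChannelSeries] = {}
        for ch in CHANNEL_ORDER:
            if ch.value in frame.columns:
                vals = frame[ch.value].to_numpy(dtype=float)
                channels[ch] = ChannelSeries(ch, t, vals)
        if not channels:
            raise ValidationError("no recognised channel columns found")
        return cls(
            run_id=run_id,
            channels=channels,
            sample_interval=step * DAY_SECONDS,
            metadata=metadata or {},
        )

    @classmethod
    def read_csv(cls, path, run_id: str | None = None) -> "BatchRun":
        frame = pd.read_csv(path)
        rid = run_id if run_id is not None else str(path)
        return cls.from_frame(frame, run_id=rid)


@dataclass
class WindowStats:
    """Trailing-window mean and standard deviation on the source grid.

    The warm-up prefix (fewer samples than one full window) is NaN.
    """

    time_days: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    window_minutes: float
    window_samples: int


def window_sample_count(window_minutes: float, interval_seconds: float) -> int:
    n = int(round(window_minutes * 60.0 / interval_seconds))
    if n < 2:
        raise ParameterError(
            f"window of {window_minutes} min spans {n} sample(s) at "
            f"{interval_seconds}s; need at least 2"
        )
    return n


def rolling_stats(
    series: ChannelSeries,
    window_minutes: float,
    estimator: str = "population",
) -> WindowStats:
    """Trailing-window mean/std at every sample with a full window behind it.

    ``estimator`` selects the population (divide by n, default) or sample
    (divide by n-1) standard deviation.
    """
    if not series.is_active:
        raise ChannelUnavailableError(f"channel {series.channel.value} is inactive")
    if estimator not in ("population", "sample"):
        raise ParameterError(f"unknown estimator {estimator!r}")
    w = window_sample_count(window_minutes, series.interval_seconds)
    s = pd.Series(series.values)
    roll = s.rolling(window=w, min_periods=w)
    mean = roll.mean().to_numpy()
    std = roll.std(ddof=0 if estimator == "population" else 1).to_numpy()
    return WindowStats(
        time_days=series.time_days,
        mean=mean,
        std=std,
        window_minutes=window_minutes,
        window_samples=w,
    )


@dataclass
class AlertSeries:
    """Binary alert stream plus its underlying continuous score."""

    name: str
    time_days: np.ndarray
    score: np.ndarray
    alert: np.ndarray

    def __post_init__(self) -> None:
        self.time_days = np.asarray(self.time_days, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        self.alert = np.asarray(self.alert)
        if self.alert.dtype != np.dtype(int):
            if not np.isin(self.alert, (0, 1)).all():
                raise ValidationError("alert entries must be 0 or 1")
            self.alert = self.alert.astype(int)
        if not np.isin(self.alert, (0, 1)).all():
            raise ValidationError("alert entries must be 0 or 1")
        if not (self.time_days.shape == self.score.shape == self.alert.shape):
            raise ValidationError("alert series arrays must share one shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_days": self.time_days, "score": self.score, "alert": self.alert}
        )


def _downsample_channel(cs: ChannelSeries, factor: int) -> ChannelSeries:
    n_out = len(cs) // factor
    used = n_out * factor
    vals = cs.values[:used].reshape(n_out, factor)
    act = cs.active[:used].reshape(n_out, factor)
    new_active = act.all(axis=1)
    new_vals = vals.mean(axis=1)  # NaN where any sample inactive
    new_vals[~new_active] = np.nan
    new_t = cs.time_days[factor - 1 : used : factor]
    return ChannelSeries(cs.channel, new_t, new_vals, new_active)


def align_run(run: BatchRun, interval_seconds: float) -> BatchRun:
    """Resample one run to a coarser grid by trailing-block means.

    The target interval must be an integer multiple of the source
    interval.  Each output sample is stamped at the last source time of
    its block and is active only if every source sample in the block is.
    """
    ratio = interval_seconds / run.sample_interval
    factor = int(round(ratio))
    if factor < 1 or not np.isclose(ratio, factor, rtol=GRID_RTOL):
        raise ParameterError(
            f"target interval {interval_seconds}s is not an integer multiple "
            f"of the source interval {run.sample_interval}s"
        )
    if factor == 1:
        return run
    if run.n_samples < factor:
        raise ParameterError("run shorter than one target interval")
    channels = {ch: _downsample_channel(cs, factor) for ch, cs in run.channels.items()}
    return BatchRun(
        run_id=run.run_id,
        channels=channels,
        sample_interval=interval_seconds,
        metadata=dict(run.metadata),
    )


def align_runs(runs: Iterable[BatchRun], interval_seconds: float) -> list[BatchRun]:
    """Resample several runs onto the same uniform grid (see align_run)."""
    return [align_run(r, interval_seconds) for r in runs]
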