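"""Bollinger-band proximity monitors for the metabolite channels.

An envelope of K trailing-window standard deviations is drawn around the
moving average; the monitor scores how close the current value sits to
the nearer band edge, as a percentage of the band width (50 = at the
moving average, 0 = on a band, negative = outside), and alerts when that
percentage falls to or below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AlertSeries, ChannelSeries, rolling_stats
from .errors import GridError, ParameterError

ZERO_WIDTH_POLICIES = ("no_alert", "alert")


@dataclass
class BandSeries:
    """Moving average and upper/lower envelope on the source grid."""

    time_days: np.ndarray
    ma: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    width: np.ndarray
    K: float


@dataclass
class ProximitySeries:
    """Distance of each sample from the nearer band, absolute and percent."""

    time_days: np.ndarray
    dv_upper: np.ndarray
    dv_lower: np.ndarray
    dv: np.ndarray
    dvp: np.ndarray
    zero_width: np.ndarray  # True where bands are defined but degenerate


def compute_bands(
    series: ChannelSeries,
    window_minutes: float = 30.0,
    K: float = 8.0,
    estimator: str = "population",
) -> BandSeries:
    if K <= 0:
        raise ParameterError("K must be positive")
    ws = rolling_stats(series, window_minutes, estimator)
    upper = ws.mean + K * ws.std
    lower = ws.mean - K * ws.std
    return BandSeries(
        time_days=series.time_days,
        ma=ws.mean,
        upper=upper,
        lower=lower,
        width=upper - lower,
        K=K,
    )


def proximity(series: ChannelSeries, bands: BandSeries) -> ProximitySeries:
    """Distance of each value from the nearer band edge, per the band width.

    Degenerate (zero-width) windows have an undefined percentage and are
    flagged instead; the alert stage applies the configured policy.
    """
    if series.time_days.shape != bands.time_days.shape or not np.allclose(
        series.time_days, bands.time_days
    ):
        raise GridError("series and bands must share one time grid")
    dv_upper = bands.upper - series.values
    dv_lower = series.values - bands.lower
    dv = np.minimum(dv_upper, dv_lower)
    defined = np.isfinite(bands.width)
    zero_width = defined & (bands.width == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dvp = np.where(defined & ~zero_width, 100.0 * dv / bands.width, np.nan)
    return ProximitySeries(
        time_days=series.time_days,
        dv_upper=dv_upper,
        dv_lower=dv_lower,
        dv=dv,
        dvp=dvp,
        zero_width=zero_width,
    )


def bollinger_alert(
    prox: ProximitySeries,
    alert_threshold: float,
    zero_width_policy: str = "no_alert",
    name: str = "Bollinger",
) -> AlertSeries:
    """Alert where the band-proximity percentage is at or below threshold.

    Values outside the bands (negative percentage) always alert.
    """
    if not 0 < alert_threshold < 50:
        raise ParameterError("alert threshold must lie in (0, 50) percent")
    if zero_width_policy not in ZERO_WIDTH_POLICIES:
        raise ParameterError(f"zero_width_policy must be one of {ZERO_WIDTH_POLICIES}")
    with np.errstate(invalid="ignore"):
        alert = (prox.dvp <= alert_threshold) & np.isfinite(prox.dvp)
    if zero_width_policy == "alert":
        alert = alert | prox.zero_width
    return AlertSeries(name, prox.time_days, prox.dvp, alert.astype(int))


def band_width_trend(bands: BandSeries, window_samples: int = 2) -> np.ndarray:
    """Diagnostic: sign of the band-width slope (-1 converging, +1 widening)."""
    w = pd.Series(bands.width)
    slope = w.diff(window_samples - 1).to_numpy()
    return np.sign(slope)


def bollinger_sensor(
    series: ChannelSeries,
    window_minutes: float = 30.0,
    K: float = 8.0,
    alert_threshold: float = 25.0,
    zero_width_policy: str = "no_alert",
    estimator: str = "population",
    name: str | None = None,
) -> tuple[AlertSeries, BandSeries, ProximitySeries]:
    """Full band-monitor pipeline for one channel."""
    bands = compute_bands(series, window_minutes, K, estimator)
    prox = proximity(series, bands)
    label = name or f"Boll_{series.channel.value}"
    alerts = bollinger_alert(prox, alert_threshold, zero_width_policy, name=label)
    return alerts, bands, prox
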