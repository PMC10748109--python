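"""Signal disturbance indicator for the glucose/lactate sensing line.

Flags time points where both metabolite signals drop simultaneously
below a multiple of their trailing-window standard deviation — the
signature of a non-biological disturbance ("bubble") rather than cell
behaviour — and raises an alert when such drops repeat within a window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import AlertSeries, ChannelSeries, rolling_stats
from .errors import ChannelUnavailableError, GridError, ParameterError

log = logging.getLogger(__name__)

GRADE_BY_KAPPA = {2: "small", 3: "medium", 4: "large"}


@dataclass(frozen=True)
class Disturbance:
    """One simultaneous drop event.

    Deficits are the signed distances below the band of the largest
    satisfied multiplier (positive = below the band).
    """

    time_days: float
    kappa: int
    grade: str
    glu_deficit: float
    lac_deficit: float


def detect_disturbances(
    glu: ChannelSeries,
    lac: ChannelSeries,
    window_minutes: float = 30.0,
    kappas: Sequence[int] = (2, 3, 4),
    estimator: str = "population",
) -> list[Disturbance]:
    """Find samples where both channels sit below their lower sigma band.

    The trailing-window statistics exclude the current sample: the band
    at sample i is built from the window ending at sample i-1.  A
    disturbance requires the condition to hold in *both* channels for at
    least the smallest multiplier; its grade is set by the largest
    multiplier whose (nested) band is also crossed.
    """
    kappas = sorted(set(int(k) for k in kappas))
    if not kappas or any(k not in GRADE_BY_KAPPA for k in kappas):
        raise ParameterError(f"kappas must be a non-empty subset of {{2, 3, 4}}, got {kappas}")
    if not glu.is_active:
        raise ChannelUnavailableError("glucose channel is inactive")
    if not lac.is_active:
        raise ChannelUnavailableError("lactate channel is inactive")
    if glu.time_days.shape != lac.time_days.shape or not np.allclose(
        glu.time_days, lac.time_days
    ):
        raise GridError("glucose and lactate must share one time grid")

    gs = rolling_stats(glu, window_minutes, estimator)
    ls = rolling_stats(lac, window_minutes, estimator)

    def prior(a: np.ndarray) -> np.ndarray:
        out = np.empty_like(a)
        out[0] = np.nan
        out[1:] = a[:-1]
        return out

    g_mean, g_std = prior(gs.mean), prior(gs.std)
    l_mean, l_std = prior(ls.mean), prior(ls.std)

    valid = (
        np.isfinite(g_mean)
        & np.isfinite(l_mean)
        & np.isfinite(glu.values)
        & np.isfinite(lac.values)
    )
    with np.errstate(invalid="ignore"):
        cond = {
            k: (glu.values < g_mean - k * g_std) & (lac.values < l_mean - k * l_std)
            for k in kappas
        }
    hits = np.nonzero(cond[kappas[0]] & valid)[0]

    events: list[Disturbance] = []
    for i in hits:
        kmax = max(k for k in kappas if cond[k][i])
        events.append(
            Disturbance(
                time_days=float(glu.time_days[i]),
                kappa=kmax,
                grade=GRADE_BY_KAPPA[kmax],
                glu_deficit=float(g_mean[i] - kmax * g_std[i] - glu.values[i]),
                lac_deficit=float(l_mean[i] - kmax * l_std[i] - lac.values[i]),
            )
        )
    if events:
        log.debug("detected %d disturbance(s); first at t=%.4f d", len(events), events[0].time_days)
    return events


def sdi_alert(
    disturbances: Iterable[Disturbance],
    time_days: np.ndarray,
    window_minutes: float = 30.0,
    min_count: int = 3,
    cumulative: bool = False,
) -> AlertSeries:
    """Alert when the disturbance count in the trailing window hits min_count.

    ``cumulative`` counts all disturbances since run start instead of
    only those inside the trailing window.
    """
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    time_days = np.asarray(time_days, dtype=float)
    times = np.sort(np.array([d.time_days for d in disturbances], dtype=float))
    upto = np.searchsorted(times, time_days, side="right")
    if cumulative:
        counts = upto
    else:
        window_days = window_minutes / 1440.0
        before = np.searchsorted(times, time_days - window_days, side="right")
        counts = upto - before
    alert = (counts >= min_count).astype(int)
    return AlertSeries("SDI", time_days, counts.astype(float), alert)


def sdi_sensor(
    glu: ChannelSeries,
    lac: ChannelSeries,
    window_minutes: float = 30.0,
    kappas: Sequence[int] = (2, 3, 4),
    min_count: int = 3,
    cumulative: bool = False,
    estimator: str = "population",
) -> tuple[AlertSeries, list[Disturbance]]:
    """Full disturbance-indicator pipeline for one run."""
    events = detect_disturbances(glu, lac, window_minutes, kappas, estimator)
    alerts = sdi_alert(events, glu.time_days, window_minutes, min_count, cumulative)
    return alerts, events
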