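"""Fuzzy stability controller over the glucose setpoint distance.

Two complementary piecewise-linear fuzzy sets, "normal" and "alert",
grade the absolute distance of the glucose reading from its setpoint:
normal membership is full up to one breakpoint, alert membership is full
beyond a second, and the two interpolate linearly in between so that
their grades always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlertSeries, ChannelSeries
from .errors import ParameterError, ValidationError
from .wwa import ReferenceSchedule, reference_at


@dataclass(frozen=True)
class FuzzySetPair:
    """Complementary "normal"/"alert" membership functions on distance.

    Normal support is [0, alert_full_from]; alert support is
    [normal_full_until, inf).
    """

    normal_full_until: float = 0.4
    alert_full_from: float = 1.2

    def __post_init__(self) -> None:
        if not 0 <= self.normal_full_until < self.alert_full_from:
            raise ValidationError(
                "need 0 <= normal_full_until < alert_full_from, got "
                f"({self.normal_full_until}, {self.alert_full_from})"
            )


def membership(pair: FuzzySetPair, distance):
    """Grades of membership (m_normal, m_alert) at the given distance(s).

    Distances must be non-negative (callers pass an absolute distance);
    NaN passes through as NaN in both grades.  Grades are rounded to 12
    decimals so that threshold comparisons at the breakpoints are not
    perturbed by floating-point subtraction noise.
    """
    d = np.asarray(distance, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(d < 0):
            raise ParameterError("distance must be an absolute (non-negative) value")
    span = pair.alert_full_from - pair.normal_full_until
    m_alert = np.round(np.clip((d - pair.normal_full_until) / span, 0.0, 1.0), 12)
    m_normal = 1.0 - m_alert
    if np.isscalar(distance) or np.ndim(distance) == 0:
        return float(m_normal), float(m_alert)
    return m_normal, m_alert


def alert_distance(pair: FuzzySetPair, threshold: float) -> float:
    """Distance at which alert membership equals the threshold (its inverse)."""
    if not 0 < threshold < 1:
        raise ParameterError("threshold must lie in (0, 1)")
    return pair.normal_full_until + threshold * (pair.alert_full_from - pair.normal_full_until)


def fuzzy_alert(
    time_days: np.ndarray,
    m_alert: np.ndarray,
    threshold: float = 0.45,
    name: str = "Fuzzy",
) -> AlertSeries:
    """Alert where the alert-set membership strictly exceeds the threshold."""
    if not 0 < threshold < 1:
        raise ParameterError("threshold must lie in (0, 1)")
    m_alert = np.asarray(m_alert, dtype=float)
    with np.errstate(invalid="ignore"):
        alert = np.isfinite(m_alert) & (m_alert > threshold)
    return AlertSeries(name, np.asarray(time_days, float), m_alert, alert.astype(int))


def fuzzy_sensor(
    glu: ChannelSeries,
    setpoint: ReferenceSchedule,
    pair: FuzzySetPair | None = None,
    threshold: float = 0.45,
) -> tuple[AlertSeries, np.ndarray]:
    """Full fuzzy pipeline for the glucose channel.

    Returns the alert series (score = alert membership) and the normal
    membership for reporting.
    """
    pair = pair or FuzzySetPair()
    ref = reference_at(setpoint, glu.time_days)
    distance = np.abs(glu.values - ref)
    m_normal, m_alert = membership(pair, distance)
    alerts = fuzzy_alert(glu.time_days, m_alert, threshold)
    return alerts, m_normal
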