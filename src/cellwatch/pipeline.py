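"""End-to-end monitoring pipeline: run -> six alert streams -> consensus.

Hard-sensor routing: the disturbance indicator reads glucose+lactate,
each band monitor reads one metabolite, the two aggregators read the
setpoint and non-setpoint groups, and the fuzzy controller reads
glucose.  A sensor whose input channels are unavailable is skipped with
a warning and the remaining streams proceed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bollinger import bollinger_sensor
from .config import PipelineConfig
from .consensus import (
    AlertMatrix,
    ConsensusEvent,
    coincidence,
    count_simultaneous,
    detect_events,
)
from .core import AlertSeries, BatchRun, Channel
from .errors import CellwatchError
from .fuzzy import FuzzySetPair, fuzzy_sensor
from .sdi import sdi_sensor
from .wwa import SensorGroup, wwa_sensor

log = logging.getLogger(__name__)


@dataclass
class MonitorResult:
    """Alert matrix plus per-sensor detail tables for reporting."""

    matrix: AlertMatrix
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def _active(run: BatchRun, channel: Channel) -> bool:
    return channel in run.channels and run.channels[channel].is_active


def monitor(run: BatchRun, config: PipelineConfig | None = None) -> MonitorResult:
    """Run every available smart sensor over one batch run."""
    cfg = config or PipelineConfig()
    t = run.time_days
    streams: list[AlertSeries] = []
    tables: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []

    def skip(name: str, reason: str) -> None:
        skipped.append(name)
        log.warning("skipping smart sensor %s: %s", name, reason)

    # disturbance indicator (glucose + lactate)
    if _active(run, Channel.GLU) and _active(run, Channel.LAC):
        alerts, _ = sdi_sensor(
            run.channel(Channel.GLU),
            run.channel(Channel.LAC),
            window_minutes=cfg.window_minutes,
            kappas=cfg.sdi_kappas,
            min_count=cfg.sdi_min_count,
            cumulative=cfg.sdi_cumulative,
            estimator=cfg.estimator,
        )
        streams.append(alerts)
        tables["SDI"] = alerts.to_frame()
    else:
        skip("SDI", "glucose or lactate channel unavailable")

    # band monitors
    for name, channel, threshold in (
        ("Boll_Glucose", Channel.GLU, cfg.bb_glucose_threshold),
        ("Boll_Lactate", Channel.LAC, cfg.bb_lactate_threshold),
    ):
        if not _active(run, channel):
            skip(name, f"{channel.value} channel unavailable")
            continue
        alerts, bands, prox = bollinger_sensor(
            run.channel(channel),
            window_minutes=cfg.window_minutes,
            K=cfg.bollinger_K,
            alert_threshold=threshold,
            zero_width_policy=cfg.zero_width_policy,
            estimator=cfg.estimator,
            name=name,
        )
        streams.append(alerts)
        tables[name] = pd.DataFrame(
            {
                "time_days": t,
                "ma": bands.ma,
                "upper": bands.upper,
                "lower": bands.lower,
                "dvp": prox.dvp,
                "alert": alerts.alert,
            }
        )

    # group aggregators
    wwa_cols: dict[str, np.ndarray] = {"time_days": t}
    for name, group, threshold in (
        ("WWA_SP", SensorGroup.SP, cfg.wwa_sp_threshold),
        ("WWA_NSP", SensorGroup.NSP, cfg.wwa_nsp_threshold),
    ):
        try:
            alerts = wwa_sensor(
                run, cfg.sensor_specs, group, threshold, cfg.wwa_distance_mode
            )
        except CellwatchError as exc:
            skip(name, str(exc))
            continue
        streams.append(alerts)
        wwa_cols[f"score_{group.value.lower()}"] = alerts.score
        wwa_cols[f"alert_{group.value.lower()}"] = alerts.alert
    if len(wwa_cols) > 1:
        tables["WWA"] = pd.DataFrame(wwa_cols)

    # fuzzy controller (glucose)
    if _active(run, Channel.GLU):
        glu_spec = next(
            (s for s in cfg.sensor_specs if s.channel == Channel.GLU), None
        )
        setpoint = glu_spec.reference if glu_spec is not None else 20.0
        pair = FuzzySetPair(cfg.fuzzy_normal_full_until, cfg.fuzzy_alert_full_from)
        alerts, m_normal = fuzzy_sensor(
            run.channel(Channel.GLU), setpoint, pair, cfg.fuzzy_threshold
        )
        streams.append(alerts)
        tables["Fuzzy"] = pd.DataFrame(
            {
                "time_days": t,
                "m_normal": m_normal,
                "m_alert": alerts.score,
                "alert": alerts.alert,
            }
        )
    else:
        skip("Fuzzy", "glucose channel unavailable")

    if not streams:
        raise CellwatchError("no smart sensor could be run on this batch")
    matrix = AlertMatrix.from_alert_series(streams)
    return MonitorResult(matrix=matrix, tables=tables, skipped=skipped)


@dataclass
class ConsensusResult:
    counts: np.ndarray
    events: list[ConsensusEvent]
    detected: dict[str, int]


def consensus_from_matrix(
    matrix: AlertMatrix, config: PipelineConfig | None = None
) -> ConsensusResult:
    """Count simultaneous alerts, detect events, and score coincidence."""
    cfg = config or PipelineConfig()
    counts = count_simultaneous(matrix)
    events = detect_events(
        counts,
        matrix.time_days,
        min_sensors=cfg.consensus_min_sensors,
        merge_gap_minutes=cfg.merge_gap_minutes,
        min_duration_minutes=cfg.min_event_duration_minutes,
    )
    detected = coincidence(events, matrix)
    return ConsensusResult(counts=counts, events=events, detected=detected)
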