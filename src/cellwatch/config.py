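"""Pipeline configuration: sensor specs, thresholds, and YAML plumbing.

Defaults reproduce the calibrated parameter set: a 30 min window, K = 8
bands, band thresholds of 25% (glucose) and 20% (lactate), an alert at
3+ disturbances, aggregation thresholds of 0.1 (SP) and 0.35 (NSP), and
a fuzzy threshold of 0.45.  Everything is data, nothing is hard-wired
into the sensor code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

from .core import Channel
from .errors import ParameterError
from .wwa import ReferenceSchedule, SensorGroup, SensorSpec

#: documented alternative preset for the glucose band threshold
BB_GLUCOSE_THRESHOLD_ALT = 15.0

#: static scaling weights (glucose and DO are damped; the rest pass through)
SCALING_WEIGHTS: dict[Channel, float] = {
    Channel.GLU: 0.5,
    Channel.O2: 1.0,
    Channel.CO2: 1.0,
    Channel.T: 1.0,
    Channel.GASFL: 1.0,
    Channel.LAC: 1.0,
    Channel.PH: 1.0,
    Channel.DO: 0.5,
}

#: per-channel critical range distances, in raw channel units
CRITICAL_DISTANCES: dict[Channel, float] = {
    Channel.GLU: 0.8,
    Channel.O2: 0.5,
    Channel.CO2: 0.5,
    Channel.T: 0.5,
    Channel.GASFL: 0.2,
    Channel.LAC: 3.0,
    Channel.PH: 0.35,
    Channel.DO: 27.5,
}

GROUPS: dict[Channel, SensorGroup] = {
    Channel.GLU: SensorGroup.SP,
    Channel.O2: SensorGroup.SP,
    Channel.CO2: SensorGroup.SP,
    Channel.T: SensorGroup.SP,
    Channel.GASFL: SensorGroup.SP,
    Channel.LAC: SensorGroup.NSP,
    Channel.PH: SensorGroup.NSP,
    Channel.DO: SensorGroup.NSP,
}

#: setpoint / reference values per historical run preset; CO2 setpoint
#: changes mid-run in two presets (change time is a shipped convention)
RUN_REFERENCES: dict[str, dict[Channel, ReferenceSchedule]] = {
    "run1_like": {Channel.GLU: 20.0, Channel.O2: 21.0, Channel.CO2: 1.9},
    "run2_like": {Channel.GLU: 20.0, Channel.O2: 19.25, Channel.CO2: [(0.0, 5.0), (3.0, 0.0)]},
    "run3_like": {Channel.GLU: 20.0, Channel.O2: 19.25, Channel.CO2: 5.0},
    "run4_like": {Channel.GLU: 20.0, Channel.O2: 19.25, Channel.CO2: [(0.0, 5.0), (3.0, 1.9)]},
    "run5_like": {Channel.GLU: 19.0, Channel.O2: 19.25, Channel.CO2: 5.0},
}

COMMON_REFERENCES: dict[Channel, float] = {
    Channel.T: 37.0,
    Channel.GASFL: 10.0,
    Channel.LAC: 10.0,
    Channel.PH: 7.1,
    Channel.DO: 72.5,
}


def default_sensor_specs(
    run_preset: str = "run1_like",
    overrides: dict[Channel, ReferenceSchedule] | None = None,
) -> list[SensorSpec]:
    """Sensor specs for one run preset, optionally overriding references."""
    if run_preset not in RUN_REFERENCES:
        raise ParameterError(
            f"unknown run preset {run_preset!r}; choices: {sorted(RUN_REFERENCES)}"
        )
    refs: dict[Channel, ReferenceSchedule] = {**COMMON_REFERENCES, **RUN_REFERENCES[run_preset]}
    if overrides:
        refs.update({Channel(k): v for k, v in overrides.items()})
    return [
        SensorSpec(
            channel=ch,
            reference=refs[ch],
            scaling_weight=SCALING_WEIGHTS[ch],
            critical_distance=CRITICAL_DISTANCES[ch],
            group=GROUPS[ch],
        )
        for ch in SCALING_WEIGHTS
    ]


@dataclass
class PipelineConfig:
    """All tunables for the six smart sensors and the consensus layer."""

    window_minutes: float = 30.0
    estimator: str = "population"
    sdi_kappas: tuple[int, ...] = (2, 3, 4)
    sdi_min_count: int = 3
    sdi_cumulative: bool = False
    bollinger_K: float = 8.0
    bb_glucose_threshold: float = 25.0
    bb_lactate_threshold: float = 20.0
    zero_width_policy: str = "no_alert"
    wwa_sp_threshold: float = 0.1
    wwa_nsp_threshold: float = 0.35
    wwa_distance_mode: str = "relative"
    fuzzy_normal_full_until: float = 0.4
    fuzzy_alert_full_from: float = 1.2
    fuzzy_threshold: float = 0.45
    consensus_min_sensors: int = 3
    merge_gap_minutes: float = 30.0
    min_event_duration_minutes: float = 0.0
    run_preset: str = "run1_like"
    sensor_specs: list[SensorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sensor_specs:
            self.sensor_specs = default_sensor_specs(self.run_preset)

    # --- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        out = asdict(self)
        out["sdi_kappas"] = list(self.sdi_kappas)
        out["sensor_specs"] = [
            {
                "channel": spec.channel.value,
                "reference": (
                    [list(p) for p in spec.reference]
                    if not isinstance(spec.reference, (int, float))
                    else spec.reference
                ),
                "scaling_weight": spec.scaling_weight,
                "critical_distance": spec.critical_distance,
                "group": spec.group.value,
            }
            for spec in self.sensor_specs
        ]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        specs_raw = data.pop("sensor_specs", None)
        specs = []
        if specs_raw:
            for item in specs_raw:
                ref = item["reference"]
                if isinstance(ref, list):
                    ref = [(float(s), float(v)) for s, v in ref]
                specs.append(
                    SensorSpec(
                        channel=Channel(item["channel"]),
                        reference=ref,
                        scaling_weight=float(item["scaling_weight"]),
                        critical_distance=float(item["critical_distance"]),
                        group=SensorGroup(item["group"]),
                    )
                )
        if "sdi_kappas" in data:
            data["sdi_kappas"] = tuple(data["sdi_kappas"])
        cfg = cls(**data)
        if specs:
            cfg.sensor_specs = specs
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
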