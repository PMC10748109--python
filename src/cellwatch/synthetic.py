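"""Synthetic batch-run generator with injectable disturbances.

The real expansion-run data are proprietary, so this module produces
runs with the same qualitative structure: a noisy pre-stabilization
phase, glucose converging exponentially to its setpoint, lactate
drifting upward, dissolved oxygen declining and oscillating, pH easing
down from fresh-media values, temperature oscillating tightly around
37 degC, and stable exhaust-gas/flow channels.  Disturbances — transient
simultaneous glucose+lactate drops ("bubbles"), temperature dips,
channel dropouts, and a full shutdown with metabolite decline and
recovery — can be superimposed on any run.

Trend shapes (exponential convergence, linear drift, sinusoid, Gaussian
noise) are this package's own modelling conventions; all parameters are
exposed on the profile.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import DAY_SECONDS, BatchRun, Channel, ChannelSeries, rolling_stats
from .errors import ParameterError, ValidationError

DISTURBANCE_KINDS = ("bubble_drop", "temperature_dip", "shutdown", "channel_dropout")


@dataclass(frozen=True)
class ChannelModel:
    """Trend model for one channel.

    value(t) = target + (initial - target) * exp(-t / tau_days)
               + drift_per_day * t
               + osc_amplitude * sin(2*pi*t / osc_period_days)
               + N(0, noise_sd)
    """

    initial: float
    target: float
    tau_days: float = 0.5
    osc_amplitude: float = 0.0
    osc_period_days: float = 0.5
    drift_per_day: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.tau_days <= 0 or self.osc_period_days <= 0:
            raise ValidationError("time constants must be positive")

    def trend(self, t_days: np.ndarray) -> np.ndarray:
        return (
            self.target
            + (self.initial - self.target) * np.exp(-t_days / self.tau_days)
            + self.drift_per_day * t_days
            + self.osc_amplitude * np.sin(2 * math.pi * t_days / self.osc_period_days)
        )


@dataclass(frozen=True)
class DisturbanceSpec:
    """One injectable disturbance.

    ``amplitude`` is in multiples of the local trailing-window standard
    deviation when ``amplitude_mode`` is "sigma" (bubbles), or in raw
    channel units when "absolute" (temperature dips).
    """

    kind: str
    onset_days: float
    duration_minutes: float
    amplitude: float = 0.0
    amplitude_mode: str = "sigma"
    channels: tuple[Channel, ...] = ()
    recovery_minutes: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in DISTURBANCE_KINDS:
            raise ValidationError(f"kind must be one of {DISTURBANCE_KINDS}")
        if self.amplitude_mode not in ("sigma", "absolute"):
            raise ValidationError("amplitude_mode must be 'sigma' or 'absolute'")
        if self.duration_minutes < 0 or self.onset_days < 0:
            raise ValidationError("onset and duration must be non-negative")
        if self.kind in ("bubble_drop", "temperature_dip") and self.amplitude <= 0:
            raise ValidationError(f"{self.kind} needs a positive amplitude")
        object.__setattr__(self, "channels", tuple(Channel(c) for c in self.channels))

    @property
    def end_days(self) -> float:
        return self.onset_days + self.duration_minutes / 1440.0


@dataclass
class RunProfile:
    """Everything needed to synthesise one batch run deterministically."""

    run_id: str
    duration_days: float
    channels: dict[Channel, ChannelModel]
    sample_interval_s: float = 10.0
    prestabilization_hours: float = 12.0
    prestabilization_noise_boost: float = 2.0
    active: dict[Channel, bool] = field(default_factory=dict)
    disturbances: list[DisturbanceSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = {Channel(k): v for k, v in self.channels.items()}
        self.active = {Channel(k): bool(v) for k, v in self.active.items()}
        if self.duration_days <= 0 or self.sample_interval_s <= 0:
            raise ValidationError("duration and sample interval must be positive")
        if self.prestabilization_hours / 24.0 >= self.duration_days:
            raise ValidationError("pre-stabilization must be shorter than the run")
        for dist in self.disturbances:
            if dist.end_days > self.duration_days:
                raise ValidationError(
                    f"disturbance at {dist.onset_days}d runs past the end of the run"
                )

    def is_channel_active(self, channel: Channel) -> bool:
        return self.active.get(channel, True)


def generate_run(profile: RunProfile, seed: int | None = None) -> BatchRun:
    """Synthesise a batch run; the seed fully determines the output.

    Any disturbances listed on the profile are injected after the clean
    trends are generated.
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    step_days = profile.sample_interval_s / DAY_SECONDS
    n = int(math.floor(profile.duration_days / step_days)) + 1
    t = np.arange(n) * step_days

    prestab_days = profile.prestabilization_hours / 24.0
    if prestab_days > 0:
        noise_scale = 1.0 + profile.prestabilization_noise_boost * np.exp(-t / prestab_days)
    else:
        noise_scale = np.ones_like(t)

    channels: dict[Channel, ChannelSeries] = {}
    for ch, model in profile.channels.items():
        values = model.trend(t)
        if model.noise_sd > 0:
            values = values + rng.normal(0.0, model.noise_sd, size=n) * noise_scale
        active = np.ones(n, dtype=bool)
        if not profile.is_channel_active(ch):
            active[:] = False
            values = np.full(n, np.nan)
        channels[ch] = ChannelSeries(ch, t, values, active)

    run = BatchRun(
        run_id=profile.run_id,
        channels=channels,
        sample_interval=profile.sample_interval_s,
        metadata={"profile": profile.run_id, "seed": int(profile.seed if seed is None else seed)},
    )
    for dist in profile.disturbances:
        run = inject(run, dist)
    return run


def _local_sigma(cs: ChannelSeries, onset_days: float, window_minutes: float = 30.0) -> float:
    """Trailing-window std of the last full window before the onset."""
    stats = rolling_stats(cs, window_minutes)
    idx = int(np.searchsorted(cs.time_days, onset_days, side="left")) - 1
    sigmas = stats.std[: idx + 1]
    finite = sigmas[np.isfinite(sigmas)]
    if finite.size == 0:
        raise ParameterError("onset precedes the first full statistics window")
    return float(finite[-1])


def inject(run: BatchRun, spec: DisturbanceSpec) -> BatchRun:
    """Return a new run with the disturbance superimposed."""
    t = run.time_days
    if spec.onset_days < t[0] or spec.end_days > t[-1]:
        raise ValidationError("disturbance lies outside the run")
    mask = (t >= spec.onset_days) & (t < spec.end_days)
    new_channels = {ch: copy.deepcopy(cs) for ch, cs in run.channels.items()}
    metadata = copy.deepcopy(run.metadata)

    if spec.kind == "bubble_drop":
        if mask.any():
            for ch in (Channel.GLU, Channel.LAC):
                cs = new_channels[ch]
                drop = (
                    spec.amplitude * _local_sigma(cs, spec.onset_days)
                    if spec.amplitude_mode == "sigma"
                    else spec.amplitude
                )
                cs.values[mask] -= drop

    elif spec.kind == "temperature_dip":
        if mask.any():
            amp = spec.amplitude
            if spec.amplitude_mode == "sigma":
                amp *= _local_sigma(new_channels[Channel.T], spec.onset_days)
            new_channels[Channel.T].values[mask] -= amp

    elif spec.kind == "channel_dropout":
        if not spec.channels:
            raise ValidationError("channel_dropout needs a channel list")
        for ch in spec.channels:
            cs = new_channels[ch]
            cs.active[mask] = False
            cs.values[mask] = np.nan

    elif spec.kind == "shutdown":
        for lo, hi in metadata.get("shutdowns", []):
            if spec.onset_days < hi and spec.end_days > lo:
                raise ValidationError("overlapping shutdowns are not allowed")
        dur_days = spec.end_days - spec.onset_days
        if dur_days <= 0:
            return BatchRun(run.run_id, new_channels, run.sample_interval, metadata)
        rec_days = spec.recovery_minutes / 1440.0
        # metabolite signals ramp to zero during the outage, then recover
        decline = np.clip((t - spec.onset_days) / dur_days, 0.0, 1.0)
        factor = np.ones_like(t)
        factor[mask] = 1.0 - decline[mask]
        if rec_days > 0:
            rec_mask = (t >= spec.end_days) & (t < spec.end_days + rec_days)
            factor[rec_mask] = np.clip((t[rec_mask] - spec.end_days) / rec_days, 0.0, 1.0)
        for ch in (Channel.GLU, Channel.LAC):
            new_channels[ch].values *= factor
        # everything else goes dark for the outage
        for ch, cs in new_channels.items():
            if ch in (Channel.GLU, Channel.LAC):
                continue
            cs.active[mask] = False
            cs.values[mask] = np.nan
        metadata.setdefault("shutdowns", []).append((spec.onset_days, spec.end_days))

    return BatchRun(run.run_id, new_channels, run.sample_interval, metadata)


# --- shipped profiles ------------------------------------------------------


def _base_channels(
    glu_setpoint: float = 20.0,
    o2_setpoint: float = 21.0,
    co2_setpoint: float = 1.9,
) -> dict[Channel, ChannelModel]:
    return {
        Channel.GLU: ChannelModel(
            initial=25.0, target=glu_setpoint, tau_days=0.4, noise_sd=0.12
        ),
        Channel.LAC: ChannelModel(
            initial=5.0, target=5.0, tau_days=0.4, drift_per_day=0.9, noise_sd=0.12
        ),
        Channel.DO: ChannelModel(
            initial=80.0,
            target=74.0,
            tau_days=1.0,
            osc_amplitude=1.2,
            osc_period_days=0.6,
            drift_per_day=-0.4,
            noise_sd=0.35,
        ),
        Channel.PH: ChannelModel(
            initial=7.3, target=7.05, tau_days=1.0, drift_per_day=-0.004, noise_sd=0.008
        ),
        Channel.T: ChannelModel(
            initial=36.8,
            target=37.0,
            tau_days=0.1,
            osc_amplitude=0.06,
            osc_period_days=0.25,
            noise_sd=0.02,
        ),
        Channel.O2: ChannelModel(
            initial=20.0, target=o2_setpoint, tau_days=0.3, noise_sd=0.06
        ),
        Channel.CO2: ChannelModel(
            initial=3.0, target=co2_setpoint, tau_days=0.3, noise_sd=0.05
        ),
        Channel.GASFL: ChannelModel(initial=10.0, target=10.0, noise_sd=0.03),
    }


def _profile_run1(seed: int, **overrides) -> RunProfile:
    return RunProfile(
        run_id="run1_like",
        duration_days=6.0,
        channels=_base_channels(glu_setpoint=20.0, o2_setpoint=21.0, co2_setpoint=1.9),
        seed=seed,
        **overrides,
    )


def _profile_run2(seed: int, **overrides) -> RunProfile:
    channels = _base_channels(glu_setpoint=20.0, o2_setpoint=19.25, co2_setpoint=5.0)
    channels[Channel.GASFL] = ChannelModel(initial=10.0, target=10.0, noise_sd=0.0)
    return RunProfile(
        run_id="run2_like",
        duration_days=6.0,
        channels=channels,
        active={Channel.CO2: False},
        seed=seed,
        **overrides,
    )


def _profile_run3(seed: int, **overrides) -> RunProfile:
    return RunProfile(
        run_id="run3_like",
        duration_days=6.0,
        channels=_base_channels(glu_setpoint=20.0, o2_setpoint=19.25, co2_setpoint=5.0),
        disturbances=[
            DisturbanceSpec(
                kind="shutdown",
                onset_days=3.3,
                duration_minutes=8 * 60.0,
                recovery_minutes=90.0,
            )
        ],
        seed=seed,
        **overrides,
    )


def _profile_run4(seed: int, **overrides) -> RunProfile:
    channels = _base_channels(glu_setpoint=20.0, o2_setpoint=19.25, co2_setpoint=5.0)
    channels[Channel.GLU] = replace(channels[Channel.GLU], tau_days=0.8, noise_sd=0.18)
    channels[Channel.PH] = replace(channels[Channel.PH], target=7.0, noise_sd=0.012)
    return RunProfile(
        run_id="run4_like",
        duration_days=6.0,
        channels=channels,
        disturbances=[
            DisturbanceSpec("bubble_drop", onset_days=2.1, duration_minutes=5.0, amplitude=6.0),
            DisturbanceSpec("bubble_drop", onset_days=4.4, duration_minutes=5.0, amplitude=6.0),
        ],
        seed=seed,
        **overrides,
    )


def _profile_run5(seed: int, **overrides) -> RunProfile:
    channels = _base_channels(glu_setpoint=19.0, o2_setpoint=19.25, co2_setpoint=5.0)
    channels[Channel.GLU] = replace(
        channels[Channel.GLU], initial=26.0, tau_days=1.2, noise_sd=0.2
    )
    channels[Channel.PH] = replace(channels[Channel.PH], target=6.9, drift_per_day=-0.01)
    return RunProfile(
        run_id="run5_like",
        duration_days=6.0,
        channels=channels,
        disturbances=[
            DisturbanceSpec("bubble_drop", onset_days=1.6, duration_minutes=5.0, amplitude=6.0),
            DisturbanceSpec("bubble_drop", onset_days=3.7, duration_minutes=10.0, amplitude=7.0),
        ],
        seed=seed,
        **overrides,
    )


PROFILES = {
    "run1_like": _profile_run1,
    "run2_like": _profile_run2,
    "run3_like": _profile_run3,
    "run4_like": _profile_run4,
    "run5_like": _profile_run5,
}


def get_profile(
    name: str,
    seed: int = 0,
    duration_days: float | None = None,
    sample_interval_s: float | None = None,
) -> RunProfile:
    """Look up a shipped profile, optionally overriding size parameters."""
    if name not in PROFILES:
        raise ParameterError(f"unknown profile {name!r}; choices: {sorted(PROFILES)}")
    profile = PROFILES[name](seed)
    if duration_days is not None:
        profile.duration_days = duration_days
        profile.disturbances = [
            d for d in profile.disturbances if d.end_days <= duration_days
        ]
    if sample_interval_s is not None:
        profile.sample_interval_s = sample_interval_s
    return profile
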