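import numpy as np
import pytest

from cellwatch.core import Channel
from cellwatch.errors import ParameterError, ValidationError
from cellwatch.sdi import detect_disturbances
from cellwatch.synthetic import (
    PROFILES,
    ChannelModel,
    DisturbanceSpec,
    RunProfile,
    generate_run,
    get_profile,
    inject,
)


def small_profile(seed=0, **kwargs):
    defaults = dict(
        run_id="small",
        duration_days=1.0,
        sample_interval_s=60.0,
        prestabilization_hours=2.0,
        channels={
            Channel.GLU: ChannelModel(initial=25.0, target=20.0, tau_days=0.2, noise_sd=0.1),
            Channel.LAC: ChannelModel(initial=5.0, target=5.0, drift_per_day=1.0, noise_sd=0.1),
            Channel.T: ChannelModel(
                initial=37.0, target=37.0, osc_amplitude=0.05, osc_period_days=0.2
            ),
        },
        seed=seed,
    )
    defaults.update(kwargs)
    return RunProfile(**defaults)


class TestGenerateRun:
    def test_same_seed_is_bit_identical(self):
        r1 = generate_run(small_profile(seed=42))
        r2 = generate_run(small_profile(seed=42))
        for ch in r1.channels:
            np.testing.assert_array_equal(r1.channels[ch].values, r2.channels[ch].values)

    def test_different_seeds_differ(self):
        r1 = generate_run(small_profile(seed=1))
        r2 = generate_run(small_profile(seed=2))
        assert not np.array_equal(
            r1.channel(Channel.GLU).values, r2.channel(Channel.GLU).values
        )

    def test_zero_noise_follows_closed_form(self):
        prof = small_profile()
        prof.channels = {
            Channel.GLU: ChannelModel(initial=25.0, target=20.0, tau_days=0.2, noise_sd=0.0),
            Channel.T: ChannelModel(
                initial=37.0, target=37.0, osc_amplitude=0.05, osc_period_days=0.2, noise_sd=0.0
            ),
        }
        run = generate_run(prof)
        t = run.time_days
        expected_glu = 20.0 + 5.0 * np.exp(-t / 0.2)
        expected_t = 37.0 + 0.05 * np.sin(2 * np.pi * t / 0.2)
        np.testing.assert_allclose(run.channel(Channel.GLU).values, expected_glu, atol=1e-12)
        np.testing.assert_allclose(run.channel(Channel.T).values, expected_t, atol=1e-12)

    def test_inactive_channel_is_all_nan(self):
        prof = small_profile(active={Channel.LAC: False})
        run = generate_run(prof)
        assert not run.channel(Channel.LAC).is_active
        assert np.isnan(run.channel(Channel.LAC).values).all()

    def test_converged_mean_tracks_setpoint(self):
        """Monte-Carlo: tail mean over replicates within 3 standard errors."""
        tail_means = []
        for seed in range(50):
            run = generate_run(small_profile(seed=seed))
            glu = run.channel(Channel.GLU).values
            tail_means.append(glu[len(glu) // 2 :].mean())
        tail_means = np.asarray(tail_means)
        # residual exponential bias over the sampled tail, same for every seed
        t = generate_run(small_profile()).time_days
        bias = (5.0 * np.exp(-t[len(t) // 2 :] / 0.2)).mean()
        se = tail_means.std(ddof=1) / np.sqrt(len(tail_means))
        assert abs(tail_means.mean() - (20.0 + bias)) < 3 * se

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValidationError):
            small_profile(duration_days=-1.0)
        with pytest.raises(ValidationError):
            small_profile(prestabilization_hours=48.0)  # longer than the run
        with pytest.raises(ValidationError):
            ChannelModel(initial=0, target=0, noise_sd=-1.0)


class TestInject:
    def test_zero_duration_is_identity(self):
        run = generate_run(small_profile(seed=5))
        out = inject(
            run,
            DisturbanceSpec("bubble_drop", onset_days=0.5, duration_minutes=0.0, amplitude=5.0),
        )
        np.testing.assert_array_equal(
            out.channel(Channel.GLU).values, run.channel(Channel.GLU).values
        )

    def test_bubble_drop_detected_by_sdi(self):
        run = generate_run(small_profile(seed=11))
        spec = DisturbanceSpec("bubble_drop", onset_days=0.6, duration_minutes=5.0, amplitude=6.0)
        out = inject(run, spec)
        events = detect_disturbances(out.channel(Channel.GLU), out.channel(Channel.LAC))
        assert any(abs(d.time_days - 0.6) <= 30.0 / 1440.0 for d in events)

    def test_bubble_outside_run_rejected(self):
        run = generate_run(small_profile())
        with pytest.raises(ValidationError):
            inject(run, DisturbanceSpec("bubble_drop", onset_days=0.99,
                                        duration_minutes=60.0, amplitude=5.0))

    def test_temperature_dip(self):
        run = generate_run(small_profile(seed=3))
        spec = DisturbanceSpec("temperature_dip", onset_days=0.5, duration_minutes=10.0,
                               amplitude=1.0, amplitude_mode="absolute")
        out = inject(run, spec)
        mask = (run.time_days >= 0.5) & (run.time_days < 0.5 + 10.0 / 1440.0)
        np.testing.assert_allclose(
            out.channel(Channel.T).values[mask],
            run.channel(Channel.T).values[mask] - 1.0,
        )

    def test_channel_dropout(self):
        run = generate_run(small_profile(seed=3))
        spec = DisturbanceSpec("channel_dropout", onset_days=0.4, duration_minutes=30.0,
                               channels=(Channel.T,))
        out = inject(run, spec)
        mask = (run.time_days >= 0.4) & (run.time_days < 0.4 + 30.0 / 1440.0)
        assert np.isnan(out.channel(Channel.T).values[mask]).all()
        assert not out.channel(Channel.T).active[mask].any()
        assert out.channel(Channel.T).active[~mask].all()

    def test_shutdown_ramps_metabolites_and_darkens_others(self):
        run = generate_run(small_profile(seed=9))
        spec = DisturbanceSpec("shutdown", onset_days=0.4, duration_minutes=4 * 60.0,
                               recovery_minutes=30.0)
        out = inject(run, spec)
        t = run.time_days
        outage = (t >= 0.4) & (t < 0.4 + 4.0 / 24.0)
        # glucose declines towards zero and reaches ~0 near the outage end
        end_idx = np.where(outage)[0][-1]
        assert out.channel(Channel.GLU).values[end_idx] < 0.1 * run.channel(
            Channel.GLU
        ).values[end_idx]
        assert not out.channel(Channel.T).active[outage].any()
        # fully restored after the recovery ramp
        after = t >= 0.4 + 4.0 / 24.0 + 30.0 / 1440.0
        np.testing.assert_allclose(
            out.channel(Channel.GLU).values[after], run.channel(Channel.GLU).values[after]
        )
        assert out.channel(Channel.T).active[after].all()

    def test_overlapping_shutdowns_rejected(self):
        run = generate_run(small_profile(seed=9))
        first = DisturbanceSpec("shutdown", onset_days=0.3, duration_minutes=120.0)
        second = DisturbanceSpec("shutdown", onset_days=0.35, duration_minutes=120.0)
        out = inject(run, first)
        with pytest.raises(ValidationError):
            inject(out, second)

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValidationError):
            DisturbanceSpec("flood", onset_days=0.1, duration_minutes=5.0)


class TestProfiles:
    def test_all_profiles_generate(self):
        for name in PROFILES:
            prof = get_profile(name, seed=1, duration_days=0.5, sample_interval_s=60.0)
            run = generate_run(prof)
            assert run.n_samples > 0

    def test_run2_has_inactive_co2_and_constant_gasfl(self):
        run = generate_run(get_profile("run2_like", seed=1, duration_days=0.5,
                                       sample_interval_s=60.0))
        assert not run.channel(Channel.CO2).is_active
        assert np.ptp(run.channel(Channel.GASFL).values) == 0.0

    def test_run3_contains_shutdown_between_days_3_and_4(self):
        run = generate_run(get_profile("run3_like", seed=1, sample_interval_s=120.0))
        (lo, hi), = run.metadata["shutdowns"]
        assert 3.0 <= lo < hi <= 4.0
        t = run.time_days
        outage = (t >= lo) & (t < hi)
        assert not run.channel(Channel.DO).active[outage].any()

    def test_unknown_profile_rejected(self):
        with pytest.raises(ParameterError):
            get_profile("run9_like")

    def test_event_recovery_rate(self):
        """Injected 5-sigma bubbles are recovered within one window >= 95%."""
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            prof = get_profile("run1_like", seed=seed, duration_days=1.0,
                               sample_interval_s=30.0)
            run = generate_run(prof)
            out = inject(run, DisturbanceSpec("bubble_drop", onset_days=0.5,
                                              duration_minutes=5.0, amplitude=5.0))
            events = detect_disturbances(out.channel(Channel.GLU), out.channel(Channel.LAC))
            if any(abs(d.time_days - 0.5) <= 30.0 / 1440.0 for d in events):
                hits += 1
        assert hits / n_runs >= 0.95
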