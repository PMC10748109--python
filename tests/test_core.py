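import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellwatch.core import (
    DAY_SECONDS,
    BatchRun,
    Channel,
    ChannelSeries,
    align_run,
    align_runs,
    rolling_stats,
)
from cellwatch.errors import ChannelUnavailableError, GridError, ParameterError

from conftest import make_series


def brute_rolling(values, w, ddof=0):
    """Independent per-window recomputation oracle."""
    n = len(values)
    mean = np.full(n, np.nan)
    std = np.full(n, np.nan)
    for i in range(w - 1, n):
        win = np.asarray(values[i - w + 1 : i + 1], dtype=float)
        mean[i] = win.mean()
        std[i] = win.std(ddof=ddof)
    return mean, std


class TestRollingStats:
    def test_constant_series_has_zero_std(self):
        s = make_series([7.5] * 50)
        ws = rolling_stats(s, window_minutes=1.0)  # 6 samples at 10 s
        assert np.allclose(ws.mean[5:], 7.5)
        assert np.allclose(ws.std[5:], 0.0)
        assert np.isnan(ws.mean[:5]).all()

    def test_three_sample_window_population(self):
        s = make_series([1.0, 2.0, 3.0])
        ws = rolling_stats(s, window_minutes=0.5)  # 3 samples
        assert ws.window_samples == 3
        assert ws.mean[2] == pytest.approx(2.0)
        assert ws.std[2] == pytest.approx(math.sqrt(2.0 / 3.0))
        assert np.isnan(ws.mean[:2]).all()

    def test_three_sample_window_sample_estimator(self):
        s = make_series([1.0, 2.0, 3.0])
        ws = rolling_stats(s, window_minutes=0.5, estimator="sample")
        assert ws.std[2] == pytest.approx(1.0)

    def test_alternating_two_sample_window(self):
        a, b = 3.0, 9.0
        s = make_series([a, b] * 10)
        ws = rolling_stats(s, window_minutes=1.0 / 3.0)  # 2 samples
        assert np.allclose(ws.mean[1:], (a + b) / 2.0)

    def test_window_too_short_rejected(self):
        s = make_series(np.arange(10.0))
        with pytest.raises(ParameterError):
            rolling_stats(s, window_minutes=10.0 / 60.0)  # one sample

    def test_inactive_channel_rejected(self):
        s = make_series([np.nan] * 10, active=np.zeros(10, bool))
        with pytest.raises(ChannelUnavailableError):
            rolling_stats(s, window_minutes=1.0)

    def test_matches_brute_force_oracle(self, rng):
        values = rng.normal(5.0, 2.0, size=500)
        s = make_series(values)
        for minutes, w in [(0.5, 3), (2.0, 12), (10.0, 60)]:
            ws = rolling_stats(s, minutes)
            bm, bs = brute_rolling(values, w)
            np.testing.assert_allclose(ws.mean, bm, equal_nan=True, atol=1e-10)
            np.testing.assert_allclose(ws.std, bs, equal_nan=True, atol=1e-10)

    @given(
        offset=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 50, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_properties(self, offset, scale):
        base = np.sin(np.arange(80) / 5.0) * 3.0 + 10.0
        ws0 = rolling_stats(make_series(base), 2.0)
        ws1 = rolling_stats(make_series(base + offset), 2.0)
        ws2 = rolling_stats(make_series(base * scale), 2.0)
        np.testing.assert_allclose(ws1.mean, ws0.mean + offset, equal_nan=True, atol=1e-8)
        np.testing.assert_allclose(ws1.std, ws0.std, equal_nan=True, atol=1e-8)
        np.testing.assert_allclose(ws2.mean, ws0.mean * scale, equal_nan=True, rtol=1e-8)
        np.testing.assert_allclose(ws2.std, ws0.std * scale, equal_nan=True, atol=1e-8)


class TestGridValidation:
    def test_non_uniform_grid_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0]) / DAY_SECONDS
        with pytest.raises(GridError):
            ChannelSeries(Channel.GLU, t, np.zeros(4))

    def test_decreasing_grid_rejected(self):
        t = np.array([0.0, 2.0, 1.0]) / DAY_SECONDS
        with pytest.raises(GridError):
            ChannelSeries(Channel.GLU, t, np.zeros(3))

    def test_mismatched_channel_grids_rejected(self):
        a = make_series(np.zeros(5), interval_s=10.0)
        b = make_series(np.zeros(5), interval_s=20.0, channel=Channel.LAC)
        with pytest.raises(GridError):
            BatchRun("r", {Channel.GLU: a, Channel.LAC: b}, sample_interval=10.0)


def _tiny_run(values_by_channel, interval_s=10.0):
    channels = {
        ch: make_series(v, interval_s=interval_s, channel=ch)
        for ch, v in values_by_channel.items()
    }
    return BatchRun("r", channels, sample_interval=interval_s)


class TestAlignRuns:
    def test_identity_interval(self):
        run = _tiny_run({Channel.GLU: np.arange(20.0)})
        out = align_run(run, 10.0)
        assert out is run

    def test_constant_stays_constant(self):
        run = _tiny_run({Channel.GLU: np.full(360, 4.2)})
        out = align_run(run, 1800.0)  # 30 min grid
        assert out.n_samples == 2
        assert np.allclose(out.channel(Channel.GLU).values, 4.2)

    def test_linear_ramp_matches_direct_averaging(self):
        values = np.arange(720, dtype=float) * 0.01
        run = _tiny_run({Channel.GLU: values})
        out = align_run(run, 600.0)  # 60:1 downsample
        expected = values[: 12 * 60].reshape(12, 60).mean(axis=1)
        np.testing.assert_allclose(out.channel(Channel.GLU).values, expected)
        # stamped at the trailing edge of each block
        np.testing.assert_allclose(
            out.time_days, run.time_days[59::60][:12], atol=1e-12
        )

    def test_incompatible_interval_rejected(self):
        run = _tiny_run({Channel.GLU: np.zeros(100)})
        with pytest.raises(ParameterError):
            align_run(run, 25.0)

    def test_activity_propagated(self):
        vals = np.full(60, 1.0)
        vals[10:20] = np.nan
        run = _tiny_run({Channel.GLU: vals})
        out = align_run(run, 100.0)  # blocks of 10
        active = out.channel(Channel.GLU).active
        assert not active[1]
        assert active[0] and active[2:].all()

    def test_align_runs_plural(self):
        runs = [_tiny_run({Channel.GLU: np.arange(60.0)}) for _ in range(2)]
        outs = align_runs(runs, 60.0)
        assert all(o.sample_interval == 60.0 for o in outs)


class TestCsvRoundTrip:
    def test_round_trip_with_inactive_channel(self, tmp_path, rng):
        n = 50
        channels = {
            Channel.GLU: make_series(rng.normal(20, 0.2, n), channel=Channel.GLU),
            Channel.LAC: make_series(rng.normal(8, 0.2, n), channel=Channel.LAC),
            Channel.CO2: make_series(
                np.full(n, np.nan), channel=Channel.CO2, active=np.zeros(n, bool)
            ),
        }
        run = BatchRun("rt", channels, sample_interval=10.0)
        path = tmp_path / "run.csv"
        run.write_csv(path)
        back = BatchRun.read_csv(path, run_id="rt")
        np.testing.assert_allclose(back.time_days, run.time_days, atol=1e-12)
        np.testing.assert_allclose(
            back.channel(Channel.GLU).values, run.channel(Channel.GLU).values, rtol=1e-9
        )
        assert not back.channel(Channel.CO2).is_active
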