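"""SMF and band-power feature contracts."""

import numpy as np
import pytest

import slowfield as sf
from slowfield import features as ft
from slowfield.errors import (
    DegenerateChannelError,
    InsufficientBaselineError,
    WindowBoundsError,
)

from conftest import make_manual_session


def _noise_session(rng, n_samples=60000, n_ch=84):
    arr = sf.make_sensor_array(n_ch, seed=0)
    data = rng.standard_normal((n_ch, n_samples))
    return make_manual_session(data, array=arr)


class TestBaseline:
    def test_standard_normal_moments(self, rng):
        ses = _noise_session(rng)
        stats = sf.compute_baseline_stats(ses)
        assert np.all(np.abs(stats.mean) < 0.02)
        assert np.allclose(stats.sd, 1.0, atol=0.02)
        assert stats.n_samples == 50000

    def test_constant_channel_raises_named_channel(self, rng):
        ses = _noise_session(rng)
        ses.data[5] = 3.14
        with pytest.raises(DegenerateChannelError) as exc:
            sf.compute_baseline_stats(ses)
        assert 5 in exc.value.channels

    def test_short_session_rejected(self, rng):
        ses = _noise_session(rng, n_samples=49000)
        with pytest.raises(InsufficientBaselineError):
            sf.compute_baseline_stats(ses)


class TestSMF:
    def test_window_arithmetic(self, rng):
        ses = _noise_session(rng)
        # overwrite channel 0: baseline mean 100, SD 50, then a 0..499 ramp
        ses.data[0, :50000] = 100.0 + 50.0 * np.tile(
            [1.0, -1.0], 25000)  # mean 100, SD 50 exactly
        ses.data[0, 55000:55500] = np.arange(500.0)
        stats = sf.compute_baseline_stats(ses)
        fw = sf.compute_smf(ses, stats, 55500.0)
        assert fw.kind == "smf"
        assert fw.values.shape == (84,)
        assert fw.values[0] == pytest.approx((249.5 - 100.0) / 50.0, abs=1e-9)
        # a window equal to the baseline mean gives exactly zero
        ses.data[0, 56000:56500] = 100.0
        fw0 = sf.compute_smf(ses, stats, 56500.0)
        assert fw0.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_window(self, rng):
        ses = _noise_session(rng)
        stats = sf.compute_baseline_stats(ses)
        with pytest.raises(WindowBoundsError):
            sf.compute_smf(ses, stats, 400.0)
        with pytest.raises(WindowBoundsError):
            sf.compute_smf(ses, stats, 60001.0)

    def test_affine_invariance(self, rng):
        """Per-channel gain/offset applied to the raw data cancels in the
        z-scored SMF."""
        ses = _noise_session(rng)
        stats = sf.compute_baseline_stats(ses)
        ref = sf.compute_smf(ses, stats, 55500.0).values
        gains = rng.uniform(0.5, 4.0, size=84)
        offsets = rng.uniform(-10, 10, size=84)
        scaled = make_manual_session(
            ses.data * gains[:, None] + offsets[:, None],
            array=ses.sensor_array)
        stats2 = sf.compute_baseline_stats(scaled)
        got = sf.compute_smf(scaled, stats2, 55500.0).values
        assert np.allclose(got, ref, atol=1e-9)

    def test_translation_equivariance(self, rng):
        ses = _noise_session(rng)
        stats = sf.compute_baseline_stats(ses)
        shift = 700  # ms == samples at 1 kHz
        rolled = make_manual_session(
            np.concatenate([ses.data[:, :50000],
                            np.zeros((84, shift)),
                            ses.data[:, 50000:]], axis=1),
            array=ses.sensor_array)
        stats2 = sf.compute_baseline_stats(rolled)
        a = sf.compute_smf(ses, stats, 55500.0).values
        b = sf.compute_smf(rolled, stats2, 55500.0 + shift).values
        assert np.allclose(a, b, atol=1e-12)


class TestBandPower:
    def test_spectral_support(self, rng):
        ses = _noise_session(rng)
        t = np.arange(500) / 1000.0
        alpha_w = np.sin(2 * np.pi * 10.0 * t)
        gamma_w = np.sin(2 * np.pi * 100.0 * t)
        pa_alpha = ft.window_band_power(alpha_w, "alpha", 1000.0)[0]
        pa_gamma = ft.window_band_power(alpha_w, "high_gamma", 1000.0)[0]
        pg_alpha = ft.window_band_power(gamma_w, "alpha", 1000.0)[0]
        pg_gamma = ft.window_band_power(gamma_w, "high_gamma", 1000.0)[0]
        assert pa_alpha > 0 and pg_gamma > 0
        assert pa_gamma < 1e-10 * pa_alpha
        assert pg_alpha < 1e-10 * pg_gamma

    def test_parseval_partition(self, rng, monkeypatch):
        """Summed one-sided power over the full band equals variance x n for
        a zero-mean window (the scaling convention of the band features)."""
        monkeypatch.setitem(ft.BANDS, "full", (0.0, 500.1))
        x = rng.standard_normal(500)
        x -= x.mean()
        total = ft.window_band_power(x, "full", 1000.0)[0]
        assert total == pytest.approx(x.var() * 500, rel=1e-9)

    def test_zscored_band_feature(self, rng):
        ses = _noise_session(rng)
        stats = sf.compute_baseline_stats(ses)
        fw = sf.compute_band_power(ses, stats, 55500.0, "alpha")
        assert fw.kind == "alpha"
        assert fw.values.shape == (84,)
        assert np.all(np.isfinite(fw.values))
        # raw (un-normalized) powers are non-negative
        raw = sf.compute_band_power(ses, stats, 55500.0, "alpha",
                                    zscore=False)
        assert np.all(raw.values >= 0)

    def test_unknown_band_rejected(self, rng):
        ses = _noise_session(rng)
        stats = sf.compute_baseline_stats(ses)
        with pytest.raises(ValueError):
            sf.compute_band_power(ses, stats, 55500.0, "delta")


class TestWindowGrid:
    def test_grid_ends(self):
        g = sf.WindowGrid(-2000, 1000, 100)
        ends = g.ends()
        assert ends[0] == -2000 and ends[-1] == 1000 and len(ends) == 31

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            sf.WindowGrid(0, 1000, 0)
        with pytest.raises(ValueError):
            sf.WindowGrid(1000, 0, 100)
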