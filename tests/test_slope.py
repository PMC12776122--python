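"""Wavelet power and aperiodic-slope estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from aperislope.slope import (
    FrequencyGrid,
    WaveletPair,
    condition_average,
    fit_slope_timecourse,
    moving_average,
    smooth_and_censor,
    wavelet_power,
)
from aperislope.synth import synthesize_power_law_epochs

FS = 512.0
INTERIOR = slice(300, 700)  # mid-epoch samples, clear of kernel edges


class TestWaveletPair:
    @pytest.mark.parametrize("f", [2.5, 5.0, 7.5, 15.0, 25.0])
    def test_kernel_invariants(self, f):
        pair = WaveletPair(freq=f, fs=FS)
        assert pair.n_samples == round(FS / f)
        assert abs(pair.cos_kernel.sum()) < 1e-12
        assert abs(pair.sin_kernel.sum()) < 1e-12
        # quadrature
        assert abs(pair.cos_kernel @ pair.sin_kernel) < 1e-12

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            FrequencyGrid(freqs=(5.0, 2.5))
        with pytest.raises(ValueError):
            FrequencyGrid(freqs=(-1.0, 5.0))
        with pytest.raises(ValueError):
            FrequencyGrid(fit_mask=(True, False, False, False, False))
        grid = FrequencyGrid()
        assert grid.fit_mask == (True, True, False, False, True)


class TestWaveletPower:
    def test_dc_input_zero_power(self):
        grid = FrequencyGrid()
        p = wavelet_power(np.full(1024, 7.0), grid, fs=FS)
        assert np.abs(p[..., INTERIOR]).max() < 1e-20

    def test_unit_sinusoid_amplitude_normalization(self):
        """Amplitude mode: unit 5 Hz sinusoid -> power 1 at 5 Hz, ~0 at 25 Hz."""
        t = np.arange(1024) / FS
        grid = FrequencyGrid()
        p = wavelet_power(np.sin(2 * np.pi * 5.0 * t), grid, fs=FS,
                          normalization="amplitude")
        k5 = grid.freqs.index(5.0)
        k25 = grid.freqs.index(25.0)
        assert p[0, 0, k5, INTERIOR].mean() == pytest.approx(1.0, abs=0.02)
        assert p[0, 0, k25, INTERIOR].mean() < 0.1

    def test_amplitude_squared_scaling(self):
        t = np.arange(1024) / FS
        grid = FrequencyGrid()
        p1 = wavelet_power(np.sin(2 * np.pi * 5.0 * t), grid, fs=FS)
        p3 = wavelet_power(3.0 * np.sin(2 * np.pi * 5.0 * t), grid, fs=FS)
        assert np.allclose(p3, 9.0 * p1, rtol=1e-10, atol=1e-12)

    def test_power_nonnegative(self, rng):
        p = wavelet_power(rng.standard_normal((4, 2, 1024)), fs=FS)
        assert (p >= 0).all()

    def test_epoch_shorter_than_kernel(self, rng):
        with pytest.raises(ValueError, match="2.5"):
            wavelet_power(rng.standard_normal(128), fs=FS)

    def test_density_mode_flat_for_white_noise(self, rng):
        """uV^2/Hz density of white noise is frequency-independent."""
        grid = FrequencyGrid()
        sig = rng.standard_normal((200, 1, 1024))
        p = wavelet_power(sig, grid, fs=FS)
        dens = p[..., INTERIOR].mean(axis=(0, 1, 3))
        assert np.ptp(dens) / dens.mean() < 0.05
        # and matches the white-noise one-sided PSD 2 sigma^2 / fs
        assert dens.mean() == pytest.approx(2.0 / FS, rel=0.05)


class TestFitSlope:
    def test_collinear_power_law_exact(self):
        """P(f) = f^-2 at the fit frequencies -> slope exactly -2."""
        grid = FrequencyGrid()
        f = np.asarray(grid.freqs)
        power = np.tile((f**-2.0)[None, None, :, None], (1, 1, 1, 64))
        ss = fit_slope_timecourse(power, grid, relative_floor=0.0, floor=0.0)
        assert np.allclose(ss.slope, -2.0, atol=1e-12)
        assert np.allclose(ss.intercept, 0.0, atol=1e-12)

    def test_equal_power_zero_slope(self):
        grid = FrequencyGrid()
        power = np.ones((2, 3, 5, 64))
        ss = fit_slope_timecourse(power, grid)
        assert np.allclose(ss.slope, 0.0, atol=1e-14)

    def test_negative_power_rejected(self):
        grid = FrequencyGrid()
        with pytest.raises(ValueError, match="negative"):
            fit_slope_timecourse(-np.ones((1, 1, 5, 64)), grid)

    def test_all_floor_flagged(self):
        grid = FrequencyGrid()
        ss = fit_slope_timecourse(np.zeros((2, 1, 5, 64)), grid)
        assert np.allclose(ss.slope, 0.0)
        assert not ss.valid_mask.any()

    @pytest.mark.parametrize("x", [1.0, 1.5, 2.0])
    def test_power_law_recovery(self, x):
        """Mean fitted slope of constant-exponent epochs is within 0.2 of -x
        (cross-checked against a Welch oracle on the same realizations)."""
        rng = np.random.default_rng(42)
        sig = synthesize_power_law_epochs(x, FS, 1024, rng, size=60)
        p = wavelet_power(sig[:, None, :], fs=FS)
        ss = fit_slope_timecourse(p, fs=FS)
        est = ss.slope[:, :, INTERIOR].mean()
        assert est == pytest.approx(-x, abs=0.2)
        f, pxx = sps.welch(sig, fs=FS, nperseg=512, axis=-1)
        m = (f >= 2) & (f <= 40)
        welch = np.polyfit(np.log10(f[m]), np.log10(pxx[:, m].mean(axis=0)), 1)[0]
        assert est == pytest.approx(welch, abs=0.25)

    def test_scale_equivariance(self, rng):
        """Scaling the signal by c leaves the slope untouched and shifts the
        intercept by 2 log10 c."""
        sig = synthesize_power_law_epochs(1.5, FS, 1024, rng, size=4)
        grid = FrequencyGrid()
        p1 = wavelet_power(sig[:, None, :], grid, fs=FS)
        p2 = wavelet_power(10.0 * sig[:, None, :], grid, fs=FS)
        s1 = fit_slope_timecourse(p1, grid)
        s2 = fit_slope_timecourse(p2, grid)
        assert np.allclose(s1.slope, s2.slope, atol=1e-9)
        assert np.allclose(s2.intercept - s1.intercept, 2.0, atol=1e-9)

    def test_alpha_immunity_at_default_level(self):
        """A 10 Hz oscillation at the generator's default amplitude ratio
        (0.3x the broadband SD) shifts the mean slope by < 0.1, because the
        7.5-15 Hz grid points are excluded from the fit."""
        shifts = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            sig = synthesize_power_law_epochs(1.5, FS, 1024, rng, size=60)
            t = np.arange(1024) / FS
            phases = rng.uniform(0, 2 * np.pi, (60, 1))
            alpha = 0.3 * np.sin(2 * np.pi * 10.0 * t + phases)
            est = []
            for s in (sig, sig + alpha):
                p = wavelet_power(s[:, None, :], fs=FS)
                ss = fit_slope_timecourse(p, fs=FS)
                est.append(ss.slope[:, :, INTERIOR].mean())
            shifts.append(abs(est[1] - est[0]))
        assert np.mean(shifts) < 0.1


class TestSmoothAndCensor:
    def test_constant_series_unchanged(self):
        from aperislope.slope import SlopeSeries

        s = np.full((3, 2, 64), -1.5)
        ss = SlopeSeries(slope=s, intercept=s * 0, valid_mask=np.ones(3, bool))
        out, n = smooth_and_censor(ss)
        assert np.allclose(out.slope, -1.5)
        assert n == 0

    def test_impulse_spread(self):
        x = np.zeros((1, 1, 64))
        x[0, 0, 32] = 1.0
        y = moving_average(x, 5)
        assert np.allclose(y[0, 0, 30:35], 0.2)
        assert y.sum() == pytest.approx(1.0)

    def test_shrinking_edges(self):
        x = np.ones((1, 1, 10))
        y = moving_average(x, 5)
        assert np.allclose(y, 1.0)  # mean of ones is one even at edges

    def test_even_k_rejected(self):
        from aperislope.slope import SlopeSeries

        ss = SlopeSeries(
            slope=np.zeros((1, 1, 16)), intercept=np.zeros((1, 1, 16)),
            valid_mask=np.ones(1, bool),
        )
        with pytest.raises(ValueError):
            smooth_and_censor(ss, k=4)
        with pytest.raises(ValueError):
            smooth_and_censor(ss, bound=-1.0)

    def test_censor_rule(self):
        from aperislope.slope import SlopeSeries

        s = np.zeros((2, 1, 64))
        s[0, 0, 20] = -5.0  # exceeds the bound after smoothing? -5/5 = -1.0
        s[0, 0, 18:23] = -5.0  # sustained, survives the moving average
        ss = SlopeSeries(
            slope=s, intercept=s * 0, valid_mask=np.ones(2, bool),
        )
        out, n = smooth_and_censor(ss, bound=4.0)
        assert n == 1
        assert list(out.valid_mask) == [False, True]


class TestConditionAverage:
    def _series(self, slopes, links=None):
        from aperislope.slope import SlopeSeries

        slopes = np.asarray(slopes, dtype=float)
        return SlopeSeries(
            slope=slopes,
            intercept=np.zeros_like(slopes),
            valid_mask=np.ones(slopes.shape[0], bool),
            times=np.arange(slopes.shape[-1], dtype=float),
            trial_link=links,
        )

    def _trials(self, cells, participant=1):
        return pd.DataFrame(
            {
                "participant": participant,
                "prev_congruency": [c[0] for c in cells],
                "curr_congruency": [c[1] for c in cells],
            }
        )

    def test_single_trial_cell(self):
        cells = [("congruent", "congruent")]
        ss = self._series(np.full((1, 2, 8), -1.3))
        with pytest.warns(UserWarning):
            maps = condition_average(ss, self._trials(cells))
        assert np.allclose(maps.values[0, 0], -1.3)
        assert maps.counts[0, 0] == 1
        assert len(maps.missing_cells) == 3

    def test_pooled_mean_identity(self, rng):
        """Pooled mean equals the trial-count-weighted mean of cell means."""
        cells = [("congruent", "congruent")] * 3 + [
            ("congruent", "incongruent")
        ] * 5
        slopes = rng.standard_normal((8, 2, 16))
        with pytest.warns(UserWarning):
            maps = condition_average(self._series(slopes), self._trials(cells))
        pooled = slopes.mean(axis=0)
        weighted = (
            3 * maps.values[0, 0] + 5 * maps.values[0, 1]
        ) / 8.0
        assert np.allclose(pooled, weighted, atol=1e-12)

    def test_censored_trials_excluded(self):
        cells = [("congruent", "congruent")] * 2
        ss = self._series(np.stack([np.full((2, 8), -1.0),
                                    np.full((2, 8), -9.0)]))
        ss.valid_mask[1] = False
        with pytest.warns(UserWarning):
            maps = condition_average(ss, self._trials(cells))
        assert np.allclose(maps.values[0, 0], -1.0)
        assert maps.counts[0, 0] == 1
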