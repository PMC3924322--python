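"""ACT, band power, orientation reduction and detrending."""

import numpy as np
import pytest
from scipy import signal as sps

from neuroais.datatypes import EpochedSeries
from neuroais.signal_features import (
    autocorrelation_decay_time,
    band_power,
    dominant_orientation,
    linear_detrend,
    multitaper_taper_count,
)
from conftest import make_ar1


class TestACT:
    def test_white_noise_decays_immediately(self, white_noise_epochs):
        act = autocorrelation_decay_time(white_noise_epochs, max_lag=50)
        assert act.lag_samples == 1 and not act.overflow
        assert act.acf_curve[0] == pytest.approx(1.0)

    def test_ar1_theoretical_decay(self):
        # phi = e^(-1/5): ACF(l) = e^(-l/5) crosses 1/e at lag 5
        phi = np.exp(-1.0 / 5.0)
        x = make_ar1(phi, 50_000, seed=21).reshape(50, 1000)
        act = autocorrelation_decay_time(EpochedSeries(x, 100.0), max_lag=100)
        assert abs(act.lag_samples - 5) <= 1
        assert act.lag_seconds == act.lag_samples / 100.0

    def test_slow_sinusoid_overflows(self):
        # ACF of a sinusoid is cos(2*pi*f*lag/fs): for f low enough it never
        # reaches 1/e within max_lag, raising the overflow flag
        t = np.arange(3000) / 300.0
        x = np.tile(np.sin(2 * np.pi * 0.5 * t), (3, 1))
        act = autocorrelation_decay_time(EpochedSeries(x, 300.0), max_lag=100)
        assert act.overflow and act.lag_samples == 100

    def test_fast_sinusoid_first_crossing(self):
        # at 10 Hz / 300 Hz the cosine ACF first dips below 1/e at lag 6
        t = np.arange(3000) / 300.0
        x = np.tile(np.sin(2 * np.pi * 10 * t), (3, 1))
        act = autocorrelation_decay_time(EpochedSeries(x, 300.0), max_lag=100)
        assert not act.overflow and abs(act.lag_samples - 6) <= 1

    def test_constant_trial_rejected(self):
        epochs = EpochedSeries(np.ones((3, 50)), 1.0)
        with pytest.raises(ValueError, match="constant"):
            autocorrelation_decay_time(epochs, max_lag=10)

    def test_max_lag_validation(self, white_noise_epochs):
        with pytest.raises(ValueError, match="max_lag"):
            autocorrelation_decay_time(white_noise_epochs, max_lag=300)

    def test_monotone_in_phi(self):
        lags = []
        for phi in (0.5, 0.7, 0.9):
            x = make_ar1(phi, 40_000, seed=31).reshape(40, 1000)
            lags.append(
                autocorrelation_decay_time(EpochedSeries(x, 1.0), max_lag=200).lag_samples
            )
        assert lags[0] < lags[1] < lags[2]

    def test_per_trial_mode(self):
        phi = np.exp(-1.0 / 5.0)
        x = make_ar1(phi, 50_000, seed=22).reshape(50, 1000)
        act = autocorrelation_decay_time(EpochedSeries(x, 1.0), max_lag=100, per_trial=True)
        assert 4.0 <= act.lag_samples <= 6.5


class TestBandPower:
    def test_taper_counts_reproduce(self):
        assert multitaper_taper_count((25.0, 60.0), 1.0) == 34
        assert multitaper_taper_count((60.0, 120.0), 1.0) == 59

    def test_sinusoid_concentrates_in_alpha(self):
        t = np.arange(300) / 300.0
        x = np.tile(np.sin(2 * np.pi * 11 * t), (20, 1))
        epochs = EpochedSeries(x, 300.0)
        alpha = band_power(epochs, (10, 12)).power
        for other in [(13, 15), (13, 25), (25, 60), (60, 120)]:
            assert alpha > 100 * band_power(epochs, other).power

    def test_white_noise_flat_across_gamma(self, rng):
        epochs = EpochedSeries(rng.standard_normal((20, 300)), 300.0)
        low = band_power(epochs, (25, 60)).power
        high = band_power(epochs, (60, 120)).power
        assert low == pytest.approx(high, rel=0.10)

    def test_methods_and_metadata(self, white_noise_epochs):
        lowband = band_power(white_noise_epochs, (10, 12))
        assert lowband.method == "hann-fft" and lowband.taper_count is None
        gamma = band_power(white_noise_epochs, (25, 60))
        assert gamma.method == "multitaper" and gamma.taper_count == 34
        assert gamma.power >= 0

    def test_band_above_nyquist_rejected(self, white_noise_epochs):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(white_noise_epochs, (100, 200))

    def test_parseval_boxcar(self, rng):
        """Periodogram integrates to the signal variance (boxcar window)."""
        x = rng.standard_normal(300)
        freqs, pxx = sps.periodogram(x, fs=300.0, window="boxcar", detrend=False)
        df = freqs[1] - freqs[0]
        # one-sided periodogram: sum * df recovers mean power
        assert np.sum(pxx) * df == pytest.approx(np.mean(x**2), rel=0.01)


class TestDominantOrientation:
    def _epochs(self, values):
        return EpochedSeries(values, 300.0)

    def test_single_axis_signal_passthrough(self, rng):
        s = rng.standard_normal((4, 100))
        x = self._epochs(s)
        y = self._epochs(np.zeros_like(s))
        z = self._epochs(np.zeros_like(s))
        out = dominant_orientation(x, y, z)
        np.testing.assert_allclose(out.values, s - s.mean(), atol=1e-10)

    def test_rank_one_loading(self, rng):
        # components (2s, s, 0): first axis = (2,1,0)/sqrt(5), output var = 5 var(s)
        s = rng.standard_normal((6, 200))
        s = (s - s.mean()) / s.std()
        out = dominant_orientation(
            self._epochs(2 * s), self._epochs(s), self._epochs(np.zeros_like(s))
        )
        assert out.values.var() == pytest.approx(5 * s.var(), rel=1e-6)
        np.testing.assert_allclose(out.values, np.sqrt(5) * s, atol=1e-8)

    def test_isotropic_noise_matches_top_eigenvalue(self, rng):
        comps = [self._epochs(rng.standard_normal((10, 500))) for _ in range(3)]
        out = dominant_orientation(*comps)
        cloud = np.stack([c.values.ravel() for c in comps], axis=1)
        cloud = cloud - cloud.mean(axis=0)
        top = np.linalg.eigvalsh(cloud.T @ cloud / cloud.shape[0])[-1]
        assert out.values.var() == pytest.approx(top, rel=0.05)

    def test_rotation_invariance_up_to_sign(self, rng):
        s = rng.standard_normal((5, 300))
        noise = [0.05 * rng.standard_normal(s.shape) for _ in range(3)]
        comps = np.stack([2 * s + noise[0], s + noise[1], noise[2]])
        # random rotation of the xyz frame
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = np.einsum("ij,jkl->ikl", q, comps)
        out_a = dominant_orientation(*(self._epochs(c) for c in comps))
        out_b = dominant_orientation(*(self._epochs(c) for c in rotated))
        corr = np.corrcoef(out_a.values.ravel(), out_b.values.ravel())[0, 1]
        assert abs(corr) > 0.9999

    def test_degenerate_cloud_rejected(self):
        flat = self._epochs(np.ones((2, 10)))
        with pytest.raises(ValueError, match="distinct"):
            dominant_orientation(flat, flat, flat)


class TestDetrend:
    def test_exact_line_removed(self):
        epochs = EpochedSeries(np.array([[1.0, 2.0, 3.0, 4.0]]), 1.0)
        out = linear_detrend(epochs)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_zero_mean_and_idempotent_under_added_trend(self, rng):
        values = rng.standard_normal((5, 100))
        t = np.arange(100)
        trended = values + 3.7 * t
        out_a = linear_detrend(EpochedSeries(values, 1.0))
        out_b = linear_detrend(EpochedSeries(trended, 1.0))
        np.testing.assert_allclose(out_a.values, out_b.values, atol=1e-8)
        np.testing.assert_allclose(out_a.values.mean(axis=1), 0.0, atol=1e-12)
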