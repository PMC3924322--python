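"""Companion signal descriptors: autocorrelation decay time, band-limited
spectral power, dominant dipole orientation, and linear detrending.

These descriptors accompany the AIS analysis: the autocorrelation decay
time (ACT) captures the linear memory timescale of a source, band power
captures oscillatory content, and the PCA orientation reduction collapses
the three cardinal dipole components of a reconstructed source onto the
direction of largest variance before any information-theoretic analysis.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal as sps

from .datatypes import ACTResult, BandPower, EpochedSeries

__all__ = [
    "autocorrelation_decay_time",
    "band_power",
    "multitaper_taper_count",
    "dominant_orientation",
    "linear_detrend",
]

#: bands entirely at or below this frequency use a Hann-windowed FFT;
#: higher bands use the DPSS multitaper estimate
_HANN_CUTOFF_HZ = 25.0


def _trial_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased-normalised autocorrelation of one trial, lags 0..max_lag."""
    x = x - x.mean()
    c0 = float(np.dot(x, x))
    if c0 == 0.0:
        raise ValueError("constant trial: autocorrelation undefined")
    full = np.correlate(x, x, mode="full")[x.size - 1 :]
    return full[: max_lag + 1] / c0


def autocorrelation_decay_time(
    epochs: EpochedSeries,
    max_lag: int = 150,
    per_trial: bool = False,
) -> ACTResult:
    """First lag at which the autocorrelation drops to 1/e.

    Per trial, the biased-normalised autocorrelation function (lag-0 value
    1) is computed; by default the ACFs are averaged across trials and the
    smallest lag l >= 1 with mean ACF(l) <= 1/e is returned.  With
    ``per_trial=True`` the decay lag is determined per trial and the
    trial-mean lag is returned instead.  If the threshold is never reached
    within ``max_lag`` the result carries ``overflow=True`` and
    ``lag_samples = max_lag``.

    Raises
    ------
    ValueError
        If ``max_lag`` is not smaller than the trial length, or a trial is
        constant.
    """
    if max_lag >= epochs.n_samples:
        raise ValueError("max_lag must be smaller than the trial length")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    acfs = np.stack([_trial_acf(tr, max_lag) for tr in epochs.values])
    mean_acf = acfs.mean(axis=0)
    thresh = 1.0 / np.e

    def first_crossing(acf: np.ndarray) -> tuple[float, bool]:
        below = np.nonzero(acf[1:] <= thresh)[0]
        if below.size == 0:
            return float(max_lag), True
        return float(below[0] + 1), False

    if per_trial:
        lags_flags = [first_crossing(a) for a in acfs]
        lag = float(np.mean([lf[0] for lf in lags_flags]))
        overflow = any(lf[1] for lf in lags_flags)
    else:
        lag, overflow = first_crossing(mean_acf)

    return ACTResult(
        lag_samples=lag,
        lag_seconds=lag / epochs.sampling_rate,
        acf_curve=mean_acf,
        overflow=overflow,
    )


def multitaper_taper_count(band: tuple[float, float], duration_s: float) -> int:
    """DPSS taper count K = 2*W*T - 1 for half-bandwidth W (Hz), duration T (s).

    W is half the band width, so a 25-60 Hz band on 1-s trials gives
    K = 2 * 17.5 * 1 - 1 = 34 tapers, and 60-120 Hz gives 59.
    """
    low, high = band
    half_width = (high - low) / 2.0
    k = int(round(2.0 * half_width * duration_s - 1.0))
    if k < 1:
        raise ValueError(f"band {band} too narrow for a multitaper estimate at T={duration_s}s")
    return k


def band_power(epochs: EpochedSeries, band: tuple[float, float]) -> BandPower:
    """Mean spectral power of the epoched series within ``band`` (Hz).

    Bands entirely at or below 25 Hz use a per-trial Hann-windowed
    periodogram averaged over trials; higher bands use a DPSS multitaper
    estimate with K = 2WT - 1 tapers (W the band half-width, T the trial
    duration), averaged over tapers and trials.  Either way the returned
    power is the mean over the in-band frequency bins.

    Raises
    ------
    ValueError
        If the band is invalid or extends beyond the Nyquist frequency.
    """
    low, high = band
    fs = epochs.sampling_rate
    if not 0 < low < high:
        raise ValueError("band must satisfy 0 < low < high")
    if high > fs / 2.0:
        raise ValueError(f"band edge {high} Hz above Nyquist frequency {fs / 2.0} Hz")

    x = epochs.values
    n = epochs.n_samples
    if high <= _HANN_CUTOFF_HZ:
        freqs, pxx = sps.periodogram(x, fs=fs, window="hann", axis=1, detrend=False)
        mean_pxx = pxx.mean(axis=0)
        method = "hann-fft"
        taper_count: Optional[int] = None
    else:
        taper_count = multitaper_taper_count(band, epochs.duration_s)
        nw = (high - low) / 2.0 * epochs.duration_s  # time-half-bandwidth product
        tapers = sps.windows.dpss(n, NW=nw, Kmax=taper_count)
        spectra = []
        for w in tapers:
            freqs, pxx = sps.periodogram(x, fs=fs, window=w, axis=1, detrend=False)
            spectra.append(pxx)
        mean_pxx = np.mean(spectra, axis=(0, 1))
        method = "multitaper"

    in_band = (freqs >= low) & (freqs <= high)
    if not in_band.any():
        raise ValueError(f"no frequency bins fall inside band {band}")
    return BandPower(
        band=(float(low), float(high)),
        power=float(mean_pxx[in_band].mean()),
        method=method,
        taper_count=taper_count,
    )


def dominant_orientation(
    x: EpochedSeries, y: EpochedSeries, z: EpochedSeries
) -> EpochedSeries:
    """Project three cardinal dipole components onto their dominant orientation.

    The principal axes of the pooled 3-D sample cloud (all trials and
    samples, mean-centred) are computed and every sample is projected onto
    the first axis (largest variance), yielding a single-component series —
    one orientation per source per subject.  The axis sign is fixed so its
    largest-magnitude loading is positive.

    Raises
    ------
    ValueError
        If trial structures differ or the cloud has fewer than 2 distinct
        samples.
    """
    if not (x.values.shape == y.values.shape == z.values.shape):
        raise ValueError("x, y, z components must share the same trial structure")
    cloud = np.stack([x.values.ravel(), y.values.ravel(), z.values.ravel()], axis=1)
    centred = cloud - cloud.mean(axis=0)
    if np.allclose(centred, 0.0):
        raise ValueError("fewer than 2 distinct samples: orientation undefined")
    # principal axis from the 3x3 covariance
    cov = centred.T @ centred / centred.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, -1]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    projected = (centred @ axis).reshape(x.values.shape)
    return EpochedSeries(
        values=projected,
        sampling_rate=x.sampling_rate,
        subject_id=x.subject_id,
        source_id=x.source_id,
        group=x.group,
    )


def linear_detrend(epochs: EpochedSeries) -> EpochedSeries:
    """Remove the least-squares line from every trial (output trial means 0)."""
    detrended = sps.detrend(epochs.values, axis=1, type="linear")
    return EpochedSeries(
        values=detrended,
        sampling_rate=epochs.sampling_rate,
        subject_id=epochs.subject_id,
        source_id=epochs.source_id,
        group=epochs.group,
    )
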