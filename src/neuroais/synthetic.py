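"""Synthetic MEG-like source baseline cohorts with full ground truth.

No raw recordings accompany the analysis this package implements, so every
stage is exercised on simulated cohorts that reproduce the statistical
shape of the study data: two groups of 14 and 10 subjects, 12 source
locations, ~132 one-second baseline trials per subject-source at 300 Hz
(~40,000 pooled samples), stationary oscillatory dynamics band-limited to
10-150 Hz, and a group difference in predictability at designated sources.

Each subject-source is an AR(2) stochastic oscillator

    x_t = a1 x_{t-1} + a2 x_{t-2} + e_t,
    a1 = 2 r cos(2 pi f / fs),  a2 = -r^2,

with unit-variance Gaussian innovations.  The pole radius r < 1 is the
predictability dial: the closer to 1, the more narrow-band and predictable
the oscillation, and — the key property for testing — the Gaussian AIS of
the unfiltered process has the closed form provided by
:func:`neuroais.estimators.gaussian_ais_oracle`.  Groups differ only in
the pole radius at the affected sources; the lower-storage parameter is
assigned to the patient-like group.  Observation noise and a zero-phase
band-pass emulate sensor noise and the beamformer bandwidth (the analytic
oracle applies to the pre-noise, pre-filter process).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import EpochedSeries
from .estimators import gaussian_ais_oracle

__all__ = [
    "CohortConfig",
    "Cohort",
    "ar2_coefficients",
    "simulate_source_epochs",
    "simulate_dipole_xyz",
    "simulate_cohort",
]

_BURN_IN = 1000  # samples discarded per trial before the retained window


def ar2_coefficients(pole_radius: float, frequency: float, sampling_rate: float) -> tuple[float, float]:
    """AR(2) coefficients of a stochastic oscillator with complex poles.

    Poles at radius r and angle 2*pi*f/fs give a1 = 2 r cos(2 pi f / fs),
    a2 = -r^2; the spectral peak sits near f for r close to 1.
    """
    if not 0 <= pole_radius < 1:
        raise ValueError("pole_radius must lie in [0, 1) for stationarity")
    if not 0 < frequency < sampling_rate / 2:
        raise ValueError("frequency must lie strictly between 0 and Nyquist")
    theta = 2.0 * np.pi * frequency / sampling_rate
    return 2.0 * pole_radius * np.cos(theta), -pole_radius**2


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    """Butterworth band-pass (or high-pass when the upper edge reaches Nyquist)."""
    low, high = band
    nyq = fs / 2.0
    if low <= 0:
        raise ValueError("band low edge must be positive")
    if high >= nyq * 0.999:
        return sps.butter(order, low, btype="highpass", fs=fs, output="sos")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def simulate_source_epochs(
    pole_radius: float,
    frequency: float,
    n_trials: int = 132,
    trial_length_s: float = 1.0,
    sampling_rate: float = 300.0,
    observation_noise_sd: float = 0.0,
    band_limits: Optional[tuple[float, float]] = None,
    seed: int | None = None,
    subject_id: str = "",
    source_id: str = "",
    group: str = "",
) -> EpochedSeries:
    """Simulate mutually independent AR(2) baseline trials for one source.

    Per trial, the AR(2) recursion is run for ``_BURN_IN`` extra samples
    that are discarded (so each trial starts in the stationary regime),
    i.i.d. Gaussian observation noise is added, and, if ``band_limits`` is
    given, a zero-phase Butterworth band-pass is applied.  Fully
    reproducible from ``seed``.
    """
    a1, a2 = ar2_coefficients(pole_radius, frequency, sampling_rate)
    length = int(round(trial_length_s * sampling_rate))
    if length < 2:
        raise ValueError("trial_length_s too short for the sampling rate")
    rng = np.random.default_rng(seed)
    innovations = rng.standard_normal((n_trials, length + _BURN_IN))
    # x_t - a1 x_{t-1} - a2 x_{t-2} = e_t  as an IIR filter
    x = sps.lfilter([1.0], [1.0, -a1, -a2], innovations, axis=1)[:, _BURN_IN:]
    if observation_noise_sd > 0:
        x = x + observation_noise_sd * rng.standard_normal(x.shape)
    if band_limits is not None:
        sos = _bandpass_sos(band_limits, sampling_rate)
        x = sps.sosfiltfilt(sos, x, axis=1)
    return EpochedSeries(
        values=x,
        sampling_rate=sampling_rate,
        subject_id=subject_id,
        source_id=source_id,
        group=group,
    )


def simulate_dipole_xyz(
    orientation: Sequence[float],
    base: EpochedSeries,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[EpochedSeries, EpochedSeries, EpochedSeries]:
    """Project a scalar source onto three cardinal axes plus independent noise.

    Component c is ``orientation[c] * base + noise``; the ground-truth
    orientation is the (normalised) input vector.  Fixture generator for
    the PCA orientation reduction.
    """
    v = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("orientation must be a non-zero vector")
    v = v / norm
    rng = np.random.default_rng(seed)
    out = []
    for c in range(3):
        comp = v[c] * base.values
        if noise_sd > 0:
            comp = comp + noise_sd * rng.standard_normal(comp.shape)
        out.append(
            EpochedSeries(
                values=comp,
                sampling_rate=base.sampling_rate,
                subject_id=base.subject_id,
                source_id=base.source_id,
                group=base.group,
            )
        )
    return out[0], out[1], out[2]


@dataclass
class CohortConfig:
    """Study-shaped cohort layout and generative parameters.

    Defaults mirror the study data: 14 control-like vs 10 patient-like
    subjects, 12 sources, 132 one-second trials at 300 Hz per
    subject-source (39,600 pooled samples), signal band 10-150 Hz.  The
    group effect is a pole-radius difference at ``affected_sources``
    (control-like 0.97 vs patient-like 0.90 — the patient-like group gets
    the lower-storage parameter); unaffected sources share
    ``unaffected_radius`` across groups.  Subject-level radii are drawn
    from a narrow normal around the group value
    (``between_subject_sd``, default 0.01).
    """

    n_group_a: int = 14
    n_group_b: int = 10
    group_a_label: str = "HC"
    group_b_label: str = "ASD"
    n_sources: int = 12
    trials_per_subject: int = 132
    trial_length_s: float = 1.0
    sampling_rate: float = 300.0
    affected_sources: tuple[int, ...] = (0,)
    radius_group_a: float = 0.97
    radius_group_b: float = 0.90
    unaffected_radius: float = 0.93
    between_subject_sd: float = 0.01
    source_frequencies: Optional[tuple[float, ...]] = None  # default: 20..80 Hz spread
    observation_noise_sd: float = 0.25
    band_limits: Optional[tuple[float, float]] = (10.0, 150.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.radius_group_a, self.radius_group_b, self.unaffected_radius):
            if not 0 <= r < 1:
                raise ValueError("pole radii must lie in [0, 1)")
        if self.n_group_a <= 0 or self.n_group_b <= 0 or self.n_sources <= 0:
            raise ValueError("subject and source counts must be positive")
        if any(s < 0 or s >= self.n_sources for s in self.affected_sources):
            raise ValueError("affected_sources must be valid source indices")

    def frequencies(self) -> np.ndarray:
        if self.source_frequencies is not None:
            if len(self.source_frequencies) != self.n_sources:
                raise ValueError("source_frequencies length must equal n_sources")
            return np.asarray(self.source_frequencies, dtype=float)
        if self.n_sources == 1:
            return np.array([40.0])
        return np.linspace(20.0, 80.0, self.n_sources)


@dataclass
class Cohort:
    """Simulated cohort: epochs per (subject, source) plus ground truth."""

    epochs: dict[tuple[str, str], EpochedSeries]
    manifest: pd.DataFrame  # one row per subject: subject_id, group
    ground_truth: pd.DataFrame  # one row per subject-source
    config: CohortConfig


def _subject_ids(config: CohortConfig) -> list[tuple[str, str]]:
    ids = [(f"{config.group_a_label}{i + 1:02d}", config.group_a_label) for i in range(config.n_group_a)]
    ids += [(f"{config.group_b_label}{i + 1:02d}", config.group_b_label) for i in range(config.n_group_b)]
    return ids


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort with per-subject-source ground truth.

    For every subject x source, the subject-level pole radius is drawn
    around the group value (group-specific at affected sources, shared
    otherwise), AR(2) epochs are simulated, and the generating parameters
    together with the analytic Gaussian AIS of the pre-noise, pre-filter
    process are recorded.  Bit-reproducible from ``config``.
    """
    freqs = config.frequencies()
    subjects = _subject_ids(config)
    master = np.random.default_rng(config.seed)
    # one child seed per subject-source, drawn in fixed (subject, source) order
    child_seeds = master.integers(0, 2**31 - 1, size=(len(subjects), config.n_sources))
    radius_rng = np.random.default_rng(master.integers(0, 2**31 - 1))

    epochs: dict[tuple[str, str], EpochedSeries] = {}
    records = []
    for si, (subject, group) in enumerate(subjects):
        for src in range(config.n_sources):
            source_id = f"src{src:02d}"
            if src in config.affected_sources:
                base_radius = (
                    config.radius_group_a if group == config.group_a_label else config.radius_group_b
                )
            else:
                base_radius = config.unaffected_radius
            radius = float(
                np.clip(
                    base_radius + config.between_subject_sd * radius_rng.standard_normal(),
                    0.0,
                    0.995,
                )
            )
            freq = float(freqs[src])
            a1, a2 = ar2_coefficients(radius, freq, config.sampling_rate)
            epochs[(subject, source_id)] = simulate_source_epochs(
                pole_radius=radius,
                frequency=freq,
                n_trials=config.trials_per_subject,
                trial_length_s=config.trial_length_s,
                sampling_rate=config.sampling_rate,
                observation_noise_sd=config.observation_noise_sd,
                band_limits=config.band_limits,
                seed=int(child_seeds[si, src]),
                subject_id=subject,
                source_id=source_id,
                group=group,
            )
            records.append(
                {
                    "subject_id": subject,
                    "source_id": source_id,
                    "group": group,
                    "pole_radius": radius,
                    "frequency_hz": freq,
                    "ar_a1": a1,
                    "ar_a2": a2,
                    "affected": src in config.affected_sources,
                    "analytic_ais_bits": gaussian_ais_oracle([a1, a2], 1.0),
                }
            )

    manifest = pd.DataFrame(
        [{"subject_id": s, "group": g} for s, g in subjects]
    )
    ground_truth = pd.DataFrame.from_records(records)
    return Cohort(epochs=epochs, manifest=manifest, ground_truth=ground_truth, config=config)
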