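"""Core containers shared across the pipeline.

All containers are plain dataclasses wrapping numpy arrays; the heavy
lifting lives in the functional modules (:mod:`neuroais.embedding`,
:mod:`neuroais.estimators`, ...).  Conventions used throughout:

* epoched data is a ``(n_trials, n_samples)`` float array of dipole-moment
  amplitude in arbitrary units, one row per 1-s baseline trial;
* information quantities are reported in **bits** (log base 2);
* embeddings never cross trial boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EpochedSeries",
    "EmbeddingSpec",
    "StateSet",
    "KernelConfig",
    "AISEstimate",
    "SurrogateSummary",
    "ACTResult",
    "BandPower",
    "GroupComparison",
    "CorrelationEntry",
]


@dataclass
class EpochedSeries:
    """Baseline trials of one subject-source.

    Parameters
    ----------
    values
        ``(n_trials, n_samples)`` array; all trials equal length >= 2,
        no missing entries.
    sampling_rate
        Sampling rate in Hz (> 0).
    subject_id, source_id, group
        Free-form labels carried through to the metric tables.
    """

    values: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    source_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (trials x samples) array")
        if self.values.shape[1] < 2:
            raise ValueError("trials must contain at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters for past-state construction.

    ``history_length`` (k) delayed samples spaced ``delay`` (tau) apart
    predict the sample ``horizon`` (u) steps ahead.  The study default is
    k=10, tau=1, u=1 at 300 Hz.
    """

    history_length: int = 10
    delay: int = 1
    horizon: int = 1

    def __post_init__(self) -> None:
        if self.history_length < 1:
            raise ValueError("history_length must be >= 1")
        if self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")

    @property
    def span(self) -> int:
        """Number of samples consumed before the first predictable point."""
        return (self.history_length - 1) * self.delay + self.horizon

    @property
    def min_trial_length(self) -> int:
        """Shortest trial that yields at least one embedded row."""
        return self.span + 1


@dataclass
class StateSet:
    """Aligned (past-state, next-value) samples pooled across trials.

    Rows are ordered by (trial, time); ``time_index`` is the index of the
    *next* value within its trial.  ``mean``/``sd`` record the pooled
    standardization of the raw series (the kernel width is expressed in
    units of this SD).
    """

    past_states: np.ndarray  # (n, k)
    next_values: np.ndarray  # (n,)
    trial_index: np.ndarray  # (n,)
    time_index: np.ndarray  # (n,)
    mean: float
    sd: float
    spec: EmbeddingSpec

    def __post_init__(self) -> None:
        if self.past_states.shape[0] != self.next_values.shape[0]:
            raise ValueError("past_states and next_values row counts differ")
        if self.past_states.shape[0] == 0:
            raise ValueError("StateSet must contain at least one row")

    def __len__(self) -> int:
        return self.past_states.shape[0]

    @property
    def k(self) -> int:
        return self.past_states.shape[1]


@dataclass(frozen=True)
class KernelConfig:
    """Box-kernel estimator settings.

    ``width`` is the kernel half-width epsilon in units of the pooled
    standard deviation of the series (study value 0.5).  Distances use the
    maximum norm over embedding dimensions; counts include the query point
    itself by default (guarantees strictly positive counts and finite
    logarithms).  ``theiler_window`` > 0 symmetrically excludes temporal
    neighbours within that many samples (same trial) from all counts.
    Results are reported in bits (base-2 logarithm).
    """

    width: float = 0.5
    include_self: bool = True
    theiler_window: int = 0
    log_base: int = 2

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("kernel width must be positive")
        if self.theiler_window < 0:
            raise ValueError("theiler_window must be >= 0")
        if self.log_base != 2:
            raise ValueError("reported values use base-2 logarithms")


@dataclass
class AISEstimate:
    """Active information storage estimate for one subject-source."""

    value: float  # bits
    n_samples: int
    config: KernelConfig
    embedding: EmbeddingSpec
    degenerate: bool = False
    surrogate_mean: Optional[float] = None
    surrogate_sd: Optional[float] = None


@dataclass
class SurrogateSummary:
    """Null distribution of the estimator under shuffled next-values."""

    mean: float
    sd: float
    samples: np.ndarray


@dataclass
class ACTResult:
    """Autocorrelation decay time: first lag with ACF <= 1/e."""

    lag_samples: float
    lag_seconds: float
    acf_curve: np.ndarray  # acf_curve[0] == 1
    overflow: bool = False


@dataclass
class BandPower:
    """Mean spectral power within a frequency band.

    ``method`` is ``"hann-fft"`` for bands entirely at or below 25 Hz and
    ``"multitaper"`` (DPSS) above; ``taper_count`` is K = 2WT - 1 for the
    multitaper path.
    """

    band: tuple[float, float]
    power: float
    method: str
    taper_count: Optional[int] = None


@dataclass
class GroupComparison:
    """Per-source randomization-test result with FDR flag."""

    source_id: str
    statistic: float  # group A mean minus group B mean, bits
    p_value: float
    significant_fdr: bool
    q: float = 0.1


@dataclass
class CorrelationEntry:
    """Pearson and Spearman association between two subject-level metrics."""

    metric_x: str
    metric_y: str
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
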