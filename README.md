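# neuroais

Active information storage (AIS) analysis for epoched neural source time
series, with the group-comparison statistics and companion signal
descriptors used in resting/baseline MEG source studies, and a fully
ground-truthed synthetic cohort generator for validation.

## The problem and the measure

Neural dynamics "store" information to the extent that the past of a
signal predicts its next sample.  AIS quantifies this as the mutual
information between a process's past state and its next value:

    A_X = ⟨ log₂ p(x_{t−1}^{(k)}, x_t) / ( p(x_{t−1}^{(k)}) · p(x_t) ) ⟩_t

where x_{t−1}^{(k)} = (x_{t−1}, x_{t−1−τ}, …, x_{t−1−(k−1)τ}) is a
delay embedding of the recent past (history length k, delay τ).  Unlike
an autoregressive prediction error, AIS is model-free and captures
non-linear self-prediction; it is reported in **bits**.

`neuroais` implements the full analysis chain for epoched (trial-based)
single-channel source signals:

* **embedding** — past-state/next-value construction strictly within
  trials, pooled across trials; embedding selection by the Ragwitz
  criterion (leave-one-out local-predictor error) or fixed k = 10, τ = 1.
* **estimators** — box-kernel (max-norm, ε = 0.5 SD) plug-in AIS with
  exact accelerated neighbour counting, a Gaussian AR(p) closed-form
  oracle (½·log₂(process variance / innovation variance)), and shuffle
  surrogates for the estimator's independence-null bias.
* **signal_features** — autocorrelation decay time (first lag with
  ACF ≤ 1/e), band-limited power (Hann FFT at/below 25 Hz, DPSS
  multitaper with K = 2WT−1 tapers above), PCA dominant dipole
  orientation, linear detrending.
* **group_stats** — two-sided randomization test on group differences,
  Benjamini–Hochberg FDR across sources at q < 0.1, Pearson/Spearman
  correlations between metrics.
* **synthetic** — cohorts of AR(2) stochastic-oscillator baseline epochs
  (pole radius = predictability dial) with analytic ground truth.
* **pipeline / cli** — end-to-end orchestration (`simulate`, `analyze`,
  `report`), deterministic given the configuration.

## Worked example

Estimate AIS of a Gaussian AR(1) process with φ = 0.8 and compare with the
closed form:

```python
import numpy as np
from neuroais import (EpochedSeries, EmbeddingSpec, KernelConfig,
                      delay_embed, kernel_ais, gaussian_ais_oracle)

rng = np.random.default_rng(0)
phi, n = 0.8, 50_000
x = np.empty(n); x[0] = rng.normal(0, 1/np.sqrt(1 - phi**2))
eps = rng.standard_normal(n)
for t in range(1, n):
    x[t] = phi * x[t-1] + eps[t]

states = delay_embed(EpochedSeries(x[None, :], 300.0), EmbeddingSpec(history_length=1))
est = kernel_ais(states, KernelConfig(width=0.5))
print(est.value, gaussian_ais_oracle([phi]))
```

prints `0.701` (estimate) against `0.737` bits (analytic
½·log₂(1/(1−0.8²))): the box-kernel estimate recovers the analytic value
to well within its documented ±0.15-bit tolerance at this sample size.

A miniature cohort with a planted predictability deficit in the
patient-like group at `src00`:

```python
from neuroais import CohortConfig, RunConfig, simulate_cohort, run_analysis

cohort = simulate_cohort(CohortConfig(n_group_a=5, n_group_b=4, n_sources=3,
                                      trials_per_subject=66, seed=7))
result = run_analysis(cohort, RunConfig(ais_max_query_rows=2000,
                                        n_permutations=5000, seed=1))
print(result.group_comparison[["source_id", "median_a_bits", "median_b_bits",
                               "p_value", "significant_fdr"]])
```

```
source_id  median_a_bits  median_b_bits  p_value  significant_fdr
    src00       1.425185       1.711093 0.007937             True
    src01       1.362647       1.347541 0.674603            False
    src02       1.403031       1.407343 0.753968            False
```

Group "a" is the patient-like (ASD) group in alphabetical order: at the
affected source its median AIS (1.43 bits) is below the control-like
group's (1.71 bits), the randomization test flags the difference
(p ≈ 0.008, FDR-significant at q < 0.1), and the two unaffected sources
show no group difference.

The same analysis from a shell:

```sh
neuroais simulate --fixture --seed 4 --out cohort.h5
neuroais analyze cohort.h5 --seed 2 --out results/
neuroais report results/
```

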