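# Methods

## Active information storage

For a stationary stochastic process X with realizations x_t, active
information storage is the mutual information between the delay-embedded
past state and the next sample,

    A_X = ⟨ log₂ p(x_{t−1}^{(k)}, x_t) / ( p(x_{t−1}^{(k)}) p(x_t) ) ⟩_t ,
    x_{t−1}^{(k)} = (x_{t−1}, x_{t−1−τ}, …, x_{t−1−(k−1)τ}).

The time average runs over every sample with a full history, pooled over
trials.  Embedding never crosses trial boundaries: 1-s epochs are too
short to concatenate without creating spurious dependencies at the seams.
A trial of length L contributes L − ((k−1)τ + u) rows (prediction horizon
u = 1 throughout).

Defaults follow the analysis this package reproduces: k = 10 samples,
τ = 1 at 300 Hz sampling.  The Ragwitz criterion is available as an
opt-in selector: it picks the (k, τ) that minimises the normalised
leave-one-out error of a locally-constant predictor (mean next value of
the `n_neighbors = 4` nearest past states, max norm, Theiler exclusion of
(k−1)τ + 1 samples).  A candidate must beat the incumbent by more than
1% relative error; otherwise the smaller k (then τ) wins.  The tolerance
makes selection deterministic on unpredictable data, where all candidates
score noise-level-identical errors near 1.

## Box-kernel estimator

Probabilities are estimated by box kernels: the mass at a point is the
fraction of samples within max-norm radius ε, with ε expressed in units
of the pooled standard deviation of the subject-source's baseline samples
(one mean/SD per subject-source, not per trial).  Default ε = 0.5 SD.
The plug-in estimate averages log₂[n·C_joint/(C_past·C_next)] over
points.  Conventions, chosen where the published analysis is silent and
switchable in `KernelConfig`:

* counts include the query point itself (all counts ≥ 1, logs finite);
* results in bits (base 2);
* Theiler window default 0; when positive, temporal neighbours within the
  window (same trial) are removed symmetrically from all three counts and
  from the effective sample size;
* no bias correction is applied to reported values — shuffle surrogates
  (`surrogate_ais`) provide the independence-null bias as a diagnostic.

Neighbour counting uses sorted-array bisection in one dimension and a
k-d tree otherwise; both are exactly equivalent to the O(n²) direct count
(`counting="direct"`), which the test-suite verifies on random state
sets.

**Query sub-sampling.** `kernel_ais(..., query_indices=...)` averages the
log-ratio over a seeded subset of rows while counting neighbours against
the full state set.  This cuts runtime roughly in proportion to the
subset size at a small variance cost, and — crucially — leaves the
estimator's sample-size-dependent bias untouched, because the reference
density is still estimated from all n rows.  Sub-sampling the reference
set as well changes the bias by hundreds of millibits in 11 dimensions
and can reorder conditions; the pipeline therefore only ever sub-samples
query rows (`ais_max_query_rows`, default 4000).

**Estimator bias.** In k+1 = 11 dimensions at ε = 0.5 SD and n ≈ 4·10⁴
the plug-in estimator is strongly positively biased (≈ +2 bits on iid
Gaussian data).  The bias shrinks as the true temporal dependence grows,
so *estimates* remain monotone in the underlying predictability for
narrow-band oscillators well below Nyquist, but absolute values must not
be read as unbiased information content.  Estimates should only be
compared at equal embedding, kernel and sample-size settings — which is
how the pipeline uses them.

## Analytic oracle

For a stationary Gaussian AR(p) process the AIS has the closed form
½·log₂(γ₀/σ²) for any k ≥ p, with γ₀ the stationary variance from the
Yule–Walker equations and σ² the innovation variance.
`gaussian_ais_oracle` solves the (p+1)-dimensional Yule–Walker system
directly and rejects non-stationary coefficient sets (roots on or inside
the unit circle).  The oracle anchors the estimator tests: on AR(1) at
n = 50,000, k = 1, ε = 0.5 SD, the kernel estimate falls within ±0.15
bits of the closed form across φ ∈ {0.3, 0.6, 0.8, 0.9}.

## Companion descriptors

* **Autocorrelation decay time (ACT).**  Per-trial biased-normalised ACF
  (lag-0 value 1), averaged over trials; ACT is the smallest integer lag
  with mean ACF ≤ 1/e (no interpolation).  If no lag within `max_lag`
  crosses the threshold the result carries an overflow flag.  A per-trial
  variant (decay lag per trial, then averaged) is available as a flag.
  Note that an oscillatory ACF *crosses* 1/e even when its envelope
  decays slowly; only signals whose ACF stays above 1/e throughout
  `max_lag` overflow.
* **Band power.**  Bands entirely at/below 25 Hz: per-trial Hann-windowed
  periodogram, averaged over trials, mean over in-band bins.  Bands above
  25 Hz: DPSS multitaper with K = 2WT − 1 tapers, W the band half-width
  in Hz and T the trial duration — 34 tapers for 25–60 Hz and 59 for
  60–120 Hz at T = 1 s — averaged over tapers, trials and in-band bins.
  Power is computed per trial because the 1-s epochs are the available
  baseline units.  The default band list ships both readings of the beta
  band (13–15 Hz and 13–25 Hz) explicitly labeled, since the two appear
  interchangeably in the literature this package targets.
* **Dominant orientation.**  The three cardinal dipole components of a
  reconstructed source are pooled over all trials and samples,
  mean-centred, and projected onto the first principal axis — one
  orientation per subject-source.  Sign convention: the largest-magnitude
  loading is positive.
* **Detrending.**  Per-trial least-squares line removal (utility).

## Group statistics

The group difference per source is mean(A) − mean(B) of subject-level AIS
(difference of medians available).  The null is built by relabeling
subjects: exhaustive when the number of relabelings fits in
`n_permutations` (default 10,000), otherwise seeded Monte-Carlo with the
observed labeling counted in the null (p > 0 guaranteed).  Two-sided p =
proportion of |null| ≥ |observed|.  Across sources, Benjamini–Hochberg
step-up selection (independence variant) at q = 0.1.  Correlations
(Pearson with t-based p, Spearman with average ranks) between AIS and
each band power and ACT are computed across all subjects pooled, at the
FDR-flagged sources by default (all sources optionally).  A correlation
against a metric that is constant across subjects (a discrete ACT lag can
be) is recorded as NaN rather than failing the run.

## Synthetic cohorts

Each subject-source is an AR(2) stochastic oscillator
x_t = a₁x_{t−1} + a₂x_{t−2} + ε_t with a₁ = 2r·cos(2πf/fs), a₂ = −r²,
unit Gaussian innovations, ≥1,000 burn-in samples discarded per trial,
trials mutually independent.  The pole radius r is the predictability
dial, with a closed-form Gaussian AIS pre-noise/pre-filter.  Defaults
mirror the emulated study's data shape: 14 control-like vs 10
patient-like subjects, 12 sources, 132 × 1-s trials at 300 Hz
(39,600 ≈ 40,000 pooled samples per subject-source), signal band
10–150 Hz (implemented as a zero-phase 4th-order Butterworth; the upper
edge coincides with Nyquist at 300 Hz, so the filter reduces to a 10-Hz
high-pass).  Group effect: the patient-like group receives the
lower-storage radius (0.90 vs 0.97) at the affected source(s); unaffected
sources share r = 0.93 across groups.  Subject-level radii are drawn with
between-subject SD 0.01.  Source frequencies default to an even spread
over 20–80 Hz; the default affected source sits at 20 Hz, inside the
regime where the kernel estimate is monotone in r.  Observation noise is
iid Gaussian with SD 0.25 innovation units (≈ 5–10% of signal SD),
emulating residual noise in averaged beamformer output.

What the generator does **not** emulate: 1/f background mixtures,
cross-source leakage, non-stationarity within or across trials,
inter-subject differences in oscillation frequency or noise level, and
any forward/inverse-model structure.  Passing tests therefore demonstrate
correctness of the estimator and statistics under stationary oscillatory
dynamics — not robustness to the full complexity of recorded MEG.

## Problem sizes used in tests and the acceptance script

Simulation scales are chosen so a full run completes in minutes on one
CPU while keeping every conclusion stable across seeds: Gaussian-oracle
checks at n = 50,000 (k = 1); the independence null at ~10,000 embedded
samples (k = 10, 10 seeds, 10 surrogates each, pooled z); calibration at
5,000 null datasets (6 vs 6, exhaustive relabeling) and 10,000 all-null
FDR replicates (m = 12); the end-to-end cohort at 66 trials per
subject-source (~19,000 embedded samples; one condition's worth of the
full 132) with 3,000 query rows per AIS estimate.  The reduced cohort
retains the full subject/source layout and preserves the group-ordering
regime of the estimator; detection of the planted effect is
near-deterministic at these settings.

## Known limitations

* Absolute AIS values are estimator-conditional (bias grows with
  embedding dimension and shrinks with dependence strength); only
  within-configuration comparisons are meaningful.
* Strong observation noise (≳ 0.5 innovation units here) moves weakly
  predictable sources into the bias-dominated regime and can invert the
  relation between estimated AIS and true storage.  The same caution
  applies to real data with low SNR.
* For oscillation frequencies approaching Nyquist/4 and above, the
  τ = 1 embedding under-resolves the cycle and the monotonicity of the
  estimate in r degrades.
* The exhaustive/Monte-Carlo permutation p has resolution 1/n_permutations;
  FDR conclusions at m = 12 sources inherit it.
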