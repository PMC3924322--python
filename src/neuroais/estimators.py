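"""Box-kernel estimation of active information storage (AIS).

AIS is the mutual information between a process's past state (a length-k
delay embedding) and its next sample,

    A_X = < log2  p(x^{k-}_{t-1}, x_t) / ( p(x^{k-}_{t-1}) p(x_t) ) >_t ,

i.e. the amount of stored information actively used in computing the next
value.  For stationary data the expectation is taken over time, pooling
all embedded samples.

The probabilities are estimated with a box kernel: the probability mass at
a point is the fraction of samples within maximum-norm distance epsilon of
it, with epsilon expressed in units of the pooled standard deviation of
the series (study value: 0.5 SD).  The plug-in estimator then averages

    log2 [ n * C_joint(i) / ( C_past(i) * C_next(i) ) ]

over all n embedded points i, where C_joint, C_past, C_next count
neighbours in the (k+1)-dimensional joint space, the k-dimensional past
space, and the scalar next space respectively.  Counts include the query
point itself by default, which keeps every count >= 1 and all logarithms
finite.

Neighbour counting is accelerated (sorted-array bisection in one
dimension, a k-d tree otherwise) but is exactly equivalent to the direct
O(n^2) count; ``counting="direct"`` exposes the brute-force path for
verification.

For Gaussian autoregressive processes the AIS has the closed form
``0.5 * log2(stationary variance / innovation variance)`` (for any k >=
the AR order), provided here as :func:`gaussian_ais_oracle` and used
throughout the test-suite as an analytic reference.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import AISEstimate, KernelConfig, StateSet, SurrogateSummary

__all__ = [
    "kernel_ais",
    "gaussian_ais_oracle",
    "surrogate_ais",
]


def _box_counts(
    points: np.ndarray,
    radius: float,
    counting: str,
    query: np.ndarray | None = None,
) -> np.ndarray:
    """Neighbour counts within max-norm ``radius``, self included.

    Counts how many of the ``points`` (the reference set) lie within
    ``radius`` of each query row (``query`` defaults to the reference set
    itself).  ``counting``: "auto" picks sorted-array bisection for 1-D
    data and a k-d tree otherwise; "tree" forces the k-d tree; "direct" is
    the O(n*m) brute-force reference.  All methods return identical
    counts.
    """
    points = np.ascontiguousarray(points, dtype=float)
    q = points if query is None else np.ascontiguousarray(query, dtype=float)
    m, dim = q.shape
    if counting == "direct":
        counts = np.empty(m, dtype=np.int64)
        for i in range(m):
            d = np.max(np.abs(points - q[i]), axis=1) if dim > 1 else np.abs(
                points[:, 0] - q[i, 0]
            )
            counts[i] = int(np.count_nonzero(d <= radius))
        return counts
    if dim == 1 and counting == "auto":
        order = np.sort(points[:, 0])
        hi = np.searchsorted(order, q[:, 0] + radius, side="right")
        lo = np.searchsorted(order, q[:, 0] - radius, side="left")
        return (hi - lo).astype(np.int64)
    if counting in ("auto", "tree"):
        tree = cKDTree(points)
        return np.asarray(
            tree.query_ball_point(q, r=radius, p=np.inf, return_length=True),
            dtype=np.int64,
        )
    raise ValueError(f"unknown counting method {counting!r}")


def _theiler_corrections(
    points: np.ndarray,
    radius: float,
    trial_index: np.ndarray,
    time_index: np.ndarray,
    window: int,
) -> np.ndarray:
    """Number of temporally-close same-trial neighbours within ``radius``.

    Rows are ordered by (trial, time), so temporal neighbours of row i are
    contiguous; scanning row offsets d >= 1 while any pair remains within
    the window covers all excluded pairs, including non-consecutive time
    indices (e.g. after sub-sampling).
    """
    n = points.shape[0]
    corrections = np.zeros(n, dtype=np.int64)
    d = 1
    while d < n:
        same_trial = trial_index[:-d] == trial_index[d:]
        close = np.abs(time_index[d:] - time_index[:-d]) <= window
        pair = same_trial & close
        if not pair.any():
            # times are sorted within trials, so larger offsets only move
            # same-trial pairs further apart
            break
        within = np.max(np.abs(points[:-d] - points[d:]), axis=1) <= radius
        hit = pair & within
        corrections[:-d][hit] += 1
        corrections[d:][hit] += 1
        d += 1
    return corrections


def kernel_ais(
    states: StateSet,
    config: KernelConfig = KernelConfig(),
    counting: str = "auto",
    query_indices: np.ndarray | None = None,
) -> AISEstimate:
    """Estimate AIS (bits) from a :class:`StateSet` with a box kernel.

    The state set is standardized to zero mean / unit SD using its recorded
    pooled standardization, so ``config.width`` is the kernel half-width in
    SD units.  A degenerate series (SD = 0) yields 0 bits with a warning
    and ``degenerate=True`` rather than a division by zero.

    ``query_indices`` restricts the *time average* to a subset of rows
    while neighbour counts still run against the full state set; this
    trades variance for runtime without changing the sample-size-dependent
    bias of the estimator (see the sub-sampling knob of the pipeline).

    Raises
    ------
    ValueError
        If the state set holds fewer than 2 rows.
    """
    n = len(states)
    if n < 2:
        raise ValueError("kernel AIS requires at least 2 embedded samples")
    if states.sd == 0.0:
        warnings.warn("degenerate (constant) series: AIS set to 0 bits")
        return AISEstimate(
            value=0.0,
            n_samples=n,
            config=config,
            embedding=states.spec,
            degenerate=True,
        )

    past = (states.past_states - states.mean) / states.sd
    nxt = (states.next_values - states.mean) / states.sd
    joint = np.column_stack([past, nxt])
    nxt2d = nxt[:, None]
    r = config.width

    if query_indices is not None:
        query_indices = np.asarray(query_indices, dtype=np.intp)
        if query_indices.size == 0:
            raise ValueError("query_indices must be non-empty")
        q_joint, q_past, q_next = joint[query_indices], past[query_indices], nxt2d[query_indices]
    else:
        q_joint = q_past = q_next = None

    c_joint = _box_counts(joint, r, counting, q_joint)
    c_past = _box_counts(past, r, counting, q_past)
    c_next = _box_counts(nxt2d, r, counting, q_next)
    m = c_joint.size
    n_eff = np.full(m, n, dtype=np.int64)

    if config.theiler_window > 0:
        w = config.theiler_window
        tj = _theiler_corrections(joint, r, states.trial_index, states.time_index, w)
        tp = _theiler_corrections(past, r, states.trial_index, states.time_index, w)
        tn = _theiler_corrections(nxt2d, r, states.trial_index, states.time_index, w)
        # each excluded row shrinks the sample available to point i
        n_excluded = _theiler_corrections(
            np.zeros((n, 1)), np.inf, states.trial_index, states.time_index, w
        )
        if query_indices is not None:
            tj, tp, tn = tj[query_indices], tp[query_indices], tn[query_indices]
            n_excluded = n_excluded[query_indices]
        c_joint = c_joint - tj
        c_past = c_past - tp
        c_next = c_next - tn
        n_eff = n_eff - n_excluded

    if not config.include_self:
        c_joint = c_joint - 1
        c_past = c_past - 1
        c_next = c_next - 1
        n_eff = n_eff - 1

    valid = (c_joint > 0) & (c_past > 0) & (c_next > 0) & (n_eff > 0)
    if not valid.any():
        warnings.warn("no valid neighbour counts; AIS set to 0 bits")
        return AISEstimate(
            value=0.0,
            n_samples=n,
            config=config,
            embedding=states.spec,
            degenerate=True,
        )
    terms = np.log2(
        n_eff[valid] * c_joint[valid] / (c_past[valid] * c_next[valid].astype(float))
    )
    return AISEstimate(
        value=float(terms.mean()),
        n_samples=n,
        config=config,
        embedding=states.spec,
    )


def gaussian_ais_oracle(
    ar_coefficients: Sequence[float],
    innovation_variance: float = 1.0,
) -> float:
    """Closed-form AIS (bits) of a stationary Gaussian AR(p) process.

    For x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t with Gaussian
    innovations of variance s2, the mutual information between the next
    sample and any past state of length k >= p is

        AIS = 0.5 * log2( gamma_0 / s2 ),

    where gamma_0 is the stationary process variance obtained from the
    Yule-Walker relations.

    Raises
    ------
    ValueError
        If the AR polynomial has roots on or inside the unit circle
        (non-stationary) or the innovation variance is not positive.
    """
    a = np.atleast_1d(np.asarray(ar_coefficients, dtype=float))
    if innovation_variance <= 0:
        raise ValueError("innovation variance must be positive")
    p = a.size
    if p == 0 or np.allclose(a, 0.0):
        return 0.0
    roots = np.roots(np.concatenate([[1.0], -a]))
    if np.any(np.abs(roots) >= 1.0):
        raise ValueError("AR coefficients describe a non-stationary process")

    # Yule-Walker: gamma_j - sum_i a_i gamma_{|j-i|} = s2 * delta_{j0},
    # unknowns gamma_0..gamma_p.
    m = np.zeros((p + 1, p + 1))
    for j in range(p + 1):
        m[j, j] += 1.0
        for i in range(1, p + 1):
            m[j, abs(j - i)] -= a[i - 1]
    rhs = np.zeros(p + 1)
    rhs[0] = innovation_variance
    gamma = np.linalg.solve(m, rhs)
    var = gamma[0]
    return float(0.5 * np.log2(var / innovation_variance))


def surrogate_ais(
    states: StateSet,
    config: KernelConfig = KernelConfig(),
    n_surrogates: int = 20,
    seed: int | None = None,
    query_indices: np.ndarray | None = None,
) -> SurrogateSummary:
    """Null distribution of the AIS estimator under shuffled next-values.

    Permuting next values relative to past states destroys the temporal
    dependence while preserving both marginals, so the resulting AIS
    samples estimate the estimator's bias under independence.  With a zero
    Theiler window the past- and next-space counts are invariant under the
    permutation and are reused; only the joint-space counts are
    recomputed per surrogate.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(states)

    if states.sd == 0.0 or config.theiler_window > 0 or not config.include_self:
        # general (slower) path: rebuild a StateSet per surrogate
        samples = np.empty(n_surrogates)
        for s in range(n_surrogates):
            perm = rng.permutation(n)
            shuffled = StateSet(
                past_states=states.past_states,
                next_values=states.next_values[perm],
                trial_index=states.trial_index,
                time_index=states.time_index,
                mean=states.mean,
                sd=states.sd,
                spec=states.spec,
            )
            samples[s] = kernel_ais(shuffled, config, query_indices=query_indices).value
    else:
        past = (states.past_states - states.mean) / states.sd
        nxt = (states.next_values - states.mean) / states.sd
        r = config.width
        qi = None if query_indices is None else np.asarray(query_indices, dtype=np.intp)
        q_past = None if qi is None else past[qi]
        c_past = _box_counts(past, r, "auto", q_past)
        c_next_all = _box_counts(nxt[:, None], r, "auto")
        samples = np.empty(n_surrogates)
        for s in range(n_surrogates):
            perm = rng.permutation(n)
            nxt_perm = nxt[perm]
            joint = np.column_stack([past, nxt_perm])
            q_joint = None if qi is None else joint[qi]
            c_joint = _box_counts(joint, r, "auto", q_joint)
            c_next = c_next_all[perm] if qi is None else c_next_all[perm][qi]
            terms = np.log2(n * c_joint / (c_past * c_next.astype(float)))
            samples[s] = float(terms.mean())

    return SurrogateSummary(
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)) if n_surrogates > 1 else 0.0,
        samples=samples,
    )
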