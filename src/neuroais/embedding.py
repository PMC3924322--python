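"""Delay embedding and embedding-parameter selection.

The active-information-storage estimator operates on (past state, next
value) pairs.  The past state of a scalar process at time t is the
delay-embedding vector

    (x_{t-u}, x_{t-u-tau}, ..., x_{t-u-(k-1)tau})

with history length k, embedding delay tau and prediction horizon u
(u = 1 throughout this study).  Embedding is performed strictly within
trials — 1-s epochs are too short to concatenate without introducing
spurious dependencies across trial boundaries — and the embedded rows are
pooled over trials in deterministic (trial, time) order.

Embedding parameters can either be fixed (the study analysis uses k = 10,
tau = 1 at 300 Hz) or selected by the Ragwitz criterion: minimise the
normalised leave-one-out prediction error of a locally constant
(nearest-neighbour) predictor of the next sample.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import EmbeddingSpec, EpochedSeries, StateSet

__all__ = ["delay_embed", "ragwitz_select"]


def delay_embed(epochs: EpochedSeries, spec: EmbeddingSpec) -> StateSet:
    """Construct pooled (past state, next value) samples from epoched data.

    For every trial and every time index t with a full history available,
    one row is produced with past state
    ``(x_{t-u}, x_{t-u-tau}, ..., x_{t-u-(k-1)tau})`` and next value
    ``x_t``.  Rows never span trial boundaries.  The returned
    :class:`StateSet` also records the mean and standard deviation of the
    pooled raw samples; the kernel width downstream is expressed in units
    of this SD.

    Raises
    ------
    ValueError
        If trials are shorter than ``spec.min_trial_length``.
    """
    values = epochs.values
    n_trials, length = values.shape
    if length < spec.min_trial_length:
        raise ValueError(
            f"trial length {length} too short for embedding "
            f"(k={spec.history_length}, tau={spec.delay}, u={spec.horizon}); "
            f"need at least {spec.min_trial_length} samples per trial"
        )

    k, tau, u = spec.history_length, spec.delay, spec.horizon
    t_next = np.arange(spec.span, length)  # indices of predictable samples
    n_per_trial = t_next.size

    # (n_trials, n_per_trial, k): lag j contributes x_{t - u - j*tau}
    lags = u + tau * np.arange(k)
    past = values[:, t_next[None, :] - lags[:, None]]  # (trials, k, T)
    past = np.transpose(past, (0, 2, 1)).reshape(-1, k)
    nxt = values[:, t_next].reshape(-1)

    trial_index = np.repeat(np.arange(n_trials), n_per_trial)
    time_index = np.tile(t_next, n_trials)

    pooled = values.ravel()
    return StateSet(
        past_states=past,
        next_values=nxt,
        trial_index=trial_index,
        time_index=time_index,
        mean=float(pooled.mean()),
        sd=float(pooled.std()),
        spec=spec,
    )


def _loo_prediction_nmse(
    states: StateSet,
    n_neighbors: int,
    theiler_window: int,
) -> float:
    """Normalised MSE of a locally-constant leave-one-out predictor.

    Each embedded point's next value is predicted as the mean next value
    of its ``n_neighbors`` nearest past states (maximum norm), excluding
    the point itself and any point of the same trial within
    ``theiler_window`` samples.  The MSE is normalised by the variance of
    the next values, so an unpredictable process scores ~1 and a
    deterministic one 0.
    """
    past = states.past_states
    nxt = states.next_values
    n = len(states)
    if n_neighbors >= n:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be smaller than the number of "
            f"embedded points ({n})"
        )
    var = float(np.var(nxt))
    if var == 0.0:
        return 0.0

    # Enough extra neighbours to survive self + Theiler filtering: at most
    # 2*W same-trial temporal neighbours plus the point itself can be excluded.
    k_query = min(n, n_neighbors + 2 * theiler_window + 1)
    tree = cKDTree(past)
    _, idx = tree.query(past, k=k_query, p=np.inf)
    if k_query == 1:
        idx = idx[:, None]

    rows = np.arange(n)[:, None]
    same_trial = states.trial_index[idx] == states.trial_index[rows]
    close_in_time = np.abs(states.time_index[idx] - states.time_index[rows]) <= theiler_window
    excluded = (idx == rows) | (same_trial & close_in_time)

    preds = np.empty(n)
    nxt_at = nxt[idx]
    for i in range(n):
        keep = nxt_at[i][~excluded[i]][:n_neighbors]
        if keep.size < n_neighbors:
            # Rare near-degenerate case: fall back to a full scan for row i.
            d = np.max(np.abs(past - past[i]), axis=1)
            order = np.argsort(d, kind="stable")
            mask = ~(
                (order == i)
                | (
                    (states.trial_index[order] == states.trial_index[i])
                    & (np.abs(states.time_index[order] - states.time_index[i]) <= theiler_window)
                )
            )
            keep = nxt[order[mask]][:n_neighbors]
        preds[i] = keep.mean()

    return float(np.mean((preds - nxt) ** 2) / var)


def ragwitz_select(
    epochs: EpochedSeries,
    k_candidates: Iterable[int],
    tau_candidates: Iterable[int] = (1,),
    n_neighbors: int = 4,
    theiler_window: int | None = None,
    rel_tol: float = 0.01,
    horizon: int = 1,
) -> EmbeddingSpec:
    """Select (k, tau) by the Ragwitz criterion.

    Evaluates the normalised leave-one-out local-predictor error for every
    candidate pair and returns the minimiser.  A candidate only replaces
    the incumbent if it improves the error by more than ``rel_tol``
    (relative), which makes the selection deterministic for unpredictable
    data where all candidates score ~1: ties resolve to the smallest k,
    then the smallest tau.

    ``theiler_window`` defaults to the embedding span (k-1)*tau + 1 of each
    candidate, excluding serially correlated neighbours from the
    prediction.
    """
    ks = sorted(set(int(k) for k in k_candidates))
    taus = sorted(set(int(t) for t in tau_candidates))
    if not ks or not taus:
        raise ValueError("candidate sets must be non-empty")

    best_spec: EmbeddingSpec | None = None
    best_nmse = np.inf
    for k in ks:
        for tau in taus:
            spec = EmbeddingSpec(history_length=k, delay=tau, horizon=horizon)
            states = delay_embed(epochs, spec)
            w = theiler_window if theiler_window is not None else (k - 1) * tau + 1
            nmse = _loo_prediction_nmse(states, n_neighbors, w)
            if nmse < best_nmse * (1.0 - rel_tol) or best_spec is None:
                best_nmse = nmse
                best_spec = spec
    assert best_spec is not None
    return best_spec
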