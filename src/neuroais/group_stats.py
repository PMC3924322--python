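"""Group-comparison statistics: randomization test, FDR, correlations.

Subject-level metrics (AIS, band power, ACT) are compared between two
groups with a permutation (randomization) test on the difference of group
means, corrected across sources with the Benjamini-Hochberg false
discovery rate at q < 0.1, and related to one another with Pearson and
Spearman correlations.
"""

from __future__ import annotations

import itertools
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .datatypes import CorrelationEntry

__all__ = ["permutation_test", "fdr_select", "correlate"]

# absolute slack when comparing |null statistic| >= |observed|, to make the
# exhaustive count robust to floating-point summation order
_PERM_TIE_TOL = 1e-12


def _group_stat(a: np.ndarray, b: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return float(a.mean() - b.mean())
    if statistic == "median":
        return float(np.median(a) - np.median(b))
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_permutations: int = 10_000,
    seed: int | None = None,
    statistic: str = "mean",
) -> tuple[float, float]:
    """Two-sided permutation test for a group difference.

    The statistic is group-A mean minus group-B mean (``statistic="median"``
    switches to the median difference).  The null distribution is built by
    relabeling subjects: exhaustively over all label assignments when
    their number does not exceed ``n_permutations``, otherwise by seeded
    Monte-Carlo sampling that counts the observed labeling as one draw
    (guaranteeing p > 0).  The two-sided p-value is the proportion of null
    statistics at least as extreme in magnitude as the observed one.

    Returns
    -------
    (statistic, p_value)
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    obs = _group_stat(a, b, statistic)
    threshold = abs(obs) - _PERM_TIE_TOL

    n_exhaustive = comb(n, na)
    if n_exhaustive <= n_permutations:
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), na)),
            dtype=np.intp,
            count=n_exhaustive * na,
        ).reshape(n_exhaustive, na)
        if statistic == "mean":
            total = pooled.sum()
            sum_a = pooled[combos].sum(axis=1)
            null = sum_a / na - (total - sum_a) / (n - na)
        else:
            in_a = np.zeros((n_exhaustive, n), dtype=bool)
            np.put_along_axis(in_a, combos, True, axis=1)
            null = np.array(
                [
                    _group_stat(pooled[row], pooled[~row], statistic)
                    for row in in_a
                ]
            )
        count = int(np.count_nonzero(np.abs(null) >= threshold))
        return obs, count / n_exhaustive

    rng = np.random.default_rng(seed)
    # vectorised Monte-Carlo: each row of `order` is a random permutation
    order = np.argsort(rng.random((n_permutations - 1, n)), axis=1)
    perm_a = pooled[order[:, :na]]
    perm_b = pooled[order[:, na:]]
    if statistic == "mean":
        null = perm_a.mean(axis=1) - perm_b.mean(axis=1)
    else:
        null = np.median(perm_a, axis=1) - np.median(perm_b, axis=1)
    count = int(np.count_nonzero(np.abs(null) >= threshold)) + 1  # observed labeling
    return obs, count / n_permutations


def fdr_select(p_values: Sequence[float], q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    Sorts the m p-values ascending, finds the largest i with
    p_(i) <= (i/m) * q, and marks every test with p <= p_(i).  This is the
    independence variant (no log-factor correction).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.sort(p)
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(order <= crit)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool)
    cutoff = order[passing[-1]]
    return p <= cutoff


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    metric_x: str = "x",
    metric_y: str = "y",
) -> CorrelationEntry:
    """Pearson and Spearman association between two metric vectors.

    Pearson r comes with a two-sided t-based p-value; Spearman rho uses
    average ranks on ties with its two-sided p-value.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 pairs, or zero-variance input.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if np.var(xv) == 0 or np.var(yv) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    pearson = sstats.pearsonr(xv, yv)
    spearman = sstats.spearmanr(xv, yv)
    return CorrelationEntry(
        metric_x=metric_x,
        metric_y=metric_y,
        pearson_r=float(pearson.statistic),
        pearson_p=float(pearson.pvalue),
        spearman_rho=float(spearman.statistic),
        spearman_p=float(spearman.pvalue),
    )
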