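"""Shared statistical primitives.

``mann_whitney_auc`` is a vectorized two-group Wilcoxon rank-sum test
over many features at once, returning both the auROC (the Mann-Whitney
win probability, ties counting one half) and a tie-corrected normal
approximation p-value — the same statistic family the fast single-cell
rank-test implementations (e.g. presto's wilcoxauc) use.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm, rankdata


def _tie_term(col: np.ndarray) -> float:
    """Σ (t³ − t) over tied groups of one feature column."""
    _, counts = np.unique(col, return_counts=True)
    t = counts[counts > 1].astype(np.float64)
    return float(np.sum(t**3 - t))


def mann_whitney_auc(X, mask1: np.ndarray, mask2: np.ndarray):
    """Rank-sum test of group1 vs group2 for every column of ``X``.

    Parameters
    ----------
    X
        Observations × features matrix (dense or sparse).
    mask1, mask2
        Disjoint boolean masks over rows selecting the two groups.

    Returns
    -------
    auc : ndarray
        Per feature, U₁/(n₁·n₂): the probability that a random group-1
        observation exceeds a random group-2 one, ties counting ½.
    pval : ndarray
        Two-sided tie-corrected normal-approximation p-value; exactly 1
        where a feature is constant across both groups.
    """
    mask1 = np.asarray(mask1, bool)
    mask2 = np.asarray(mask2, bool)
    if np.any(mask1 & mask2):
        raise ValueError("groups overlap")
    sel = mask1 | mask2
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X)[sel]
    in1 = mask1[sel]
    n1 = int(in1.sum())
    n2 = X.shape[0] - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2

    ranks = rankdata(X, axis=0)
    r1 = ranks[in1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n2)

    ties = np.array([_tie_term(X[:, j]) for j in range(X.shape[1])])
    var = (n1 * n2 / 12.0) * ((n + 1) - ties / (n * (n - 1.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
    pval = np.where(var > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
    pval = np.minimum(pval, 1.0)
    return auc, pval


class RankedMatrix:
    """Precomputed column ranks and tie terms of a matrix, for repeated
    one-vs-rest rank-sum tests over the *same* observations.

    Ranks do not depend on how rows are grouped, so partition-heavy
    callers (four quarters × several pathway partitions) rank once.
    """

    def __init__(self, X):
        if sp.issparse(X):
            X = np.asarray(X.todense())
        self.X = np.asarray(X)
        self.n = self.X.shape[0]
        self.ranks = rankdata(self.X, axis=0)
        self.ties = np.array([_tie_term(self.X[:, j]) for j in range(self.X.shape[1])])

    def one_vs_rest(self, mask1: np.ndarray):
        """auROC and tie-corrected p of rows in ``mask1`` vs all others."""
        mask1 = np.asarray(mask1, bool)
        n1 = int(mask1.sum())
        n2 = self.n - n1
        if n1 == 0 or n2 == 0:
            raise ValueError("both groups must be non-empty")
        n = self.n
        r1 = self.ranks[mask1].sum(axis=0)
        u1 = r1 - n1 * (n1 + 1) / 2.0
        auc = u1 / (n1 * n2)
        var = (n1 * n2 / 12.0) * ((n + 1) - self.ties / (n * (n - 1.0)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
        pval = np.where(var > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
        return auc, np.minimum(pval, 1.0)


def fivenum(x: np.ndarray) -> np.ndarray:
    """Tukey's five-number summary (min, lower hinge, median, upper
    hinge, max), matching R's ``fivenum``."""
    x = np.sort(np.asarray(x, dtype=float))
    x = x[~np.isnan(x)]
    n = x.size
    if n == 0:
        return np.full(5, np.nan)
    n4 = np.floor((n + 3) / 2.0) / 2.0
    d = np.array([1.0, n4, (n + 1) / 2.0, n + 1 - n4, float(n)])
    lo = np.floor(d).astype(int) - 1
    hi = np.ceil(d).astype(int) - 1
    return 0.5 * (x[lo] + x[hi])
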