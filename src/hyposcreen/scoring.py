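"""Per-cell gene-set scoring, TF filtering/activity and correlation reports.

Gene-set scores are *fraction* scores: the percent of a cell's raw counts
falling in the set (the PercentageFeatureSet convention), so they are
invariant to per-cell sequencing depth.  TF activity follows the
univariate-linear-model approach: for each cell, the normalized
expression of all genes is regressed on a TF's target-weight vector
(weight 0 outside the regulon) and the activity is the t-statistic of
the slope.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .config import AnalysisConfig
from .dataset import ExpressionDataset, GeneSet, GeneSetCollection

log = logging.getLogger(__name__)


# ----------------------------------------------------------------- scores
def score_fraction(d: ExpressionDataset, s: GeneSet) -> pd.Series:
    """Percent of each cell's raw counts in gene set ``s`` (0–100).

    Members absent from the gene universe are ignored; if none are
    present the score is all-zero with a warning.  Cells with zero total
    counts are rejected.
    """
    total = d.obs["total_umi"].to_numpy()
    if (total == 0).any():
        bad = d.obs.index[total == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    present = [g for g in s.members if g in d.var.index]
    if not present:
        log.warning("gene set %r has no members in the dataset; score is 0", s.name)
        return pd.Series(0.0, index=d.obs.index, name=s.name)
    idx = d.var.index.get_indexer(present)
    in_set = np.asarray(d.counts[:, idx].sum(axis=1)).ravel()
    return pd.Series(100.0 * in_set / total, index=d.obs.index, name=s.name)


def score_collection(d: ExpressionDataset, coll: GeneSetCollection) -> pd.DataFrame:
    """Cells × sets table of fraction scores."""
    return pd.DataFrame({gs.name: score_fraction(d, gs) for gs in coll})


# --------------------------------------------------------------------- TF
def filter_tfs(d: ExpressionDataset, tf_list, cfg: AnalysisConfig | None = None) -> list:
    """TFs with mean raw count across all cells strictly above
    ``tf_min_mean`` (default 0.1); order of ``tf_list`` preserved."""
    cfg = cfg or AnalysisConfig()
    kept = []
    for tf in tf_list:
        if tf not in d.var.index:
            log.warning("TF %r not in gene universe; dropped", tf)
            continue
        j = d.var.index.get_loc(tf)
        mean = d.counts[:, j].sum() / d.n_cells
        if mean > cfg.tf_min_mean:
            kept.append(tf)
    if not kept:
        log.warning("no TF passed the mean-count filter")
    return kept


def tf_activity_ulm(d: ExpressionDataset, regulons: dict) -> pd.DataFrame:
    """Cells × TFs activity table (t-statistic of the univariate slope).

    For each cell and TF, fit OLS of the cell's normalized expression
    across all genes on the TF's weight vector (0 for non-targets), with
    intercept.  The slope t-statistic equals r·√(df/(1−r²)) with r the
    Pearson correlation between expression and weights, which is how it
    is computed here (vectorized over cells and TFs).  Constant-expression
    cells get activity 0; zero-variance regulons are reported as NaN.
    """
    genes = d.var.index
    W = np.zeros((len(genes), len(regulons)))
    tf_names = list(regulons)
    for k, tf in enumerate(tf_names):
        for target, w in regulons[tf]:
            if target in genes:
                W[genes.get_loc(target), k] = w
        if not np.any(W[:, k]):
            log.warning("regulon %r has no targets in the gene universe", tf)

    Y = d.normalized_dense().T  # genes × cells
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    Wc = W - W.mean(axis=0, keepdims=True)
    wss = (Wc**2).sum(axis=0)  # per TF
    yss = (Yc**2).sum(axis=0)  # per cell
    cov = Wc.T @ Yc            # TFs × cells

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(wss, yss))
        r = np.where(denom > 0, cov / denom, 0.0)
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    t[:, yss == 0] = 0.0          # constant cell ⇒ zero activity
    t[wss == 0, :] = np.nan       # degenerate regulon ⇒ undefined
    return pd.DataFrame(t.T, index=d.obs.index, columns=tf_names)


# ------------------------------------------------------------ correlation
def pairwise_correlation(
    x: pd.DataFrame,
    y: pd.DataFrame | None = None,
    cfg: AnalysisConfig | None = None,
    top_k: int | None = None,
) -> dict:
    """Pearson correlation of every (x-column, y-column) pair.

    Returns a dict with a long-format ``table`` (feature_a, feature_b,
    r, p, significant), and ``top`` / ``bottom`` K pairs by r.  With
    ``y=None`` the x columns are correlated among themselves (unordered
    pairs, no self-pairs).  Zero-variance features yield missing r.
    Requires ≥3 paired observations.
    """
    cfg = cfg or AnalysisConfig()
    k = top_k if top_k is not None else cfg.screen_k
    symmetric = y is None
    if symmetric:
        y = x
    if len(x) != len(y):
        raise ValueError("x and y must share observations")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")

    X = x.to_numpy(float)
    Y = y.to_numpy(float)
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    xs = np.sqrt((Xc**2).sum(0))
    ys = np.sqrt((Yc**2).sum(0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc.T @ Yc) / np.outer(xs, ys)
    R = np.clip(R, -1.0, 1.0)
    R[np.outer(xs == 0, np.ones(len(ys), bool))] = np.nan
    R[np.outer(np.ones(len(xs), bool), ys == 0)] = np.nan

    rows = []
    for i, a in enumerate(x.columns):
        js = range(i + 1, len(y.columns)) if symmetric else range(len(y.columns))
        for j in js:
            r = R[i, j]
            if np.isnan(r):
                p = np.nan
            else:
                # exact two-sided p via the t transform of Pearson r
                tstat = r * np.sqrt((n - 2) / max(1.0 - r**2, 1e-300))
                p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
            rows.append(
                {
                    "feature_a": a,
                    "feature_b": y.columns[j],
                    "r": r,
                    "p": p,
                    "significant": bool(p < cfg.corr_p) if not np.isnan(r) else False,
                }
            )
    table = pd.DataFrame(rows)
    ranked = table.dropna(subset=["r"]).sort_values(
        "r", ascending=False, kind="mergesort"
    )
    return {
        "table": table,
        "top": ranked.head(k).reset_index(drop=True),
        "bottom": ranked.tail(k).iloc[::-1].reset_index(drop=True),
    }
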