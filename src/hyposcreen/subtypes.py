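"""Supervised neuron subtyping and condition-perturbation prioritization.

Subtypes are defined top-down from a curated catalog of neuropeptide,
hormone and receptor genes: a neuron belongs to subtype *S* exactly when
its raw count for *S*'s defining gene is positive.  Memberships overlap
freely — a neuron co-expressing Oxt and Avp belongs to both subtypes.

Perturbation prioritization asks, per subtype, how separable two sample
conditions are from expression alone: small balanced subsamples are drawn
repeatedly, a decision-tree ensemble is cross-validated to predict the
condition, and the subtype's score is the mean held-out classifier AUC
(the Augur approach, with the study's subsample size of 6).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import AnalysisConfig
from .dataset import ExpressionDataset, SubtypeCatalog

log = logging.getLogger(__name__)


@dataclass
class SubtypeAssignment:
    """Subtype → member cell ids (overlapping), plus per-subtype category."""

    members: dict          # subtype -> pd.Index of cell ids
    categories: dict       # subtype -> "peptide" | "receptor"
    n_neurons_by_group: pd.Series

    def sizes(self) -> pd.Series:
        return pd.Series({s: len(m) for s, m in self.members.items()}, name="n_cells")


def assign_subtypes(d: ExpressionDataset, catalog: SubtypeCatalog) -> SubtypeAssignment:
    """Membership rule: neurons (cell_type == 'Neuron') with raw count > 0
    for the subtype's defining gene.  Catalog genes missing from the
    dataset are logged and skipped."""
    is_neuron = (d.obs["cell_type"] == "Neuron").to_numpy()
    if not is_neuron.any():
        raise ValueError("dataset contains no neurons")
    members, categories = {}, {}
    for row in catalog.table.itertuples(index=False):
        if row.gene not in d.var.index:
            log.warning("catalog gene %r not in dataset; subtype %r skipped",
                        row.gene, row.subtype)
            continue
        j = d.var.index.get_loc(row.gene)
        expressed = np.asarray(d.counts[:, j].todense()).ravel() > 0
        members[row.subtype] = d.obs.index[is_neuron & expressed]
        categories[row.subtype] = row.category
    n_by_group = d.obs.loc[is_neuron, "group"].value_counts()
    return SubtypeAssignment(members, categories, n_by_group)


def count_rank(
    a: SubtypeAssignment,
    d: ExpressionDataset,
    group: str,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Subtype member counts within ``group``, per category, descending.

    Subtypes with fewer than ``subtype_min_cells`` members in the
    reference group are excluded (the study's n ≥ 10 rule); ties break
    alphabetically for determinism.
    """
    cfg = cfg or AnalysisConfig()
    in_group = set(d.obs.index[(d.obs["group"] == group).to_numpy()])
    rows = []
    for s, mem in a.members.items():
        n = sum(c in in_group for c in mem)
        if n >= cfg.subtype_min_cells:
            rows.append({"subtype": s, "category": a.categories[s], "n_cells": n})
    df = pd.DataFrame(rows, columns=["subtype", "category", "n_cells"])
    return df.sort_values(
        ["category", "n_cells", "subtype"], ascending=[True, False, True]
    ).reset_index(drop=True)


def weighted_proportions(a: SubtypeAssignment, d: ExpressionDataset) -> pd.DataFrame:
    """Per subtype and group: members / total neurons of that group, plus
    the cross-group relative share (three proportions scaled to unit sum,
    the display convention of the study's proportion panels)."""
    groups = ("Y", "O", "O.T")
    totals = {g: a.n_neurons_by_group.get(g, 0) for g in groups}
    if any(t == 0 for t in totals.values()):
        empty = [g for g, t in totals.items() if t == 0]
        raise ValueError(f"group(s) with zero neurons: {empty}")
    group_of = d.obs["group"]
    rows = []
    for s, mem in a.members.items():
        counts = group_of.loc[mem].value_counts()
        props = {g: counts.get(g, 0) / totals[g] for g in groups}
        tot = sum(props.values())
        rel = {g: (props[g] / tot if tot > 0 else np.nan) for g in groups}
        rows.append(
            {"subtype": s,
             **{f"prop_{g}": props[g] for g in groups},
             **{f"rel_{g}": rel[g] for g in groups},
             **{f"n_{g}": int(counts.get(g, 0)) for g in groups}}
        )
    return pd.DataFrame(rows).set_index("subtype")


def subtype_similarity(
    a: SubtypeAssignment,
    d: ExpressionDataset,
    cfg: AnalysisConfig | None = None,
) -> dict:
    """Two subtype × subtype similarity matrices: Pearson r between mean
    normalized expression profiles, and membership Jaccard overlap.

    Only subtypes with at least ``subtype_min_cells`` members enter;
    zero-variance profiles give missing correlations.
    """
    cfg = cfg or AnalysisConfig()
    keep = [s for s, m in a.members.items() if len(m) >= cfg.subtype_min_cells]
    if len(keep) < 2:
        raise ValueError("need at least two subtypes above the cell floor")
    X = d.normalized
    pos = {c: i for i, c in enumerate(d.obs.index)}
    profiles = np.vstack([
        np.asarray(X[[pos[c] for c in a.members[s]]].mean(axis=0)).ravel()
        for s in keep
    ])
    Pc = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.sqrt((Pc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Pc @ Pc.T) / np.outer(norms, norms)
    R = np.clip(R, -1.0, 1.0)
    R[norms == 0, :] = np.nan
    R[:, norms == 0] = np.nan
    np.fill_diagonal(R, 1.0)

    sets = {s: set(a.members[s]) for s in keep}
    J = np.ones((len(keep), len(keep)))
    for i, si in enumerate(keep):
        for j in range(i + 1, len(keep)):
            u = len(sets[si] | sets[keep[j]])
            J[i, j] = J[j, i] = (len(sets[si] & sets[keep[j]]) / u) if u else 0.0
    return {
        "profile_r": pd.DataFrame(R, index=keep, columns=keep),
        "jaccard": pd.DataFrame(J, index=keep, columns=keep),
    }


# ----------------------------------------------------------- prioritization
def _select_hvg(X: np.ndarray, n_hvg: int) -> np.ndarray:
    """Indices of the ``n_hvg`` highest-variance columns (ties by index)."""
    var = X.var(axis=0)
    if n_hvg >= X.shape[1]:
        return np.arange(X.shape[1])
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:n_hvg])


def prioritize(
    d: ExpressionDataset,
    a: SubtypeAssignment,
    pair: tuple,
    cfg: AnalysisConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean cross-validated classifier AUC per subtype for one condition
    pair, sorted descending.

    Per subtype with at least ``augur_min_cells`` cells in *each*
    condition, ``augur_n_subsamples`` balanced subsamples of
    ``augur_subsample_size`` cells per condition are drawn without
    replacement; a random forest on the subtype's top variable genes is
    evaluated by 3-fold stratified cross-validation and the held-out
    predictions pooled into one AUC per subsample.  Subtypes below the
    cell floor are skipped with a log entry.
    """
    cfg = cfg or AnalysisConfig()
    g1, g2 = pair
    present = set(d.obs["group"])
    if g1 not in present or g2 not in present:
        raise ValueError(f"both groups of {pair} must be present")
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    pos = {c: i for i, c in enumerate(d.obs.index)}
    group_of = d.obs["group"]

    rows = []
    for s in sorted(a.members):
        mem = a.members[s]
        cells1 = [c for c in mem if group_of.loc[c] == g1]
        cells2 = [c for c in mem if group_of.loc[c] == g2]
        if len(cells1) < cfg.augur_min_cells or len(cells2) < cfg.augur_min_cells:
            log.info("subtype %r below %d cells in a condition; skipped",
                     s, cfg.augur_min_cells)
            continue
        idx = np.array([pos[c] for c in cells1 + cells2])
        X = np.asarray(d.normalized[idx].todense())
        y_all = np.array([0] * len(cells1) + [1] * len(cells2))
        hvg = _select_hvg(X, cfg.augur_n_hvg)
        X = X[:, hvg]

        # per-subtype stream keyed by a stable hash of the subtype name,
        # so results do not depend on which other subtypes are present
        key = zlib.crc32(s.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(key,))
        )
        aucs = []
        for _rep in range(cfg.augur_n_subsamples):
            i1 = rng.choice(np.flatnonzero(y_all == 0), cfg.augur_subsample_size, replace=False)
            i2 = rng.choice(np.flatnonzero(y_all == 1), cfg.augur_subsample_size, replace=False)
            sel = np.concatenate([i1, i2])
            Xs, ys = X[sel], y_all[sel]
            skf = StratifiedKFold(3, shuffle=True,
                                  random_state=int(rng.integers(2**31)))
            prob = np.empty(len(ys))
            for tr, te in skf.split(Xs, ys):
                clf = RandomForestClassifier(
                    n_estimators=cfg.augur_n_trees,
                    random_state=int(rng.integers(2**31)),
                )
                clf.fit(Xs[tr], ys[tr])
                prob[te] = clf.predict_proba(Xs[te])[:, list(clf.classes_).index(1)]
            aucs.append(roc_auc_score(ys, prob))
        rows.append(
            {"subtype": s, "mean_auc": float(np.mean(aucs)),
             "n_subsamples": len(aucs), "pair": f"{g1}_vs_{g2}",
             "n_cells_1": len(cells1), "n_cells_2": len(cells2)}
        )
    out = pd.DataFrame(rows, columns=["subtype", "mean_auc", "n_subsamples",
                                      "pair", "n_cells_1", "n_cells_2"])
    return out.sort_values(["mean_auc", "subtype"],
                           ascending=[False, True]).reset_index(drop=True)
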