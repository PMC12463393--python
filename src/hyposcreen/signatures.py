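"""Quartile-partition signature derivation, auROC ranking, differential
expression, rank/intersection screens and over-representation analysis.

The signature derivation pipeline: score neurons on each of several
pathways (fraction scores), split the pooled neurons into four
equal-count quarters per pathway (c1 = highest scores), find each
quarter's *unique* positive markers (significant in exactly one quarter),
and intersect those lists across the pathway partitions.  The c1 and c4
intersections form a pair of opposing gene signatures tracking the high-
and low-score ends of the shared program axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import RankedMatrix, fivenum, mann_whitney_auc
from .config import AnalysisConfig
from .dataset import ExpressionDataset, GeneSet, GeneSetCollection
from .scoring import score_fraction

log = logging.getLogger(__name__)

QUARTERS = ("c1", "c2", "c3", "c4")


# ----------------------------------------------------------- partition
@dataclass
class QuartileLabels:
    """Per-cell quarter labels for one pathway score, with the
    five-number-summary breakpoints of the score for reference."""

    pathway: str
    labels: pd.Series           # cell id -> c1..c4 (c1 = highest scores)
    breakpoints: np.ndarray     # Tukey five-number summary of the score


def quartile_partition(scores: pd.Series, pathway: str | None = None) -> QuartileLabels:
    """Split cells into four contiguous equal-count blocks by descending
    score: c1 the highest-scoring quarter, c4 the lowest.

    When the cell count is not divisible by 4, the earlier (higher-score)
    blocks take the extra cells, so block sizes differ by at most one.
    Ties are resolved by stable cell-id order.  Requires ≥ 4 cells.
    """
    n = len(scores)
    if n < 4:
        raise ValueError("quartile partition needs at least 4 cells")
    order = scores.sort_values(ascending=False, kind="mergesort").index
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    labels = pd.Series(index=scores.index, dtype=object)
    start = 0
    for q, size in zip(QUARTERS, sizes):
        labels.loc[order[start : start + size]] = q
        start += size
    return QuartileLabels(
        pathway=pathway or (scores.name or "score"),
        labels=labels,
        breakpoints=fivenum(scores.to_numpy()),
    )


def quarter_group_proportions(q: QuartileLabels, d: ExpressionDataset) -> pd.DataFrame:
    """Group × quarter proportions weighted by each group's neuron total:
    entry (g, c) = group-g cells in quarter c / group-g cells overall, so
    each group's row sums to one."""
    df = pd.DataFrame({"group": d.obs.loc[q.labels.index, "group"], "quarter": q.labels})
    counts = df.groupby(["group", "quarter"], observed=True).size().unstack(fill_value=0)
    counts = counts.reindex(columns=list(QUARTERS), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


# -------------------------------------------------------------- markers
def quarter_unique_markers(
    d: ExpressionDataset,
    q: QuartileLabels,
    cfg: AnalysisConfig | None = None,
    ranked: RankedMatrix | None = None,
) -> pd.DataFrame:
    """One-vs-rest positive markers per quarter, then restricted to genes
    marking exactly one quarter.

    Per quarter, a Wilcoxon rank-sum test of the quarter's cells against
    all others on the normalized layer; positive markers must satisfy
    fraction-expressing ≥ ``deg.min_pct`` in the quarter, mean log
    difference ≥ ``deg.logfc`` and BH-adjusted p < ``deg.adj_p``.  Genes
    significant in more than one quarter are removed from all lists.

    ``ranked`` may carry precomputed column ranks of the normalized layer
    (ranks are partition-independent, so callers deriving several pathway
    partitions over the same cells rank once).
    """
    cfg = cfg or AnalysisConfig()
    labels = q.labels.loc[d.obs.index]
    if ranked is None:
        ranked = RankedMatrix(d.normalized)
    X = ranked.X
    raw_pos = d.expressed
    results = []
    for quarter in QUARTERS:
        in_q = (labels == quarter).to_numpy()
        if in_q.sum() < 3:
            raise ValueError(f"quarter {quarter} has fewer than 3 cells")
        out_q = ~in_q
        auc, pval = ranked.one_vs_rest(in_q)
        mean_in = X[in_q].mean(axis=0)
        mean_out = X[out_q].mean(axis=0)
        logfc = mean_in - mean_out
        pct_in = raw_pos[in_q].mean(axis=0)
        pct_out = raw_pos[out_q].mean(axis=0)
        padj = multipletests(pval, method="fdr_bh")[1]
        keep = (
            (logfc >= cfg.deg.logfc)
            & (pct_in >= cfg.deg.min_pct)
            & (padj < cfg.deg.adj_p)
        )
        for j in np.flatnonzero(keep):
            results.append(
                {"quarter": quarter, "gene": d.var.index[j], "avg_logfc": logfc[j],
                 "pct_in": pct_in[j], "pct_out": pct_out[j], "auc": auc[j],
                 "p": pval[j], "p_adj": padj[j]}
            )
    table = pd.DataFrame(results, columns=["quarter", "gene", "avg_logfc", "pct_in",
                                           "pct_out", "auc", "p", "p_adj"])
    if table.empty:
        return table.assign(unique=pd.Series(dtype=bool))
    hits = table.groupby("gene")["quarter"].nunique()
    table["unique"] = table["gene"].map(hits) == 1
    return table


def intersect_quarter_markers(tables: list, quarter: str) -> list:
    """Genes that are unique markers of ``quarter`` in *every* supplied
    marker table (one table per pathway partition).  An empty result is
    valid — mid quarters typically share no unique markers."""
    if len(tables) < 2:
        raise ValueError("need at least two pathway partitions to intersect")
    sets = []
    for t in tables:
        u = t.loc[(t["quarter"] == quarter) & t["unique"], "gene"]
        sets.append(set(u))
    common = set.intersection(*sets) if sets else set()
    return sorted(common)


# ------------------------------------------------------------ signatures
@dataclass
class SignaturePair:
    """The two opposing derived signatures with their provenance."""

    c1_up: tuple
    c4_up: tuple
    pathways: tuple = ()
    marker_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.c1_up) & set(self.c4_up)
        if overlap:
            raise ValueError(f"signatures overlap: {sorted(overlap)[:5]}")

    def to_collection(self) -> GeneSetCollection:
        """Export the nonempty signatures as gene sets (an empty
        signature is a valid derivation outcome and is simply omitted)."""
        coll = GeneSetCollection()
        if self.c1_up:
            coll.add(GeneSet("c1_up_signature", tuple(self.c1_up), source="derived"))
        if self.c4_up:
            coll.add(GeneSet("c4_up_signature", tuple(self.c4_up), source="derived"))
        return coll


def derive_signature_pair(
    d: ExpressionDataset,
    pathways: GeneSetCollection,
    cfg: AnalysisConfig | None = None,
) -> SignaturePair:
    """Full derivation: per pathway, fraction scores → quartile partition
    → unique quarter markers; then the c1 and c4 intersections across all
    pathway partitions form the signature pair."""
    cfg = cfg or AnalysisConfig()
    ranked = RankedMatrix(d.normalized)
    tables, names = [], []
    for gs in pathways:
        scores = score_fraction(d, gs)
        part = quartile_partition(scores, pathway=gs.name)
        tables.append(quarter_unique_markers(d, part, cfg, ranked=ranked))
        names.append(gs.name)
    c1 = intersect_quarter_markers(tables, "c1")
    c4 = intersect_quarter_markers(tables, "c4")
    marker_counts = {
        name: t.groupby("quarter")["unique"].sum().to_dict()
        for name, t in zip(names, tables)
    }
    return SignaturePair(tuple(c1), tuple(c4), tuple(names), marker_counts)


def validate_opposing(pair: SignaturePair, d: ExpressionDataset) -> dict:
    """Pearson correlation between the per-cell fraction scores of the two
    signatures; passes iff the correlation is negative."""
    if not pair.c1_up or not pair.c4_up:
        raise ValueError("both signatures must be nonempty")
    s1 = score_fraction(d, GeneSet("c1_up", tuple(pair.c1_up)))
    s4 = score_fraction(d, GeneSet("c4_up", tuple(pair.c4_up)))
    r, p = stats.pearsonr(s1, s4)
    return {"r": float(r), "p": float(p), "pass": bool(r < 0)}


# ----------------------------------------------------------------- auROC
def auroc_rank(
    scores: pd.DataFrame,
    groups: pd.Series,
    pair: tuple,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """auROC of group1 vs group2 per score column, sorted descending.

    AUC is the Mann-Whitney win probability U/(n₁·n₂) with ties counting
    one half; the p-value is the two-sided tie-corrected rank-sum test.
    Requires at least ``auroc_min_cells`` cells in each group (the
    study's 15-cell floor); otherwise the comparison is refused.
    """
    cfg = cfg or AnalysisConfig()
    g1, g2 = pair
    mask1 = (groups == g1).to_numpy()
    mask2 = (groups == g2).to_numpy()
    if mask1.sum() < cfg.auroc_min_cells or mask2.sum() < cfg.auroc_min_cells:
        raise ValueError(
            f"both groups need ≥ {cfg.auroc_min_cells} cells "
            f"({g1}: {mask1.sum()}, {g2}: {mask2.sum()})"
        )
    auc, pval = mann_whitney_auc(scores.to_numpy(float), mask1, mask2)
    out = pd.DataFrame(
        {"item": scores.columns, "auc": auc, "p": pval, "pair": f"{g1}_vs_{g2}"}
    )
    return out.sort_values(["auc", "item"], ascending=[False, True]).reset_index(drop=True)


# ------------------------------------------------------------------- DEG
def _bimod_loglik(x: np.ndarray) -> float:
    """Log-likelihood of the zero-inflated location model: point mass at
    zero plus a normal on the positive normalized values."""
    n = x.size
    pos = x[x > 0]
    k = pos.size
    ll = 0.0
    if 0 < k < n:
        p = k / n
        ll += k * np.log(p) + (n - k) * np.log1p(-p)
    if k >= 2:
        sd = pos.std()
        if sd > 0:
            ll += float(np.sum(stats.norm.logpdf(pos, loc=pos.mean(), scale=sd)))
    return ll


def deg_test(
    d: ExpressionDataset,
    pair: tuple,
    cfg: AnalysisConfig | None = None,
    genes: list | None = None,
) -> pd.DataFrame:
    """Differential expression between two groups with a bimodal
    likelihood-ratio test.

    Genes passing the ``min_pct`` and ``logfc`` pre-filters are tested by
    a 2-df likelihood-ratio comparing a pooled zero-inflated location
    model against per-group models (point mass at zero + normal on
    positive log-normalized values); BH adjustment across tested genes;
    the final table keeps genes with |avg_diff| above the configured
    threshold.  Genes that are all-zero in both groups are skipped.
    """
    cfg = cfg or AnalysisConfig()
    g1, g2 = pair
    m1 = (d.obs["group"] == g1).to_numpy()
    m2 = (d.obs["group"] == g2).to_numpy()
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError("both groups need at least 3 cells")
    X = d.normalized_dense()
    raw_pos = d.expressed
    gene_idx = (
        np.arange(d.n_genes)
        if genes is None
        else d.gene_indices(genes)
    )

    rows = []
    for j in gene_idx:
        x1, x2 = X[m1, j], X[m2, j]
        if not (np.any(x1 > 0) or np.any(x2 > 0)):
            continue
        pct1 = raw_pos[m1, j].mean()
        pct2 = raw_pos[m2, j].mean()
        if max(pct1, pct2) < cfg.deg.min_pct:
            continue
        avg_diff = x1.mean() - x2.mean()
        if abs(avg_diff) < cfg.deg.logfc:
            continue
        lr = 2.0 * (
            _bimod_loglik(x1) + _bimod_loglik(x2) - _bimod_loglik(np.concatenate([x1, x2]))
        )
        p = float(stats.chi2.sf(max(lr, 0.0), 2))
        rows.append(
            {"gene": d.var.index[j], "avg_diff": avg_diff, "pct_1": pct1,
             "pct_2": pct2, "p": p}
        )
    table = pd.DataFrame(rows, columns=["gene", "avg_diff", "pct_1", "pct_2", "p"])
    if table.empty:
        return table.assign(p_adj=pd.Series(dtype=float), direction=pd.Series(dtype=object))
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["direction"] = np.where(table["avg_diff"] > 0, "up", "down")
    table = table[np.abs(table["avg_diff"]) > cfg.deg.avg_diff]
    return table.sort_values("p").reset_index(drop=True)


# ----------------------------------------------------------- rank screens
@dataclass
class RankScreenResult:
    """Per score set: subtype mean/sd/rank plus top-K and bottom-K lists."""

    stats: dict      # score set -> DataFrame(subtype, mean, sd, rank)
    top: dict        # score set -> list of subtypes (size ≤ K)
    bottom: dict
    k: int


def rank_subtype_scores(
    assignment,
    score_table: pd.DataFrame,
    d: ExpressionDataset,
    reference_group: str,
    cfg: AnalysisConfig | None = None,
) -> RankScreenResult:
    """Rank subtypes by their members' mean per-cell score within the
    reference group, one ranking per score column.

    Subtypes below ``subtype_min_cells`` members in the reference group
    are excluded.  Ranks descend by mean with alphabetical tie-break; sd
    is the sample standard deviation.  K larger than the number of ranked
    subtypes degrades gracefully (top-K = all, logged).
    """
    cfg = cfg or AnalysisConfig()
    in_ref = d.obs["group"] == reference_group
    stats_d, top_d, bottom_d = {}, {}, {}
    eligible = {}
    for s, mem in assignment.members.items():
        cells = [c for c in mem if in_ref.loc[c]]
        if len(cells) >= cfg.subtype_min_cells:
            eligible[s] = cells
    for col in score_table.columns:
        rows = []
        for s, cells in eligible.items():
            vals = score_table.loc[cells, col]
            rows.append({"subtype": s, "mean": vals.mean(),
                         "sd": vals.std(ddof=1), "n": len(cells)})
        df = pd.DataFrame(rows).sort_values(
            ["mean", "subtype"], ascending=[False, True]
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        k = cfg.screen_k
        if k > len(df):
            log.info("K=%d exceeds %d ranked subtypes for %r; using all", k, len(df), col)
        stats_d[col] = df
        top_d[col] = df["subtype"].head(k).tolist()
        bottom_d[col] = df["subtype"].tail(min(k, len(df))).tolist()
    return RankScreenResult(stats_d, top_d, bottom_d, cfg.screen_k)


def intersection_screen(r: RankScreenResult, cfg: AnalysisConfig | None = None) -> dict:
    """Subtypes appearing in the top-K (separately, bottom-K) lists of at
    least ``screen_min_hits`` score sets, with their hit counts — the
    study's "top 20 in at least 4 out of 5" rule."""
    cfg = cfg or AnalysisConfig()
    n_sets = len(r.top)
    if n_sets < cfg.screen_min_hits:
        raise ValueError(
            f"only {n_sets} score sets but screen_min_hits={cfg.screen_min_hits}"
        )

    def tally(lists: dict) -> pd.DataFrame:
        counts: dict = {}
        for subs in lists.values():
            for s in subs:
                counts[s] = counts.get(s, 0) + 1
        rows = [
            {"subtype": s, "hits": h}
            for s, h in counts.items()
            if h >= cfg.screen_min_hits
        ]
        df = pd.DataFrame(rows, columns=["subtype", "hits"])
        return df.sort_values(["hits", "subtype"], ascending=[False, True]).reset_index(drop=True)

    return {"top": tally(r.top), "bottom": tally(r.bottom)}


# -------------------------------------------------------------------- ORA
def ora_enrich(
    genes,
    sets: GeneSetCollection,
    universe,
    cfg: AnalysisConfig | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene list in each
    set, BH-corrected across sets; significant iff FDR < 0.05.

    Genes must be a subset of the universe; set members outside the
    universe are ignored.  An empty gene list yields p = 1 everywhere.
    """
    universe = set(universe)
    genes = set(genes)
    if not genes <= universe:
        raise ValueError("gene list must be a subset of the universe")
    M, N = len(universe), len(genes)
    rows = []
    for gs in sets:
        members = set(gs.members) & universe
        n = len(members)
        k = len(members & genes)
        p = 1.0 if (N == 0 or n == 0) else float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append({"set": gs.name, "set_size": n, "overlap": k, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if table.empty:
        return table.assign(fdr=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["fdr"] < fdr
    return table
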