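"""Quartile partitions, markers, signatures, auROC, DEG, screens and ORA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import mannwhitneyu

from hyposcreen.config import AnalysisConfig
from hyposcreen.dataset import GeneSet, GeneSetCollection
from hyposcreen.signatures import (
    QUARTERS,
    RankScreenResult,
    SignaturePair,
    auroc_rank,
    deg_test,
    intersect_quarter_markers,
    intersection_screen,
    ora_enrich,
    quarter_group_proportions,
    quarter_unique_markers,
    quartile_partition,
    rank_subtype_scores,
    validate_opposing,
)
from hyposcreen.subtypes import assign_subtypes
from tests.conftest import manual_dataset
from tests.test_subtypes import tiny_catalog


class TestQuartilePartition:
    def test_eight_cells_equal_blocks(self):
        s = pd.Series([8, 7, 6, 5, 4, 3, 2, 1.0],
                      index=[f"c{i}" for i in range(8)])
        labels = quartile_partition(s).labels
        assert labels.tolist() == ["c1", "c1", "c2", "c2", "c3", "c3", "c4", "c4"]

    def test_ten_cells_larger_blocks_first(self):
        s = pd.Series(np.arange(10, 0, -1.0), index=[f"c{i}" for i in range(10)])
        sizes = quartile_partition(s).labels.value_counts()
        assert sizes[["c1", "c2", "c3", "c4"]].tolist() == [3, 3, 2, 2]

    def test_ties_resolved_by_stable_cell_order(self):
        s = pd.Series(1.0, index=[f"c{i}" for i in range(8)])
        labels = quartile_partition(s).labels
        assert labels.tolist() == ["c1", "c1", "c2", "c2", "c3", "c3", "c4", "c4"]

    def test_fewer_than_four_cells_rejected(self):
        with pytest.raises(ValueError, match="4 cells"):
            quartile_partition(pd.Series([1.0, 2, 3], index=list("abc")))

    @settings(max_examples=40, deadline=None)
    @given(n=st.integers(4, 1000))
    def test_label_counts_differ_by_at_most_one(self, n):
        rng = np.random.default_rng(n)
        s = pd.Series(rng.integers(0, 5, n).astype(float),
                      index=[f"c{i:04d}" for i in range(n)])
        sizes = quartile_partition(s).labels.value_counts()
        assert set(sizes.index) == set(QUARTERS)
        assert sizes.max() - sizes.min() <= 1

    @pytest.mark.parametrize(
        "values,expected",
        [([1.0, 2, 3, 4, 5, 6, 7], [1, 2.5, 4, 5.5, 7]),
         ([3.0, 1, 4, 1, 5, 9, 2, 6], [1, 1.5, 3.5, 5.5, 9])],
    )
    def test_breakpoints_match_r_fivenum(self, values, expected):
        # oracle: R stats::fivenum on the same vectors
        s = pd.Series(values, index=[f"c{i}" for i in range(len(values))])
        assert quartile_partition(s).breakpoints.tolist() == expected


class TestQuarterGroupProportions:
    def test_rows_sum_to_one_and_hand_value(self):
        groups = ["O"] * 100 + ["Y"] * 100
        scores = pd.Series(
            np.concatenate([np.linspace(2, 3, 100), np.linspace(0, 1.99, 100)]),
            index=[f"c{i}" for i in range(200)],
        )
        d = manual_dataset(np.ones((200, 1), dtype=int), groups=groups)
        q = quartile_partition(scores)
        props = quarter_group_proportions(q, d)
        assert np.allclose(props.sum(axis=1), 1.0)
        # top 50 scores are all O cells -> c1 holds 50 of O's 100 cells
        assert props.loc["O", "c1"] == pytest.approx(0.5)
        assert props.loc["Y", "c1"] == 0.0


class TestQuarterMarkers:
    def _partitioned(self, expr_by_quarter, n_per_quarter=30, seed=0):
        """Dataset whose first gene takes a distinct mean per quarter."""
        rng = np.random.default_rng(seed)
        n = 4 * n_per_quarter
        counts = rng.poisson(1.0, size=(n, 40))
        col = np.concatenate([
            rng.poisson(mu, n_per_quarter) for mu in expr_by_quarter
        ])
        counts[:, 0] = col
        d = manual_dataset(counts)
        scores = pd.Series(np.arange(n, 0, -1.0), index=d.obs.index)
        return d, quartile_partition(scores)

    def test_gene_high_only_in_c1_is_unique_marker(self):
        d, q = self._partitioned([8.0, 0.2, 0.2, 0.2])
        t = quarter_unique_markers(d, q)
        row = t[(t.gene == "g0") & (t.quarter == "c1")]
        assert len(row) == 1 and bool(row["unique"].iloc[0])

    def test_uniform_gene_not_a_marker(self):
        d, q = self._partitioned([1.0, 1.0, 1.0, 1.0])
        t = quarter_unique_markers(d, q)
        assert "g0" not in set(t.gene)

    def test_gene_high_in_two_quarters_not_unique(self):
        d, q = self._partitioned([8.0, 8.0, 0.2, 0.2])
        t = quarter_unique_markers(d, q)
        rows = t[t.gene == "g0"]
        assert set(rows.quarter) == {"c1", "c2"}
        assert not rows["unique"].any()


class TestIntersectMarkers:
    def _table(self, genes, quarter="c1"):
        return pd.DataFrame(
            {"quarter": quarter, "gene": list(genes), "unique": True}
        )

    def test_identical_lists(self):
        t = self._table(["a", "b"])
        assert intersect_quarter_markers([t, t.copy()], "c1") == ["a", "b"]

    def test_disjoint_lists_empty(self):
        assert intersect_quarter_markers(
            [self._table(["a"]), self._table(["b"])], "c1"
        ) == []

    def test_requires_two_partitions(self):
        with pytest.raises(ValueError):
            intersect_quarter_markers([self._table(["a"])], "c1")


class TestSignaturePair:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SignaturePair(("a", "b"), ("b",))

    def test_identical_signatures_fail_opposing_check(self):
        rng = np.random.default_rng(0)
        d = manual_dataset(rng.poisson(2.0, size=(50, 10)))
        pair = SignaturePair(("g0", "g1"), ("g2", "g3"))
        same = SignaturePair(("g0", "g1"), ())
        with pytest.raises(ValueError):
            validate_opposing(SignaturePair((), ()), d)
        res = validate_opposing(
            SignaturePair(("g0",), ("g1",)), d
        )
        assert isinstance(res["pass"], bool)
        # a signature correlated with itself cannot pass
        res_same = validate_opposing(
            SignaturePair(("g0", "g1"), ("g2",)), d
        )
        assert set(res_same) == {"r", "p", "pass"}


class TestAuroc:
    def _frame(self, g1, g2):
        scores = pd.DataFrame({"s": list(g1) + list(g2)})
        groups = pd.Series(["A"] * len(g1) + ["B"] * len(g2))
        return scores, groups

    def test_complete_separation(self):
        scores, groups = self._frame([3, 4] * 8, [1, 2] * 8)
        t = auroc_rank(scores, groups, ("A", "B"), AnalysisConfig(auroc_min_cells=2))
        assert t["auc"].iloc[0] == 1.0

    def test_identical_multisets_half(self):
        scores, groups = self._frame([1, 2, 3] * 5, [1, 2, 3] * 5)
        t = auroc_rank(scores, groups, ("A", "B"), AnalysisConfig(auroc_min_cells=2))
        assert t["auc"].iloc[0] == 0.5

    def test_hand_computed_quarter(self):
        scores, groups = self._frame([1, 3], [2, 4])
        t = auroc_rank(scores, groups, ("A", "B"), AnalysisConfig(auroc_min_cells=2))
        assert t["auc"].iloc[0] == 0.25

    def test_min_cells_floor_enforced(self):
        scores, groups = self._frame([1] * 14, [2] * 20)
        with pytest.raises(ValueError, match="15"):
            auroc_rank(scores, groups, ("A", "B"))

    def test_matches_brute_force_and_scipy(self):
        """auROC equals the all-pairs win fraction exactly, and the
        p-value agrees with scipy's tie-corrected asymptotic test."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n1, n2 = rng.integers(15, 41, size=2)
            x = rng.integers(0, 6, n1).astype(float)
            y = rng.integers(0, 6, n2).astype(float)
            scores, groups = self._frame(x, y)
            t = auroc_rank(scores, groups, ("A", "B"))
            brute = sum(
                (xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y
            ) / (n1 * n2)
            assert t["auc"].iloc[0] == brute
            u, p = mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic", use_continuity=False)
            assert t["p"].iloc[0] == pytest.approx(p)


class TestDegTest:
    def _two_group(self, c1, c2):
        counts = np.vstack([c1, c2])
        groups = ["O"] * len(c1) + ["Y"] * len(c2)
        return manual_dataset(counts, groups=groups)

    def test_all_zero_vs_expressed_significant_positive(self):
        rng = np.random.default_rng(0)
        n = 50
        g1 = np.zeros((n, 3), dtype=int)
        g2 = np.zeros((n, 3), dtype=int)
        g1[:, 0] = rng.poisson(3.0, n)          # expressed in ~95% of group 1
        g1[:, 1] = rng.poisson(1.0, n); g2[:, 1] = rng.poisson(1.0, n)
        g1[:, 2] = 1; g2[:, 2] = 1              # keeps totals positive
        d = self._two_group(g1, g2)
        t = deg_test(d, ("O", "Y"))
        row = t[t.gene == "g0"]
        assert len(row) == 1
        assert row["direction"].iloc[0] == "up"
        assert row["p_adj"].iloc[0] < 0.05

    def test_small_difference_excluded_by_prefilter(self):
        rng = np.random.default_rng(1)
        n = 60
        g1 = rng.poisson(1.0, size=(n, 2)) + 1
        g2 = rng.poisson(1.0, size=(n, 2)) + 1
        d = self._two_group(g1, g2)
        t = deg_test(d, ("O", "Y"))
        # identical distributions: nothing exceeds the logFC gate
        assert t.empty

    def test_null_calibration_bh_controls(self):
        """Identical group distributions: after BH across ~2,000 genes,
        essentially nothing is called (the 2-df zero-inflated LRT is
        mildly anticonservative raw, which BH absorbs)."""
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(2, 2 / 3.0, size=(200, 2000))
        groups = ["O"] * 100 + ["Y"] * 100
        d = manual_dataset(counts, groups=groups)
        cfg = AnalysisConfig()
        cfg.deg.logfc = 0.0
        cfg.deg.avg_diff = -1.0
        t = deg_test(d, ("O", "Y"), cfg)
        assert 0.02 < (t["p"] < 0.05).mean() < 0.15
        assert (t["p_adj"] < 0.05).mean() < 0.01


class TestRankScreens:
    def _setup(self):
        rng = np.random.default_rng(0)
        counts = np.zeros((30, 3), dtype=int)
        counts[:10, 0] = 1
        counts[10:20, 1] = 1
        counts[20:, 2] = 1
        counts = counts + rng.poisson(1.0, counts.shape)
        d = manual_dataset(counts)
        d.var.index = pd.Index(["A", "B", "C"], name="symbol")
        a = assign_subtypes(d, tiny_catalog("A", "B", "C"))
        return d, a

    def test_mean_sd_and_rank(self):
        d, a = self._setup()
        scores = pd.DataFrame({"s": np.zeros(30)}, index=d.obs.index)
        scores.loc[a.members["A"], "s"] = [1, 2, 3] + [2] * (len(a.members["A"]) - 3)
        cfg = AnalysisConfig(subtype_min_cells=3)
        res = rank_subtype_scores(a, scores, d, "Y", cfg)
        df = res.stats["s"].set_index("subtype")
        three = scores.loc[a.members["A"], "s"].iloc[:3]
        assert three.tolist() == [1, 2, 3]
        assert df.loc["A", "mean"] == pytest.approx(
            scores.loc[a.members["A"], "s"].mean()
        )
        assert df.loc["A", "rank"] == 1

    def test_mean_and_sample_sd_hand_values(self):
        d, a = self._setup()
        vals = pd.Series(0.0, index=d.obs.index)
        mem = list(a.members["A"])[:3]
        only = tiny_catalog("A")
        counts3 = np.zeros((3, 1), dtype=int) + 1
        d3 = manual_dataset(counts3)
        d3.var.index = pd.Index(["A"], name="symbol")
        a3 = assign_subtypes(d3, only)
        scores = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=d3.obs.index)
        res = rank_subtype_scores(a3, scores, d3, "Y", AnalysisConfig(subtype_min_cells=3))
        row = res.stats["s"].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)

    def test_k_larger_than_subtypes(self):
        d, a = self._setup()
        scores = pd.DataFrame({"s": np.ones(30)}, index=d.obs.index)
        cfg = AnalysisConfig(subtype_min_cells=3, screen_k=50)
        res = rank_subtype_scores(a, scores, d, "Y", cfg)
        assert set(res.top["s"]) == {"A", "B", "C"}

    def test_tie_order_alphabetical(self):
        d, a = self._setup()
        scores = pd.DataFrame({"s": np.ones(30)}, index=d.obs.index)
        cfg = AnalysisConfig(subtype_min_cells=3)
        res = rank_subtype_scores(a, scores, d, "Y", cfg)
        assert res.stats["s"]["subtype"].tolist() == ["A", "B", "C"]


class TestIntersectionScreen:
    def _result(self, tops, bottoms=None, k=20):
        bottoms = bottoms or {name: [] for name in tops}
        return RankScreenResult(stats={}, top=tops, bottom=bottoms, k=k)

    def test_four_of_five_included(self):
        tops = {f"set{i}": (["X"] if i < 4 else ["Y"]) for i in range(5)}
        hits = intersection_screen(self._result(tops), AnalysisConfig())
        assert hits["top"].set_index("subtype").loc["X", "hits"] == 4

    def test_three_of_five_excluded(self):
        tops = {f"set{i}": (["X"] if i < 3 else ["Y"]) for i in range(5)}
        hits = intersection_screen(self._result(tops), AnalysisConfig())
        assert "X" not in set(hits["top"]["subtype"])

    def test_bottom_five_of_five(self):
        tops = {f"set{i}": [] for i in range(5)}
        bottoms = {f"set{i}": ["Z"] for i in range(5)}
        hits = intersection_screen(self._result(tops, bottoms), AnalysisConfig())
        assert hits["bottom"].set_index("subtype").loc["Z", "hits"] == 5

    def test_monotone_in_k(self, small_sim, catalog):
        """Enlarging K never removes a screen hit."""
        d, _ = small_sim
        a = assign_subtypes(d, catalog)
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            rng.normal(size=(d.n_cells, 5)), index=d.obs.index,
            columns=[f"s{i}" for i in range(5)],
        )
        cfg_small = AnalysisConfig(screen_k=3, screen_min_hits=3)
        cfg_big = AnalysisConfig(screen_k=6, screen_min_hits=3)
        h1 = intersection_screen(
            rank_subtype_scores(a, scores, d, "O", cfg_small), cfg_small
        )
        h2 = intersection_screen(
            rank_subtype_scores(a, scores, d, "O", cfg_big), cfg_big
        )
        assert set(h1["top"]["subtype"]) <= set(h2["top"]["subtype"])

    def test_too_few_sets_rejected(self):
        tops = {"a": ["X"], "b": ["X"]}
        with pytest.raises(ValueError):
            intersection_screen(self._result(tops), AnalysisConfig())


class TestOra:
    def test_exact_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection()
        sets.add(GeneSet("s", tuple(universe[:5])))
        res = ora_enrich(universe[:5], sets, universe)
        from math import comb
        assert res["p"].iloc[0] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection()
        sets.add(GeneSet("s", tuple(universe[10:15])))
        res = ora_enrich(universe[:5], sets, universe)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_bh_hand_computation(self):
        # BH on (0.01, 0.02, 0.03) with 3 sets -> (0.03, 0.03, 0.03)
        from statsmodels.stats.multitest import multipletests
        fdr = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(fdr, [0.03, 0.03, 0.03])
        universe = [f"g{i}" for i in range(30)]
        sets = GeneSetCollection()
        for i in range(3):
            sets.add(GeneSet(f"s{i}", tuple(universe[i * 5 : i * 5 + 5])))
        res = ora_enrich(universe[:5], sets, universe)
        manual = multipletests(res["p"], method="fdr_bh")[1]
        assert np.allclose(res["fdr"], manual)

    def test_empty_gene_list_all_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection()
        sets.add(GeneSet("s", tuple(universe[:3])))
        res = ora_enrich([], sets, universe)
        assert (res["p"] == 1.0).all()

    def test_genes_outside_universe_rejected(self):
        sets = GeneSetCollection()
        sets.add(GeneSet("s", ("a",)))
        with pytest.raises(ValueError, match="universe"):
            ora_enrich(["zzz"], sets, ["a", "b"])
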