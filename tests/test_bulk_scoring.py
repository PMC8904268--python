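import numpy as np
import pandas as pd
import pytest

from occuscore.bulk_scoring import (
    ExpressionMatrix,
    GroupDesign,
    ScoringError,
    compare_panel,
    group_medians,
    relative_expression,
    score_cell_types,
)
from occuscore.signatures import SignatureSet
from occuscore.synthetic_data import BulkSimParams, simulate_bulk

from conftest import perm_dunn_p


@pytest.fixture
def small_matrix():
    data = {
        "c1": [2.0, 4.0], "c2": [4.0, 4.0], "c3": [6.0, 4.0], "c4": [10.0, 4.0],
        "t1": [10.0, 0.0], "t2": [10.0, 0.0],
    }
    return ExpressionMatrix(pd.DataFrame(data, index=["gA", "gB"]))


@pytest.fixture
def small_design():
    return GroupDesign(
        assignment={"c1": "ctrl", "c2": "ctrl", "c3": "ctrl", "c4": "ctrl",
                    "t1": "TO", "t2": "TO"},
        control_group="ctrl",
    )


class TestGroupMedians:
    def test_odd_count_median(self):
        expr = ExpressionMatrix(pd.DataFrame({"a": [2.0], "b": [4.0], "c": [6.0],
                                              "d": [9.0]}, index=["g"]))
        design = GroupDesign({"a": "x", "b": "x", "c": "x", "d": "y"}, "x")
        med = group_medians(expr, design)
        assert med.loc["g", "x"] == 4.0

    def test_even_count_midpoint(self, small_matrix, small_design):
        med = group_medians(small_matrix, small_design)
        # {2, 4, 6, 10} -> (4 + 6) / 2
        assert med.loc["gA", "ctrl"] == 5.0

    def test_single_sample_group(self):
        expr = ExpressionMatrix(pd.DataFrame({"a": [3.0], "b": [7.0]}, index=["g"]))
        design = GroupDesign({"a": "x", "b": "y"}, "x")
        med = group_medians(expr, design)
        assert med.loc["g", "y"] == 7.0

    def test_missing_sample_named_in_error(self, small_matrix):
        design = GroupDesign({"c1": "ctrl", "nope": "TO"}, "ctrl")
        with pytest.raises(ScoringError, match="nope"):
            group_medians(small_matrix, design)


class TestRelativeExpression:
    def test_hand_ratio(self):
        med = pd.DataFrame({"ctrl": [4.0], "TO": [10.0]}, index=["gA"])
        rel = relative_expression(med, "ctrl")
        assert rel.ratios.loc["gA", "TO"] == 2.5

    def test_end_to_end_ratio(self, small_matrix, small_design):
        # control median of gA is (4 + 6) / 2 = 5, TO median is 10
        rel = relative_expression(group_medians(small_matrix, small_design), "ctrl")
        assert rel.ratios.loc["gA", "TO"] == 2.0

    def test_control_column_exactly_one(self, rng):
        med = pd.DataFrame(rng.uniform(0.5, 20, (50, 3)),
                           columns=["ctrl", "a", "b"],
                           index=[f"g{i}" for i in range(50)])
        rel = relative_expression(med, "ctrl")
        assert (rel.ratios["ctrl"] == 1.0).all()

    def test_zero_control_median_dropped(self):
        med = pd.DataFrame({"ctrl": [4.0, 0.0], "TO": [10.0, 5.0]},
                           index=["gA", "gB"])
        rel = relative_expression(med, "ctrl", epsilon=1e-6)
        assert rel.dropped_genes == ("gB",)
        assert "gB" not in rel.ratios.index
        assert rel.ratios.loc["gA", "TO"] == 2.5

    def test_all_dropped_raises(self):
        med = pd.DataFrame({"ctrl": [0.0], "TO": [5.0]}, index=["g"])
        with pytest.raises(ScoringError, match="dropped"):
            relative_expression(med, "ctrl")

    def test_scale_equivariance(self, small_matrix, small_design):
        rel1 = relative_expression(group_medians(small_matrix, small_design), "ctrl")
        scaled = ExpressionMatrix(small_matrix.values * 1.0 + 0.0)
        scaled.values.loc["gA"] *= 37.0
        rel2 = relative_expression(group_medians(scaled, small_design), "ctrl")
        np.testing.assert_allclose(rel1.ratios.loc["gA"], rel2.ratios.loc["gA"])

    def test_sample_order_permutation_invariance(self, rng):
        genes = [f"g{i}" for i in range(20)]
        samples = [f"s{i}" for i in range(8)]
        df = pd.DataFrame(rng.uniform(1, 50, (20, 8)), index=genes, columns=samples)
        design = GroupDesign({s: ("ctrl" if i < 4 else "TO")
                              for i, s in enumerate(samples)}, "ctrl")
        rel1 = relative_expression(group_medians(ExpressionMatrix(df), design), "ctrl")
        shuffled = df[rng.permutation(samples)]
        rel2 = relative_expression(
            group_medians(ExpressionMatrix(shuffled), design), "ctrl")
        pd.testing.assert_frame_equal(rel1.ratios, rel2.ratios)


class TestScoreCellTypes:
    def _rel(self, ratios):
        df = pd.DataFrame(ratios)
        df["ctrl"] = 1.0
        from occuscore.bulk_scoring import RelativeExpressionTable
        return RelativeExpressionTable(df[["ctrl"] + [c for c in df if c != "ctrl"]],
                                       "ctrl", ())

    def test_median_summary(self):
        rel = self._rel({"TO": pd.Series([1.0, 2.0, 4.0], index=["g1", "g2", "g3"])})
        sigs = SignatureSet({"basal": ["g1", "g2", "g3"]})
        panel = score_cell_types(rel, sigs)
        assert panel.scores["basal"].summary["TO"] == 2.0

    def test_control_summary_is_one(self):
        rel = self._rel({"TO": pd.Series([1.3, 0.7, 2.0], index=["g1", "g2", "g3"])})
        panel = score_cell_types(rel, SignatureSet({"basal": ["g1", "g2", "g3"]}))
        assert panel.scores["basal"].summary["ctrl"] == 1.0

    def test_absent_gene_shrinks_vector(self):
        rel = self._rel({"TO": pd.Series([1.5, 3.0], index=["g1", "g2"])})
        panel = score_cell_types(rel, SignatureSet({"basal": ["g1", "g2", "gX"]}))
        assert panel.scores["basal"].n_genes == 2
        assert len(panel.scores["basal"].ratio_vectors["TO"]) == 2

    def test_fully_absent_cell_type_reported(self):
        rel = self._rel({"TO": pd.Series([1.5], index=["g1"])})
        panel = score_cell_types(
            rel, SignatureSet({"basal": ["g1"], "club": ["gX", "gY"]}))
        assert panel.absent_cell_types == ("club",)

    def test_all_absent_raises(self):
        rel = self._rel({"TO": pd.Series([1.5], index=["g1"])})
        with pytest.raises(ScoringError, match="no signature gene"):
            score_cell_types(rel, SignatureSet({"club": ["gX"]}))


class TestComparePanel:
    def _panel(self, vectors_by_group, genes=None):
        from occuscore.bulk_scoring import CellTypeScore, CellTypeScorePanel
        genes = genes or [f"g{i}" for i in
                          range(len(next(iter(vectors_by_group.values()))))]
        vecs = {g: np.asarray(v, float) for g, v in vectors_by_group.items()}
        score = CellTypeScore(
            cell_type="basal", genes=genes, ratio_vectors=vecs,
            summary={g: float(np.median(v)) for g, v in vecs.items()},
            n_genes=len(genes),
        )
        return CellTypeScorePanel({"basal": score}, control_group="ctrl")

    def test_identical_vectors_not_significant(self):
        panel = self._panel({"ctrl": [1.0, 1.0, 1.0], "TO": [1.0, 1.0, 1.0]})
        compare_panel(panel)
        sc = panel.scores["basal"]
        assert sc.omnibus.p_value == 1.0
        assert not any(sc.significant.values())

    def test_small_n_pairwise_matches_permutation_oracle(self):
        # {1,2,3} vs {10,11,12}: significance is not guaranteed at n = 3;
        # instead the analytic Dunn p must match the permutation oracle
        panel = self._panel({"ctrl": [1.0, 2.0, 3.0], "TO": [10.0, 11.0, 12.0]})
        compare_panel(panel, adjust="none")
        p = panel.scores["basal"].pairwise["TO"].p_value
        oracle = perm_dunn_p([[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]], 0, 1, seed=3)
        assert abs(p - oracle) <= 0.02

    def test_short_vector_untestable(self):
        panel = self._panel({"ctrl": [1.0], "TO": [2.0]}, genes=["g1"])
        compare_panel(panel)
        assert not panel.scores["basal"].testable

    def test_auto_adjust_thresholds_on_group_count(self):
        vecs4 = {g: list(np.linspace(1, 2, 5)) for g in
                 ["ctrl", "a", "b", "c"]}
        panel = self._panel(vecs4)
        compare_panel(panel, adjust="auto")  # 4 groups -> no Bonferroni
        res = panel.scores["basal"].pairwise["a"]
        assert res.extra["p_adjusted"] == pytest.approx(res.p_value)
        vecs5 = {**vecs4, "d": vecs4["ctrl"]}
        panel5 = self._panel(vecs5)
        compare_panel(panel5, adjust="auto")  # 5 groups -> Bonferroni m=4
        res5 = panel5.scores["basal"].pairwise["a"]
        assert res5.extra["p_adjusted"] == pytest.approx(min(1.0, 4 * res5.p_value))

    def test_simulated_basal_expansion_detected(self):
        hits = 0
        n_reps = 25
        for rep in range(n_reps):
            params = BulkSimParams(
                cell_types=("basal", "other"),
                proportions={"ctrl": [0.015, 0.985], "TO": [0.025, 0.975]},
                markers_per_type=20, pure_markers=True, n_samples=6,
                noise_sigma=0.2, seed=9000 + rep,
            )
            expr, design, truth = simulate_bulk(params)
            rel = relative_expression(group_medians(expr, design), "ctrl")
            panel = compare_panel(score_cell_types(rel, truth.signatures))
            hits += panel.scores["basal"].significant["TO"]
        assert hits >= 0.9 * n_reps


def test_expression_matrix_rejects_negative():
    with pytest.raises(ScoringError, match="negative"):
        ExpressionMatrix(pd.DataFrame({"s1": [-1.0]}, index=["g"]))


def test_design_requires_two_groups():
    with pytest.raises(ScoringError, match=">= 2 groups"):
        GroupDesign({"a": "x", "b": "x"}, "x")


def test_design_control_must_exist():
    with pytest.raises(ScoringError, match="control group"):
        GroupDesign({"a": "x", "b": "y"}, "z")
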