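"""Cohort merging, correlation pruning and majority-vote search."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from icb_bench.combine import (
    _min_vertex_cover,
    enumerate_combinations,
    evaluate_combination,
    frequency_report,
    majority_vote,
    merge_cohorts,
    pearson_filter,
    search_combinations,
)
from icb_bench.errors import (
    DegenerateLabelsError,
    IdentifierCollisionError,
    MissingVoteError,
    SchemaError,
    UndefinedCorrelationError,
)


def exhaustive_min_cover_size(nodes, edges):
    """Oracle: smallest vertex set touching every edge, by subset enumeration."""
    if not edges:
        return 0
    for size in range(1, len(nodes) + 1):
        for cand in combinations(nodes, size):
            cover = set(cand)
            if all(a in cover or b in cover for a, b in edges):
                return size
    raise AssertionError("unreachable")


class TestMergeCohorts:
    def _tables(self, sizes, markers=("m1", "m2")):
        tables, labels = {}, {}
        rng = np.random.default_rng(1)
        for k, size in enumerate(sizes):
            idx = [f"c{k}-P{i}" for i in range(size)]
            tables[f"c{k}"] = pd.DataFrame(
                rng.integers(0, 2, size=(size, len(markers))), index=idx, columns=list(markers)
            )
            labels[f"c{k}"] = pd.Series(
                np.where(rng.random(size) < 0.5, "responder", "non-responder"), index=idx
            )
        return tables, labels

    def test_row_count_additivity(self):
        tables, labels = self._tables([28, 49, 41])
        merged = merge_cohorts(tables, labels)
        assert len(merged) == 118
        assert set(merged["cohort"]) == {"c0", "c1", "c2"}

    def test_single_cohort_identity(self):
        tables, labels = self._tables([10])
        merged = merge_cohorts(tables, labels)
        pd.testing.assert_frame_equal(merged[["m1", "m2"]], tables["c0"])

    def test_duplicate_patient_ids_collide(self):
        tables, labels = self._tables([5, 5])
        tables["c1"].index = tables["c0"].index
        labels["c1"].index = labels["c0"].index
        with pytest.raises(IdentifierCollisionError):
            merge_cohorts(tables, labels)

    def test_disjoint_markers_error_unless_restricted(self):
        tables, labels = self._tables([6, 6], markers=("m1", "m2", "m3"))
        tables["c1"] = tables["c1"][["m1", "m2"]]
        with pytest.raises(SchemaError):
            merge_cohorts(tables, labels)
        merged = merge_cohorts(tables, labels, restrict_to_shared=True)
        assert set(merged.columns) == {"m1", "m2", "label", "cohort"}


class TestPearsonFilter:
    def _correlated_scores(self, n=120, seed=4):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n)
        return pd.DataFrame(
            {
                "PDCD1": base + 0.5 * rng.normal(size=n),
                "IFN-y (reduced set)": base + 0.5 * rng.normal(size=n),
                "TIDE": rng.normal(size=n),
                "CTLA4": rng.normal(size=n),
            }
        )

    def test_single_pair_excludes_lower_priority(self):
        scores = self._correlated_scores()
        priority = {"PDCD1": 0.60, "IFN-y (reduced set)": 0.68, "TIDE": 0.7, "CTLA4": 0.66}
        report = pearson_filter(scores, priority=priority)
        assert report.excluded == ["PDCD1"]
        assert len(report.retained) == 3
        assert report.edges == [("PDCD1", "IFN-y (reduced set)")]

    def test_no_edges_excludes_nothing(self):
        rng = np.random.default_rng(8)
        scores = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        report = pearson_filter(scores)
        assert report.excluded == []
        assert report.retained == list("abcde")

    def test_triangle_excludes_exactly_two(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=150)
        scores = pd.DataFrame(
            {
                "a": base + 0.3 * rng.normal(size=150),
                "b": base + 0.3 * rng.normal(size=150),
                "c": base + 0.3 * rng.normal(size=150),
                "d": rng.normal(size=150),
            }
        )
        report = pearson_filter(scores)
        assert set(report.edges) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert len(report.excluded) == 2

    def test_matrix_invariants(self):
        report = pearson_filter(self._correlated_scores())
        r = report.r.to_numpy()
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r, r.T)
        assert (np.abs(r) <= 1.0 + 1e-12).all()
        for a in report.retained:
            for b in report.retained:
                if a != b:
                    strong = abs(report.r.loc[a, b]) > report.r_cut
                    significant = report.p.loc[a, b] < report.alpha
                    assert not (strong and significant)

    def test_constant_marker_errors(self):
        scores = self._correlated_scores()
        scores["flat"] = 1.0
        with pytest.raises(UndefinedCorrelationError, match="flat"):
            pearson_filter(scores)

    def test_cover_minimality_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(3, 13))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.25
            ]
            cover = _min_vertex_cover(nodes, edges, {m: 0.0 for m in nodes})
            assert len(cover) == exhaustive_min_cover_size(nodes, edges)
            assert all(a in cover or b in cover for a, b in edges)


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 4), (17, 131054)])
    def test_counts(self, n, expected):
        assert enumerate_combinations(n).count == expected

    def test_count_matches_binomial_sum(self):
        for n in range(2, 21):
            assert enumerate_combinations(n).count == sum(comb(n, j) for j in range(2, n + 1))

    def test_iterator_is_exhaustive_and_deterministic(self):
        enum = enumerate_combinations(5)
        subsets = list(enum.subsets())
        assert len(subsets) == enum.count
        assert len(set(subsets)) == len(subsets)
        assert subsets == list(enumerate_combinations(5).subsets())

    def test_domain_error(self):
        with pytest.raises(ValueError):
            enumerate_combinations(1)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes,expected",
        [((1, 1, 0), 1), ((1, 0), 1), ((0, 0, 0, 1), 0), ((0, 1, 0, 1), 1)],
    )
    def test_at_least_half_rule(self, votes, expected):
        assert majority_vote(np.array([votes]))[0] == expected

    def test_tie_flag_flips_even_splits(self):
        assert majority_vote(np.array([[1, 0]]), tie_to_responder=False)[0] == 0

    def test_missing_vote_errors(self):
        with pytest.raises(MissingVoteError):
            majority_vote(np.array([[1.0, np.nan]]))

    def test_identical_copies_vote_like_single_marker(self):
        rng = np.random.default_rng(12)
        calls = rng.integers(0, 2, size=30)
        for k in (2, 3, 5):
            stacked = np.tile(calls[:, None], (1, k))
            np.testing.assert_array_equal(majority_vote(stacked), calls)

    def test_always_responder_marker_never_decreases_sensitivity(self):
        rng = np.random.default_rng(13)
        y = rng.random(40) < 0.5
        calls = pd.DataFrame(rng.integers(0, 2, size=(40, 3)), columns=["a", "b", "c"])
        base = evaluate_combination(["a", "b", "c"], calls, y)
        calls["ones"] = 1
        boosted = evaluate_combination(["a", "b", "c", "ones"], calls, y)
        assert boosted.sensitivity >= base.sensitivity


class TestEvaluateCombination:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 0], dtype=bool)
        calls = pd.DataFrame({"a": [1, 1, 0, 0], "b": [1, 1, 0, 0]})
        rec = evaluate_combination(["a", "b"], calls, y)
        assert (rec.sensitivity, rec.specificity, rec.auc) == (1.0, 1.0, 1.0)

    def test_all_responder_predictions(self):
        y = np.array([1, 0, 1, 0], dtype=bool)
        calls = pd.DataFrame({"a": [1] * 4, "b": [1] * 4})
        rec = evaluate_combination(["a", "b"], calls, y)
        assert (rec.sensitivity, rec.specificity, rec.auc) == (1.0, 0.0, 0.5)

    def test_hand_tallied_confusion_matrix(self):
        y = np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0], dtype=bool)
        calls = pd.DataFrame(
            {
                "a": [1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0],
                "b": [1, 0, 1, 1, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0, 1, 0, 1, 0, 0, 1],
                "c": [0, 1, 1, 1, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 1, 0, 1, 0],
            }
        )
        # hand tally of the 2-of-3 vote:
        # predictions: 1,1,1,1,0,1,1,0,0,1,0,0,0,0,0,0,1,0,0,0
        rec = evaluate_combination(["a", "b", "c"], calls, y)
        assert (rec.tp, rec.fp, rec.tn, rec.fn) == (7, 1, 9, 3)
        assert rec.tp + rec.fp + rec.tn + rec.fn == 20
        assert rec.sensitivity == pytest.approx(0.7)
        assert rec.specificity == pytest.approx(0.9)
        assert rec.auc == pytest.approx(0.8)

    def test_single_class_errors(self):
        calls = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(DegenerateLabelsError):
            evaluate_combination(["a", "b"], calls, np.array([True, True]))


class TestSearch:
    def test_batch_search_matches_per_subset_evaluation(self):
        rng = np.random.default_rng(30)
        y = rng.random(25) < 0.5
        calls = pd.DataFrame(
            rng.integers(0, 2, size=(25, 6)), columns=[f"m{i}" for i in range(6)]
        )
        table = search_combinations(calls, y)
        assert len(table) == enumerate_combinations(6).count
        for _, row in table.sample(20, random_state=0).iterrows():
            rec = evaluate_combination(list(row["subset"]), calls, y)
            assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (rec.tp, rec.fp, rec.tn, rec.fn)
            assert row["auc"] == pytest.approx(rec.auc)

    def test_sorted_by_auc_then_size(self):
        rng = np.random.default_rng(31)
        y = rng.random(20) < 0.5
        calls = pd.DataFrame(rng.integers(0, 2, size=(20, 4)), columns=list("abcd"))
        table = search_combinations(calls, y)
        aucs = table["auc"].to_numpy()
        assert (np.diff(aucs) <= 1e-12).all()


class TestFrequencyReport:
    def test_all_records_acceptable(self):
        records = pd.DataFrame(
            {"subset": [("a", "b"), ("a", "c"), ("b", "c"), ("a", "b", "c")], "auc": [0.9] * 4}
        )
        report = frequency_report(records, auc_floor=0.65)
        assert report.acceptable_fraction == 1.0
        assert report.frequency["a"] == pytest.approx(3 / 4)

    def test_unreachable_floor(self):
        records = pd.DataFrame({"subset": [("a", "b")], "auc": [0.99]})
        with pytest.warns(UserWarning):
            report = frequency_report(records, auc_floor=1.01)
        assert report.acceptable_fraction == 0.0
        assert report.frequency == {}

    def test_strong_markers_rank_top_in_simulated_search(self):
        """Informative markers dominate the acceptable combinations."""
        rng = np.random.default_rng(33)
        n = 600
        y = rng.random(n) < 0.5
        strong = {f"s{i}": (rng.random(n) < np.where(y, 0.85, 0.15)).astype(int) for i in range(3)}
        null = {f"n{i}": rng.integers(0, 2, size=n) for i in range(14)}
        calls = pd.DataFrame({**strong, **null})
        table = search_combinations(calls, y)
        report = frequency_report(table, auc_floor=0.65)
        assert 0 < report.acceptable_fraction < 1
        top3 = list(report.frequency)[:3]
        assert set(top3) == {"s0", "s1", "s2"}
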