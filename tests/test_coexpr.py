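"""Screening-cascade checks against hand evaluations and brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from shorescan.coexpr import (
    Cohort,
    CohortCollection,
    collapse_probes,
    consensus_genes,
    correlate_seed_gene,
    differential_expression_filter,
    intersect_histologies,
    run_signature_pipeline,
)


def exact_mannwhitney_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (no ties).

    Enumerates every assignment of the pooled values to the two groups and
    measures how extreme the observed U is relative to the symmetric null.
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    center = n1 * len(y) / 2

    def u_stat(group):
        rest = [v for v in pooled if v not in group]
        return sum(1 for a in group for b in rest if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    count = total = 0
    for combo in itertools.combinations(pooled, n1):
        total += 1
        if abs(u_stat(combo) - center) >= abs(u_obs - center):
            count += 1
    return count / total


def _matrix(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows, dtype=float).T


class TestCorrelateSeedGene:
    def test_identical_gene_has_r_one(self):
        m = _matrix({"SEED": [1, 2, 3, 5], "twin": [1, 2, 3, 5], "noise": [4, 1, 3, 2]})
        table = correlate_seed_gene(m, "SEED")
        assert table.loc["twin", "r"] == pytest.approx(1.0)

    def test_hand_evaluated_four_point_example(self):
        m = _matrix({"SEED": [1, 2, 3, 4], "g": [1, 3, 2, 4]})
        assert correlate_seed_gene(m, "SEED").loc["g", "r"] == pytest.approx(0.8, abs=1e-12)

    def test_constant_gene_is_flagged_not_adjusted(self):
        m = _matrix({"SEED": [1, 2, 3, 4], "flat": [5, 5, 5, 5], "g": [2, 1, 4, 3]})
        table = correlate_seed_gene(m, "SEED")
        assert not table.loc["flat", "tested"]
        assert np.isnan(table.loc["flat", "p"]) and np.isnan(table.loc["flat", "q"])
        assert table.loc["g", "tested"]

    def test_missing_seed_and_tiny_n_raise(self):
        m = _matrix({"SEED": [1, 2], "g": [2, 1]})
        with pytest.raises(ValueError, match="3 samples"):
            correlate_seed_gene(m, "SEED")
        with pytest.raises(KeyError, match="absent"):
            correlate_seed_gene(_matrix({"g": [1, 2, 3]}), "SEED")

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame(rng.normal(size=(20, 12)), index=[f"g{i}" for i in range(20)])
        m.loc["SEED"] = rng.normal(size=12)
        table = correlate_seed_gene(m, "SEED")
        from scipy import stats

        for g in (x for x in m.index if x != "SEED"):
            r_ref, p_ref = stats.pearsonr(m.loc[g], m.loc["SEED"])
            assert table.loc[g, "r"] == pytest.approx(r_ref, abs=1e-12)
            assert table.loc[g, "p"] == pytest.approx(p_ref, rel=1e-9)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(5, 15)), index=[f"g{i}" for i in range(4)] + ["SEED"])
        t1 = correlate_seed_gene(m, "SEED", method="spearman")
        t2 = correlate_seed_gene(np.exp(m), "SEED", method="spearman")
        pd.testing.assert_frame_equal(t1, t2)

    def test_sample_permutation_leaves_output_unchanged(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(6, 10)), index=[f"g{i}" for i in range(5)] + ["SEED"])
        perm = rng.permutation(m.columns)
        pd.testing.assert_frame_equal(
            correlate_seed_gene(m, "SEED"), correlate_seed_gene(m[perm], "SEED")
        )


class TestConsensus:
    @staticmethod
    def _table(genes, rs, qs):
        return pd.DataFrame({"r": rs, "q": qs, "tested": True}, index=genes)

    def test_all_pass_and_one_fail(self):
        t1 = self._table(["a", "b"], [0.5, 0.4], [0.01, 0.01])
        t2 = self._table(["a", "b"], [0.6, 0.3], [0.02, 0.20])
        genes, ev = consensus_genes({"c1": t1, "c2": t2}, alpha=0.05)
        assert genes == ["a"]
        assert not ev.loc["b", "included"]

    def test_sign_consistency_required(self):
        t1 = self._table(["a"], [0.5], [0.01])
        t2 = self._table(["a"], [-0.5], [0.01])
        assert consensus_genes({"c1": t1, "c2": t2}, require_sign="positive")[0] == []
        assert consensus_genes({"c1": t1, "c2": t2}, require_sign="any")[0] == []
        assert consensus_genes({"c1": t1, "c2": t1}, require_sign="any")[0] == ["a"]

    def test_empty_table_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            consensus_genes({})


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ({"a", "b", "c"}, {"b", "c", "d"}, ["b", "c"]),
        ({"a"}, {"b"}, []),
        ({"a", "b"}, {"a", "b", "c"}, ["a", "b"]),
    ],
)
def test_intersect_histologies(a, b, expected):
    assert intersect_histologies(a, b) == expected


class TestDifferentialExpression:
    def test_exact_three_vs_three_p(self):
        m = _matrix({"g1": [1, 2, 3, 4, 5, 6]})
        groups = pd.Series(["tumor"] * 3 + ["normal"] * 3, index=m.columns)
        kept, table = differential_expression_filter(m, groups, ["g1"])
        assert table.loc["g1", "p"] == pytest.approx(0.1, abs=1e-12)
        assert table.loc["g1", "p"] == pytest.approx(exact_mannwhitney_p([1, 2, 3], [4, 5, 6]), abs=1e-12)
        assert kept == []  # p = 0.1 > alpha
        assert table.loc["g1", "direction"] == "down"

    def test_identical_groups_dropped(self):
        m = _matrix({"g1": [2, 2, 2, 2, 2, 2]})
        groups = pd.Series(["tumor"] * 3 + ["normal"] * 3, index=m.columns)
        kept, table = differential_expression_filter(m, groups, ["g1"])
        assert table.loc["g1", "p"] == 1.0 and kept == []

    def test_small_group_raises(self):
        m = _matrix({"g1": [1, 2, 3]})
        groups = pd.Series(["tumor", "normal", "normal"], index=m.columns)
        with pytest.raises(ValueError, match="2 samples"):
            differential_expression_filter(m, groups, ["g1"])

    @pytest.mark.parametrize("n1,n2", [(3, 4), (4, 4), (5, 3)])
    def test_matches_enumeration_oracle_without_ties(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.permutation(n1 + n2)[:n1] + rng.random(n1) * 0.01
        y = rng.permutation(n1 + n2)[:n2] + rng.random(n2) * 0.01 + 10 * rng.integers(0, 2)
        m = pd.DataFrame([np.concatenate([x, y])], index=["g"], dtype=float)
        m.columns = [f"s{i}" for i in range(n1 + n2)]
        groups = pd.Series(["tumor"] * n1 + ["normal"] * n2, index=m.columns)
        _, table = differential_expression_filter(m, groups, ["g"])
        assert table.loc["g", "p"] == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-12)


def test_collapse_probes_keeps_max_variance():
    expr = pd.DataFrame(
        [[1, 1, 1.1], [0, 5, 10], [2, 2, 2]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3"],
        dtype=float,
    )
    mapping = pd.Series({"p1": "A", "p2": "A", "p3": "B"})
    collapsed, dropped = collapse_probes(expr, mapping)
    assert dropped == 1
    assert collapsed.loc["A"].tolist() == [0, 5, 10]


class TestSignaturePipeline:
    @staticmethod
    def _collection(rng, planted=True, histologies=("h1", "h2"), n=120):
        genes = ["SEED"] + [f"M{i}" for i in range(5)] + [f"G{i}" for i in range(40)]
        cohorts = []
        for hist in histologies:
            factor = rng.standard_normal(n)
            X = rng.standard_normal((len(genes), n))
            if planted:
                X[:6] = 0.8 * factor + 0.6 * X[:6]
            X[:6, : n // 2] += 1.5 * planted
            cols = [f"{hist}s{i}" for i in range(n)]
            groups = pd.Series(["tumor"] * (n // 2) + ["normal"] * (n // 2), index=cols)
            cohorts.append(Cohort(hist + "_c", hist, pd.DataFrame(X, index=genes, columns=cols), groups))
        return CohortCollection(cohorts)

    def test_monotone_filtering_and_recovery(self):
        rng = np.random.default_rng(3)
        result = run_signature_pipeline(self._collection(rng), "SEED")
        for hist, genes in result.per_histology.items():
            assert set(result.common) <= set(genes)
        assert set(result.de_filtered) <= set(result.common)
        assert set(result.de_filtered) >= {f"M{i}" for i in range(5)}

    def test_single_cohort_per_histology_reduces_to_its_significant_set(self):
        rng = np.random.default_rng(4)
        collection = self._collection(rng, histologies=("only",))
        result = run_signature_pipeline(collection, "SEED")
        assert result.common == result.per_histology["only"]

    def test_stage_error_carries_stage_name(self):
        rng = np.random.default_rng(5)
        with pytest.raises(RuntimeError, match="stage correlate"):
            run_signature_pipeline(self._collection(rng), "NOT_A_GENE")

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        collection = self._collection(rng)
        shuffled = CohortCollection(
            [
                Cohort(c.name, c.histology, c.expression.iloc[:, ::-1], c.groups.iloc[::-1])
                for c in collection.cohorts
            ]
        )
        a = run_signature_pipeline(collection, "SEED")
        b = run_signature_pipeline(shuffled, "SEED")
        assert a.de_filtered == b.de_filtered and a.per_histology == b.per_histology
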