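"""Methylation-layer checks: map parsing, profiles, the cumulative curve,
per-CpG testing, region calling, classification and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from shorescan.methyl import (
    BetaMatrix,
    CpGMap,
    classify_methylation,
    cluster_samples,
    cumulative_difference,
    detect_consistent_region,
    group_mean_profile,
    load_cpg_map,
    per_cpg_test,
    write_cpg_map,
)
from conftest import make_beta


def _bed_text(rows):
    head = "chrom\tstart\tend\tprobe_id\tregion\n"
    return head + "\n".join("\t".join(map(str, r)) for r in rows) + "\n"


class TestCpGMapIO:
    def test_well_formed_file(self, tmp_path):
        f = tmp_path / "map.tsv"
        f.write_text(_bed_text([
            ("chr1", 100, 101, "cg00000001", "north_shore"),
            ("chr1", 200, 201, "cg00000002", "island"),
            ("chr1", 300, 301, "cg00000003", "south_shore"),
        ]))
        m = load_cpg_map(f)
        assert m.probe_ids == ["cg00000001", "cg00000002", "cg00000003"]

    def test_shuffled_rows_normalize_to_position_order(self, tmp_path):
        rows = [
            ("chr1", 300, 301, "cg00000003", "south_shore"),
            ("chr1", 100, 101, "cg00000001", "north_shore"),
            ("chr1", 200, 201, "cg00000002", "island"),
        ]
        f = tmp_path / "map.tsv"
        f.write_text(_bed_text(rows))
        assert load_cpg_map(f).probe_ids == ["cg00000001", "cg00000002", "cg00000003"]

    def test_duplicate_probe_id_is_named_in_error(self, tmp_path):
        f = tmp_path / "map.tsv"
        f.write_text(_bed_text([
            ("chr1", 100, 101, "cg00000001", "island"),
            ("chr1", 200, 201, "cg00000001", "island"),
        ]))
        with pytest.raises(ValueError, match="cg00000001"):
            load_cpg_map(f)

    def test_unknown_region_and_bad_order_raise(self, tmp_path):
        f = tmp_path / "map.tsv"
        f.write_text(_bed_text([("chr1", 100, 101, "cg1", "enhancer")]))
        with pytest.raises(ValueError, match="unknown region"):
            load_cpg_map(f)
        g = tmp_path / "map2.tsv"
        g.write_text(_bed_text([
            ("chr1", 100, 101, "cg1", "island"),
            ("chr1", 200, 201, "cg2", "north_shore"),
        ]))
        with pytest.raises(ValueError, match="north_shore"):
            load_cpg_map(g)

    def test_round_trip(self, tmp_path, toy_map):
        write_cpg_map(toy_map, tmp_path / "m.tsv")
        assert load_cpg_map(tmp_path / "m.tsv").probe_ids == toy_map.probe_ids


class TestGroupMeanProfile:
    def test_constant_half_gives_fifty_percent(self, toy_map):
        beta = make_beta(np.full((6, 4), 0.5), {"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"},
                         probe_ids=toy_map.probe_ids)
        prof = group_mean_profile(beta, toy_map)
        assert (prof["mean_pct_normal"] == 50).all() and (prof["mean_pct_tumor"] == 50).all()

    def test_two_by_two_toy_arithmetic(self, toy_map):
        vals = np.tile([[0.6, 0.8, 0.2, 0.4]], (6, 1))
        beta = make_beta(vals, {"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"},
                         probe_ids=toy_map.probe_ids)
        prof = group_mean_profile(beta, toy_map)
        assert prof["mean_pct_normal"].iloc[0] == pytest.approx(30)
        assert prof["mean_pct_tumor"].iloc[0] == pytest.approx(70)

    def test_column_permutation_invariance(self, toy_map):
        rng = np.random.default_rng(0)
        vals = rng.random((6, 8))
        groups = {f"s{i}": ("tumor" if i < 4 else "normal") for i in range(8)}
        beta = make_beta(vals, groups, probe_ids=toy_map.probe_ids)
        perm = rng.permutation(beta.values.columns)
        beta2 = BetaMatrix(beta.values[perm], beta.groups[perm])
        pd.testing.assert_frame_equal(group_mean_profile(beta, toy_map), group_mean_profile(beta2, toy_map))

    def test_low_coverage_probe_excluded(self, toy_map):
        vals = np.full((6, 4), 0.5)
        beta_df = pd.DataFrame(vals, index=toy_map.probe_ids, columns=["t1", "t2", "n1", "n2"])
        beta_df.iloc[0, :2] = np.nan  # tumor coverage 0 at first probe
        beta = BetaMatrix(beta_df, pd.Series(["tumor", "tumor", "normal", "normal"],
                                             index=beta_df.columns))
        prof = group_mean_profile(beta, toy_map)
        assert toy_map.probe_ids[0] in prof.attrs["excluded"]
        assert len(prof) == 5


class TestCumulativeDifference:
    def test_hand_prefix_sum(self):
        frame = pd.DataFrame(
            {"chrom": "chr1", "pos": range(5), "region": ["north_shore"] * 5},
            index=pd.Index([f"cg{i}" for i in range(5)]),
        )
        cmap = CpGMap(frame)
        prof = pd.DataFrame(
            {"mean_pct_normal": [60, 55, 10, 10, 58], "mean_pct_tumor": [40, 35, 10, 10, 48]},
            index=cmap.probe_ids, dtype=float,
        )
        cum = cumulative_difference(prof, cmap)
        assert cum["delta"].tolist() == [20, 20, 0, 0, 10]
        assert cum["cumulative"].tolist() == [20, 40, 40, 40, 50]

    def test_identical_groups_are_flat(self, toy_map):
        prof = pd.DataFrame(
            {"mean_pct_normal": np.full(6, 33.0), "mean_pct_tumor": np.full(6, 33.0)},
            index=toy_map.probe_ids,
        )
        cum = cumulative_difference(prof, toy_map)
        assert (cum["delta"] == 0).all() and (cum["cumulative"] == 0).all()

    def test_reversal_conserves_total(self):
        rng = np.random.default_rng(1)
        n, ids = 8, [f"cg{i}" for i in range(8)]
        fwd = CpGMap(pd.DataFrame({"chrom": "chr1", "pos": range(n), "region": ["island"] * n}, index=ids))
        rev = CpGMap(pd.DataFrame({"chrom": "chr1", "pos": range(n), "region": ["island"] * n},
                                  index=ids[::-1]))
        normal, tumor = rng.random(n) * 100, rng.random(n) * 100
        prof_f = pd.DataFrame({"mean_pct_normal": normal, "mean_pct_tumor": tumor}, index=ids)
        prof_r = pd.DataFrame({"mean_pct_normal": normal[::-1], "mean_pct_tumor": tumor[::-1]},
                              index=ids[::-1])
        total_f = cumulative_difference(prof_f, fwd)["cumulative"].iloc[-1]
        total_r = cumulative_difference(prof_r, rev)["cumulative"].iloc[-1]
        assert total_f == pytest.approx(total_r)

    def test_order_mismatch_raises(self, toy_map):
        prof = pd.DataFrame(
            {"mean_pct_normal": np.zeros(6), "mean_pct_tumor": np.zeros(6)},
            index=toy_map.probe_ids[::-1],
        )
        with pytest.raises(ValueError, match="order"):
            cumulative_difference(prof, toy_map)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=1, max_size=30))
    def test_prefix_sum_property(self, pairs):
        ids = [f"cg{i}" for i in range(len(pairs))]
        cmap = CpGMap(pd.DataFrame(
            {"chrom": "chr1", "pos": range(len(pairs)), "region": ["island"] * len(pairs)}, index=ids))
        prof = pd.DataFrame(
            {"mean_pct_normal": [a for a, _ in pairs], "mean_pct_tumor": [b for _, b in pairs]},
            index=ids,
        )
        cum = cumulative_difference(prof, cmap)
        np.testing.assert_allclose(np.diff(cum["cumulative"]), cum["delta"].iloc[1:], atol=1e-9)
        assert cum["cumulative"].iloc[0] == cum["delta"].iloc[0]
        assert cum["cumulative"].iloc[-1] == pytest.approx(cum["delta"].sum())


class TestPerCpGTest:
    def test_identical_groups_p_one(self):
        beta = make_beta([[0.1, 0.2, 0.3, 0.1, 0.2, 0.3]],
                         ["tumor"] * 3 + ["normal"] * 3)
        assert per_cpg_test(beta)["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_three_vs_three(self):
        beta = make_beta([[0.1, 0.2, 0.3, 0.6, 0.7, 0.8]], ["tumor"] * 3 + ["normal"] * 3)
        assert per_cpg_test(beta)["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_group_flagged_untested(self):
        vals = pd.DataFrame([[0.1, 0.2, 0.3, np.nan, np.nan, 0.8]],
                            index=["cg1"], columns=[f"s{i}" for i in range(6)])
        beta = BetaMatrix(vals, pd.Series(["tumor"] * 3 + ["normal"] * 3, index=vals.columns))
        out = per_cpg_test(beta)
        assert not out["tested"].iloc[0] and np.isnan(out["p"].iloc[0])


class TestRegionCalling:
    @staticmethod
    def _inputs(delta, q):
        ids = [f"cg{i}" for i in range(len(delta))]
        cmap = CpGMap(pd.DataFrame(
            {"chrom": "chr1", "pos": range(len(delta)), "region": ["north_shore"] * len(delta)},
            index=ids))
        cum = pd.DataFrame({"delta": delta, "cumulative": np.cumsum(delta)}, index=ids)
        return cum, pd.Series(q, index=ids), cmap

    def test_null_data_gives_no_calls(self):
        cum, q, cmap = self._inputs([0.0] * 10, [1.0] * 10)
        assert detect_consistent_region(cum, q, cmap) == []

    def test_single_failing_probe_splits_runs(self):
        delta = [20] * 5 + [0] + [20] * 5
        q = [0.01] * 11
        cum, qs, cmap = self._inputs(delta, q)
        calls = detect_consistent_region(cum, qs, cmap)
        assert [(c.start_index, c.end_index) for c in calls] == [(0, 4), (6, 10)]

    def test_short_runs_are_dropped_and_min_run_validated(self):
        cum, q, cmap = self._inputs([20] * 4 + [0] * 6, [0.01] * 10)
        assert detect_consistent_region(cum, q, cmap, min_run=5) == []
        assert len(detect_consistent_region(cum, q, cmap, min_run=4)) == 1
        with pytest.raises(ValueError, match="min_run"):
            detect_consistent_region(cum, q, cmap, min_run=0)

    def test_calls_invariant_to_probes_outside_span(self):
        delta = [1.0] * 3 + [20.0] * 5 + [1.0] * 3
        q = [0.9] * 3 + [0.001] * 5 + [0.9] * 3
        cum, qs, cmap = self._inputs(delta, q)
        inner = detect_consistent_region(cum, qs, cmap)
        delta2, q2 = [0.0, 0.0] + delta, [1.0, 1.0] + q
        ids2 = [f"fl{i}" for i in range(2)] + list(cum.index)
        cmap2 = CpGMap(pd.DataFrame(
            {"chrom": "chr1", "pos": range(len(ids2)), "region": ["north_shore"] * len(ids2)},
            index=ids2))
        cum2 = pd.DataFrame({"delta": delta2, "cumulative": np.cumsum(delta2)}, index=ids2)
        outer = detect_consistent_region(cum2, pd.Series(q2, index=ids2), cmap2)
        assert [c.probe_ids for c in inner] == [c.probe_ids for c in outer]


class TestClassification:
    @pytest.mark.parametrize("beta,expected", [(0.6, "methylated"), (0.2, "unmethylated"),
                                               (0.5, "methylated")])
    def test_threshold_convention(self, beta, expected):
        assert classify_methylation(beta) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            classify_methylation(1.2)


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        beta = make_beta(np.tile([[0.3], [0.7]], (1, 2)), ["tumor", "tumor"])
        res = cluster_samples(beta)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_planted_clusters_recovered(self):
        rng = np.random.default_rng(0)
        a = 0.2 + 0.02 * rng.standard_normal((20, 10))
        b = 0.8 + 0.02 * rng.standard_normal((20, 10))
        beta = make_beta(np.hstack([a, b]), ["tumor"] * 20)
        res = cluster_samples(beta)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, res.cut(2)) == 1.0

    def test_star_dendrogram_for_duplicated_sample(self):
        beta = make_beta(np.tile([[0.4], [0.6]], (1, 5)), ["tumor"] * 5)
        res = cluster_samples(beta)
        assert np.allclose(res.linkage[:, 2], 0.0)

    def test_all_missing_sample_raises(self):
        vals = pd.DataFrame([[0.5, np.nan], [0.5, np.nan]], index=["cg1", "cg2"],
                            columns=["s1", "s2"])
        beta = BetaMatrix(vals, pd.Series(["tumor", "normal"], index=vals.columns))
        with pytest.raises(ValueError, match="no observed"):
            cluster_samples(beta)
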