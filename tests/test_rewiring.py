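"""Network overlap, rewiring types, D(z) scoring, DC selection, loop ranking."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regrewire.rewiring import (
    classify_rewiring,
    compare_overlap_across_cohorts,
    dc_select,
    dz,
    overlap_stats,
    rank_bitm_across_cohorts,
)

from conftest import make_network, make_records


class TestOverlap:
    def test_set_arithmetic_by_hand(self):
        net_n = make_network([("A", "B", "TFout", 3.0), ("A", "C", "TFout", 3.0)], "normal")
        net_t = make_network([("A", "B", "TFout", 3.0), ("B", "D", "TFout", 3.0)], "tumor")
        ov = overlap_stats(net_n, net_t)
        assert ov.jaccard_interactions == pytest.approx(1 / 3)
        assert ov.jaccard_interactors == pytest.approx(0.5)  # {A,B} of {A,B,C,D}

    def test_identical_networks(self):
        net = make_network([("A", "B", "TFout", 3.0)])
        ov = overlap_stats(net, net)
        assert ov.jaccard_interactions == 1.0 and ov.jaccard_interactors == 1.0

    def test_disjoint_networks(self):
        ov = overlap_stats(
            make_network([("A", "B", "TFout", 3.0)]),
            make_network([("C", "D", "TFout", 3.0)]),
        )
        assert ov.jaccard_interactions == 0.0 and ov.jaccard_interactors == 0.0

    def test_both_empty_warns_and_reports_zero(self):
        empty = make_network([])
        with pytest.warns(UserWarning):
            ov = overlap_stats(empty, empty)
        assert ov.jaccard_interactors == 0.0


class TestRankSumComparison:
    def test_complete_separation_exact(self):
        p = compare_overlap_across_cohorts([0.9, 0.9, 0.9], [0.1, 0.1, 0.1])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples(self):
        assert compare_overlap_across_cohorts([0.5, 0.5], [0.5, 0.5]) == 1.0

    def test_exact_matches_scipy_enumeration_for_4_plus_4(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.random(4)
            y = rng.random(4)
            ours = compare_overlap_across_cohorts(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            compare_overlap_across_cohorts([], [0.5])


class TestRewiringTypes:
    def test_type_i_retains_both_endpoints(self):
        net_n = make_network(
            [("A", "B", "TFout", 3.0), ("A", "C", "TFout", 3.0), ("D", "B", "TFout", 3.0)],
            "normal",
        )
        net_t = make_network([("A", "C", "TFout", 3.0), ("D", "B", "TFout", 3.0)], "tumor")
        table = classify_rewiring(net_n, net_t)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["edge_key"], row["direction"], row["type"]) == ("A>B", "lost", "I")

    def test_type_ii_one_endpoint_kept(self):
        table = classify_rewiring(
            make_network([("A", "B", "TFout", 3.0)], "normal"),
            make_network([("A", "C", "TFout", 3.0)], "tumor"),
        )
        by_key = table.set_index("edge_key")
        assert by_key.loc["A>B", "type"] == "II"
        assert by_key.loc["A>C", "type"] == "II"

    def test_type_iii_disjoint_nodes(self):
        table = classify_rewiring(
            make_network([("A", "B", "TFout", 3.0)], "normal"),
            make_network([("C", "D", "TFout", 3.0)], "tumor"),
        )
        assert set(table["type"]) == {"III"}
        assert set(table["direction"]) == {"lost", "gained"}

    def _random_pair(self, rng):
        pool = [(f"n{i}", f"n{j}") for i, j in combinations(range(8), 2)]
        rows_n = [(a, b, "TFout", 3.0) for a, b in rng.permutation(pool)[:6]]
        rows_t = [(a, b, "TFout", 3.0) for a, b in rng.permutation(pool)[:6]]
        return make_network(rows_n, "normal"), make_network(rows_t, "tumor")

    def test_conservation_over_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            net_n, net_t = self._random_pair(rng)
            table = classify_rewiring(net_n, net_t)
            sym_diff = net_n.edge_keys ^ net_t.edge_keys
            assert len(table) == len(sym_diff)
            assert set(table["edge_key"]) == sym_diff

    def test_symmetry_under_condition_swap(self):
        rng = np.random.default_rng(9)
        net_n, net_t = self._random_pair(rng)
        fwd = classify_rewiring(net_n, net_t).set_index("edge_key")
        rev = classify_rewiring(net_t, net_n).set_index("edge_key")
        assert set(fwd.index) == set(rev.index)
        for key in fwd.index:
            assert fwd.loc[key, "type"] == rev.loc[key, "type"]
            assert {fwd.loc[key, "direction"], rev.loc[key, "direction"]} <= {"gained", "lost"}
            assert fwd.loc[key, "direction"] != rev.loc[key, "direction"]


class TestDz:
    def _records(self, z_n, z_t):
        return (
            make_records([("TF1", "mir1", "BiTM", z_n)], condition="normal"),
            make_records([("TF1", "mir1", "BiTM", z_t)], condition="tumor"),
        )

    @pytest.mark.parametrize(
        "z_n, z_t, expected_d",
        [(2.85, 2.85, 0.0), (2.85, -2.85, 5.70), (0.5, 3.0, 2.5)],
    )
    def test_d_arithmetic(self, z_n, z_t, expected_d):
        records, omitted = dz(*self._records(z_n, z_t))
        assert len(records) == 1 and len(omitted) == 0
        assert records.iloc[0]["D"] == pytest.approx(expected_d)

    def test_insignificant_in_both_conditions_omitted(self):
        records, omitted = dz(*self._records(0.5, 1.0))
        assert len(records) == 0
        assert omitted.iloc[0]["reason"] == "not_significant"

    def test_missing_condition_omitted(self):
        recs_n = make_records([("TF1", "mir1", "BiTM", 3.0)], condition="normal")
        recs_t = make_records([("TF2", "mir2", "BiTM", 3.0)], condition="tumor")
        records, omitted = dz(recs_n, recs_t)
        assert len(records) == 0
        assert set(omitted["reason"]) == {"missing_condition"}

    def test_d_invariant_under_condition_exchange(self):
        rng = np.random.default_rng(5)
        rows = [("TF1", f"g{i}", "TFout", float(z)) for i, z in enumerate(rng.normal(3, 1, 20))]
        rows_t = [("TF1", f"g{i}", "TFout", float(z)) for i, z in enumerate(rng.normal(0, 2, 20))]
        a, _ = dz(make_records(rows, condition="normal"), make_records(rows_t, condition="tumor"))
        b, _ = dz(make_records(rows_t, condition="normal"), make_records(rows, condition="tumor"))
        merged = a.merge(b, on="edge_key", suffixes=("_a", "_b"))
        assert np.allclose(merged["D_a"], merged["D_b"])
        assert (a["D"] >= 0).all()


class TestDcSelect:
    @pytest.mark.parametrize("n_records, expected", [(20, 2), (25, 3)])
    def test_ceiling_rule(self, n_records, expected):
        rows = [("TF1", f"g{i:03d}", "TFout", 3.0 + 0.1 * i) for i in range(n_records)]
        recs, _ = dz(
            make_records(rows, condition="normal"),
            make_records([(r, t, c, 0.0) for r, t, c, _ in rows], condition="tumor"),
        )
        flagged = dc_select(recs, 0.10)
        assert int(flagged["dc_flag"].sum()) == expected

    def test_all_equal_d_uses_pair_key_order(self):
        rows = [("TF1", f"g{i:03d}", "TFout", 3.0) for i in range(10)]
        recs, _ = dz(
            make_records(rows, condition="normal"),
            make_records([(r, t, c, 0.0) for r, t, c, _ in rows], condition="tumor"),
        )
        flagged = dc_select(recs, 0.10)
        assert int(flagged["dc_flag"].sum()) == 1
        assert flagged.loc[flagged["dc_flag"], "target_id"].iloc[0] == "g000"

    def test_empty_input(self):
        recs, _ = dz(make_records([]), make_records([]))
        assert dc_select(recs).empty


class TestBitmRanking:
    def _per_cohort(self, d_map):
        out = {}
        for cohort, pair_d in d_map.items():
            rows_n = [(tf, mir, "BiTM", 3.0 + d) for (tf, mir), d in pair_d.items()]
            rows_t = [(tf, mir, "BiTM", 3.0) for (tf, mir), _ in pair_d.items()]
            recs, _ = dz(
                make_records(rows_n, condition="normal"),
                make_records(rows_t, condition="tumor"),
            )
            out[cohort] = recs
        return out

    def test_mean_d_ordering(self):
        pairs = {("TF1", "mir1"): None, ("TF2", "mir2"): None}
        d_map = {
            "c1": {("TF1", "mir1"): 5.0, ("TF2", "mir2"): 1.0},
            "c2": {("TF1", "mir1"): 5.0, ("TF2", "mir2"): 1.0},
            "c3": {("TF1", "mir1"): 5.0, ("TF2", "mir2"): 9.0},
        }
        ranking, partial = rank_bitm_across_cohorts(self._per_cohort(d_map))
        assert len(partial) == 0
        assert ranking.iloc[0]["pair_key"] == "TF1|mir1"  # mean 5 > 11/3
        assert ranking.iloc[0]["mean_D"] == pytest.approx(5.0)

    def test_single_cohort_degenerates_to_d_order(self):
        d_map = {"c1": {("TF1", "mir1"): 2.0, ("TF2", "mir2"): 7.0}}
        ranking, _ = rank_bitm_across_cohorts(self._per_cohort(d_map))
        assert ranking.iloc[0]["pair_key"] == "TF2|mir2"

    def test_partial_coverage_reported_not_ranked(self):
        d_map = {
            "c1": {("TF1", "mir1"): 5.0, ("TF2", "mir2"): 1.0},
            "c2": {("TF1", "mir1"): 5.0},
        }
        ranking, partial = rank_bitm_across_cohorts(self._per_cohort(d_map))
        assert list(ranking["pair_key"]) == ["TF1|mir1"]
        assert list(partial["pair_key"]) == ["TF2|mir2"]

    def test_no_common_pair_warns(self):
        d_map = {"c1": {("TF1", "mir1"): 5.0}, "c2": {("TF2", "mir2"): 5.0}}
        with pytest.warns(UserWarning):
            ranking, partial = rank_bitm_across_cohorts(self._per_cohort(d_map))
        assert ranking.empty and len(partial) == 2
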