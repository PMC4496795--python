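"""Exact 2x2 tests, association categories, gene-set enrichment, combined p, DE."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from regrewire.enrichment import (
    cancer_assoc_enrichment,
    de_test,
    fisher_combined,
    fisher_exact,
    geneset_enrichment,
    read_gmt,
    regulator_module,
    write_gmt,
)

from conftest import make_records


def enumerate_fisher(a, b, c, d, alternative):
    """Independent oracle: hypergeometric enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_p(k):
        return (
            gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
            + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    ks = [k for k in range(max(0, c1 - r2), min(r1, c1) + 1)]
    probs = {k: math.exp(log_p(k)) for k in ks}
    if alternative == "greater":
        return sum(p for k, p in probs.items() if k >= a)
    if alternative == "less":
        return sum(p for k, p in probs.items() if k <= a)
    cutoff = probs[a] * (1 + 1e-9)
    return sum(p for p in probs.values() if p <= cutoff)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, alternative, expected",
        [
            ([[3, 1], [1, 3]], "greater", 17 / 70),
            ([[5, 0], [0, 5]], "greater", 1 / 252),
            ([[0, 5], [5, 0]], "greater", 1.0),
        ],
    )
    def test_worked_examples(self, table, alternative, expected):
        assert fisher_exact(table, alternative) == pytest.approx(expected, rel=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(17)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 9, 4)
            ours = fisher_exact([[a, b], [c, d]], alternative)
            oracle = enumerate_fisher(int(a), int(b), int(c), int(d), alternative)
            assert ours == pytest.approx(oracle, abs=1e-9)


class TestGenesetEnrichment:
    def test_degenerate_query_equals_universe(self):
        universe = {f"g{i}" for i in range(10)}
        res = geneset_enrichment(universe, {"s": universe}, universe)
        assert res.iloc[0]["p"] == 1.0

    def test_explicit_hypergeometric_sum(self):
        universe = [f"g{i}" for i in range(100)]
        gset = set(universe[:10])
        query = set(universe[5:15])  # overlap 5
        res = geneset_enrichment(query, {"s": gset}, universe)
        oracle = sum(
            math.comb(10, i) * math.comb(90, 10 - i) / math.comb(100, 10)
            for i in range(5, 11)
        )
        assert res.iloc[0]["k"] == 5
        assert res.iloc[0]["p"] == pytest.approx(oracle, rel=1e-9)

    def test_zero_overlap_is_uninformative(self):
        universe = [f"g{i}" for i in range(50)]
        res = geneset_enrichment(set(universe[:5]), {"s": set(universe[40:])}, universe)
        assert res.iloc[0]["p"] == 1.0

    def test_equals_fisher_exact_parameterization(self):
        rng = np.random.default_rng(23)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(25):
            gset = set(rng.choice(universe, size=rng.integers(3, 25), replace=False))
            query = set(rng.choice(universe, size=rng.integers(3, 25), replace=False))
            res = geneset_enrichment(query, {"s": gset}, universe)
            k = len(gset & query)
            K, n, N = len(gset), len(query), len(universe)
            ref = fisher_exact([[k, K - k], [n - k, N - K - n + k]], "greater")
            assert res.iloc[0]["p"] == pytest.approx(ref, rel=1e-9)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="universe"):
            geneset_enrichment({"a"}, {}, set())
        with pytest.raises(ValueError, match="subset"):
            geneset_enrichment({"zz"}, {"s": {"a"}}, {"a", "b"})

    def test_gmt_round_trip(self, tmp_path):
        sets = {"alpha": {"g1", "g2"}, "beta": {"g3"}}
        p = write_gmt(sets, tmp_path / "c.gmt")
        assert read_gmt(p) == sets


class TestFisherCombined:
    def test_worked_examples(self):
        assert fisher_combined([1.0, 1.0]) == 1.0
        assert fisher_combined([0.2]) == pytest.approx(0.2, rel=1e-12)
        assert fisher_combined([0.05, 0.05]) == pytest.approx(0.01747, abs=2e-5)

    def test_monotone_in_replication(self):
        ps = [fisher_combined([0.05] * k) for k in range(1, 6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_chi_square_closed_form(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            ps = rng.uniform(0.001, 1.0, size=rng.integers(1, 8))
            x = -2 * np.sum(np.log(ps))
            ref = float(stats.chi2.sf(x, 2 * len(ps)))
            assert fisher_combined(ps) == pytest.approx(ref, rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_combined([])
        with pytest.raises(ValueError):
            fisher_combined([0.0, 0.5])


class TestDeTest:
    def test_identical_groups(self):
        lfc, p = de_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert lfc == 0.0 and p == 1.0

    def test_two_fold_change_at_large_values(self):
        rng = np.random.default_rng(6)
        normal = rng.uniform(100, 1000, 50)
        lfc, _ = de_test(normal, 2 * normal)
        assert lfc == pytest.approx(1.0, abs=0.02)  # +1 pseudocount bias bounded

    def test_complete_separation_small_n(self):
        lfc, p = de_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)
        assert lfc > 0

    def test_rank_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        a, b = rng.random(15) * 10, rng.random(12) * 10
        _, p1 = de_test(a, b)
        _, p2 = de_test(np.exp(a / 3), np.exp(b / 3))
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_group_too_small_is_undefined(self):
        lfc, p = de_test([1, 2], [3, 4, 5])
        assert math.isnan(lfc) and math.isnan(p)


class TestCancerAssociation:
    def _pairs(self, n, cls="BiTM", prefix="TF"):
        rows = [(f"{prefix}{i}", f"mir{i}", cls, 3.0) for i in range(n)]
        return make_records(rows)

    def test_fully_annotated_dc_set_is_overrepresented(self):
        background = self._pairs(200)
        dc = background.head(20)
        cancer_genes = set(dc["regulator_id"]) | {
            f"TF{i}" for i in range(20, 110)
        }  # background ~50% annotated
        res = cancer_assoc_enrichment(dc, background, cancer_genes, set())
        # oracle: 20 annotated of 20 drawn, universe 200 with 110 annotated
        oracle = stats.hypergeom.sf(19, 200, 110, 20)
        assert res["overall"]["p_over"] == pytest.approx(oracle, rel=1e-6)
        assert res["overall"]["p_over"] < 0.05
        assert res["overall"]["prop_dc_assoc"] == 1.0

    def test_category_absent_from_dc_is_underrepresented(self):
        background = self._pairs(40)
        cancer_mirnas = {f"mir{i}" for i in range(40)}  # all pairs NC at least
        cancer_genes = {f"TF{i}" for i in range(20, 40)}  # half CC
        dc = background.head(10)  # all CC absent? dc TFs 0..9 -> NC only
        res = cancer_assoc_enrichment(dc, background, cancer_genes, cancer_mirnas)
        cc = res["bitm_categories"].set_index("category").loc["CC"]
        assert cc["k_dc"] == 0
        assert cc["p_over"] == 1.0
        assert cc["p_under"] < 0.05

    def test_dc_must_be_subset_of_background(self):
        background = self._pairs(10)
        stranger = self._pairs(3, prefix="ZZ")
        with pytest.raises(ValueError, match="subset"):
            cancer_assoc_enrichment(stranger, background, set(), set())

    def test_empty_background_is_error(self):
        with pytest.raises(ValueError):
            cancer_assoc_enrichment(self._pairs(0), self._pairs(0), set(), set())


class TestRegulatorModule:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["feature", "log2fc", "p"])

    def test_inclusion_rule(self):
        scored = make_records([("TF1", "g1", "TFout", 3.0), ("TF1", "g2", "TFout", 3.0)])
        de = self._de([("g1", 1.0, 0.01), ("g2", -1.0, 0.01)])
        assert regulator_module("TF1", scored, de) == {"g1"}

    def test_negative_correlation_excluded_regardless_of_de(self):
        scored = make_records([("TF1", "g1", "TFout", -3.0)])
        de = self._de([("g1", 2.0, 0.001)])
        assert regulator_module("TF1", scored, de) == set()

    def test_subthreshold_correlation_excluded(self):
        scored = make_records([("TF1", "g1", "TFout", 2.0)])
        de = self._de([("g1", 2.0, 0.001)])
        assert regulator_module("TF1", scored, de) == set()

    def test_absent_regulator_warns_empty(self):
        scored = make_records([("TF1", "g1", "TFout", 3.0)])
        with pytest.warns(UserWarning):
            assert regulator_module("TF9", scored, self._de([])) == set()
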