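"""Shrinkage-t statistics, BH-FDR, signature calling, enrichment."""

import numpy as np
import pytest
from scipy import stats

from conftest import bh_stepup_direct, hypergeom_upper_tail
from lymphosig import (
    CohortLabels,
    DifferentialExpression,
    ExpressionMatrix,
    bh_fdr,
    call_signature,
    fisher_enrichment,
    shrinkage_t,
)


def shrinkage_t_oracle(xa, xb):
    """Step-by-step transcription of the moderated-t formulas (plain loops)."""
    n_a, n_b = xa.shape[1], xb.shape[1]
    n = n_a + n_b
    g = xa.shape[0]
    delta, v, var_v = [], [], []
    residuals = []
    for gi in range(g):
        ra = [xa[gi, i] - np.mean(xa[gi]) for i in range(n_a)]
        rb = [xb[gi, i] - np.mean(xb[gi]) for i in range(n_b)]
        r = ra + rb
        residuals.append(r)
        delta.append(np.mean(xa[gi]) - np.mean(xb[gi]))
        v.append(sum(ri**2 for ri in r) / (n - 2))
        w = [ri**2 for ri in r]
        wbar = sum(w) / n
        var_v.append(n / (n - 1) ** 3 * sum((wi - wbar) ** 2 for wi in w))
    v_median = float(np.median(v))
    denom = sum((vi - v_median) ** 2 for vi in v)
    lam = 1.0 if denom == 0 else min(1.0, sum(var_v) / denom)
    t_star = []
    for gi in range(g):
        v_star = lam * v_median + (1 - lam) * v[gi]
        t_star.append(delta[gi] / np.sqrt(v_star * (1 / n_a + 1 / n_b)))
    return np.array(delta), lam, np.array(t_star)


def two_group(values, n_a):
    g, n = values.shape
    ids = [f"s{i}" for i in range(n)]
    x = ExpressionMatrix(values, [f"g{i}" for i in range(g)], ids)
    labels = CohortLabels({s: ("A" if i < n_a else "B") for i, s in enumerate(ids)})
    return x, labels


class TestShrinkageT:
    def test_matches_independent_oracle_to_1e12(self):
        rng = np.random.default_rng(2024)
        values = rng.normal(8.0, 1.0, size=(5, 40))
        values[:2, :20] += rng.uniform(0.5, 2.0, size=(2, 1))
        x, labels = two_group(values, 20)
        table = shrinkage_t(x, labels, "A", "B")
        delta, lam, t_star = shrinkage_t_oracle(values[:, :20], values[:, 20:])
        assert table.lambda_star == pytest.approx(lam, abs=1e-12)
        np.testing.assert_allclose(table.frame["delta"], delta, atol=1e-12)
        np.testing.assert_allclose(table.frame["t_star"], t_star, atol=1e-12)

    def test_equal_pooled_variances_force_full_shrinkage_to_pooled_t(self):
        # identical residual pattern per gene -> all pooled variances equal
        base = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5, 1.5, -1.5])
        means = np.array([[0.0, 3.0], [5.0, 5.0], [2.0, 1.0]])
        values = np.empty((3, 8))
        for gi in range(3):
            values[gi, :4] = means[gi, 0] + base[:4]
            values[gi, 4:] = means[gi, 1] + base[4:]
        x, labels = two_group(values, 4)
        table = shrinkage_t(x, labels, "A", "B")
        assert table.lambda_star == 1.0
        t_ordinary, _ = stats.ttest_ind(values[:, :4], values[:, 4:], axis=1)
        np.testing.assert_allclose(table.frame["t_star"], t_ordinary, atol=1e-12)

    def test_zero_shrinkage_override_reproduces_ordinary_t(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(20, 12))
        x, labels = two_group(values, 6)
        table = shrinkage_t(x, labels, "A", "B", lambda_override=0.0)
        t_ordinary, p_ordinary = stats.ttest_ind(values[:, :6], values[:, 6:], axis=1)
        np.testing.assert_allclose(table.frame["t_star"], t_ordinary, atol=1e-12)
        np.testing.assert_allclose(table.frame["p"], p_ordinary, atol=1e-12)

    def test_identical_group_means_give_zero_statistic(self):
        values = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 5.0, 6.0, 4.0]])
        x, labels = two_group(values, 3)
        table = shrinkage_t(x, labels, "A", "B")
        assert table.frame.loc["g0", "delta"] == 0.0
        assert table.frame.loc["g0", "t_star"] == 0.0
        assert table.frame.loc["g0", "p"] == 1.0

    def test_degenerate_inputs_rejected(self):
        values = np.random.default_rng(0).normal(size=(4, 6))
        x, labels = two_group(values, 3)
        with pytest.raises(ValueError, match=">= 2 samples"):
            shrinkage_t(x, CohortLabels({s: ("A" if i == 0 else "B") for i, s in
                                         enumerate(x.sample_ids)}), "A", "B")
        flat = ExpressionMatrix(np.full((2, 6), 3.0), ["g0", "g1"], x.sample_ids)
        with pytest.raises(ValueError, match="g0"):
            shrinkage_t(flat, labels, "A", "B")

    def test_permutation_p_option_is_seeded_and_detects_shift(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(30, 16))
        values[0, :8] += 4.0
        x, labels = two_group(values, 8)
        a = shrinkage_t(x, labels, "A", "B", p_method="permutation",
                        n_permutations=200, seed=4)
        b = shrinkage_t(x, labels, "A", "B", p_method="permutation",
                        n_permutations=200, seed=4)
        np.testing.assert_array_equal(a.frame["p"], b.frame["p"])
        assert a.frame.loc["g0", "p"] == pytest.approx(1 / 201)
        assert a.frame["p"].median() > 0.1


class TestNullCalibration:
    def test_no_fdr_calls_on_structureless_cohorts(self):
        """On delta=0 cohorts (1000 genes, 10+10) BH at 0.05 calls nothing
        in nearly every seed (here: >= 18 of 20)."""
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(4000 + seed)
            sd = rng.uniform(0.5, 1.5, size=1000)
            values = 8.0 + rng.standard_normal((1000, 20)) * sd[:, None]
            x, labels = two_group(values, 10)
            table = shrinkage_t(x, labels, "A", "B")
            clean += int((table.frame["q"] < 0.05).sum() == 0)
        assert clean >= 18


class TestBHFDR:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_fdr([1.0]), [1.0])

    def test_matches_direct_definition_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_fdr(p)
            np.testing.assert_allclose(q, bh_stepup_direct(p), atol=1e-14)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCallSignature:
    def _tables(self):
        rng = np.random.default_rng(5)
        values = rng.normal(8, 1, size=(30, 24))
        values[:6, :8] += 2.5  # DE in contrast A-vs-B and A-vs-C
        ids = [f"s{i}" for i in range(24)]
        x = ExpressionMatrix(values, [f"g{i:02d}" for i in range(30)], ids)
        labels = CohortLabels(
            {s: ("A" if i < 8 else "B" if i < 16 else "C") for i, s in enumerate(ids)}
        )
        res = DifferentialExpression(x, labels).fit([("A", "B"), ("A", "C")])
        return res.tables

    def test_union_vs_intersection_rule(self):
        tables = self._tables()
        # force a one-contrast-only pass by editing the second table's q
        tables[1].frame.loc["g00", "q"] = 0.9
        union = call_signature(tables, 1.0, 0.05, rule="union")
        inter = call_signature(tables, 1.0, 0.05, rule="intersection")
        assert "g00" in union.index
        assert "g00" not in inter.index
        assert set(inter.index) <= set(union.index)

    def test_empty_signature_is_not_an_error(self):
        tables = self._tables()
        out = call_signature(tables, lfc_threshold=50.0, fdr_threshold=0.05)
        assert len(out) == 0

    def test_mismatched_universes_rejected(self):
        tables = self._tables()
        tables[1].frame = tables[1].frame.iloc[:-1]
        with pytest.raises(ValueError, match="universe"):
            call_signature(tables)


class TestFisherEnrichment:
    def test_closed_form_small_example(self):
        table = fisher_enrichment(
            {"g1", "g2"}, {"g1", "g2", "g3", "g4"}, {"cat": {"g1", "g2"}}
        )
        assert table.loc["cat", "p"] == pytest.approx(1 / 6)
        assert table.loc["cat", "overlap"] == 2

    def test_disjoint_category_has_p_one(self):
        table = fisher_enrichment({"g1"}, {"g1", "g2", "g3"}, {"cat": {"g2", "g3"}})
        assert table.loc["cat", "p"] == 1.0

    def test_matches_hypergeometric_sum_on_random_configurations(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n_univ = int(rng.integers(4, 30))
            universe = {f"g{i}" for i in range(n_univ)}
            signature = set(rng.choice(sorted(universe), rng.integers(1, n_univ), replace=False))
            category = set(rng.choice(sorted(universe), rng.integers(1, n_univ), replace=False))
            table = fisher_enrichment(signature, universe, {"c": category})
            expected = hypergeom_upper_tail(
                len(category & signature), n_univ, len(category), len(signature)
            )
            assert table.loc["c", "p"] == pytest.approx(expected, abs=1e-12)

    def test_signature_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="gx"):
            fisher_enrichment({"gx"}, {"g1"}, {})

    def test_empty_category_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            table = fisher_enrichment({"g1"}, {"g1", "g2"}, {"c": {"zz"}, "d": {"g1"}})
        assert list(table.index) == ["d"]
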