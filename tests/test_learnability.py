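"""CV accuracy, relabeling enumeration and the learnability test."""

import itertools

import numpy as np
import pytest

from lymphosig import (
    CohortLabels,
    ExpressionMatrix,
    SyntheticSpec,
    cross_validated_accuracy,
    enumerate_relabelings,
    generate_cohort,
    merge_classes,
    relabeling_test,
    subset_by_signature,
)


def separable_cohort(n_per=10, gap=10.0, seed=0, n_genes=2):
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, 1.0, size=(n_genes, 2 * n_per))
    values[0, n_per:] += gap
    ids = [f"s{i}" for i in range(2 * n_per)]
    x = ExpressionMatrix(values, [f"g{i}" for i in range(n_genes)], ids)
    labels = CohortLabels({s: ("A" if i < n_per else "B") for i, s in enumerate(ids)})
    return x, labels


def brute_force_three_class_labelings(labels, roles=("M", "A", "G")):
    """All distinct labelings from the double swap, by direct materialization."""
    vec = list(labels.label_vector())
    m_idx = [i for i, v in enumerate(vec) if v == roles[0]]
    a_idx = [i for i, v in enumerate(vec) if v == roles[1]]
    g_idx = [i for i, v in enumerate(vec) if v == roles[2]]
    out = set()
    for m1, m2 in itertools.permutations(m_idx, 2):
        for a in a_idx:
            for g in g_idx:
                new = list(vec)
                new[m1], new[a] = roles[1], roles[0]
                new[m2], new[g] = roles[2], roles[0]
                out.add(tuple(new))
    return out


class TestCrossValidatedAccuracy:
    def test_separable_two_class_cohort_is_perfect(self):
        x, labels = separable_cohort()
        res = cross_validated_accuracy(x, labels, folds=5, reps=3, seed=0)
        assert res.mean_accuracy == 1.0
        assert res.fold_accuracies.shape == (3, 5)

    def test_fold_matrix_shape_and_range(self):
        x, labels = separable_cohort(gap=1.0)
        res = cross_validated_accuracy(x, labels, folds=10, reps=10, seed=1)
        assert res.fold_accuracies.shape == (10, 10)
        assert np.all((res.fold_accuracies >= 0) & (res.fold_accuracies <= 1))

    def test_null_accuracy_is_centered_at_chance(self):
        """Permuted labels on pure noise: mean accuracy ~0.5 over 200 seeds."""
        rng = np.random.default_rng(99)
        accs = []
        for s in range(200):
            values = rng.normal(size=(20, 20))
            ids = [f"s{i}" for i in range(20)]
            x = ExpressionMatrix(values, [f"g{i}" for i in range(20)], ids)
            perm = rng.permutation(20)
            labels = CohortLabels({ids[j]: ("A" if i < 10 else "B") for i, j in enumerate(perm)})
            accs.append(cross_validated_accuracy(x, labels, 5, 5, seed=s).mean_accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.05

    def test_class_smaller_than_folds_names_class(self):
        x, labels = separable_cohort(n_per=4)
        with pytest.raises(ValueError, match="'A'"):
            cross_validated_accuracy(x, labels, folds=5, reps=2)

    def test_constant_matrix_rejected(self):
        x = ExpressionMatrix(np.full((3, 8), 2.0), list("abc"), [f"s{i}" for i in range(8)])
        labels = CohortLabels({f"s{i}": ("A" if i < 4 else "B") for i in range(8)})
        with pytest.raises(ValueError, match="constant"):
            cross_validated_accuracy(x, labels, folds=2, reps=2)

    def test_deterministic_given_seed(self):
        x, labels = separable_cohort(gap=1.5)
        a = cross_validated_accuracy(x, labels, 5, 3, seed=7)
        b = cross_validated_accuracy(x, labels, 5, 3, seed=7)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)


class TestEnumerateRelabelings:
    @pytest.mark.parametrize("n_m,n_a,n_g", [(2, 1, 1), (3, 2, 2), (4, 3, 2), (5, 3, 3), (2, 3, 1)])
    def test_count_law_matches_brute_force(self, n_m, n_a, n_g):
        assignments = {}
        for role, n in zip("MAG", (n_m, n_a, n_g)):
            for i in range(n):
                assignments[f"{role}{i}"] = role
        labels = CohortLabels(assignments)
        got, n_total, exhaustive = enumerate_relabelings(
            labels, "three_class_exchange", roles=("M", "A", "G"), cap=10**6
        )
        assert exhaustive
        assert n_total == n_m * (n_m - 1) * n_a * n_g
        materialized = {tuple(v) for v in got}
        assert len(materialized) == n_total
        assert materialized == brute_force_three_class_labelings(labels)

    def test_single_putative_sample_is_rejected(self):
        labels = CohortLabels({"m": "M", "a": "A", "g": "G"})
        with pytest.raises(ValueError, match=">= 2"):
            enumerate_relabelings(labels, "three_class_exchange", roles=("M", "A", "G"))

    def test_capped_sampling_is_uniform_without_replacement(self):
        assignments = {f"M{i}": "M" for i in range(4)}
        assignments.update({f"A{i}": "A" for i in range(3)})
        assignments.update({f"G{i}": "G" for i in range(3)})
        labels = CohortLabels(assignments)
        got, n_total, exhaustive = enumerate_relabelings(
            labels, "three_class_exchange", roles=("M", "A", "G"), cap=50, seed=1
        )
        assert n_total == 4 * 3 * 3 * 3 and not exhaustive
        assert len({tuple(v) for v in got}) == 50

    @pytest.mark.parametrize("n_a,n_b,m", [(3, 3, 1), (4, 3, 2), (5, 5, 3)])
    def test_pair_exchange_counts_match_subset_enumeration(self, n_a, n_b, m):
        from math import comb

        assignments = {f"a{i}": "A" for i in range(n_a)}
        assignments.update({f"b{i}": "B" for i in range(n_b)})
        labels = CohortLabels(assignments)
        got, n_total, exhaustive = enumerate_relabelings(
            labels, "pair_exchange", n_swaps=m, cap=10**6
        )
        assert exhaustive and n_total == comb(n_a, m) * comb(n_b, m)
        vectors = {tuple(v) for v in got}
        assert len(vectors) == n_total
        for v in vectors:  # class sizes conserved by construction
            assert sum(1 for lab in v if lab == "A") == n_a

    def test_pair_exchange_invalid_swap_count(self):
        labels = CohortLabels({"a": "A", "b": "B"})
        with pytest.raises(ValueError, match="n_swaps"):
            enumerate_relabelings(labels, "pair_exchange", n_swaps=2)


class TestMergeClasses:
    def test_merge_and_size_arithmetic(self):
        assignments = {f"m{i}": "MZBL" for i in range(22)}
        assignments.update({f"a{i}": "ABC" for i in range(3)})
        assignments.update({f"g{i}": "GCB" for i in range(3)})
        labels = CohortLabels(assignments)
        merged = merge_classes(labels, "MZBL", "ABC")
        assert merged.class_sizes() == {"ABC": 25, "GCB": 3}
        assert merged.n_samples == labels.n_samples

    def test_identical_or_unknown_labels_rejected(self):
        labels = CohortLabels({"a": "A", "b": "B"})
        with pytest.raises(ValueError):
            merge_classes(labels, "A", "A")
        with pytest.raises(ValueError):
            merge_classes(labels, "Z", "A")


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec.planted(
        3, 8, 60, delta=3.0, sigma=0.8, signature_fraction=0.2,
        class_labels=["MZBL", "ABC", "GCB"], layout="rotation", seed=21,
    )
    cohort = generate_cohort(spec)
    return subset_by_signature(cohort.matrix, cohort.signature), cohort.labels


class TestRelabelingTest:
    def test_strong_structure_gives_small_p(self, planted):
        x, labels = planted
        r = relabeling_test(x, labels, folds=4, reps=3, cap=80, seed=0)
        assert r.p_empirical <= 0.05
        n = len(r.perturbed_accuracies)
        exceed = int(np.sum(r.perturbed_accuracies >= r.original_accuracy - 1e-12))
        assert r.p_empirical == pytest.approx((1 + exceed) / (1 + n))

    def test_all_perturbed_below_original_gives_add_one_floor(self):
        x, labels3 = separable_cohort(n_per=8, gap=50.0)
        # add a third, equally separated class on another gene
        rng = np.random.default_rng(5)
        extra = rng.normal(0.0, 1.0, size=(2, 8))
        extra[1] += 50.0
        values = np.concatenate([x.values, extra], axis=1)
        ids = x.sample_ids + [f"t{i}" for i in range(8)]
        x3 = ExpressionMatrix(values, x.gene_ids, ids)
        labels = CohortLabels(
            {**labels3.assignments, **{f"t{i}": "C" for i in range(8)}}
        )
        r = relabeling_test(
            x3, labels, scheme="three_class_exchange", roles=("C", "A", "B"),
            folds=4, reps=2, cap=40, seed=3,
        )
        n = len(r.perturbed_accuracies)
        assert r.original_accuracy == 1.0
        assert np.all(r.perturbed_accuracies < 1.0)
        assert r.p_empirical == pytest.approx(1 / (1 + n))

    def test_identical_inputs_and_seed_reproduce_result(self, planted):
        x, labels = planted
        a = relabeling_test(x, labels, folds=4, reps=3, cap=30, seed=11)
        b = relabeling_test(x, labels, folds=4, reps=3, cap=30, seed=11)
        assert a.p_empirical == b.p_empirical
        np.testing.assert_array_equal(a.perturbed_accuracies, b.perturbed_accuracies)

    def test_two_class_variant_after_merge(self, planted):
        x, labels = planted
        merged = merge_classes(labels, "MZBL", "ABC")
        r = relabeling_test(
            x, merged, scheme="pair_exchange", n_swaps=1, folds=4, reps=2,
            cap=60, seed=2,
        )
        assert r.scheme == "pair_exchange"
        assert 0 < r.p_empirical <= 1
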