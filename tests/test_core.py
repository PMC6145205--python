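"""Cell models, scorers, cross-validated search and permutation machinery."""

from itertools import combinations

import numpy as np
import pytest

from gfqmdr import (
    GenotypeMatrix,
    UNLABELED,
    balanced_accuracy_crisp,
    balanced_accuracy_fuzzy,
    cross_validated_search,
    final_selection,
    fuzzy_counts,
    index_cells,
    label_cells,
    tau_b,
)
from gfqmdr.core import Candidate, SearchResult, _TraitData, training_scores

from _reference import ref_training_scores


class TestIndexCells:
    @pytest.mark.parametrize(
        "row,snp_set,expected",
        [([0, 0], (0, 1), 0), ([2, 1], (0, 1), 5), ([2, 2, 2], (0, 1, 2), 26)],
    )
    def test_base3_encoding(self, row, snp_set, expected):
        g = GenotypeMatrix(codes=np.array([row]))
        assert index_cells(g, snp_set)[0] == expected

    def test_bijective_over_all_combinations(self):
        codes = np.array(list(np.ndindex(3, 3)))
        g = GenotypeMatrix(codes=codes)
        assert sorted(index_cells(g, (0, 1))) == list(range(9))

    def test_missing_codes_rejected(self):
        g = GenotypeMatrix(codes=np.array([[0, -1]]))
        with pytest.raises(ValueError, match="impute"):
            index_cells(g, (0, 1))


class TestFuzzyCounts:
    def test_single_sample_at_high_midpoint(self, unit_scheme):
        # extended memberships at P3 are (-1, 0, 1); traditional are (0, 0, 1)
        cells = np.array([0])
        trait = np.array([unit_scheme.midpoints[2]])
        n_ij, n_plus = fuzzy_counts(cells, trait, unit_scheme, n_cells=2)
        assert np.allclose(n_ij[0], [-1.0, 0.0, 1.0])
        assert np.allclose(n_plus, [0.0, 0.0, 1.0])
        assert np.allclose(n_ij[1], 0.0)  # empty cell row stays zero


class TestLabelCells:
    def test_argmax_of_normalized_counts(self):
        n_ij = np.array([[-1.0, 0.0, 1.0]])
        assert label_cells(n_ij, np.ones(3))[0] == 3

    def test_tie_breaks_to_lower_level(self):
        n_ij = np.array([[0.5, 0.5, -1.0]])
        assert label_cells(n_ij, np.array([1.0, 1.0, 2.0]))[0] == 1

    def test_empty_cell_unlabeled(self):
        n_ij = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        labels = label_cells(n_ij, np.ones(3))
        assert labels[0] == UNLABELED and labels[1] == 1

    def test_all_zero_class_sizes_rejected(self):
        with pytest.raises(ValueError):
            label_cells(np.ones((1, 3)), np.zeros(3))


class TestBalancedAccuracy:
    def test_single_labeled_cell_scores_one_third(self, unit_scheme):
        cells = np.array([0])
        trait = np.array([unit_scheme.midpoints[2]])
        labels = np.array([3])
        score = balanced_accuracy_fuzzy(cells, labels, trait, unit_scheme)
        assert np.isclose(score, 1 / 3)

    def test_perfect_midpoint_classifier_scores_one(self, midpoint_fixture):
        genotypes, trait, scheme = midpoint_fixture
        cells = index_cells(genotypes, (0,))
        labels = np.array([1, 2, 3])
        assert np.isclose(balanced_accuracy_fuzzy(cells, labels, trait, scheme), 1.0)

    def test_all_unlabeled_scores_zero(self, unit_scheme):
        cells = np.array([0, 1])
        trait = np.array([0.5, 2.5])
        labels = np.array([UNLABELED, UNLABELED])
        assert balanced_accuracy_fuzzy(cells, labels, trait, unit_scheme) == 0.0

    def test_crisp_perfect_and_constant(self):
        cells = np.array([0, 0, 1, 1])
        cats = np.array([1, 1, 2, 2])
        assert balanced_accuracy_crisp(cells, np.array([1, 2]), cats) == 1.0
        # everything predicted class 1 on balanced two-class data
        assert balanced_accuracy_crisp(cells, np.array([1, 1]), cats) == 0.5


class TestTauB:
    def test_perfect_and_reversed(self):
        assert tau_b([1, 2, 3], [1, 2, 3]) == 1.0
        assert tau_b([1, 2, 3], [3, 2, 1]) == -1.0

    def test_tied_example_matches_pair_enumeration(self):
        true, pred = [1, 1, 2, 3], [1, 2, 2, 3]
        # brute force over all 6 sample pairs
        C = D = tx = ty = 0
        for (t1, p1), (t2, p2) in combinations(zip(true, pred), 2):
            dt, dp = t2 - t1, p2 - p1
            if dt == 0 and dp == 0:
                tx += 1
                ty += 1
            elif dt == 0:
                tx += 1
            elif dp == 0:
                ty += 1
            elif dt * dp > 0:
                C += 1
            else:
                D += 1
        n0 = 6
        # N1 counts pairs tied in true, N2 pairs tied in pred (shared ties in both)
        n1 = sum(1 for (a, b) in combinations(true, 2) if a == b)
        n2 = sum(1 for (a, b) in combinations(pred, 2) if a == b)
        expected = (C - D) / np.sqrt((n0 - n1) * (n0 - n2))
        assert np.isclose(tau_b(true, pred), expected)

    def test_constant_vector_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert tau_b([1, 1, 1], [1, 2, 3]) == 0.0


class TestCrispReduction:
    """With every trait value on a midpoint, fuzzy counting is integer counting."""

    def test_all_methods_agree_on_midpoint_data(self, midpoint_fixture):
        genotypes, trait, scheme = midpoint_fixture
        data = _TraitData(trait, scheme)
        # traditional counts collapse to integer counts at midpoints, so the
        # traditional-fuzzy scorer matches the crisp scorer on every set
        all_sets = np.array([(0,), (1,)], dtype=np.int64)
        fq, fq_lab = training_scores(genotypes.codes, data, all_sets, "fqmdr")
        md, md_lab = training_scores(genotypes.codes, data, all_sets, "mdr")
        assert np.allclose(fq, md)
        assert np.array_equal(fq_lab, md_lab)
        # extended counts penalize opposite levels, so the full equivalence
        # needs pure cells: marker 0 determines the level, alone or paired
        for sets in (np.array([(0,)], dtype=np.int64), np.array([(0, 1)], dtype=np.int64)):
            gf, gf_lab = training_scores(genotypes.codes, data, sets, "gfqmdr")
            md2, md2_lab = training_scores(genotypes.codes, data, sets, "mdr")
            assert np.allclose(gf, md2)
            assert np.array_equal(gf_lab, md2_lab)
            assert np.isclose(gf[0], 1.0)

    def test_fuzzy_score_equals_mean_recall(self, midpoint_fixture):
        genotypes, trait, scheme = midpoint_fixture
        cells = index_cells(genotypes, (0, 1))
        from gfqmdr import assign_crisp_category

        cats = assign_crisp_category(scheme, trait)
        n_ij, n_plus = fuzzy_counts(cells, trait, scheme, n_cells=9)
        labels = label_cells(n_ij, n_plus)
        fuzz = balanced_accuracy_fuzzy(cells, labels, trait, scheme)
        crisp = balanced_accuracy_crisp(cells, labels, cats)
        assert np.isclose(fuzz, crisp)


class TestOracleEquivalence:
    @pytest.mark.parametrize("method", ["gfqmdr", "fqmdr", "omdr", "mdr"])
    def test_vectorized_matches_per_sample_reference(self, method):
        from conftest import random_instance
        from gfqmdr import build_equal_length_scheme, assign_crisp_category

        rng = np.random.default_rng(2024)
        for trial in range(5):
            n = int(rng.integers(20, 61))
            m = int(rng.integers(3, 7))
            order = int(rng.integers(1, min(3, m) + 1))
            genotypes, trait = random_instance(rng, n, m)
            scheme = build_equal_length_scheme(trait, J=3)
            data = _TraitData(trait, scheme)
            cats = assign_crisp_category(scheme, trait)
            sets = list(combinations(range(m), order))
            idx = rng.permutation(n)[: int(0.8 * n)]
            got, _ = training_scores(
                genotypes.codes, data, np.array(sets, dtype=np.int64), method, np.sort(idx)
            )
            want = ref_training_scores(
                genotypes.codes, trait, cats, tuple(scheme.midpoints), sets, np.sort(idx), method
            )
            assert np.allclose(got, want, atol=1e-12)


class TestPermutationInvariance:
    def test_joint_sample_reorder_leaves_scores_unchanged(self):
        from conftest import random_instance
        from gfqmdr import build_equal_length_scheme

        rng = np.random.default_rng(7)
        genotypes, trait = random_instance(rng, 40, 5)
        scheme = build_equal_length_scheme(trait, J=3)
        sets = np.array(list(combinations(range(5), 2)), dtype=np.int64)
        base, _ = training_scores(genotypes.codes, _TraitData(trait, scheme), sets)
        perm = rng.permutation(40)
        shuffled = GenotypeMatrix(codes=genotypes.codes[perm])
        moved, _ = training_scores(shuffled.codes, _TraitData(trait[perm], scheme), sets)
        assert np.allclose(base, moved)


class TestSearch:
    def test_enumerates_all_pairs_and_bounds_gcvc(self):
        from conftest import random_instance
        from gfqmdr import build_equal_length_scheme

        rng = np.random.default_rng(11)
        genotypes, trait = random_instance(rng, 60, 4)
        scheme = build_equal_length_scheme(trait, J=3)
        res = cross_validated_search(genotypes, trait, scheme, order=2, L=5, k=2, seed=0)
        assert all(len(fold) == 2 for fold in res.per_fold_topk)
        seen = {s for fold in res.per_fold_topk for s in fold}
        assert seen <= set(combinations(range(4), 2))
        assert all(1 <= c.gcvc <= 5 for c in res.candidates)
        mts = [c.mtsbca for c in res.candidates]
        assert mts == sorted(mts, reverse=True)

    def test_order_larger_than_m_rejected(self):
        g = GenotypeMatrix(codes=np.zeros((10, 2), dtype=int))
        with pytest.raises(ValueError):
            cross_validated_search(g, np.arange(10.0), None, order=3)

    def test_search_deterministic_under_seed(self):
        from conftest import random_instance
        from gfqmdr import build_equal_length_scheme

        rng = np.random.default_rng(5)
        genotypes, trait = random_instance(rng, 50, 5)
        scheme = build_equal_length_scheme(trait, J=3)
        a = cross_validated_search(genotypes, trait, scheme, order=2, seed=3)
        b = cross_validated_search(genotypes, trait, scheme, order=2, seed=3)
        assert [(c.snp_set, c.mtsbca, c.gcvc) for c in a.candidates] == [
            (c.snp_set, c.mtsbca, c.gcvc) for c in b.candidates
        ]


class TestFinalSelection:
    def _result(self, pvals):
        cands = [
            Candidate(snp_set=(0, i + 1), mtsbca=1.0 - 0.1 * i, gcvc=10 - i, p_value=None)
            for i in range(len(pvals))
        ]
        return SearchResult(order=2, candidates=cands, per_fold_topk=[], scheme=None)

    def test_alpha_filtering(self):
        res = self._result([0.0, 0.5, 0.009])
        kept = final_selection(res, [0.0, 0.5, 0.009], alpha=0.01)
        assert [c.snp_set for c in kept] == [(0, 1), (0, 3)]

    def test_all_above_alpha_empty(self):
        res = self._result([0.5, 0.9])
        assert final_selection(res, [0.5, 0.9], alpha=0.01) == []

    def test_alpha_one_keeps_everything(self):
        res = self._result([0.3, 0.99])
        assert len(final_selection(res, [0.3, 0.99], alpha=1.0)) == 2
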