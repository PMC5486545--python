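from fractions import Fraction

import numpy as np
import pytest

from morphospace import (
    CharacterMatrix,
    DegenerateMatrixError,
    FieldError,
    MissingDataError,
    character_clusters,
    cooccurrence_matrix,
    cooccurrence_rank,
    epsilon_rank,
    feature_frequencies,
    independence_test,
    matrix_rank,
    pair_frequencies,
    rank_decompose,
)
from morphospace.algebra import _peel_decompose


def exact_equal(A, B):
    A, B = np.asarray(A), np.asarray(B)
    return A.shape == B.shape and all(
        Fraction(x) == Fraction(y) for x, y in zip(A.flat, B.flat)
    )


class TestMatrixRank:
    def test_printed_examples(self, eq7, eq8, eq21, eq23, eq24):
        assert matrix_rank(eq7) == 3
        assert matrix_rank(eq8) == 1
        assert matrix_rank(eq21) == 5
        assert matrix_rank(eq23) == 1
        assert matrix_rank(eq24) == 2

    @pytest.mark.parametrize("field", ["real", "integer", "gf2"])
    def test_zero_matrix(self, field):
        assert matrix_rank(CharacterMatrix(np.zeros((3, 4)), field_tag=field)) == 0

    def test_missing_entries_refused(self):
        M = CharacterMatrix([[1.0, np.nan]], field_tag="real")
        with pytest.raises(MissingDataError):
            matrix_rank(M)

    def test_gf2_rank_below_real_rank(self):
        # the three cyclic pair-sums over GF(2) satisfy c1+c2+c3 = 0
        M = CharacterMatrix([[1, 1, 0], [0, 1, 1], [1, 0, 1]], field_tag="gf2")
        M_q = CharacterMatrix(M.values, field_tag="integer")
        assert matrix_rank(M) == 2
        assert matrix_rank(M_q) == 3
        assert matrix_rank(M) < matrix_rank(M_q)

    def test_real_rank_matches_exact_on_integer_data(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            X = rng.integers(0, 3, size=rng.integers(1, 6, size=2))
            exact = matrix_rank(CharacterMatrix(X, field_tag="integer"))
            numeric = matrix_rank(CharacterMatrix(X.astype(float), field_tag="real"))
            assert exact == numeric


class TestRankDecompose:
    def test_rank_one_factors(self, eq8):
        dec = rank_decompose(eq8)
        assert dec.rank == 1
        a, b = dec.terms[0]
        assert list(a) == [1, 2]
        assert list(b) == [1, 2, 5]
        assert dec.reconstruction_error == 0

    def test_identity_two_terms(self):
        dec = rank_decompose(CharacterMatrix(np.eye(2), field_tag="integer"))
        assert dec.rank == 2
        assert exact_equal(dec.reconstruct(), np.eye(2))

    def test_overlay_reconstructs_exactly(self, eq24):
        dec = rank_decompose(eq24)
        assert dec.rank == 2
        assert exact_equal(dec.reconstruct(), eq24.values)

    def test_real_svd_form_reconstructs(self, eq7):
        dec = rank_decompose(eq7)
        total = sum(np.outer(a, b) for a, b in dec.terms)
        assert np.allclose(total, eq7.values)
        assert dec.rank <= min(eq7.shape)

    @pytest.mark.parametrize("field", ["integer", "gf2"])
    def test_exact_reconstruction_and_minimality_random(self, field):
        rng = np.random.default_rng(11)
        for _ in range(30):
            shape = rng.integers(1, 6, size=2)
            X = rng.integers(0, 2 if field == "gf2" else 3, size=shape)
            M = CharacterMatrix(X, field_tag=field)
            dec = rank_decompose(M)
            target = X % 2 if field == "gf2" else X
            assert exact_equal(dec.reconstruct(), target)
            assert dec.rank == matrix_rank(M) <= min(shape)


class TestEpsilonRank:
    def test_small_perturbation_recovers_low_rank(self, eq8_real):
        rng = np.random.default_rng(0)
        noisy = eq8_real.values + 1e-6 * rng.standard_normal(eq8_real.shape)
        M = CharacterMatrix(noisy, field_tag="real")
        assert matrix_rank(M, tol=1e-12) == 2  # noise fills the rank
        assert epsilon_rank(M, 1e-3) == 1

    def test_tiny_eps_recovers_plain_rank(self, eq7):
        assert epsilon_rank(eq7, 1e-12) == matrix_rank(eq7)

    def test_dominating_eps_gives_zero(self, eq8_real):
        big = float(np.linalg.norm(eq8_real.values)) + 1.0
        assert epsilon_rank(eq8_real, big) == 0

    def test_boundary_is_strict(self):
        # singular values 2 and 1: tail energy exactly 1 at eps=1 keeps rank 2
        M = CharacterMatrix(np.diag([2.0, 1.0]), field_tag="real")
        assert epsilon_rank(M, 1.0) == 2
        assert epsilon_rank(M, 1.0 + 1e-9) == 1

    def test_errors(self, eq8, eq8_real):
        with pytest.raises(ValueError):
            epsilon_rank(eq8_real, 0.0)
        with pytest.raises(FieldError):
            epsilon_rank(eq8, 0.5)


class TestCharacterClusters:
    def test_fully_correlated_single_cluster(self, eq8):
        clusters = character_clusters(eq8)
        assert len(clusters) == 1
        assert clusters[0].representative_features == ["f1", "f2", "f3"]

    def test_overlay_splits_into_feature_blocks(self, eq24):
        clusters = character_clusters(eq24)
        reps = sorted((frozenset(c.representative_features) for c in clusters), key=sorted)
        assert reps == sorted(
            [frozenset({"teeth", "feet"}), frozenset({"fur", "color"})], key=sorted
        )

    def test_identity_gives_singletons(self):
        n = 4
        clusters = character_clusters(CharacterMatrix(np.eye(n), field_tag="integer"))
        assert len(clusters) == n
        assert sorted(c.representative_features[0] for c in clusters) == [
            f"f{j + 1}" for j in range(n)
        ]

    def test_eps_clustering_sees_through_noise(self, eq8_real):
        rng = np.random.default_rng(1)
        noisy = CharacterMatrix(
            eq8_real.values + 1e-6 * rng.standard_normal(eq8_real.shape),
            field_tag="real",
        )
        clusters = character_clusters(noisy, eps=1e-3)
        assert len(clusters) == 1
        assert clusters[0].representative_features == ["f1", "f2", "f3"]


class TestCooccurrence:
    def test_hand_computed_example(self, eq8):
        F = cooccurrence_matrix(eq8)
        expected = [[Fraction(1, 9), Fraction(2, 9)], [Fraction(2, 9), Fraction(4, 9)]]
        assert exact_equal(F.cooccurrence, expected)
        assert F.Z == 270

    def test_single_cell_normalizes_to_one(self):
        F = cooccurrence_matrix(CharacterMatrix([[3]], field_tag="integer"))
        assert exact_equal(F.cooccurrence, [[1]])

    def test_rank_preserved_on_example(self, eq8):
        assert cooccurrence_rank(cooccurrence_matrix(eq8)) == matrix_rank(eq8)

    def test_zero_matrix_raises(self):
        with pytest.raises(DegenerateMatrixError):
            cooccurrence_matrix(CharacterMatrix(np.zeros((2, 2)), field_tag="integer"))

    def test_symmetry_and_total_mass(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = rng.integers(0, 3, size=(4, 3))
            if not X.any():
                continue
            F = cooccurrence_matrix(CharacterMatrix(X, field_tag="integer"))
            P = F.cooccurrence
            assert exact_equal(P, P.T)
            assert sum(Fraction(x) for x in P.flat) == 1


class TestFrequencies:
    def test_identical_carriers(self, m18):
        F = feature_frequencies(m18)
        assert F.marginals[0] == 1 and F.marginals[3] == 1
        assert F.marginals[1] == 0 and F.marginals[2] == 0
        assert F.pairwise[0, 3] == 1

    def test_dependent_features(self, m19):
        F = feature_frequencies(m19)
        assert F.marginals[0] == Fraction(1, 2)
        assert F.pairwise[0, 3] == Fraction(1, 2)
        pair = pair_frequencies(F, 0, 3)
        assert pair["product"] == Fraction(1, 4)
        assert not pair["independent_pair"]

    def test_total_normalized_marginals_sum_to_one(self, m19):
        F = feature_frequencies(m19, convention="total_normalized")
        assert sum(F.marginals) == 1

    def test_distributional_row_sums_are_marginals(self, m19):
        F = feature_frequencies(m19, convention="distributional")
        m = len(F.feature_ids)
        for j in range(m):
            assert sum(F.pairwise[j, k] for k in range(m)) == F.marginals[j]

    def test_pairwise_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X = rng.integers(0, 2, size=(5, 4))
            M = CharacterMatrix(X, field_tag="gf2")
            for conv in ("carrier_fraction", "total_normalized"):
                if conv == "total_normalized" and not X.any():
                    continue
                F = feature_frequencies(M, convention=conv)
                assert exact_equal(F.pairwise, F.pairwise.T)

    def test_requires_binary(self, eq24):
        with pytest.raises(FieldError):
            feature_frequencies(eq24)


class TestIndependence:
    def test_worked_examples(self, m18, m19):
        ok, dev = independence_test(feature_frequencies(m18))
        assert ok and dev == 0
        ok, dev = independence_test(feature_frequencies(m19))
        assert not ok and dev == 0.25

    def test_single_feature_trivially_independent(self):
        M = CharacterMatrix([[1], [0]], field_tag="gf2")
        ok, dev = independence_test(feature_frequencies(M, max_order=1), order=1)
        assert ok and dev == 0

    def test_missing_order_raises(self, m18):
        with pytest.raises(ValueError):
            independence_test(feature_frequencies(m18, max_order=2), order=3)

    def test_independence_iff_rank_one_pairwise(self):
        """Order-2 independence holds exactly when the pairwise table is the
        rank-1 outer square of the marginals (exact arithmetic)."""
        rng = np.random.default_rng(9)
        for _ in range(40):
            X = rng.integers(0, 2, size=(4, 3))
            if not X.any():
                continue
            F = feature_frequencies(
                CharacterMatrix(X, field_tag="gf2"), convention="total_normalized"
            )
            ok, _ = independence_test(F)
            outer = np.outer(F.marginals, F.marginals)
            is_outer_square = exact_equal(F.pairwise, outer)
            assert ok == is_outer_square
            if ok and any(x != 0 for x in F.pairwise.flat):
                rows = [[Fraction(x) for x in row] for row in F.pairwise]
                assert len(_peel_decompose(rows, gf2=False)) == 1


class TestCooccurrenceRankPreservation:
    """rank(C C^T / Z) equals the rational/real rank of C.

    The co-occurrence normalization works over the rationals, so the
    comparison rank is the rational one even for 0/1 palettes.
    """

    @pytest.mark.parametrize("palette", ["real", "integer", "gf2"])
    def test_random_matrices(self, palette):
        rng = np.random.default_rng({"real": 0, "integer": 1, "gf2": 2}[palette])
        checked = 0
        while checked < 60:
            n, m = rng.integers(1, 7, size=2)
            if palette == "real":
                X = np.round(rng.standard_normal((n, m)), 3)
                M = CharacterMatrix(X, field_tag="real")
                if abs((X @ X.T).sum()) < 1e-9:
                    continue
            else:
                hi = 2 if palette == "gf2" else 4
                X = rng.integers(0, hi, size=(n, m))
                if not X.any():
                    continue
                M = CharacterMatrix(X, field_tag="integer")
            F = cooccurrence_matrix(M)
            assert cooccurrence_rank(F) == matrix_rank(M)
            checked += 1
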