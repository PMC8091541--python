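"""Pair sampling, feature-difference decomposition, and secondary metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modalign import (
    DegenerateModalityError,
    InvalidInputError,
    PairSample,
    PrimaryModality,
    SecondaryModality,
    feature_diffs,
    precomputed_distances,
    sample_pairs,
    secondary_distances,
)

from conftest import all_pairs


class TestSamplePairs:
    def test_exhaustive_case_returns_all_pairs_lexicographically(self):
        ps = sample_pairs(N=4, requested_count=100, seed=0)
        assert [tuple(p) for p in ps.pairs] == all_pairs(4)

    def test_exhaustive_case_is_seed_free(self):
        a = sample_pairs(N=4, requested_count=6, seed=0)
        b = sample_pairs(N=4, requested_count=6, seed=1)
        assert np.array_equal(a.pairs, b.pairs)

    def test_subsample_reproducible_and_seed_sensitive(self):
        a = sample_pairs(N=100, requested_count=50, seed=7)
        b = sample_pairs(N=100, requested_count=50, seed=7)
        c = sample_pairs(N=100, requested_count=50, seed=8)
        assert np.array_equal(a.pairs, b.pairs)
        assert not np.array_equal(a.pairs, c.pairs)
        assert len(c) == 50
        assert len({tuple(p) for p in c.pairs}) == 50

    def test_minimum_observations_enforced(self):
        with pytest.raises(InvalidInputError, match="3"):
            sample_pairs(N=2, requested_count=1, seed=0)
        with pytest.raises(InvalidInputError):
            sample_pairs(N=10, requested_count=0, seed=0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        N=st.integers(min_value=3, max_value=120),
        count=st.integers(min_value=1, max_value=500),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_sampled_pairs_are_valid_distinct_and_sized(self, N, count, seed):
        ps = sample_pairs(N, count, seed)
        total = N * (N - 1) // 2
        assert len(ps) == min(count, total)
        assert np.all(ps.left < ps.right)
        assert ps.pairs.min() >= 0 and ps.pairs.max() < N
        assert len({tuple(p) for p in ps.pairs}) == len(ps)


class TestFeatureDiffs:
    def test_identical_rows_give_zero_row(self, exhaustive_pairs):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        D = feature_diffs(PrimaryModality(X=X), exhaustive_pairs(3))
        assert np.all(D[0] == 0)  # pair (0, 1)

    def test_hand_computed_squared_differences(self, exhaustive_pairs):
        X = np.array([[1.0, 0.0], [0.0, 0.0], [2.0, 2.0]])
        D = feature_diffs(PrimaryModality(X=X), exhaustive_pairs(3))
        assert np.allclose(D[0], [1.0, 0.0])  # (1,0) vs (0,0)

    def test_hamming_rows_with_null_padding(self, exhaustive_pairs):
        X = np.array([list("CASS-"), list("CASR-"), list("CASS-")])
        prim = PrimaryModality(X=X, metric_kind="hamming")
        D = feature_diffs(prim, exhaustive_pairs(3))
        assert np.array_equal(D[0], [0, 0, 0, 1, 0])
        assert D[0].sum() == 1  # the number of disagreeing positions
        assert np.all(D[1] == 0)  # identical sequences, nulls match nulls

    def test_row_sums_equal_brute_force_squared_distances(self, rng, exhaustive_pairs):
        X = rng.standard_normal((5, 3))
        D = feature_diffs(PrimaryModality(X=X), exhaustive_pairs(5))
        for row, (n, m) in zip(D, all_pairs(5)):
            expected = sum((X[n, i] - X[m, i]) ** 2 for i in range(3))
            assert row.sum() == pytest.approx(expected, rel=1e-12)
            assert np.all(row >= 0)

    def test_non_finite_entry_rejected_with_coordinates(self):
        X = np.ones((4, 2))
        X[2, 1] = np.nan
        X[0, 0] = 2.0
        with pytest.raises(InvalidInputError, match="row 2.*column 1"):
            PrimaryModality(X=X)


class TestSecondaryDistances:
    def test_categorical_mismatch_indicator(self, exhaustive_pairs):
        mod = SecondaryModality(
            payload=np.array(["A", "A", "B"]), metric_kind="categorical_mismatch"
        )
        rho = secondary_distances(mod, exhaustive_pairs(3))
        assert np.array_equal(rho, [0.0, 1.0, 1.0])

    def test_scalar_absolute_difference(self, exhaustive_pairs):
        mod = SecondaryModality(
            payload=np.array([0.2, 0.5, 0.2]), metric_kind="absolute_diff"
        )
        rho = secondary_distances(mod, exhaustive_pairs(3))
        assert np.allclose(rho, [0.3, 0.0, 0.3])

    def test_boolean_binding_vectors_count_discordant_ligands(self, rng, exhaustive_pairs):
        B = rng.integers(0, 2, size=(6, 44)).astype(bool)
        mod = SecondaryModality(payload=B, metric_kind="euclidean_sq")
        rho = secondary_distances(mod, exhaustive_pairs(6))
        for val, (n, m) in zip(rho, all_pairs(6)):
            assert val == np.sum(B[n] != B[m])

    def test_post_transform_applied_last(self, exhaustive_pairs):
        mod = SecondaryModality(
            payload=np.array([0.0, 1.0, 3.0]),
            metric_kind="absolute_diff",
            post_transform=np.square,
        )
        rho = secondary_distances(mod, exhaustive_pairs(3))
        assert np.allclose(rho, [1.0, 9.0, 4.0])

    def test_constant_distance_vector_rejected(self, exhaustive_pairs):
        mod = SecondaryModality(
            payload=np.array(["A", "B", "C"]), metric_kind="categorical_mismatch"
        )
        with pytest.raises(DegenerateModalityError):
            secondary_distances(mod, exhaustive_pairs(3))

    def test_symmetry_and_zero_on_self_pairs(self, rng):
        V = rng.standard_normal((5, 3))
        mod = SecondaryModality(payload=V, metric_kind="euclidean_sq")
        fwd = PairSample(pairs=np.array([[0, 3], [1, 2]]), seed=0, requested_count=2)
        rev = PairSample(pairs=np.array([[3, 0], [2, 1]]), seed=0, requested_count=2)
        selfp = PairSample(pairs=np.array([[2, 2], [0, 3]]), seed=0, requested_count=2)
        assert secondary_distances(mod, fwd) == pytest.approx(
            secondary_distances(mod, rev)
        )
        assert secondary_distances(mod, selfp)[0] == 0.0

    def test_gamma_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            SecondaryModality(payload=np.arange(4.0), metric_kind="absolute_diff", gamma=0)

    def test_precomputed_vector_validation(self):
        assert np.allclose(precomputed_distances([0.0, 1.0, 2.0]), [0, 1, 2])
        with pytest.raises(DegenerateModalityError):
            precomputed_distances([1.0, 1.0, 1.0])


class TestPrimaryValidation:
    def test_constant_features_dropped_with_warning(self, rng):
        X = rng.standard_normal((6, 3))
        X[:, 1] = 7.0
        prim = PrimaryModality(X=X, feature_names=["a", "b", "c"])
        with pytest.warns(UserWarning, match="constant"):
            reduced = prim.drop_constant_features()
        assert reduced.feature_names == ["a", "c"]
        assert reduced.X.shape == (6, 2)

    def test_hamming_requires_symbolic_entries(self):
        with pytest.raises(InvalidInputError, match="symbolic"):
            PrimaryModality(X=np.ones((4, 2)), metric_kind="hamming")

    def test_too_few_observations_rejected(self):
        with pytest.raises(InvalidInputError, match="3"):
            PrimaryModality(X=np.ones((2, 2)))
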