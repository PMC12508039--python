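"""Standardization contract and Euclidean distance geometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdss.space import (
    SpaceStandardizer,
    build_scale_space,
    build_space,
    euclidean_distance,
    pairwise_distances,
    standardize,
)

from conftest import pairwise_oracle


class TestStandardizer:
    def test_hand_computed_two_point_column(self):
        """(0, 2) standardizes to (-1, +1) under the population SD."""
        Z = SpaceStandardizer().fit_transform(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(Z.ravel(), [-1.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(3.0, 2.5, size=(50, 7))
        Z = SpaceStandardizer().fit_transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(Z.std(axis=0, ddof=0), 1.0, atol=1e-8)

    def test_idempotent_and_invertible(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4)) * 5 + 1
        std = SpaceStandardizer().fit(X)
        Z = std.transform(X)
        Z2 = SpaceStandardizer().fit_transform(Z)
        np.testing.assert_allclose(Z2, Z, atol=1e-10)
        np.testing.assert_allclose(std.inverse_transform(Z), X, atol=1e-10)

    def test_constant_column_flagged_not_error(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        std = SpaceStandardizer().fit(X)
        Z = std.transform(X)
        assert std.constant_mask_.tolist() == [True, False]
        assert np.all(Z[:, 0] == 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            SpaceStandardizer().fit(np.ones((1, 3)))


class TestEuclidean:
    def test_identical_vectors_distance_zero(self):
        assert euclidean_distance([1, 2, 0], [1, 2, 0]) == 0.0

    def test_formula_evaluation(self):
        assert euclidean_distance([0, 0, 0], [1, 2, 2]) == pytest.approx(3.0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=10),
        st.data(),
    )
    def test_symmetry_property(self, u, data):
        v = data.draw(st.lists(st.floats(-50, 50), min_size=len(u), max_size=len(u)))
        assert euclidean_distance(u, v) == euclidean_distance(v, u)


class TestPairwise:
    def test_single_observation_is_zero_matrix(self):
        space = standardize(np.array([[1.0, 2.0], [1.0, 2.0]]))
        sub = pairwise_distances(space)
        assert sub.values.shape == (2, 2)
        np.testing.assert_allclose(sub.values, 0.0)

    def test_right_triangle_distances(self):
        # legs 3 and 4, hypotenuse 5 (raw-space flag path)
        X = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        space = standardize(X)
        D = pairwise_distances(space, use_raw=True).values
        np.testing.assert_allclose(D[0, 1], 3.0)
        np.testing.assert_allclose(D[0, 2], 4.0)
        np.testing.assert_allclose(D[1, 2], 5.0)

    @pytest.mark.parametrize("n,p", [(20, 5), (60, 30), (200, 122)])
    def test_matches_double_loop_oracle(self, n, p):
        rng = np.random.default_rng(n + p)
        space = standardize(rng.normal(size=(n, p)))
        D = pairwise_distances(space).values
        np.testing.assert_allclose(D, pairwise_oracle(space.values), atol=1e-9)

    def test_metric_axioms_with_sampled_triangles(self):
        rng = np.random.default_rng(9)
        space = standardize(rng.normal(size=(80, 10)))
        dm = pairwise_distances(space)
        dm.validate()
        D = dm.values
        idx = rng.integers(0, 80, size=(1200, 3))
        i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
        assert np.all(D[i, k] <= D[i, j] + D[j, k] + 1e-9)

    def test_adding_feature_never_decreases_distances(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 6))
        extra = rng.normal(size=(40, 1))
        d_small = pairwise_oracle(X)
        d_big = pairwise_oracle(np.hstack([X, extra]))
        assert np.all(d_big >= d_small - 1e-12)


class TestBuildSpace:
    def test_pooled_standardization_covers_all_timepoints(self, small_sim):
        cohort, _, _ = small_sim
        space = build_space(cohort)
        assert space.n_observations == len(cohort)
        nc = ~space.constant_mask
        np.testing.assert_allclose(space.values[:, nc].mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(
            space.values[:, nc].std(axis=0, ddof=0), 1.0, atol=1e-8
        )

    def test_projection_matches_fitted_rows(self, small_sim):
        cohort, _, _ = small_sim
        space = build_space(cohort)
        np.testing.assert_allclose(space.project(space.raw[:5]), space.values[:5], atol=1e-12)


class TestScaleSpace:
    def _tscores(self, n=40, seed=3):
        rng = np.random.default_rng(seed)
        idx = pd.MultiIndex.from_arrays(
            [[f"p{i}" for i in range(n)], [1] * n], names=["person_id", "timepoint"]
        )
        cols = [
            "total_problems",
            "internalizing",
            "externalizing",
            "attention_problems",
            "somatic_complaints",
        ]
        return pd.DataFrame(rng.normal(50, 10, size=(n, 5)), index=idx, columns=cols)

    def test_five_features(self):
        space = build_scale_space(self._tscores())
        assert space.n_features == 5

    def test_missing_scale_named(self):
        t = self._tscores().drop(columns=["somatic_complaints"])
        with pytest.raises(ValueError, match="somatic_complaints"):
            build_scale_space(t)

    def test_identical_rows_distance_zero_and_oracle(self):
        t = self._tscores()
        t.iloc[1] = t.iloc[0]
        space = build_scale_space(t)
        D = pairwise_distances(space).values
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(D, pairwise_oracle(space.values), atol=1e-9)
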