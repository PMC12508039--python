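"""Average person vector, centroid distances, severity regressions."""

import numpy as np
import pandas as pd
import pytest

from hdss.centroid import (
    average_person_vector,
    distance_from_centroid,
    distance_severity_correlation,
    person_severity_index,
    rose_data,
    severity_regression,
)
from hdss.scoring import score_cohort
from hdss.space import build_space, standardize


def _space(n=30, p=6, seed=0):
    rng = np.random.default_rng(seed)
    return standardize(rng.normal(size=(n, p)))


class TestCentroid:
    def test_global_centroid_is_origin(self, small_sim):
        cohort, _, _ = small_sim
        space = build_space(cohort)
        c = average_person_vector(space)
        np.testing.assert_allclose(c.standardized, 0.0, atol=1e-8)
        assert c.n_observations == space.n_observations

    def test_two_observations_midpoint(self):
        space = standardize(np.array([[0.0, 0.0], [4.0, 2.0]]))
        c = average_person_vector(space)
        d = distance_from_centroid(space, c)
        assert d.iloc[0] == pytest.approx(d.iloc[1])
        np.testing.assert_allclose(c.raw, [2.0, 1.0])

    def test_stratified_counts_partition_n(self, small_sim):
        cohort, _, _ = small_sim
        space = build_space(cohort)
        demo = cohort[["gender"]]
        cents = average_person_vector(space, demographics=demo, stratify_by=["gender"])
        assert len(cents) == 2
        assert sum(c.n_observations for c in cents.values()) == space.n_observations

    def test_stratified_weighted_mean_recovers_global(self, small_sim):
        cohort, _, _ = small_sim
        space = build_space(cohort)
        demo = cohort[["race"]]
        cents = average_person_vector(space, demographics=demo, stratify_by=["race"])
        weighted = sum(
            c.n_observations * c.standardized for c in cents.values()
        ) / space.n_observations
        np.testing.assert_allclose(weighted, np.zeros(space.n_features), atol=1e-9)

    def test_empty_stratum_named(self):
        space = _space(n=4)
        demo = pd.DataFrame({"g": ["x", "x", "x", "y"]})
        with pytest.raises(ValueError, match="g=y"):
            average_person_vector(space, demographics=demo, stratify_by=["g"])


class TestCentroidDistance:
    def test_observation_at_centroid_distance_zero(self):
        space = _space()
        c = average_person_vector(space)
        d = distance_from_centroid(space, c)
        norms = np.linalg.norm(space.values - c.standardized, axis=1)
        np.testing.assert_allclose(d.to_numpy(), norms, atol=1e-12)

    def test_global_distance_is_row_norm(self, small_sim):
        cohort, _, _ = small_sim
        space = build_space(cohort)
        c = average_person_vector(space)
        d = distance_from_centroid(space, c)
        np.testing.assert_allclose(
            d.to_numpy(), np.linalg.norm(space.values, axis=1), atol=1e-8
        )

    def test_dimension_mismatch_errors(self):
        space = _space(p=4)
        c = average_person_vector(_space(p=5, seed=1))
        with pytest.raises(ValueError, match="mismatch"):
            distance_from_centroid(space, c)

    def test_dominance_monotonicity_500_cases(self, small_sim):
        """For rows deviating nonnegatively from the centroid, raising any
        raw item strictly increases the centroid distance."""
        cohort, _, _ = small_sim
        space = build_space(cohort)
        rng = np.random.default_rng(12)
        n_items = sum(1 for f in space.spec.features if f.kind == "item")
        for _ in range(500):
            dev = np.zeros(space.n_features)
            dev[:n_items] = rng.uniform(0.0, 2.0, size=n_items)
            row_raw = space.mean + dev * space.scale  # all deviations >= 0
            j = int(rng.integers(0, n_items))
            bumped = row_raw.copy()
            bumped[j] += 1.0
            d0 = np.linalg.norm(space.project(row_raw))
            d1 = np.linalg.norm(space.project(bumped))
            assert d1 > d0


class TestRose:
    def test_shape_determinism_and_segments(self, medium_sim):
        cohort, _, scale_map = medium_sim
        space = build_space(cohort)
        c = average_person_vector(space)
        d = distance_from_centroid(space, c)
        _, status = score_cohort(cohort, scale_map)
        rose1 = rose_data(d, status, "oppositional_defiant", n_sample=10, seed=4)
        rose2 = rose_data(d, status, "oppositional_defiant", n_sample=10, seed=4)
        pd.testing.assert_frame_equal(rose1, rose2)
        assert rose1["person_id"].nunique() == 10
        # each sampled person contributes every timepoint, in order
        per = rose1.groupby("person_id")["timepoint"].apply(list)
        assert all(tps == [1, 2, 3, 4] for tps in per)

    def test_warns_when_fewer_than_requested(self, small_sim):
        cohort, _, scale_map = small_sim
        space = build_space(cohort)
        c = average_person_vector(space)
        d = distance_from_centroid(space, c)
        _, status = score_cohort(cohort, scale_map)
        n_elig = int(status.at_timepoint(1).elevated["somatic_problems"].sum())
        with pytest.warns(UserWarning, match="sampling all"):
            rose = rose_data(d, status, "somatic_problems", n_sample=n_elig + 5, seed=0)
        assert rose["person_id"].nunique() == n_elig


class TestSeverityRegression:
    def _obs_index(self, n):
        return pd.MultiIndex.from_arrays(
            [[f"p{i}" for i in range(n)], [1] * n], names=["person_id", "timepoint"]
        )

    def test_noiseless_linear_recovers_slope_exactly(self):
        idx = self._obs_index(50)
        counts = pd.Series(np.arange(50) % 5, index=idx, dtype=float)
        dist = pd.Series(2.5 * counts.to_numpy() + 1.0, index=idx)
        reg = severity_regression(dist, counts)
        assert reg.slope == pytest.approx(2.5, abs=1e-8)
        assert reg.intercept == pytest.approx(1.0, abs=1e-8)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_simulated_cohort_positive_slope(self, medium_sim):
        cohort, _, scale_map = medium_sim
        space = build_space(cohort)
        c = average_person_vector(space)
        d = distance_from_centroid(space, c)
        _, status = score_cohort(cohort, scale_map)
        reg = severity_regression(d, status.n_diagnoses)
        assert reg.slope > 0
        assert reg.p_value < 0.001
        assert reg.adj_r_squared <= reg.r_squared

    def test_permutation_null_contains_shuffled_t(self, medium_sim):
        """With shuffled counts the t statistic behaves like the null."""
        cohort, _, scale_map = medium_sim
        space = build_space(cohort)
        c = average_person_vector(space)
        d = distance_from_centroid(space, c)
        _, status = score_cohort(cohort, scale_map)
        rng = np.random.default_rng(21)
        shuffled = pd.Series(
            rng.permutation(status.n_diagnoses.to_numpy()), index=d.index
        )
        t_obs = severity_regression(d, shuffled).t_value
        # permutation oracle: distribution of t under random pairing
        t_null = []
        dvals = d.to_numpy()
        cvals = status.n_diagnoses.to_numpy().astype(float)
        for _ in range(999):
            perm = rng.permutation(cvals)
            r = np.corrcoef(dvals, perm)[0, 1]
            n = len(dvals)
            t_null.append(r * np.sqrt((n - 2) / (1 - r**2)))
        lo, hi = np.quantile(t_null, [0.005, 0.995])
        assert lo <= t_obs <= hi

    def test_zero_variance_predictor_errors(self):
        idx = self._obs_index(20)
        d = pd.Series(np.arange(20.0), index=idx)
        with pytest.raises(ValueError, match="variance"):
            severity_regression(d, pd.Series(1.0, index=idx))


class TestDistanceSeverityCorrelation:
    def test_identity_gives_r_one(self):
        idx = pd.MultiIndex.from_arrays(
            [[f"p{i}" for i in range(20)], [1] * 20], names=["person_id", "timepoint"]
        )
        s = pd.Series(np.arange(20.0), index=idx)
        out = distance_severity_correlation(s, s)
        assert out.r == pytest.approx(1.0)
        assert out.slope == pytest.approx(1.0)

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(3)
        idx = pd.MultiIndex.from_arrays(
            [[f"p{i}" for i in range(1000)], [1] * 1000],
            names=["person_id", "timepoint"],
        )
        a = pd.Series(rng.normal(size=1000), index=idx)
        b = pd.Series(rng.normal(size=1000), index=idx)
        assert abs(distance_severity_correlation(a, b).r) < 0.1


class TestPersonSeverityIndex:
    def test_static_person_index_equals_observation_distance(self, small_sim):
        cohort, _, _ = small_sim
        space = build_space(cohort)
        idx = person_severity_index(space)
        assert set(idx.index) == set(cohort["person_id"].unique())
        # index of a person is the norm of their mean standardized row
        frame = space.to_frame()
        pid = idx.index[0]
        manual = np.linalg.norm(frame.xs(pid, level="person_id").mean(axis=0))
        assert idx.loc[pid] == pytest.approx(manual, abs=1e-10)
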