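"""Trajectory bookkeeping and boundary-crossing detection."""

import numpy as np
import pandas as pd
import pytest

from hdss.embedding import Embedding2D, LinearBoundary
from hdss.space import build_space
from hdss.trajectories import (
    build_trajectories,
    detect_transitions,
    step_displacements,
)


def _embedding(coords: dict) -> Embedding2D:
    """coords: {(person, timepoint): (x, y)}"""
    idx = pd.MultiIndex.from_tuples(list(coords), names=["person_id", "timepoint"])
    frame = pd.DataFrame(list(coords.values()), index=idx, columns=["dim1", "dim2"])
    return Embedding2D(coords=frame, stress=0.0, n_iter=0, seed=0, converged=True)


def _series(values: dict, name="v") -> pd.Series:
    idx = pd.MultiIndex.from_tuples(list(values), names=["person_id", "timepoint"])
    return pd.Series(list(values.values()), index=idx, name=name)


# boundary: clinical iff x < 0 (coefficients point toward negative x)
X_NEG_CLINICAL = LinearBoundary(
    intercept=0.0, coefficients=np.array([-4.0, 0.0]), threshold=0.5,
    training_accuracy=1.0,
)


class TestBuild:
    def _simple(self):
        coords = {}
        for t in range(1, 5):
            coords[("a", t)] = (1.0, 1.0)  # static person
            coords[("b", t)] = (float(t), 0.0)  # moving person
        emb = _embedding(coords)
        clin = _series({k: k[0] == "a" for k in coords})
        cdist = _series({k: float(k[1]) for k in coords})
        return emb, clin, cdist

    def test_four_timepoints_three_steps(self):
        emb, clin, cdist = self._simple()
        trajs = build_trajectories(emb, clin, cdist)
        assert len(trajs) == 2
        for traj in trajs:
            assert len(step_displacements(traj)) == 3

    def test_static_person_zero_displacement(self):
        emb, clin, cdist = self._simple()
        trajs = build_trajectories(emb, clin, cdist)
        a = next(t for t in trajs if t.person_id == "a")
        np.testing.assert_allclose(step_displacements(a), 0.0)

    def test_union_of_points_equals_embedding_rows(self):
        emb, clin, cdist = self._simple()
        trajs = build_trajectories(emb, clin, cdist)
        seen = {(t.person_id, tp) for t in trajs for tp in t.timepoints}
        assert seen == set(emb.coords.index)

    def test_duplicate_observation_rejected(self):
        idx = pd.MultiIndex.from_tuples(
            [("a", 1), ("a", 1)], names=["person_id", "timepoint"]
        )
        frame = pd.DataFrame([[0.0, 0.0]] * 2, index=idx, columns=["dim1", "dim2"])
        emb = Embedding2D(coords=frame, stress=0, n_iter=0, seed=0, converged=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_trajectories(emb, _series({("a", 1): True}), _series({("a", 1): 0.0}))


class TestFullSpaceDisplacement:
    def test_single_item_change_is_one_standardized_unit(self, small_sim):
        """A one-point change on one item moves a person by 1/sigma_item."""
        cohort, _, _ = small_sim
        # plant: person 0 changes item_001 by one point between tp 1 and 2
        mod = cohort.copy()
        pid = mod["person_id"].iloc[0]
        sel = (mod["person_id"] == pid) & (mod["timepoint"] == 2)
        base = (mod["person_id"] == pid) & (mod["timepoint"] == 1)
        for c in mod.columns:
            if c.startswith("item_"):
                mod.loc[sel, c] = mod.loc[base, c].to_numpy()
        mod.loc[sel, "age"] = mod.loc[base, "age"].to_numpy()
        mod.loc[sel, "item_001"] = min(int(mod.loc[base, "item_001"].iloc[0]) + 1, 2)
        delta = int(mod.loc[sel, "item_001"].iloc[0]) - int(
            mod.loc[base, "item_001"].iloc[0]
        )
        space = build_space(mod)
        j = space.feature_names.index("item_001")
        row1 = space.to_frame().loc[(pid, 1)].to_numpy()
        row2 = space.to_frame().loc[(pid, 2)].to_numpy()
        expected = abs(delta) / space.scale[j]
        assert np.linalg.norm(row2 - row1) == pytest.approx(expected, rel=1e-9)


class TestTransitions:
    def test_static_cohort_no_events(self):
        coords = {("a", t): (2.0, 0.0) for t in range(1, 5)}
        emb = _embedding(coords)
        trajs = build_trajectories(
            emb, _series({k: False for k in coords}), _series({k: 0.0 for k in coords})
        )
        assert detect_transitions(trajs, X_NEG_CLINICAL) == []

    def test_single_planted_crossing(self):
        # person starts clinical (x<0), crosses at step 2->3
        coords = {("a", 1): (-2.0, 0.0), ("a", 2): (-1.0, 0.0),
                  ("a", 3): (1.0, 0.0), ("a", 4): (2.0, 0.0)}
        emb = _embedding(coords)
        trajs = build_trajectories(
            emb, _series({k: True for k in coords}), _series({k: 0.0 for k in coords})
        )
        events = detect_transitions(trajs, X_NEG_CLINICAL)
        assert len(events) == 1
        assert events[0].direction == "improved"
        assert (events[0].from_timepoint, events[0].to_timepoint) == (2, 3)

    def test_out_and_back_two_opposite_events(self):
        coords = {("a", 1): (-1.0, 0.0), ("a", 2): (1.0, 0.0), ("a", 3): (-1.0, 0.0)}
        emb = _embedding(coords)
        trajs = build_trajectories(
            emb, _series({k: True for k in coords}), _series({k: 0.0 for k in coords})
        )
        events = detect_transitions(trajs, X_NEG_CLINICAL)
        assert [e.direction for e in events] == ["improved", "worsened"]

    def test_event_count_matches_label_diff_oracle(self):
        rng = np.random.default_rng(8)
        coords = {}
        for i in range(40):
            for t in range(1, 5):
                coords[(f"p{i:02d}", t)] = tuple(rng.normal(size=2))
        emb = _embedding(coords)
        trajs = build_trajectories(
            emb, _series({k: False for k in coords}), _series({k: 0.0 for k in coords})
        )
        events = detect_transitions(trajs, X_NEG_CLINICAL)
        # oracle: count label changes directly from the raw coordinates
        expected = 0
        for i in range(40):
            labels = [coords[(f"p{i:02d}", t)][0] < 0 for t in range(1, 5)]
            expected += sum(a != b for a, b in zip(labels, labels[1:]))
        assert len(events) == expected

    def test_by_tscore_uses_stored_flags(self):
        coords = {("a", 1): (5.0, 0.0), ("a", 2): (5.0, 0.0)}
        emb = _embedding(coords)
        clin = _series({("a", 1): True, ("a", 2): False})
        trajs = build_trajectories(emb, clin, _series({k: 0.0 for k in coords}))
        events = detect_transitions(trajs, by_tscore=True)
        assert len(events) == 1 and events[0].direction == "improved"
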