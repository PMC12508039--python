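"""Per-person trajectories through the common space and boundary crossings.

Because every timepoint's observations share one standardized space and one
joint embedding, a person's assessments form an ordered path.  Step
displacements quantify symptom change; crossings of the fitted clinical
boundary mark improvement (clinical -> non-clinical) or worsening
(non-clinical -> clinical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import Embedding2D, LinearBoundary, classify_region
from .space import StandardizedSpace


@dataclass
class Trajectory:
    """One person's ordered path through the common space."""

    person_id: str
    timepoints: list[int]
    coords: np.ndarray  # (T, n_components), joint-embedding coordinates
    centroid_distances: np.ndarray  # (T,), full-space distances
    clinical: np.ndarray  # (T,) bool
    n_diagnoses: np.ndarray  # (T,) int

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)


@dataclass(frozen=True)
class TransitionEvent:
    """A boundary crossing between consecutive timepoints."""

    person_id: str
    from_timepoint: int
    to_timepoint: int
    direction: str  # "improved" | "worsened"


def build_trajectories(
    embedding: Embedding2D,
    clinical: pd.Series,
    centroid_distances: pd.Series,
    n_diagnoses: pd.Series | None = None,
) -> list[Trajectory]:
    """Assemble one trajectory per person from the joint embedding.

    ``clinical``, ``centroid_distances`` and ``n_diagnoses`` are
    observation-indexed series aligned to the embedding.  Persons are
    returned in sorted order; duplicate observations are an error.
    """
    coords = embedding.coords
    if coords.index.duplicated().any():
        dup = coords.index[coords.index.duplicated()][0]
        raise ValueError(f"duplicate (person_id, timepoint) in embedding: {dup}")
    clinical = clinical.reindex(coords.index)
    centroid_distances = centroid_distances.reindex(coords.index)
    if n_diagnoses is None:
        n_diagnoses = pd.Series(0, index=coords.index)
    else:
        n_diagnoses = n_diagnoses.reindex(coords.index)
    out: list[Trajectory] = []
    for pid in sorted(coords.index.get_level_values("person_id").unique()):
        sub = coords.xs(pid, level="person_id").sort_index()
        tps = [int(t) for t in sub.index]
        key = [(pid, t) for t in tps]
        out.append(
            Trajectory(
                person_id=pid,
                timepoints=tps,
                coords=sub.to_numpy(),
                centroid_distances=centroid_distances.loc[key].to_numpy(dtype=float),
                clinical=clinical.loc[key].to_numpy(dtype=bool),
                n_diagnoses=n_diagnoses.loc[key].to_numpy(dtype=int),
            )
        )
    return out


def step_displacements(
    traj: Trajectory,
    *,
    metric: str = "embedded",
    space: StandardizedSpace | None = None,
) -> np.ndarray:
    """Euclidean distance between consecutive positions of one person.

    ``metric="embedded"`` uses the 2-D coordinates; ``metric="fullspace"``
    uses the standardized high-dimensional rows (requires ``space``).  Note
    the embedded displacement is an MDS approximation and is neither an
    upper nor a lower bound on the full-space displacement.
    """
    if traj.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if metric == "embedded":
        diffs = np.diff(traj.coords, axis=0)
        return np.sqrt((diffs**2).sum(axis=1))
    if metric == "fullspace":
        if space is None:
            raise ValueError("fullspace metric requires the standardized space")
        rows = space.to_frame().loc[[(traj.person_id, t) for t in traj.timepoints]]
        diffs = np.diff(rows.to_numpy(), axis=0)
        return np.sqrt((diffs**2).sum(axis=1))
    raise ValueError(f"unknown metric {metric!r}")


def detect_transitions(
    trajectories: list[Trajectory],
    boundary: LinearBoundary | None = None,
    *,
    by_tscore: bool = False,
) -> list[TransitionEvent]:
    """Boundary crossings between consecutive timepoints, per person.

    By default a person's clinical label at each timepoint comes from the
    fitted boundary's region (the geometric reading); ``by_tscore=True``
    uses the stored T-score-based clinical flags instead.
    """
    if not by_tscore and boundary is None:
        raise ValueError("either supply a boundary or set by_tscore=True")
    events: list[TransitionEvent] = []
    for traj in trajectories:
        if by_tscore:
            labels = traj.clinical
        else:
            labels, _ = classify_region(boundary, traj.coords[:, :2])
        for k in range(len(labels) - 1):
            if labels[k] == labels[k + 1]:
                continue
            direction = "improved" if labels[k] else "worsened"
            events.append(
                TransitionEvent(
                    person_id=traj.person_id,
                    from_timepoint=traj.timepoints[k],
                    to_timepoint=traj.timepoints[k + 1],
                    direction=direction,
                )
            )
    return events


def trajectories_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories to a tidy observation-per-row table."""
    rows = []
    for traj in trajectories:
        for k, tp in enumerate(traj.timepoints):
            rec = {"person_id": traj.person_id, "timepoint": tp}
            for d in range(traj.coords.shape[1]):
                rec[f"dim{d + 1}"] = traj.coords[k, d]
            rec["centroid_distance"] = traj.centroid_distances[k]
            rec["clinical"] = bool(traj.clinical[k])
            rec["n_diagnoses"] = int(traj.n_diagnoses[k])
            rows.append(rec)
    return pd.DataFrame(rows)


def events_frame(events: list[TransitionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person_id": e.person_id,
                "from_timepoint": e.from_timepoint,
                "to_timepoint": e.to_timepoint,
                "direction": e.direction,
            }
            for e in events
        ],
        columns=["person_id", "from_timepoint", "to_timepoint", "direction"],
    )
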