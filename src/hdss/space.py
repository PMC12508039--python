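"""Standardized symptom space and its Euclidean distance geometry.

Every feature of the raw design matrix is z-scored (mean 0, SD 1 with the
population convention) over the pooled person-timepoint observations, so
that all timepoints live in one comparable space and each feature
contributes a single, equally weighted dimension.  Dissimilarity between
observations is plain Euclidean distance in that space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortEncoder, FeatureSpec


class SpaceStandardizer(BaseEstimator, TransformerMixin):
    """Per-feature z-scoring with the population-SD convention.

    Unlike a generic scaler this transformer implements the symptom-space
    standardization contract: SDs divide by n (not n-1), constant raw
    features map to all-zero columns and are flagged rather than erroring,
    and the fitted (mean, scale) pair makes the transform exactly
    invertible for non-constant features.

    Attributes
    ----------
    mean_ : ndarray of shape (n_features,)
        Raw per-feature means.
    scale_ : ndarray of shape (n_features,)
        Raw per-feature population SDs (1.0 stored for constant features).
    constant_mask_ : ndarray of bool
        True for features with zero raw variance.
    """

    def fit(self, X, y=None) -> "SpaceStandardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        if X.shape[0] < 2:
            raise ValueError(
                "standardization requires at least 2 observations (SD undefined)"
            )
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.constant_mask_ = sd == 0.0
        self.scale_ = np.where(self.constant_mask_, 1.0, sd)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        if self.constant_mask_.any():
            Z[:, self.constant_mask_] = 0.0
        return Z

    def inverse_transform(self, Z) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        X = Z * self.scale_ + self.mean_
        if self.constant_mask_.any():
            X[:, self.constant_mask_] = self.mean_[self.constant_mask_]
        return X


@dataclass
class StandardizedSpace:
    """The symptom space: standardized observations plus frozen parameters.

    ``values`` holds the standardized matrix (observations x features);
    ``mean``/``scale`` are the frozen raw-space normalization parameters so
    new raw observations can be projected into the same space.
    """

    values: np.ndarray
    index: pd.MultiIndex
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray
    spec: FeatureSpec | None = None
    raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.index):
            raise ValueError("observation index length does not match matrix rows")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature name count does not match matrix columns")

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def project(self, raw_rows: np.ndarray) -> np.ndarray:
        """Project raw-space rows into the space with the frozen (mean, SD)."""
        raw_rows = np.atleast_2d(np.asarray(raw_rows, dtype=float))
        if raw_rows.shape[1] != self.n_features:
            raise ValueError(
                f"dimension mismatch: got {raw_rows.shape[1]} features, "
                f"space has {self.n_features}"
            )
        Z = (raw_rows - self.mean) / self.scale
        Z[:, self.constant_mask] = 0.0
        return Z

    def unproject(self, standardized_rows: np.ndarray) -> np.ndarray:
        """Invert :meth:`project` (constant features return their raw mean)."""
        Z = np.atleast_2d(np.asarray(standardized_rows, dtype=float))
        X = Z * self.scale + self.mean
        X[:, self.constant_mask] = self.mean[self.constant_mask]
        return X

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index, columns=self.feature_names)


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean dissimilarities between observations."""

    values: np.ndarray
    index: pd.MultiIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(self.index) != n:
            raise ValueError("index length does not match matrix size")

    def validate(self, atol: float = 1e-8) -> None:
        d = self.values
        if not np.allclose(d, d.T, atol=atol):
            raise ValueError("distance matrix is not symmetric")
        if (d < -atol).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(d), 0.0, atol=atol):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def positions(self, labels) -> np.ndarray:
        """Integer row positions of the given observation labels."""
        return self.index.get_indexer(labels)

    def to_frame(self) -> pd.DataFrame:
        flat = [f"{p}|{t}" for p, t in self.index]
        return pd.DataFrame(self.values, index=flat, columns=flat)


def euclidean_distance(u, v) -> float:
    """Euclidean distance sqrt(sum_k (u_k - v_k)^2) between two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def pairwise_distances(space: StandardizedSpace, *, use_raw: bool = False) -> DistanceMatrix:
    """All pairwise Euclidean distances between observations of the space.

    Distances are computed in standardized coordinates; ``use_raw=True``
    computes them on the stored raw matrix instead (diagnostics only).
    """
    if space.n_observations < 1:
        raise ValueError("empty space")
    if use_raw:
        if space.raw is None:
            raise ValueError("raw matrix not stored on this space")
        X = space.raw
    else:
        X = space.values
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(values=d, index=space.index)


def build_space(
    cohort: pd.DataFrame,
    *,
    demographics: str = "onehot",
    include_demographics: bool = True,
    keep_raw: bool = True,
) -> StandardizedSpace:
    """Encode and standardize a cohort into its symptom space.

    Fits the feature encoding and the normalization over ALL pooled
    person-timepoint observations, so every timepoint lives in the same
    standardized space.
    """
    from .cohort import observation_index, validate_cohort

    cohort = validate_cohort(cohort)
    enc = CohortEncoder(
        demographics=demographics, include_demographics=include_demographics
    ).fit(cohort)
    raw = enc.transform(cohort)
    std = SpaceStandardizer().fit(raw)
    return StandardizedSpace(
        values=std.transform(raw),
        index=observation_index(cohort),
        feature_names=enc.spec_.names,
        mean=std.mean_,
        scale=std.scale_,
        constant_mask=std.constant_mask_,
        spec=enc.spec_,
        raw=raw if keep_raw else None,
    )


def standardize(raw: np.ndarray, index: pd.MultiIndex | None = None) -> StandardizedSpace:
    """Standardize a raw feature matrix into a :class:`StandardizedSpace`."""
    raw = np.asarray(raw, dtype=float)
    std = SpaceStandardizer().fit(raw)
    if index is None:
        index = pd.MultiIndex.from_arrays(
            [[f"obs_{i}" for i in range(raw.shape[0])], [1] * raw.shape[0]],
            names=["person_id", "timepoint"],
        )
    names = [f"f{k}" for k in range(raw.shape[1])]
    return StandardizedSpace(
        values=std.transform(raw),
        index=index,
        feature_names=names,
        mean=std.mean_,
        scale=std.scale_,
        constant_mask=std.constant_mask_,
        raw=raw,
    )


HITOP_SCALE_ORDER = (
    "total_problems",
    "internalizing",
    "externalizing",
    "attention_problems",
    "somatic_complaints",
)


def build_scale_space(
    tscores: pd.DataFrame, scale_columns: tuple[str, ...] = HITOP_SCALE_ORDER
) -> StandardizedSpace:
    """Five-dimensional scale-score space from broad-band T-scores.

    ``tscores`` is an observation-indexed frame with one column per broad
    scale (total problems, internalizing, externalizing, attention,
    somatic).  Each scale is standardized and the result behaves exactly
    like the item-level space — the low-dimensional counterpart used to
    relate centroid distance to overall severity.
    """
    missing = [c for c in scale_columns if c not in tscores.columns]
    if missing:
        raise ValueError(f"missing scale column(s): {missing}")
    raw = tscores[list(scale_columns)].to_numpy(dtype=float)
    std = SpaceStandardizer().fit(raw)
    index = tscores.index
    if not isinstance(index, pd.MultiIndex):
        raise ValueError("tscores must be indexed by (person_id, timepoint)")
    return StandardizedSpace(
        values=std.transform(raw),
        index=index,
        feature_names=list(scale_columns),
        mean=std.mean_,
        scale=std.scale_,
        constant_mask=std.constant_mask_,
        raw=raw,
    )
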