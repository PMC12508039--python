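"""2-D common space via metric MDS and the logistic clinical boundary.

The joint distance matrix over all person-timepoint observations is
embedded into two dimensions with metric multidimensional scaling so that
embedded distances approximate the high-dimensional dissimilarities.  The
SMACOF stress-majorization solver is implemented here directly because the
embedding contract includes the per-iteration stress trajectory and its
guaranteed monotone decrease; a classical-scaling (Torgerson)
eigendecomposition provides both the deterministic alternative and the
default warm start.  A logistic regression on the two embedding dimensions
then defines the linear clinical/non-clinical frontier at p = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import eigsh
from scipy.special import expit
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .space import DistanceMatrix

_MONOTONE_SLACK = 1e-9  # relative slack for the stress-decrease assertion


def _as_matrix(dist) -> tuple[np.ndarray, pd.MultiIndex | None]:
    if isinstance(dist, DistanceMatrix):
        dist.validate()
        return dist.values, dist.index
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance input must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix has negative entries")
    return D, None


def raw_stress(X: np.ndarray, D: np.ndarray) -> float:
    """Raw stress: sum over pairs of (embedded distance - target distance)^2."""
    d = pdist(X)
    delta = squareform(D, checks=False)
    return float(np.sum((d - delta) ** 2))


def classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers the squared distances and takes the top eigenpairs.
    Deterministic; exact when the distances are realizable in
    ``n_components`` dimensions.
    """
    n = D.shape[0]
    D2 = D**2
    # B = -0.5 J D^2 J without forming J explicitly
    row = D2.mean(axis=1, keepdims=True)
    B = -0.5 * (D2 - row - row.T + D2.mean())
    B = (B + B.T) / 2.0
    if n > 400:
        vals, vecs = eigsh(B, k=n_components, which="LA", v0=np.ones(n) / np.sqrt(n))
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    else:
        vals, vecs = np.linalg.eigh(B)
        vals, vecs = vals[::-1][:n_components], vecs[:, ::-1][:, :n_components]
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def smacof_single(
    D: np.ndarray,
    init: np.ndarray,
    *,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, list[float], bool]:
    """One SMACOF run from a given initial configuration.

    Iterates the Guttman transform; stress is guaranteed nonincreasing and
    is asserted so on every run.  Stops when the relative stress decrease
    falls below ``tol``.  Returns (coordinates, stress history, converged).
    """
    n = D.shape[0]
    X = np.array(init, dtype=float, copy=True)
    delta = squareform(D, checks=False)  # condensed target distances
    d = pdist(X)
    history = [float(np.sum((d - delta) ** 2))]
    converged = False
    ratio = np.empty_like(delta)
    for _ in range(max_iter):
        # Guttman transform, condensed form: X <- (diag(rowsum) - W) X / n
        nz = d > 0
        np.divide(delta, d, out=ratio, where=nz)
        ratio[~nz] = 0.0
        W = squareform(ratio, checks=False)
        rowsum = W.sum(axis=1)
        X = (rowsum[:, None] * X - W @ X) / n
        d = pdist(X)
        s = float(np.sum((d - delta) ** 2))
        prev = history[-1]
        if not (s <= prev * (1.0 + _MONOTONE_SLACK) + 1e-12):
            raise AssertionError(
                f"SMACOF stress increased: {prev} -> {s} (majorization violated)"
            )
        history.append(s)
        if prev == 0.0 or (prev - s) / prev < tol:
            converged = True
            break
    return X, history, converged


@dataclass
class Embedding2D:
    """Joint low-dimensional coordinates of all observations."""

    coords: pd.DataFrame  # observation-indexed, columns dim1..dimK
    stress: float
    n_iter: int
    seed: int | None
    converged: bool
    stress_history: list[float] | None = None

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


class MDSEmbedding(BaseEstimator):
    """Metric MDS estimator (SMACOF with restarts, or classical scaling).

    Parameters
    ----------
    n_components : int, default 2
        Output dimensionality.
    method : {"smacof", "classical"}, default "smacof"
        SMACOF minimizes raw stress by majorization; classical scaling is
        the deterministic eigendecomposition (no restarts, no iterations).
    n_init : int, default 4
        SMACOF restarts.  The first start is the classical-scaling
        configuration (a strong warm start); the rest are random.  The
        lowest-stress solution is kept.
    max_iter, tol : SMACOF stopping rule (relative stress decrease).
    random_state : seed for the random restarts.

    Attributes
    ----------
    embedding_ : ndarray (n, n_components), column-centered coordinates.
    stress_ : float, final raw stress.
    stress_history_ : per-iteration stress of the winning run.
    n_iter_ : iterations of the winning run.
    converged_ : whether the winning run met the tolerance.
    """

    def __init__(
        self,
        n_components: int = 2,
        method: str = "smacof",
        n_init: int = 4,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.method = method
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, dist, y=None) -> "MDSEmbedding":
        D, index = _as_matrix(dist)
        n = D.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 observations, got {n}")
        self.index_ = index
        if self.method == "classical":
            X = classical_mds(D, self.n_components)
            self.embedding_ = X - X.mean(axis=0)
            self.stress_ = raw_stress(self.embedding_, D)
            self.stress_history_ = [self.stress_]
            self.n_iter_ = 0
            self.converged_ = True
            return self
        if self.method != "smacof":
            raise ValueError(f"unknown MDS method {self.method!r}")

        rng = np.random.default_rng(self.random_state)
        scale = D[D > 0].mean() if (D > 0).any() else 1.0
        best: tuple[float, np.ndarray, list[float], bool] | None = None
        for k in range(self.n_init):
            if k == 0:
                init = classical_mds(D, self.n_components)
            else:
                init = rng.normal(scale=scale, size=(n, self.n_components))
            X, hist, conv = smacof_single(
                D, init, max_iter=self.max_iter, tol=self.tol
            )
            if best is None or hist[-1] < best[0]:
                best = (hist[-1], X, hist, conv)
        assert best is not None
        _, X, hist, conv = best
        self.embedding_ = X - X.mean(axis=0)
        self.stress_ = hist[-1]
        self.stress_history_ = hist
        self.n_iter_ = len(hist) - 1
        self.converged_ = conv
        return self

    def fit_transform(self, dist, y=None) -> np.ndarray:
        return self.fit(dist).embedding_


def mds_embed(
    dist,
    n_components: int = 2,
    *,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
    method: str = "smacof",
    n_init: int = 4,
) -> Embedding2D:
    """Embed a distance matrix into a low-dimensional common space."""
    est = MDSEmbedding(
        n_components=n_components,
        method=method,
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(dist)
    if est.index_ is not None:
        index = est.index_
    else:
        D, _ = _as_matrix(dist)
        index = pd.MultiIndex.from_arrays(
            [[f"obs_{i}" for i in range(D.shape[0])], [1] * D.shape[0]],
            names=["person_id", "timepoint"],
        )
    coords = pd.DataFrame(
        est.embedding_,
        index=index,
        columns=[f"dim{k + 1}" for k in range(n_components)],
    )
    return Embedding2D(
        coords=coords,
        stress=est.stress_,
        n_iter=est.n_iter_,
        seed=seed,
        converged=est.converged_,
        stress_history=est.stress_history_,
    )


class ClinicalBoundary(BaseEstimator, ClassifierMixin):
    """Logistic clinical/non-clinical classifier on embedding coordinates.

    A tiny ridge penalty (1e-8) keeps the maximum-likelihood fit finite on
    perfectly separable embeddings.  The decision boundary is the straight
    line where the predicted probability equals ``threshold``; a point
    exactly on the line is classified clinical (conservative tie rule).
    """

    def __init__(self, threshold: float = 0.5, ridge: float = 1e-8):
        self.threshold = threshold
        self.ridge = ridge

    def fit(self, X, y) -> "ClinicalBoundary":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        if len(np.unique(y)) < 2:
            raise ValueError("clinical labels contain a single class")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        self._lr = LogisticRegression(
            C=1.0 / self.ridge, solver="lbfgs", max_iter=10_000, tol=1e-10
        ).fit(X, y.astype(int))
        self.intercept_ = float(self._lr.intercept_[0])
        self.coef_ = self._lr.coef_[0].copy()
        self.classes_ = np.array([False, True])
        self.training_accuracy_ = float(np.mean(self.predict(X) == y))
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1] >= self.threshold


@dataclass
class LinearBoundary:
    """The fitted clinical frontier: a line in embedding coordinates."""

    intercept: float
    coefficients: np.ndarray
    threshold: float
    training_accuracy: float

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the boundary line (points toward clinical)."""
        c = np.asarray(self.coefficients, dtype=float)
        return c / np.linalg.norm(c)


def fit_clinical_boundary(
    embedding: Embedding2D, clinical: pd.Series | np.ndarray, *, threshold: float = 0.5
) -> LinearBoundary:
    """Fit the logistic clinical boundary on the first two dimensions."""
    X = embedding.coords.iloc[:, :2].to_numpy()
    if isinstance(clinical, pd.Series):
        clinical = clinical.reindex(embedding.coords.index).to_numpy()
    est = ClinicalBoundary(threshold=threshold).fit(X, np.asarray(clinical, dtype=bool))
    return LinearBoundary(
        intercept=est.intercept_,
        coefficients=est.coef_,
        threshold=threshold,
        training_accuracy=est.training_accuracy_,
    )


def classify_region(
    boundary: LinearBoundary, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Clinical-region labels and probabilities for arbitrary 2-D points.

    Probability is the logistic of the linear score; the label is True
    (clinical) when probability >= threshold, including exactly on the
    boundary line.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    score = pts @ np.asarray(boundary.coefficients, dtype=float) + boundary.intercept
    proba = expit(score)
    return proba >= boundary.threshold, proba
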