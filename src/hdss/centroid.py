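"""Centroid analysis: the average person vector and distances from it.

The centroid (feature-wise mean vector of a cohort or of a demographic
stratum) acts as a dynamically normed reference point: each observation's
Euclidean distance from it is a severity-like index that grows with the
endorsement of more, or more deviant, symptoms.  This module also provides
the rose-diagram data (seeded per-disorder samples of per-timepoint
centroid distances) and the distance-vs-severity regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scoring import ClinicalStatus
from .space import StandardizedSpace


@dataclass
class CentroidVector:
    """Average person vector of a cohort or demographic stratum."""

    raw: np.ndarray
    standardized: np.ndarray
    stratum: str  # "global" or "col=val/..." label
    n_observations: int
    feature_names: list[str]


def _stratum_label(keys: tuple[str, ...], values) -> str:
    values = values if isinstance(values, tuple) else (values,)
    return "/".join(f"{k}={v}" for k, v in zip(keys, values))


def average_person_vector(
    space: StandardizedSpace,
    *,
    demographics: pd.DataFrame | None = None,
    stratify_by: list[str] | None = None,
) -> CentroidVector | dict[str, CentroidVector]:
    """The average person vector, globally or per demographic stratum.

    With ``stratify_by``, ``demographics`` must be an observation-aligned
    frame holding the stratification columns; one centroid is returned per
    observed combination.  Raw and standardized representations are both
    stored; the global centroid of the space it was fitted on is the zero
    vector in standardized coordinates.
    """
    if stratify_by is None:
        z = space.values.mean(axis=0)
        return CentroidVector(
            raw=space.unproject(z)[0],
            standardized=z,
            stratum="global",
            n_observations=space.n_observations,
            feature_names=space.feature_names,
        )
    if demographics is None:
        raise ValueError("stratify_by requires a demographics frame")
    missing = [c for c in stratify_by if c not in demographics.columns]
    if missing:
        raise ValueError(f"demographics frame missing column(s): {missing}")
    if len(demographics) != space.n_observations:
        raise ValueError("demographics frame must align with the space's observations")

    keys = tuple(stratify_by)
    out: dict[str, CentroidVector] = {}
    grouped = demographics.reset_index(drop=True).groupby(list(keys), observed=True)
    for values, sub in grouped:
        label = _stratum_label(keys, values)
        if len(sub) < 2:
            raise ValueError(f"stratum {label!r} has fewer than 2 observations")
        z = space.values[sub.index.to_numpy()].mean(axis=0)
        out[label] = CentroidVector(
            raw=space.unproject(z)[0],
            standardized=z,
            stratum=label,
            n_observations=len(sub),
            feature_names=space.feature_names,
        )
    return out


def distance_from_centroid(
    space: StandardizedSpace,
    centroid: CentroidVector,
    *,
    restrict_to_stratum: bool = False,
    demographics: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-observation Euclidean distance from a centroid.

    With ``restrict_to_stratum`` only the centroid's own stratum members
    are scored — the dynamic-norming rule under which each person is
    compared to the average of people sharing their demographic profile.
    """
    if len(centroid.standardized) != space.n_features:
        raise ValueError(
            f"dimension mismatch: centroid has {len(centroid.standardized)} "
            f"features, space has {space.n_features}"
        )
    diffs = space.values - centroid.standardized
    d = np.sqrt(np.sum(diffs**2, axis=1))
    out = pd.Series(d, index=space.index, name="centroid_distance")
    if restrict_to_stratum and centroid.stratum != "global":
        if demographics is None:
            raise ValueError("restrict_to_stratum requires a demographics frame")
        mask = np.ones(space.n_observations, dtype=bool)
        for part in centroid.stratum.split("/"):
            col, val = part.split("=", 1)
            mask &= demographics[col].astype(str).to_numpy() == val
        out = out[mask]
    return out


def person_severity_index(
    space: StandardizedSpace, centroid: CentroidVector | None = None
) -> pd.Series:
    """Per-person severity index: distance of the person's mean position.

    Each person's standardized response vectors are averaged over their
    timepoints and the Euclidean distance of that time-averaged position
    from the centroid (global by default) is returned.  This is the
    person-level counterpart of the per-observation centroid distance:
    year-to-year fluctuation cancels in the mean position, so the index
    tracks a person's sustained displacement from the average person
    vector over the whole follow-up.
    """
    frame = space.to_frame()
    pmean = frame.groupby(level="person_id", sort=True).mean()
    ref = (
        np.zeros(space.n_features)
        if centroid is None
        else np.asarray(centroid.standardized, dtype=float)
    )
    d = np.sqrt(((pmean.to_numpy() - ref) ** 2).sum(axis=1))
    return pd.Series(d, index=pmean.index, name="person_severity_index")


def rose_data(
    distances: pd.Series,
    status: ClinicalStatus,
    disorder: str,
    *,
    n_sample: int = 30,
    seed: int | None = None,
    baseline_timepoint: int = 1,
) -> pd.DataFrame:
    """Rose-diagram table: sampled persons' per-timepoint centroid distances.

    Persons elevated on ``disorder`` at baseline are eligible; ``n_sample``
    of them are drawn without replacement under ``seed``.  Each person
    contributes one polar bar whose ordered segments are the centroid
    distances at each timepoint, colored by the diagnosis count there.
    """
    if disorder not in status.elevated.columns:
        raise ValueError(f"unknown disorder scale {disorder!r}")
    base = status.at_timepoint(baseline_timepoint)
    eligible = sorted(
        base.elevated.index.get_level_values("person_id")[base.elevated[disorder]]
    )
    if len(eligible) < n_sample:
        warnings.warn(
            f"only {len(eligible)} persons meet the {disorder!r} criterion at "
            f"baseline; sampling all of them",
            stacklevel=2,
        )
        chosen = list(eligible)
    else:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(eligible, size=n_sample, replace=False))
    rows = []
    for pid in chosen:
        sub = distances.xs(pid, level="person_id").sort_index()
        counts = status.n_diagnoses.xs(pid, level="person_id").sort_index()
        for tp, dist in sub.items():
            rows.append(
                {
                    "person_id": pid,
                    "timepoint": int(tp),
                    "segment_length": float(dist),
                    "diagnosis_count": int(counts.loc[tp]),
                }
            )
    return pd.DataFrame(rows, columns=["person_id", "timepoint", "segment_length", "diagnosis_count"])


@dataclass
class RegressionSummary:
    """OLS summary for the distance-vs-severity models.

    BIC uses the Gaussian-likelihood convention with the MLE variance,
    counting intercept + slopes + the variance parameter.
    """

    slopes: dict[str, float]
    intercept: float
    t_values: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    adj_r_squared: float
    bic: float
    n: int

    @property
    def slope(self) -> float:
        """The first (primary) slope."""
        return next(iter(self.slopes.values()))

    @property
    def t_value(self) -> float:
        return next(iter(self.t_values.values()))

    @property
    def p_value(self) -> float:
        return next(iter(self.p_values.values()))


def _ols_summary(y: np.ndarray, X: pd.DataFrame) -> RegressionSummary:
    design = sm.add_constant(X)
    res = sm.OLS(y, design).fit()
    names = [c for c in design.columns if c != "const"]
    n = int(res.nobs)
    # Gaussian BIC counting intercept + slopes + variance
    k = len(names) + 2
    bic = -2.0 * res.llf + np.log(n) * k
    return RegressionSummary(
        slopes={c: float(res.params[c]) for c in names},
        intercept=float(res.params["const"]),
        t_values={c: float(res.tvalues[c]) for c in names},
        p_values={c: float(res.pvalues[c]) for c in names},
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        bic=float(bic),
        n=n,
    )


def severity_regression(
    distances: pd.Series,
    diagnosis_counts: pd.Series,
    *,
    covariates: pd.DataFrame | None = None,
) -> RegressionSummary:
    """OLS of centroid distance on the DSM-proxy diagnosis count.

    Optional covariates join the design matrix; the diagnosis count remains
    the regressor of record (its slope, t and p are reported first).
    """
    d, c = distances.align(diagnosis_counts, join="inner")
    if len(d) < 10:
        raise ValueError("need at least 10 observations")
    if np.std(c.to_numpy(dtype=float)) == 0.0:
        raise ValueError("diagnosis counts have zero variance")
    X = pd.DataFrame({"n_diagnoses": c.to_numpy(dtype=float)})
    if covariates is not None:
        for col in covariates.columns:
            X[col] = covariates[col].to_numpy(dtype=float)
    return _ols_summary(d.to_numpy(dtype=float), X)


@dataclass
class CorrelationSummary:
    """Pearson correlation plus the simple-regression slope."""

    r: float
    p_value: float
    slope: float
    n: int


def distance_severity_correlation(
    distances: pd.Series, total_scores: pd.Series
) -> CorrelationSummary:
    """Pearson r (with p) and OLS slope of distance on the total score."""
    d, s = distances.align(total_scores, join="inner")
    if len(d) < 10:
        raise ValueError("need at least 10 observations")
    dv = d.to_numpy(dtype=float)
    sv = s.to_numpy(dtype=float)
    if np.std(dv) == 0.0 or np.std(sv) == 0.0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(sv, dv)
    slope = float(np.cov(sv, dv, ddof=1)[0, 1] / np.var(sv, ddof=1))
    return CorrelationSummary(r=float(r), p_value=float(p), slope=slope, n=len(d))
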