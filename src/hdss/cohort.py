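"""Cohort tables and the symptom-space feature encoding.

A cohort table is a :class:`pandas.DataFrame` with one row per observation
(person x timepoint), ordinal item columns ``item_001..item_NNN`` scored
0/1/2, and demographic columns ``race`` (categorical), ``gender``
(categorical) and ``age`` (years).  The feature encoding turns such a table
into the raw design matrix of the symptom space: items pass through as raw
ordinal values, categorical demographics are expanded according to a
dialect, and age enters as a real column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

ITEM_PATTERN = re.compile(r"^item_(\d+)$")
DEMOGRAPHIC_COLUMNS = ("race", "gender", "age")
VALID_ITEM_VALUES = frozenset({0, 1, 2})


def item_name(i: int, width: int = 3) -> str:
    """Canonical zero-padded item column name for item id ``i`` (1-based)."""
    return f"item_{i:0{width}d}"


def item_columns(frame: pd.DataFrame) -> list[str]:
    """Item columns of ``frame`` in ascending item-id order."""
    found = [(int(m.group(1)), c) for c in frame.columns if (m := ITEM_PATTERN.match(c))]
    return [c for _, c in sorted(found)]


def validate_cohort(
    cohort: pd.DataFrame,
    *,
    n_timepoints: int | None = None,
    complete_case: bool = False,
) -> pd.DataFrame:
    """Validate a cohort table and return it with a clean integer index.

    Checks the cohort-table invariants: unique ``(person_id, timepoint)``
    keys, item responses in {0, 1, 2}, and — under ``complete_case`` — that
    every person has all ``n_timepoints`` timepoints with no missing cells.

    Raises
    ------
    ValueError
        On a duplicated key, an out-of-range item response (named by row),
        or a missing cell in complete-case mode (named by person, timepoint
        and column).
    """
    required = {"person_id", "timepoint"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing required columns: {sorted(missing)}")
    items = item_columns(cohort)
    if not items:
        raise ValueError("cohort has no item_* columns")

    dup = cohort.duplicated(subset=["person_id", "timepoint"])
    if dup.any():
        first = cohort.loc[dup, ["person_id", "timepoint"]].iloc[0]
        raise ValueError(
            f"duplicate (person_id, timepoint) pair: ({first['person_id']}, {first['timepoint']})"
        )

    vals = cohort[items]
    bad_mask = ~vals.isin(VALID_ITEM_VALUES) & vals.notna()
    if bad_mask.to_numpy().any():
        r, c = np.argwhere(bad_mask.to_numpy())[0]
        row = cohort.iloc[r]
        raise ValueError(
            f"item response out of range at person {row['person_id']} "
            f"timepoint {row['timepoint']} column {items[c]}: {vals.iloc[r, c]!r}"
        )

    if complete_case:
        if n_timepoints is None:
            n_timepoints = int(cohort["timepoint"].max())
        check_cols = items + [c for c in DEMOGRAPHIC_COLUMNS if c in cohort.columns]
        na = cohort[check_cols].isna()
        if na.to_numpy().any():
            r, c = np.argwhere(na.to_numpy())[0]
            row = cohort.iloc[r]
            raise ValueError(
                f"missing cell in complete-case mode: person {row['person_id']} "
                f"timepoint {row['timepoint']} column {check_cols[c]}"
            )
        counts = cohort.groupby("person_id")["timepoint"].nunique()
        short = counts[counts < n_timepoints]
        if not short.empty:
            raise ValueError(
                f"complete-case mode: {len(short)} person(s) lack all "
                f"{n_timepoints} timepoints (first: {short.index[0]})"
            )
    return cohort.reset_index(drop=True)


def complete_case_filter(
    cohort: pd.DataFrame, n_timepoints: int | None = None
) -> tuple[pd.DataFrame, int]:
    """Drop persons without complete data at every timepoint.

    Returns the filtered cohort and the number of persons dropped,
    mirroring the complete-case inclusion rule of longitudinal studies.
    """
    if n_timepoints is None:
        n_timepoints = int(cohort["timepoint"].max())
    items = item_columns(cohort)
    check_cols = items + [c for c in DEMOGRAPHIC_COLUMNS if c in cohort.columns]
    ok_rows = cohort[check_cols].notna().all(axis=1)
    counts = cohort[ok_rows].groupby("person_id")["timepoint"].nunique()
    keep = set(counts[counts >= n_timepoints].index)
    dropped = cohort["person_id"].nunique() - len(keep)
    out = cohort[cohort["person_id"].isin(keep) & ok_rows].reset_index(drop=True)
    return out, dropped


def observation_index(cohort: pd.DataFrame) -> pd.MultiIndex:
    """(person_id, timepoint) MultiIndex for the cohort's rows, in row order."""
    return pd.MultiIndex.from_frame(
        cohort[["person_id", "timepoint"]], names=["person_id", "timepoint"]
    )


@dataclass(frozen=True)
class Feature:
    """One column of the raw design matrix."""

    name: str
    kind: str  # item | demographic_dummy | demographic_code | age
    source: str
    level: str | None = None  # dummy level, or None


@dataclass
class FeatureSpec:
    """Ordered feature list that fully determines the raw design matrix.

    ``dialect`` controls how categorical demographics enter the space:

    ``onehot``
        one indicator column per observed level (statistically clean);
    ``compact``
        one integer-coded column per categorical demographic, so that 119
        items + race + gender + age give a 122-dimensional space.
    """

    features: list[Feature]
    dialect: str = "onehot"
    levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        *,
        demographics: str = "onehot",
        include_demographics: bool = True,
    ) -> "FeatureSpec":
        """Build the spec from a cohort's columns.

        Categorical levels are learned from the cohort (sorted for
        determinism); unseen levels at encode time are an error.
        """
        if demographics not in ("onehot", "compact"):
            raise ValueError(f"unknown demographics dialect: {demographics!r}")
        feats = [Feature(c, "item", c) for c in item_columns(cohort)]
        levels: dict[str, list[str]] = {}
        if include_demographics:
            for col in ("race", "gender"):
                if col not in cohort.columns:
                    continue
                lv = sorted(str(v) for v in cohort[col].dropna().unique())
                levels[col] = lv
                if demographics == "onehot":
                    feats += [Feature(f"{col}_{v}", "demographic_dummy", col, v) for v in lv]
                else:
                    feats.append(Feature(col, "demographic_code", col))
            if "age" in cohort.columns:
                feats.append(Feature("age", "age", "age"))
        return cls(features=feats, dialect=demographics, levels=levels)


def encode_features(cohort: pd.DataFrame, spec: FeatureSpec) -> np.ndarray:
    """Encode a cohort into the raw design matrix defined by ``spec``.

    Items pass through as raw ordinal values; categorical demographics are
    expanded per the spec's dialect; age is a real column.  Column order is
    exactly ``spec.names``.
    """
    n = len(cohort)
    out = np.empty((n, spec.n_features), dtype=float)
    for k, feat in enumerate(spec.features):
        if feat.source not in cohort.columns:
            raise ValueError(f"cohort is missing source column {feat.source!r}")
        col = cohort[feat.source]
        if feat.kind in ("item", "age"):
            vals = col.to_numpy(dtype=float)
        elif feat.kind == "demographic_dummy":
            vals = (col.astype(str) == feat.level).to_numpy(dtype=float)
        elif feat.kind == "demographic_code":
            lv = spec.levels[feat.source]
            codes = pd.Categorical(col.astype(str), categories=lv).codes
            if (codes < 0).any():
                bad = col.astype(str)[codes < 0].iloc[0]
                raise ValueError(
                    f"unknown {feat.source} level {bad!r}; known levels: {lv}"
                )
            vals = codes.astype(float)
        else:  # pragma: no cover - spec construction prevents this
            raise ValueError(f"unknown feature kind {feat.kind!r}")
        if np.isnan(vals).any():
            r = int(np.flatnonzero(np.isnan(vals))[0])
            row = cohort.iloc[r]
            raise ValueError(
                f"missing value: person {row['person_id']} "
                f"timepoint {row['timepoint']} column {feat.source}"
            )
        out[:, k] = vals
    if spec.dialect == "onehot":
        # unseen onehot level: all dummies of that source are zero
        for col in spec.levels:
            dummy_idx = [k for k, f in enumerate(spec.features) if f.source == col]
            if dummy_idx and not np.allclose(out[:, dummy_idx].sum(axis=1), 1.0):
                r = int(np.flatnonzero(out[:, dummy_idx].sum(axis=1) != 1.0)[0])
                bad = str(cohort[col].iloc[r])
                raise ValueError(
                    f"unknown {col} level {bad!r}; known levels: {spec.levels[col]}"
                )
    return out


class CohortEncoder(BaseEstimator, TransformerMixin):
    """Transformer from cohort tables to raw symptom-space design matrices.

    Parameters
    ----------
    demographics : {"onehot", "compact"}, default "onehot"
        Encoding dialect for categorical demographics.
    include_demographics : bool, default True
        If False, only the ordinal items enter the space.

    Attributes
    ----------
    spec_ : FeatureSpec
        The fitted feature specification (column names, order, levels).
    """

    def __init__(self, demographics: str = "onehot", include_demographics: bool = True):
        self.demographics = demographics
        self.include_demographics = include_demographics

    def fit(self, cohort: pd.DataFrame, y=None) -> "CohortEncoder":
        validate_cohort(cohort)
        self.spec_ = FeatureSpec.from_cohort(
            cohort,
            demographics=self.demographics,
            include_demographics=self.include_demographics,
        )
        self.feature_names_out_ = self.spec_.names
        return self

    def transform(self, cohort: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "spec_"):
            raise ValueError("CohortEncoder is not fitted")
        return encode_features(cohort, self.spec_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
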