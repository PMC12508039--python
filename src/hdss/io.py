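"""Readers and writers for the pipeline's tabular artifacts.

CSV is the interchange format throughout (questionnaire records are plain
tables).  Floats are written with 17 significant digits so that reruns
under the same seed reproduce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import complete_case_filter, item_columns, validate_cohort
from .space import DistanceMatrix, StandardizedSpace

FLOAT_FMT = "%.17g"


def _fmt(x) -> str:
    return FLOAT_FMT % x if isinstance(x, float) else str(x)


def read_cohort(
    path,
    fmt: str = "auto",
    *,
    complete_case: bool = False,
    n_timepoints: int | None = None,
) -> pd.DataFrame:
    """Read a cohort CSV in wide or long format.

    Wide: one row per observation with ``person_id,timepoint,item_*,...``.
    Long: ``person_id,timepoint,variable,value`` rows.  ``auto`` detects
    the long layout by its column names.  With ``complete_case`` persons
    lacking any timepoint or cell are dropped; the count of dropped
    persons is stored in ``df.attrs["n_persons_dropped"]``.
    """
    df = pd.read_csv(path)
    if fmt not in ("auto", "wide", "long"):
        raise ValueError(f"unknown cohort format {fmt!r}")
    if fmt == "auto":
        fmt = "long" if {"variable", "value"} <= set(df.columns) else "wide"
    if fmt == "long":
        df = (
            df.pivot(index=["person_id", "timepoint"], columns="variable", values="value")
            .reset_index()
            .rename_axis(columns=None)
        )
        for c in item_columns(df):
            df[c] = pd.to_numeric(df[c])
        if "age" in df.columns:
            df["age"] = pd.to_numeric(df["age"])
    dropped = 0
    if complete_case:
        df, dropped = complete_case_filter(df, n_timepoints)
    df = validate_cohort(df, n_timepoints=n_timepoints, complete_case=complete_case)
    df.attrs["n_persons_dropped"] = dropped
    return df


def write_cohort(cohort: pd.DataFrame, path, fmt: str = "wide") -> None:
    """Write a cohort CSV in wide or long format."""
    if fmt == "wide":
        cohort.to_csv(path, index=False, float_format=FLOAT_FMT)
        return
    if fmt != "long":
        raise ValueError(f"unknown cohort format {fmt!r}")
    value_cols = [c for c in cohort.columns if c not in ("person_id", "timepoint")]
    long = cohort.melt(
        id_vars=["person_id", "timepoint"],
        value_vars=value_cols,
        var_name="variable",
        value_name="value",
    )
    long.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    """Distance matrix as CSV with ``person|timepoint`` header row/column."""
    dist.to_frame().to_csv(path, float_format=FLOAT_FMT, index_label="observation")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    pairs = [lbl.rsplit("|", 1) for lbl in df.index]
    index = pd.MultiIndex.from_tuples(
        [(p, int(t)) for p, t in pairs], names=["person_id", "timepoint"]
    )
    return DistanceMatrix(values=df.to_numpy(dtype=float), index=index)


def write_space(space: StandardizedSpace, outdir) -> None:
    """Standardized matrix as CSV plus a JSON sidecar of (mean, SD) params."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = space.to_frame().reset_index()
    frame.to_csv(outdir / "space.csv", index=False, float_format=FLOAT_FMT)
    params = {
        "feature_names": space.feature_names,
        "mean": [float(v) for v in space.mean],
        "scale": [float(v) for v in space.scale],
        "constant_mask": [bool(v) for v in space.constant_mask],
    }
    write_json(params, outdir / "standardization.json")


def read_space(outdir) -> StandardizedSpace:
    outdir = Path(outdir)
    frame = pd.read_csv(outdir / "space.csv")
    with open(outdir / "standardization.json") as fh:
        params = json.load(fh)
    index = pd.MultiIndex.from_frame(
        frame[["person_id", "timepoint"]], names=["person_id", "timepoint"]
    )
    names = params["feature_names"]
    return StandardizedSpace(
        values=frame[names].to_numpy(dtype=float),
        index=index,
        feature_names=names,
        mean=np.asarray(params["mean"], dtype=float),
        scale=np.asarray(params["scale"], dtype=float),
        constant_mask=np.asarray(params["constant_mask"], dtype=bool),
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_observation_series(series: pd.Series, path, value_name: str) -> None:
    """Observation-indexed series as ``person_id,timepoint,<value>`` CSV."""
    frame = series.rename(value_name).reset_index()
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_observation_series(path, value_name: str) -> pd.Series:
    frame = pd.read_csv(path)
    index = pd.MultiIndex.from_frame(
        frame[["person_id", "timepoint"]], names=["person_id", "timepoint"]
    )
    return pd.Series(frame[value_name].to_numpy(), index=index, name=value_name)


def write_observation_frame(frame: pd.DataFrame, path) -> None:
    """Observation-indexed frame as CSV with flattened key columns."""
    frame.reset_index().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_observation_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    return frame.set_index(["person_id", "timepoint"])
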