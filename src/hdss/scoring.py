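"""Scale scoring, sample-referenced T-scores and clinical status.

Raw scale scores are plain item sums.  T-scores are norm-referenced
standard scores, T = 50 + 10 z, computed against a designated reference
sample (here: a reference subset of the cohort itself rather than licensed
published norm tables, optionally stratified by gender and age band).  An
observation is clinically elevated on a scale when T >= 65, i.e. at least
1.5 reference SDs above the reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import item_columns, item_name, observation_index

CLINICAL_T = 65.0
TOTAL_SCALE = "total_problems"


@dataclass
class ScaleMap:
    """Item membership of named scales, tagged by family.

    Two families coexist: ``hitop`` holds the broad-band dimensional scales
    (total problems, internalizing, externalizing, attention, somatic) and
    ``dsm_proxy`` holds DSM-oriented scales whose T >= 65 elevations stand
    in for disorder diagnoses.  Scales may share items (transdiagnostic
    symptoms); names are unique across families.
    """

    scales: dict[str, list[int]]
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, items in self.scales.items():
            fam = self.families.get(name)
            if fam not in ("hitop", "dsm_proxy"):
                raise ValueError(f"scale {name!r} has unknown family {fam!r}")
            if not items:
                raise ValueError(f"scale {name!r} is empty")

    def family(self, family: str) -> list[str]:
        """Scale names belonging to ``family``, in insertion order."""
        return [s for s in self.scales if self.families[s] == family]

    @property
    def hitop(self) -> list[str]:
        return self.family("hitop")

    @property
    def dsm_proxy(self) -> list[str]:
        return self.family("dsm_proxy")

    def to_yaml(self, path) -> None:
        doc = {
            "scales": {
                name: {"family": self.families[name], "items": list(map(int, items))}
                for name, items in self.scales.items()
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScaleMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        scales = {n: [int(i) for i in d["items"]] for n, d in doc["scales"].items()}
        families = {n: d["family"] for n, d in doc["scales"].items()}
        return cls(scales=scales, families=families)


def raw_scale_scores(cohort: pd.DataFrame, scales: ScaleMap) -> pd.DataFrame:
    """Raw scale scores (item sums) per observation and scale."""
    items = item_columns(cohort)
    width = max(3, len(str(max(int(c.split("_")[1]) for c in items))))
    available = set(items)
    out = {}
    for name, ids in scales.scales.items():
        cols = [item_name(i, width) for i in ids]
        missing = [c for c in cols if c not in available]
        if missing:
            raise ValueError(f"scale {name!r} references missing item(s): {missing}")
        out[name] = cohort[cols].sum(axis=1).to_numpy(dtype=float)
    return pd.DataFrame(out, index=observation_index(cohort))


class TScorer(BaseEstimator, TransformerMixin):
    """Sample-referenced T-scoring: T = 50 + 10 (raw - mu_ref) / sd_ref.

    Fit on a reference frame of raw scale scores (>= 30 observations per
    scale); transform maps any raw-score frame with the same columns onto
    the T metric with the frozen reference parameters.
    """

    def __init__(self, min_reference: int = 30):
        self.min_reference = min_reference

    def fit(self, reference: pd.DataFrame, y=None) -> "TScorer":
        if len(reference) < self.min_reference:
            raise ValueError(
                f"reference sample has {len(reference)} observations; "
                f"need >= {self.min_reference}"
            )
        mu = reference.mean(axis=0)
        sd = reference.std(axis=0, ddof=0)
        zero = sd[sd == 0.0]
        if not zero.empty:
            raise ValueError(f"zero reference SD for scale {zero.index[0]!r}")
        self.columns_ = list(reference.columns)
        self.ref_mean_ = mu
        self.ref_sd_ = sd
        return self

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns_ if c not in raw.columns]
        if missing:
            raise ValueError(f"raw scores missing scale column(s): {missing}")
        z = (raw[self.columns_] - self.ref_mean_) / self.ref_sd_
        return 50.0 + 10.0 * z


@dataclass
class TScoreTable:
    """Raw and T-scores per observation and scale."""

    raw: pd.DataFrame
    t: pd.DataFrame
    scale_map: ScaleMap

    def __post_init__(self) -> None:
        if not self.raw.index.equals(self.t.index):
            raise ValueError("raw and T frames must share one observation index")


def tscores_from_reference(
    raw: pd.DataFrame,
    reference: pd.DataFrame,
    scale_map: ScaleMap,
    *,
    min_reference: int = 30,
) -> TScoreTable:
    """T-score a raw-score frame against a reference sample of raw scores."""
    scorer = TScorer(min_reference=min_reference).fit(reference)
    return TScoreTable(raw=raw, t=scorer.transform(raw), scale_map=scale_map)


@dataclass
class ClinicalStatus:
    """Per-observation clinical elevations and diagnosis counts.

    ``elevated`` is a boolean frame over every scale; ``n_diagnoses``
    counts elevated dsm_proxy scales (the DSM-style diagnosis count);
    ``any_clinical`` is True when any dsm_proxy scale is elevated (the DSM
    approach); ``total_clinical`` is True when the total-problems scale is
    elevated (the dimensional approach).
    """

    elevated: pd.DataFrame
    n_diagnoses: pd.Series
    any_clinical: pd.Series
    total_clinical: pd.Series
    threshold: float

    def at_timepoint(self, timepoint: int) -> "ClinicalStatus":
        mask = self.elevated.index.get_level_values("timepoint") == timepoint
        return ClinicalStatus(
            elevated=self.elevated[mask],
            n_diagnoses=self.n_diagnoses[mask],
            any_clinical=self.any_clinical[mask],
            total_clinical=self.total_clinical[mask],
            threshold=self.threshold,
        )


def assign_clinical_status(
    tscores: TScoreTable,
    threshold: float = CLINICAL_T,
    *,
    total_scale: str = TOTAL_SCALE,
) -> ClinicalStatus:
    """Threshold T-scores into elevations and count dsm_proxy diagnoses.

    The rule is inclusive: T exactly at the threshold counts as elevated.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    elevated = tscores.t >= threshold
    dsm = tscores.scale_map.dsm_proxy
    n_dx = elevated[dsm].sum(axis=1).astype(int) if dsm else pd.Series(
        0, index=elevated.index, dtype=int
    )
    any_clin = elevated[dsm].any(axis=1) if dsm else pd.Series(False, index=elevated.index)
    if total_scale in elevated.columns:
        total_clin = elevated[total_scale]
    else:
        total_clin = pd.Series(False, index=elevated.index)
    return ClinicalStatus(
        elevated=elevated,
        n_diagnoses=n_dx,
        any_clinical=any_clin,
        total_clinical=total_clin,
        threshold=float(threshold),
    )


def score_cohort(
    cohort: pd.DataFrame,
    scale_map: ScaleMap,
    *,
    reference_timepoint: int = 1,
    threshold: float = CLINICAL_T,
) -> tuple[TScoreTable, ClinicalStatus]:
    """Raw scores -> T-scores -> clinical status for a whole cohort.

    The baseline timepoint serves as the norm reference: T-scores for every
    observation are computed against the frozen baseline mean and SD, so
    longitudinal change is expressed on a fixed metric.
    """
    raw = raw_scale_scores(cohort, scale_map)
    ref = raw[raw.index.get_level_values("timepoint") == reference_timepoint]
    ts = tscores_from_reference(raw, ref, scale_map)
    return ts, assign_clinical_status(ts, threshold=threshold)
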