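"""Within- versus between-category distance geometry.

For a set of (possibly overlapping) diagnostic categories or dimensional
elevations, this module computes the K x K matrix of mean Euclidean
distances: each diagonal cell is the mean distance over unordered pairs of
distinct members of one category, each off-diagonal cell the mean over
cross-category pairs.  If categories carved the space well, within-category
means would sit far below between-category means; transdiagnostic symptom
overlap shrinks that gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import ClinicalStatus
from .space import DistanceMatrix


@dataclass
class CategoryAssignment:
    """Observation membership per category (overlap allowed)."""

    membership: pd.DataFrame  # boolean, observation-indexed, one column per category
    family: str

    def __post_init__(self) -> None:
        if self.membership.dtypes.apply(lambda d: d != bool).any():
            self.membership = self.membership.astype(bool)

    @property
    def categories(self) -> list[str]:
        return list(self.membership.columns)


def assignment_from_status(
    status: ClinicalStatus,
    scale_map,
    family: str,
    *,
    timepoint: int | None = 1,
) -> CategoryAssignment:
    """Build category membership from clinical elevations of one family.

    By default only baseline (timepoint 1) observations are assigned,
    matching the cross-sectional reading of the category comparison.
    """
    cols = scale_map.family(family)
    if not cols:
        raise ValueError(f"scale map has no scales in family {family!r}")
    elev = status.elevated[cols]
    if timepoint is not None:
        elev = elev[elev.index.get_level_values("timepoint") == timepoint]
    return CategoryAssignment(membership=elev, family=family)


@dataclass
class CategoryDistanceSummary:
    """K x K mean-distance matrix with pair counts and flags."""

    matrix: pd.DataFrame  # mean distances; NaN where flagged
    counts: pd.DataFrame  # number of pairs per cell
    flagged: pd.DataFrame  # boolean: cell had no valid pairs

    @property
    def categories(self) -> list[str]:
        return list(self.matrix.columns)


def within_between_matrix(
    dist: DistanceMatrix, assign: CategoryAssignment
) -> CategoryDistanceSummary:
    """Mean within- (diagonal) and between-category (off-diagonal) distances.

    Comorbid observations contribute to every category they hold.  For a
    pair of overlapping categories, self-pairs (the same observation on
    both sides) are excluded.  A category with fewer than 2 members gets a
    flagged (NaN) diagonal cell and a warning.
    """
    cats = assign.categories
    m = assign.membership.reindex(dist.index).fillna(False).to_numpy(dtype=bool)
    D = dist.values
    K = len(cats)
    mat = np.full((K, K), np.nan)
    cnt = np.zeros((K, K), dtype=int)
    flag = np.zeros((K, K), dtype=bool)
    members = [np.flatnonzero(m[:, k]) for k in range(K)]
    for a in range(K):
        ia = members[a]
        for b in range(a, K):
            ib = members[b]
            if a == b:
                n = len(ia)
                n_pairs = n * (n - 1) // 2
                if n_pairs == 0:
                    flag[a, a] = True
                    warnings.warn(
                        f"category {cats[a]!r} has fewer than 2 members; "
                        "cell flagged",
                        stacklevel=2,
                    )
                    continue
                total = D[np.ix_(ia, ia)].sum() / 2.0
                mat[a, a] = total / n_pairs
                cnt[a, a] = n_pairs
            else:
                overlap = len(np.intersect1d(ia, ib, assume_unique=True))
                n_pairs = len(ia) * len(ib) - overlap
                if n_pairs == 0:
                    flag[a, b] = flag[b, a] = True
                    continue
                # self-pairs contribute distance 0, so the sum needs no fixup
                total = D[np.ix_(ia, ib)].sum()
                mat[a, b] = mat[b, a] = total / n_pairs
                cnt[a, b] = cnt[b, a] = n_pairs
    return CategoryDistanceSummary(
        matrix=pd.DataFrame(mat, index=cats, columns=cats),
        counts=pd.DataFrame(cnt, index=cats, columns=cats),
        flagged=pd.DataFrame(flag, index=cats, columns=cats),
    )


def summarize_within_between(
    summary: CategoryDistanceSummary, *, pooled: bool = False
) -> tuple[float, float, float, float]:
    """(M_within, SD_within, M_between, SD_between) of the cell values.

    By default the mean and SD are taken over category-level cell values
    (the diagonal cells, and the upper-triangle off-diagonal cells),
    matching a matrix-of-means presentation; ``pooled=True`` instead pools
    raw pairs by weighting each cell by its pair count.  SDs use the sample
    (n-1) convention.
    """
    M = summary.matrix.to_numpy()
    C = summary.counts.to_numpy()
    K = M.shape[0]
    diag = np.array([M[i, i] for i in range(K) if not summary.flagged.iloc[i, i]])
    iu = np.triu_indices(K, k=1)
    off_mask = ~summary.flagged.to_numpy()[iu]
    off = M[iu][off_mask]
    if diag.size < 1 or off.size < 1:
        raise ValueError("all cells flagged; nothing to summarize")
    if pooled:
        wd = np.array([C[i, i] for i in range(K) if not summary.flagged.iloc[i, i]])
        wo = C[iu][off_mask]
        mw = float(np.average(diag, weights=wd))
        mb = float(np.average(off, weights=wo))
        sw = float(np.sqrt(np.average((diag - mw) ** 2, weights=wd)))
        sb = float(np.sqrt(np.average((off - mb) ** 2, weights=wo)))
        return mw, sw, mb, sb
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(diag.mean()), sd(diag), float(off.mean()), sd(off)
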