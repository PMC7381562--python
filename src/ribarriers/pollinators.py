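"""Pollinator-assemblage isolation from a morphospecies visitation table.

Visit counts (rows = insect morphospecies, columns = the two ecotypes, pooled
across trees) are compared with the Bray-Curtis dissimilarity d; the
assemblage RI is the RI4C index with U = d and S = 1 - d, which reduces to d
itself and is identical in both directions.  A rank-sum test (two-sample
Wilcoxon across morphospecies by default; a paired signed-rank variant is also
provided) screens for a visitation bias toward one ecotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _sp_braycurtis

from .ri_core import CooccurrenceCounts, UndefinedInputError, ri_cooccurrence

__all__ = [
    "VisitationTable",
    "RankTestResult",
    "read_visitation",
    "bray_curtis",
    "ri_pollinator",
    "visitation_rank_test",
]


@dataclass(frozen=True)
class VisitationTable:
    """Morphospecies-by-ecotype visit counts."""

    counts: pd.DataFrame  # index: morphospecies, two ecotype columns

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[1] != 2:
            raise ValueError("visitation table must have exactly two ecotype columns")
        if df.shape[0] < 1:
            raise ValueError("visitation table must have at least one morphospecies row")
        if (df.values < 0).any():
            raise ValueError("visit counts must be non-negative")
        if (df.sum(axis=0) <= 0).any():
            raise ValueError("each ecotype column needs at least one positive count")

    @property
    def ecotypes(self) -> tuple[str, str]:
        return tuple(self.counts.columns)

    def column(self, ecotype: str) -> np.ndarray:
        return self.counts[ecotype].to_numpy(dtype=float)


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    z: float
    p_value: float
    method: str

    def as_dict(self) -> dict:
        return {"statistic": self.statistic, "z": self.z, "p_value": self.p_value, "method": self.method}


def read_visitation(path: str | Path) -> VisitationTable:
    """Read a visitation CSV: first column morphospecies, then two count columns."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    return VisitationTable(df.astype(int))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x,y)) / (sum(x) + sum(y)).

    0 for identical communities, 1 for disjoint support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() + y.sum() == 0:
        raise UndefinedInputError("both communities are empty")
    return float(_sp_braycurtis(x, y))


def ri_pollinator(table: VisitationTable) -> float:
    """Assemblage RI4C: S = 1 - d, U = d for Bray-Curtis dissimilarity d.

    Equals d itself and is symmetric between ecotypes.
    """
    a, b = table.ecotypes
    d = bray_curtis(table.column(a), table.column(b))
    return ri_cooccurrence(CooccurrenceCounts(S=1.0 - d, U=d))


def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U for x and tie-corrected normal-approximation Z."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u1, 0.0
    return u1, (u1 - mu) / math.sqrt(var)


def visitation_rank_test(table: VisitationTable, paired: bool = False) -> RankTestResult:
    """Rank test for differential visitation between the two ecotypes.

    Default is the two-sample Wilcoxon rank-sum (Mann-Whitney) across
    morphospecies with midranks and tie-corrected normal approximation;
    ``paired=True`` runs the signed-rank test on per-morphospecies
    differences instead.  Degenerate identical columns return p = 1.
    """
    a, b = table.ecotypes
    x = table.column(a)
    y = table.column(b)
    if len(x) < 2:
        raise ValueError("rank test needs at least two morphospecies rows")
    if np.array_equal(x, y):
        stat = len(x) * len(y) / 2.0 if not paired else 0.0
        return RankTestResult(stat, 0.0, 1.0, "signed_rank" if paired else "rank_sum")
    if paired:
        res = stats.wilcoxon(x, y, zero_method="wilcox", method="approx")
        z = stats.norm.ppf(res.pvalue / 2.0) * np.sign(np.median(x - y) or 1)
        return RankTestResult(float(res.statistic), float(z), float(res.pvalue), "signed_rank")
    u1, z = _rank_sum_z(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankTestResult(float(res.statistic), z, float(res.pvalue), "rank_sum")
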