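"""Partition pairwise distances by taxonomic rank and summarize the barcode gap.

Every unordered pair of specimens falls into exactly one relationship
category: conspecific (S), congeneric (G), confamilial across genera (F),
same order across families (O), or same class across orders (C).  The module
produces per-category summary rows (count, mean, median, min, max, SE),
SPSS-style boxplot statistics with Tukey hinges, Mann-Whitney comparisons
between category distributions, and overlap reports that localize violations
of the barcode gap.

All distances handled here are on the percentage scale (substitutions per
site x 100).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from skbio import DistanceMatrix

from .records_io import BarcodeError, BarcodeRecord

__all__ = [
    "RankCategory",
    "RankSummary",
    "BoxplotStats",
    "OverlapReport",
    "classify_pair",
    "partition_distances",
    "summarize_rank",
    "boxplot_stats",
    "mann_whitney_u",
    "overlap_report",
    "PairEntry",
]

#: (idA, idB) and the distance between them, in percent.
PairEntry = tuple[tuple[str, str], float]


class RankCategory(str, Enum):
    """Lowest shared rank of a specimen pair."""

    S = "S"  # same species
    G = "G"  # same genus, different species
    F = "F"  # same family, different genus
    O = "O"  # same order, different family
    C = "C"  # same class, different order

    #: taxonomy attribute naming the taxon a category's pairs share
    @property
    def rank_attr(self) -> str:
        return {
            "S": "species", "G": "genus", "F": "family",
            "O": "order", "C": "class_name",
        }[self.value]


def classify_pair(a: BarcodeRecord, b: BarcodeRecord) -> RankCategory:
    """Deterministic category of a record pair; cross-class pairs are errors."""
    if a.species == b.species:
        return RankCategory.S
    if a.genus == b.genus:
        return RankCategory.G
    if a.family == b.family:
        return RankCategory.F
    if a.order == b.order:
        return RankCategory.O
    if a.class_name == b.class_name:
        return RankCategory.C
    raise BarcodeError(
        f"records {a.record_id!r} and {b.record_id!r} belong to different classes"
    )


def partition_distances(matrix: DistanceMatrix, records: Sequence[BarcodeRecord]
                        ) -> dict[RankCategory, list[PairEntry]]:
    """Assign every unordered pair to its category, distances in percent."""
    by_id = {r.record_id: r for r in records}
    missing = [i for i in matrix.ids if i not in by_id]
    if missing:
        raise BarcodeError(f"matrix ids without records: {missing}")
    out: dict[RankCategory, list[PairEntry]] = {c: [] for c in RankCategory}
    ids = list(matrix.ids)
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = by_id[ids[i]], by_id[ids[j]]
        out[classify_pair(a, b)].append(((ids[i], ids[j]), float(100.0 * matrix[i, j])))
    return out


@dataclass(frozen=True)
class RankSummary:
    """One summary row for a rank category (percent units throughout).

    ``taxa`` counts distinct taxa at the category's rank contributing at
    least one pair.  ``se`` treats the pairwise distances as independent
    observations — the conventional barcode-library summary, not a defensible
    variance for correlated pairs.
    """

    category: RankCategory
    taxa: int
    comparisons: int
    mean: float
    median: float
    minimum: float
    maximum: float
    se: float


def summarize_rank(category: RankCategory, entries: Sequence[PairEntry],
                   records: Sequence[BarcodeRecord]) -> RankSummary:
    if not entries:
        raise BarcodeError(f"no entries for category {category.value}")
    by_id = {r.record_id: r for r in records}
    values = np.array([d for _, d in entries], dtype=float)
    attr = category.rank_attr
    taxa = {getattr(by_id[a], attr) for (a, _), _ in entries}
    n = len(values)
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return RankSummary(
        category=category,
        taxa=len(taxa),
        comparisons=n,
        mean=float(values.mean()),
        median=float(np.median(values)),
        minimum=float(values.min()),
        maximum=float(values.max()),
        se=se,
    )


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey-hinge boxplot statistics with the SPSS outlier convention.

    Hinges are medians of the lower/upper halves (halves include the overall
    median when the sample size is odd).  Values beyond 1.5 x IQR from a hinge
    are mild outliers; beyond 3 x IQR, extreme outliers.  Whiskers sit at the
    most extreme observed values inside the 1.5 x IQR fences.
    """

    median: float
    q1: float
    q3: float
    iqr: float
    lower_whisker: float
    upper_whisker: float
    mild_outliers: tuple[float, ...] = field(default_factory=tuple)
    extreme_outliers: tuple[float, ...] = field(default_factory=tuple)


def _tukey_hinges(sorted_values: np.ndarray) -> tuple[float, float]:
    n = len(sorted_values)
    half = (n + 1) // 2  # lower half includes median when n odd
    lower = sorted_values[:half]
    upper = sorted_values[n - half:]
    return float(np.median(lower)), float(np.median(upper))


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    values = np.sort(np.asarray(values, dtype=float))
    if len(values) < 5:
        raise BarcodeError("boxplot statistics require at least 5 values")
    med = float(np.median(values))
    q1, q3 = _tukey_hinges(values)
    iqr = q3 - q1
    lo_inner, hi_inner = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lo_outer, hi_outer = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    inside = values[(values >= lo_inner) & (values <= hi_inner)]
    mild = values[((values < lo_inner) & (values >= lo_outer))
                  | ((values > hi_inner) & (values <= hi_outer))]
    extreme = values[(values < lo_outer) | (values > hi_outer)]
    return BoxplotStats(
        median=med,
        q1=q1,
        q3=q3,
        iqr=iqr,
        lower_whisker=float(inside.min()),
        upper_whisker=float(inside.max()),
        mild_outliers=tuple(float(v) for v in mild),
        extreme_outliers=tuple(float(v) for v in extreme),
    )


def mann_whitney_u(sampleA: Sequence[float], sampleB: Sequence[float]
                   ) -> tuple[float, float, float]:
    """Mann-Whitney U with midrank ties; returns (U, z, two-sided p).

    The p-value comes from the exact null distribution when the smaller
    sample has at most 8 observations and there are no ties, otherwise from
    the normal approximation with tie-corrected variance and continuity
    correction.  ``U`` is the statistic of the first sample; ``z`` is its
    continuity-corrected standardization.
    """
    a = np.asarray(sampleA, dtype=float)
    b = np.asarray(sampleB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise BarcodeError("Mann-Whitney requires two non-empty samples")
    nA, nB = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    U = float(ranks[:nA].sum() - nA * (nA + 1) / 2)

    n = nA + nB
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    mu = nA * nB / 2.0
    var = nA * nB / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var > 0 and U != mu:
        z = math.copysign(max(abs(U - mu) - 0.5, 0.0), U - mu) / math.sqrt(var)
    else:
        z = 0.0

    has_ties = bool((tie_counts > 1).any())
    method = "exact" if (min(nA, nB) <= 8 and not has_ties) else "asymptotic"
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    return U, z, p


@dataclass(frozen=True)
class OverlapReport:
    """Do two category distributions overlap, and which pairs cause it?

    ``overlapping_pairs`` lists entries of the upper (higher-divergence)
    category falling at or below the lower category's maximum, and entries of
    the lower category at or above the upper category's minimum.
    """

    category_pair: str
    max_lower: float
    min_upper: float
    overlapping_pairs: tuple[PairEntry, ...]

    @property
    def overlaps(self) -> bool:
        return bool(self.min_upper < self.max_lower)

    @property
    def gap(self) -> float:
        """Width of the barcode gap (negative when the distributions overlap)."""
        return self.min_upper - self.max_lower


def overlap_report(entries_lower: Sequence[PairEntry], entries_upper: Sequence[PairEntry],
                   category_pair: str = "S vs G") -> OverlapReport:
    if not entries_lower or not entries_upper:
        raise BarcodeError("overlap report requires two non-empty categories")
    max_lower = max(d for _, d in entries_lower)
    min_upper = min(d for _, d in entries_upper)
    overlapping: list[PairEntry] = []
    if min_upper < max_lower:
        overlapping.extend(e for e in entries_upper if e[1] <= max_lower)
        overlapping.extend(e for e in entries_lower if e[1] >= min_upper)
    return OverlapReport(
        category_pair=category_pair,
        max_lower=max_lower,
        min_upper=min_upper,
        overlapping_pairs=tuple(overlapping),
    )
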