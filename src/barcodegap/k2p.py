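"""Kimura two-parameter distances between aligned barcode sequences.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the observed proportions of transition- and transversion-type
mismatches over the sites compared, the distance in substitutions per site is

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites are masked per pair (pairwise deletion): a column is compared only when
both rows carry an unambiguous A/C/G/T.  Saturated pairs, for which a log
argument is non-positive, are hard errors rather than clamped values —
clamping would silently corrupt downstream rank summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix

from .alignment import AlignedSet
from .records_io import BarcodeError

__all__ = [
    "SitePairCounts",
    "SaturationError",
    "NoComparableSitesError",
    "count_site_differences",
    "k2p_distance",
    "pairwise_matrix",
]


class SaturationError(BarcodeError):
    """Observed divergence too high for a finite K2P distance."""


class NoComparableSitesError(BarcodeError):
    """A sequence pair shares no unambiguous, unpadded columns."""


@dataclass(frozen=True)
class SitePairCounts:
    """Mismatch classes for one aligned sequence pair under pairwise deletion."""

    compared_sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.compared_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.compared_sites


# base encoding: A=0 C=1 G=2 T=3; anything else (pad, ambiguity) = 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
# purines {A,G} -> 0, pyrimidines {C,T} -> 1; a mismatch within one class is
# a transition, across classes a transversion
_CLASS = np.array([0, 1, 0, 1], dtype=np.uint8)


def encode(row: str) -> np.ndarray:
    return _CODE[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


def count_site_differences(rowA: str, rowB: str, pair: tuple[str, str] | None = None
                           ) -> SitePairCounts:
    """Count compared sites, transitions and transversions for two rows."""
    if len(rowA) != len(rowB):
        raise BarcodeError("rows of unequal length")
    a, b = encode(rowA), encode(rowB)
    return _counts_from_codes(a, b, pair)


def _counts_from_codes(a: np.ndarray, b: np.ndarray, pair=None) -> SitePairCounts:
    valid = (a != 255) & (b != 255)
    compared = int(valid.sum())
    if compared == 0:
        label = f" for pair {pair}" if pair else ""
        raise NoComparableSitesError(f"no comparable sites{label}")
    av, bv = a[valid], b[valid]
    diff = av != bv
    transitions = int((diff & (_CLASS[av] == _CLASS[bv])).sum())
    transversions = int(diff.sum()) - transitions
    return SitePairCounts(compared, transitions, transversions)


def k2p_distance(counts: SitePairCounts, pair: tuple[str, str] | None = None) -> float:
    """Evaluate the K2P closed form; saturated inputs raise."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        label = f" for pair {pair}" if pair else ""
        raise SaturationError(
            f"saturated divergence (P={P:.4f}, Q={Q:.4f}){label}: K2P distance undefined"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # +0.0 avoids -0.0


def pairwise_matrix(aligned: AlignedSet) -> DistanceMatrix:
    """K2P distances for all unordered pairs of an aligned set.

    Returns a symmetric, hollow matrix in substitutions per site keyed by
    record id (multiply by 100 for the percentage scale used in reports).
    """
    n = len(aligned.record_ids)
    if n < 2:
        raise BarcodeError("pairwise_matrix needs at least 2 sequences")
    codes = [encode(row) for row in aligned.matrix]
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            pair = (aligned.record_ids[i], aligned.record_ids[j])
            counts = _counts_from_codes(codes[i], codes[j], pair)
            values[i, j] = values[j, i] = k2p_distance(counts, pair)
    return DistanceMatrix(values, ids=list(aligned.record_ids))
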