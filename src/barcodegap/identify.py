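"""Threshold-based species identification against a barcode reference library.

A query is compared to every reference sequence by K2P distance; each
reference species is represented by its best (minimum-distance) match.  With
a divergence threshold t (percent):

* ``match``            — exactly one species within t of the query;
* ``ambiguous``        — two or more species within t;
* ``novel_candidate``  — no reference species within t.

Distances at exactly the threshold count as within it.  The default
threshold of 2.0% brackets typical fish COI intraspecific divergence while
staying far below the >10% congeneric regime, and every report states the
threshold used.  ``flag_cryptic`` inverts the logic within species: deep
intraspecific splits beyond a threshold mark candidate cryptic species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from skbio import DistanceMatrix

from .alignment import AlignedSet, PAD
from .k2p import NoComparableSitesError, count_site_differences, k2p_distance
from .records_io import BarcodeError, BarcodeRecord, infer_reading_frame

__all__ = [
    "IdentificationResult",
    "identify_query",
    "CrypticFlag",
    "flag_cryptic",
    "DEFAULT_THRESHOLD",
]

#: Default identification threshold, percent K2P distance.
DEFAULT_THRESHOLD = 2.0


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    nearest_species: str
    nearest_distance: float
    decision: str
    threshold: float
    runner_up_species: str | None = None
    runner_up_distance: float | None = None


def identify_query(query: BarcodeRecord, reference: AlignedSet,
                   taxonomy: Mapping[str, str] | Sequence[BarcodeRecord],
                   threshold: float = DEFAULT_THRESHOLD) -> IdentificationResult:
    """Identify one query barcode against an aligned reference library.

    ``taxonomy`` maps reference record ids to species names (a sequence of
    records is accepted and converted).  The query is frame-anchored onto the
    reference window before distances are computed.
    """
    if not isinstance(taxonomy, Mapping):
        taxonomy = {r.record_id: r.species for r in taxonomy}
    if not reference.record_ids:
        raise BarcodeError("empty reference library")

    frame, _ = infer_reading_frame(query.sequence)
    body = query.sequence[frame:]
    window = min(len(body), reference.consensus_length)
    row = body[:window].ljust(reference.consensus_length, PAD)

    best_per_species: dict[str, float] = {}
    comparable = False
    for rid, ref_row in zip(reference.record_ids, reference.matrix):
        species = taxonomy[rid]
        try:
            counts = count_site_differences(row, ref_row, pair=(query.record_id, rid))
        except NoComparableSitesError:
            continue
        comparable = True
        dist = 100.0 * k2p_distance(counts, pair=(query.record_id, rid))
        if dist < best_per_species.get(species, float("inf")):
            best_per_species[species] = dist
    if not comparable:
        raise NoComparableSitesError(
            f"query {query.record_id!r} shares no comparable sites with any reference"
        )

    ranked = sorted(best_per_species.items(), key=lambda kv: (kv[1], kv[0]))
    nearest_species, nearest_distance = ranked[0]
    runner_up = ranked[1] if len(ranked) > 1 else None
    within = [s for s, d in ranked if d <= threshold]
    if len(within) == 0:
        decision = "novel_candidate"
    elif len(within) == 1:
        decision = "match"
    else:
        decision = "ambiguous"
    return IdentificationResult(
        query_id=query.record_id,
        nearest_species=nearest_species,
        nearest_distance=nearest_distance,
        decision=decision,
        threshold=threshold,
        runner_up_species=runner_up[0] if runner_up else None,
        runner_up_distance=runner_up[1] if runner_up else None,
    )


@dataclass(frozen=True)
class CrypticFlag:
    """A species whose deepest intraspecific split exceeds the threshold."""

    species: str
    max_intraspecific_distance: float
    pair: tuple[str, str]


def flag_cryptic(records: Sequence[BarcodeRecord], matrix: DistanceMatrix,
                 threshold: float = 1.0) -> list[CrypticFlag]:
    """List species with maximum intraspecific K2P distance above ``threshold`` (%)."""
    by_species: dict[str, list[str]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r.record_id)
    index = {rid: k for k, rid in enumerate(matrix.ids)}
    flags: list[CrypticFlag] = []
    for species, ids in sorted(by_species.items()):
        if len(ids) < 2:
            continue
        worst_pair, worst = None, -1.0
        for a, b in itertools.combinations(sorted(ids), 2):
            d = float(100.0 * matrix.data[index[a], index[b]])
            if d > worst:
                worst_pair, worst = (a, b), d
        if worst > threshold:
            flags.append(CrypticFlag(species, worst, worst_pair))
    return flags
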