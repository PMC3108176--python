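"""Frame-anchored placement of indel-free coding sequences on a common grid.

Barcode fragments of one gene region that passed the open-reading-frame QC
carry no insertions or deletions, so a full aligner is unnecessary: it is
enough to trim each sequence to its first complete codon and compare columns
on the shared codon grid.  Inputs with true indels fail QC upstream and never
reach this step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .records_io import (
    BarcodeError,
    BarcodeRecord,
    VERTEBRATE_MITO_TABLE,
    infer_reading_frame,
)

__all__ = ["AlignedSet", "AlignmentError", "align_by_frame", "PAD"]

#: Padding character for row ends outside a record's coverage.  Distinct from
#: IUPAC ``N`` so that reports can tell genuine ambiguity from absent data;
#: both are skipped during distance computation.
PAD = "-"


class AlignmentError(BarcodeError):
    pass


@dataclass(frozen=True)
class AlignedSet:
    """Equal-length rows of sequences anchored at codon position 1.

    Column 0 is codon position 1 for every row; ``offsets`` records how many
    leading bases were trimmed from each source sequence to reach its first
    complete codon.
    """

    record_ids: tuple[str, ...]
    matrix: tuple[str, ...]
    consensus_length: int
    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.matrix:
            raise AlignmentError("empty alignment")
        lengths = {len(row) for row in self.matrix}
        if lengths != {self.consensus_length}:
            raise AlignmentError("rows of unequal length")
        if self.consensus_length <= 0:
            raise AlignmentError("empty alignment window")

    def row(self, record_id: str) -> str:
        return self.matrix[self.record_ids.index(record_id)]


def align_by_frame(records: Sequence[BarcodeRecord], min_coverage: float = 1.0,
                   genetic_code: int = VERTEBRATE_MITO_TABLE) -> AlignedSet:
    """Anchor each sequence at its reading frame and trim to a common window.

    With ``min_coverage=1.0`` (default) the window is the strict intersection
    of all rows, so every pairwise comparison uses identical columns; lower
    values keep columns covered by at least that fraction of records, padding
    shorter rows at their 3' end.
    """
    if not records:
        raise AlignmentError("align_by_frame called with no records")
    if not 0.5 <= min_coverage <= 1.0:
        raise AlignmentError("min_coverage must be in [0.5, 1.0]")

    trimmed: list[str] = []
    offsets: list[int] = []
    for record in records:
        frame, _ = infer_reading_frame(record.sequence, genetic_code)
        body = record.sequence[frame:]
        if not body:
            raise AlignmentError(f"record {record.record_id!r} has no frame-anchored overlap")
        trimmed.append(body)
        offsets.append(frame)

    lengths = sorted((len(t) for t in trimmed), reverse=True)
    # longest window still covered by >= min_coverage of the rows
    n_required = max(1, math.ceil(min_coverage * len(trimmed) - 1e-9))
    window = lengths[n_required - 1]

    rows = []
    for record, body in zip(records, trimmed):
        row = body[:window]
        if not row:
            raise AlignmentError(
                f"record {record.record_id!r} has empty overlap with the common window"
            )
        rows.append(row.ljust(window, PAD))

    return AlignedSet(
        record_ids=tuple(r.record_id for r in records),
        matrix=tuple(rows),
        consensus_length=window,
        offsets=tuple(offsets),
    )
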