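"""Reading, validation and quality filtering of barcode records.

A barcode dataset is a FASTA file of COI-like nucleotide sequences plus a
tab-separated taxonomy table keyed on ``record_id``.  Quality control mirrors
standard barcode-library curation: a record is kept when its sequence is long
enough and its best reading frame under the vertebrate mitochondrial code
contains no internal stop codons (indels and sequencing errors in a
protein-coding gene almost always surface as frame-shifts and premature
stops).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeRecord",
    "QCReport",
    "BarcodeError",
    "TaxonomyError",
    "read_dataset",
    "write_dataset",
    "write_qc_report",
    "qc_filter",
    "infer_reading_frame",
    "VERTEBRATE_MITO_TABLE",
    "DEFAULT_MIN_LENGTH",
]

#: NCBI translation table id for the vertebrate mitochondrial code.
VERTEBRATE_MITO_TABLE = 2

#: Records must be strictly longer than this many unambiguous-or-not bases.
DEFAULT_MIN_LENGTH = 500

IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")

REQUIRED_TAXONOMY_COLUMNS = ("record_id", "species", "genus", "family", "order", "class")
OPTIONAL_TAXONOMY_COLUMNS = ("accession", "locality")


class BarcodeError(ValueError):
    """Base class for hard errors raised by the pipeline."""


class TaxonomyError(BarcodeError):
    """Taxonomy table malformed or inconsistent with the FASTA input."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One specimen: a nucleotide barcode with its full Linnean annotation."""

    record_id: str
    sequence: str
    species: str
    genus: str
    family: str
    order: str
    class_name: str
    accession: str | None = None
    locality: str | None = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise BarcodeError("record_id must be non-empty")
        if not self.sequence:
            raise BarcodeError(f"{self.record_id}: empty sequence")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise BarcodeError(
                f"{self.record_id}: non-IUPAC characters {sorted(bad)!r} in sequence"
            )
        for rank in ("species", "genus", "family", "order", "class_name"):
            if not getattr(self, rank):
                raise BarcodeError(f"{self.record_id}: missing {rank}")


@dataclass(frozen=True)
class QCReport:
    """Per-record quality-control outcome.

    ``passed`` is true exactly when the length check passed and the best
    reading frame has zero internal stop codons.
    """

    record_id: str
    passed: bool
    length_ok: bool
    frame: int | None
    stop_codons: int
    reasons: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def _read_taxonomy(taxonomy_source, delimiter: str = "\t") -> pd.DataFrame:
    table = pd.read_csv(taxonomy_source, sep=delimiter, dtype=str).fillna("")
    missing = [c for c in REQUIRED_TAXONOMY_COLUMNS if c not in table.columns]
    if missing:
        raise TaxonomyError(f"taxonomy table missing required columns: {missing}")
    dups = table["record_id"][table["record_id"].duplicated()].tolist()
    if dups:
        raise TaxonomyError(f"duplicate record_id in taxonomy table: {sorted(set(dups))}")
    return table


def _check_consistency(records: Sequence[BarcodeRecord]) -> None:
    seen: dict[str, tuple[str, str, str, str]] = {}
    for r in records:
        lineage = (r.genus, r.family, r.order, r.class_name)
        prev = seen.setdefault(r.species, lineage)
        if prev != lineage:
            raise TaxonomyError(
                f"species {r.species!r} mapped to conflicting lineages {prev} and {lineage}"
            )


def read_dataset(fasta_source, taxonomy_source, delimiter: str = "\t") -> list[BarcodeRecord]:
    """Read a FASTA file plus taxonomy table into annotated records.

    Sequences are uppercased and U is mapped to T.  Every FASTA id must have a
    taxonomy row; duplicated ids and taxonomically inconsistent rows (one
    species name under two genera, families, ...) are hard errors.
    """
    table = _read_taxonomy(taxonomy_source, delimiter=delimiter)
    taxonomy = {row["record_id"]: row for row in table.to_dict("records")}

    records: list[BarcodeRecord] = []
    seen_ids: set[str] = set()
    orphans: list[str] = []
    for entry in SeqIO.parse(fasta_source, "fasta"):
        rid = entry.id
        if rid in seen_ids:
            raise BarcodeError(f"duplicate record_id in FASTA: {rid!r}")
        seen_ids.add(rid)
        row = taxonomy.get(rid)
        if row is None:
            orphans.append(rid)
            continue
        records.append(
            BarcodeRecord(
                record_id=rid,
                sequence=str(entry.seq).upper().replace("U", "T"),
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                order=row["order"],
                class_name=row["class"],
                accession=row.get("accession", "") or None,
                locality=row.get("locality", "") or None,
            )
        )
    if orphans:
        raise TaxonomyError(f"FASTA ids absent from taxonomy table: {orphans}")
    _check_consistency(records)
    return records


def write_dataset(records: Iterable[BarcodeRecord], fasta_path, taxonomy_path,
                  delimiter: str = "\t") -> None:
    """Write records back out as FASTA plus taxonomy TSV (round-trips read_dataset)."""
    records = list(records)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description="") for r in records
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    frame = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "species": [r.species for r in records],
            "genus": [r.genus for r in records],
            "family": [r.family for r in records],
            "order": [r.order for r in records],
            "class": [r.class_name for r in records],
            "accession": [r.accession or "" for r in records],
            "locality": [r.locality or "" for r in records],
        }
    )
    frame.to_csv(taxonomy_path, sep=delimiter, index=False)


def write_qc_report(reports: Iterable[QCReport], path) -> None:
    frame = pd.DataFrame(
        {
            "record_id": [r.record_id for r in reports],
            "passed": [r.passed for r in reports],
            "length_ok": [r.length_ok for r in reports],
            "frame": [r.frame if r.frame is not None else "" for r in reports],
            "stop_codons": [r.stop_codons for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reading frames and stop codons
# ---------------------------------------------------------------------------

def _stop_codons(genetic_code: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)


def _count_internal_stops(sequence: str, frame: int, stops: frozenset[str]) -> int:
    """Internal stop codons of ``sequence`` read in ``frame``.

    The terminal (possibly partial) codon is excluded: barcode fragments
    routinely end mid-codon.  Codons containing any ambiguity code are never
    counted as stops.
    """
    n_codons = (len(sequence) - frame) // 3
    count = 0
    for k in range(n_codons - 1):  # skip terminal codon
        codon = sequence[frame + 3 * k : frame + 3 * k + 3]
        if codon in stops:
            count += 1
    return count


def infer_reading_frame(sequence: str, genetic_code: int = VERTEBRATE_MITO_TABLE
                        ) -> tuple[int, int]:
    """Best reading frame of a coding fragment and its internal stop count.

    Returns the frame in {0, 1, 2} minimizing internal stop codons; ties break
    to the lowest frame index.
    """
    if len(sequence) < 3:
        raise BarcodeError("sequence shorter than one codon")
    stops = _stop_codons(genetic_code)
    best_frame, best_count = 0, _count_internal_stops(sequence, 0, stops)
    for frame in (1, 2):
        count = _count_internal_stops(sequence, frame, stops)
        if count < best_count:
            best_frame, best_count = frame, count
    return best_frame, best_count


def qc_filter(records: Sequence[BarcodeRecord], min_length: int = DEFAULT_MIN_LENGTH,
              genetic_code: int = VERTEBRATE_MITO_TABLE
              ) -> tuple[list[BarcodeRecord], list[QCReport]]:
    """Filter records on length and open-reading-frame integrity.

    A record passes iff its ungapped length is strictly greater than
    ``min_length`` and its best reading frame contains zero internal stop
    codons.  Failures are reported, never raised.
    """
    if min_length <= 0:
        raise BarcodeError("min_length must be positive")
    passing: list[BarcodeRecord] = []
    reports: list[QCReport] = []
    for record in records:
        seq = record.sequence.replace("-", "")
        length_ok = len(seq) > min_length
        reasons: list[str] = []
        if not length_ok:
            reasons.append("length")
        if len(seq) >= 3:
            frame, stop_count = infer_reading_frame(seq, genetic_code)
        else:
            frame, stop_count = None, 0
            reasons.append("too_short_for_frame")
        if stop_count > 0:
            reasons.append("stop_codons")
        passed = length_ok and stop_count == 0 and frame is not None
        reports.append(
            QCReport(
                record_id=record.record_id,
                passed=passed,
                length_ok=length_ok,
                frame=frame,
                stop_codons=stop_count,
                reasons=tuple(reasons),
            )
        )
        if passed:
            passing.append(record)
    return passing, reports
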