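"""End-to-end orchestration: records -> alignment -> distances -> reports.

``run_analysis`` executes the whole identification workflow on a FASTA +
taxonomy input and writes every artifact (QC report, per-pair distance
table, rank summaries, Newick tree, JSON report) into one output directory.
Every number in the report is recomputable from the inputs and configuration
alone; reruns on identical inputs are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .alignment import align_by_frame
from .identify import flag_cryptic
from .k2p import pairwise_matrix
from .njtree import flag_introgression, neighbor_joining, species_monophyly, write_newick
from .rank_partition import (
    RankCategory,
    boxplot_stats,
    mann_whitney_u,
    overlap_report,
    partition_distances,
    summarize_rank,
)
from .records_io import (
    BarcodeError,
    BarcodeRecord,
    DEFAULT_MIN_LENGTH,
    VERTEBRATE_MITO_TABLE,
    qc_filter,
    read_dataset,
    write_qc_report,
)
from .simulate import SimulationConfig, simulate_dataset, write_simulation

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "run_simulation"]

logger = logging.getLogger("barcodegap")

#: Comparisons per category run through Mann-Whitney, in (lower, upper) order.
_MW_PAIRS = (("S", "G"), ("G", "F"), ("S", "F"))


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of one analysis run (all thresholds in percent K2P)."""

    min_length: int = DEFAULT_MIN_LENGTH
    genetic_code: int = VERTEBRATE_MITO_TABLE
    min_coverage: float = 1.0
    identify_threshold: float = 2.0
    cryptic_threshold: float = 1.0
    introgression_threshold: float = 2.0
    delimiter: str = "\t"


@dataclass
class AnalysisReport:
    """JSON-serializable results of one run; round-trips through to_dict/from_dict."""

    qc: dict
    consensus_length: int | None
    rank_summaries: list
    boxplots: dict
    per_family: dict
    mann_whitney: dict
    overlaps: dict
    tree_newick: str | None
    monophyly: dict | None
    introgression_flags: list
    cryptic_flags: list
    metadata: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisReport":
        return cls(**data)


def _summary_row(s) -> dict:
    return {
        "category": s.category.value,
        "taxa": s.taxa,
        "comparisons": s.comparisons,
        "mean": s.mean,
        "median": s.median,
        "minimum": s.minimum,
        "maximum": s.maximum,
        "se": s.se,
    }


def _box_dict(b) -> dict:
    return {
        "median": b.median,
        "q1": b.q1,
        "q3": b.q3,
        "iqr": b.iqr,
        "lower_whisker": b.lower_whisker,
        "upper_whisker": b.upper_whisker,
        "mild_outliers": list(b.mild_outliers),
        "extreme_outliers": list(b.extreme_outliers),
    }


def _overlap_dict(o) -> dict:
    return {
        "category_pair": o.category_pair,
        "max_lower": o.max_lower,
        "min_upper": o.min_upper,
        "overlaps": o.overlaps,
        "gap": o.gap,
        "overlapping_pairs": [[list(p), d] for p, d in o.overlapping_pairs],
    }


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("stage %-14s %.2fs", stage, time.perf_counter() - self.t0)

    return _Timer()


def run_analysis(fasta, taxonomy, out_dir, config: AnalysisConfig | None = None
                 ) -> AnalysisReport:
    """Run the full pipeline and write all artifacts under ``out_dir``."""
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _timed("read+qc"):
        records = read_dataset(fasta, taxonomy, delimiter=config.delimiter)
        passing, reports = qc_filter(records, config.min_length, config.genetic_code)
        write_qc_report(reports, out / "qc_report.tsv")
    qc_summary = {
        "total": len(records),
        "passed": len(passing),
        "failed": len(records) - len(passing),
        "failure_reasons": _reason_counts(reports),
    }
    if len(passing) < 2:
        raise BarcodeError("fewer than 2 records passed QC; nothing to compare")

    with _timed("align"):
        aligned = align_by_frame(passing, config.min_coverage, config.genetic_code)
    with _timed("distances"):
        matrix = pairwise_matrix(aligned)
    with _timed("rank stats"):
        partition = partition_distances(matrix, passing)
        summaries = {
            cat: summarize_rank(cat, entries, passing)
            for cat, entries in partition.items() if entries
        }
        boxplots = {
            cat.value: _box_dict(boxplot_stats([d for _, d in entries]))
            for cat, entries in partition.items() if len(entries) >= 5
        }
        mw = {}
        for lo, hi in _MW_PAIRS:
            a = [d for _, d in partition[RankCategory(lo)]]
            b = [d for _, d in partition[RankCategory(hi)]]
            if a and b:
                U, z, p = mann_whitney_u(a, b)
                mw[f"{lo} vs {hi}"] = {"U": U, "z": z, "p_two_sided": p}
        overlaps = {}
        for lo, hi in (("S", "G"), ("G", "F")):
            a, b = partition[RankCategory(lo)], partition[RankCategory(hi)]
            if a and b:
                overlaps[f"{lo} vs {hi}"] = _overlap_dict(
                    overlap_report(a, b, f"{lo} vs {hi}")
                )
        per_family = _per_family_reports(matrix, passing)
        _write_pair_table(partition, out / "distance_pairs.tsv")
        _write_summary_table(summaries, out / "rank_summaries.tsv")

    tree_newick = None
    monophyly_dict = None
    intro_flags: list = []
    if len(passing) >= 3:
        with _timed("nj tree"):
            tree = neighbor_joining(matrix)
            tree_newick = write_newick(tree)
            (out / "tree.nwk").write_text(tree_newick + "\n")
            mono = species_monophyly(tree, passing)
            monophyly_dict = {
                "species": dict(sorted(mono.species.items())),
                "singleton_species": list(mono.singleton_species),
                "families": [dataclasses.asdict(f) | {"strays": list(f.strays)}
                             for f in mono.families],
                "specimen_family_cohesion": mono.specimen_family_cohesion,
            }
            intro_flags = [
                dataclasses.asdict(f) | {"nested_leaf_ids": list(f.nested_leaf_ids)}
                for f in flag_introgression(
                    tree, matrix, passing, config.introgression_threshold)
            ]
    else:
        logger.warning("fewer than 3 sequences passed QC; tree stage skipped")

    with _timed("cryptic"):
        cryptic = [
            dataclasses.asdict(f) | {"pair": list(f.pair)}
            for f in flag_cryptic(passing, matrix, config.cryptic_threshold)
        ]

    report = AnalysisReport(
        qc=qc_summary,
        consensus_length=aligned.consensus_length,
        rank_summaries=[_summary_row(summaries[c]) for c in RankCategory if c in summaries],
        boxplots=boxplots,
        per_family=per_family,
        mann_whitney=mw,
        overlaps=overlaps,
        tree_newick=tree_newick,
        monophyly=monophyly_dict,
        introgression_flags=intro_flags,
        cryptic_flags=cryptic,
        metadata={
            "config": dataclasses.asdict(config),
            "version": __version__,
            "taxa_counting_rule": "taxa contributing >= 1 pair to the category",
            "family_cohesion_rule": "largest family-pure edge-defined cluster",
        },
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    return report


def _reason_counts(reports) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in reports:
        for reason in r.reasons:
            counts[reason] = counts.get(reason, 0) + 1
    return counts


def _per_family_reports(matrix, records: Sequence[BarcodeRecord]) -> dict:
    """Boxplot stats and S/G overlap per family with >= 2 genera."""
    out: dict = {}
    by_family: dict[str, list[BarcodeRecord]] = {}
    for r in records:
        by_family.setdefault(r.family, []).append(r)
    index = {rid: k for k, rid in enumerate(matrix.ids)}
    for family, members in sorted(by_family.items()):
        if len({r.genus for r in members}) < 2:
            continue
        ids = [r.record_id for r in members]
        sub = matrix.filter(ids)
        partition = partition_distances(sub, members)
        entry: dict = {"boxplots": {}, "overlap_S_vs_G": None}
        for cat in (RankCategory.S, RankCategory.G, RankCategory.F):
            values = [d for _, d in partition[cat]]
            if len(values) >= 5:
                entry["boxplots"][cat.value] = _box_dict(boxplot_stats(values))
        s, g = partition[RankCategory.S], partition[RankCategory.G]
        if s and g:
            entry["overlap_S_vs_G"] = _overlap_dict(overlap_report(s, g, "S vs G"))
        out[family] = entry
    return out


def _write_pair_table(partition, path) -> None:
    rows = []
    for cat in RankCategory:
        for (a, b), d in partition[cat]:
            rows.append((a, b, cat.value, f"{d:.3f}"))
    pd.DataFrame(rows, columns=["idA", "idB", "category", "distance_percent"]).to_csv(
        path, sep="\t", index=False
    )


def _write_summary_table(summaries, path) -> None:
    rows = []
    for cat in RankCategory:
        if cat not in summaries:
            continue
        s = summaries[cat]
        # mirror printed-table conventions: percent to 3 decimals, median
        # suppressed in display above family rank
        rows.append(
            (
                cat.value,
                s.taxa,
                s.comparisons,
                f"{s.mean:.3f}",
                f"{s.median:.3f}" if cat.value in ("S", "G", "F") else "-",
                f"{s.minimum:.3f}",
                f"{s.maximum:.3f}",
                f"{s.se:.3f}",
            )
        )
    pd.DataFrame(
        rows,
        columns=["category", "taxa", "comparisons", "mean", "median",
                 "minimum", "maximum", "se"],
    ).to_csv(path, sep="\t", index=False)


def run_simulation(config: SimulationConfig, out_dir) -> dict:
    """Simulate a dataset and write FASTA + taxonomy + truth JSON."""
    config.validate()
    with _timed("simulate"):
        records, truth = simulate_dataset(config)
        paths = write_simulation(records, truth, out_dir)
    return {name: str(p) for name, p in paths.items()}
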