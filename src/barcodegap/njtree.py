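"""Neighbor-joining trees and tree-based species/family diagnostics.

The tree builder is the classic Saitou-Nei agglomeration run on a K2P
distance matrix: at each step the pair minimizing

    Q(i, j) = (m - 2) * d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined, branch lengths follow the standard two-point formulas, and the
last three nodes meet at a trifurcation, giving an unrooted tree.  Ties in Q
break to the lexicographically smallest pair of node creation indices, so the
output is deterministic even for degenerate all-equal matrices.  Negative
branch lengths, which NJ can produce, are clamped to zero with the deficit
moved to the sibling edge; raw lengths are kept on each node as metadata.

Downstream diagnostics work on the tree's edge-defined clusters
(bipartitions): species monophyly, family cohesion, and flags for the
introgression signature in which one species' haplotypes nest inside
another species' cluster at intraspecific-scale distances.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import skbio
from skbio import DistanceMatrix, TreeNode

from .records_io import BarcodeError, BarcodeRecord

__all__ = [
    "neighbor_joining",
    "write_newick",
    "parse_newick",
    "tree_sides",
    "MonophylyReport",
    "FamilyCohesion",
    "species_monophyly",
    "IntrogressionFlag",
    "flag_introgression",
]


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _clamped(length: float, sibling: float) -> tuple[float, float]:
    """Clamp a negative branch to zero, shifting the deficit to its sibling."""
    if length < 0.0:
        return 0.0, sibling + length
    return length, sibling


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Build the unrooted NJ tree for a distance matrix.

    Returns a :class:`skbio.TreeNode` whose root is the final trifurcation.
    Every node carries ``raw_length`` (the NJ two-point estimate before
    negative-branch clamping) alongside the clamped ``length``.
    """
    ids = list(matrix.ids)
    n = len(ids)
    if n < 3:
        raise BarcodeError("neighbor joining requires at least 3 sequences")
    D = np.array(matrix.data, dtype=float)
    if not np.isfinite(D).all():
        raise BarcodeError("distance matrix contains non-finite entries")

    nodes: list[TreeNode] = []
    for name in ids:
        leaf = TreeNode(name=name)
        leaf.raw_length = None
        nodes.append(leaf)
    # creation index of each active row; rows of D track `active` positions
    active = list(range(n))
    next_index = n

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        # restrict to the upper triangle: rounding can break Q's symmetry in
        # the last ulp, and each unordered pair must be considered once
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        # lexicographically smallest creation-index pair among ties
        best = min(
            (tuple(sorted((active[i], active[j]))), (int(i), int(j)))
            for i, j in ties
        )
        i, j = best[1]
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        raw_li, raw_lj = li, lj
        li, lj = _clamped(li, lj)
        lj, li = _clamped(lj, li)

        child_i, child_j = nodes[active[i]], nodes[active[j]]
        child_i.length, child_i.raw_length = float(li), float(raw_li)
        child_j.length, child_j.raw_length = float(lj), float(raw_lj)
        parent = TreeNode(children=[child_i, child_j])
        parent.raw_length = None
        nodes.append(parent)

        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], d_new[keep]])
        D = np.column_stack([D, np.append(d_new[keep], 0.0)])
        active = [active[k] for k in keep] + [next_index]
        next_index += 1

    (a, b, c) = active
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    raw = (la, lb, lc)
    # clamp negatives at the trifurcation, sharing the deficit across siblings
    lengths = [la, lb, lc]
    for k in range(3):
        if lengths[k] < 0.0:
            deficit = lengths[k] / 2.0
            lengths[k] = 0.0
            for other in range(3):
                if other != k:
                    lengths[other] += deficit
    for node_idx, length, raw_length in zip((a, b, c), lengths, raw):
        nodes[node_idx].length = float(max(length, 0.0))
        nodes[node_idx].raw_length = float(raw_length)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    root.raw_length = None
    return root


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string; malformed input raises with a position hint."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise BarcodeError(f"unbalanced ')' at position {pos} in Newick input")
    if depth != 0:
        raise BarcodeError(
            f"unbalanced '(' (depth {depth} at end, position {len(text)}) in Newick input"
        )
    try:
        return TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio NewickFormatError and friends
        raise BarcodeError(f"malformed Newick input: {exc}") from exc


# ---------------------------------------------------------------------------
# edge-defined clusters
# ---------------------------------------------------------------------------

def tree_sides(tree: TreeNode) -> set[frozenset[str]]:
    """All edge-defined leaf clusters of an unrooted tree, both sides per edge."""
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    sides: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        cluster = (frozenset((node.name,)) if node.is_tip()
                   else frozenset(leaf.name for leaf in node.tips()))
        sides.add(cluster)
        sides.add(all_leaves - cluster)
    return sides


@dataclass(frozen=True)
class FamilyCohesion:
    family: str
    cohesive: bool
    strays: tuple[str, ...]


@dataclass(frozen=True)
class MonophylyReport:
    """Tree-topology diagnostics derived purely from bipartitions.

    ``species`` flags monophyly for every species with >= 2 individuals;
    singletons are listed separately (monophyly of one leaf is vacuous).
    A family is cohesive when its largest family-pure cluster holds all its
    specimens; ``specimen_family_cohesion`` is the fraction of specimens
    lying inside their family's largest pure cluster.
    """

    species: Mapping[str, bool]
    singleton_species: tuple[str, ...]
    families: tuple[FamilyCohesion, ...]
    specimen_family_cohesion: float

    @property
    def all_species_monophyletic(self) -> bool:
        return all(self.species.values())


def _leaf_taxonomy(tree: TreeNode, records: Sequence[BarcodeRecord]
                   ) -> dict[str, BarcodeRecord]:
    by_id = {r.record_id: r for r in records}
    out = {}
    for leaf in tree.tips():
        if leaf.name not in by_id:
            raise BarcodeError(f"leaf {leaf.name!r} has no taxonomy record")
        out[leaf.name] = by_id[leaf.name]
    return out


def species_monophyly(tree: TreeNode, records: Sequence[BarcodeRecord]
                      ) -> MonophylyReport:
    taxonomy = _leaf_taxonomy(tree, records)
    sides = tree_sides(tree)

    species_leaves: dict[str, set[str]] = {}
    family_leaves: dict[str, set[str]] = {}
    for leaf, rec in taxonomy.items():
        species_leaves.setdefault(rec.species, set()).add(leaf)
        family_leaves.setdefault(rec.family, set()).add(leaf)

    species_flags: dict[str, bool] = {}
    singletons: list[str] = []
    for sp, leaves in sorted(species_leaves.items()):
        if len(leaves) < 2:
            singletons.append(sp)
        else:
            species_flags[sp] = frozenset(leaves) in sides

    families: list[FamilyCohesion] = []
    cohesive_specimens = 0
    for fam, leaves in sorted(family_leaves.items()):
        pure = [s for s in sides if s and s <= leaves]
        core = max(pure, key=lambda s: (len(s), sorted(s)))
        strays = tuple(sorted(leaves - core))
        cohesive_specimens += len(core)
        if len(leaves) >= 2:
            families.append(FamilyCohesion(fam, cohesive=not strays, strays=strays))

    return MonophylyReport(
        species=species_flags,
        singleton_species=tuple(singletons),
        families=tuple(families),
        specimen_family_cohesion=cohesive_specimens / len(taxonomy),
    )


# ---------------------------------------------------------------------------
# introgression signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntrogressionFlag:
    """One species carrying another species' haplotypes.

    ``nested_leaf_ids`` are the ``nested_species`` individuals found at
    intraspecific K2P distance (below the threshold, percent) of
    ``host_species`` — in the NJ tree they group with or inside the host's
    cluster.  ``min_interspecific_distance`` is the species-level minimum.
    """

    host_species: str
    nested_species: str
    nested_leaf_ids: tuple[str, ...]
    min_interspecific_distance: float


def flag_introgression(tree: TreeNode, matrix: DistanceMatrix,
                       records: Sequence[BarcodeRecord],
                       intra_threshold: float = 2.0) -> list[IntrogressionFlag]:
    """Detect mitochondrial-introgression signatures.

    A species pair is screened when its minimum between-species K2P distance
    falls below ``intra_threshold`` percent (haplotype sharing — orders of
    magnitude below normal congeneric divergence).  The nested (recipient)
    side is the species whose sub-threshold individuals are simultaneously
    deeply diverged (beyond the threshold) from their own remaining
    conspecifics: the classic pattern of foreign individuals carried within
    a host species' haplotype cluster.  When an entire species lies within
    the threshold of the other (full mitochondrial capture), distance cannot
    orient the pair and the tree decides: the host is the species whose
    smallest edge-defined cluster encloses the other's leaves.  One flag is
    emitted per species pair.
    """
    taxonomy = _leaf_taxonomy(tree, records)
    index = {rid: k for k, rid in enumerate(matrix.ids)}

    species_leaves: dict[str, set[str]] = {}
    for leaf, rec in taxonomy.items():
        species_leaves.setdefault(rec.species, set()).add(leaf)
    sides = tree_sides(tree)

    def dist(a: str, b: str) -> float:
        return 100.0 * float(matrix.data[index[a], index[b]])

    def intruders(x: str, y: str) -> set[str]:
        """Leaves of x within the threshold of any leaf of y."""
        return {
            a for a in species_leaves[x]
            if any(dist(a, b) < intra_threshold for b in species_leaves[y])
        }

    def detached(x: str, subset: set[str]) -> bool:
        """subset is a proper part of x, deeply diverged from the rest of x."""
        rest = species_leaves[x] - subset
        if not subset or not rest:
            return False
        return all(
            min(dist(a, b) for b in rest) > intra_threshold for a in subset
        )

    def smallest_cluster(x: str) -> frozenset[str]:
        containing = [s for s in sides if species_leaves[x] <= s]
        return min(containing, key=lambda s: (len(s), sorted(s)))

    flags: list[IntrogressionFlag] = []
    all_species = sorted(species_leaves)
    for i, x in enumerate(all_species):
        for y in all_species[i + 1:]:
            pair_min = 100.0 * float(min(
                matrix.data[index[a], index[b]]
                for a in species_leaves[x] for b in species_leaves[y]
            ))
            if pair_min >= intra_threshold:
                continue
            x_in, y_in = intruders(x, y), intruders(y, x)
            x_det, y_det = detached(x, x_in), detached(y, y_in)
            if x_det and not y_det:
                host, nested, leaves = y, x, x_in
            elif y_det and not x_det:
                host, nested, leaves = x, y, y_in
            else:
                # mutual sharing (e.g. full capture): orient by nesting
                x_inside = species_leaves[x] <= smallest_cluster(y)
                y_inside = species_leaves[y] <= smallest_cluster(x)
                if x_inside and not y_inside:
                    host, nested, leaves = y, x, x_in
                elif y_inside and not x_inside:
                    host, nested, leaves = x, y, y_in
                elif len(x_in) != len(y_in):  # smaller intruder set is nested
                    if len(x_in) < len(y_in):
                        host, nested, leaves = y, x, x_in
                    else:
                        host, nested, leaves = x, y, y_in
                else:
                    host, nested, leaves = x, y, y_in
            flags.append(
                IntrogressionFlag(
                    host_species=host,
                    nested_species=nested,
                    nested_leaf_ids=tuple(sorted(leaves)),
                    min_interspecific_distance=pair_min,
                )
            )
    return flags
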