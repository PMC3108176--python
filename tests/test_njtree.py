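import io

import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from barcodegap import (
    BarcodeError,
    flag_introgression,
    neighbor_joining,
    parse_newick,
    species_monophyly,
    write_newick,
)
from barcodegap.njtree import tree_sides
from conftest import make_record


def leaf_lengths(tree):
    return {t.name: t.length for t in tree.tips()}


def bipartitions(tree):
    """Nontrivial splits as frozensets of the smaller side (independent impl)."""
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(min(side, leaves - side, key=lambda s: (len(s), sorted(s))))
    return splits


def random_additive_tree(rng, n):
    """Random binary topology with positive branch lengths; returns
    (skbio tree, its exact path-length DistanceMatrix)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 0.5))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes.pop(j), nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.05, 0.5))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root, root.tip_tip_distances()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        m = DistanceMatrix(np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
                           ids=["a", "b", "c"])
        tree = neighbor_joining(m)
        assert leaf_lengths(tree) == pytest.approx(
            {"a": 0.05, "b": 0.15, "c": 0.25})

    def test_four_taxon_additive_matrix_recovers_split_and_lengths(self):
        # tree ((A:0.1,B:0.2):0.05,(C:0.1,D:0.3))
        ids = ["A", "B", "C", "D"]
        d = {("A", "B"): 0.3, ("A", "C"): 0.25, ("A", "D"): 0.45,
             ("B", "C"): 0.35, ("B", "D"): 0.55, ("C", "D"): 0.4}
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        tree = neighbor_joining(DistanceMatrix(mat, ids=ids))
        assert bipartitions(tree) == {frozenset({"A", "B"})}
        paths = tree.tip_tip_distances()
        for (x, y), v in d.items():
            assert paths[x, y] == pytest.approx(v, abs=1e-12)

    def test_all_equal_matrix_reproduces_distances(self):
        n = 4
        m = DistanceMatrix(np.ones((n, n)) - np.eye(n), ids=list("abcd"))
        tree = neighbor_joining(m)
        paths = tree.tip_tip_distances()
        for i in "abcd":
            for j in "abcd":
                if i != j:
                    assert paths[i, j] == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_under_reruns(self):
        rng = np.random.default_rng(0)
        _, m = random_additive_tree(rng, 8)
        assert write_newick(neighbor_joining(m)) == write_newick(neighbor_joining(m))

    def test_consistency_on_random_additive_matrices(self):
        """NJ recovers generating topology and path lengths (n <= 12)."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(4, 13))
            true_tree, matrix = random_additive_tree(rng, n)
            recovered = neighbor_joining(matrix)
            assert bipartitions(recovered) == bipartitions(true_tree)
            paths = recovered.tip_tip_distances(list(matrix.ids))
            assert np.abs(paths.data - matrix.filter(paths.ids).data).max() <= 1e-10

    def test_matches_reference_nj_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            _, m = random_additive_tree(rng, 9)
            noisy = m.data + rng.uniform(0, 0.01, m.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0)
            dm = DistanceMatrix(noisy, ids=list(m.ids))
            ours = neighbor_joining(dm)
            reference = skbio_nj(dm)
            assert bipartitions(ours) == bipartitions(reference)

    def test_edge_and_split_counts(self):
        rng = np.random.default_rng(3)
        _, m = random_additive_tree(rng, 10)
        tree = neighbor_joining(m)
        n = 10
        edges = sum(1 for node in tree.traverse(include_self=False))
        assert edges == 2 * n - 3
        assert len(bipartitions(tree)) == n - 3

    def test_too_small_matrix_raises(self):
        m = DistanceMatrix(np.array([[0, 0.1], [0.1, 0]]), ids=["a", "b"])
        with pytest.raises(BarcodeError):
            neighbor_joining(m)


class TestNewick:
    def test_three_leaf_output(self):
        m = DistanceMatrix(np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
                           ids=["a", "b", "c"])
        text = write_newick(neighbor_joining(m))
        parsed = parse_newick(text)
        assert leaf_lengths(parsed) == pytest.approx({"a": 0.05, "b": 0.15, "c": 0.25})

    def test_round_trip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            _, m = random_additive_tree(rng, int(rng.integers(4, 12)))
            tree = neighbor_joining(m)
            again = parse_newick(write_newick(tree))
            assert bipartitions(again) == bipartitions(tree)
            a = tree.tip_tip_distances(sorted(x.name for x in tree.tips()))
            b = again.tip_tip_distances(list(a.ids))
            assert np.allclose(a.data, b.data, atol=1e-9)

    @pytest.mark.parametrize("bad", ["((a,b);", "(a,b)));", "((a:1,b:2:3;"])
    def test_malformed_newick_raises_with_position(self, bad):
        with pytest.raises(BarcodeError, match="position|malformed"):
            parse_newick(bad)


class TestSpeciesMonophyly:
    def _records(self, assignment):
        return [make_record(rid, "ACGT", species=sp, family=fam)
                for rid, (sp, fam) in assignment.items()]

    def test_sorted_cherries_are_monophyletic(self):
        tree = parse_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        records = self._records({r: ("A sp", "F1") for r in ("a1", "a2")}
                                | {r: ("B sp", "F1") for r in ("b1", "b2")})
        report = species_monophyly(tree, records)
        assert report.species == {"A sp": True, "B sp": True}

    def test_interleaved_species_are_not_monophyletic(self):
        tree = parse_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        records = self._records({"a1": ("A sp", "F1"), "a2": ("A sp", "F1"),
                                 "b1": ("B sp", "F1"), "b2": ("B sp", "F1")})
        report = species_monophyly(tree, records)
        assert report.species == {"A sp": False, "B sp": False}

    def test_flags_agree_with_dendropy_oracle_on_random_trees(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(6, 13))
            newick = _random_newick(rng, n)
            tree = parse_newick(newick)
            leaves = sorted(t.name for t in tree.tips())
            n_species = int(rng.integers(2, 5))
            species = {leaf: f"sp{rng.integers(0, n_species)}" for leaf in leaves}
            records = self._records({l: (species[l], "F1") for l in leaves})
            report = species_monophyly(tree, records)
            oracle = _dendropy_monophyly(newick, species)
            assert report.species == oracle

    def test_family_cohesion_counts_strays(self):
        tree = parse_newick("(((a1:1,a2:1):1,x1:1):1,((b1:1,b2:1):1,x2:1):1);")
        assignment = {"a1": ("A sp", "F1"), "a2": ("A sp", "F1"),
                      "b1": ("B sp", "F2"), "b2": ("B sp", "F2"),
                      "x1": ("X sp", "F2"), "x2": ("X sp2", "F1")}
        report = species_monophyly(tree, self._records(assignment))
        by_family = {f.family: f for f in report.families}
        assert not by_family["F1"].cohesive and "x2" in by_family["F1"].strays
        assert not by_family["F2"].cohesive
        assert 0 < report.specimen_family_cohesion < 1


def _random_newick(rng, n):
    names = [f"L{i}" for i in range(n)]

    def build(group):
        if len(group) == 1:
            return f"{group[0]}:{rng.uniform(0.1, 1):.3f}"
        k = int(rng.integers(1, len(group)))
        left, right = group[:k], group[k:]
        return (f"({build(left)},{build(right)}):{rng.uniform(0.1, 1):.3f}")

    perm = [names[i] for i in rng.permutation(n)]
    k = max(1, int(rng.integers(1, n)))
    return f"({build(perm[:k])},{build(perm[k:])});"


def _dendropy_monophyly(newick, species):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    sides = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        sides.add(side)
        sides.add(all_taxa - side)
    leaf_sets = {}
    for leaf, sp in species.items():
        leaf_sets.setdefault(sp, set()).add(leaf)
    return {sp: frozenset(ls) in sides
            for sp, ls in leaf_sets.items() if len(ls) >= 2}


class TestIntrogressionFlag:
    def test_fully_sorted_dataset_yields_no_flags(self, small_dataset):
        records, _, matrix, _ = small_dataset
        tree = neighbor_joining(matrix)
        assert flag_introgression(tree, matrix, records, 2.0) == []

    def test_copied_haplotype_event_is_flagged_once(self):
        from barcodegap import SimulationConfig, simulate_dataset, qc_filter
        from barcodegap import align_by_frame, pairwise_matrix

        config = SimulationConfig(n_families=2, genera_per_family=2,
                                  species_per_genus=2, individuals_per_species=3,
                                  n_introgression_events=1, seed=21)
        records, truth = simulate_dataset(config)
        passing, _ = qc_filter(records)
        matrix = pairwise_matrix(align_by_frame(passing))
        tree = neighbor_joining(matrix)
        flags = flag_introgression(tree, matrix, passing, 2.0)
        assert len(flags) == 1
        event = truth.introgression_events[0]
        assert flags[0].host_species == event["donor_species"]
        assert flags[0].nested_species == event["recipient_species"]
        assert set(flags[0].nested_leaf_ids) == set(event["leaf_ids"])
        assert flags[0].min_interspecific_distance < 2.0
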