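"""Distances, neighbor joining, bootstrap supports and clade extraction."""

import math

import dendropy
import networkx as nx
import numpy as np
import pytest

from polydup import phylo, seqio
from polydup.msa import Alignment
from polydup.phylo import (
    DistanceMatrix,
    bootstrap_supports,
    neighbor_joining,
    p_distance,
    robinson_foulds,
    supported_clades,
)


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(ids=["a", "b"], rows=["ACDE", "ACDE"])
        assert p_distance(aln).values[0, 1] == 0.0

    def test_poisson_correction_half(self):
        """p = 0.5 -> -ln(0.5) = 0.6931."""
        aln = Alignment(ids=["a", "b"], rows=["AAAA", "AACC"])
        d = p_distance(aln, correction="poisson")
        assert d.values[0, 1] == pytest.approx(-math.log(0.5), abs=1e-4)

    def test_pairwise_deletion(self):
        aln = Alignment(ids=["a", "b"], rows=["A-CD", "AB-D"])
        d = p_distance(aln)
        assert d.values[0, 1] == 0.0  # only columns 0 and 3 compared

    def test_saturation_capped(self):
        aln = Alignment(ids=["a", "b"], rows=["AAAA", "CCCC"])
        d = p_distance(aln, correction="poisson")
        assert d.values[0, 1] == pytest.approx(-math.log(1 - 0.95))

    def test_no_shared_columns_names_the_pair(self):
        aln = Alignment(ids=["left", "right"], rows=["A--", "-CC"])
        with pytest.raises(ValueError, match="left.*right"):
            p_distance(aln)

    def test_symmetry_random_alignments(self, rng):
        rows = ["".join(rng.choice(list("ACDE-"), size=30)) for _ in range(6)]
        rows = [r if r.strip("-") else "A" * 30 for r in rows]
        aln = Alignment(ids=[f"s{i}" for i in range(6)], rows=rows)
        d = p_distance(aln).values
        assert np.allclose(d, d.T)


def _matrix(ids, pairs):
    n = len(ids)
    vals = np.zeros((n, n))
    for (a, b), dist in pairs.items():
        i, j = ids.index(a), ids.index(b)
        vals[i, j] = vals[j, i] = dist
    return DistanceMatrix(ids=list(ids), values=vals)


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        """Additive matrix AB=0.3, CD=0.3, AC=0.4, AD=0.5, BC=0.5, BD=0.6
        has the unique tree AB|CD with internal edge 0.2 and leaf edges
        A=0.1, B=0.2, C=0.1, D=0.2."""
        D = _matrix("ABCD", {("A", "B"): 0.3, ("C", "D"): 0.3, ("A", "C"): 0.4,
                             ("A", "D"): 0.5, ("B", "C"): 0.5, ("B", "D"): 0.6})
        tree = neighbor_joining(D)
        assert phylo.tree_bipartitions(tree) == {frozenset({"C", "D"})}
        leaf_len = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert leaf_len == pytest.approx(
            {"A": 0.1, "B": 0.2, "C": 0.1, "D": 0.2}
        )
        internal = [
            n.edge.length
            for n in tree.preorder_node_iter()
            if n is not tree.seed_node and not n.is_leaf()
        ]
        assert internal == pytest.approx([0.2])

    def test_three_taxon_closed_form(self):
        """Unique star resolution: la = (dab + dac - dbc) / 2 etc."""
        D = _matrix("ABC", {("A", "B"): 0.4, ("A", "C"): 0.6, ("B", "C"): 0.8})
        tree = neighbor_joining(D)
        leaf_len = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert leaf_len == pytest.approx({"A": 0.1, "B": 0.3, "C": 0.5})

    def test_fewer_than_three_taxa_rejected(self):
        D = _matrix("AB", {("A", "B"): 0.5})
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(D)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_random_additive_topologies(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(7):
            n_leaves = int(rng.integers(8, 33))
            true_tree = phylo.random_binary_tree(n_leaves, rng)
            D = phylo.additive_matrix_from_tree(true_tree)
            nj = neighbor_joining(D)
            assert robinson_foulds(true_tree, nj) == 0

    def test_path_lengths_reproduce_additive_input(self):
        rng = np.random.default_rng(99)
        true_tree = phylo.random_binary_tree(12, rng)
        D = phylo.additive_matrix_from_tree(true_tree)
        nj = neighbor_joining(D)
        recovered = phylo.patristic_distances(nj)
        assert recovered.ids == D.ids
        assert np.allclose(recovered.values, D.values, atol=1e-9)

    def test_agrees_with_dendropy_rf_oracle(self):
        """Our bipartition-based RF agrees with dendropy's tree comparison."""
        rng = np.random.default_rng(4)
        t1 = phylo.random_binary_tree(10, rng)
        t2 = phylo.random_binary_tree(10, rng)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=seqio.newick_string(t1), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=seqio.newick_string(t2), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert robinson_foulds(t1, t2) == expected


def _diagnostic_alignment(rng, n_diag=30, n_noise=30):
    """8 taxa; A-D and E-H are separated by n_diag invariant-within-clade
    diagnostic columns, plus i.i.d. noise columns."""
    ids = list("ABCDEFGH")
    diag = [["A"] * 4 + ["C"] * 4 for _ in range(n_diag)]
    noise = [list(rng.choice(list("DEFGHIKL"), size=8)) for _ in range(n_noise)]
    cols = diag + noise
    rows = ["".join(col[i] for col in cols) for i in range(8)]
    return Alignment(ids=ids, rows=rows)


class TestBootstrap:
    def test_deterministic_per_seed(self, rng):
        aln = _diagnostic_alignment(rng)
        base = neighbor_joining(p_distance(aln, correction="poisson"))
        t1 = bootstrap_supports(aln, base, n_reps=25, seed=7)
        t2 = bootstrap_supports(aln, base, n_reps=25, seed=7)
        assert seqio.newick_string(t1) == seqio.newick_string(t2)

    def test_single_replicate_supports_are_zero_or_one(self, rng):
        aln = _diagnostic_alignment(rng)
        base = neighbor_joining(p_distance(aln, correction="poisson"))
        boot = bootstrap_supports(aln, base, n_reps=1, seed=3)
        sups = [
            float(n.label)
            for n in boot.preorder_node_iter()
            if n.label not in (None, "")
        ]
        assert sups and all(s in (0.0, 1.0) for s in sups)

    def test_n_reps_below_one_rejected(self, rng):
        aln = _diagnostic_alignment(rng)
        base = neighbor_joining(p_distance(aln, correction="poisson"))
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap_supports(aln, base, n_reps=0)

    def test_diagnostic_clade_gets_high_support(self, rng):
        """30 diagnostic invariant-within-clade columns fix the A-D|E-H
        split in essentially every resample."""
        aln = _diagnostic_alignment(rng)
        base = neighbor_joining(p_distance(aln, correction="poisson"))
        boot = bootstrap_supports(aln, base, n_reps=200, seed=11)
        target = frozenset("EFGH")
        all_leaves = frozenset("ABCDEFGH")
        found = None
        for node in boot.preorder_node_iter():
            if node is boot.seed_node or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if below in (target, all_leaves - target):
                found = float(node.label)
        assert found is not None and found >= 0.99

    def test_supports_invariant_to_row_order(self, rng):
        aln = _diagnostic_alignment(rng)
        perm = list(reversed(range(aln.n_rows)))
        shuffled = Alignment(
            ids=[aln.ids[i] for i in perm], rows=[aln.rows[i] for i in perm]
        )

        def support_map(a):
            base = neighbor_joining(p_distance(a, correction="poisson"))
            boot = bootstrap_supports(a, base, n_reps=50, seed=13)
            out = {}
            for node in boot.preorder_node_iter():
                if node is boot.seed_node or node.is_leaf() or node.label is None:
                    continue
                below = frozenset(l.taxon.label for l in node.leaf_iter())
                key = min(below, frozenset(a.ids) - below, key=sorted)
                out[key] = float(node.label)
            return out

        assert support_map(aln) == support_map(shuffled)


def _decorated_random_tree(rng, n_leaves):
    tree = phylo.random_binary_tree(n_leaves, rng)
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node and not node.is_leaf():
            node.label = f"{rng.uniform():.3f}"
    return tree


def clades_graph_oracle(tree, threshold, orientation):
    """Independent clade extraction: cut each supported internal edge of
    the node graph and read the component away from the orientation leaf."""
    G = nx.Graph()
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            G.add_edge(id(node), id(child))
    label_of = {id(l): l.taxon.label for l in tree.leaf_node_iter()}
    all_leaves = frozenset(label_of.values())
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        support = float(node.label) if node.label else 0.0
        if support < threshold:
            continue
        H = G.copy()
        H.remove_edge(id(node.parent_node), id(node))
        comp = nx.node_connected_component(H, id(node))
        side = frozenset(label_of[n] for n in comp if n in label_of)
        if orientation in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves):
            out.add(side)
    return out


class TestSupportedClades:
    def test_threshold_boundary(self):
        tree = seqio.parse_newick(
            "(((A:1,B:1)0.95:1,C:1)0.85:1,D:1,E:1);"
        )
        assert supported_clades(tree, 0.9, "E") == {frozenset("AB")}
        assert supported_clades(tree, 0.8, "E") == {
            frozenset("AB"), frozenset("ABC")
        }

    def test_zero_threshold_returns_every_internal_edge(self, rng):
        tree = _decorated_random_tree(rng, 12)
        n_internal = sum(
            1
            for n in tree.preorder_node_iter()
            if n is not tree.seed_node and not n.is_leaf()
        )
        assert len(supported_clades(tree, 0.0, "t01")) == n_internal

    def test_above_one_threshold_returns_empty(self, rng):
        tree = _decorated_random_tree(rng, 12)
        assert supported_clades(tree, 1.0 + 1e-9, "t01") == set()

    def test_missing_orientation_leaf_rejected(self, rng):
        tree = _decorated_random_tree(rng, 8)
        with pytest.raises(ValueError, match="orientation"):
            supported_clades(tree, 0.5, "nope")

    def test_graph_cut_oracle_on_random_trees(self, rng):
        for _ in range(30):
            n_leaves = int(rng.integers(6, 20))
            tree = _decorated_random_tree(rng, n_leaves)
            for threshold in (0.0, 0.3, 0.7, 0.9):
                ours = supported_clades(tree, threshold, "t01")
                oracle = clades_graph_oracle(tree, threshold, "t01")
                assert ours == oracle
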