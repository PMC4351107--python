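"""Subfamily anchoring, phylogroup/subgroup assignment, duplication-mode
calls, fusion detection and the motif association test."""

import math
import warnings
from itertools import product

import networkx as nx
import numpy as np
import pytest
from scipy.stats import fisher_exact

from polydup import archclass, phylo, seqio, validate
from polydup.archclass import (
    assign_phylogroups,
    assign_subfamilies,
    classify_duplication_mode,
    detect_fusion_loci,
    fisher_exact_p,
    motif_group_association,
)
from polydup.phylo import DistanceMatrix


ANCHORS = {"ref_R": "R", "ref_F": "F"}


class TestAssignSubfamilies:
    def test_cherry_with_anchor(self):
        tree = seqio.parse_newick(
            "((u1:0.05,ref_R:0.05)0.9:1.0,ref_F:0.1,u2:0.1);"
        )
        labels = assign_subfamilies(tree, ANCHORS)
        assert labels["u1"] == "R"
        assert labels["u2"] == "F"  # 0.2 to ref_F vs 1.2 to ref_R

    def test_equidistant_tie_is_other(self):
        tree = seqio.parse_newick("(u1:0.1,ref_R:0.1,ref_F:0.1);")
        assert assign_subfamilies(tree, ANCHORS)["u1"] == "other"

    def test_missing_anchor_subfamily_rejected(self):
        tree = seqio.parse_newick("(u1:0.1,ref_R:0.1,u2:0.1);")
        with pytest.raises(ValueError, match="anchor"):
            assign_subfamilies(tree, {"ref_R": "R"})

    def test_graph_path_oracle_on_random_trees(self, rng):
        """Nearest anchor by patristic distance agrees with shortest-path
        lengths computed on the node graph."""
        for _ in range(10):
            tree = phylo.random_binary_tree(int(rng.integers(6, 15)), rng)
            leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
            anchors = {leaves[0]: "R", leaves[1]: "F"}
            labels = assign_subfamilies(tree, anchors)
            G = nx.Graph()
            for node in tree.preorder_node_iter():
                for child in node.child_nodes():
                    G.add_edge(id(node), id(child), weight=child.edge.length)
            node_of = {l.taxon.label: id(l) for l in tree.leaf_node_iter()}
            for leaf in leaves[2:]:
                d_r = nx.shortest_path_length(
                    G, node_of[leaf], node_of[leaves[0]], weight="weight")
                d_f = nx.shortest_path_length(
                    G, node_of[leaf], node_of[leaves[1]], weight="weight")
                expected = "other" if abs(d_r - d_f) <= 1e-12 else (
                    "R" if d_r < d_f else "F")
                assert labels[leaf] == expected


class TestAssignPhylogroups:
    def test_group_with_two_subgroups(self):
        """A six-unit F clade at 0.95 holding two 0.85 triples becomes
        group F1 with subgroups 1 and 2."""
        tree = seqio.parse_newick(
            "(((u1:0.1,u2:0.1,u3:0.1)0.85:0.1,(u4:0.1,u5:0.1,u6:0.1)0.85:0.1)"
            "0.95:0.1,ref_F:0.1,(rx:0.1,ref_R:0.1)0.5:0.5);"
        )
        subfam = assign_subfamilies(tree, ANCHORS)
        labels, groups = assign_phylogroups(tree, subfam, ANCHORS)
        assert groups["F1"] == frozenset({"u1", "u2", "u3", "u4", "u5", "u6"})
        assert labels["u1"] == ("F1", 1)
        assert labels["u2"] == ("F1", 1)
        assert labels["u4"] == ("F1", 2)
        assert labels["ref_F"] == ("F0", 0)
        assert labels["rx"] == ("R0", 0)

    def test_all_supports_low_means_group_zero(self):
        tree = seqio.parse_newick(
            "((u1:0.1,u2:0.1)0.5:0.1,ref_F:0.1,(rx:0.1,ref_R:0.1)0.5:0.5);"
        )
        subfam = assign_subfamilies(tree, ANCHORS)
        labels, groups = assign_phylogroups(tree, subfam, ANCHORS)
        assert groups == {}
        assert labels["u1"] == ("F0", 0)
        assert labels["rx"] == ("R0", 0)

    def test_every_leaf_gets_exactly_one_label(self, rng):
        for _ in range(5):
            tree = phylo.random_binary_tree(int(rng.integers(8, 16)), rng)
            for node in tree.preorder_node_iter():
                if node is not tree.seed_node and not node.is_leaf():
                    node.label = f"{rng.uniform():.2f}"
            leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
            anchors = {leaves[0]: "R", leaves[1]: "F"}
            subfam = assign_subfamilies(tree, anchors)
            labels, _ = assign_phylogroups(tree, subfam, anchors)
            assert set(labels) == set(leaves)

    def test_brute_force_maximality_oracle(self, rng):
        """Group membership equals an independent enumeration: take all
        supported single-subfamily clades from the graph-cut oracle, keep
        the subset-maximal ones, and number them by size."""
        from tests.test_phylo import clades_graph_oracle

        for _ in range(25):
            tree = phylo.random_binary_tree(int(rng.integers(8, 18)), rng)
            for node in tree.preorder_node_iter():
                if node is not tree.seed_node and not node.is_leaf():
                    node.label = f"{rng.uniform():.2f}"
            leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
            anchors = {leaves[0]: "R", leaves[1]: "F"}
            subfam = assign_subfamilies(tree, anchors)
            labels, groups = assign_phylogroups(tree, subfam, anchors)
            for subfamily in ("R", "F"):
                other_anchor = leaves[1] if subfamily == "R" else leaves[0]
                cands = {
                    c
                    for c in clades_graph_oracle(tree, 0.9, other_anchor)
                    if all(subfam[m] == subfamily for m in c)
                }
                expected_maximal = {
                    c for c in cands if not any(c < o for o in cands)
                }
                ours = {
                    m for g, m in groups.items() if g.startswith(subfamily)
                }
                assert ours == expected_maximal
                # subgroups: maximal supported proper subsets of each group
                # (a laminar family, so the maximal ones partition cleanly)
                for gname, gclade in groups.items():
                    if not gname.startswith(subfamily):
                        continue
                    subs = {
                        c
                        for c in clades_graph_oracle(tree, 0.8, other_anchor)
                        if c < gclade
                    }
                    subs = {c for c in subs if not any(c < o for o in subs)}
                    numbered = {labels[m][1] for m in gclade} - {0}
                    got = {
                        frozenset(m for m in gclade if labels[m] == (gname, si))
                        for si in numbered
                    }
                    assert got == subs


def _dmat(ids, dists):
    n = len(ids)
    vals = np.zeros((n, n))
    for (a, b), d in dists.items():
        i, j = ids.index(a), ids.index(b)
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids=list(ids), values=vals)


class TestDuplicationMode:
    def test_adjacent_tandem_pair_intragenic(self):
        dmat = _dmat(["u1", "u2", "u3"],
                     {("u1", "u2"): 0.01, ("u1", "u3"): 0.5, ("u2", "u3"): 0.5})
        locus = {"u1": "L1", "u2": "L1", "u3": "L9"}
        calls = classify_duplication_mode(dmat, locus)
        assert calls["u1"].mode == "intragenic"
        assert calls["u2"].mode == "intragenic"
        assert calls["u3"].mode == "intergenic"

    def test_identical_single_unit_loci_intergenic(self):
        dmat = _dmat(["u1", "u2"], {("u1", "u2"): 0.0})
        calls = classify_duplication_mode(dmat, {"u1": "L1", "u2": "L2"})
        assert calls["u1"].mode == "intergenic"
        assert calls["u2"].mode == "intergenic"

    def test_two_sided_exact_tie_is_ambiguous(self):
        dmat = _dmat(["u1", "u2", "u3"],
                     {("u1", "u2"): 0.0, ("u1", "u3"): 0.0, ("u2", "u3"): 0.1})
        locus = {"u1": "L1", "u2": "L1", "u3": "L2"}
        assert classify_duplication_mode(dmat, locus)["u1"].mode == "ambiguous"

    def test_single_unit_rejected(self):
        dmat = _dmat(["u1"], {})
        with pytest.raises(ValueError, match="at least 2"):
            classify_duplication_mode(dmat, {"u1": "L1"})

    def test_excluded_ids_ignored(self):
        dmat = _dmat(["u1", "u2", "ref"],
                     {("u1", "u2"): 0.3, ("u1", "ref"): 0.01, ("u2", "ref"): 0.3})
        locus = {"u1": "L1", "u2": "L2", "ref": "L0"}
        calls = classify_duplication_mode(dmat, locus, exclude=["ref"])
        assert set(calls) == {"u1", "u2"}
        assert calls["u1"].nearest_id == "u2"

    def test_conversion_noise_degrades_recovery_monotonically(self):
        """Raising the gene-conversion rate strictly lowers mode-recovery
        accuracy over the same replicate seeds."""
        seeds = range(20)
        accs = [
            validate.mode_accuracy_at_conversion(seeds, conv)
            for conv in (0.0, 0.3, 0.9)
        ]
        assert accs[0] > accs[1] > accs[2]


class TestFusionLoci:
    def test_mixed_locus_detected_with_composition(self):
        subfam = {"a": "F", "b": "F", "c": "R"}
        fusions = detect_fusion_loci(subfam, {"L1": ["a", "b", "c"]})
        assert fusions == {"L1": "F×2+R×1"}

    def test_pure_locus_not_fusion(self):
        assert detect_fusion_loci({"a": "F", "b": "F"}, {"L1": ["a", "b"]}) == {}

    def test_truth_log_oracle_on_replicates(self, default_sim):
        """Set-intersection brute force over truth labels agrees with the
        detector fed the same labels."""
        _, genome, truth = default_sim
        locus_units = {l.id: list(l.unit_ids) for l in genome.loci}
        detected = set(detect_fusion_loci(truth.subfamily, locus_units))
        brute = {
            lid
            for lid, uids in locus_units.items()
            if {"R", "F"} <= {truth.subfamily[u] for u in uids}
        }
        assert detected == brute


def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration with exact integer arithmetic."""
    n_total, row, col = a + b + c + d, a + b, a + c
    if row in (0, n_total) or col in (0, n_total):
        return 1.0
    denom = math.comb(n_total, col)

    def pmf(k):
        return math.comb(row, k) * math.comb(n_total - row, col - k) / denom

    lo, hi = max(0, row + col - n_total), min(row, col)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_diagonal_three_table(self):
        """[[3,0],[0,3]]: P(0)=P(3)=1/20, two-sided sum = 0.1."""
        assert fisher_exact_p([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_degenerate_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_p([[0, 0], [0, 5]]) == 1.0

    def test_enumeration_oracle_small_tables(self):
        for a, b, c, d in product(range(4), repeat=4):
            if not 0 < a + b + c + d <= 8:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # degenerate-margin tables
                ours = fisher_exact_p([[a, b], [c, d]])
            assert ours == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_matches_scipy_two_sided(self):
        """Independent route: scipy's Fisher exact on nondegenerate tables."""
        for table in ([[3, 1], [1, 3]], [[5, 0], [2, 4]], [[2, 2], [2, 2]],
                      [[7, 1], [0, 4]]):
            _, scipy_p = fisher_exact(table, alternative="two-sided")
            assert fisher_exact_p(table) == pytest.approx(scipy_p, abs=1e-12)


class TestMotifAssociation:
    def test_table_orientation_and_p(self):
        motif = {"L1": True, "L2": True, "L3": True, "L4": False,
                 "L5": False, "L6": False}
        focal = {"L1": True, "L2": True, "L3": True, "L4": False,
                 "L5": False, "L6": False}
        table, p = motif_group_association(motif, focal)
        assert table.tolist() == [[3, 0], [0, 3]]
        assert p == pytest.approx(0.1)

    def test_indicator_domains_must_match(self):
        with pytest.raises(ValueError, match="different loci"):
            motif_group_association({"L1": True}, {"L2": True})
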