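"""Distance-based phylogenetics: p-distances, neighbor-joining, bootstrap
supports, and support-thresholded clade extraction.

Supports are bootstrap proportions on [0, 1]; the classification layer
applies its thresholds (0.9 for groups, 0.8 for subgroups) directly to
these values. Negative NJ branch-length estimates are clamped to zero
with the deficit moved to the sister edge, as is standard practice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .msa import GAP, Alignment
from .simfamily import RES_INDEX


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix has nonzero diagonal")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix has non-finite entries")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def _encode_alignment(aln: Alignment) -> np.ndarray:
    """Integer-encode rows; gaps and unknown residues become -1."""
    enc = np.full((aln.n_rows, aln.n_cols), -1, dtype=np.int16)
    for i, row in enumerate(aln.rows):
        for j, res in enumerate(row):
            if res != GAP:
                enc[i, j] = RES_INDEX.get(res, -1)
    return enc


def _pdist_encoded(
    enc: np.ndarray, ids: Sequence[str], correction: str
) -> DistanceMatrix:
    valid = enc >= 0
    # broadcast all-pairs comparison; n^2 * L booleans
    both = valid[:, None, :] & valid[None, :, :]
    compared = both.sum(axis=2)
    mism = (both & (enc[:, None, :] != enc[None, :, :])).sum(axis=2)
    n = enc.shape[0]
    bad = (compared == 0) & ~np.eye(n, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"no pairwise-complete columns between {ids[i]!r} and {ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        p = np.where(compared > 0, mism / np.maximum(compared, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    if correction == "poisson":
        d = -np.log(1.0 - np.minimum(p, 0.95))
    elif correction == "none":
        d = p
    else:
        raise ValueError(f"unknown correction {correction!r}")
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(ids), values=d)


def p_distance(aln: Alignment, correction: str = "none") -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gapped columns.

    ``correction="poisson"`` applies d = -ln(1-p) with p capped at 0.95.
    A pair with zero pairwise-complete columns is an error naming the pair.
    """
    return _pdist_encoded(_encode_alignment(aln), aln.ids, correction)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining.

    Deterministic tie-break on the Q criterion by the lexicographically
    smallest (cluster key) pair, where a cluster's key is its smallest
    leaf label. Returns an unrooted dendropy tree whose seed node is the
    final trifurcation.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(D.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for label in D.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        keys.append(label)
    mat = D.values.astype(float).copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = mat.sum(axis=1)
        Q = (m - 2) * mat - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qmin = Q[iu].min()
        cand = [
            (i, j)
            for i, j in zip(*iu)
            if Q[i, j] <= qmin + 1e-12
        ]
        i, j = min(cand, key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))))
        dij = mat[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_row = 0.5 * (mat[i, :] + mat[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        new_mat = np.zeros((m - 1, m - 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_row[keep]
        new_mat[:-1, -1] = new_row[keep]
        new_key = min(keys[i], keys[j])
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [new_key]
        mat = new_mat

    # final three clusters join at the seed trifurcation
    a, b, c = 0, 1, 2
    la = 0.5 * (mat[a, b] + mat[a, c] - mat[b, c])
    lb = 0.5 * (mat[a, b] + mat[b, c] - mat[a, c])
    lc = 0.5 * (mat[a, c] + mat[b, c] - mat[a, b])
    for node, length in zip(nodes, (la, lb, lc)):
        tree.seed_node.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------

def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets, normalised to the side
    NOT containing the lexicographically smallest leaf."""
    all_leaves = _leaf_labels(tree)
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(all_leaves) - 1:
            continue
        if ref in below:
            below = frozenset(all_leaves - below)
        out.add(below)
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    b1, b2 = tree_bipartitions(t1), tree_bipartitions(t2)
    return len(b1 ^ b2)


def bootstrap_supports(
    aln: Alignment,
    tree: dendropy.Tree,
    n_reps: int = 400,
    seed: int = 0,
    correction: str = "poisson",
) -> dendropy.Tree:
    """Attach bootstrap-proportion supports to a tree's internal edges.

    Columns are resampled with replacement ``n_reps`` times, a NJ tree is
    rebuilt from each resampled alignment, and each internal edge's support
    is the fraction of replicate trees containing the same bipartition.
    Supports are written as internal-node labels; deterministic per seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa_tree = _leaf_labels(tree)
    if taxa_tree != set(aln.ids):
        raise ValueError("alignment taxa do not match tree taxa")
    enc = _encode_alignment(aln)
    ncol = enc.shape[1]
    rng = np.random.default_rng(seed)
    counts: Counter[frozenset[str]] = Counter()
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        sub = enc[:, cols]
        try:
            d = _pdist_encoded(sub, aln.ids, correction)
        except ValueError:
            continue  # a resample with an all-gap pair contributes nothing
        rep_tree = neighbor_joining(d)
        counts.update(tree_bipartitions(rep_tree))

    out = dendropy.Tree(tree)  # deep clone, shared taxon namespace semantics
    all_leaves = _leaf_labels(out)
    ref = min(all_leaves)
    for node in out.preorder_node_iter():
        if node is out.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        key = frozenset(all_leaves - below) if ref in below else below
        if len(key) <= 1 or len(key) >= len(all_leaves) - 1:
            node.label = None
            continue
        node.label = f"{counts[key] / n_reps:.6g}"
    return out


def supported_clades(
    tree: dendropy.Tree,
    threshold: float,
    orientation_leaf: str,
) -> set[frozenset[str]]:
    """Leaf-sets of internal edges with support >= threshold.

    Bipartitions are turned into clades by reading each internal edge from
    the side NOT containing ``orientation_leaf`` (the outgroup anchor).
    Unlabelled internal edges count as support 0.
    """
    all_leaves = _leaf_labels(tree)
    if orientation_leaf not in all_leaves:
        raise ValueError(f"orientation leaf {orientation_leaf!r} absent from tree")
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        clade = frozenset(all_leaves - below) if orientation_leaf in below else below
        if len(clade) <= 1 or len(clade) >= len(all_leaves):
            continue
        label = node.label
        support = float(label) if label not in (None, "") else 0.0
        if support >= threshold:
            out.add(clade)
    return out


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (patristic) distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(_leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids=labels, values=vals)


# ---------------------------------------------------------------------------
# Random additive trees (validation utilities)
# ---------------------------------------------------------------------------

def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_bl: float = 0.05,
    max_bl: float = 0.5,
) -> dendropy.Tree:
    """Random unrooted binary tree with U(min_bl, max_bl) branch lengths.

    Grown by repeatedly splitting a uniformly chosen edge to attach the
    next leaf; leaves are labelled t01, t02, ...
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves for a non-trivial unrooted tree")
    labels = [f"t{i + 1:02d}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    for label in labels[:3]:
        child = dendropy.Node(taxon=taxa.get_taxon(label))
        tree.seed_node.add_child(child)
    for label in labels[3:]:
        edges = [
            node for node in tree.preorder_node_iter() if node is not tree.seed_node
        ]
        host = edges[int(rng.integers(len(edges)))]
        parent = host.parent_node
        mid = dendropy.Node()
        parent.remove_child(host)
        parent.add_child(mid)
        mid.add_child(host)
        leaf = dendropy.Node(taxon=taxa.get_taxon(label))
        mid.add_child(leaf)
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.edge.length = float(rng.uniform(min_bl, max_bl))
    tree.is_rooted = False
    return tree


def additive_matrix_from_tree(tree: dendropy.Tree) -> DistanceMatrix:
    return patristic_distances(tree)
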