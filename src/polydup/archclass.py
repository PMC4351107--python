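"""Classification of antenna-protein units: subfamily anchoring,
phylogroup/subgroup assignment from supported clades, intragenic- vs
intergenic-duplication calls, fusion-locus detection, and the junction
motif / group association test.

Scheme: each unit is anchored to a subfamily (R or F) by its nearest
reference sequence in patristic distance; phylogroups are the maximal
single-subfamily clades supported at >= 0.9, subgroups the maximal
supported clades at >= 0.8 nested strictly inside a group. Group labels
are ordinal by descending size (F1 is always the largest F group by
construction). A unit's duplication mode is read off its nearest homolog:
same locus = intragenic, different locus = intergenic, exact tie both
ways = ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.stats import hypergeom

from .phylo import DistanceMatrix, patristic_distances, supported_clades

SUBFAMILIES = ("R", "F")


@dataclass
class Assignment:
    unit_id: str
    locus_id: str
    position: int
    subfamily: str  # 'R', 'F' or 'other'
    group: str  # e.g. 'F1'; '<subfamily>0' = no supported group
    subgroup: int  # 0 = no phylogenetic affiliation with any other subgroup


@dataclass
class DuplicationCall:
    unit_id: str
    mode: str  # 'intragenic', 'intergenic' or 'ambiguous'
    nearest_id: str
    distance: float


def assign_subfamilies(
    tree: dendropy.Tree, anchors: Mapping[str, str]
) -> dict[str, str]:
    """Label every leaf by the subfamily of its nearest anchor.

    ``anchors`` maps leaf label -> 'R' or 'F'; at least one anchor per
    subfamily must be present in the tree. Distance is patristic; an exact
    tie between the nearest R and F anchors yields 'other'.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    by_subfam: dict[str, list[str]] = {"R": [], "F": []}
    for label, subfam in anchors.items():
        if subfam not in SUBFAMILIES:
            raise ValueError(f"anchor {label!r} has unknown subfamily {subfam!r}")
        if label not in leaves:
            raise ValueError(f"anchor {label!r} is not a leaf of the tree")
        by_subfam[subfam].append(label)
    if not by_subfam["R"] or not by_subfam["F"]:
        raise ValueError("need at least one anchor per subfamily (R and F)")
    dmat = patristic_distances(tree)
    idx = {label: i for i, label in enumerate(dmat.ids)}
    out: dict[str, str] = {}
    for label in leaves:
        if label in anchors:
            out[label] = anchors[label]
            continue
        i = idx[label]
        d_r = min(dmat.values[i, idx[a]] for a in by_subfam["R"])
        d_f = min(dmat.values[i, idx[a]] for a in by_subfam["F"])
        if abs(d_r - d_f) <= 1e-12:
            out[label] = "other"
        else:
            out[label] = "R" if d_r < d_f else "F"
    return out


def _maximal(clades: set[frozenset[str]]) -> list[frozenset[str]]:
    return [
        c for c in clades if not any(c < other for other in clades)
    ]


def _ordinal_sort(clades: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    return sorted(clades, key=lambda c: (-len(c), min(c)))


def assign_phylogroups(
    tree: dendropy.Tree,
    subfamilies: Mapping[str, str],
    anchors: Mapping[str, str],
    group_threshold: float = 0.9,
    subgroup_threshold: float = 0.8,
) -> tuple[dict[str, tuple[str, int]], dict[str, frozenset[str]]]:
    """Assign (group, subgroup) labels to every leaf.

    Groups are the maximal supported clades (support >= group_threshold)
    whose members all share one subfamily; within each group, subgroups are
    the maximal supported clades at >= subgroup_threshold that are proper
    subsets of the group. Labels are ordinal by descending member count
    (ties by smallest member id); units in no group get '<subfamily>0',
    units in no subgroup get subgroup 0.

    Orientation for turning bipartitions into clades is the opposite
    subfamily's (lexicographically first) anchor, so each subfamily is
    read as rooted by the other.

    Returns (labels per leaf, group label -> member leaf-set).
    """
    anchor_of = {
        subfam: min(l for l, s in anchors.items() if s == subfam)
        for subfam in SUBFAMILIES
    }
    labels: dict[str, tuple[str, int]] = {}
    group_members: dict[str, frozenset[str]] = {}
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for subfam in SUBFAMILIES:
        other = "F" if subfam == "R" else "R"
        orientation = anchor_of[other]
        clades_group = {
            c
            for c in supported_clades(tree, group_threshold, orientation)
            if all(subfamilies.get(m) == subfam for m in c)
        }
        groups = _ordinal_sort(_maximal(clades_group))
        clades_sub = supported_clades(tree, subgroup_threshold, orientation)
        members_of_subfam = {m for m in leaves if subfamilies.get(m) == subfam}
        placed: set[str] = set()
        for gi, gclade in enumerate(groups, start=1):
            gname = f"{subfam}{gi}"
            group_members[gname] = gclade
            sub_cands = {c for c in clades_sub if c < gclade}
            subs = _ordinal_sort(_maximal(sub_cands))
            sub_of: dict[str, int] = {}
            for si, sclade in enumerate(subs, start=1):
                for m in sclade:
                    sub_of.setdefault(m, si)
            for m in gclade:
                labels[m] = (gname, sub_of.get(m, 0))
            placed |= gclade
        for m in members_of_subfam - placed:
            labels[m] = (f"{subfam}0", 0)
    for m in leaves:
        if m not in labels:  # subfamily 'other'
            labels[m] = ("other0", 0)
    return labels, group_members


def classify_duplication_mode(
    dmat: DistanceMatrix,
    locus_of: Mapping[str, str],
    tolerance: float = 1e-9,
    exclude: Sequence[str] = (),
) -> dict[str, DuplicationCall]:
    """Call intragenic vs intergenic duplication per unit.

    The nearest homolog is the arg-min distance over all other units; all
    candidates within ``tolerance`` of the minimum are considered tied.
    Ties within the unit's own locus only -> intragenic; across loci only
    -> intergenic; both -> ambiguous.
    """
    excluded = set(exclude)
    ids = [i for i in dmat.ids if i not in excluded]
    if len(ids) < 2:
        raise ValueError("duplication-mode calling needs at least 2 units")
    pos = {label: i for i, label in enumerate(dmat.ids)}
    calls: dict[str, DuplicationCall] = {}
    for uid in ids:
        i = pos[uid]
        others = [o for o in ids if o != uid]
        dists = np.array([dmat.values[i, pos[o]] for o in others])
        dmin = float(dists.min())
        cands = [o for o, d in zip(others, dists) if d <= dmin + tolerance]
        same = [c for c in cands if locus_of[c] == locus_of[uid]]
        cross = [c for c in cands if locus_of[c] != locus_of[uid]]
        if same and cross:
            mode = "ambiguous"
            nearest = min(same + cross)
        elif same:
            mode = "intragenic"
            nearest = min(same)
        else:
            mode = "intergenic"
            nearest = min(cross)
        calls[uid] = DuplicationCall(uid, mode, nearest, dmin)
    return calls


def detect_fusion_loci(
    subfamilies: Mapping[str, str],
    locus_units: Mapping[str, Sequence[str]],
) -> dict[str, str]:
    """Loci whose units span both subfamilies, with a composition string.

    A locus is a fusion locus iff it carries at least one R-labelled and
    one F-labelled unit. Composition strings look like 'F×2+R×1'.
    """
    out: dict[str, str] = {}
    for locus_id, unit_ids in locus_units.items():
        tally = {"F": 0, "R": 0, "other": 0}
        for uid in unit_ids:
            tally[subfamilies.get(uid, "other")] += 1
        if tally["R"] >= 1 and tally["F"] >= 1:
            parts = [
                f"{sub}×{tally[sub]}" for sub in ("F", "R", "other") if tally[sub]
            ]
            out[locus_id] = "+".join(parts)
    return out


def fisher_exact_p(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    point probability is <= the observed one (relative slack 1e-12).
    Degenerate margins (an all-zero row or column) give p = 1 with a
    warning.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        warnings.warn("degenerate margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_total, row1, col1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def motif_group_association(
    motif_by_locus: Mapping[str, bool],
    focal_by_locus: Mapping[str, bool],
) -> tuple[np.ndarray, float]:
    """2x2 association of junction-motif presence vs focal-group membership.

    Rows: locus in the focal group (yes/no); columns: junction motif
    present (yes/no). Both indicators must be defined for every locus.
    Returns (table, two-sided Fisher exact p).
    """
    if set(motif_by_locus) != set(focal_by_locus):
        raise ValueError("motif and group indicators cover different loci")
    table = np.zeros((2, 2), dtype=int)
    for locus_id, has_motif in motif_by_locus.items():
        row = 0 if focal_by_locus[locus_id] else 1
        col = 0 if has_motif else 1
        table[row, col] += 1
    return table, fisher_exact_p(table.tolist())
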