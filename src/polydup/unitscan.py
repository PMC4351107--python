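"""Decompose polyproteins into single antenna-protein units.

A fixed-length position weight matrix (PWM) built from a gapless seed
alignment is slid over every start offset of each polyprotein; high-scoring,
non-overlapping windows become unit spans. This is a deliberately simple
profile scan: the simulator emits fixed-length units without indels, and
downstream classification needs unit presence and identity, not HMM-grade
boundary modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import Locus
from .simfamily import NRES, RES_INDEX

#: log-odds background: uniform residue frequencies
BACKGROUND = 1.0 / NRES


@dataclass
class Profile:
    """Per-position log-odds scores (bits) over the 20 residues.

    score(pos, r) = log2( (count(pos, r) + 1) / (N + 20) / 0.05 )
    with pseudocount 1 per cell and uniform background 0.05.
    """

    scores: np.ndarray  # (length, 20)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def consensus_self_score(self) -> float:
        """Score of the consensus sequence against the profile."""
        return float(self.scores.max(axis=1).sum())


@dataclass
class UnitSpan:
    unit_id: str
    locus_id: str
    start: int
    end: int
    score: float
    sequence: str

    @property
    def rank(self) -> int:
        # rank within locus is positional; assigned by scan order helpers
        return getattr(self, "_rank", 0)


def build_profile(seed_alignment: Sequence[str]) -> Profile:
    """Build a PWM from gapless, equal-length aligned sequences."""
    seqs = list(seed_alignment)
    if not seqs:
        raise ValueError("empty seed alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged seed alignment: sequences differ in length")
    counts = np.zeros((length, NRES), dtype=float)
    for seq in seqs:
        for pos, res in enumerate(seq):
            if res not in RES_INDEX:
                raise ValueError(f"unknown residue {res!r} in seed alignment")
            counts[pos, RES_INDEX[res]] += 1
    n = len(seqs)
    scores = np.log2(((counts + 1.0) / (n + NRES)) / BACKGROUND)
    return Profile(scores=scores)


def _encode(seq: str) -> np.ndarray:
    return np.array([RES_INDEX.get(r, -1) for r in seq], dtype=np.int64)


def scan_polyprotein(
    locus: Locus,
    profile: Profile,
    min_score: float | None = None,
    min_len: int | None = None,
    max_len: int | None = None,
) -> list[UnitSpan]:
    """Scan one polyprotein with the profile.

    Every start offset is scored; candidates are accepted greedily in
    descending score order (ties broken by smaller start), skipping any
    candidate overlapping an accepted span, then filtered at ``min_score``
    (default: half the profile's consensus self-score).
    """
    plen = profile.length
    if min_len is not None and plen < min_len:
        raise ValueError("profile shorter than min_len")
    if max_len is not None and plen > max_len:
        raise ValueError("profile longer than max_len")
    if min_score is None:
        min_score = 0.5 * profile.consensus_self_score
    seq = locus.polyprotein
    n_offsets = len(seq) - plen + 1
    if n_offsets <= 0:
        return []
    enc = _encode(seq)
    # unknown residues contribute the worst score in their column
    col_min = profile.scores.min(axis=1)
    offsets_scores = np.empty(n_offsets)
    positions = np.arange(plen)
    for off in range(n_offsets):
        window = enc[off : off + plen]
        known = window >= 0
        vals = np.where(known, profile.scores[positions, np.where(known, window, 0)], col_min)
        offsets_scores[off] = vals.sum()
    order = sorted(range(n_offsets), key=lambda o: (-offsets_scores[o], o))
    accepted: list[tuple[int, int, float]] = []
    occupied = np.zeros(len(seq), dtype=bool)
    for off in order:
        if offsets_scores[off] < min_score:
            break  # descending order: nothing further can pass
        if occupied[off : off + plen].any():
            continue
        accepted.append((off, off + plen, float(offsets_scores[off])))
        occupied[off : off + plen] = True
    accepted.sort()
    spans = []
    for i, (start, end, score) in enumerate(accepted):
        span = UnitSpan(
            unit_id=f"{locus.id}.{i + 1}",
            locus_id=locus.id,
            start=start,
            end=end,
            score=score,
            sequence=seq[start:end],
        )
        span._rank = i + 1
        spans.append(span)
    return spans


def collapse_redundant(
    units: Iterable[UnitSpan],
) -> tuple[list[UnitSpan], list[tuple[str, str]]]:
    """Remove same-locus identical-sequence duplicates (splice-form echoes).

    Among units sharing residue sequence AND locus id, the one with the
    smallest start survives. Identical sequences on *different* loci are
    retained — they are exactly the intergenic-duplication signal.

    Returns (kept units, removal log of (removed_id, kept_id) pairs).
    """
    best: dict[tuple[str, str], UnitSpan] = {}
    order: list[tuple[str, str]] = []
    removed: list[tuple[str, str]] = []
    for unit in units:
        key = (unit.locus_id, unit.sequence)
        if key not in best:
            best[key] = unit
            order.append(key)
        elif unit.start < best[key].start:
            removed.append((best[key].unit_id, unit.unit_id))
            best[key] = unit
        else:
            removed.append((unit.unit_id, best[key].unit_id))
    kept = [best[k] for k in order]
    kept.sort(key=lambda u: (u.locus_id, u.start))
    return kept, removed


@dataclass
class MotifHits:
    """Positions (0-based start) of exact motif hits in one polyprotein."""

    junction: list[int]
    within_unit: list[int]
    flanking: list[int]

    @property
    def n_junction(self) -> int:
        return len(self.junction)


def find_junction_motifs(locus: Locus, motif: str) -> MotifHits:
    """Locate exact motif hits relative to the locus's unit spans.

    A hit is a *junction* hit if it is not fully inside a unit and
    intersects the gap between two consecutive unit spans (boundary
    overlaps up to len(motif)-1 residues count). Hits fully inside a
    unit body are reported separately; hits in terminal flanks are
    classified as flanking.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not locus.unit_spans:
        raise ValueError(f"locus {locus.id} has no unit spans")
    seq = locus.polyprotein
    m = len(motif)
    hits: list[int] = []
    pos = seq.find(motif)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(motif, pos + 1)  # overlapping hits allowed
    gaps = [
        (self_end, next_start)
        for (_, self_end), (next_start, _) in zip(locus.unit_spans, locus.unit_spans[1:])
    ]
    out = MotifHits([], [], [])
    for h in hits:
        h_end = h + m
        if any(s <= h and h_end <= e for s, e in locus.unit_spans):
            out.within_unit.append(h)
        elif any(h < g_end and h_end > g_start for g_start, g_end in gaps):
            out.junction.append(h)
        else:
            out.flanking.append(h)
    return out


# ---------------------------------------------------------------------------
# TSV i/o for unit tables
# ---------------------------------------------------------------------------

UNITS_TSV_HEADER = "unit_id\tlocus_id\tstart\tend\tscore\tsequence"


def write_units_tsv(units: Sequence[UnitSpan], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(UNITS_TSV_HEADER + "\n")
        for u in units:
            handle.write(
                f"{u.unit_id}\t{u.locus_id}\t{u.start}\t{u.end}\t{u.score:.4f}\t{u.sequence}\n"
            )


def read_units_tsv(path: str | Path) -> list[UnitSpan]:
    units: list[UnitSpan] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header != UNITS_TSV_HEADER:
            raise ValueError(f"unexpected units.tsv header in {path}")
        for line in handle:
            uid, lid, start, end, score, seq = line.rstrip("\n").split("\t")
            units.append(
                UnitSpan(
                    unit_id=uid,
                    locus_id=lid,
                    start=int(start),
                    end=int(end),
                    score=float(score),
                    sequence=seq,
                )
            )
    return units
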