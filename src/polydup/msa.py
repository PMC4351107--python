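"""Progressive multiple alignment of unit sequences and gap-column trimming.

Pairwise global alignment is affine-gap Needleman-Wunsch (Gotoh) with
BLOSUM62 defaults; a gap of length k costs ``gap_open + (k-1)*gap_extend``.
Progressive alignment builds a UPGMA guide tree on a k-mer multiset
distance and merges profiles by profile-profile NW, scoring column pairs
by the mean pairwise substitution score of their non-gap residues.

Traceback tie-break is fixed (diagonal, then up = gap in the second
sequence, then left), so alignments are deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .simfamily import ALPHABET, NRES, RES_INDEX

GAP = "-"
DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0

_NEG = float("-inf")


def blosum62() -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    out: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            out[(a, b)] = float(mat[a][b])
    return out


_BLOSUM62 = None


def _default_matrix() -> dict[tuple[str, str], float]:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = blosum62()
    return _BLOSUM62


def _blosum_array() -> np.ndarray:
    """BLOSUM62 restricted to the 20-residue alphabet, as a (20, 20) array."""
    mat = _default_matrix()
    arr = np.zeros((NRES, NRES))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            arr[i, j] = mat[(a, b)]
    return arr


@dataclass
class Alignment:
    """Ordered rows of equal-length gapped sequences."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise ValueError("alignment rows differ in length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


# ---------------------------------------------------------------------------
# Pairwise affine-gap global alignment (Gotoh)
# ---------------------------------------------------------------------------

def pairwise_nw(
    a: str,
    b: str,
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[str, str, float]:
    """Global alignment of two sequences maximising the affine-gap score.

    Returns (aligned_a, aligned_b, score). A length-k gap costs
    ``gap_open + (k-1)*gap_extend``. Deterministic traceback preferring
    diagonal, then up (consume a), then left (consume b).
    """
    if matrix is None:
        matrix = _default_matrix()
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return "", "", 0.0
    if n == 0:
        return GAP * m, b, gap_open + (m - 1) * gap_extend
    if m == 0:
        return a, GAP * n, gap_open + (n - 1) * gap_extend

    # state matrices: M ends in a match column, X ends with gap in b
    # (a consumed; "up"), Y ends with gap in a ("left")
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = matrix[(ai, b[j - 1])]
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(
                M[i - 1, j] + gap_open,
                X[i - 1, j] + gap_extend,
                Y[i - 1, j] + gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] + gap_open,
                X[i, j - 1] + gap_open,
                Y[i, j - 1] + gap_extend,
            )

    # traceback; preference order M (diag) > X (up) > L (left) at every step
    states = {"M": M, "X": X, "Y": Y}
    score = max(M[n, m], X[n, m], Y[n, m])
    state = next(k for k in ("M", "X", "Y") if states[k][n, m] == score)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - matrix[(a[i - 1], b[j - 1])]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = next(k for k in ("M", "X", "Y") if states[k][i, j] == target)
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            val = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + gap_open == val:
                state = "M"
            elif X[i, j] + gap_extend == val:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + gap_open == val:
                state = "M"
            elif X[i, j] + gap_open == val:
                state = "X"
            else:
                state = "Y"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - |shared k-mer multiset| / max(len(a), len(b))."""
    if not a or not b:
        return 1.0
    ka = Counter(a[i : i + k] for i in range(max(len(a) - k + 1, 0)))
    kb = Counter(b[i : i + k] for i in range(max(len(b) - k + 1, 0)))
    shared = sum((ka & kb).values())
    return 1.0 - shared / max(len(a), len(b))


def _profile_columns(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Residue-count matrix (ncol, 20) and non-gap totals per column."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, NRES))
    for row in rows:
        for pos, res in enumerate(row):
            if res == GAP:
                continue
            idx = RES_INDEX.get(res)
            if idx is None:
                raise ValueError(f"residue {res!r} outside the 20-letter alphabet")
            counts[pos, idx] += 1
    return counts, counts.sum(axis=1)


def _profile_nw(
    rows_a: list[str],
    rows_b: list[str],
    subst: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Align two profiles; returns gap-expanded copies of each row set.

    Column-column score = mean pairwise substitution score over non-gap
    residue pairs (0 if either column is all-gap). The horizontal-gap
    state is computed with a running-max unroll so each DP row is
    vectorised.
    """
    ca, ta = _profile_columns(rows_a)
    cb, tb = _profile_columns(rows_b)
    la, lb = ca.shape[0], cb.shape[0]
    denom = ta[:, None] * tb[None, :]
    colscore = np.zeros((la, lb))
    np.divide(ca @ subst @ cb.T, denom, out=colscore, where=denom > 0)

    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)
    Y = np.full((la + 1, lb + 1), _NEG)
    M[0, 0] = 0.0
    X[1:, 0] = gap_open + np.arange(la) * gap_extend
    Y[0, 1:] = gap_open + np.arange(lb) * gap_extend
    for i in range(1, la + 1):
        prev_best = np.maximum.reduce([M[i - 1], X[i - 1], Y[i - 1]])
        M[i, 1:] = colscore[i - 1] + prev_best[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + gap_open,
            X[i - 1, 1:] + gap_extend,
        )
        # Y[i, j] = max_k<j ( max(M,X)[i, k] + open + (j-1-k)*extend )
        base = np.maximum(M[i, :-1], X[i, :-1]) + gap_open
        idx = np.arange(lb)
        Y[i, 1:] = gap_extend * idx + np.maximum.accumulate(base - gap_extend * idx)

    tol = 1e-9
    states = {"M": M, "X": X, "Y": Y}
    end_score = max(M[la, lb], X[la, lb], Y[la, lb])
    state = next(k for k in ("M", "X", "Y") if states[k][la, lb] >= end_score - tol)
    ops: list[str] = []  # 'D' diagonal, 'U' up (gap in b), 'L' left (gap in a)
    i, j = la, lb
    while i > 0 or j > 0:
        if state == "M":
            ops.append("D")
            target = M[i, j] - colscore[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = next(k for k in ("M", "X", "Y") if states[k][i, j] >= target - tol)
        elif state == "X":
            ops.append("U")
            val = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if i == 0:
                state = "X"
            elif abs(M[i, j] + gap_open - val) <= tol:
                state = "M"
            elif abs(X[i, j] + gap_extend - val) <= tol:
                state = "X"
            else:
                state = "Y"
        else:
            ops.append("L")
            val = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if j == 0:
                state = "Y"
            elif abs(M[i, j] + gap_open - val) <= tol:
                state = "M"
            elif abs(X[i, j] + gap_open - val) <= tol:
                state = "X"
            else:
                state = "Y"
    ops.reverse()

    def expand(rows: list[str], consume: str) -> list[str]:
        width = len(rows[0])
        out = [[] for _ in rows]
        pos = 0
        for op in ops:
            if op == consume or op == "D":
                for r, row in enumerate(rows):
                    out[r].append(row[pos])
                pos += 1
            else:
                for r in range(len(rows)):
                    out[r].append(GAP)
        assert pos == width
        return ["".join(chars) for chars in out]

    return expand(rows_a, "U"), expand(rows_b, "L")


def progressive_align(
    sequences: Sequence[tuple[str, str]],
    k: int = 3,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Progressive alignment along a UPGMA guide tree on k-mer distances.

    ``sequences`` is an ordered collection of (id, sequence); the output
    preserves the input row order. De-gapping any output row reproduces
    its input sequence exactly (asserted).
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Alignment(ids=[seqs[0][0]], rows=[seqs[0][1]])
    subst = _blosum_array()
    if len(seqs) == 2:
        (id_a, a), (id_b, b) = seqs
        ra, rb = _profile_nw([a], [b], subst, gap_open, gap_extend)
        aln = Alignment(ids=[id_a, id_b], rows=[ra[0], rb[0]])
    else:
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        n = len(seqs)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = kmer_distance(seqs[i][1], seqs[j][1], k)
        Z = linkage(squareform(dist, checks=False), method="average")
        clusters: dict[int, tuple[list[str], list[str]]] = {
            i: ([seqs[i][0]], [seqs[i][1]]) for i in range(n)
        }
        for step, (left, right, _d, _n) in enumerate(Z):
            ids_a, rows_a = clusters.pop(int(left))
            ids_b, rows_b = clusters.pop(int(right))
            new_a, new_b = _profile_nw(rows_a, rows_b, subst, gap_open, gap_extend)
            clusters[n + step] = (ids_a + ids_b, new_a + new_b)
        (ids, rows), = clusters.values()
        row_of = dict(zip(ids, rows))
        aln = Alignment(
            ids=[sid for sid, _ in seqs], rows=[row_of[sid] for sid, _ in seqs]
        )
    for (sid, seq), row in zip(seqs, aln.rows):
        assert row.replace(GAP, "") == seq, f"row {sid} does not de-gap to its input"
    return aln


def trim_columns(
    aln: Alignment, max_gap_fraction: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds the threshold.

    Returns the trimmed alignment and the kept-column index map (indices
    into the input alignment), for projecting coordinates back.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    n = aln.n_rows
    kept = []
    for col in range(aln.n_cols):
        gaps = sum(1 for row in aln.rows if row[col] == GAP)
        if gaps / n <= max_gap_fraction:
            kept.append(col)
    if not kept:
        raise ValueError(
            "all columns removed by trimming; raise max_gap_fraction"
        )
    rows = ["".join(row[c] for c in kept) for row in aln.rows]
    return Alignment(ids=list(aln.ids), rows=rows), kept
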