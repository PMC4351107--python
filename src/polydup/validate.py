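"""Parameter-recovery experiments against the simulator's ground truth.

These are the package's own validation harness: simulate a gene family
with a known event history, push the rendered FASTA/GFF3 through the
detection/alignment/classification stack, and score the recovered calls
against the truth log. Used by both the test suite and the acceptance
script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import archclass, msa, phylo, simfamily, unitscan


@dataclass
class RecoveryResult:
    """Scores for one simulate-and-recover replicate."""

    n_true_units: int
    n_scanned: int
    n_matched: int  # scanned spans matched to true units
    n_boundary_exact: int
    mode_correct: int = 0
    mode_committed: int = 0
    mode_ambiguous: int = 0
    mode_evaluated: int = 0
    fusion_tp: int = 0
    fusion_fp: int = 0
    fusion_fn: int = 0

    @property
    def unit_recall(self) -> float:
        return self.n_matched / self.n_true_units if self.n_true_units else 1.0


def _match_spans(
    rendered: list, scanned: list[unitscan.UnitSpan], slack: int = 2
) -> dict[str, tuple[str, int]]:
    """Map scanned unit ids to true unit ids by span proximity.

    Returns {scanned_id: (true_id, boundary_error)} where boundary_error is
    the larger of the start/end offsets; spans are matched greedily to the
    overlapping true span with the same locus.
    """
    true_spans: dict[str, list[tuple[str, int, int]]] = {}
    for locus in rendered:
        true_spans[locus.id] = [
            (uid, s, e) for uid, (s, e) in zip(locus.unit_ids, locus.unit_spans)
        ]
    out: dict[str, tuple[str, int]] = {}
    for span in scanned:
        best: tuple[int, str] | None = None
        for uid, s, e in true_spans.get(span.locus_id, ()):
            if span.start < e and span.end > s:  # overlap
                err = max(abs(span.start - s), abs(span.end - e))
                if best is None or err < best[0]:
                    best = (err, uid)
        if best is not None:
            out[span.unit_id] = (best[1], best[0])
    return out


def recovery_replicate(
    seed: int, sim_overrides: dict | None = None
) -> RecoveryResult:
    """One full simulate -> render -> scan -> classify recovery run.

    Classification runs on the *uncollapsed* scanned units: the redundancy
    collapse step exists to merge alternative-splice echoes, which the
    simulator does not emit, and same-locus identical copies here are
    genuine tandem duplicates. Mode truth is each unit's most recent
    duplication event (see :meth:`TruthLog.latest_duplication_mode`);
    accuracy is scored over committed (non-ambiguous) calls.
    """
    overrides = dict(sim_overrides or {})
    overrides["seed"] = seed
    config = simfamily.SimConfig(**overrides)
    genome, truth = simfamily.evolve(config)
    rendered = simfamily.render(genome, config)
    profile = unitscan.build_profile(list(genome.references.values()))
    scanned: list[unitscan.UnitSpan] = []
    for locus in rendered:
        scanned.extend(unitscan.scan_polyprotein(locus, profile))
    matches = _match_spans(rendered, scanned)
    result = RecoveryResult(
        n_true_units=genome.n_units,
        n_scanned=len(scanned),
        n_matched=len(matches),
        n_boundary_exact=sum(1 for _, err in matches.values() if err == 0),
    )
    if len(scanned) < 2:
        return result

    # identity distances over the aligned (trimmed) scanned units + anchors
    refs = sorted(genome.references.items())
    aln = msa.progressive_align(
        [(u.unit_id, u.sequence) for u in scanned] + refs
    )
    trimmed, _ = msa.trim_columns(aln)
    anchor_ids = [rid for rid, _ in refs]
    dmat = phylo.p_distance(trimmed, correction="none")
    locus_of = {u.unit_id: u.locus_id for u in scanned}
    calls = archclass.classify_duplication_mode(
        dmat, locus_of, exclude=anchor_ids
    )
    truth_mode = truth.latest_duplication_mode()
    for scan_id, call in calls.items():
        match = matches.get(scan_id)
        if match is None:
            continue
        expected = truth_mode.get(match[0])
        if expected is None:
            continue  # founders and never-duplicated units carry no mode
        result.mode_evaluated += 1
        if call.mode == "ambiguous":
            result.mode_ambiguous += 1
            continue
        result.mode_committed += 1
        result.mode_correct += int(call.mode == expected)

    # fusion loci: subfamily labels from the NJ tree anchored at the founders
    dist_corr = phylo.p_distance(trimmed, correction="poisson")
    tree = phylo.neighbor_joining(dist_corr)
    anchors = {rid: rid.split("_")[-1] for rid in anchor_ids}
    subfam = archclass.assign_subfamilies(tree, anchors)
    locus_units: dict[str, list[str]] = {}
    for u in scanned:
        locus_units.setdefault(u.locus_id, []).append(u.unit_id)
    predicted = set(archclass.detect_fusion_loci(subfam, locus_units))
    actual = {
        locus.id
        for locus in genome.loci
        if len({truth.subfamily[uid] for uid in locus.unit_ids}) > 1
    }
    result.fusion_tp = len(predicted & actual)
    result.fusion_fp = len(predicted - actual)
    result.fusion_fn = len(actual - predicted)
    return result


@dataclass
class RecoverySummary:
    replicates: list[RecoveryResult] = field(default_factory=list)

    @property
    def mode_accuracy(self) -> float:
        """Pooled accuracy over committed calls across replicates."""
        committed = sum(r.mode_committed for r in self.replicates)
        correct = sum(r.mode_correct for r in self.replicates)
        return correct / committed if committed else float("nan")

    @property
    def committed_fraction(self) -> float:
        evaluated = sum(r.mode_evaluated for r in self.replicates)
        committed = sum(r.mode_committed for r in self.replicates)
        return committed / evaluated if evaluated else float("nan")

    @property
    def fusion_precision(self) -> float:
        tp = sum(r.fusion_tp for r in self.replicates)
        fp = sum(r.fusion_fp for r in self.replicates)
        return tp / (tp + fp) if tp + fp else 1.0

    @property
    def fusion_recall(self) -> float:
        tp = sum(r.fusion_tp for r in self.replicates)
        fn = sum(r.fusion_fn for r in self.replicates)
        return tp / (tp + fn) if tp + fn else 1.0

    @property
    def unit_recall(self) -> float:
        matched = sum(r.n_matched for r in self.replicates)
        true = sum(r.n_true_units for r in self.replicates)
        return matched / true if true else 1.0


def run_recovery(
    seeds: list[int] | range, sim_overrides: dict | None = None
) -> RecoverySummary:
    summary = RecoverySummary()
    for seed in seeds:
        summary.replicates.append(recovery_replicate(seed, sim_overrides))
    return summary


def mode_accuracy_at_conversion(
    seeds: list[int] | range, conversion_rate: float
) -> float:
    """Registry-level mode recovery at a given conversion rate.

    Classifies directly on the simulator's unit registry (no scan/align),
    isolating the classifier's response to gene-conversion noise.
    """
    OK = TOT = 0
    for seed in seeds:
        config = simfamily.SimConfig(seed=seed, rate_conversion=conversion_rate)
        genome, truth = simfamily.evolve(config)
        ids = [uid for locus in genome.loci for uid in locus.unit_ids]
        rows = [genome.units[uid].sequence() for uid in ids]
        aln = msa.Alignment(ids=ids, rows=rows)
        dmat = phylo.p_distance(aln, correction="none")
        calls = archclass.classify_duplication_mode(dmat, genome.locus_of())
        truth_mode = truth.latest_duplication_mode()
        for uid, call in calls.items():
            expected = truth_mode.get(uid)
            if expected is None or call.mode == "ambiguous":
                continue
            TOT += 1
            OK += int(call.mode == expected)
    return OK / TOT if TOT else float("nan")


def nj_additive_recovery(n_trials: int, seed: int, n_leaves_range=(8, 32)) -> float:
    """Fraction of random additive matrices whose NJ tree matches the
    generating topology (Robinson-Foulds distance 0)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_trials):
        n_leaves = int(rng.integers(n_leaves_range[0], n_leaves_range[1] + 1))
        true_tree = phylo.random_binary_tree(n_leaves, rng)
        dmat = phylo.additive_matrix_from_tree(true_tree)
        nj = phylo.neighbor_joining(dmat)
        hits += int(phylo.robinson_foulds(true_tree, nj) == 0)
    return hits / n_trials
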