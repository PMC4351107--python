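"""Pipeline orchestration: simulate -> scan -> align -> tree -> classify,
as one reproducible run with logging and a machine-readable summary.

One global seed governs every stochastic stage; each stage derives its own
sub-seed from a hash of (seed, stage name), so adding a stage never shifts
another stage's randomness. Every stage reads its inputs from disk and
writes its outputs to disk, so any stage can be re-run in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import archclass, msa, phylo, seqio, simfamily, unitscan

log = logging.getLogger("polydup.pipeline")


def derive_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    ``sim`` holds :class:`~.simfamily.SimConfig` field overrides; set
    ``sim = None`` and supply ``fasta``/``gff``/``references``/``anchors``
    paths to run on externally provided gene models instead.
    """

    seed: int = 0
    sim: dict | None = field(default_factory=dict)
    fasta: str | None = None
    gff: str | None = None
    references: str | None = None
    anchors: str | None = None
    motif: str = "SPLR"
    min_score_frac: float = 0.5
    trim_max_gap: float = 0.5
    distance_correction: str = "poisson"
    bootstrap_reps: int = 400
    group_threshold: float = 0.9
    subgroup_threshold: float = 0.8
    mode_distance: str = "identity"  # or "patristic"
    mode_tolerance: float = 1e-9

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=False)


def _setup_run_log(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("polydup")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> None:
    sim_kwargs = dict(config.sim or {})
    sim_kwargs.setdefault("seed", derive_seed(config.seed, "simulate"))
    sim_config = simfamily.SimConfig(**sim_kwargs)
    log.info("simulate: %s", sim_config)
    genome, truth = simfamily.evolve(sim_config)
    simfamily.write_outputs(genome, truth, sim_config, outdir)
    log.info(
        "simulate: %d loci, %d units, %d events",
        len(genome.loci),
        genome.n_units,
        len(truth.events),
    )


def stage_scan(config: RunConfig, outdir: Path) -> None:
    fasta = Path(config.fasta) if config.fasta else outdir / "genome.fasta"
    gff = Path(config.gff) if config.gff else outdir / "loci.gff3"
    refs = (
        Path(config.references) if config.references else outdir / "references.fasta"
    )
    seqs = {rec.id: str(rec.seq) for rec in seqio.read_fasta(fasta)}
    loci = seqio.read_gff3(gff, sequences=seqs)
    seed_seqs = [str(rec.seq) for rec in seqio.read_fasta(refs)]
    profile = unitscan.build_profile(seed_seqs)
    min_score = config.min_score_frac * profile.consensus_self_score
    log.info(
        "scan: profile length %d, min_score %.1f bits (frac %.2f)",
        profile.length,
        min_score,
        config.min_score_frac,
    )
    all_units: list[unitscan.UnitSpan] = []
    motif_rows: list[tuple[str, int, int]] = []
    for locus in loci:
        spans = unitscan.scan_polyprotein(locus, profile, min_score=min_score)
        all_units.extend(spans)
        scanned = seqio.Locus(
            id=locus.id,
            scaffold=locus.scaffold,
            strand=locus.strand,
            polyprotein=locus.polyprotein,
            unit_spans=[(s.start, s.end) for s in spans],
            unit_ids=[s.unit_id for s in spans],
        )
        if spans:
            hits = unitscan.find_junction_motifs(scanned, config.motif)
            motif_rows.append((locus.id, hits.n_junction, len(hits.within_unit)))
        else:
            motif_rows.append((locus.id, 0, 0))
    unitscan.write_units_tsv(all_units, outdir / "units_raw.tsv")
    kept, removed = unitscan.collapse_redundant(all_units)
    unitscan.write_units_tsv(kept, outdir / "units.tsv")
    with open(outdir / "units_removed.tsv", "w") as handle:
        handle.write("removed_id\tkept_id\n")
        for removed_id, kept_id in removed:
            handle.write(f"{removed_id}\t{kept_id}\n")
    with open(outdir / "motif_hits.tsv", "w") as handle:
        handle.write("locus_id\tjunction_hits\twithin_unit_hits\n")
        for locus_id, nj, nw in motif_rows:
            handle.write(f"{locus_id}\t{nj}\t{nw}\n")
    log.info("scan: %d raw units, %d after redundancy collapse", len(all_units), len(kept))


def stage_align(config: RunConfig, outdir: Path) -> None:
    units = unitscan.read_units_tsv(outdir / "units.tsv")
    refs = (
        Path(config.references) if config.references else outdir / "references.fasta"
    )
    ref_records = [(rec.id, str(rec.seq)) for rec in seqio.read_fasta(refs)]
    seqs = [(u.unit_id, u.sequence) for u in units] + ref_records
    aln = msa.progressive_align(seqs)
    trimmed, kept_cols = msa.trim_columns(aln, config.trim_max_gap)
    seqio.write_fasta(zip(aln.ids, aln.rows), outdir / "aln_full.fasta")
    seqio.write_fasta(zip(trimmed.ids, trimmed.rows), outdir / "aln.fasta")
    with open(outdir / "aln_kept_columns.txt", "w") as handle:
        handle.write(",".join(map(str, kept_cols)) + "\n")
    log.info(
        "align: %d rows, %d columns (%d kept after trimming at %.2f)",
        aln.n_rows,
        aln.n_cols,
        trimmed.n_cols,
        config.trim_max_gap,
    )


def _read_alignment(path: Path) -> msa.Alignment:
    records = seqio.read_fasta(path)
    return msa.Alignment(ids=[r.id for r in records], rows=[str(r.seq) for r in records])


def stage_tree(config: RunConfig, outdir: Path) -> None:
    aln = _read_alignment(outdir / "aln.fasta")
    dmat = phylo.p_distance(aln, correction=config.distance_correction)
    tree = phylo.neighbor_joining(dmat)
    tree = phylo.bootstrap_supports(
        aln,
        tree,
        n_reps=config.bootstrap_reps,
        seed=derive_seed(config.seed, "bootstrap"),
        correction=config.distance_correction,
    )
    seqio.write_newick(tree, outdir / "tree.nwk")
    log.info(
        "tree: %d taxa, %d bootstrap replicates (%s-corrected distances)",
        aln.n_rows,
        config.bootstrap_reps,
        config.distance_correction,
    )


def stage_classify(config: RunConfig, outdir: Path) -> dict:
    tree = seqio.read_newick(outdir / "tree.nwk")
    aln = _read_alignment(outdir / "aln.fasta")
    units = unitscan.read_units_tsv(outdir / "units.tsv")
    anchors_path = (
        Path(config.anchors) if config.anchors else outdir / "anchors.tsv"
    )
    anchors: dict[str, str] = {}
    with open(anchors_path) as handle:
        handle.readline()
        for line in handle:
            label, subfam = line.rstrip("\n").split("\t")
            anchors[label] = subfam

    subfam = archclass.assign_subfamilies(tree, anchors)
    labels, groups = archclass.assign_phylogroups(
        tree,
        subfam,
        anchors,
        group_threshold=config.group_threshold,
        subgroup_threshold=config.subgroup_threshold,
    )
    if config.mode_distance == "patristic":
        dmat = phylo.patristic_distances(tree)
    else:
        dmat = phylo.p_distance(aln, correction="none")
    locus_of = {u.unit_id: u.locus_id for u in units}
    calls = archclass.classify_duplication_mode(
        dmat,
        locus_of,
        tolerance=config.mode_tolerance,
        exclude=sorted(anchors),
    )
    locus_units: dict[str, list[str]] = {}
    for u in units:
        locus_units.setdefault(u.locus_id, []).append(u.unit_id)
    fusions = archclass.detect_fusion_loci(subfam, locus_units)

    motif_by_locus: dict[str, bool] = {}
    with open(outdir / "motif_hits.tsv") as handle:
        handle.readline()
        for line in handle:
            locus_id, n_junction, _ = line.rstrip("\n").split("\t")
            if locus_id in locus_units:
                motif_by_locus[locus_id] = int(n_junction) > 0
    # focal clade for the motif association: the most expanded F lineage —
    # the largest detected F subgroup, or the largest F group if no
    # subgroup resolved
    unit_ids_set = {u.unit_id for u in units}
    subgroup_sizes: dict[tuple[str, int], int] = {}
    for uid in unit_ids_set:
        grp, sub = labels[uid]
        if grp.startswith("F") and sub != 0:
            subgroup_sizes[(grp, sub)] = subgroup_sizes.get((grp, sub), 0) + 1
    if subgroup_sizes:
        focal = min(subgroup_sizes, key=lambda k: (-subgroup_sizes[k], k))
        focal_group = f"{focal[0]}.{focal[1]}"
        in_focal = lambda uid: labels[uid] == focal  # noqa: E731
    else:
        f_groups = sorted(g for g in groups if g.startswith("F"))
        focal_group = f_groups[0] if f_groups else None
        in_focal = lambda uid: labels[uid][0] == focal_group  # noqa: E731
    focal_by_locus = {
        locus_id: any(in_focal(u) for u in uids)
        for locus_id, uids in locus_units.items()
    }
    if focal_group is not None and motif_by_locus:
        table, motif_p = archclass.motif_group_association(
            motif_by_locus, focal_by_locus
        )
    else:
        table, motif_p = np.zeros((2, 2), dtype=int), 1.0

    # position within locus, by start coordinate
    position: dict[str, int] = {}
    for locus_id, uids in locus_units.items():
        starts = {u.unit_id: u.start for u in units if u.locus_id == locus_id}
        for pos, uid in enumerate(sorted(uids, key=lambda x: starts[x])):
            position[uid] = pos
    with open(outdir / "assign.tsv", "w") as handle:
        handle.write(
            "unit_id\tlocus_id\tposition\tsubfamily\tgroup\tsubgroup\t"
            "mode\tnearest_id\tnearest_dist\n"
        )
        for u in units:
            grp, sub = labels[u.unit_id]
            call = calls[u.unit_id]
            handle.write(
                f"{u.unit_id}\t{u.locus_id}\t{position[u.unit_id]}\t"
                f"{subfam[u.unit_id]}\t{grp}\t{sub}\t{call.mode}\t"
                f"{call.nearest_id}\t{call.distance:.6f}\n"
            )
    with open(outdir / "fusion.tsv", "w") as handle:
        handle.write("locus_id\tcomposition\n")
        for locus_id in sorted(fusions):
            handle.write(f"{locus_id}\t{fusions[locus_id]}\n")
    with open(outdir / "motif_assoc.tsv", "w") as handle:
        handle.write("focal_group\tmotif_yes\tmotif_no\n")
        handle.write(f"{focal_group}\t{table[0, 0]}\t{table[0, 1]}\n")
        handle.write(f"other\t{table[1, 0]}\t{table[1, 1]}\n")
        handle.write(f"# two-sided Fisher exact p = {motif_p:.6g}\n")

    mode_counts = {"intragenic": 0, "intergenic": 0, "ambiguous": 0}
    for call in calls.values():
        mode_counts[call.mode] += 1
    n_groups = {
        s: len([g for g in groups if g.startswith(s)]) for s in ("F", "R")
    }
    n_subgroups = len(
        {
            (labels[u.unit_id][0], labels[u.unit_id][1])
            for u in units
            if labels[u.unit_id][1] != 0
        }
    )
    raw_units = unitscan.read_units_tsv(outdir / "units_raw.tsv")
    trimmed = _read_alignment(outdir / "aln.fasta")
    summary = {
        "n_loci": len(locus_units),
        "n_units_detected": len(raw_units),
        "n_units_nonredundant": len(units),
        "alignment_columns": trimmed.n_cols,
        "n_groups": n_groups,
        "n_subgroups": n_subgroups,
        "mode_counts": mode_counts,
        "n_fusion_loci": len(fusions),
        "motif_table": table.tolist(),
        "motif_fisher_p": motif_p,
        "focal_group": focal_group,
    }
    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    log.info("classify: %s", summary)
    return summary


STAGES = ("simulate", "scan", "align", "tree", "classify")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages into ``outdir``; returns the summary dict.

    A stage failure aborts with the stage name and cause; outputs of
    completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir)
    config.to_yaml(outdir / "run_config.yaml")
    summary: dict = {}
    try:
        for stage in STAGES:
            if stage == "simulate" and config.sim is None:
                continue
            func = {
                "simulate": stage_simulate,
                "scan": stage_scan,
                "align": stage_align,
                "tree": stage_tree,
                "classify": stage_classify,
            }[stage]
            try:
                result = func(config, outdir)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            if stage == "classify":
                summary = result
    finally:
        logging.getLogger("polydup").removeHandler(handler)
        handler.close()
    return summary


def report(outdir: str | Path) -> str:
    """Per-locus architecture strings, units in genomic order.

    One line per locus: ``locus_id<TAB>F1.2|F1.2|R3.1`` where each field is
    ``<group>.<subgroup>``. Loci appear in the order of the input locus map;
    single-member groups are flagged as singleton lineages.
    """
    outdir = Path(outdir)
    rows: dict[str, dict] = {}
    with open(outdir / "assign.tsv") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        for line in handle:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            rows[rec["unit_id"]] = rec
    gff = outdir / "loci.gff3"
    if gff.exists():
        locus_order = [locus.id for locus in seqio.read_gff3(gff)]
    else:
        locus_order = sorted({r["locus_id"] for r in rows.values()})
    group_sizes: dict[str, int] = {}
    for rec in rows.values():
        group_sizes[rec["group"]] = group_sizes.get(rec["group"], 0) + 1
    lines = []
    for locus_id in locus_order:
        members = sorted(
            (r for r in rows.values() if r["locus_id"] == locus_id),
            key=lambda r: int(r["position"]),
        )
        if not members:
            continue
        fields = []
        for rec in members:
            tag = f"{rec['group']}.{rec['subgroup']}"
            if group_sizes[rec["group"]] == 1 and not rec["group"].endswith("0"):
                tag += "*"  # singleton lineage, distinct from 'unplaced'
            fields.append(tag)
        lines.append(f"{locus_id}\t" + "|".join(fields))
    text = "\n".join(lines) + "\n"
    with open(outdir / "report.txt", "w") as handle:
        handle.write(text)
    return text


def compare_to_reference(summary: dict, reference: dict) -> dict:
    """Per-quantity diffs against externally published counts.

    ``reference`` maps summary keys (e.g. ``n_units_detected``) to expected
    integers; returns {key: {"observed", "expected", "diff"}}. Intended for
    the external benchmark mode where real gene models are supplied; exact
    agreement is not promised across tool substitutions, so this reports
    rather than asserts.
    """
    out = {}
    for key, expected in reference.items():
        observed = summary.get(key)
        diff = None if observed is None else observed - expected
        out[key] = {"observed": observed, "expected": expected, "diff": diff}
    return out
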