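"""Forward simulator of multigene-family evolution on polyprotein loci.

The model: two divergent founder subfamilies (R-like, associated with PSI-type
antenna proteins; F-like, the fucoxanthin/peridinin-type antenna lineage),
each starting as a single-unit locus. Per generation, Poisson numbers of five
event kinds act on the genome:

* ``intragenic_dup`` — a unit is copied in place, the copy inserted adjacent
  to its template within the same locus (tandem repeat growth);
* ``intergenic_dup`` — a unit (or, with probability 0.5, its whole locus) is
  copied into a brand-new locus (dispersed duplication);
* ``fusion`` — a copy of a unit is appended to a locus whose units all belong
  to the *other* subfamily, creating a mixed-subfamily (fusion) locus;
* ``conversion`` — a unit's sequence is overwritten by a uniformly chosen
  paralog (non-reciprocal homogenisation, modelled as full-unit overwrite);
* ``loss`` — a unit is deleted, guarded so a subfamily never goes extinct.

After the events of a generation, every site of every unit mutates
independently with a fixed per-site probability to a uniformly chosen
different residue. All randomness flows from one seeded generator, so a
config (including its seed) maps to byte-identical outputs.

Every event is recorded in a :class:`TruthLog`; downstream classification is
validated by recovering this log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .seqio import Locus, write_fasta, write_gff3

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NRES = len(ALPHABET)
RES_INDEX = {r: i for i, r in enumerate(ALPHABET)}

#: residues inserted between units when rendering a polyprotein
LINKER = "GSGSGSGS"

EVENT_KINDS = ("intragenic_dup", "intergenic_dup", "fusion", "conversion", "loss")


@dataclass
class SimConfig:
    """Simulation parameters.

    Rates are expected events per generation (Poisson); the substitution
    probability is per site per generation. ``founder_divergence`` is the
    exact fraction of sites at which the two subfamily founders differ.
    ``motif_subgroup`` names the single true subgroup whose junctions carry
    the cleavage motif in rendered polyproteins; the default ``"auto"``
    resolves, at render time, to the largest surviving F subgroup — the
    motif belongs to the most expanded lineage, and an explicit label could
    denote a lineage that went extinct during the run.
    """

    n_generations: int = 60
    rate_intragenic: float = 0.3
    rate_intergenic: float = 0.3
    rate_fusion: float = 0.05
    rate_conversion: float = 0.0
    rate_loss: float = 0.05
    subst_per_site_per_generation: float = 3e-4
    unit_length: int = 120
    founder_divergence: float = 0.4
    motif: str = "SPLR"
    motif_subgroup: str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "rate_intragenic": self.rate_intragenic,
            "rate_intergenic": self.rate_intergenic,
            "rate_fusion": self.rate_fusion,
            "rate_conversion": self.rate_conversion,
            "rate_loss": self.rate_loss,
        }
        for name, rate in rates.items():
            if not np.isfinite(rate) or rate < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not 0.0 <= self.subst_per_site_per_generation < 1.0:
            raise ValueError("subst_per_site_per_generation must be in [0, 1)")
        if not 0.0 <= self.founder_divergence <= 1.0:
            raise ValueError("founder_divergence must be in [0, 1]")
        if self.unit_length < 4 * len(self.motif):
            raise ValueError("unit_length must be at least 4x the motif length")
        if self.n_generations < 0:
            raise ValueError("n_generations must be non-negative")
        other = (
            self.rate_intragenic + self.rate_intergenic + self.rate_fusion
        )
        if self.rate_loss > 0 and other == 0:
            warnings.warn(
                "loss rate > 0 with all duplication rates 0: the genome will "
                "shrink to the two guarded subfamily survivors",
                stacklevel=2,
            )


@dataclass
class SimUnit:
    id: str
    seq: np.ndarray  # int codes into ALPHABET
    subfamily: str  # current (sequence-level) subfamily, 'R' or 'F'
    subgroup: str  # current true subgroup lineage label

    def sequence(self) -> str:
        return "".join(ALPHABET[i] for i in self.seq)


@dataclass
class SimLocus:
    id: str
    scaffold: str
    strand: str
    unit_ids: list[str] = field(default_factory=list)


@dataclass
class SimGenome:
    loci: list[SimLocus]
    units: dict[str, SimUnit]
    #: pristine founder sequences, usable as subfamily anchors downstream
    references: dict[str, str] = field(default_factory=dict)

    def locus_of(self) -> dict[str, str]:
        return {uid: loc.id for loc in self.loci for uid in loc.unit_ids}

    @property
    def n_units(self) -> int:
        return sum(len(loc.unit_ids) for loc in self.loci)


@dataclass
class TruthEvent:
    generation: int
    kind: str
    parent: str
    child: str  # empty string for loss
    source_locus: str
    target_locus: str


@dataclass
class TruthLog:
    """Ground-truth event history plus per-unit lineage bookkeeping.

    ``subfamily``/``subgroup`` reflect the *current* sequence-level lineage
    (conversion relabels a unit to its donor's lineage); ``creation`` holds
    the event kind that created each unit and never changes.
    """

    events: list[TruthEvent] = field(default_factory=list)
    subfamily: dict[str, str] = field(default_factory=dict)
    subgroup: dict[str, str] = field(default_factory=dict)
    creation: dict[str, str] = field(default_factory=dict)
    #: Poisson-drawn event attempts per kind. An attempt may realize no
    #: event (fusion without a pure opposite-subfamily target, loss blocked
    #: by the extinction guard); a whole-locus intergenic copy is one draw
    #: that logs one per-unit event record per copied unit
    draws: dict[str, int] = field(default_factory=lambda: dict.fromkeys(EVENT_KINDS, 0))

    def counts(self) -> dict[str, int]:
        out = {kind: 0 for kind in EVENT_KINDS}
        for ev in self.events:
            out[ev.kind] += 1
        return out

    def latest_duplication_mode(self) -> dict[str, str]:
        """Expected duplication-mode call per unit.

        A unit's nearest-homolog relationship reflects the most recent
        duplication it took part in — whether as the copied template or as
        the copy — so the recovery truth for each unit is the mode of its
        latest intragenic_dup / intergenic_dup / fusion event (fusion
        children arrive from another locus, hence intergenic). Conversion
        is deliberately excluded: it corrupts the sequence signal without
        redefining the duplication relationship, which is why raising the
        conversion rate degrades recovery accuracy.
        """
        mode_of = {
            "intragenic_dup": "intragenic",
            "intergenic_dup": "intergenic",
            "fusion": "intergenic",
        }
        last: dict[str, str] = {}
        for ev in self.events:  # chronological; later events overwrite
            if ev.kind in mode_of:
                for uid in (ev.parent, ev.child):
                    if uid:
                        last[uid] = mode_of[ev.kind]
        return last

    def true_mode(self, unit_id: str) -> str | None:
        """Expected duplication-mode call for a unit, from its creating event.

        Fusion children arrive from another locus, so their nearest homolog
        is expected across loci (intergenic). Founders have no mode.
        """
        kind = self.creation.get(unit_id)
        if kind == "intragenic_dup":
            return "intragenic"
        if kind in ("intergenic_dup", "fusion"):
            return "intergenic"
        return None


def make_founders(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[tuple[str, str], tuple[str, str]]:
    """Draw the two subfamily founder sequences.

    Founder A (labelled R) is uniform over residues; founder B (labelled F)
    equals A with exactly ``round(founder_divergence * unit_length)``
    positions replaced by a different residue.

    Returns ``((seq_r, "R"), (seq_f, "F"))``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    length = config.unit_length
    a = rng.integers(0, NRES, size=length)
    b = a.copy()
    n_diff = round(config.founder_divergence * length)
    if n_diff:
        positions = rng.choice(length, size=n_diff, replace=False)
        offsets = rng.integers(1, NRES, size=n_diff)
        b[positions] = (b[positions] + offsets) % NRES
    seq_a = "".join(ALPHABET[i] for i in a)
    seq_b = "".join(ALPHABET[i] for i in b)
    return (seq_a, "R"), (seq_b, "F")


class _Simulator:
    """Mutable state for one :func:`evolve` run."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.units: dict[str, SimUnit] = {}
        self.loci: list[SimLocus] = []
        self.locus_by_id: dict[str, SimLocus] = {}
        self.locus_of: dict[str, str] = {}
        self.alive: list[str] = []  # creation order, deterministic iteration
        self.truth = TruthLog()
        self._unit_counter = 0
        self._locus_counter = 0
        self._subgroup_counter = {"R": 1, "F": 1}

    # -- bookkeeping -------------------------------------------------------

    def _new_unit_id(self) -> str:
        self._unit_counter += 1
        return f"u{self._unit_counter:06d}"

    def _new_locus(self) -> SimLocus:
        self._locus_counter += 1
        locus = SimLocus(
            id=f"L{self._locus_counter:04d}",
            scaffold=f"sc{self._locus_counter:04d}",
            strand="+",
        )
        self.loci.append(locus)
        self.locus_by_id[locus.id] = locus
        return locus

    def _register(
        self, seq: np.ndarray, subfamily: str, subgroup: str, creation: str
    ) -> SimUnit:
        unit = SimUnit(self._new_unit_id(), seq.copy(), subfamily, subgroup)
        self.units[unit.id] = unit
        self.alive.append(unit.id)
        self.truth.subfamily[unit.id] = subfamily
        self.truth.subgroup[unit.id] = subgroup
        self.truth.creation[unit.id] = creation
        return unit

    def _pick_alive(self) -> SimUnit:
        idx = int(self.rng.integers(len(self.alive)))
        return self.units[self.alive[idx]]

    # -- event kinds -------------------------------------------------------

    def init_founders(self) -> None:
        (seq_r, _), (seq_f, _) = make_founders(self.config, self.rng)
        for seq, subfam in ((seq_r, "R"), (seq_f, "F")):
            codes = np.array([RES_INDEX[r] for r in seq], dtype=np.int64)
            unit = self._register(codes, subfam, f"{subfam}1", "founder")
            locus = self._new_locus()
            locus.unit_ids.append(unit.id)
            self.locus_of[unit.id] = locus.id
        self.references = {"ref_R": seq_r, "ref_F": seq_f}

    def intragenic_dup(self, gen: int) -> None:
        self.truth.draws["intragenic_dup"] += 1
        template = self._pick_alive()
        locus = self.locus_by_id[self.locus_of[template.id]]
        child = self._register(
            template.seq, template.subfamily, template.subgroup, "intragenic_dup"
        )
        pos = locus.unit_ids.index(template.id)
        locus.unit_ids.insert(pos + 1, child.id)
        self.locus_of[child.id] = locus.id
        self.truth.events.append(
            TruthEvent(gen, "intragenic_dup", template.id, child.id, locus.id, locus.id)
        )

    def intergenic_dup(self, gen: int) -> None:
        self.truth.draws["intergenic_dup"] += 1
        template = self._pick_alive()
        source = self.locus_by_id[self.locus_of[template.id]]
        whole_locus = bool(self.rng.random() < 0.5)
        target = self._new_locus()
        if whole_locus:
            # the whole source locus duplicates; lineages travel with it
            for uid in list(source.unit_ids):
                parent = self.units[uid]
                child = self._register(
                    parent.seq, parent.subfamily, parent.subgroup, "intergenic_dup"
                )
                target.unit_ids.append(child.id)
                self.locus_of[child.id] = target.id
                self.truth.events.append(
                    TruthEvent(gen, "intergenic_dup", uid, child.id, source.id, target.id)
                )
        else:
            # a dispersed single-unit copy founds a new subgroup lineage
            subfam = template.subfamily
            self._subgroup_counter[subfam] += 1
            subgroup = f"{subfam}{self._subgroup_counter[subfam]}"
            child = self._register(template.seq, subfam, subgroup, "intergenic_dup")
            target.unit_ids.append(child.id)
            self.locus_of[child.id] = target.id
            self.truth.events.append(
                TruthEvent(gen, "intergenic_dup", template.id, child.id, source.id, target.id)
            )

    def fusion(self, gen: int) -> None:
        self.truth.draws["fusion"] += 1
        template = self._pick_alive()
        other = "F" if template.subfamily == "R" else "R"
        source_id = self.locus_of[template.id]
        targets = [
            loc
            for loc in self.loci
            if loc.id != source_id
            and loc.unit_ids
            and all(self.units[u].subfamily == other for u in loc.unit_ids)
        ]
        if not targets:
            return  # no pure opposite-subfamily locus to fuse into
        target = targets[int(self.rng.integers(len(targets)))]
        child = self._register(
            template.seq, template.subfamily, template.subgroup, "fusion"
        )
        target.unit_ids.append(child.id)
        self.locus_of[child.id] = target.id
        self.truth.events.append(
            TruthEvent(gen, "fusion", template.id, child.id, source_id, target.id)
        )

    def conversion(self, gen: int) -> None:
        self.truth.draws["conversion"] += 1
        if len(self.alive) < 2:
            return
        target = self._pick_alive()
        others = [uid for uid in self.alive if uid != target.id]
        donor = self.units[others[int(self.rng.integers(len(others)))]]
        target.seq = donor.seq.copy()
        # sequence identity defines lineage: relabel to the donor's
        target.subfamily = donor.subfamily
        target.subgroup = donor.subgroup
        self.truth.subfamily[target.id] = donor.subfamily
        self.truth.subgroup[target.id] = donor.subgroup
        self.truth.events.append(
            TruthEvent(
                gen,
                "conversion",
                donor.id,
                target.id,
                self.locus_of[donor.id],
                self.locus_of[target.id],
            )
        )

    def loss(self, gen: int) -> None:
        self.truth.draws["loss"] += 1
        counts = {"R": 0, "F": 0}
        for uid in self.alive:
            counts[self.units[uid].subfamily] += 1
        eligible = [uid for uid in self.alive if counts[self.units[uid].subfamily] >= 2]
        if not eligible:
            return
        victim_id = eligible[int(self.rng.integers(len(eligible)))]
        locus = self.locus_by_id[self.locus_of[victim_id]]
        locus.unit_ids.remove(victim_id)
        self.alive.remove(victim_id)
        del self.locus_of[victim_id]
        if not locus.unit_ids:
            self.loci.remove(locus)
            del self.locus_by_id[locus.id]
        self.truth.events.append(
            TruthEvent(gen, "loss", victim_id, "", locus.id, "")
        )

    def substitute(self) -> None:
        p = self.config.subst_per_site_per_generation
        if p <= 0:
            return
        length = self.config.unit_length
        for uid in self.alive:
            k = int(self.rng.binomial(length, p))
            if not k:
                continue
            unit = self.units[uid]
            positions = self.rng.choice(length, size=k, replace=False)
            offsets = self.rng.integers(1, NRES, size=k)
            unit.seq[positions] = (unit.seq[positions] + offsets) % NRES

    # -- main loop ---------------------------------------------------------

    def run(self) -> tuple[SimGenome, TruthLog]:
        self.init_founders()
        cfg = self.config
        rates = (
            ("intragenic_dup", cfg.rate_intragenic, self.intragenic_dup),
            ("intergenic_dup", cfg.rate_intergenic, self.intergenic_dup),
            ("fusion", cfg.rate_fusion, self.fusion),
            ("conversion", cfg.rate_conversion, self.conversion),
            ("loss", cfg.rate_loss, self.loss),
        )
        for gen in range(1, cfg.n_generations + 1):
            for _kind, rate, handler in rates:
                n_events = int(self.rng.poisson(rate)) if rate > 0 else 0
                for _ in range(n_events):
                    handler(gen)
            self.substitute()
        alive_set = set(self.alive)
        genome = SimGenome(
            loci=[loc for loc in self.loci if loc.unit_ids],
            units={uid: u for uid, u in self.units.items() if uid in alive_set},
            references=self.references,
        )
        return genome, self.truth


def evolve(config: SimConfig) -> tuple[SimGenome, TruthLog]:
    """Run the forward simulation; same config (incl. seed) => same output."""
    return _Simulator(config).run()


# ---------------------------------------------------------------------------
# Rendering to on-disk formats
# ---------------------------------------------------------------------------

def resolve_motif_subgroup(genome: SimGenome, config: SimConfig) -> str | None:
    """The true-subgroup label whose junctions carry the cleavage motif.

    ``"auto"`` picks the largest surviving F subgroup (ties by label), so
    the motif always marks the most expanded lineage, as observed for the
    real cleavage motif; an explicit label is used verbatim.
    """
    if config.motif_subgroup != "auto":
        return config.motif_subgroup
    tallies: dict[str, int] = {}
    for unit in genome.units.values():
        if unit.subfamily == "F":
            tallies[unit.subgroup] = tallies.get(unit.subgroup, 0) + 1
    if not tallies:
        return None
    return min(tallies, key=lambda s: (-tallies[s], s))


def render(genome: SimGenome, config: SimConfig) -> list[Locus]:
    """Render each simulated locus as a polyprotein :class:`~.seqio.Locus`.

    Units are joined by a fixed 8-residue linker. At every junction whose
    *downstream* unit belongs to the motif subgroup (see
    :func:`resolve_motif_subgroup`), the linker's first four residues are
    the cleavage motif.
    """
    rendered: list[Locus] = []
    motif = config.motif
    motif_subgroup = resolve_motif_subgroup(genome, config)
    plain_tail = LINKER[len(motif):]
    for sim_locus in genome.loci:
        parts: list[str] = []
        spans: list[tuple[int, int]] = []
        pos = 0
        for i, uid in enumerate(sim_locus.unit_ids):
            unit = genome.units[uid]
            if i > 0:
                linker = (
                    motif + plain_tail
                    if unit.subgroup == motif_subgroup
                    else LINKER
                )
                parts.append(linker)
                pos += len(linker)
            seq = unit.sequence()
            parts.append(seq)
            spans.append((pos, pos + len(seq)))
            pos += len(seq)
        rendered.append(
            Locus(
                id=sim_locus.id,
                scaffold=sim_locus.scaffold,
                strand=sim_locus.strand,
                polyprotein="".join(parts),
                unit_spans=spans,
                unit_ids=list(sim_locus.unit_ids),
            )
        )
    return rendered


def write_truth_tsv(truth: TruthLog, genome: SimGenome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    with open(outdir / "truth_events.tsv", "w") as handle:
        handle.write("generation\tkind\tparent\tchild\tsource_locus\ttarget_locus\n")
        for ev in truth.events:
            handle.write(
                f"{ev.generation}\t{ev.kind}\t{ev.parent}\t{ev.child}\t"
                f"{ev.source_locus}\t{ev.target_locus}\n"
            )
    locus_of = genome.locus_of()
    with open(outdir / "truth_units.tsv", "w") as handle:
        handle.write("unit_id\tsubfamily\tsubgroup\tcreation\tlocus\tposition\n")
        for locus in genome.loci:
            for pos, uid in enumerate(locus.unit_ids):
                handle.write(
                    f"{uid}\t{truth.subfamily[uid]}\t{truth.subgroup[uid]}\t"
                    f"{truth.creation[uid]}\t{locus_of[uid]}\t{pos}\n"
                )


def write_outputs(
    genome: SimGenome, truth: TruthLog, config: SimConfig, outdir: str | Path
) -> None:
    """Write the full simulator output bundle.

    ``genome.fasta`` + ``loci.gff3`` (the pipeline inputs),
    ``references.fasta`` + ``anchors.tsv`` (pristine founders, used as the
    subfamily anchors and profile seed), the truth log, and a YAML echo of
    the config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rendered = render(genome, config)
    records = []
    for locus in rendered:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records.append(
            SeqRecord(
                Seq(locus.polyprotein),
                id=locus.id,
                description=f"scaffold={locus.scaffold} units=" + "|".join(locus.unit_ids),
            )
        )
    write_fasta(records, outdir / "genome.fasta")
    write_gff3(rendered, outdir / "loci.gff3")
    write_fasta(sorted(genome.references.items()), outdir / "references.fasta")
    with open(outdir / "anchors.tsv", "w") as handle:
        handle.write("unit_id\tsubfamily\n")
        for rid in sorted(genome.references):
            handle.write(f"{rid}\t{rid.split('_')[-1]}\n")
    write_truth_tsv(truth, genome, outdir)
    with open(outdir / "sim_config.yaml", "w") as handle:
        yaml.safe_dump(asdict(config), handle, sort_keys=False)
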