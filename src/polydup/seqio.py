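"""Readers and writers for the on-disk formats the pipeline touches.

Conventions
-----------
* In-memory coordinates are 0-based half-open everywhere. The GFF3
  reader/writer is the single place where the on-disk 1-based inclusive
  convention is converted, so off-by-one drift cannot accumulate.
* Branch supports are proportions in [0, 1], never percentages.
* FASTA is wrapped at 60 columns on output; residues are upper-cased on
  input (a lowercase input is flagged in the log, not rejected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

GFF_SOURCE = "polydup"
GENE_TYPE = "gene"
UNIT_TYPE = "mature_protein_region"


@dataclass
class Locus:
    """A gene model holding one polyprotein and the spans of its units.

    ``unit_spans`` are 0-based half-open residue coordinates into
    ``polyprotein``; ``unit_ids`` parallels ``unit_spans``.
    """

    id: str
    scaffold: str
    strand: str
    polyprotein: str = ""
    unit_spans: list[tuple[int, int]] = field(default_factory=list)
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"locus {self.id}: unknown strand symbol {self.strand!r}"
            )
        self.validate_spans()

    def validate_spans(self) -> None:
        prev_end = 0
        for start, end in self.unit_spans:
            if end <= start:
                raise ValueError(
                    f"locus {self.id}: empty or inverted span ({start}, {end})"
                )
            if start < prev_end:
                raise ValueError(
                    f"locus {self.id}: overlapping or unsorted unit spans"
                )
            prev_end = end
        if self.polyprotein and self.unit_spans:
            if self.unit_spans[-1][1] > len(self.polyprotein):
                raise ValueError(
                    f"locus {self.id}: unit span exceeds sequence length"
                )
        if self.unit_ids and len(self.unit_ids) != len(self.unit_spans):
            raise ValueError(f"locus {self.id}: unit_ids/unit_spans mismatch")

    @property
    def n_units(self) -> int:
        return len(self.unit_spans)

    def unit_sequence(self, i: int) -> str:
        start, end = self.unit_spans[i]
        return self.polyprotein[start:end]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a protein FASTA; ids must be unique, residues are upper-cased."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for lineno, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            log.warning("record %s: lowercase residues upper-cased on read", rec.id)
            rec = SeqRecord(Seq(seq.upper()), id=rec.id, description=rec.description)
        records.append(rec)
    return records


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path) -> None:
    """Write records (SeqRecord or (id, sequence) pairs), wrapped at 60 cols."""
    out: list[SeqRecord] = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            out.append(rec)
        else:
            rid, seq = rec
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as handle:
        SeqIO.write(out, handle, "fasta")


# ---------------------------------------------------------------------------
# GFF3 locus maps
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key] = value
    return attrs


def read_gff3(
    path: str | Path,
    sequences: Mapping[str, str] | None = None,
) -> list[Locus]:
    """Read a locus map: ``gene`` features with ``mature_protein_region``
    children, coordinates in polyprotein residues (1-based inclusive on
    disk, converted here to 0-based half-open).

    ``sequences`` optionally maps locus id -> polyprotein string.
    """
    loci: dict[str, Locus] = {}
    order: list[str] = []
    spans: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            attrs = _parse_attributes(attr_s)
            if ftype == GENE_TYPE:
                lid = attrs["ID"]
                seq = sequences.get(lid, "") if sequences else ""
                loci[lid] = Locus(id=lid, scaffold=seqid, strand=strand, polyprotein=seq)
                order.append(lid)
                spans[lid] = []
            elif ftype == UNIT_TYPE:
                parent = attrs["Parent"]
                # 1-based inclusive -> 0-based half-open
                spans.setdefault(parent, []).append((start - 1, end, attrs.get("ID", "")))
    out = []
    for lid in order:
        locus = loci[lid]
        unit_rows = sorted(spans.get(lid, []))
        locus.unit_spans = [(s, e) for s, e, _ in unit_rows]
        locus.unit_ids = [uid for _, _, uid in unit_rows]
        locus.validate_spans()
        out.append(locus)
    return out


def write_gff3(loci: Sequence[Locus], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for locus in loci:
            gene_end = len(locus.polyprotein) if locus.polyprotein else (
                locus.unit_spans[-1][1] if locus.unit_spans else 1
            )
            handle.write(
                "\t".join(
                    [
                        locus.scaffold,
                        GFF_SOURCE,
                        GENE_TYPE,
                        "1",
                        str(gene_end),
                        ".",
                        locus.strand,
                        ".",
                        f"ID={locus.id}",
                    ]
                )
                + "\n"
            )
            for i, (start, end) in enumerate(locus.unit_spans):
                uid = locus.unit_ids[i] if locus.unit_ids else f"{locus.id}.u{i + 1}"
                handle.write(
                    "\t".join(
                        [
                            locus.scaffold,
                            GFF_SOURCE,
                            UNIT_TYPE,
                            str(start + 1),  # 0-based half-open -> 1-based inclusive
                            str(end),
                            ".",
                            locus.strand,
                            ".",
                            f"ID={uid};Parent={locus.id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a single-tree Newick file; internal node labels hold supports."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports the character offset itself
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return tree


def newick_string(tree: dendropy.Tree) -> str:
    """Canonical Newick rendering: 6-decimal branch lengths, verbatim labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    ).strip() + "\n"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(newick_string(tree))


def branch_support(node: dendropy.Node) -> float | None:
    """Support of the edge above ``node``, parsed from its label ("1" -> 1.0)."""
    if node.label is None:
        return None
    value = float(node.label)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"support {value} outside [0, 1]")
    return value
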