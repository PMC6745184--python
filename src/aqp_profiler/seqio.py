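"""Sequence, anchor-table and exon-table I/O.

All coordinates in this package are 1-based inclusive, matching the protein
coordinates used in the AQP literature and by NCBI.  The reference-anchor
table is a tab-separated format defined here (documented in the README)
because no machine-readable anchor file exists for function-known AQPs.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP")

#: ordered feature keys of a reference anchor (NPA starts, ar/R filter,
#: Froger's P1-P5, and the nine specificity-determining positions)
FEATURE_KEYS = (
    "NPA_LB", "NPA_LE", "H2", "H5", "LE1", "LE2",
    "P1", "P2", "P3", "P4", "P5",
    "SDP1", "SDP2", "SDP3", "SDP4", "SDP5", "SDP6", "SDP7", "SDP8", "SDP9",
)

ANCHOR_COLUMNS = ("id", "subfamily", "class") + FEATURE_KEYS + ("sequence",)


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein record: identifier, free-text description, residue string."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residue string")
        bad = sorted(set(self.residues) - _VALID_RESIDUES)
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue character(s) {''.join(bad)!r}"
            )
        if "X" in self.residues:
            warnings.warn(f"record {self.id!r} contains ambiguous residue X")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, pos: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]


@dataclass(frozen=True)
class ReferenceAnchor:
    """A function-known AQP with annotated feature positions (1-based).

    ``feature_positions`` must carry all 20 keys of :data:`FEATURE_KEYS`;
    NPA_LB / NPA_LE point at the first residue of each tripeptide motif.
    """

    sequence: ProteinSequence
    subfamily: str
    class_label: str
    feature_positions: Mapping[str, int]

    def __post_init__(self):
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        missing = [k for k in FEATURE_KEYS if k not in self.feature_positions]
        if missing:
            raise ValueError(f"anchor {self.id!r}: missing feature(s) {missing}")
        n = len(self.sequence)
        for key in FEATURE_KEYS:
            pos = self.feature_positions[key]
            if not 1 <= pos <= n:
                raise ValueError(
                    f"anchor {self.id!r}: {key} position {pos} outside sequence "
                    f"of length {n}"
                )
        if not self.feature_positions["NPA_LB"] < self.feature_positions["NPA_LE"]:
            raise ValueError(f"anchor {self.id!r}: NPA_LB must precede NPA_LE")

    @property
    def id(self) -> str:
        return self.sequence.id


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene: ordered genomic intervals, 1-based inclusive."""

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id!r}: exon {s}-{e} reversed")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id!r}: overlapping exons")
        object.__setattr__(self, "exons", exons)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[ProteinSequence]:
    """Read a protein FASTA file (wrapped or unwrapped lines).

    The first whitespace in a header splits the id from the description.
    Residues are uppercased.  Raises :class:`FormatError` on an empty file
    and a record-level ``ValueError`` naming the offending id on an illegal
    residue character.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinSequence(id=rec.id, residues=str(rec.seq).upper(),
                            description=rec.description)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinSequence], path, width: int = 60) -> None:
    records = list(records)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Anchor tables

def read_anchor_table(path) -> list[ReferenceAnchor]:
    """Read a tab-separated reference-anchor table.

    Expected header: ``id subfamily class NPA_LB NPA_LE H2 H5 LE1 LE2
    P1..P5 SDP1..SDP9 sequence``.  Every row is validated against the
    :class:`ReferenceAnchor` invariants.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: anchor table missing column(s) {missing}")
    anchors = []
    for _, row in df.iterrows():
        seq = ProteinSequence(id=row["id"], residues=row["sequence"].upper())
        positions = {k: int(row[k]) for k in FEATURE_KEYS}
        anchors.append(
            ReferenceAnchor(sequence=seq, subfamily=row["subfamily"],
                            class_label=row["class"], feature_positions=positions)
        )
    return anchors


def write_anchor_table(anchors: Sequence[ReferenceAnchor], path) -> None:
    rows = []
    for a in anchors:
        row = {"id": a.id, "subfamily": a.subfamily, "class": a.class_label}
        row.update({k: a.feature_positions[k] for k in FEATURE_KEYS})
        row["sequence"] = a.sequence.residues
        rows.append(row)
    pd.DataFrame(rows, columns=list(ANCHOR_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Exon tables

def read_exon_table(path) -> list[GeneModel]:
    """Read gene models from GFF3 (``exon`` features) or a 4-column TSV.

    The TSV dialect is ``gene_id  start  end  strand`` with one row per exon
    (header optional).  GFF3 is detected by extension (.gff/.gff3) or the
    ``##gff-version`` pragma.
    """
    path = Path(path)
    text_head = path.read_text().lstrip()[:64]
    if path.suffix.lower() in {".gff", ".gff3"} or text_head.startswith("##gff-version"):
        return _read_gff3_exons(path)
    return _read_exon_tsv(path)


def _read_gff3_exons(path: Path) -> list[GeneModel]:
    import skbio.io

    by_gene: dict[str, dict] = {}
    for seq_id, im in skbio.io.read(str(path), format="gff3"):
        for interval in im.query(metadata={"type": "exon"}):
            md = interval.metadata
            parent = md.get("Parent") or md.get("ID") or seq_id
            lo, hi = interval.bounds[0]
            entry = by_gene.setdefault(parent, {"exons": [], "strand": md.get("strand", "+")})
            # skbio stores 0-based half-open bounds; convert to 1-based inclusive
            entry["exons"].append((lo + 1, hi))
    return [GeneModel(gene_id=g, exons=tuple(v["exons"]), strand=v["strand"])
            for g, v in by_gene.items()]


def _read_exon_tsv(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "start", "end", "strand"], dtype=str)
    if df.iloc[0]["start"] in ("start", "Start"):  # header row present
        df = df.iloc[1:]
    by_gene: dict[str, dict] = {}
    for _, row in df.iterrows():
        entry = by_gene.setdefault(row["gene_id"], {"exons": [], "strand": row["strand"]})
        entry["exons"].append((int(row["start"]), int(row["end"])))
    return [GeneModel(gene_id=g, exons=tuple(v["exons"]), strand=v["strand"])
            for g, v in by_gene.items()]


def exon_count(model: GeneModel) -> int:
    """Number of exons of a gene model."""
    return len(model.exons)


@dataclass
class ExonPatternReport:
    """Per-subfamily exon-count distributions with deviants flagged.

    ``distribution[subfamily]`` maps exon count -> number of genes;
    ``flags`` lists (gene_id, subfamily, exon_count) for genes deviating
    from their subfamily's modal exon count; genes with no subfamily
    assignment are listed in ``skipped``.
    """

    distribution: dict[str, dict[int, int]] = field(default_factory=dict)
    flags: list[tuple[str, str, int]] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def validate_exon_pattern(models: Sequence[GeneModel],
                          subfamily_assignments: Mapping[str, str]) -> ExonPatternReport:
    """Summarize exon counts per subfamily and flag deviants.

    Plant AQP subfamilies have characteristic exon counts (e.g., PIP genes
    carry four exons); a gene whose count differs from its subfamily's mode
    is flagged, never rejected.  Unassigned genes are skipped with a warning.
    """
    report = ExonPatternReport()
    by_subfam: dict[str, list[GeneModel]] = {}
    for m in models:
        subfam = subfamily_assignments.get(m.gene_id)
        if subfam is None:
            warnings.warn(f"gene {m.gene_id!r} has no subfamily assignment; skipped")
            report.skipped.append(m.gene_id)
            continue
        by_subfam.setdefault(subfam, []).append(m)
    for subfam, members in by_subfam.items():
        counts = [exon_count(m) for m in members]
        dist: dict[int, int] = {}
        for c in counts:
            dist[c] = dist.get(c, 0) + 1
        report.distribution[subfam] = dict(sorted(dist.items()))
        mode = max(dist.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        for m, c in zip(members, counts):
            if c != mode:
                report.flags.append((m.gene_id, subfam, c))
    return report
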