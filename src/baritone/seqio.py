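"""Sequence and annotation I/O, and the coordinate conventions used package-wide.

All internal coordinates are 0-based, half-open, on the plus strand; minus-strand
features carry a strand flag and are reverse-complemented on extraction. External
formats (GFF3, BLAST outfmt-6, RepeatMasker .out) are converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

IUPAC_NT = set("ACGTN")

#: superfamilies recognised for co-occurrence analysis
SUPERFAMILIES = (
    "Copia", "Gypsy", "PAO", "LOA", "I", "Jockey", "Tc1-mariner", "Helitron", "other",
)

#: default RepeatMasker class/family -> superfamily mapping (prefix match, longest first)
DEFAULT_CLASS_MAP = {
    "LTR/Copia": "Copia",
    "LTR/Gypsy": "Gypsy",
    "LTR/Pao": "PAO",
    "LTR/PAO": "PAO",
    "LINE/LOA": "LOA",
    "LINE/I": "I",
    "LINE/Jockey": "Jockey",
    "DNA/TcMar": "Tc1-mariner",
    "DNA/Tc1": "Tc1-mariner",
    "RC/Helitron": "Helitron",
}


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeRecord:
    """A named nucleotide sequence (contig/scaffold) with species metadata."""

    id: str
    residues: str
    species_code: str = "Dxxx"
    softmask: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        self.residues = self.residues.upper()
        bad = set(self.residues) - IUPAC_NT
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"{self.id}: non-IUPAC character {self.residues[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def extract(self, iv: Interval) -> str:
        """Sequence of ``iv``; reverse-complemented for minus-strand intervals."""
        from .align import revcomp

        if iv.end > len(self.residues):
            raise ValueError(f"interval end {iv.end} beyond {self.id} length")
        s = self.residues[iv.start:iv.end]
        return revcomp(s) if iv.strand == "-" else s


@dataclass
class HomologyHit:
    """One row of 12-column tabular homology-search output (1-based coordinates)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def subject_interval(self) -> Interval:
        """Subject interval in internal convention; s_start > s_end means minus strand."""
        if self.s_start <= self.s_end:
            return Interval(self.subject_id, self.s_start - 1, self.s_end, "+")
        return Interval(self.subject_id, self.s_end - 1, self.s_start, "-")


@dataclass
class RepeatFeature:
    interval: Interval
    family: str
    superfamily: str = "other"

    def __post_init__(self):
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords.

    Lowercase (soft-masked) residues are uppercased; the masked runs are kept in
    ``softmask``. The species code is taken from a ``species=Xxxx`` token in the
    header when present.
    """
    records: list[GenomeRecord] = []
    name = None
    desc = ""
    chunks: list[str] = []

    def flush():
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{name}: header with no residues")
        mask, run_start = [], None
        for i, c in enumerate(seq):
            low = c.islower()
            if low and run_start is None:
                run_start = i
            elif not low and run_start is not None:
                mask.append((run_start, i))
                run_start = None
        if run_start is not None:
            mask.append((run_start, len(seq)))
        species = "Dxxx"
        for tok in desc.split():
            if tok.startswith("species="):
                species = tok.split("=", 1)[1]
        records.append(GenomeRecord(id=name, residues=seq, species_code=species, softmask=mask))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                fields = line[1:].split(None, 1)
                if not fields:
                    raise ValueError("FASTA header with no identifier")
                name = fields[0]
                desc = fields[1] if len(fields) > 1 else ""
                chunks = []
            elif line.strip():
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise ValueError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} species={rec.species_code}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_tabular_hits(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column tab-separated homology hits (outfmt-6 layout)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(parts)}")
            hits.append(HomologyHit(
                query_id=parts[0], subject_id=parts[1],
                pct_identity=float(parts[2]), aln_length=int(parts[3]),
                mismatches=int(parts[4]), gap_opens=int(parts[5]),
                q_start=int(parts[6]), q_end=int(parts[7]),
                s_start=int(parts[8]), s_end=int(parts[9]),
                evalue=float(parts[10]), bitscore=float(parts[11]),
            ))
    return hits


def write_tabular_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query_id, h.subject_id, h.pct_identity, h.aln_length,
                h.mismatches, h.gap_opens, h.q_start, h.q_end,
                h.s_start, h.s_end, h.evalue, h.bitscore)) + "\n")


def map_repeat_class(cls: str, class_map: dict[str, str] | None = None) -> str:
    table = DEFAULT_CLASS_MAP if class_map is None else class_map
    for prefix in sorted(table, key=len, reverse=True):
        if cls.startswith(prefix):
            return table[prefix]
    return "other"


def read_repeat_out(path: str | Path, class_map: dict[str, str] | None = None) -> list[RepeatFeature]:
    """Parse RepeatMasker .out (3 header lines, whitespace-separated records).

    Unparseable lines are logged and skipped, not fatal.
    """
    feats = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        parts = line.split()
        if not parts or parts[0] in ("SW", "score") or line.startswith("  SW"):
            continue
        try:
            int(parts[0])
        except ValueError:
            continue  # header / banner line
        try:
            seq_id = parts[4]
            start = int(parts[5]) - 1
            end = int(parts[6])
            strand = "-" if parts[8] in ("C", "-") else "+"
            family = parts[9]
            cls = parts[10]
            feats.append(RepeatFeature(
                interval=Interval(seq_id, start, end, strand),
                family=family,
                superfamily=map_repeat_class(cls, class_map),
            ))
        except (IndexError, ValueError) as exc:
            logger.warning("%s line %d unparseable (%s); skipped", path, lineno, exc)
    return feats


def read_bed_repeats(path: str | Path, class_map: dict[str, str] | None = None) -> list[RepeatFeature]:
    """BED file of repeats; column 4 (name) holds the repeat class/family string."""
    feats = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or line.startswith(("#", "track")):
                continue
            cls = parts[3] if len(parts) > 3 else "other"
            strand = parts[5] if len(parts) > 5 else "+"
            feats.append(RepeatFeature(
                interval=Interval(parts[0], int(parts[1]), int(parts[2]), strand),
                family=cls,
                superfamily=map_repeat_class(cls, class_map),
            ))
    return feats


def write_gff3(annotations: Sequence, path: str | Path) -> None:
    """Write ElementAnnotations as GFF3 (1-based inclusive), sorted by (seq_id, start)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in sorted(annotations, key=lambda a: (a.interval.seq_id, a.interval.start, a.interval.end)):
            iv = ann.interval
            attrs = (
                f"ID={ann.name};category={ann.category};subfamily={ann.subfamily};"
                f"tir_type={ann.tir_type};dr_left={ann.dr_counts[0]};dr_right={ann.dr_counts[1]};"
                f"tsd={ann.tsd}"
            )
            if getattr(ann, "notes", ""):
                attrs += f";notes={ann.notes}"
            fh.write("\t".join([
                iv.seq_id, "baritone", "transposable_element",
                str(iv.start + 1), str(iv.end), ".", iv.strand, ".", attrs,
            ]) + "\n")


def read_gff3(path: str | Path) -> list[dict]:
    """Read GFF3 rows back into dicts with an internal-convention Interval."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append({
                "interval": Interval(parts[0], int(parts[3]) - 1, int(parts[4]),
                                     parts[6] if parts[6] in "+-" else "+"),
                "type": parts[2],
                "attributes": attrs,
            })
    return rows


def write_element_table(annotations: Sequence, path: str | Path) -> None:
    """TSV projection of the element inventory (one row per annotation)."""
    cols = ["species", "contig", "start", "end", "length", "strand",
            "category", "subfamily", "tir_type", "dr_left", "dr_right", "tsd", "name", "notes"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in sorted(annotations, key=lambda a: (a.interval.seq_id, a.interval.start)):
            iv = a.interval
            fh.write("\t".join(str(v) for v in (
                a.species_code, iv.seq_id, iv.start, iv.end, len(iv), iv.strand,
                a.category, a.subfamily, a.tir_type, a.dr_counts[0], a.dr_counts[1],
                a.tsd, a.name, getattr(a, "notes", ""))) + "\n")
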