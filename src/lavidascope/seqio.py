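"""Sequence and annotation I/O.

Readers and writers for the plain-text formats the pipeline touches (FASTA,
a strict GFF3 subset, habitat TSV), the two universal value types
(:class:`SequenceRecord`, :class:`GeneAnnotation`), and a minimal ORF caller
used in place of a full gene predictor on synthetic contigs.

Coordinates are 0-based half-open internally and 1-based inclusive on disk
(GFF3 convention); :func:`to_gff_coords` / :func:`from_gff_coords` are the
single conversion layer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

CORE_LABELS = ("MCP", "mCP", "ATPase", "PRO")
EXTENDED_LABELS = CORE_LABELS + ("MTase", "integrase")
PRODUCT_LABELS = EXTENDED_LABELS + ("other",)

FASTA_WRAP = 80


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA contig or protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_dna(self) -> bool:
        return set(self.residues.upper()) <= DNA_ALPHABET

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, residues=str(Seq(self.residues).reverse_complement()))


@dataclass
class GeneAnnotation:
    """A located, stranded gene with its protein product.

    ``start``/``end`` are 0-based half-open on the contig's forward strand;
    serialization converts to GFF3 1-based inclusive.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    product_label: str = "other"
    protein: SequenceRecord | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise FormatError(f"gene {self.gene_id}: bad interval {self.start}..{self.end}")
        if self.product_label not in PRODUCT_LABELS:
            raise FormatError(f"gene {self.gene_id}: unknown product {self.product_label!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def nt_sequence(self, contig: SequenceRecord) -> str:
        """Coding-strand nucleotide sequence of the gene."""
        sub = contig.residues[self.start:self.end]
        return sub if self.strand == "+" else str(Seq(sub).reverse_complement())


def to_gff_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_gff_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start1 < 1 or end1 < start1:
        raise FormatError(f"invalid 1-based interval {start1}..{end1}")
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path | io.TextIOBase, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read FASTA into records, validating ids and residues.

    ``alphabet`` may be ``"dna"`` or ``"protein"`` to enforce residue checks.
    """
    handle = open(path) if not isinstance(path, io.TextIOBase) else path
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    desc = ""
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        residues = "".join(chunks).upper()
        if not residues:
            raise FormatError(f"empty sequence for record {header!r}")
        if alphabet == "dna" and not set(residues) <= DNA_ALPHABET:
            bad = sorted(set(residues) - DNA_ALPHABET)
            raise FormatError(f"record {header!r}: illegal DNA characters {bad}")
        if alphabet == "protein" and not set(residues) <= PROTEIN_ALPHABET:
            bad = sorted(set(residues) - PROTEIN_ALPHABET)
            raise FormatError(f"record {header!r}: illegal protein characters {bad}")
        records.append(SequenceRecord(header, residues, desc))

    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(maxsplit=1)
                if not parts:
                    raise FormatError("FASTA header with no id")
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                if header in seen:
                    raise FormatError(f"duplicate sequence id {header!r}")
                seen.add(header)
                chunks = []
            else:
                if header is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line.strip())
        flush()
    finally:
        if handle is not path:
            handle.close()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            out.write(head + "\n")
            for i in range(0, len(rec.residues), FASTA_WRAP):
                out.write(rec.residues[i:i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (strict minimal subset: gene features with ID= and product=)


def write_gff3(annotations: Sequence[GeneAnnotation], path: str | Path) -> None:
    anns = sorted(annotations, key=lambda a: (a.contig_id, a.start, a.strand, a.gene_id))
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for a in anns:
            s1, e1 = to_gff_coords(a.start, a.end)
            attrs = f"ID={a.gene_id};product={a.product_label}"
            out.write(
                f"{a.contig_id}\tlavidascope\tgene\t{s1}\t{e1}\t.\t{a.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path, proteins: dict[str, SequenceRecord] | None = None) -> list[GeneAnnotation]:
    """Parse the gene features of a GFF3 file.

    If ``proteins`` maps gene ids to protein records, they are attached.
    """
    anns: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            contig, _src, ftype, s1, e1, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            try:
                start, end = from_gff_coords(int(s1), int(e1))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates {s1}..{e1}") from exc
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
            product = attr_map.get("product", "other")
            ann = GeneAnnotation(contig, start, end, strand, gene_id, product)
            if proteins and gene_id in proteins:
                ann.protein = proteins[gene_id]
            anns.append(ann)
    return anns


# ---------------------------------------------------------------------------
# Habitat TSV


def write_habitats(habitats: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("contig_id\thabitat\n")
        for cid in sorted(habitats):
            out.write(f"{cid}\t{habitats[cid]}\n")


def read_habitats(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig_id"):
            raise FormatError("habitat TSV must start with a contig_id header row")
        for line in fh:
            if not line.strip():
                continue
            cid, hab = line.rstrip("\n").split("\t")
            out[cid] = hab
    return out


# ---------------------------------------------------------------------------
# ORF calling

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _orfs_on_strand(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal ATG->stop ORFs (0-based half-open, incl. stop) on the forward
    strand of ``seq``; one ORF per stop (the first ATG after the previous
    in-frame stop)."""
    n = len(seq)
    out = []
    for frame in range(3):
        start_candidate: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if start_candidate is not None:
                    aa_len = (pos - start_candidate) // 3
                    if aa_len >= min_len:
                        out.append((start_candidate, pos + 3))
                    start_candidate = None
            elif codon == "ATG" and start_candidate is None:
                start_candidate = pos
    return out


def call_orfs(contig: SequenceRecord, min_len: int = 100) -> list[GeneAnnotation]:
    """Call maximal ATG-to-stop ORFs of at least ``min_len`` aa on both strands.

    Within a frame, nested ORFs are suppressed (only the first ATG after the
    previous stop starts an ORF). Output is ordered by start coordinate, then
    strand, and includes the translated protein (stop codon excluded).
    """
    seq = contig.residues.upper()
    n = len(seq)
    anns: list[GeneAnnotation] = []
    fwd = _orfs_on_strand(seq, min_len)
    rc = str(Seq(seq).reverse_complement())
    rev = [(n - e, n - s) for s, e in _orfs_on_strand(rc, min_len)]
    entries = [(s, e, "+") for s, e in fwd] + [(s, e, "-") for s, e in rev]
    entries.sort(key=lambda t: (t[0], t[2], t[1]))
    for i, (s, e, strand) in enumerate(entries):
        sub = seq[s:e] if strand == "+" else str(Seq(seq[s:e]).reverse_complement())
        protein = str(Seq(sub[:-3]).translate())
        gene_id = f"{contig.id}|orf{i + 1:03d}"
        anns.append(
            GeneAnnotation(
                contig.id, s, e, strand, gene_id, "other",
                SequenceRecord(gene_id, protein),
            )
        )
    return anns
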