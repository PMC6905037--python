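"""Virophage-giant-virus co-infection prediction via the MIMIVIRE criterion.

The MIMIVIRE defence system leaves a sequence signature: a short stretch
(24-30 nt) shared at 100% identity between a virophage and its associated
giant virus, with a repeated ~18 nt subset of that stretch occurring multiple
times inside one giant-virus gene. Inverting the observation, a virophage
contig and a giant-virus contig are linked when they share such a seed and
the repeat criterion holds; translated motifs around the seed are recorded
to check whether both genomes encode the same peptide in some reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .align import maximal_exact_matches
from .seqio import GeneAnnotation, SequenceRecord

SEED_LEN_RANGE = (24, 30)
UNIT_LEN = 18
UNIT_LEN_SLOP = 2          # units of length 16-20 are acceptable
MIN_COPIES = 2


@dataclass
class GiantVirusContig:
    record: SequenceRecord
    genes: list[GeneAnnotation] = field(default_factory=list)
    taxon: str | None = None

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.end > len(self.record):
                raise ValueError(f"gene {g.gene_id} extends beyond contig {self.record.id}")


@dataclass
class SharedSeed:
    seed: str
    virophage_start: int
    giant_start: int          # forward-strand coordinate on the giant contig
    giant_strand: str


@dataclass
class MimivireLink:
    virophage_id: str
    gv_id: str
    gene_id: str
    seed: str
    virophage_start: int
    giant_start: int
    giant_strand: str
    repeat_unit: str
    copy_count: int
    motifs_virophage: list[str] = field(default_factory=list)
    motifs_giant: list[str] = field(default_factory=list)
    frame_agreement: bool | None = None
    co_occurrence: bool = False

    @property
    def seed_len(self) -> int:
        return len(self.seed)


# ---------------------------------------------------------------------------
# Seed discovery


def shared_seeds(
    virophage: SequenceRecord,
    giant: SequenceRecord,
    len_range: tuple[int, int] = SEED_LEN_RANGE,
) -> list[SharedSeed]:
    """All maximal exact common substrings of at least ``len_range[0]`` nt.

    Both strands of the giant-virus contig are searched (the virophage is
    kept as given); matches longer than the upper bound still qualify - the
    24-30 window is a minimum-information criterion, not an exclusion of
    longer identity. k-mer anchoring at k = 24 guarantees every qualifying
    match is found. Coordinates are forward-strand positions in each contig.
    """
    min_len = len_range[0]
    out: list[SharedSeed] = []
    for strand in "+-":
        g = giant.residues if strand == "+" else str(Seq(giant.residues).reverse_complement())
        for sv, sg, length in maximal_exact_matches(virophage.residues, g, min_len):
            seed = virophage.residues[sv:sv + length]
            if strand == "+":
                gstart = sg
            else:
                gstart = len(giant.residues) - (sg + length)
            out.append(SharedSeed(seed, sv, gstart, strand))
    # a perfect match found on both strands (palindromic seed) is one event
    uniq: dict[tuple, SharedSeed] = {}
    for s in out:
        uniq.setdefault((s.virophage_start, s.giant_start, len(s.seed)), s)
    return sorted(uniq.values(), key=lambda s: (s.virophage_start, s.giant_start))


def shared_seeds_bruteforce(a: str, b: str, min_len: int = 24) -> set[tuple[int, int, int]]:
    """Quadratic-time oracle enumerating maximal common substrings >= min_len.

    For cross-checking :func:`shared_seeds` on small contigs only.
    """
    matches = set()
    for i in range(len(a)):
        for j in range(len(b)):
            if a[i] != b[j]:
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue  # not maximal on the left
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k >= min_len:
                matches.add((i, j, k))
    return matches


# ---------------------------------------------------------------------------
# Repeated-subset rule


def repeated_subset(
    seed: str,
    gene_sequence: str,
    unit_len: int = UNIT_LEN,
    min_copies: int = MIN_COPIES,
) -> tuple[str, int] | None:
    """Best repeated ~18 nt subset of the seed within one giant-virus gene.

    All substrings of the seed with length ``unit_len`` +/- 2 are counted in
    the gene's coding-strand sequence; occurrences may overlap but identical
    spans are counted once. Returns the unit with the highest copy count
    (ties: longer unit, then leftmost in the seed) when it reaches
    ``min_copies``, else None.
    """
    best: tuple[int, int, int] | None = None   # (copies, length, -offset) maximized
    best_unit = None
    for length in range(unit_len + UNIT_LEN_SLOP, unit_len - UNIT_LEN_SLOP - 1, -1):
        if length > len(seed):
            continue
        for off in range(0, len(seed) - length + 1):
            unit = seed[off:off + length]
            copies = _count_spans(gene_sequence, unit)
            key = (copies, length, -off)
            if best is None or key > best:
                best = key
                best_unit = unit
    if best is None or best[0] < min_copies:
        return None
    return best_unit, best[0]


def _count_spans(haystack: str, needle: str) -> int:
    count = 0
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


# ---------------------------------------------------------------------------
# Translated motifs


def _frames(seq: str) -> list[str]:
    out = []
    for f in range(3):
        sub = seq[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()) if len(sub) >= 3 else "")
    return out


def translated_motif_check(link: MimivireLink,
                           virophage: SequenceRecord,
                           giant: SequenceRecord) -> MimivireLink:
    """Translate the seed region in all three frames in both genomes.

    ``frame_agreement`` is set when some frame pair yields an identical
    peptide of at least 6 aa (an exact nucleotide match of >= 18 nt always
    provides one). Seeds shorter than 18 nt skip the check with a flag.
    """
    n = len(link.seed)
    if n < 18:
        link.frame_agreement = None
        return link
    v_region = virophage.residues[link.virophage_start:link.virophage_start + n]
    if link.giant_strand == "+":
        g_region = giant.residues[link.giant_start:link.giant_start + n]
    else:
        g_region = str(
            Seq(giant.residues[link.giant_start:link.giant_start + n]).reverse_complement()
        )
    link.motifs_virophage = _frames(v_region)
    link.motifs_giant = _frames(g_region)
    link.frame_agreement = any(
        len(mv) >= 6 and mv == mg
        for mv in link.motifs_virophage
        for mg in link.motifs_giant
    )
    return link


# ---------------------------------------------------------------------------
# End-to-end linking


def link_all(
    virophages: list[SequenceRecord],
    giants: list[GiantVirusContig],
    co_occurrence: dict[str, str] | None = None,
    len_range: tuple[int, int] = SEED_LEN_RANGE,
    unit_len: int = UNIT_LEN,
    min_copies: int = MIN_COPIES,
) -> list[MimivireLink]:
    """All virophage x giant-virus pairs passing the MIMIVIRE criterion.

    For every shared seed, the repeat rule is evaluated inside each
    giant-virus gene overlapping the seed (coding strand). Links are ranked
    by copy count, seed length, frame agreement and same-sample co-occurrence
    (``co_occurrence`` maps contig ids to sample ids), with a deterministic
    final ordering.
    """
    links: list[MimivireLink] = []
    for vp in sorted(virophages, key=lambda r: r.id):
        for gv in sorted(giants, key=lambda g: g.record.id):
            for seed in shared_seeds(vp, gv.record, len_range):
                seed_span = (seed.giant_start, seed.giant_start + len(seed.seed))
                for gene in sorted(gv.genes, key=lambda g: (g.start, g.gene_id)):
                    if seed_span[0] < gene.start or seed_span[1] > gene.end:
                        continue
                    gene_seq = gene.nt_sequence(gv.record)
                    hit = repeated_subset(seed.seed, gene_seq, unit_len, min_copies)
                    if hit is None:
                        continue
                    unit, copies = hit
                    link = MimivireLink(
                        virophage_id=vp.id,
                        gv_id=gv.record.id,
                        gene_id=gene.gene_id,
                        seed=seed.seed,
                        virophage_start=seed.virophage_start,
                        giant_start=seed.giant_start,
                        giant_strand=seed.giant_strand,
                        repeat_unit=unit,
                        copy_count=copies,
                    )
                    translated_motif_check(link, vp, gv.record)
                    if co_occurrence is not None:
                        link.co_occurrence = (
                            co_occurrence.get(vp.id) is not None
                            and co_occurrence.get(vp.id) == co_occurrence.get(gv.record.id)
                        )
                    links.append(link)
    links.sort(
        key=lambda l: (
            -l.copy_count,
            -l.seed_len,
            not l.frame_agreement,
            not l.co_occurrence,
            l.virophage_id,
            l.gv_id,
            l.gene_id,
        )
    )
    return links
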