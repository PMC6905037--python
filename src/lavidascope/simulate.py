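"""Synthetic metagenome generator with full ground truth.

Emulates the input side of a virophage survey without any external data:
multi-gene dsDNA contigs (10.9-42.3 kb by default) carrying the four core
genes (MCP, mCP, ATPase, PRO, optionally MTase) in configurable per-lineage
order and strand, protein families diverged to target identities
(substitutions only), circular-overlap and inverted-terminal-repeat
topologies, random decoy contigs, and giant-virus contigs sharing a planted
24-30 nt seed whose ~18 nt substring recurs inside one giant-virus gene.

Every planted fact (family membership, gene coordinates, topology lengths,
virophage-giant-virus links) is recorded in :class:`GroundTruth` and is
verifiable by direct string inspection of the emitted FASTA, so each
downstream stage can be scored exactly.

Design notes: intergenic DNA is i.i.d. uniform over ACGT (makes chance 24-mer
matches vanishingly rare); back-translation draws uniformly over synonymous
codons; circularity is encoded as an exact terminal duplication of the first
``circular_overlap_len`` bases (assembler-overlap convention). Each planted
gene is flanked by a short guard sequence carrying stop codons in all six
frames and no ATG/CAT, so the in-repo ORF caller recovers planted coordinates
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .seqio import (
    CORE_LABELS,
    GeneAnnotation,
    SequenceRecord,
    write_fasta,
    write_gff3,
    write_habitats,
)

#: stop codons in all six frames, no ATG on either strand
GUARD = "TTAACTAACTAACGC"

DNA = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: realistic core-gene protein lengths (aa); MCP matches the published mean
CORE_LENGTHS = {
    "MCP": 593,
    "mCP": 500,
    "ATPase": 250,
    "PRO": 210,
    "MTase": 220,
    "integrase": 300,
}

_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for aa in _BACK_TABLE:
    _BACK_TABLE[aa].sort()
_STOPS = sorted(standard_dna_table.stop_codons)

DEFAULT_ORDERS: list[list[tuple[str, str]]] = [
    # ancestral five-gene block
    [("MTase", "+"), ("PRO", "+"), ("ATPase", "+"), ("mCP", "+"), ("MCP", "+")],
    # ATPase-mCP-MCP colocalized in this order, PRO elsewhere on the minus strand
    [("ATPase", "+"), ("mCP", "+"), ("MCP", "+"), ("PRO", "-")],
    # plain four-gene order
    [("MCP", "+"), ("mCP", "+"), ("PRO", "+"), ("ATPase", "+")],
]


class GenerationError(RuntimeError):
    """Raised when a genome cannot be assembled under the configuration."""


@dataclass
class SimConfig:
    """Knobs of the synthetic corpus; defaults are the study conditions."""

    seed: int = 7
    n_virophages: int = 50
    n_decoys: int = 100
    genome_len_range: tuple[int, int] = (10_900, 42_300)
    n_lineages: int = 3
    core_gene_orders: list[list[tuple[str, str]]] | None = None
    within_family_identity: tuple[float, float] = (0.6, 0.9)
    seed_member_identity: float = 0.85
    n_seed_members: int = 4
    topology_mix: dict[str, float] = field(
        default_factory=lambda: {"circular": 0.4, "itr": 0.4, "linear": 0.2}
    )
    itr_len_range: tuple[int, int] = (100, 500)
    circular_overlap_len: int = 50
    n_giant_viruses: int = 5
    n_links: int | None = None
    mimivire_seed_len: int = 27
    mimivire_copies: int = 3
    mimivire_seed_motif: str | None = None
    habitat_labels: tuple[str, ...] = ("freshwater", "marine", "soil", "human_gut", "rumen")
    habitat_bias: float = 0.8
    fraction_partial: float = 0.2
    n_accessory_families: int = 4
    accessory_len_range: tuple[int, int] = (150, 300)
    accessory_prevalence_range: tuple[float, float] = (0.1, 0.55)
    decoy_len_range: tuple[int, int] = (5_000, 20_000)

    def __post_init__(self) -> None:
        if self.genome_len_range[0] < 1_000:
            raise ValueError("genome_len_range minimum must be >= 1000 bp")
        if not (24 <= self.mimivire_seed_len <= 30):
            raise ValueError("mimivire_seed_len must lie in [24, 30]")
        total = sum(self.topology_mix.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.topology_mix.values()):
            raise ValueError("topology_mix fractions must be non-negative and sum to 1")
        if not (0.0 <= self.habitat_bias <= 1.0 and 0.0 <= self.fraction_partial <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.core_gene_orders is None:
            self.core_gene_orders = [
                [tuple(g) for g in DEFAULT_ORDERS[k % len(DEFAULT_ORDERS)]]
                for k in range(self.n_lineages)
            ]
        if len(self.core_gene_orders) != self.n_lineages:
            raise ValueError("need one core gene order per lineage")
        for order in self.core_gene_orders:
            labels = [g for g, _s in order]
            if not set(CORE_LABELS) <= set(labels):
                raise ValueError(f"order {labels} lacks one of the four core genes")


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass
class GTGene:
    gene_id: str
    label: str
    family_id: str | None
    start: int
    end: int
    strand: str
    protein: str


@dataclass
class GTContig:
    contig_id: str
    kind: str                      # virophage | decoy | giant_virus
    lineage: int | None
    tier: str | None               # HQ_complete | HQ | partial (virophages)
    topology: dict
    habitat: str | None
    genes: list[GTGene]
    intergenic: list[tuple[int, int]]


@dataclass
class GTLink:
    virophage_id: str
    seed_start_virophage: int
    gv_id: str
    gene_id: str
    seed: str
    unit: str
    copies: int


@dataclass
class GroundTruth:
    contigs: dict[str, GTContig] = field(default_factory=dict)
    families: dict[str, list[str]] = field(default_factory=dict)
    links: list[GTLink] = field(default_factory=list)

    def hq_ids(self) -> set[str]:
        return {
            c.contig_id
            for c in self.contigs.values()
            if c.kind == "virophage" and c.tier in ("HQ", "HQ_complete")
        }

    def family_of_protein(self) -> dict[str, str]:
        return {pid: fam for fam, members in self.families.items() for pid in members}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "contigs": {
                cid: dataclasses.asdict(c) for cid, c in sorted(self.contigs.items())
            },
            "families": {k: sorted(v) for k, v in sorted(self.families.items())},
            "links": [dataclasses.asdict(l) for l in self.links],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        gt = cls()
        for cid, c in payload["contigs"].items():
            genes = [GTGene(**g) for g in c.pop("genes")]
            c["intergenic"] = [tuple(t) for t in c["intergenic"]]
            gt.contigs[cid] = GTContig(genes=genes, **c)
        gt.families = {k: list(v) for k, v in payload["families"].items()}
        gt.links = [GTLink(**l) for l in payload["links"]]
        return gt


# ---------------------------------------------------------------------------
# Elementary generators


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=n)])


def random_protein(n: int, rng: np.random.Generator) -> str:
    body = "".join(np.array(list(AA20))[rng.integers(0, 20, size=n - 1)])
    return "M" + body


def back_translate(protein: str, rng: np.random.Generator, with_stop: bool = True) -> str:
    codons = [_BACK_TABLE[aa][rng.integers(0, len(_BACK_TABLE[aa]))] for aa in protein]
    if with_stop:
        codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(codons)


def mutate_protein(ancestor: str, identity: float, rng: np.random.Generator) -> str:
    """Substitution-only mutant with exact identity to the ancestor.

    Position 0 (the initiator M) is never touched so the coding sequence keeps
    an ATG start.
    """
    n_sub = int(round((1.0 - identity) * len(ancestor)))
    n_sub = min(n_sub, len(ancestor) - 1)
    positions = rng.choice(np.arange(1, len(ancestor)), size=n_sub, replace=False)
    seq = list(ancestor)
    for p in positions:
        alternatives = [a for a in AA20 if a != seq[p]]
        seq[p] = alternatives[rng.integers(0, 19)]
    return "".join(seq)


def make_two_hop_homolog(
    ancestor: str,
    rng: np.random.Generator,
    intermediate_identity: float = 0.35,
    hop_identity: float = 0.40,
) -> tuple[str, str]:
    """A two-hop homolog chain for exercising iterative model refinement.

    Returns (B, C): B is a direct mutant of the ancestor at
    ``intermediate_identity``; C sits at ``hop_identity`` to B but is pushed
    out of direct detection range of the ancestor's family by mutating to
    residues that differ from both B and the ancestor (leaving C at roughly
    ``intermediate_identity * hop_identity`` to the ancestor). A model built
    from a tight ancestor family detects B but not C; once B is recruited and
    the model rebuilt, C becomes detectable.
    """
    b = mutate_protein(ancestor, intermediate_identity, rng)
    n_sub = int(round((1.0 - hop_identity) * len(b)))
    positions = rng.choice(np.arange(1, len(b)), size=n_sub, replace=False)
    c = list(b)
    for p in positions:
        alts = [a for a in AA20 if a != b[p] and a != ancestor[p]]
        c[p] = alts[rng.integers(0, len(alts))]
    return b, "".join(c)


def make_protein_family(
    ancestor: str,
    n_members: int,
    identity: float,
    rng: np.random.Generator,
    family_id: str,
    member_prefix: str = "p",
) -> tuple[list[SequenceRecord], str]:
    """Generate ``n_members`` mutants of ``ancestor`` at the given identity."""
    if not (0.0 < identity <= 1.0):
        raise ValueError(f"identity must lie in (0, 1], got {identity}")
    if len(ancestor) < 30:
        raise ValueError("ancestor must be at least 30 aa")
    members = [
        SequenceRecord(f"{member_prefix}{i + 1:03d}", mutate_protein(ancestor, identity, rng))
        for i in range(n_members)
    ]
    return members, family_id


# ---------------------------------------------------------------------------
# Lineages


@dataclass
class LineageSpec:
    lineage: int
    order: list[tuple[str, str]]
    ancestors: dict[str, str]              # label -> ancestor protein
    family_ids: dict[str, str]             # label -> family id
    identity: dict[str, float]             # label -> within-family identity


def build_lineages(config: SimConfig, rng: np.random.Generator) -> list[LineageSpec]:
    shared: dict[str, str] = {}
    lineages = []
    lo, hi = config.within_family_identity
    for k, order in enumerate(config.core_gene_orders, start=1):
        ancestors: dict[str, str] = {}
        fam_ids: dict[str, str] = {}
        idents: dict[str, float] = {}
        for label, _strand in order:
            if label in ("MTase", "integrase"):
                # horizontally shared accessory-like genes: one family corpus-wide
                if label not in shared:
                    shared[label] = random_protein(CORE_LENGTHS[label], rng)
                ancestors[label] = shared[label]
                fam_ids[label] = f"fam_{label}"
            else:
                ancestors[label] = random_protein(CORE_LENGTHS[label], rng)
                fam_ids[label] = f"fam_{label}_L{k}"
            idents[label] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        lineages.append(LineageSpec(k, [tuple(g) for g in order], ancestors, fam_ids, idents))
    return lineages


# ---------------------------------------------------------------------------
# Virophage assembly


def _draw_topology(config: SimConfig, rng: np.random.Generator) -> str:
    kinds = sorted(config.topology_mix)
    probs = np.array([config.topology_mix[k] for k in kinds])
    return kinds[rng.choice(len(kinds), p=probs / probs.sum())]


def _assemble_contig(
    contig_id: str,
    gene_nts: list[tuple[str, str, str, str | None]],  # (label, strand, nt, family_id)
    target_len: int,
    rng: np.random.Generator,
    margin: int = 600,
    min_gap: int = 60,
) -> tuple[str, list[GTGene], list[tuple[int, int]]]:
    """Lay out guarded genes with random intergenic filler to ``target_len``."""
    guarded = [GUARD + nt + GUARD for _l, _s, nt, _f in gene_nts]
    fixed = sum(len(g) for g in guarded)
    n_gaps = len(guarded) + 1
    budget = target_len - fixed - 2 * margin
    if budget < n_gaps * min_gap:
        raise GenerationError(
            f"{contig_id}: target length {target_len} too small for gene cassette"
        )
    extra = budget - n_gaps * min_gap
    bars = np.sort(rng.integers(0, extra + 1, size=n_gaps - 1))
    gap_lens = np.diff(np.concatenate([[0], bars, [extra]])) + min_gap
    parts: list[str] = [random_dna(margin, rng)]
    genes: list[GTGene] = []
    intergenic: list[tuple[int, int]] = [(0, margin)]
    pos = margin
    for idx, (g, (label, strand, nt, fam)) in enumerate(zip(guarded, gene_nts)):
        gap = random_dna(int(gap_lens[idx]), rng)
        parts.append(gap)
        intergenic.append((pos, pos + len(gap)))
        pos += len(gap)
        parts.append(g)
        gstart = pos + len(GUARD)
        gend = gstart + len(nt)
        protein = _protein_of(nt, strand)
        genes.append(GTGene(f"{contig_id}|g{idx + 1}", label, fam, gstart, gend, strand, protein))
        pos += len(g)
    tail = int(gap_lens[-1])
    parts.append(random_dna(tail, rng))
    intergenic.append((pos, pos + tail))
    pos += tail
    parts.append(random_dna(margin, rng))
    intergenic.append((pos, pos + margin))
    seq = "".join(parts)
    assert len(seq) == target_len, (len(seq), target_len)
    return seq, genes, intergenic


def _protein_of(nt: str, strand: str) -> str:
    coding = nt if strand == "+" else str(Seq(nt).reverse_complement())
    return str(Seq(coding[:-3]).translate())


def make_virophage(
    config: SimConfig,
    lineage: LineageSpec,
    rng: np.random.Generator,
    contig_id: str,
    extra_genes: list[tuple[str, str, str | None]] | None = None,
    force_tier: str | None = None,
) -> tuple[GTContig, str]:
    """Generate one virophage contig in the lineage's gene order.

    ``extra_genes`` are (label, protein, family_id) accessory insertions.
    ``force_tier`` of ``"partial"`` degrades the genome (undersized or one
    core gene dropped). Returns the ground-truth entry; the sequence is stored
    in ``topology['sequence']`` transiently by the caller.
    """
    order = list(lineage.order)
    target_len = int(rng.integers(config.genome_len_range[0], config.genome_len_range[1] + 1))
    topology_kind = _draw_topology(config, rng)
    drop_label = None
    if force_tier == "partial":
        if rng.random() < 0.5:
            target_len = int(rng.integers(8_800, 9_900))
        else:
            droppable = [l for l, _s in order if l in ("mCP", "ATPase", "PRO")]
            drop_label = droppable[rng.integers(0, len(droppable))]
            order = [(l, s) for l, s in order if l != drop_label]

    gene_nts: list[tuple[str, str, str, str | None]] = []
    for label, strand in order:
        protein = mutate_protein(lineage.ancestors[label], lineage.identity[label], rng)
        nt = back_translate(protein, rng)
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        gene_nts.append((label, strand, nt, lineage.family_ids[label]))
    for label, protein, fam in extra_genes or []:
        nt = back_translate(protein, rng)
        gene_nts.append((label, "+", nt, fam))

    itr_len = 0
    if topology_kind == "itr":
        itr_len = int(rng.integers(config.itr_len_range[0], config.itr_len_range[1] + 1))
    body_len = target_len - (2 * itr_len if topology_kind == "itr" else 0)
    seq, genes, intergenic = _assemble_contig(contig_id, gene_nts, body_len, rng)

    topo: dict = {"kind": topology_kind}
    if topology_kind == "circular":
        ov = config.circular_overlap_len
        seq = seq + seq[:ov]
        topo["overlap_len"] = ov
    elif topology_kind == "itr":
        left = random_dna(itr_len, rng)
        right = str(Seq(left).reverse_complement())
        seq = left + seq + right
        # prevent chance one-base inward extension of the repeat
        inner_left = seq[itr_len]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if inner_left == comp[seq[-itr_len - 1]]:
            choices = [c for c in DNA if c != inner_left]
            seq = seq[:itr_len] + choices[rng.integers(0, 3)] + seq[itr_len + 1:]
        genes = [dataclasses.replace(g, start=g.start + itr_len, end=g.end + itr_len)
                 for g in genes]
        intergenic = [(s + itr_len, e + itr_len) for s, e in intergenic]
        topo["itr_len"] = itr_len
        topo["left_span"] = [0, itr_len]
        topo["right_span"] = [len(seq) - itr_len, len(seq)]

    has_core = {l for l, _s in order} >= set(CORE_LABELS)
    if len(seq) >= 10_000 and has_core:
        tier = "HQ_complete" if topology_kind in ("circular", "itr") else "HQ"
    else:
        tier = "partial"
    gt = GTContig(contig_id, "virophage", lineage.lineage, tier, topo, None, genes, intergenic)
    return gt, seq


# ---------------------------------------------------------------------------
# Giant viruses and MIMIVIRE links


def make_giant_virus_with_link(
    virophage: GTContig,
    virophage_seq: str,
    config: SimConfig,
    rng: np.random.Generator,
    gv_id: str,
) -> tuple[GTContig, str, GTLink, str]:
    """Generate a giant-virus contig sharing a planted seed with a virophage.

    The seed (``mimivire_seed_len`` nt) is copied verbatim from a virophage
    intergenic region into one giant-virus gene; an 18-nt codon-aligned
    substring of the seed is inserted ``mimivire_copies - 1`` further times
    into the same gene at codon boundaries.
    """
    slen = config.mimivire_seed_len
    vlen = len(virophage_seq)
    gaps = [g for g in virophage.intergenic
            if g[1] - g[0] >= slen + 40 and g[0] >= 600 and g[1] <= vlen - 600]
    if not gaps:
        raise GenerationError(f"{virophage.contig_id}: no intergenic region fits the seed")
    gs, ge = gaps[rng.integers(0, len(gaps))]
    seed_start = int(rng.integers(gs + 10, ge - slen - 10))
    seed = virophage_seq[seed_start:seed_start + slen]
    if config.mimivire_seed_motif is not None:
        seed = config.mimivire_seed_motif
        if len(seed) != slen:
            raise GenerationError("mimivire_seed_motif length must equal mimivire_seed_len")
        virophage_seq = (
            virophage_seq[:seed_start] + seed + virophage_seq[seed_start + slen:]
        )

    # giant-virus scaffold: three genes, the middle one carries the insertions
    glen = int(rng.integers(15_000, 30_000))
    proteins = [random_protein(int(rng.integers(300, 500)), rng) for _ in range(3)]
    gene_nts = [("other", "+", back_translate(p, rng), None) for p in proteins]
    seq, genes, _inter = _assemble_contig(gv_id, gene_nts, glen, rng)

    target = genes[1]
    gene_nt = seq[target.start:target.end]
    offset_choices = [o for o in range(0, slen - 18 + 1, 3)] or [0]
    u0 = offset_choices[rng.integers(0, len(offset_choices))]
    unit = seed[u0:u0 + 18]
    n_codons = (len(gene_nt) - 3) // 3
    # codon slots: seed plus copies-1 units, well separated
    n_ins = 1 + max(config.mimivire_copies - 1, 0)
    slots = np.sort(rng.choice(np.arange(20, n_codons - 20), size=n_ins, replace=False))
    pieces = []
    prev = 0
    for si, slot in enumerate(slots):
        cut = int(slot) * 3
        pieces.append(gene_nt[prev:cut])
        pieces.append(seed if si == 0 else unit)
        prev = cut
    pieces.append(gene_nt[prev:])
    new_gene_nt = "".join(pieces)
    seq = seq[:target.start] + new_gene_nt + seq[target.end:]
    shift = len(new_gene_nt) - len(gene_nt)
    new_genes = []
    for g in genes:
        if g.gene_id == target.gene_id:
            new_genes.append(dataclasses.replace(g, end=g.end + shift,
                                                 protein=_protein_of(new_gene_nt, "+")))
        elif g.start > target.start:
            new_genes.append(dataclasses.replace(g, start=g.start + shift, end=g.end + shift))
        else:
            new_genes.append(g)
    copies = _count_occurrences(new_gene_nt, unit)
    gt = GTContig(gv_id, "giant_virus", None, None, {"kind": "linear"}, None, new_genes, [])
    link = GTLink(virophage.contig_id, seed_start, gv_id, target.gene_id, seed, unit, copies)
    return gt, seq, link, virophage_seq


def _count_occurrences(haystack: str, needle: str) -> int:
    count = 0
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


# ---------------------------------------------------------------------------
# Decoys


def make_decoy(config: SimConfig, rng: np.random.Generator, contig_id: str,
               core_ancestors: list[str]) -> tuple[GTContig, str]:
    """Random contig; rejection-sampled so no ORF protein resembles a core
    ancestor (>= 30% identity over >= 70% of both)."""
    from .align import protein_identity
    from .seqio import call_orfs

    for _attempt in range(20):
        n = int(rng.integers(config.decoy_len_range[0], config.decoy_len_range[1] + 1))
        seq = random_dna(n, rng)
        rec = SequenceRecord(contig_id, seq)
        clean = True
        for orf in call_orfs(rec, min_len=100):
            for anc in core_ancestors:
                st = protein_identity(orf.protein.residues, anc)
                if st.identity >= 0.30 and st.coverage_a >= 0.70 and st.coverage_b >= 0.70:
                    clean = False
                    break
            if not clean:
                break
        if clean:
            gt = GTContig(contig_id, "decoy", None, None, {"kind": "linear"}, None, [], [])
            return gt, seq
    raise GenerationError(f"{contig_id}: could not generate a clean decoy")


# ---------------------------------------------------------------------------
# Whole corpus


@dataclass
class SyntheticCorpus:
    config: SimConfig
    contigs: dict[str, SequenceRecord]         # virophages + decoys
    giants: dict[str, SequenceRecord]
    annotations: list[GeneAnnotation]
    giant_annotations: list[GeneAnnotation]
    proteins: list[SequenceRecord]
    habitats: dict[str, str]
    seed_alignments: dict[str, list[SequenceRecord]]   # "<label>_L<k>" -> members
    ground_truth: GroundTruth


def make_metagenome(config: SimConfig, outdir: str | Path | None = None) -> SyntheticCorpus:
    """Generate the full corpus; byte-identical files under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    gt = GroundTruth()
    lineages = build_lineages(config, rng)

    # accessory families with planted prevalences
    accessory: list[tuple[str, str, float, float]] = []  # (fam_id, ancestor, prevalence, identity)
    lo, hi = config.within_family_identity
    for a in range(config.n_accessory_families):
        alen = int(rng.integers(config.accessory_len_range[0], config.accessory_len_range[1] + 1))
        prev = float(rng.uniform(*config.accessory_prevalence_range))
        ident = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        accessory.append((f"fam_acc{a + 1:02d}", random_protein(alen, rng), prev, ident))

    n_partial = int(round(config.fraction_partial * config.n_virophages))
    accessory_members: dict[str, set[int]] = {}
    for fam_id, _anc, prev, _ident in accessory:
        k = int(round(prev * config.n_virophages))
        chosen = rng.choice(np.arange(config.n_virophages), size=min(k, config.n_virophages),
                            replace=False)
        accessory_members[fam_id] = set(int(x) for x in chosen)

    contigs: dict[str, SequenceRecord] = {}
    seqs: dict[str, str] = {}
    habitats: dict[str, str] = {}
    for i in range(config.n_virophages):
        cid = f"vp_{i + 1:03d}"
        lineage = lineages[i % len(lineages)]
        extra = []
        for fam_id, anc, _prev, ident in accessory:
            if i in accessory_members[fam_id]:
                extra.append(("other", mutate_protein(anc, ident, rng), fam_id))
        force = "partial" if i < n_partial else None
        entry, seq = make_virophage(config, lineage, rng, cid, extra_genes=extra,
                                    force_tier=force)
        # habitat: lineage-biased
        labels = config.habitat_labels
        home = labels[(lineage.lineage - 1) % len(labels)]
        if rng.random() < config.habitat_bias:
            hab = home
        else:
            hab = labels[rng.integers(0, len(labels))]
        entry.habitat = hab
        habitats[cid] = hab
        gt.contigs[cid] = entry
        seqs[cid] = seq

    core_ancestors = sorted(
        {anc for lin in lineages for anc in lin.ancestors.values()}
    ) + [anc for _f, anc, _p, _i in accessory]
    for i in range(config.n_decoys):
        cid = f"decoy_{i + 1:03d}"
        entry, seq = make_decoy(config, rng, cid, core_ancestors)
        hab = config.habitat_labels[rng.integers(0, len(config.habitat_labels))]
        entry.habitat = hab
        habitats[cid] = hab
        gt.contigs[cid] = entry
        seqs[cid] = seq

    # giant viruses; the first n_links get a planted virophage link
    n_links = config.n_links if config.n_links is not None else config.n_giant_viruses
    n_links = min(n_links, config.n_giant_viruses, config.n_virophages)
    giants: dict[str, SequenceRecord] = {}
    giant_seqs: dict[str, str] = {}
    linkable = [cid for cid in sorted(gt.contigs)
                if gt.contigs[cid].kind == "virophage"
                and gt.contigs[cid].tier in ("HQ", "HQ_complete")]
    for i in range(config.n_giant_viruses):
        gvid = f"gv_{i + 1:03d}"
        if i < n_links and i < len(linkable):
            vcid = linkable[i]
            entry, seq, link, new_vseq = make_giant_virus_with_link(
                gt.contigs[vcid], seqs[vcid], config, rng, gvid
            )
            seqs[vcid] = new_vseq
            gt.links.append(link)
        else:
            glen = int(rng.integers(15_000, 30_000))
            proteins3 = [random_protein(int(rng.integers(300, 500)), rng) for _ in range(3)]
            gene_nts = [("other", "+", back_translate(p, rng), None) for p in proteins3]
            seq, genes, _ = _assemble_contig(gvid, gene_nts, glen, rng)
            entry = GTContig(gvid, "giant_virus", None, None, {"kind": "linear"}, None, genes, [])
        gt.contigs[gvid] = entry
        giant_seqs[gvid] = seq

    # families ledger (genome members only)
    for cid, entry in gt.contigs.items():
        for g in entry.genes:
            if g.family_id:
                gt.families.setdefault(g.family_id, []).append(g.gene_id)
    for fam in gt.families.values():
        fam.sort()

    # seed alignments (reference members, not placed on any genome)
    seed_alignments: dict[str, list[SequenceRecord]] = {}
    for lin in lineages:
        for label, _strand in lin.order:
            key = f"{label}_L{lin.lineage}"
            if key in seed_alignments:
                continue
            members = [
                SequenceRecord(
                    f"seed_{key}_{m + 1}",
                    mutate_protein(lin.ancestors[label], config.seed_member_identity, rng),
                )
                for m in range(config.n_seed_members)
            ]
            seed_alignments[key] = members

    for cid, s in seqs.items():
        contigs[cid] = SequenceRecord(cid, s)
    for gvid, s in giant_seqs.items():
        giants[gvid] = SequenceRecord(gvid, s)

    annotations: list[GeneAnnotation] = []
    giant_annotations: list[GeneAnnotation] = []
    proteins: list[SequenceRecord] = []
    for cid in sorted(gt.contigs):
        entry = gt.contigs[cid]
        for g in entry.genes:
            ann = GeneAnnotation(cid, g.start, g.end, g.strand, g.gene_id, g.label,
                                 SequenceRecord(g.gene_id, g.protein))
            if entry.kind == "giant_virus":
                giant_annotations.append(ann)
            else:
                annotations.append(ann)
                proteins.append(SequenceRecord(g.gene_id, g.protein))

    corpus = SyntheticCorpus(
        config=config,
        contigs=contigs,
        giants=giants,
        annotations=annotations,
        giant_annotations=giant_annotations,
        proteins=proteins,
        habitats=habitats,
        seed_alignments=seed_alignments,
        ground_truth=gt,
    )
    if outdir is not None:
        write_corpus(corpus, outdir)
    return corpus


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([corpus.contigs[c] for c in sorted(corpus.contigs)], outdir / "contigs.fasta")
    write_fasta([corpus.giants[c] for c in sorted(corpus.giants)], outdir / "giants.fasta")
    write_gff3(corpus.annotations, outdir / "annotations.gff3")
    write_gff3(corpus.giant_annotations, outdir / "giants.gff3")
    write_fasta(sorted(corpus.proteins, key=lambda r: r.id), outdir / "proteins.faa")
    write_habitats(corpus.habitats, outdir / "habitats.tsv")
    corpus.ground_truth.to_json(outdir / "ground_truth.json")
    seeds_dir = outdir / "seeds"
    seeds_dir.mkdir(exist_ok=True)
    for key in sorted(corpus.seed_alignments):
        write_fasta(corpus.seed_alignments[key], seeds_dir / f"{key}.aln.fasta")
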