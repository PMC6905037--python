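"""Virophage genome quality control.

Implements the discovery pipeline's filters: completeness signals
(circular-overlap ends, inverted terminal repeats), per-gene core-label
assignment by profile search, quality tiering (>= 10 kb with all four core
genes = high quality; plus a completeness signal = complete), and greedy
identity/coverage de-replication of genes (95/95) and contigs (95/80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .align import PairwiseStats, dna_identity, protein_identity
from .profiles import ProfileModel, search
from .seqio import CORE_LABELS, GeneAnnotation, SequenceRecord

HQ_MIN_LEN = 10_000


@dataclass
class Topology:
    kind: str                      # linear | circular | itr | circular+itr
    overlap_len: int = 0
    itr_len: int = 0
    itr_left: tuple[int, int] | None = None
    itr_right: tuple[int, int] | None = None

    @property
    def complete(self) -> bool:
        return self.kind != "linear"


@dataclass
class VirophageGenome:
    """A candidate virophage contig with its annotations and QC state."""

    record: SequenceRecord
    annotations: list[GeneAnnotation] = field(default_factory=list)
    topology: Topology | None = None
    quality: str | None = None     # HQ_complete | HQ | partial
    clade_id: str | None = None
    synteny_signature: str | None = None
    habitat: str | None = None

    @property
    def contig_id(self) -> str:
        return self.record.id

    def core_labels(self) -> set[str]:
        return {a.product_label for a in self.annotations if a.product_label in CORE_LABELS}


# ---------------------------------------------------------------------------
# Topology detection


def detect_circularity(contig: SequenceRecord, min_overlap: int = 20) -> int | None:
    """Longest exact overlap between the 5' and 3' ends, or None.

    The longest k with ``prefix(k) == suffix(k)`` is the longest border of the
    sequence, found with the KMP prefix function in one linear pass; only
    borders of at least ``min_overlap`` and at most half the contig count.
    """
    s = contig.residues
    n = len(s)
    if n < 2 * min_overlap:
        return None
    pi = [0] * n
    k = 0
    for i in range(1, n):
        c = s[i]
        while k and s[k] != c:
            k = pi[k - 1]
        if s[k] == c:
            k += 1
        pi[i] = k
    best = pi[-1]
    while best > n // 2:
        best = pi[best - 1]
    return best if best >= min_overlap else None


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def detect_itr(
    contig: SequenceRecord,
    min_len: int = 100,
    max_mismatch: int = 0,
    search_window: int = 5_000,
) -> Topology | None:
    """Longest inverted terminal repeat of at least ``min_len`` bp.

    The left copy is sought in the first ``search_window`` bp and must equal
    the reverse complement of a right copy in the last ``search_window`` bp.
    Matching is exact by default (``max_mismatch`` reserved for future use; a
    nonzero value is rejected). A fully palindromic contig yields one repeat
    spanning the two halves, reported once.
    """
    if max_mismatch != 0:
        raise NotImplementedError("only exact ITR matching is supported")
    s = contig.residues
    n = len(s)
    w = min(search_window, n)
    left = s[:w]
    right = s[n - w:]
    right_rc = right.translate(_COMPLEMENT)[::-1]
    from .align import maximal_exact_matches

    best = None
    for la, lb, length in maximal_exact_matches(left, right_rc, min_len):
        # lb indexes right_rc; map back to the right window's forward coords
        right_start = n - w + (w - lb - length)
        left_span = (la, la + length)
        right_span = (right_start, right_start + length)
        if right_span[0] < left_span[1]:
            # degenerate palindrome: the two copies overlap; shorten the match
            # so the copies abut (a length-L' prefix of the left copy pairs
            # with the length-L' suffix of the right copy)
            trimmed = (right_span[0] + length - left_span[0]) // 2
            if trimmed < min_len:
                continue
            left_span = (la, la + trimmed)
            right_span = (right_start + length - trimmed, right_start + length)
            length = trimmed
        if best is None or length > best.itr_len:
            best = Topology("itr", itr_len=length, itr_left=left_span, itr_right=right_span)
    return best


def detect_topology(contig: SequenceRecord, min_overlap: int = 20,
                    itr_min_len: int = 100, search_window: int = 5_000) -> Topology:
    ov = detect_circularity(contig, min_overlap)
    itr = detect_itr(contig, itr_min_len, 0, search_window)
    if ov and itr:
        t = Topology("circular+itr", overlap_len=ov, itr_len=itr.itr_len,
                     itr_left=itr.itr_left, itr_right=itr.itr_right)
        return t
    if ov:
        return Topology("circular", overlap_len=ov)
    if itr:
        return itr
    return Topology("linear")


# ---------------------------------------------------------------------------
# Core-gene assignment


def assign_core_genes(
    genome: VirophageGenome,
    models: list[ProfileModel],
    label_of_model: dict[str, str],
    e_cut: float = 1e-3,
    db_size: int | None = None,
) -> VirophageGenome:
    """Label each core gene with its best-scoring profile model.

    ``label_of_model`` maps model ids to core labels; several models may share
    a label (e.g., alternative mCP variants). Each label goes to at most one
    gene (the best hit); exact ties break deterministically by gene
    coordinate with a warning. Genes without a hit keep ``other``.
    """
    proteins = [a.protein for a in genome.annotations if a.protein is not None]
    if not proteins:
        return genome
    n = db_size if db_size is not None else max(len(proteins), 1)
    best_per_label: dict[str, tuple[float, GeneAnnotation]] = {}
    by_id = {a.protein.id: a for a in genome.annotations if a.protein is not None}
    for model in models:
        label = label_of_model[model.model_id]
        for hit in search(model, proteins, e_cut=e_cut, db_size=n):
            ann = by_id[hit.protein_id]
            cur = best_per_label.get(label)
            if cur is None or hit.score > cur[0]:
                best_per_label[label] = (hit.score, ann)
            elif cur is not None and hit.score == cur[0] and ann is not cur[1]:
                keep = min(cur[1], ann, key=lambda a: (a.start, a.gene_id))
                warnings.warn(
                    f"{genome.contig_id}: exact score tie for {label}; keeping {keep.gene_id}"
                )
                best_per_label[label] = (hit.score, keep)
    for ann in genome.annotations:
        ann.product_label = "other"
    for label, (_score, ann) in best_per_label.items():
        ann.product_label = label
    return genome


# ---------------------------------------------------------------------------
# Quality tiering


def tier_quality(genomes: list[VirophageGenome]) -> dict[str, int]:
    """Set the quality tier of each genome; returns counts per tier.

    HQ: length >= 10 kb and all four core genes; HQ_complete: additionally a
    completeness signal (circular overlap and/or ITR); otherwise partial.
    """
    counts = {"HQ_complete": 0, "HQ": 0, "partial": 0}
    for g in genomes:
        has_core = g.core_labels() >= set(CORE_LABELS)
        if len(g.record) >= HQ_MIN_LEN and has_core:
            if g.topology is not None and g.topology.complete:
                g.quality = "HQ_complete"
            else:
                g.quality = "HQ"
        else:
            g.quality = "partial"
        counts[g.quality] += 1
    return counts


# ---------------------------------------------------------------------------
# De-replication


def _pair_stats(a: SequenceRecord, b: SequenceRecord, mode: str) -> PairwiseStats:
    if mode == "gene":
        return protein_identity(a.residues, b.residues) if not a.is_dna \
            else dna_identity(a.residues, b.residues)
    return dna_identity(a.residues, b.residues)


def dereplicate(
    items: list[SequenceRecord],
    id_thresh: float = 0.95,
    cov_thresh: float = 0.95,
    mode: str = "gene",
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy longest-first de-replication.

    Items are sorted by length descending (ties by id); each item joins the
    first existing representative it matches (identity >= ``id_thresh`` over
    >= ``cov_thresh`` of the shorter sequence, from a local alignment), else
    founds a new cluster. Returns representatives (input order of founding)
    and an item -> representative map. Gene mode defaults to 95/95 and contig
    mode to 95/80 at the call sites.
    """
    if not (0 < id_thresh <= 1 and 0 < cov_thresh <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if mode not in ("gene", "contig"):
        raise ValueError("mode must be 'gene' or 'contig'")
    ordered = sorted(items, key=lambda r: (-len(r), r.id))
    reps: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    for item in ordered:
        assigned = None
        for rep in reps:
            st = _pair_stats(item, rep, mode)
            if st.identity >= id_thresh and st.coverage_short >= cov_thresh:
                assigned = rep
                break
        if assigned is None:
            reps.append(item)
            membership[item.id] = item.id
        else:
            membership[item.id] = assigned.id
    return reps, membership


def dereplicate_contigs(items: list[SequenceRecord], id_thresh: float = 0.95,
                        cov_thresh: float = 0.80):
    return dereplicate(items, id_thresh, cov_thresh, mode="contig")
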