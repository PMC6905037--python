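"""Concatenated core-gene phylogeny, clade collapse, and synteny analysis.

The classification unit is a clade of a tree built from the concatenated
alignment of the four core genes (MCP, mCP, ATPase, PRO) of high-quality
genomes: per-gene alignment, gappy-column trimming, neighbor joining on
Poisson-corrected (equal-rates ML) protein distances with column-bootstrap
supports, then auto-collapse of subtrees whose mean root-to-leaf path length
is below 1.2 substitutions per site at support >= 0.8.

Synteny signatures record core-gene order and strand in a canonical
orientation (MCP forward; circular genomes rotated so MCP comes first), so a
genome and its reverse complement map to the same signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .align import align_proteins
from .seqio import CORE_LABELS, SequenceRecord

GAP = "-"
SYNTENY_LABELS = CORE_LABELS + ("MTase",)

CORE_ORDER = ("MCP", "mCP", "ATPase", "PRO")


class AlignmentError(ValueError):
    pass


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise AlignmentError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def gap_fractions(self) -> np.ndarray:
        arr = np.array([list(r) for r in self.rows])
        return (arr == GAP).mean(axis=0)

    def ungapped(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)].replace(GAP, "")


def align(records: list[SequenceRecord]) -> MultipleAlignment:
    """Multiple-align a protein family (single sequences pass through)."""
    if not records:
        raise AlignmentError("nothing to align")
    aligned = align_proteins(records)
    return MultipleAlignment([r.id for r in aligned], [r.residues for r in aligned])


def trim(alignment: MultipleAlignment, max_gap_fraction: float = 0.90) -> MultipleAlignment:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``."""
    if not alignment.rows:
        raise AlignmentError("empty alignment")
    keep = alignment.gap_fractions() <= max_gap_fraction
    if not keep.any():
        raise AlignmentError(
            "trimming removed every column; raise max_gap_fraction"
        )
    idx = np.nonzero(keep)[0]
    rows = ["".join(r[i] for i in idx) for r in alignment.rows]
    return MultipleAlignment(list(alignment.ids), rows, list(alignment.partitions))


def concatenate(gene_alignments: dict[str, MultipleAlignment],
                order: tuple[str, ...] = CORE_ORDER) -> MultipleAlignment:
    """Concatenate per-gene alignments row-wise by genome id.

    Row ids of each block must be genome ids. Genomes missing any block are
    excluded with a warning (they violate the high-quality contract).
    """
    blocks = [gene_alignments[label] for label in order]
    common = set(blocks[0].ids)
    for b in blocks[1:]:
        common &= set(b.ids)
    dropped = set().union(*(set(b.ids) for b in blocks)) - common
    if dropped:
        warnings.warn(f"genomes missing core genes excluded: {sorted(dropped)}")
    if not common:
        raise AlignmentError("no genome has all core genes")
    genomes = sorted(common)
    rows = []
    for g in genomes:
        rows.append("".join(b.rows[b.ids.index(g)] for b in blocks))
    partitions = []
    pos = 0
    for label, b in zip(order, blocks):
        partitions.append((label, pos, pos + b.n_columns))
        pos += b.n_columns
    return MultipleAlignment(genomes, rows, partitions)


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def _encode_rows(rows: list[str]) -> np.ndarray:
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])


_GAP_BYTE = ord(GAP)
# saturation ceiling: beyond ~p=0.94 the log correction explodes, and the
# resulting variance distorts neighbor-joining branch lengths elsewhere in
# the tree, so saturated pairs are clamped to a common finite distance
_MAX_DIST = 5.0


def poisson_distances(rows: list[str]) -> np.ndarray:
    """Pairwise equal-rates ML protein distances d = -19/20 ln(1 - 20/19 p).

    ``p`` is the mismatch fraction over columns where neither row is gapped;
    saturated pairs (p at or beyond the 19/20 ceiling) are clamped to a
    finite maximum.
    """
    enc = _encode_rows(rows)
    n = enc.shape[0]
    out = np.zeros((n, n))
    valid = enc != _GAP_BYTE
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diffs = (enc[i] != enc[i + 1:]) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, diffs.sum(axis=1) / np.maximum(denom, 1), 0.0)
            inner = 1.0 - 20.0 / 19.0 * p
            d = np.where(inner > 1e-6, -19.0 / 20.0 * np.log(np.maximum(inner, 1e-6)),
                         _MAX_DIST)
        d = np.minimum(d, _MAX_DIST)
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return out


@dataclass
class CladeTree:
    tree: TreeNode                     # midpoint-rooted, branch lengths >= 0
    leaf_ids: list[str]
    supports: dict[frozenset, float]   # canonical bipartition -> support

    def newick(self) -> str:
        clone = self.tree.copy()
        for node in clone.non_tips():
            key = _bipartition(node, set(self.leaf_ids))
            if key in self.supports:
                node.name = f"{self.supports[key]:.2f}"
        return str(clone).strip()


def _bipartition(node: TreeNode, all_leaves: set[str]) -> frozenset:
    side = frozenset(t.name for t in node.tips())
    other = frozenset(all_leaves - side)
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def _nj_tree(dm: np.ndarray, ids: list[str]) -> TreeNode:
    tree = nj(DistanceMatrix(dm, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_tree(alignment: MultipleAlignment, method: str = "nj",
               bootstrap: int = 100, seed: int = 0) -> CladeTree:
    """Neighbor-joining tree with column-bootstrap bipartition supports.

    Distances are Poisson-corrected ML protein distances; the tree is
    midpoint-rooted. An external maximum-likelihood backend can replace this
    behind the same contract.
    """
    if method != "nj":
        raise NotImplementedError("only the in-repo nj backend is built in")
    if len(alignment.ids) < 4:
        raise AlignmentError("tree inference needs at least 4 sequences")
    ids = list(alignment.ids)
    dm = poisson_distances(alignment.rows)
    main = _nj_tree(dm, ids).root_at_midpoint()
    rng = np.random.default_rng(seed)
    ncol = alignment.n_columns
    counts: dict[frozenset, int] = {}
    all_leaves = set(ids)
    for _ in range(bootstrap):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r[c] for c in cols) for r in alignment.rows]
        rep = _nj_tree(poisson_distances(rows), ids)
        seen = set()
        for node in rep.non_tips(include_self=True):
            key = _bipartition(node, all_leaves)
            if 1 < len(key) < len(ids) and key not in seen:
                seen.add(key)
                counts[key] = counts.get(key, 0) + 1
    supports = {k: v / bootstrap for k, v in counts.items()}
    return CladeTree(main, ids, supports)


# ---------------------------------------------------------------------------
# Clade collapse


@dataclass
class Clade:
    clade_id: str
    members: list[str]
    support: float
    singleton: bool = False
    dominant_signature: str | None = None
    signature_fraction: float | None = None
    habitat_composition: dict[str, int] = field(default_factory=dict)
    length_stats: tuple[float, float] | None = None   # mean, sd of genome length


def _mean_leaf_depth(node: TreeNode) -> float:
    depths = [node.distance(t) for t in node.tips()]
    return float(np.mean(depths)) if depths else 0.0


def collapse_clades(clade_tree: CladeTree, max_avg_branch_length: float = 1.2,
                    min_support: float = 0.8) -> list[Clade]:
    """Collapse maximal well-supported shallow subtrees into clades.

    A node founds a clade when the mean path length from it to its leaves is
    below ``max_avg_branch_length`` and its bipartition support is at least
    ``min_support`` (the root counts as fully supported). Leaves not captured
    by any such subtree become singleton clades, flagged as such. Clades are
    numbered in tree traversal order.
    """
    tree = clade_tree.tree
    all_leaves = set(clade_tree.leaf_ids)
    clades: list[Clade] = []

    def support_of(node: TreeNode) -> float:
        if node.is_root():
            return 1.0
        key = _bipartition(node, all_leaves)
        return clade_tree.supports.get(key, 1.0 if len(key) <= 1 else 0.0)

    def visit(node: TreeNode) -> None:
        if node.is_tip():
            clades.append(Clade("", [node.name], support_of(node), singleton=True))
            return
        if _mean_leaf_depth(node) < max_avg_branch_length and support_of(node) >= min_support:
            members = sorted(t.name for t in node.tips())
            clades.append(Clade("", members, support_of(node)))
            return
        for child in node.children:
            visit(child)

    visit(tree)
    for k, clade in enumerate(clades, start=1):
        clade.clade_id = f"Vp.cl{k:02d}"
    return clades


# ---------------------------------------------------------------------------
# Synteny signatures


@dataclass(frozen=True)
class SyntenySignature:
    genes: tuple[tuple[str, str], ...]     # (label, strand) in canonical order
    oriented: bool                          # False when MCP absent
    mcp_mcp_adjacent: bool

    @property
    def gene_order(self) -> str:
        return "–".join(l for l, _s in self.genes)

    def __str__(self) -> str:
        return "–".join(f"{l}({s})" for l, s in self.genes)


def synteny_signature(genome) -> SyntenySignature:
    """Canonical core-gene order/strand signature of a genome.

    Canonical orientation puts MCP on the forward strand (otherwise the gene
    list is reverse-complemented); circular genomes are additionally rotated
    so MCP comes first. Adjacency is judged on the full gene order including
    unlabeled genes. Without an MCP the signature is emitted unoriented.
    """
    anns = sorted(genome.annotations, key=lambda a: (a.start, a.gene_id))
    labeled = [(a.product_label, a.strand) for a in anns
               if a.product_label in SYNTENY_LABELS]
    full_labels = [a.product_label for a in anns]
    mcp_mcp = any(
        {full_labels[i], full_labels[i + 1]} == {"MCP", "mCP"}
        for i in range(len(full_labels) - 1)
    )
    mcp_entries = [(i, s) for i, (l, s) in enumerate(labeled) if l == "MCP"]
    if not mcp_entries:
        return SyntenySignature(tuple(labeled), False, mcp_mcp)
    idx, strand = mcp_entries[0]
    genes = list(labeled)
    if strand == "-":
        genes = [(l, "+" if s == "-" else "-") for l, s in reversed(genes)]
        idx = len(genes) - 1 - idx
    circular = (
        genome.topology is not None
        and getattr(genome.topology, "kind", "linear").startswith("circular")
    )
    if circular:
        genes = genes[idx:] + genes[:idx]
    return SyntenySignature(tuple(genes), True, mcp_mcp)


@dataclass
class BlockReport:
    n_genomes: int
    five_gene_block: int        # 4 core genes + MTase contiguous
    four_gene_block: int        # 4 core genes contiguous (no MTase in block)
    three_gene_no_atpase: int   # MCP, mCP, PRO contiguous; ATPase absent
    atpase_mcp_mcp_in_order: int
    mcp_mcp_adjacent: int


def _contiguous(full_labels: list[str], wanted: set[str]) -> bool:
    idx = [i for i, l in enumerate(full_labels) if l in wanted]
    present = {full_labels[i] for i in idx}
    if present != wanted:
        return False
    return max(idx) - min(idx) == len(idx) - 1


def detect_blocks(genomes) -> BlockReport:
    """Count conserved gene-block arrangements across genomes."""
    five = four = three = amm = adj = 0
    for g in genomes:
        anns = sorted(g.annotations, key=lambda a: (a.start, a.gene_id))
        labels = [a.product_label for a in anns]
        present = set(labels) & set(SYNTENY_LABELS)
        sig = synteny_signature(g)
        core = set(CORE_LABELS)
        if "MTase" in present and _contiguous(labels, core | {"MTase"}):
            five += 1
        elif present >= core and _contiguous(labels, core):
            four += 1
        elif "ATPase" not in present and _contiguous(labels, {"MCP", "mCP", "PRO"}):
            three += 1
        canon = [l for l, _s in sig.genes]
        for i in range(len(canon) - 2):
            if canon[i:i + 3] == ["ATPase", "mCP", "MCP"]:
                amm += 1
                break
        adj += sig.mcp_mcp_adjacent
    return BlockReport(len(list(genomes)), five, four, three, amm, adj)


# ---------------------------------------------------------------------------
# Habitat profile (model x habitat matrix)


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean sorted profile (classic quantile norm)."""
    ranks = df.rank(axis=0, method="first").astype(int) - 1
    mean_sorted = np.sort(df.values, axis=0).mean(axis=1)
    out = df.copy()
    for col in df.columns:
        out[col] = mean_sorted[ranks[col].values]
    return out


def habitat_profile(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Normalize a model x habitat hit-count matrix and cluster both axes.

    Columns (habitats) are converted to percentages, quantile-normalized, and
    both axes are ordered by complete-linkage hierarchical clustering on
    Euclidean distances. All-zero rows/columns are dropped with a warning.
    Returns the normalized matrix and the two leaf orders (rows, columns).
    """
    df = counts.astype(float)
    zero_rows = df.index[(df.sum(axis=1) == 0)]
    zero_cols = df.columns[(df.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping all-zero rows {list(zero_rows)} / columns {list(zero_cols)}"
        )
        df = df.drop(index=zero_rows, columns=zero_cols)
    if df.empty:
        raise ValueError("habitat matrix is empty after dropping zero rows/columns")
    pct = df / df.sum(axis=0) * 100.0
    norm = quantile_normalize(pct)
    if len(norm.index) > 1:
        row_order = [norm.index[i] for i in
                     leaves_list(linkage(norm.values, method="complete"))]
    else:
        row_order = list(norm.index)
    if len(norm.columns) > 1:
        col_order = [norm.columns[i] for i in
                     leaves_list(linkage(norm.values.T, method="complete"))]
    else:
        col_order = list(norm.columns)
    return norm, row_order, col_order
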