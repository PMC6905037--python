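"""Two-step clustering of virophage proteins into protein clusters (VpPCs).

Step one builds a weighted similarity graph from an all-vs-all Smith-Waterman
comparison (edges admitted at score >= 30 and E <= 0.01, weight proportional
to the alignment score) and partitions it with a seeded community detection.
Step two de-replicates each community at 90% identity, builds a profile per
community, and merges communities whose profile-profile comparison passes
either acceptance rule: calibrated match probability >= 0.90 with coverage
>= 0.50, or probability >= 0.99 with coverage >= 0.20 and aligned length
>= 100 aa. Connected components of merged communities become VpPCs (groups
of two or more proteins; residual singletons are dropped).

VpPCs are then categorized by prevalence across high-quality genomes: core
(all genomes), common (25-60%), accessory (<25%); the band between 60% and
100% is reported as ``common_high`` rather than silently folded into a named
category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .align import best_ungapped_segment, encode_protein, protein_score
from .profiles import ProfileModel, build_profile, shuffled
from .qc import dereplicate
from .seqio import SequenceRecord

SCORE_CUT = 30.0
EVALUE_CUT = 0.01


@dataclass(frozen=True)
class SimilarityEdge:
    protein_a: str
    protein_b: str
    score: float
    e_value: float


@dataclass
class VpPC:
    """A virophage protein cluster: a family of homologous proteins."""

    pc_id: str
    member_ids: list[str]
    prevalence: float | None = None
    category: str | None = None
    profile: ProfileModel | None = None
    annotation: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


# ---------------------------------------------------------------------------
# Step 1a: the similarity graph


def _fit_null(proteins: list[SequenceRecord], rng: np.random.Generator,
              n_pairs: int = 200) -> tuple[float, float]:
    """Gumbel fit to Smith-Waterman scores of shuffled decoy pairs."""
    recs = sorted(proteins, key=lambda r: r.id)
    scores = []
    for _ in range(n_pairs):
        a = recs[rng.integers(0, len(recs))].residues
        b = recs[rng.integers(0, len(recs))].residues
        scores.append(protein_score(shuffled(a, rng), shuffled(b, rng)))
    mu, beta = stats.gumbel_r.fit(np.array(scores))
    return float(mu), float(1.0 / beta)


def all_vs_all(
    proteins: list[SequenceRecord],
    score_cut: float = SCORE_CUT,
    e_cut: float = EVALUE_CUT,
    rng: np.random.Generator | None = None,
) -> list[SimilarityEdge]:
    """All-vs-all Smith-Waterman comparison yielding admitted edges.

    Scores use BLOSUM62 with affine gaps 11/1 and are symmetric by
    construction. E-values come from a Gumbel null fitted to shuffled decoy
    pairs, scaled by the database size. Edges failing either the raw score or
    the E-value threshold are dropped.
    """
    if len(proteins) < 2:
        raise ValueError("all_vs_all requires at least 2 proteins")
    rng = rng or np.random.default_rng(0)
    recs = sorted(proteins, key=lambda r: r.id)
    mu, lam = _fit_null(recs, rng)
    n = len(recs)
    edges: list[SimilarityEdge] = []
    for i in range(n):
        for j in range(i + 1, n):
            s = protein_score(recs[i].residues, recs[j].residues)
            if s < score_cut:
                continue
            e = n * np.exp(-lam * (s - mu))
            if e <= e_cut:
                edges.append(SimilarityEdge(recs[i].id, recs[j].id, s, float(e)))
    return edges


# ---------------------------------------------------------------------------
# Step 1b: community detection


def detect_communities(
    edges: list[SimilarityEdge],
    proteins: list[SequenceRecord] | None = None,
    seed: int = 0,
) -> list[list[str]]:
    """Partition the weighted similarity graph into communities.

    Louvain on edge weights (deterministic under ``seed``) stands behind the
    two-level map-equation contract; communities are returned sorted, and
    proteins without any admitted edge form singleton groups when the full
    protein list is supplied.
    """
    graph = nx.Graph()
    if proteins is not None:
        graph.add_nodes_from(r.id for r in proteins)
    for e in edges:
        graph.add_edge(e.protein_a, e.protein_b, weight=e.score)
    if graph.number_of_edges() == 0:
        groups = [[n] for n in graph.nodes]
    else:
        comms = nx.community.louvain_communities(graph, weight="weight", seed=seed)
        groups = [sorted(c) for c in comms]
    groups = [sorted(g) for g in groups]
    groups.sort(key=lambda g: g[0])
    return groups


# ---------------------------------------------------------------------------
# Step 2: profile-profile merging


@dataclass
class _GroupProfile:
    index: int
    members: list[SequenceRecord]
    model: ProfileModel | None       # None when degenerate


def _group_profile(index: int, members: list[SequenceRecord],
                   min_columns: int = 10) -> _GroupProfile:
    reps, _ = dereplicate(members, id_thresh=0.90, cov_thresh=0.90, mode="gene")
    from .align import align_proteins

    aligned = align_proteins(reps)
    if len(aligned[0].residues) < min_columns:
        warnings.warn(f"group {index}: profile shorter than {min_columns} columns; kept unmerged")
        return _GroupProfile(index, members, None)
    model = build_profile(aligned, f"group_{index}", n_calibration_decoys=0) \
        if len(aligned) >= 2 else build_profile(aligned * 2, f"group_{index}",
                                                n_calibration_decoys=0)
    return _GroupProfile(index, members, model)


def _profile_pair_score(a: ProfileModel, b: ProfileModel) -> tuple[float, int]:
    """Max of consensus-vs-PSSM scores in both directions and aligned length."""
    s_ab = best_ungapped_segment(b.column_scores, encode_protein(a.consensus))
    s_ba = best_ungapped_segment(a.column_scores, encode_protein(b.consensus))
    if s_ab[0] >= s_ba[0]:
        score, m0, m1, s0, s1 = s_ab
    else:
        score, m0, m1, s0, s1 = s_ba
    return float(score), int(m1 - m0)


def _calibrate_profile_null(profiles: list[_GroupProfile],
                            rng: np.random.Generator,
                            n_pairs: int = 60) -> tuple[float, float]:
    """Null mean/sd of profile-pair scores from shuffled-member decoy groups."""
    usable = [p for p in profiles if p.model is not None]
    if len(usable) < 2:
        return 0.0, 1.0
    decoys = []
    for p in usable[: min(len(usable), 12)]:
        shuffled_members = [
            SequenceRecord(m.id, shuffled(m.residues, rng)) for m in p.members
        ]
        decoys.append(_group_profile(-p.index - 1, shuffled_members))
    scores = []
    k = 0
    while len(scores) < n_pairs and k < 4 * n_pairs:
        i = rng.integers(0, len(decoys))
        j = rng.integers(0, len(decoys))
        k += 1
        if i == j or decoys[i].model is None or decoys[j].model is None:
            continue
        s, _l = _profile_pair_score(decoys[i].model, decoys[j].model)
        scores.append(s)
    if not scores:
        return 0.0, 1.0
    return float(np.mean(scores)), float(max(np.std(scores), 1.0))


def profile_match_probability(score: float, null_mean: float, null_sd: float) -> float:
    """Logistic calibration of a profile-pair score against the decoy null.

    Centred four null standard deviations above the decoy mean with the null
    standard deviation as scale, so decoy-level scores map to ~0 and scores
    far beyond the null map to ~1.
    """
    z = (score - (null_mean + 4.0 * null_sd)) / null_sd
    return float(1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))))


def merge_by_profiles(
    groups: list[list[SequenceRecord]],
    rng: np.random.Generator | None = None,
    prob_high: float = 0.90,
    cov_high: float = 0.50,
    prob_very_high: float = 0.99,
    cov_low: float = 0.20,
    min_len: int = 100,
) -> list[VpPC]:
    """Merge communities into VpPCs by profile-profile comparison.

    Two groups link iff (p >= 0.90 and coverage >= 0.50) or (p >= 0.99 and
    coverage >= 0.20 and aligned length >= 100 aa), where coverage is the
    aligned column count over the shorter profile length. Connected
    components of linked groups become VpPCs; single-protein leftovers are
    dropped.
    """
    rng = rng or np.random.default_rng(0)
    profiles = [_group_profile(i, sorted(g, key=lambda r: r.id))
                for i, g in enumerate(groups)]
    null_mean, null_sd = _calibrate_profile_null(profiles, rng)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(profiles)))
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            pi, pj = profiles[i], profiles[j]
            if pi.model is None or pj.model is None:
                continue
            score, aligned_len = _profile_pair_score(pi.model, pj.model)
            cov = aligned_len / min(pi.model.consensus_length, pj.model.consensus_length)
            p = profile_match_probability(score, null_mean, null_sd)
            if (p >= prob_high and cov >= cov_high) or (
                p >= prob_very_high and cov >= cov_low and aligned_len >= min_len
            ):
                graph.add_edge(i, j)
    pcs: list[VpPC] = []
    component_members: list[list[str]] = []
    for comp in nx.connected_components(graph):
        members = sorted({m.id for k in comp for m in profiles[k].members})
        if len(members) >= 2:
            component_members.append(members)
    component_members.sort(key=lambda m: m[0])
    for k, members in enumerate(component_members, start=1):
        pcs.append(VpPC(f"VpPC_{k:03d}", members))
    return pcs


# ---------------------------------------------------------------------------
# Categorization and markers


def genome_of_protein(protein_id: str) -> str:
    """Genome (contig) id from the ``<contig>|<gene>`` protein id convention."""
    return protein_id.split("|", 1)[0]


def prevalence_category(prevalence: float) -> str:
    """Band logic: core at 1.0; common in [0.25, 0.60]; accessory below 0.25.

    Prevalence strictly between 0.60 and 1.0 has no published name and is
    reported as ``common_high``.
    """
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must lie in [0, 1]")
    if prevalence == 1.0:
        return "core"
    if 0.25 <= prevalence <= 0.60:
        return "common"
    if prevalence < 0.25:
        return "accessory"
    return "common_high"


def categorize(
    pcs: list[VpPC],
    hq_genome_ids: set[str],
    genome_of: dict[str, str] | None = None,
) -> list[VpPC]:
    """Set prevalence (fraction of HQ genomes holding >= 1 member) and band."""
    if not hq_genome_ids:
        raise ValueError("HQ genome set must be non-empty")
    for pc in pcs:
        genomes = {
            genome_of[m] if genome_of else genome_of_protein(m)
            for m in pc.member_ids
        }
        pc.prevalence = len(genomes & hq_genome_ids) / len(hq_genome_ids)
        pc.category = prevalence_category(pc.prevalence)
    return pcs


@dataclass
class MarkerRow:
    pc_id: str
    clades: tuple[str, ...]
    habitats: tuple[str, ...]
    n_genomes: int
    clade_marker: bool
    habitat_marker: bool


def clade_and_habitat_markers(
    pcs: list[VpPC],
    genome_clades: dict[str, str],
    genome_habitats: dict[str, str],
    genome_of: dict[str, str] | None = None,
) -> list[MarkerRow]:
    """Flag PCs restricted to one clade (or habitat) and >= 2 genomes."""
    rows = []
    for pc in pcs:
        genomes = sorted({
            genome_of[m] if genome_of else genome_of_protein(m)
            for m in pc.member_ids
        })
        clades = tuple(sorted({genome_clades[g] for g in genomes if g in genome_clades}))
        habitats = tuple(sorted({genome_habitats[g] for g in genomes if g in genome_habitats}))
        rows.append(
            MarkerRow(
                pc.pc_id, clades, habitats, len(genomes),
                clade_marker=len(clades) == 1 and len(genomes) >= 2,
                habitat_marker=len(habitats) == 1 and len(genomes) >= 2,
            )
        )
    return rows
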