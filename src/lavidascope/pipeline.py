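"""End-to-end discovery pipeline: models -> search -> QC -> de-replication ->
protein clusters -> classification -> host linkage.

Stages communicate through files (FASTA/GFF3/TSV/JSON) so a run can be
inspected and restarted stage by stage; a manifest records the configuration
hash, per-stage outputs with checksums, timings and warnings. With internal
backends and a fixed seed the deterministic stages are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as pc
from . import phylo, qc
from .align import align_proteins
from .linkage import GiantVirusContig, link_all
from .profiles import (
    DEFAULT_E_CUT,
    ProfileModel,
    build_profile,
    iterate_models,
    mcp_completeness,
    models_from_json,
    models_to_json,
    search,
)
from .seqio import (
    CORE_LABELS,
    GeneAnnotation,
    SequenceRecord,
    read_fasta,
    read_gff3,
    read_habitats,
    write_fasta,
)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a discovery run (defaults = published)."""

    # inputs
    contigs: str = "contigs.fasta"
    annotations: str = "annotations.gff3"
    proteins: str = "proteins.faa"
    habitats: str | None = "habitats.tsv"
    seeds_dir: str = "seeds"
    giants: str | None = None
    giants_gff: str | None = None
    samples: str | None = None
    outdir: str = "out"
    # model building
    model_rounds: int = 2
    model_min_len_nt: int = 700
    search_e_cut: float = DEFAULT_E_CUT          # 1e-06
    assign_e_cut: float = 1e-3
    cluster_identity: float = 0.30
    cluster_align_frac: float = 0.70
    # genome QC
    hq_min_len: int = 10_000
    min_circular_overlap: int = 20
    min_itr_len: int = 100
    itr_window: int = 5_000
    # de-replication
    gene_derep: tuple[float, float] = (0.95, 0.95)
    contig_derep: tuple[float, float] = (0.95, 0.80)
    # protein clusters
    pc_score_cut: float = 30.0
    pc_e_cut: float = 0.01
    pc_prob_high: float = 0.90
    pc_cov_high: float = 0.50
    pc_prob_very_high: float = 0.99
    pc_cov_low: float = 0.20
    pc_min_len: int = 100
    # classification
    trim_max_gap: float = 0.90
    collapse_branch_length: float = 1.2
    collapse_min_support: float = 0.8
    bootstrap: int = 100
    # host linkage
    mimivire_len_range: tuple[int, int] = (24, 30)
    mimivire_unit_len: int = 18
    mimivire_min_copies: int = 2
    # misc
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("gene_derep", "contig_derep", "mimivire_len_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StageRecord:
    name: str
    seconds: float
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    config_hash: str
    stages: list[StageRecord] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "stages": [dataclasses.asdict(s) for s in self.stages],
                },
                indent=1,
                sort_keys=True,
            )
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Context helper that times a stage and checksums its outputs."""

    def __init__(self, manifest: RunManifest, name: str):
        self.record = StageRecord(name, 0.0)
        self.manifest = manifest
        self._t0 = 0.0

    def __enter__(self):
        self._t0 = time.time()
        return self.record

    def __exit__(self, exc_type, exc, tb):
        self.record.seconds = round(time.time() - self._t0, 3)
        for out in self.record.outputs:
            p = Path(out)
            if p.exists():
                self.record.outputs[out] = _sha256(p)
        self.manifest.stages.append(self.record)
        return False


def _label_of_seed_key(key: str) -> str:
    # seed alignment files are named "<label>_L<k>.aln.fasta"
    return key.split("_L")[0] if "_L" in key else key


def load_seed_alignments(seeds_dir: str | Path) -> dict[str, list[SequenceRecord]]:
    out = {}
    for path in sorted(Path(seeds_dir).glob("*.aln.fasta")):
        key = path.name[: -len(".aln.fasta")]
        out[key] = read_fasta(path, alphabet="protein")
    if not out:
        raise FileNotFoundError(f"no *.aln.fasta seed alignments under {seeds_dir}")
    return out


# ---------------------------------------------------------------------------
# Stages


def stage_models(config: PipelineConfig, proteins: list[SequenceRecord],
                 outdir: Path, record: StageRecord) -> tuple[list[ProfileModel], dict[str, str]]:
    """Build calibrated core-gene models; the MCP models are refined
    iteratively against the protein database (the bait step)."""
    rng = np.random.default_rng(config.seed)
    seeds = load_seed_alignments(config.seeds_dir)
    mcp_keys = [k for k in seeds if _label_of_seed_key(k) == "MCP"]
    other_keys = [k for k in seeds if _label_of_seed_key(k) != "MCP"]
    mcp_models = iterate_models(
        [seeds[k] for k in mcp_keys],
        proteins,
        rounds=config.model_rounds,
        min_len_nt=config.model_min_len_nt,
        e_cut=config.search_e_cut,
        rng=rng,
    )
    label_of: dict[str, str] = {}
    models: list[ProfileModel] = []
    for i, m in enumerate(mcp_models):
        m.model_id = f"MCP_model_{i + 1:02d}"
        label_of[m.model_id] = "MCP"
        models.append(m)
    for key in other_keys:
        m = build_profile(seeds[key], model_id=f"{key}_model", rng=rng)
        label_of[m.model_id] = _label_of_seed_key(key)
        models.append(m)
    path = outdir / "models.json"
    models_to_json(models, path)
    (outdir / "model_labels.json").write_text(json.dumps(label_of, indent=1, sort_keys=True))
    record.outputs[str(path)] = ""
    record.outputs[str(outdir / "model_labels.json")] = ""
    record.counts["models"] = len(models)
    record.counts["mcp_models"] = len(mcp_models)
    return models, label_of


def stage_search(config: PipelineConfig, models: list[ProfileModel],
                 label_of: dict[str, str], proteins: list[SequenceRecord],
                 outdir: Path, record: StageRecord) -> tuple[pd.DataFrame, set[str]]:
    """Screen all proteins with the MCP models (E < 1e-06 by default)."""
    rows = []
    for m in models:
        if label_of[m.model_id] != "MCP":
            continue
        for h in search(m, proteins, e_cut=config.search_e_cut):
            rows.append((m.model_id, h.protein_id, h.score, h.e_value, h.start, h.end,
                         mcp_completeness(h.end - h.start)))
    hits = pd.DataFrame(
        rows, columns=["model_id", "protein_id", "score", "evalue", "start", "end",
                       "mcp_completeness"],
    ).sort_values(["protein_id", "evalue"], kind="stable").reset_index(drop=True)
    candidates = {p.split("|", 1)[0] for p in hits["protein_id"]}
    path = outdir / "mcp_hits.tsv"
    hits.to_csv(path, sep="\t", index=False)
    record.outputs[str(path)] = ""
    record.counts["mcp_hits"] = len(hits)
    record.counts["candidate_contigs"] = len(candidates)
    return hits, candidates


def stage_qc(config: PipelineConfig, contig_map: dict[str, SequenceRecord],
             ann_by_contig: dict[str, list[GeneAnnotation]], candidates: set[str],
             models: list[ProfileModel], label_of: dict[str, str],
             habitats: dict[str, str], outdir: Path,
             record: StageRecord) -> list[qc.VirophageGenome]:
    """Topology, core-gene labels, and quality tier for candidate contigs."""
    genomes = []
    for cid in sorted(candidates):
        g = qc.VirophageGenome(contig_map[cid], list(ann_by_contig.get(cid, [])))
        g.topology = qc.detect_topology(
            g.record, config.min_circular_overlap, config.min_itr_len, config.itr_window
        )
        qc.assign_core_genes(g, models, label_of, e_cut=config.assign_e_cut)
        g.habitat = habitats.get(cid)
        genomes.append(g)
    counts = qc.tier_quality(genomes)
    rows = []
    for g in genomes:
        rows.append((
            g.contig_id, len(g.record), g.topology.kind, g.topology.overlap_len,
            g.topology.itr_len, ",".join(sorted(g.core_labels())), g.quality,
            g.habitat or "",
        ))
    table = pd.DataFrame(rows, columns=[
        "contig_id", "length", "topology", "overlap_len", "itr_len",
        "core_genes", "tier", "habitat"]).sort_values("contig_id")
    path = outdir / "qc_report.tsv"
    table.to_csv(path, sep="\t", index=False)
    record.outputs[str(path)] = ""
    record.counts.update(counts)
    return genomes


def stage_dereplicate(config: PipelineConfig, genomes: list[qc.VirophageGenome],
                      mcp_hits: pd.DataFrame, proteins: list[SequenceRecord],
                      outdir: Path, record: StageRecord) -> list[qc.VirophageGenome]:
    """Non-redundant MCP genes (95/95) and candidate contigs (95/80)."""
    prot_map = {p.id: p for p in proteins}
    mcp_prot = [prot_map[p] for p in sorted(set(mcp_hits["protein_id"])) if p in prot_map]
    id_t, cov_t = config.gene_derep
    nr_mcp, _ = qc.dereplicate(mcp_prot, id_t, cov_t, mode="gene") if mcp_prot else ([], {})
    id_t, cov_t = config.contig_derep
    reps, membership = qc.dereplicate([g.record for g in genomes], id_t, cov_t, mode="contig")
    rep_ids = {r.id for r in reps}
    kept = [g for g in genomes if g.contig_id in rep_ids]
    pd.DataFrame(
        sorted(membership.items()), columns=["contig_id", "representative"]
    ).to_csv(outdir / "contig_derep.tsv", sep="\t", index=False)
    write_fasta(sorted(nr_mcp, key=lambda r: r.id), outdir / "nr_mcp.faa")
    record.outputs[str(outdir / "contig_derep.tsv")] = ""
    record.outputs[str(outdir / "nr_mcp.faa")] = ""
    record.counts["nr_mcp"] = len(nr_mcp)
    record.counts["nr_contigs"] = len(kept)
    return kept


def stage_clusters(config: PipelineConfig, genomes: list[qc.VirophageGenome],
                   outdir: Path, record: StageRecord) -> list[pc.VpPC]:
    """Two-step protein clustering of all proteins from >= 10 kb contigs."""
    prots = [a.protein for g in genomes if len(g.record) >= config.hq_min_len
             for a in g.annotations if a.protein is not None]
    hq = {g.contig_id for g in genomes if g.quality in ("HQ", "HQ_complete")}
    if len(prots) < 2 or not hq:
        record.counts["vppcs"] = 0
        return []
    rng = np.random.default_rng(config.seed + 1)
    edges = pc.all_vs_all(prots, config.pc_score_cut, config.pc_e_cut, rng)
    groups = pc.detect_communities(edges, prots, seed=config.seed)
    rec_map = {p.id: p for p in prots}
    pcs = pc.merge_by_profiles(
        [[rec_map[p] for p in g] for g in groups],
        rng=rng,
        prob_high=config.pc_prob_high,
        cov_high=config.pc_cov_high,
        prob_very_high=config.pc_prob_very_high,
        cov_low=config.pc_cov_low,
        min_len=config.pc_min_len,
    )
    pc.categorize(pcs, hq)
    rows = [(p.pc_id, m, pc.genome_of_protein(m)) for p in pcs for m in p.member_ids]
    pd.DataFrame(rows, columns=["pc_id", "protein_id", "genome_id"]).to_csv(
        outdir / "pc_membership.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(p.pc_id, p.size, round(p.prevalence, 4), p.category) for p in pcs],
        columns=["pc_id", "n_members", "prevalence", "category"],
    ).to_csv(outdir / "pc_categories.tsv", sep="\t", index=False)
    record.outputs[str(outdir / "pc_membership.tsv")] = ""
    record.outputs[str(outdir / "pc_categories.tsv")] = ""
    record.counts["vppcs"] = len(pcs)
    return pcs


def stage_classify(config: PipelineConfig, genomes: list[qc.VirophageGenome],
                   outdir: Path, record: StageRecord):
    """Concatenated core-gene tree, clade collapse, synteny signatures."""
    hq = [g for g in genomes if g.quality in ("HQ", "HQ_complete")]
    if len(hq) < 4:
        record.counts["clades"] = 0
        return [], None
    per_gene = {}
    for label in phylo.CORE_ORDER:
        members = []
        for g in hq:
            core = [a for a in g.annotations if a.product_label == label]
            if core:
                members.append(SequenceRecord(g.contig_id, core[0].protein.residues))
        aligned = phylo.align(members)
        per_gene[label] = phylo.trim(aligned, config.trim_max_gap)
    concat = phylo.concatenate(per_gene)
    tree = phylo.build_tree(concat, bootstrap=config.bootstrap, seed=config.seed)
    clades = phylo.collapse_clades(
        tree, config.collapse_branch_length, config.collapse_min_support
    )
    clade_of = {m: c.clade_id for c in clades for m in c.members}
    sig_rows = []
    for g in hq:
        sig = phylo.synteny_signature(g)
        g.synteny_signature = str(sig)
        g.clade_id = clade_of.get(g.contig_id)
        sig_rows.append((g.contig_id, g.clade_id or "", sig.gene_order, str(sig),
                         sig.oriented, sig.mcp_mcp_adjacent, g.habitat or ""))
    blocks = phylo.detect_blocks(hq)
    for c in clades:
        sigs = [str(phylo.synteny_signature(g)) for g in hq if g.contig_id in set(c.members)]
        if sigs:
            top = max(sorted(set(sigs)), key=sigs.count)
            c.dominant_signature = top
            c.signature_fraction = sigs.count(top) / len(sigs)
        habs = [g.habitat for g in hq if g.contig_id in set(c.members) and g.habitat]
        c.habitat_composition = {h: habs.count(h) for h in sorted(set(habs))}
        lens = [len(g.record) for g in hq if g.contig_id in set(c.members)]
        c.length_stats = (float(np.mean(lens)), float(np.std(lens)))
    (outdir / "tree.nwk").write_text(tree.newick() + "\n")
    pd.DataFrame(sig_rows, columns=[
        "genome_id", "clade_id", "gene_order", "signature", "oriented",
        "mcp_mcp_adjacent", "habitat"]).to_csv(outdir / "clades.tsv", sep="\t", index=False)
    (outdir / "synteny_blocks.json").write_text(
        json.dumps(dataclasses.asdict(blocks), indent=1))
    record.outputs[str(outdir / "tree.nwk")] = ""
    record.outputs[str(outdir / "clades.tsv")] = ""
    record.outputs[str(outdir / "synteny_blocks.json")] = ""
    record.counts["hq_classified"] = len(hq)
    record.counts["clades"] = len(clades)
    return clades, blocks


def stage_linkage(config: PipelineConfig, genomes: list[qc.VirophageGenome],
                  outdir: Path, record: StageRecord) -> list:
    if not config.giants:
        record.counts["links"] = 0
        return []
    giant_recs = read_fasta(config.giants, alphabet="dna")
    g_ann = read_gff3(config.giants_gff) if config.giants_gff else []
    ann_by = {}
    for a in g_ann:
        ann_by.setdefault(a.contig_id, []).append(a)
    giants = [GiantVirusContig(r, ann_by.get(r.id, [])) for r in giant_recs]
    samples = read_habitats(config.samples) if config.samples else None
    links = link_all(
        [g.record for g in genomes], giants, co_occurrence=samples,
        len_range=config.mimivire_len_range,
        unit_len=config.mimivire_unit_len,
        min_copies=config.mimivire_min_copies,
    )
    rows = [(l.virophage_id, l.gv_id, l.gene_id, l.seed, l.seed_len, l.repeat_unit,
             l.copy_count, l.frame_agreement, l.co_occurrence) for l in links]
    pd.DataFrame(rows, columns=[
        "virophage_id", "gv_id", "gene_id", "seed", "seed_len", "unit",
        "copies", "frame_agreement", "co_occurrence"]).to_csv(
        outdir / "links.tsv", sep="\t", index=False)
    record.outputs[str(outdir / "links.tsv")] = ""
    record.counts["links"] = len(links)
    return links


def stage_report(config: PipelineConfig, genomes, pcs, clades, mcp_hits,
                 habitats: dict[str, str], outdir: Path, record: StageRecord) -> None:
    """Summary tables: clade composition, PC categories, habitat profile."""
    clade_rows = []
    for c in clades or []:
        clade_rows.append((
            c.clade_id, len(c.members), round(c.support, 3), c.singleton,
            c.dominant_signature or "", round(c.signature_fraction or 0.0, 3),
            json.dumps(c.habitat_composition, sort_keys=True),
            round(c.length_stats[0], 1) if c.length_stats else "",
            round(c.length_stats[1], 1) if c.length_stats else "",
        ))
    pd.DataFrame(clade_rows, columns=[
        "clade_id", "n_members", "support", "singleton", "dominant_signature",
        "signature_fraction", "habitat_composition", "mean_length", "sd_length",
    ]).to_csv(outdir / "clade_summary.tsv", sep="\t", index=False)
    cat_counts = {}
    for p in pcs or []:
        cat_counts[p.category] = cat_counts.get(p.category, 0) + 1
    pd.DataFrame(sorted(cat_counts.items()), columns=["category", "n_pcs"]).to_csv(
        outdir / "pc_category_counts.tsv", sep="\t", index=False)
    # model x habitat matrix from MCP hits
    if habitats is not None and len(mcp_hits):
        df = mcp_hits.copy()
        df["contig"] = [p.split("|", 1)[0] for p in df["protein_id"]]
        df["habitat"] = [habitats.get(c, "unknown") for c in df["contig"]]
        counts = df.pivot_table(index="model_id", columns="habitat", values="protein_id",
                                aggfunc="count", fill_value=0)
        counts.to_csv(outdir / "model_habitat_counts.tsv", sep="\t")
        try:
            norm, row_order, col_order = phylo.habitat_profile(counts)
            norm.loc[row_order, col_order].to_csv(
                outdir / "model_habitat_profile.tsv", sep="\t")
            record.outputs[str(outdir / "model_habitat_profile.tsv")] = ""
        except ValueError:
            pass
        record.outputs[str(outdir / "model_habitat_counts.tsv")] = ""
    record.outputs[str(outdir / "clade_summary.tsv")] = ""
    record.outputs[str(outdir / "pc_category_counts.tsv")] = ""


# ---------------------------------------------------------------------------
# Orchestration


def run_discovery(config: PipelineConfig) -> RunManifest:
    """Run every stage in order; each stage's files land before the next starts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.digest())
    config.to_yaml(outdir / "config.yaml")

    contigs = read_fasta(config.contigs, alphabet="dna")
    contig_map = {c.id: c for c in contigs}
    proteins = read_fasta(config.proteins, alphabet="protein")
    annotations = read_gff3(config.annotations, proteins={p.id: p for p in proteins})
    ann_by_contig: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        ann_by_contig.setdefault(a.contig_id, []).append(a)
    habitats = read_habitats(config.habitats) if config.habitats else {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        with _Stage(manifest, "models") as rec:
            models, label_of = stage_models(config, proteins, outdir, rec)
        with _Stage(manifest, "search") as rec:
            mcp_hits, candidates = stage_search(config, models, label_of, proteins,
                                                outdir, rec)
        with _Stage(manifest, "qc") as rec:
            genomes = stage_qc(config, contig_map, ann_by_contig, candidates, models,
                               label_of, habitats, outdir, rec)
        with _Stage(manifest, "dereplicate") as rec:
            genomes = stage_dereplicate(config, genomes, mcp_hits, proteins, outdir, rec)
        with _Stage(manifest, "clusters") as rec:
            pcs = stage_clusters(config, genomes, outdir, rec)
        with _Stage(manifest, "classify") as rec:
            clades, _blocks = stage_classify(config, genomes, outdir, rec)
        with _Stage(manifest, "linkage") as rec:
            stage_linkage(config, genomes, outdir, rec)
        with _Stage(manifest, "report") as rec:
            stage_report(config, genomes, pcs, clades, mcp_hits, habitats, outdir, rec)
    if manifest.stages and caught:
        manifest.stages[-1].warnings = sorted({str(w.message) for w in caught})
    manifest.save(outdir / "manifest.json")
    return manifest
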