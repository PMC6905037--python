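# lavidascope

Virophage genome mining, classification, and giant-virus host prediction
from assembled metagenomes.

Virophages (family *Lavidaviridae*) are small dsDNA viruses that co-infect
unicellular eukaryotes alongside a giant virus (NCLDV) and parasitize its
replication factory. Only four genes are conserved across nearly all known
virophages — the major and minor capsid proteins (MCP, mCP), a DNA-packaging
ATPase, and a cysteine protease (PRO) — which makes marker-gene mining the
practical route to discovering them in metagenome assemblies. `lavidascope`
implements that route as a reusable, tested pipeline for people who work on
viral dark matter: viromics researchers screening their own assemblies, and
methods developers who need a ground-truthed sandbox for marker-gene
discovery pipelines.

## What the pipeline does

1. **MCP profile models** ("bait"). Position-specific log-odds models
   (bits against a uniform background) are built from seed alignments and
   calibrated on shuffled decoys with a Gumbel fit, so a raw segment score
   `S` converts to an E-value `E = N·exp(−λ(S−μ))` over a database of `N`
   proteins. Models are refined iteratively: search at `E < 10⁻⁶`, recruit
   hits with gene length ≥ 700 nt, re-cluster (≥ 30% identity over ≥ 70% of
   both sequences, single linkage), rebuild.
2. **Genome QC.** Candidate contigs are tiered: *high quality* (HQ) at
   ≥ 10 kb with all four core genes; *complete* when circular (exact
   overlapping 5′/3′ ends, ≥ 20 nt) or bounded by inverted terminal repeats
   (ITR, ≥ 100 bp). MCP genes are length-classified against the published
   593 ± 40.1 aa statistics. De-replication is greedy longest-first at
   95% identity over 95% (genes) or 80% (contigs) of the shorter sequence.
3. **Protein clusters (VpPCs).** All-vs-all Smith–Waterman (BLOSUM62,
   gaps 11/1; edges at score ≥ 30 and E ≤ 0.01) → seeded community
   detection → per-community profiles merged when the calibrated match
   probability and coverage pass `p ≥ 0.90 ∧ cov ≥ 0.50` or
   `p ≥ 0.99 ∧ cov ≥ 0.20 ∧ len ≥ 100 aa`. Clusters are categorized by
   prevalence across HQ genomes: core (100%), common (25–60%),
   accessory (< 25%).
4. **Classification.** Per-gene alignments of the four core genes are
   trimmed (columns > 90% gaps), concatenated, and a neighbor-joining tree
   with column-bootstrap supports is built on Poisson-corrected protein
   distances. Subtrees with mean root-to-leaf path < 1.2 substitutions/site
   and support ≥ 0.8 collapse into clades (`Vp.cl` labels); each genome also
   gets a canonical core-gene synteny signature (MCP oriented forward).
5. **Host prediction (MIMIVIRE).** A virophage and a giant-virus contig are
   linked when they share an exact 24–30 nt sequence and an ~18 nt subset of
   it recurs (≥ 2 copies) inside one giant-virus gene; the seed region is
   translated in all frames in both genomes to check for a shared peptide
   motif.

A synthetic-data module (`lavidascope.simulate`) generates metagenome-like
corpora — multi-gene contigs of 10.9–42.3 kb with planted families,
topologies, lineages, decoys, and virophage–giant-virus links — with full
ground truth, so every stage is testable without downloading anything.

## Worked example

```bash
lavidascope simulate --seed 7 --n-virophages 15 --n-decoys 20 \
    --n-giant-viruses 3 --outdir corpus
lavidascope run-all --indir corpus --outdir out --seed 0
```

```
[models] 33.3s {'models': 13, 'mcp_models': 3}
[search] 1.6s {'mcp_hits': 15, 'candidate_contigs': 15}
[qc] 4.6s {'HQ_complete': 12, 'HQ': 0, 'partial': 3}
[dereplicate] 4.3s {'nr_mcp': 15, 'nr_contigs': 15}
[clusters] 15.2s {'vppcs': 17}
[classify] 0.4s {'hq_classified': 12, 'clades': 3}
[linkage] 6.0s {'links': 3}
```

Reading the funnel: the three per-lineage MCP models bait 15 candidate
contigs out of 35; 12 pass the HQ rules and all carry a completeness signal
(`HQ_complete`), while 3 planted degraded genomes land in `partial`; the 17
protein clusters are the 12 core-gene families (4 per lineage, with the
methyltransferase shared), plus accessory families; the 12 HQ genomes
collapse into the 3 planted lineages. `out/clade_summary.tsv` shows each
clade with its support, dominant gene-order signature and habitat makeup:

```
clade_id  n_members  support  dominant_signature               habitat_composition
Vp.cl01   4          1.0      MCP(+)–mCP(+)–PRO(+)–ATPase(+)   {"soil": 4}
Vp.cl02   4          1.0      ATPase(+)–mCP(+)–MCP(+)–PRO(-)   {"marine": 3, "soil": 1}
Vp.cl03   4          1.0      MCP(+)–MTase(+)–PRO(+)–ATPase(+)–mCP(+)  {"freshwater": 4}
```

and `out/links.tsv` lists the predicted co-infection pairs, each with the
shared seed and the three copies of its 18-mer inside one giant-virus gene:

```
virophage_id  gv_id   gene_id     copies
vp_006        gv_003  gv_003|g2   3
vp_004        gv_001  gv_001|g2   3
vp_005        gv_002  gv_002|g2   3
```

All stage outputs are plain TSV/FASTA/JSON under `out/`, and
`out/manifest.json` records the configuration hash, per-stage timings and
output checksums (two runs with the same seed are byte-identical).

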