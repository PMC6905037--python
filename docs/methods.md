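# Methods

This note documents the models behind `lavidascope`, the defaults and why
they are set where they are, what the synthetic corpora do and do not
emulate, and the numerical choices that matter for reproducibility. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Profile models and E-values

A profile model is a per-column log-odds matrix over the 20 amino acids,
`score(c, a) = log₂(p_c(a) / q(a))`, built from an aligned family after
dropping columns with more than 50% gaps. Column frequencies `p_c` use one
pseudocount per residue; the background `q` is uniform (1/20). With a
uniform background the expected per-column score is `−KL(q‖p_c) ≤ 0`, which
guarantees that random sequence drifts downward and local maximal-segment
statistics apply.

Scoring is the best *ungapped* local segment of a protein against the
matrix (a clamped Smith–Waterman recurrence without gap states, vectorized
over the whole database). Ungapped scoring is exact for the synthetic
corpora (the generator introduces substitutions only) and is the
conservative choice for real data, where it can only lose sensitivity,
never specificity. E-values come from a Gumbel fit
(`scipy.stats.gumbel_r`) to the maximal-segment scores of ≥ 1000
residue-shuffled copies of the training members:
`E(S) = N·exp(−λ(S−μ))` for a database of `N` sequences. The screening
threshold is `E < 10⁻⁶` (the discovery convention for marker searches) and
`E < 10⁻³` for per-genome core-gene labeling, where the database is a
single genome's proteome and the stakes of a missed label are higher than
those of a spurious one (tiering still requires all four labels).

Iterative refinement alternates search → recruit (gene length ≥ 700 nt,
i.e. ≥ ~233 aa, to keep fragments from diluting the alignment) → pool with
current members → re-cluster at ≥ 30% identity over ≥ 70% of *both*
sequences (single linkage over Smith–Waterman local alignments, BLOSUM62,
gap open/extend 11/1) → rebuild one model per family. A round that recruits
nothing ends the iteration with a warning. Model membership grows
monotonically; provenance (which seeds fed which model) is carried along.

An important calibration fact, measured while designing the acceptance
fixtures: against a model built from a tight family, a full-length homolog
at 40% identity scores so far above the shuffled-decoy null (E ≈ 10⁻⁴⁰)
that no calibrated threshold can miss it. Demonstrating the value of
iteration therefore requires a genuinely two-hop target: the test fixture
plants a homolog at 40% identity to a round-1 *recruit* but ~14% to the
seed family, which round 1 misses and round 2 finds. This mirrors how
iterative searches extend reach in practice — through chains of
intermediates, not by lowering thresholds.

## Genome quality control

- **Circularity**: the longest exact border (prefix equal to suffix) of
  length ≥ 20 nt and ≤ half the contig, found with the KMP prefix function
  in linear time. At 20 nt the chance of a false border on a random contig
  is ~L·4⁻²⁰ ≈ 10⁻⁶ per contig.
- **ITR**: the longest block of ≥ 100 bp within the terminal 5 kb windows
  whose left copy equals the reverse complement of a right copy, found by
  anchoring exact 100-mers and extending maximally. Matching is exact;
  a mismatch allowance is reserved in the interface but not implemented.
  A palindromic contig is reported once, with the match shortened so the
  two copies abut instead of overlapping.
- **Tiers**: HQ requires length ≥ 10 kb and all four core labels;
  HQ_complete additionally requires a completeness signal (circular
  overlap and/or ITR). Everything else is partial. Tiers partition the
  input by construction.
- **MCP completeness**: `complete` at length ≥ 593 − 40.1 aa (one-sided:
  longer-than-average capsid genes are still complete), `ge_half` at
  ≥ 296.5 aa, else `partial`.
- **De-replication** is greedy longest-first (ties by id): an item joins
  the first representative it matches at ≥ 95% identity over ≥ 95% (gene
  mode) or ≥ 80% (contig mode) of the shorter sequence, else founds a new
  cluster — the cd-hit convention, which makes representative choice
  deterministic. Identity is matches over aligned columns of a local
  alignment; pairs whose DP matrix would exceed ~3×10⁷ cells fall back to
  a k-mer (k = 31) anchor-and-chain estimate, which is exact in the
  near-duplicate regime where merging decisions happen and returns zero
  for unrelated contigs.

## Protein clusters (VpPCs)

Step one scores all protein pairs with Smith–Waterman (BLOSUM62, 11/1) and
admits edges at raw score ≥ 30 and E ≤ 0.01, with the E-value calibrated on
shuffled decoy pairs per corpus. The weighted graph is partitioned with
seeded Louvain; the two-level map-equation objective is the documented
contract and the community backend is pluggable behind it. Step two builds
a profile per community (after 90%-identity de-replication of members),
scores communities pairwise by consensus-vs-matrix in both directions
(taking the max), and converts scores to a match probability with a
logistic map centred four null standard deviations above the decoy-pair
mean (decoy profiles are built from residue-shuffled members). Communities
link when `p ≥ 0.90` with coverage ≥ 0.50, or `p ≥ 0.99` with coverage
≥ 0.20 and aligned length ≥ 100 columns, coverage being aligned columns
over the shorter profile. Connected components become VpPCs; clusters need
≥ 2 proteins. The calibrated-logistic probability stands in for an
HHsearch-style probability, which has no closed form; the two acceptance
disjuncts are exposed verbatim as configuration.

Prevalence bands over HQ genomes: core at exactly 100%, common at 25–60%,
accessory below 25%. The band strictly between 60% and 100% has no
published name; it is reported as `common_high` rather than silently folded
into a neighbour. Marker calling: a VpPC restricted to exactly one clade
(or one habitat) and present in ≥ 2 genomes.

## Classification

Per-gene alignments use mafft (default parameters) when rows differ in
length; substitution-only families are already aligned and pass through.
Columns with > 90% gaps are trimmed. Blocks are concatenated in the fixed
order MCP‖mCP‖ATPase‖PRO with partition boundaries recorded; genomes
missing a block are excluded with a warning.

Pairwise distances are the equal-rates ML (Poisson) protein correction
`d = −19/20·ln(1 − 20/19·p)` with `p` the mismatch fraction over mutually
ungapped columns. Saturated pairs are clamped at d = 5 substitutions/site:
beyond p ≈ 0.94 the log correction explodes and its sampling variance
distorts neighbor-joining branch lengths elsewhere in the tree; a common
finite ceiling keeps deep structure star-like and stable. A WAG-based ML
distance was considered and set aside — the closed-form correction is
self-contained and monotone in p, and an external ML tree backend
(e.g. fasttree) can replace the whole tree step behind the same interface.

Trees are neighbor-joining (scikit-bio), midpoint-rooted, negative branch
lengths clamped to zero. Supports are column-bootstrap bipartition
frequencies (default 100 replicates, seeded). Clade collapse takes maximal
nodes whose mean root-to-leaf path is < 1.2 substitutions/site with
support ≥ 0.8 — "average branch length distance" read as mean
leaf-to-subtree-root path, the auto-collapse semantics of common tree
viewers. Leaves captured by no qualifying subtree become singleton clades,
flagged. Clades are numbered in traversal order; published clade numbers
depend on the published data and are not reproduced. The published
workflow's manual-adjustment step is replaced by these deterministic rules.

Synteny signatures list core + MTase genes in genomic order with strands,
canonicalized so MCP is forward (otherwise the list is
reverse-complemented) and, for circular genomes, rotated so MCP is first;
a genome and its reverse complement therefore share one signature. Without
an MCP the signature is emitted unoriented and flagged. Adjacency (e.g.
MCP–mCP) is judged on the full gene order including unlabeled genes.

The model × habitat matrix is column-normalized to percentages,
quantile-normalized (every column mapped onto the mean sorted profile,
ties broken by first occurrence), and both axes are ordered by
complete-linkage hierarchical clustering on Euclidean distances.

## MIMIVIRE host linkage

Shared seeds are all maximal exact common substrings of ≥ 24 nt between a
virophage contig and either strand of a giant-virus contig, found by 24-mer
anchoring and extension (every qualifying match contains an anchor, so the
search is exhaustive; a brute-force enumeration oracle confirms this on
small contigs). Matches longer than 30 nt still qualify: the 24–30 window
is read as a minimum-information criterion, not an exclusion of longer
identity. The repeat rule scans all substrings of the seed of length
18 ± 2 and counts occurrences on the coding strand of each giant-virus gene
containing the seed — overlapping occurrences count as distinct spans,
identical spans once — and requires ≥ 2 copies by default (the seed's own
occurrence plus at least one more; the published example shows three, and
the generator's default plants three). The seed region is translated in
all three frames in both genomes; frame agreement means some frame pair
yields an identical peptide of ≥ 6 aa (guaranteed when ≥ 18 identical nt
align in-frame). Links are ranked by copy count, seed length, frame
agreement, and same-sample co-occurrence. On intergenic DNA that is i.i.d.
uniform, the expected number of chance 24-mer matches per contig pair is
~L₁L₂/4²⁴ ≈ 10⁻⁶, which the decoy-pair checks bear out.

## The synthetic corpus: what it emulates, and what it does not

The generator plants, per virophage: a lineage-specific cassette of the
four core genes (plus optionally MTase) in configurable order and strand,
back-translated from protein families mutated to target identities
(substitutions only, exact counts, uniform over the 19 alternatives;
synonymous codons uniform); random intergenic DNA; a topology drawn from
the configured mix (terminal duplication of the first 50 bp for circular;
exact reverse-complement terminal repeats of 100–500 bp for ITR); a
habitat label biased toward the lineage's home habitat; and optionally a
giant-virus partner sharing a planted seed. Genome lengths default to
10.9–42.3 kb, the span observed for complete virophage genomes. A
configurable fraction of genomes (default 20%) is degraded — undersized or
with one non-MCP core gene dropped — to populate the partial tier. Decoy
contigs are uniform random DNA, rejection-sampled so that no decoy ORF
reaches 30% identity over 70% coverage against any planted family.

Every planted gene is flanked by a fixed 15-nt guard with stop codons in
all six frames and no ATG/CAT, so the ORF caller (maximal ATG→stop, both
strands, non-nested within a frame, standard code) recovers planted
coordinates exactly; its output may be a superset of the planted genes.

Deliberately not emulated: indels within families (alignment robustness is
exercised separately through mafft on indel-bearing inputs), sequencing
error and assembly artefacts, compositional bias (real intergenic DNA is
not uniform, so real chance-match rates differ from the 4⁻²⁴ null),
provirophages integrated in host genomes, and realistic codon usage.
Passing tests on these corpora show that the machinery implements its
rules exactly and recovers planted structure at realistic divergences;
they do not show robustness to assembly noise or to homology structure
absent from the generator.

Two corpus regimes are mutually exclusive by arithmetic, so different
checks use different corpora: making the four core families merge into
single corpus-wide VpPCs requires detectable between-lineage homology,
while making three lineages collapse-separable at the 1.2 subs/site
threshold requires between-lineage distances ≥ ~2.4, i.e. near-random
identity. The protein-clustering check therefore runs on a single-lineage
corpus (10 families at 0.6 within-family identity) and the clade check on
three deeply diverged lineages (0.9 within); the end-to-end corpus uses
independent lineage ancestors.

## Problem sizes and determinism

The reference end-to-end corpus is 50 virophages across 3 lineages plus
100 decoys and 5 giant viruses (~4 Mb of contigs, ~350 proteins); the full
pipeline runs in about two minutes on one CPU, and the acceptance script's
complete battery in under five. These sizes were chosen so the planted
effects (topology, families, lineages, links) are estimated essentially
without sampling noise while the whole battery stays desk-scale.

All randomness flows from explicit seeds: corpus generation from
`SimConfig.seed`, pipeline randomness (decoy shuffles, community
detection, bootstrap) from `PipelineConfig.seed`. mafft and the NJ
construction are deterministic. Two runs with identical configuration and
seed produce byte-identical stage outputs, which the manifest's SHA-256
checksums make checkable. Ties are broken lexicographically by id (model
clustering, de-replication representatives) or by genomic coordinate
(core-label assignment, with a warning on exact score ties).

## Known limitations

- Ungapped profile scoring will under-score genuinely indel-rich homologs;
  the interface accepts an HMMER-style backend for that regime.
- The Gumbel calibration extrapolates far into the tail at E ≪ 10⁻⁶;
  this is standard practice but tail E-values should be read as ranks,
  not probabilities.
- The anchor-and-chain DNA identity is an estimate outside the
  near-duplicate regime; it is used only where decisions concern
  near-duplicates.
- Neighbor joining with bootstrap supports is a desk-scale default, not a
  substitute for ML inference on real, large alignments.
- Giant-virus inputs are taken as given (FASTA + GFF3); mining an NCLDV
  database from raw metagenomes, NCLDV phylogenomics, tRNA detection, and
  provirophage detection are out of scope.
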