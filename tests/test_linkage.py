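"""MIMIVIRE shared-seed detection and link ranking."""

import numpy as np
import pytest
from Bio.Seq import Seq

from lavidascope.linkage import (
    GiantVirusContig,
    MimivireLink,
    link_all,
    repeated_subset,
    shared_seeds,
    shared_seeds_bruteforce,
    translated_motif_check,
)
from lavidascope.seqio import GeneAnnotation, SequenceRecord
from lavidascope.simulate import random_dna


def _rc(s: str) -> str:
    return str(Seq(s).reverse_complement())


class TestSharedSeeds:
    def test_planted_seed_found_at_positions(self, rng):
        a = random_dna(4_000, rng)
        b = random_dna(4_000, rng)
        seed = a[1000:1027]
        b = b[:2000] + seed + b[2000:]
        hits = shared_seeds(SequenceRecord("v", a), SequenceRecord("g", b))
        assert any(h.virophage_start == 1000 and h.giant_start == 2000
                   and h.seed.startswith(seed) for h in hits)

    def test_matches_bruteforce_enumeration(self, rng):
        a = random_dna(2_500, rng)
        b = random_dna(2_500, rng)
        for pos, length in [(300, 24), (900, 31), (1500, 27)]:
            b = b[:pos] + a[pos:pos + length] + b[pos + length:]
        fast = {(h.virophage_start, h.giant_start, len(h.seed))
                for h in shared_seeds(SequenceRecord("a", a), SequenceRecord("b", b))
                if h.giant_strand == "+"}
        brute = shared_seeds_bruteforce(a, b, 24)
        assert fast == brute

    def test_long_match_reported_once_maximal(self, rng):
        a = random_dna(2_000, rng)
        b = random_dna(2_000, rng)
        b = b[:500] + a[600:631] + b[500:]   # 31-nt shared block
        hits = shared_seeds(SequenceRecord("a", a), SequenceRecord("b", b))
        long_hits = [h for h in hits if len(h.seed) >= 31]
        assert len(long_hits) == 1

    def test_reverse_strand_matches_found(self, rng):
        a = random_dna(3_000, rng)
        b = random_dna(3_000, rng)
        seed = a[500:527]
        b = b[:1200] + _rc(seed) + b[1200:]
        hits = shared_seeds(SequenceRecord("a", a), SequenceRecord("b", b))
        minus = [h for h in hits if h.giant_strand == "-"]
        assert minus and minus[0].virophage_start == 500
        assert minus[0].giant_start == 1200

    def test_random_pairs_share_nothing(self, rng):
        for _ in range(20):
            a, b = random_dna(20_000, rng), random_dna(20_000, rng)
            assert shared_seeds(SequenceRecord("a", a), SequenceRecord("b", b)) == []


class TestRepeatedSubset:
    def test_planted_three_copies(self, rng):
        seed = random_dna(27, rng)
        unit = seed[3:21]
        gene = random_dna(300, rng) + seed + random_dna(200, rng) + unit \
            + random_dna(150, rng) + unit + random_dna(100, rng)
        result = repeated_subset(seed, gene)
        assert result is not None
        best_unit, copies = result
        assert copies == 3
        assert best_unit in seed

    def test_single_occurrence_insufficient(self, rng):
        seed = random_dna(27, rng)
        gene = random_dna(200, rng) + seed + random_dna(200, rng)
        # the whole seed occurs once, so every 18-mer occurs once: no repeat
        assert repeated_subset(seed, gene, min_copies=2) is None

    def test_overlapping_occurrences_counted_by_span(self):
        seed = "A" * 27
        gene = "GC" + "A" * 20 + "GC"
        # a length-u run of A inside 20 As has 20-u+1 distinct (overlapping)
        # spans; the search prefers the unit length maximizing the copy count
        unit, copies = repeated_subset(seed, gene, unit_len=18, min_copies=2)
        assert set(unit) == {"A"}
        assert copies == 20 - len(unit) + 1 == 5


class TestTranslatedMotifs:
    def test_dd_es_pattern_two_motifs(self):
        seed = "GATGACGAGAGTGATGACGAGAGTGAC"  # DDESDDESD
        vp = SequenceRecord("v", "CCC" + seed + "GGG")
        gv = SequenceRecord("g", "TTTTTT" + seed + "AAA")
        link = MimivireLink("v", "g", "g|g1", seed, 3, 6, "+", seed[:18], 3)
        translated_motif_check(link, vp, gv)
        assert link.frame_agreement
        assert link.motifs_virophage[0].count("DDES") == 2

    def test_frameshifted_placement_still_agrees(self, rng):
        seed = random_dna(27, rng)
        vp = SequenceRecord("v", "C" + seed + random_dna(10, rng))      # offset 1
        gv = SequenceRecord("g", "GG" + seed + random_dna(10, rng))     # offset 2
        link = MimivireLink("v", "g", "g|g1", seed, 1, 2, "+", seed[:18], 2)
        translated_motif_check(link, vp, gv)
        assert link.frame_agreement  # identical nt implies a matching frame pair

    def test_short_seed_skipped(self, rng):
        link = MimivireLink("v", "g", "g|g1", "ACGTACGTACGT", 0, 0, "+", "", 2)
        translated_motif_check(link, SequenceRecord("v", "ACGTACGTACGT" * 3),
                               SequenceRecord("g", "ACGTACGTACGT" * 3))
        assert link.frame_agreement is None


class TestLinkAll:
    def _planted_pair(self, rng, copies=3):
        vp_seq = random_dna(6_000, rng)
        seed = vp_seq[3000:3027]
        unit = seed[0:18]
        gene_nt = random_dna(600, rng) + seed + random_dna(300, rng)
        for _ in range(copies - 1):
            cut = int(rng.integers(30, len(gene_nt) - 30))
            cut -= cut % 3
            gene_nt = gene_nt[:cut] + unit + gene_nt[cut:]
        gv_seq = random_dna(1_000, rng) + gene_nt + random_dna(1_000, rng)
        gene = GeneAnnotation("gv", 1_000, 1_000 + len(gene_nt), "+", "gv|g1")
        vp = SequenceRecord("vp", vp_seq)
        gv = GiantVirusContig(SequenceRecord("gv", gv_seq), [gene])
        return vp, gv, seed, unit

    def test_planted_link_recovered(self, rng):
        vp, gv, seed, unit = self._planted_pair(rng)
        links = link_all([vp], [gv])
        assert len(links) == 1
        link = links[0]
        assert seed in link.seed and link.copy_count >= 3

    def test_empty_giant_set(self, rng):
        assert link_all([SequenceRecord("v", random_dna(5_000, rng))], []) == []

    def test_strand_symmetry(self, rng):
        vp, gv, _seed, _unit = self._planted_pair(rng)
        n = len(gv.record.residues)
        flipped_genes = [
            GeneAnnotation("gv", n - g.end, n - g.start,
                           "-" if g.strand == "+" else "+", g.gene_id)
            for g in gv.genes
        ]
        gv_rc = GiantVirusContig(gv.record.reverse_complement(), flipped_genes)
        fwd = link_all([vp], [gv])
        rev = link_all([vp], [gv_rc])
        assert len(fwd) == len(rev) == 1
        assert fwd[0].seed == rev[0].seed
        assert fwd[0].copy_count == rev[0].copy_count

    def test_co_occurrence_boosts_rank(self, rng):
        vp1, gv1, _, _ = self._planted_pair(rng)
        vp2, gv2, _, _ = self._planted_pair(rng)
        vp2 = SequenceRecord("vp2", vp2.residues)
        gv2 = GiantVirusContig(SequenceRecord("gv2", gv2.record.residues),
                               [GeneAnnotation("gv2", g.start, g.end, g.strand,
                                               "gv2|g1") for g in gv2.genes])
        samples = {"vp2": "lake1", "gv2": "lake1", "vp": "lake2", "gv": "ocean"}
        links = link_all([vp1, vp2], [gv1, gv2], co_occurrence=samples)
        flagged = [l for l in links if l.co_occurrence]
        assert [(l.virophage_id, l.gv_id) for l in flagged] == [("vp2", "gv2")]
        same_copies = [l for l in links if l.copy_count == flagged[0].copy_count
                       and l.seed_len == flagged[0].seed_len
                       and l.frame_agreement == flagged[0].frame_agreement]
        if len(same_copies) > 1:
            assert same_copies[0].co_occurrence

    def test_corpus_links_and_no_false_pairs(self, small_corpus):
        corpus, _ = small_corpus
        gt = corpus.ground_truth
        giants = []
        for gvid in sorted(corpus.giants):
            genes = [g for g in corpus.giant_annotations if g.contig_id == gvid]
            giants.append(GiantVirusContig(corpus.giants[gvid], genes))
        links = link_all(list(corpus.contigs.values()), giants)
        found = {(l.virophage_id, l.gv_id) for l in links}
        planted = {(l.virophage_id, l.gv_id) for l in gt.links}
        assert found == planted
        by_pair = {(l.virophage_id, l.gv_id): l for l in links}
        for pl in gt.links:
            link = by_pair[(pl.virophage_id, pl.gv_id)]
            assert pl.seed in link.seed
            assert link.copy_count == pl.copies
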