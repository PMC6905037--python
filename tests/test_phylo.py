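"""Alignment, trimming, tree/clade inference, synteny, habitat profiles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lavidascope.phylo import (
    AlignmentError,
    MultipleAlignment,
    align,
    build_tree,
    collapse_clades,
    concatenate,
    detect_blocks,
    habitat_profile,
    poisson_distances,
    quantile_normalize,
    synteny_signature,
    trim,
)
from lavidascope.qc import Topology, VirophageGenome
from lavidascope.seqio import GeneAnnotation, SequenceRecord
from lavidascope.simulate import (
    make_protein_family,
    mutate_protein,
    random_dna,
    random_protein,
)


class TestAlign:
    def test_identical_pair_gapless(self, rng):
        seq = random_protein(120, rng)
        aln = align([SequenceRecord("a", seq), SequenceRecord("b", seq)])
        assert aln.rows == [seq, seq]
        assert (aln.gap_fractions() == 0).all()

    def test_substitution_only_family_gapless(self, rng):
        members, _ = make_protein_family(random_protein(150, rng), 5, 0.7, rng, "f")
        aln = align(members)
        assert (aln.gap_fractions() == 0).all()

    def test_ungap_recovers_input(self, rng):
        # indel-bearing inputs force a real (mafft) alignment
        base = random_protein(120, rng)
        recs = [
            SequenceRecord("full", base),
            SequenceRecord("del", base[:50] + base[60:]),
            SequenceRecord("var", mutate_protein(base, 0.8, rng)),
        ]
        aln = align(recs)
        assert aln.n_columns >= 120
        for rec in recs:
            assert aln.ungapped(rec.id) == rec.residues

    def test_single_sequence_trivial(self, rng):
        rec = SequenceRecord("x", random_protein(50, rng))
        aln = align([rec])
        assert aln.ids == ["x"] and aln.rows == [rec.residues]


class TestTrim:
    def test_gapless_unchanged(self, rng):
        aln = MultipleAlignment(["a", "b"], ["MKVAL", "MKVAW"])
        assert trim(aln).rows == aln.rows

    def test_gappy_column_removed(self):
        # column 2 is 75% gaps (> 0.5 threshold used here); boundary exact
        aln = MultipleAlignment(list("abcd"), ["MK-A", "MK-A", "MKWA", "MK-A"])
        trimmed = trim(aln, max_gap_fraction=0.70)
        assert trimmed.rows == ["MKA", "MKA", "MKA", "MKA"]

    def test_exactly_at_threshold_kept(self):
        aln = MultipleAlignment(list("ab"), ["M-", "MW"])
        # gap fraction 0.5 <= 0.9: kept
        assert trim(aln, 0.9).n_columns == 2

    def test_idempotent(self):
        aln = MultipleAlignment(list("abcd"), ["MK-A", "MK-A", "MKWA", "MK-A"])
        once = trim(aln, 0.7)
        assert trim(once, 0.7).rows == once.rows

    def test_all_columns_removed_error(self):
        aln = MultipleAlignment(list("ab"), ["--", "-W"])
        with pytest.raises(AlignmentError, match="max_gap_fraction"):
            trim(aln, 0.4)


class TestConcatenate:
    def _blocks(self, rng, genomes=("g1", "g2", "g3")):
        blocks = {}
        for label, n in [("MCP", 100), ("mCP", 80), ("ATPase", 120), ("PRO", 60)]:
            rows = [random_protein(n, rng) for _ in genomes]
            blocks[label] = MultipleAlignment(list(genomes), rows)
        return blocks

    def test_row_length_and_partitions(self, rng):
        aln = concatenate(self._blocks(rng))
        assert aln.n_columns == 360
        assert [p[0] for p in aln.partitions] == ["MCP", "mCP", "ATPase", "PRO"]
        assert aln.partitions[-1][2] == 360

    def test_reordering_rows_irrelevant(self, rng):
        blocks = self._blocks(rng)
        shuffledb = {
            k: MultipleAlignment(list(reversed(v.ids)), list(reversed(v.rows)))
            for k, v in blocks.items()
        }
        a, b = concatenate(blocks), concatenate(shuffledb)
        assert a.ids == b.ids and a.rows == b.rows

    def test_missing_gene_excluded_with_warning(self, rng):
        blocks = self._blocks(rng)
        mcp = blocks["MCP"]
        blocks["MCP"] = MultipleAlignment(mcp.ids[:2], mcp.rows[:2])
        with pytest.warns(UserWarning, match="g3"):
            aln = concatenate(blocks)
        assert aln.ids == ["g1", "g2"]


class TestTree:
    def test_too_few_rows(self, rng):
        aln = MultipleAlignment(["a", "b", "c"], [random_protein(50, rng)] * 3)
        with pytest.raises(AlignmentError):
            build_tree(aln)

    def test_identical_rows_zero_branch_lengths(self, rng):
        seq = random_protein(80, rng)
        aln = MultipleAlignment(list("abcde"), [seq] * 5)
        ct = build_tree(aln, bootstrap=10)
        total = sum(n.length or 0 for n in ct.tree.traverse())
        assert total == pytest.approx(0.0)

    def test_poisson_distance_formula(self):
        rows = ["AAAA", "AAAC"]  # p = 0.25
        d = poisson_distances(rows)[0, 1]
        assert d == pytest.approx(-19 / 20 * np.log(1 - 20 / 19 * 0.25))

    def test_three_lineages_recovered_with_support(self, rng):
        blocks = {}
        for label, n in [("MCP", 400), ("mCP", 300), ("ATPase", 200), ("PRO", 150)]:
            per = {}
            for lin in range(3):
                anc = random_protein(n, rng)
                for m in range(5):
                    per[f"L{lin}_m{m}"] = mutate_protein(anc, 0.9, rng)
            blocks[label] = MultipleAlignment(sorted(per), [per[k] for k in sorted(per)])
        ct = build_tree(concatenate(blocks), bootstrap=100, seed=1)
        clades = collapse_clades(ct)
        assert len(clades) == 3
        assert all(c.support >= 0.9 for c in clades)
        truth = [m.split("_")[0] for c in clades for m in c.members]
        pred = [c.clade_id for c in clades for _ in c.members]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_newick_contains_supports(self, rng):
        seqs = {}
        for lin in range(2):
            anc = random_protein(200, rng)
            for m in range(3):
                seqs[f"L{lin}x{m}"] = mutate_protein(anc, 0.9, rng)
        aln = MultipleAlignment(sorted(seqs), [seqs[k] for k in sorted(seqs)])
        nwk = build_tree(aln, bootstrap=20, seed=0).newick()
        assert nwk.endswith(";") and "L0x0" in nwk


def _genome(order, strands, topo="linear", with_other=()):
    seq = random_dna(2_000, np.random.default_rng(1))
    g = VirophageGenome(SequenceRecord("gX", seq))
    pos = 100
    entries = list(zip(order, strands))
    for i, (label, strand) in enumerate(entries):
        g.annotations.append(
            GeneAnnotation("gX", pos, pos + 150, strand, f"gX|g{i}", label))
        pos += 200
    for j, label in enumerate(with_other):
        g.annotations.append(
            GeneAnnotation("gX", pos, pos + 150, "+", f"gX|x{j}", label))
        pos += 200
    g.topology = Topology(topo)
    return g


class TestSynteny:
    def test_five_gene_block_signature(self):
        g = _genome(("MTase", "PRO", "ATPase", "mCP", "MCP"), "+++++")
        sig = synteny_signature(g)
        assert sig.gene_order == "MTase–PRO–ATPase–mCP–MCP"
        assert sig.oriented and sig.mcp_mcp_adjacent

    def test_atpase_mcp_mcp_template(self):
        g = _genome(("ATPase", "mCP", "MCP"), "+++")
        sig = synteny_signature(g)
        assert sig.gene_order == "ATPase–mCP–MCP"
        report = detect_blocks([g])
        assert report.atpase_mcp_mcp_in_order == 1
        assert report.mcp_mcp_adjacent == 1

    def test_reverse_complement_same_signature(self):
        g = _genome(("ATPase", "mCP", "MCP", "PRO"), "+++-")
        sig_fwd = synteny_signature(g)
        # reverse-complement view: reversed order, flipped strands
        rc = _genome(("PRO", "MCP", "mCP", "ATPase"), "+---")
        sig_rc = synteny_signature(rc)
        assert sig_fwd.genes == sig_rc.genes

    def test_circular_rotation_puts_mcp_first(self):
        g = _genome(("PRO", "ATPase", "MCP", "mCP"), "++++", topo="circular")
        sig = synteny_signature(g)
        assert sig.genes[0][0] == "MCP"

    def test_missing_mcp_flagged_unoriented(self):
        g = _genome(("PRO", "ATPase", "mCP"), "+++")
        sig = synteny_signature(g)
        assert not sig.oriented

    def test_block_census(self):
        genomes = [
            _genome(("MTase", "PRO", "ATPase", "mCP", "MCP"), "+++++"),
            _genome(("MCP", "mCP", "PRO", "ATPase"), "++++"),
            _genome(("MCP", "mCP", "PRO"), "+++"),
        ]
        rep = detect_blocks(genomes)
        assert (rep.five_gene_block, rep.four_gene_block, rep.three_gene_no_atpase) \
            == (1, 1, 1)
        assert rep.mcp_mcp_adjacent == 3


class TestHabitatProfile:
    def test_quantile_norm_equalizes_column_multisets(self):
        df = pd.DataFrame({"h1": [5.0, 1.0, 0.0], "h2": [10.0, 100.0, 30.0]},
                          index=["m1", "m2", "m3"])
        norm = quantile_normalize(df)
        assert sorted(norm["h1"]) == pytest.approx(sorted(norm["h2"]))

    def test_identical_columns_join_first(self):
        df = pd.DataFrame(
            {"a": [10, 0, 5], "b": [10, 0, 5], "c": [0, 9, 1]},
            index=["m1", "m2", "m3"], dtype=float)
        norm, _rows, cols = habitat_profile(df)
        assert abs(cols.index("a") - cols.index("b")) == 1  # joined at distance 0
        assert (norm["a"] == norm["b"]).all()

    def test_zero_rows_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [2.0, 0.0]}, index=["m1", "m2"])
        with pytest.warns(UserWarning, match="m2"):
            norm, _r, _c = habitat_profile(df)
        assert list(norm.index) == ["m1"]
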