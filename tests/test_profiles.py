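"""Profile models: scoring, calibration, clustering, iteration, completeness."""

import numpy as np
import pytest

from lavidascope.align import batch_best_segment_scores, best_ungapped_segment, encode_protein
from lavidascope.profiles import (
    CalibrationError,
    build_profile,
    cluster_for_models,
    iterate_models,
    mcp_completeness,
    models_from_json,
    models_to_json,
    search,
    shuffled,
)
from lavidascope.seqio import SequenceRecord
from lavidascope.simulate import make_protein_family, mutate_protein, random_protein


@pytest.fixture(scope="module")
def family_model(request):
    rng = np.random.default_rng(42)
    ancestor = random_protein(250, rng)
    members = [SequenceRecord(f"m{i}", mutate_protein(ancestor, 0.85, rng))
               for i in range(5)]
    model = build_profile(members, "fam", np.random.default_rng(1))
    return ancestor, members, model


class TestBuildProfile:
    def test_identical_members_consensus(self):
        seq = random_protein(80, np.random.default_rng(3))
        members = [SequenceRecord(f"m{i}", seq) for i in range(3)]
        model = build_profile(members, "ident", np.random.default_rng(0))
        assert model.consensus_length == len(seq)
        assert model.consensus == seq

    def test_expected_background_score_negative(self, family_model):
        _, _, model = family_model
        probs = 2.0 ** model.column_scores / 20.0
        expected = (model.background * model.column_scores).sum(axis=1)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (expected < 0).all()

    def test_gappy_columns_excluded(self):
        rows = [SequenceRecord("a", "MKV-AL"), SequenceRecord("b", "MKV-AL"),
                SequenceRecord("c", "MKVWAL"), SequenceRecord("d", "MKV-AL")]
        model = build_profile(rows, "gap", n_calibration_decoys=0)
        assert model.consensus_length == 5  # the 75%-gap column is dropped

    def test_all_gap_alignment_rejected(self):
        rows = [SequenceRecord("a", "---"), SequenceRecord("b", "---")]
        with pytest.raises(ValueError, match="gap"):
            build_profile(rows, "bad", n_calibration_decoys=0)

    def test_ancestor_beats_every_shuffle(self, family_model):
        ancestor, _, model = family_model
        rng = np.random.default_rng(7)
        anc_score, _, _ = model.segment_score(ancestor)
        shuffle_scores = [model.segment_score(shuffled(ancestor, rng))[0]
                          for _ in range(100)]
        assert all(anc_score > s for s in shuffle_scores)

    def test_calibration_expected_false_positives(self, family_model):
        """By the E-value definition, ~1 of N decoys reaches E <= 1."""
        _, members, model = family_model
        rng = np.random.default_rng(9)
        n = 10_000
        decoys = [encode_protein(shuffled(members[i % len(members)].residues, rng))
                  for i in range(n)]
        scores = batch_best_segment_scores(model.column_scores, decoys)
        evalues = n * np.exp(-model.lam * (scores - model.mu))
        hits = int((evalues <= 1.0).sum())
        assert hits <= 6  # Poisson(1): P(>6) ~ 1e-4


class TestSearch:
    def test_ancestor_hit_dominates(self, family_model):
        ancestor, members, model = family_model
        db = [SequenceRecord("anc", ancestor)] + [
            SequenceRecord(f"d{i}", random_protein(250, np.random.default_rng(100 + i)))
            for i in range(50)
        ]
        hits = search(model, db)
        assert hits and hits[0].protein_id == "anc"
        assert hits[0].e_value < 1e-6

    def test_decoys_yield_no_hits(self, family_model):
        _, _, model = family_model
        rng = np.random.default_rng(11)
        db = [SequenceRecord(f"d{i}", random_protein(250, rng)) for i in range(1000)]
        assert search(model, db) == []

    def test_empty_protein_set(self, family_model):
        assert search(family_model[2], []) == []

    def test_uncalibrated_model_rejected(self):
        rows = [SequenceRecord("a", "MKVAL" * 10), SequenceRecord("b", "MKVAL" * 10)]
        model = build_profile(rows, "raw", n_calibration_decoys=0)
        with pytest.raises(CalibrationError):
            search(model, rows)

    def test_batch_scores_match_exact_scan(self, family_model):
        _, members, model = family_model
        idx = [encode_protein(m.residues) for m in members]
        batch = batch_best_segment_scores(model.column_scores, idx)
        exact = [best_ungapped_segment(model.column_scores, i)[0] for i in idx]
        assert np.allclose(batch, exact, atol=0.01)

    def test_pyhmmer_cross_check(self, family_model):
        """An independent HMM backend agrees on which sequences are homologs."""
        pyhmmer = pytest.importorskip("pyhmmer")
        ancestor, members, model = family_model
        rng = np.random.default_rng(13)
        alphabet = pyhmmer.easel.Alphabet.amino()
        seqs = [pyhmmer.easel.TextSequence(name=m.id.encode(), sequence=m.residues)
                for m in members]
        msa = pyhmmer.easel.TextMSA(name=b"fam", sequences=seqs).digitize(alphabet)
        hmm, _, _ = pyhmmer.plan7.Builder(alphabet).build_msa(
            msa, pyhmmer.plan7.Background(alphabet))
        db = [SequenceRecord("anc", ancestor)] + [
            SequenceRecord(f"d{i}", random_protein(250, rng)) for i in range(200)
        ]
        targets = pyhmmer.easel.TextSequenceBlock(
            [pyhmmer.easel.TextSequence(name=r.id.encode(), sequence=r.residues)
             for r in db]).digitize(alphabet)
        hmmer_hits = {
            h.name.decode() if isinstance(h.name, bytes) else h.name
            for h in next(pyhmmer.hmmsearch([hmm], targets, E=1e-6))
            if h.reported
        }
        ours = {h.protein_id for h in search(model, db)}
        assert ours == hmmer_hits == {"anc"}


class TestClusterForModels:
    def test_identical_pair_one_family(self):
        seq = random_protein(120, np.random.default_rng(5))
        fams = cluster_for_models([SequenceRecord("a", seq), SequenceRecord("b", seq)])
        assert len(fams) == 1 and len(fams[0]) == 2

    def test_three_planted_families_recovered(self, rng):
        prots, truth = [], {}
        for f in range(3):
            members, _ = make_protein_family(
                random_protein(200, rng), 5, 0.6, rng, f"f{f}", member_prefix=f"f{f}_")
            prots.extend(members)
            truth.update({m.id: f for m in members})
        fams = cluster_for_models(prots)
        assert len(fams) == 3
        for fam in fams:
            assert len({truth[m.id] for m in fam}) == 1

    def test_bidirectional_alignment_fraction(self, rng):
        """High identity over only 69% of one sequence yields no edge."""
        a = random_protein(200, rng)
        short_cov = SequenceRecord("b", mutate_protein(a[:138], 0.9, rng))  # 69% of a
        ok_cov = SequenceRecord("c", mutate_protein(a[:144], 0.9, rng))     # 72% of a
        fams_no = cluster_for_models([SequenceRecord("a", a), short_cov])
        assert fams_no == []  # singletons dropped
        fams_yes = cluster_for_models([SequenceRecord("a", a), ok_cov])
        assert len(fams_yes) == 1


class TestIterateModels:
    def test_single_round_equals_direct_build(self, rng):
        anc = random_protein(240, rng)
        seeds = [SequenceRecord(f"s{i}", mutate_protein(anc, 0.85, rng)) for i in range(4)]
        db = [SequenceRecord(f"d{i}", random_protein(240, rng)) for i in range(20)]
        models = iterate_models([seeds], db, rounds=1, rng=np.random.default_rng(1))
        direct = build_profile(seeds, "direct", np.random.default_rng(1))
        assert len(models) == 1
        assert np.allclose(models[0].column_scores, direct.column_scores)

    def test_rounds_must_be_positive(self):
        with pytest.raises(ValueError):
            iterate_models([], [], rounds=0)

    def test_empty_recruitment_stops_early(self, rng):
        anc = random_protein(240, rng)
        seeds = [SequenceRecord(f"s{i}", mutate_protein(anc, 0.9, rng)) for i in range(3)]
        db = [SequenceRecord(f"d{i}", random_protein(240, rng)) for i in range(30)]
        with pytest.warns(UserWarning, match="recruited no new"):
            models = iterate_models([seeds], db, rounds=3, rng=np.random.default_rng(2))
        assert len(models) == 1

    def test_disjoint_seed_families_stay_specific(self, rng):
        fams = []
        for f in range(2):
            anc = random_protein(260, rng)
            fams.append(([SequenceRecord(f"s{f}_{i}", mutate_protein(anc, 0.85, rng))
                          for i in range(4)], anc))
        db = [SequenceRecord(f"t{f}", mutate_protein(anc, 0.7, rng))
              for f, (_seeds, anc) in enumerate(fams)]
        db += [SequenceRecord(f"d{i}", random_protein(260, rng)) for i in range(40)]
        models = iterate_models([s for s, _ in fams], db, rounds=2,
                                rng=np.random.default_rng(3))
        assert len(models) >= 2
        hit_sets = [{h.protein_id for h in search(m, db)} for m in models]
        union = set().union(*hit_sets)
        assert union == {"t0", "t1"}
        for hits in hit_sets:
            assert len({h[1] for h in hits}) <= 1  # each model hits one family


class TestMcpCompleteness:
    @pytest.mark.parametrize(
        "length, expected",
        [(593, "complete"), (553, "complete"), (552, "ge_half"),
         (297, "ge_half"), (296, "partial"), (200, "partial")],
    )
    def test_bands(self, length, expected):
        assert mcp_completeness(length) == expected

    def test_positive_length_required(self):
        with pytest.raises(ValueError):
            mcp_completeness(0)


def test_model_json_round_trip(tmp_path, family_model):
    _, _, model = family_model
    path = tmp_path / "models.json"
    models_to_json([model], path)
    back = models_from_json(path)[0]
    assert back.model_id == model.model_id
    assert back.member_ids == model.member_ids
    assert back.mu == pytest.approx(model.mu)
    assert np.allclose(back.column_scores, model.column_scores, atol=1e-5)
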