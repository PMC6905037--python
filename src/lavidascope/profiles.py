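"""Position-specific scoring models for the virophage major capsid protein.

The MCP is the marker ("bait") gene of the discovery pipeline: models are
built from seed alignments, calibrated on shuffled decoys so that raw segment
scores convert to E-values, and refined iteratively by recruiting database
hits back into the training set.

A model is a per-column log-odds matrix (bits against a uniform background)
over the 20 amino acids, with a Gumbel (EVD) fit to decoy maximal-segment
scores providing the E-value calibration: ``E(S) = N * exp(-lambda*(S - mu))``
for a database of ``N`` sequences. This is the same contract as an
hmmsearch-style screen (E < 1e-06 by default) and an HMMER backend can be
substituted behind the same interface.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .align import (
    AA20,
    AA_INDEX,
    batch_best_segment_scores,
    best_ungapped_segment,
    encode_protein,
    protein_identity,
)
from .seqio import SequenceRecord

GAP = "-"
DEFAULT_E_CUT = 1e-6

#: completeness constants: mean and standard deviation (aa) of published MCPs
MCP_MEAN_AA = 593.0
MCP_SD_AA = 40.1


class CalibrationError(RuntimeError):
    """Raised when an uncalibrated model is asked for E-values."""


@dataclass
class ProfileHit:
    model_id: str
    protein_id: str
    score: float
    e_value: float
    start: int  # aligned span on the protein, half-open
    end: int


@dataclass
class ProfileModel:
    """Calibrated position-specific scoring model over amino acids."""

    model_id: str
    column_scores: np.ndarray          # (consensus_length, 20) bits
    background: np.ndarray             # length-20 frequencies
    member_ids: list[str]
    mu: float | None = None            # Gumbel location of decoy scores
    lam: float | None = None           # Gumbel rate (1 / scale)
    seed_provenance: list[str] = field(default_factory=list)

    @property
    def consensus_length(self) -> int:
        return int(self.column_scores.shape[0])

    @property
    def member_count(self) -> int:
        return len(self.member_ids)

    @property
    def calibrated(self) -> bool:
        return self.mu is not None and self.lam is not None

    @property
    def consensus(self) -> str:
        return "".join(AA20[i] for i in np.argmax(self.column_scores, axis=1))

    def segment_score(self, protein: str) -> tuple[float, int, int]:
        """Best ungapped local segment score and its protein span."""
        score, _ms, _me, s0, s1 = best_ungapped_segment(
            self.column_scores, encode_protein(protein)
        )
        return score, s0, s1

    def e_value(self, score: float, db_size: int) -> float:
        if not self.calibrated:
            raise CalibrationError(f"model {self.model_id} has no Gumbel calibration")
        return float(db_size) * math.exp(-self.lam * (score - self.mu))


def shuffled(seq: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode()


def build_profile(
    alignment: list[SequenceRecord],
    model_id: str = "model_1",
    rng: np.random.Generator | None = None,
    n_calibration_decoys: int = 1000,
    max_gap_fraction: float = 0.5,
    pseudocount: float = 1.0,
) -> ProfileModel:
    """Build and calibrate a profile from an aligned protein family.

    Columns with more than ``max_gap_fraction`` gaps are excluded from the
    consensus. Scores are log2 of the pseudocounted column frequency over a
    uniform background (one pseudocount per residue), which makes the expected
    per-column score under the background strictly negative. Calibration fits
    a Gumbel distribution to maximal ungapped segment scores of
    ``n_calibration_decoys`` residue-shuffled member sequences.
    """
    if len(alignment) < 2 and n_calibration_decoys > 0:
        raise ValueError("profile requires an alignment of at least 2 members")
    rng = rng or np.random.default_rng(0)
    ncol = len(alignment[0].residues)
    if any(len(r.residues) != ncol for r in alignment):
        raise ValueError("alignment rows differ in length")
    rows = np.array([[c for c in r.residues.upper()] for r in alignment])
    gap_frac = (rows == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise ValueError("alignment is all gaps after column filtering")
    rows = rows[:, keep]
    n_keep = rows.shape[1]
    background = np.full(20, 1.0 / 20)
    # +pseudocount per residue per column
    counts = np.full((n_keep, 20), float(pseudocount))
    for r in range(rows.shape[0]):
        idx = np.array([AA_INDEX.get(c, -1) for c in rows[r]])
        valid = idx >= 0
        counts[np.nonzero(valid)[0], idx[valid]] += 1.0
    probs = counts / counts.sum(axis=1, keepdims=True)
    column_scores = np.log2(probs / background)

    model = ProfileModel(
        model_id=model_id,
        column_scores=column_scores,
        background=background,
        member_ids=sorted(r.id for r in alignment),
    )
    if n_calibration_decoys == 0:
        # uncalibrated profile: usable for profile-profile scoring only
        return model
    # calibration on shuffled decoys, scored in one vectorized batch
    members_ungapped = [r.residues.replace(GAP, "") for r in alignment]
    decoys = [
        encode_protein(shuffled(members_ungapped[d % len(members_ungapped)], rng))
        for d in range(n_calibration_decoys)
    ]
    scores = batch_best_segment_scores(model.column_scores, decoys)
    mu, beta = stats.gumbel_r.fit(scores)
    model.mu = float(mu)
    model.lam = float(1.0 / beta)
    return model


def search(
    model: ProfileModel,
    proteins: list[SequenceRecord],
    e_cut: float = DEFAULT_E_CUT,
    db_size: int | None = None,
) -> list[ProfileHit]:
    """Profile search over a protein set; hits with E < ``e_cut`` sorted by E."""
    if not model.calibrated:
        raise CalibrationError(f"model {model.model_id} is not calibrated")
    n = db_size if db_size is not None else len(proteins)
    recs = sorted(proteins, key=lambda r: r.id)
    scores = batch_best_segment_scores(
        model.column_scores, [encode_protein(r.residues) for r in recs]
    )
    hits = []
    for rec, score in zip(recs, scores):
        e = model.e_value(float(score), n)
        if e < e_cut:
            # exact span (and score) recomputed only for passing sequences
            s, s0, s1 = model.segment_score(rec.residues)
            hits.append(ProfileHit(model.model_id, rec.id, s, e, s0, s1))
    hits.sort(key=lambda h: (h.e_value, h.protein_id))
    return hits


# ---------------------------------------------------------------------------
# Family clustering for model building (30% identity over 70% of both)


def cluster_for_models(
    proteins: list[SequenceRecord],
    identity_cut: float = 0.30,
    align_frac: float = 0.70,
) -> list[list[SequenceRecord]]:
    """Single-linkage families under the bidirectional 30/70 rule.

    An edge joins two proteins iff local-alignment identity >= ``identity_cut``
    and the aligned span covers >= ``align_frac`` of *both* sequences.
    Singletons are dropped. Deterministic: members and families are ordered
    by lexicographic id.
    """
    if len(proteins) < 2:
        raise ValueError("clustering requires at least 2 proteins")
    recs = sorted(proteins, key=lambda r: r.id)
    parent = list(range(len(recs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            st = protein_identity(recs[i].residues, recs[j].residues)
            if (
                st.identity >= identity_cut
                and st.coverage_a >= align_frac
                and st.coverage_b >= align_frac
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[SequenceRecord]] = {}
    for i, rec in enumerate(recs):
        groups.setdefault(find(i), []).append(rec)
    families = [g for g in groups.values() if len(g) > 1]
    families.sort(key=lambda g: g[0].id)
    return families


# ---------------------------------------------------------------------------
# Iterative model refinement


def iterate_models(
    seed_alignments: list[list[SequenceRecord]],
    database_proteins: list[SequenceRecord],
    rounds: int = 2,
    min_len_nt: int = 700,
    e_cut: float = DEFAULT_E_CUT,
    rng: np.random.Generator | None = None,
    n_calibration_decoys: int = 1000,
) -> list[ProfileModel]:
    """Iterative build-search-recruit refinement of marker models.

    Each round: search the database with the current models, recruit hits
    whose gene length (3*aa + 3 nt) is at least ``min_len_nt``, pool them with
    the current members, re-cluster under the 30/70 rule and rebuild one model
    per family. A round that recruits nothing ends the iteration early.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = rng or np.random.default_rng(0)
    db_by_id = {r.id: r for r in database_proteins}
    pool: dict[str, SequenceRecord] = {}
    provenance: dict[str, list[str]] = {}
    for aln in seed_alignments:
        for rec in aln:
            pool[rec.id] = SequenceRecord(rec.id, rec.residues.replace(GAP, ""))
            provenance[rec.id] = [rec.id]

    models: list[ProfileModel] = []
    current_alignments = [list(a) for a in seed_alignments]
    for rnd in range(1, rounds + 1):
        models = []
        for k, aln in enumerate(current_alignments):
            m = build_profile(
                aln, model_id=f"round{rnd}_m{k + 1:02d}", rng=rng,
                n_calibration_decoys=n_calibration_decoys,
            )
            m.seed_provenance = sorted(
                {s for rec in aln for s in provenance.get(rec.id, [rec.id])}
            )
            models.append(m)
        if rnd == rounds:
            break
        recruits: dict[str, SequenceRecord] = {}
        for m in models:
            for hit in search(m, database_proteins, e_cut=e_cut):
                rec = db_by_id[hit.protein_id]
                if 3 * len(rec.residues) + 3 >= min_len_nt and rec.id not in pool:
                    recruits[rec.id] = rec
                    provenance.setdefault(rec.id, []).extend(m.seed_provenance)
        if not recruits:
            warnings.warn(f"round {rnd} recruited no new sequences; stopping early")
            break
        pool.update(recruits)
        families = cluster_for_models(list(pool.values()))
        from .align import align_proteins
        current_alignments = [align_proteins(f) for f in families]
    return models


# ---------------------------------------------------------------------------
# Completeness rule for MCP genes


def mcp_completeness(length_aa: int, mean: float = MCP_MEAN_AA, sd: float = MCP_SD_AA) -> str:
    """Classify an MCP gene by length against published MCP statistics.

    ``complete`` at >= mean - sd (one-sided: longer than average is still
    complete), ``ge_half`` at >= half the mean, else ``partial``.
    """
    if length_aa <= 0:
        raise ValueError("length must be positive")
    if length_aa >= mean - sd:
        return "complete"
    if length_aa >= 0.5 * mean:
        return "ge_half"
    return "partial"


# ---------------------------------------------------------------------------
# Serialization (versioned JSON)


def models_to_json(models: list[ProfileModel], path: str | Path) -> None:
    payload = {
        "format": "lavidascope-profiles",
        "version": 1,
        "models": [
            {
                "model_id": m.model_id,
                "column_scores": np.round(m.column_scores, 6).tolist(),
                "background": m.background.tolist(),
                "member_ids": m.member_ids,
                "mu": m.mu,
                "lambda": m.lam,
                "seed_provenance": m.seed_provenance,
            }
            for m in models
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def models_from_json(path: str | Path) -> list[ProfileModel]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "lavidascope-profiles":
        raise ValueError(f"{path} is not a profile JSON file")
    out = []
    for m in payload["models"]:
        out.append(
            ProfileModel(
                model_id=m["model_id"],
                column_scores=np.asarray(m["column_scores"], dtype=float),
                background=np.asarray(m["background"], dtype=float),
                member_ids=list(m["member_ids"]),
                mu=m["mu"],
                lam=m["lambda"],
                seed_provenance=list(m.get("seed_provenance", [])),
            )
        )
    return out
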