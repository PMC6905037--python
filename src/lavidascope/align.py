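"""Pairwise and multiple alignment utilities shared across the pipeline.

Protein-protein comparisons use Smith-Waterman via ``Bio.Align.PairwiseAligner``
(BLOSUM62, affine gaps 11/1, the BLAST defaults the field expects). DNA
identity uses the same machinery up to a cell budget, above which a k-mer
anchor-and-chain estimate takes over (contigs are tens of kb; only
near-duplicates matter there). Multiple alignment shells out to ``mafft``;
families generated without indels align trivially and are handled in-process.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, read_fasta, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}

# cap on DP cells for exact local alignment of DNA pairs
_MAX_DP_CELLS = 30_000_000


def protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


def dna_aligner(mode: str = "local") -> Align.PairwiseAligner:
    # megablast-like scoring
    aligner = Align.PairwiseAligner()
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    aligner.mode = mode
    return aligner


_PROT_LOCAL = protein_aligner()
_DNA_LOCAL = dna_aligner()


def protein_score(a: str, b: str) -> float:
    """Smith-Waterman score (BLOSUM62, 11/1) between two proteins."""
    return float(_PROT_LOCAL.score(_sanitize(a), _sanitize(b)))


def _sanitize(seq: str) -> str:
    """Map residues outside the 20-letter alphabet to A for scoring."""
    return "".join(c if c in AA_INDEX else "A" for c in seq.upper().replace("*", ""))


@dataclass(frozen=True)
class PairwiseStats:
    identity: float        # matches / aligned columns
    coverage_a: float      # aligned span on sequence a / len(a)
    coverage_b: float      # aligned span on sequence b / len(b)
    score: float

    @property
    def coverage_short(self) -> float:
        return max(self.coverage_a, self.coverage_b)


def _stats_from_alignment(aln, len_a: int, len_b: int, score: float) -> PairwiseStats:
    blocks_a, blocks_b = aln.aligned
    matches = 0
    aligned_cols = 0
    seq_a, seq_b = aln.sequences
    span_a = 0
    span_b = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        seg_a = seq_a[a0:a1]
        seg_b = seq_b[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        aligned_cols += a1 - a0
        span_a += a1 - a0
        span_b += b1 - b0
        if prev_a_end is not None:
            # internal gap columns
            aligned_cols += max(a0 - prev_a_end, b0 - prev_b_end)
        prev_a_end, prev_b_end = a1, b1
    if aligned_cols == 0:
        return PairwiseStats(0.0, 0.0, 0.0, score)
    return PairwiseStats(matches / aligned_cols, span_a / len_a, span_b / len_b, score)


def protein_identity(a: str, b: str) -> PairwiseStats:
    """Local-alignment identity and shorter-sequence coverage for proteins."""
    sa, sb = _sanitize(a), _sanitize(b)
    alns = _PROT_LOCAL.align(sa, sb)
    if len(alns) == 0:
        return PairwiseStats(0.0, 0.0, 0.0, 0.0)
    aln = alns[0]
    return _stats_from_alignment(aln, len(a), len(b), float(aln.score))


def dna_identity(a: str, b: str) -> PairwiseStats:
    """Local-alignment identity/coverage for DNA; anchor-chained for long pairs."""
    if len(a) * len(b) <= _MAX_DP_CELLS:
        alns = _DNA_LOCAL.align(a, b)
        if len(alns) == 0:
            return PairwiseStats(0.0, 0.0, 0.0, 0.0)
        aln = alns[0]
        return _stats_from_alignment(aln, len(a), len(b), float(aln.score))
    return _chained_identity(a, b)


def _chained_identity(a: str, b: str, k: int = 31) -> PairwiseStats:
    """Identity/coverage estimate for long near-duplicate DNA pairs.

    Exact k-mer anchors are chained colinearly per diagonal band; bases between
    consecutive anchors on the same band count as aligned (mismatching)
    columns. Unrelated pairs share no anchors and score zero.
    """
    if len(a) > len(b):
        a, b = b, a
    pos: dict[str, int] = {}
    for i in range(len(a) - k + 1):
        pos.setdefault(a[i:i + k], i)
    anchors: list[tuple[int, int]] = []
    for j in range(len(b) - k + 1):
        i = pos.get(b[j:j + k])
        if i is not None:
            anchors.append((i, j))
    if not anchors:
        return PairwiseStats(0.0, 0.0, 0.0, 0.0)
    anchors.sort()
    # greedy colinear chain with exact bookkeeping of matched vs aligned bases
    matched = aligned = 0
    first_i: int | None = None
    first_j = 0
    end_i = end_j = -1
    prev_d: int | None = None
    for i, j in anchors:
        d = j - i
        if first_i is None:
            matched += k
            aligned += k
            first_i, first_j = i, j
        elif d == prev_d and i < end_i:
            ext = i + k - end_i
            if ext > 0:
                matched += ext
                aligned += ext
        elif i >= end_i and j >= end_j:
            gap = max(i - end_i, j - end_j)
            matched += k
            aligned += k + gap
        else:
            continue
        end_i, end_j, prev_d = max(end_i, i + k), max(end_j, j + k), d
    identity = min(1.0, matched / max(aligned, 1))
    cov_a = (end_i - (first_i or 0)) / len(a)
    cov_b = (end_j - first_j) / len(b)
    return PairwiseStats(identity, cov_a, cov_b, float(matched))


# ---------------------------------------------------------------------------
# Multiple alignment


def mafft_available() -> bool:
    return shutil.which("mafft") is not None


def align_proteins(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Multiple-align protein records, preserving input order.

    Equal-length inputs that already form a gap-free alignment are returned
    as-is (the synthetic generator emits substitution-only families); anything
    else goes through mafft with default parameters.
    """
    if len(records) == 1:
        return list(records)
    lengths = {len(r.residues) for r in records}
    if len(lengths) == 1:
        return list(records)
    if not mafft_available():
        raise RuntimeError("mafft not found on PATH and inputs need gapped alignment")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.faa"
        write_fasta(records, inp)
        proc = subprocess.run(
            ["mafft", "--quiet", "--anysymbol", str(inp)],
            capture_output=True, text=True, check=True,
        )
        import io as _io
        aligned = {r.id: r for r in read_fasta(_io.StringIO(proc.stdout))}
    return [aligned[r.id] for r in records]


# ---------------------------------------------------------------------------
# Ungapped position-specific scanning (shared by profile search)


def best_ungapped_segment(col_scores: np.ndarray, seq_idx: np.ndarray
                          ) -> tuple[float, int, int, int, int]:
    """Best-scoring ungapped local segment of a sequence against a PSSM.

    Parameters
    ----------
    col_scores : (L_model, 20) float array of per-column residue scores.
    seq_idx : integer indices of the sequence residues into the 20-letter
        alphabet (out-of-alphabet residues should be pre-mapped).

    Returns ``(score, model_start, model_end, seq_start, seq_end)`` with
    half-open coordinates. Kadane's rule is run down the sheared diagonals in
    one vectorized pass.
    """
    lm = col_scores.shape[0]
    ls = seq_idx.shape[0]
    if ls == 0:
        return 0.0, 0, 0, 0, 0
    m = col_scores[:, seq_idx]          # (lm, ls)
    pad = -1e9
    ncol = lm + ls - 1
    sheared = np.full((lm, ncol), pad)
    ii = np.arange(lm)[:, None]
    jj = np.arange(ls)[None, :]
    sheared[ii, jj - ii + (lm - 1)] = m  # column c = j - i + lm - 1 (constant per diagonal)
    # pads accumulate -1e9 per row, so no optimal segment can cross them
    csum = np.cumsum(sheared, axis=0)
    prev = np.vstack([np.zeros(ncol), csum[:-1]])
    runmin = np.minimum.accumulate(prev, axis=0)
    gain = csum - runmin
    flat = int(np.argmax(gain))
    i_end, col = divmod(flat, ncol)
    best = float(gain[i_end, col])
    if best <= 0:
        return 0.0, 0, 0, 0, 0
    k = int(np.argmin(prev[:i_end + 1, col]))
    diag = col - (lm - 1)
    m_start, m_end = k, i_end + 1
    s_start, s_end = k + diag, i_end + 1 + diag
    return best, m_start, m_end, s_start, s_end


def encode_protein(seq: str) -> np.ndarray:
    """Residues -> indices into the 20-letter alphabet (others -> 0)."""
    return np.array([AA_INDEX.get(c, 0) for c in seq.upper().replace("*", "")],
                    dtype=np.int64)


def batch_best_segment_scores(col_scores: np.ndarray,
                              seqs_idx: list[np.ndarray]) -> np.ndarray:
    """Maximal ungapped local segment scores of many sequences at once.

    Same objective as :func:`best_ungapped_segment` but score-only, using the
    classic clamped recurrence ``H[i, j] = max(0, H[i-1, j-1] + M[i, j])``
    vectorized over the whole batch; the Python loop runs over model columns
    only. Short sequences are padded with a sentinel residue whose score
    resets the recurrence.
    """
    b = len(seqs_idx)
    if b == 0:
        return np.zeros(0)
    lm = col_scores.shape[0]
    ls = max(len(s) for s in seqs_idx)
    if ls == 0:
        return np.zeros(b)
    cs = np.hstack([col_scores.astype(np.float32),
                    np.full((lm, 1), -1e9, dtype=np.float32)])
    mat = np.full((b, ls), 20, dtype=np.int64)
    for r, s in enumerate(seqs_idx):
        mat[r, :len(s)] = s
    h = np.zeros((b, ls + 1), dtype=np.float32)
    best = np.zeros(b, dtype=np.float32)
    for i in range(lm):
        row = cs[i][mat]
        nxt = np.zeros_like(h)
        np.maximum(h[:, :-1] + row, 0.0, out=nxt[:, 1:])
        np.maximum(best, nxt.max(axis=1), out=best)
        h = nxt
    return best.astype(float)


# ---------------------------------------------------------------------------
# Exact-match anchoring (shared by ITR detection and MIMIVIRE seed search)


def maximal_exact_matches(a: str, b: str, min_len: int
                          ) -> list[tuple[int, int, int]]:
    """All maximal exact common substrings of length >= min_len.

    Returns ``(start_a, start_b, length)`` triples; matches contained in a
    longer reported match on the same diagonal are suppressed. Anchoring uses
    k = min_len, so every qualifying match contains at least one anchor.
    """
    k = min_len
    if len(a) < k or len(b) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i:i + k], []).append(i)
    seen: dict[int, list[tuple[int, int]]] = {}  # diagonal -> [(start_b, end_b)]
    out: list[tuple[int, int, int]] = []
    for j in range(len(b) - k + 1):
        starts = index.get(b[j:j + k])
        if not starts:
            continue
        for i in starts:
            d = j - i
            covered = False
            for s, e in seen.get(d, ()):
                if s <= j and j + k <= e:
                    covered = True
                    break
            if covered:
                continue
            # extend
            si, sj = i, j
            while si > 0 and sj > 0 and a[si - 1] == b[sj - 1]:
                si -= 1
                sj -= 1
            ei, ej = i + k, j + k
            while ei < len(a) and ej < len(b) and a[ei] == b[ej]:
                ei += 1
                ej += 1
            seen.setdefault(d, []).append((sj, ej))
            out.append((si, sj, ei - si))
    out.sort(key=lambda t: (t[0], t[1], -t[2]))
    # dedupe identical spans
    uniq = []
    for t in out:
        if not uniq or uniq[-1] != t:
            uniq.append(t)
    return uniq
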