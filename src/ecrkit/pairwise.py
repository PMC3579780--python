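"""Pairwise global/local alignment and the sequential chunked homology search.

Global alignment is Needleman-Wunsch with affine gaps (Gotoh); local
alignment is Smith-Waterman with affine gaps.  Both use full O(n*m) dynamic
programming with no heuristic seeding: inputs here are promoter-scale
(<= ~10 kb) so exactness is affordable.  The chunked search divides a query
into sequential fixed-length sections (500 nt by default) and locally aligns
each section against a full-length target on both strands, which tolerates
genomic insertions or deletions between species: sections downstream of an
indel simply map at an offset.

Significance is assessed by identity, score, and alignment-length thresholds
rather than E-values; sub-threshold sections are still reported (flagged
not significant) so that a complete per-section identity table can be
emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from . import _kernels
from .seqcoords import GenomicInterval, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch and affine gap parameters.

    Defaults mirror classic BLASTN-style scoring: +2 match, -3 mismatch,
    gap of length L costing gap_open + (L - 1) * gap_extend.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")

    def substitution_matrix(self) -> np.ndarray:
        """5x5 score lookup over A,C,G,T,N; N never matches anything."""
        s = np.full((5, 5), self.mismatch, dtype=np.float32)
        for i in range(4):
            s[i, i] = self.match
        return s


DEFAULT_SCHEME = ScoringScheme()


_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _v in _CODE.items():
    _CODE_LUT[ord(_c)] = _v


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T/N string to integer codes 0..4."""
    codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"invalid nucleotide {bad!r}")
    return codes


@dataclass
class PairwiseAlignment:
    """Two gapped rows plus column <-> sequence coordinate maps.

    ``a_span``/``b_span`` give the 1-based closed coordinates of the aligned
    slices on the *input* sequences (b in its own forward coordinates even
    when ``strand_b`` is '-', in which case ``row_b`` holds the
    reverse-complemented slice).
    """

    row_a: str
    row_b: str
    a_span: GenomicInterval
    b_span: GenomicInterval
    strand_b: str = "+"
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")
        if any(a == "-" and b == "-" for a, b in zip(self.row_a, self.row_b)):
            raise ValueError("alignment contains an all-gap column")

    def __len__(self) -> int:
        return len(self.row_a)

    @cached_property
    def col_to_a(self) -> np.ndarray:
        """Per column: 1-based position on sequence a, or 0 at gap columns."""
        out = np.zeros(len(self.row_a), dtype=np.int64)
        pos = self.a_span.start - 1
        for i, c in enumerate(self.row_a):
            if c != "-":
                pos += 1
                out[i] = pos
        return out

    @cached_property
    def col_to_b(self) -> np.ndarray:
        """Per column: 1-based position on (forward-strand) sequence b, or 0."""
        out = np.zeros(len(self.row_b), dtype=np.int64)
        if self.strand_b == "+":
            pos = self.b_span.start - 1
            for i, c in enumerate(self.row_b):
                if c != "-":
                    pos += 1
                    out[i] = pos
        else:
            pos = self.b_span.end + 1
            for i, c in enumerate(self.row_b):
                if c != "-":
                    pos -= 1
                    out[i] = pos
        return out

    @cached_property
    def a_to_col(self) -> dict[int, int]:
        return {int(p): i for i, p in enumerate(self.col_to_a) if p}

    @cached_property
    def b_to_col(self) -> dict[int, int]:
        return {int(p): i for i, p in enumerate(self.col_to_b) if p}

    @cached_property
    def match_mask(self) -> np.ndarray:
        """Per column: True where both rows carry the same non-N nucleotide."""
        a = np.frombuffer(self.row_a.encode(), dtype="S1")
        b = np.frombuffer(self.row_b.encode(), dtype="S1")
        return (a == b) & (a != b"-") & (a != b"N")


@dataclass
class ChunkHit:
    """Best local alignment of one query section against a full target."""

    chunk_index: int
    query_span: GenomicInterval
    target_span: GenomicInterval | None
    percent_identity: float
    alignment_length: int
    strand: str
    score: float
    significant: bool = True
    alignment: PairwiseAlignment | None = None


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identical non-gap, non-N columns over all alignment columns.

    Gap columns and N-containing columns count in the denominator only.
    """
    if len(aln) == 0:
        raise ValueError("empty alignment")
    return float(aln.match_mask.sum()) / len(aln)


def _traceback(pM, pX, pY, i, j, state, local=False):
    """Walk the traceback pointers; returns lists of (consume_a, consume_b)."""
    moves = []
    ptrs = (pM, pX, pY)
    while True:
        if local:
            if state == 0 and pM[i, j] == 3:
                moves.append((True, True))
                i -= 1
                j -= 1
                break
        else:
            if i == 0 and j == 0:
                break
        if state == 0:
            prev = pM[i, j]
            moves.append((True, True))
            i -= 1
            j -= 1
        elif state == 1:
            prev = pX[i, j]
            moves.append((True, False))
            i -= 1
        else:
            prev = pY[i, j]
            moves.append((False, True))
            j -= 1
        state = prev
    moves.reverse()
    return moves, i, j


def _rows_from_moves(a: str, b: str, moves, ai0: int, bj0: int) -> tuple[str, str]:
    ra, rb = [], []
    ai, bj = ai0, bj0
    for ca, cb in moves:
        if ca and cb:
            ra.append(a[ai]); rb.append(b[bj]); ai += 1; bj += 1
        elif ca:
            ra.append(a[ai]); rb.append("-"); ai += 1
        else:
            ra.append("-"); rb.append(b[bj]); bj += 1
    return "".join(ra), "".join(rb)


def global_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                 seq_id_a: str = "a", seq_id_b: str = "b") -> PairwiseAlignment:
    """Optimal affine-gap global alignment (Needleman-Wunsch-Gotoh).

    The returned score is the maximum attainable under ``scheme``; traceback
    ties are broken deterministically (diagonal, then gap-in-b, then
    gap-in-a).
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    smat = scheme.substitution_matrix()[np.ix_(encode(a), encode(b))]
    score, end_state, pM, pX, pY = _kernels.gotoh_global(
        smat, np.float32(scheme.gap_open), np.float32(scheme.gap_extend))
    moves, _, _ = _traceback(pM, pX, pY, len(a), len(b), end_state)
    row_a, row_b = _rows_from_moves(a, b, moves, 0, 0)
    return PairwiseAlignment(
        row_a, row_b,
        a_span=GenomicInterval(seq_id_a, 1, len(a)),
        b_span=GenomicInterval(seq_id_b, 1, len(b)),
        strand_b="+", score=float(score))


def _local_one_strand(a: str, b: str, scheme: ScoringScheme):
    smat = scheme.substitution_matrix()[np.ix_(encode(a), encode(b))]
    score, bi, bj, bstate, pM, pX, pY = _kernels.gotoh_local(
        smat, np.float32(scheme.gap_open), np.float32(scheme.gap_extend))
    if score <= 0 or bi == 0:
        return None
    moves, si, sj = _traceback(pM, pX, pY, bi, bj, bstate, local=True)
    return float(score), si, sj, bi, bj, moves


def local_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                both_strands: bool = False, min_score: float | None = None,
                seq_id_a: str = "a", seq_id_b: str = "b",
                chunk_index: int = 0, query_offset: int = 0) -> ChunkHit | None:
    """Highest-scoring local alignment (Smith-Waterman-Gotoh).

    With ``both_strands`` the reverse complement of ``b`` is also scanned and
    the reported hit carries strand '-' with ``target_span`` in forward
    coordinates of ``b``.  Returns None when no alignment reaches
    ``min_score`` (or no positive-scoring alignment exists at all).
    """
    if not a or not b:
        raise ValueError("local_align requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    candidates = []
    fwd = _local_one_strand(a, b, scheme)
    if fwd is not None:
        candidates.append(("+", b, fwd))
    if both_strands:
        brc = reverse_complement(b)
        rev = _local_one_strand(a, brc, scheme)
        if rev is not None:
            candidates.append(("-", brc, rev))
    if not candidates:
        return None
    # prefer higher score; '+' wins ties
    strand, bused, (score, si, sj, bi, bj, moves) = max(
        candidates, key=lambda c: (c[2][0], c[0] == "+"))
    if min_score is not None and score < min_score:
        return None
    row_a, row_b = _rows_from_moves(a, bused, moves, si, sj)
    L = len(b)
    if strand == "+":
        b_span = GenomicInterval(seq_id_b, sj + 1, bj)
    else:
        # positions on the reverse complement map back to forward coordinates
        b_span = GenomicInterval(seq_id_b, L - bj + 1, L - sj)
    aln = PairwiseAlignment(
        row_a, row_b,
        a_span=GenomicInterval(seq_id_a, query_offset + si + 1, query_offset + bi),
        b_span=b_span, strand_b=strand, score=score)
    return ChunkHit(
        chunk_index=chunk_index,
        query_span=aln.a_span,
        target_span=b_span,
        percent_identity=percent_identity(aln),
        alignment_length=len(aln),
        strand=strand,
        score=score,
        alignment=aln)


def split_chunks(length: int, chunk_len: int) -> list[tuple[int, int]]:
    """Sequential non-overlapping chunk spans (1-based closed).

    A final remainder shorter than chunk_len / 2 is merged into the previous
    chunk; otherwise it is kept as its own (shorter) chunk.
    """
    if chunk_len > length:
        logger.warning("chunk_len %d exceeds query length %d: using one chunk",
                       chunk_len, length)
        return [(1, length)]
    bounds = list(range(0, length, chunk_len))
    spans = [(s + 1, min(s + chunk_len, length)) for s in bounds]
    if len(spans) > 1 and spans[-1][1] - spans[-1][0] + 1 < chunk_len / 2:
        last = spans.pop()
        spans[-1] = (spans[-1][0], last[1])
    return spans


def chunked_search(query: SequenceRecord, target: SequenceRecord,
                   chunk_len: int = 500,
                   scheme: ScoringScheme = DEFAULT_SCHEME,
                   min_identity: float = 0.60,
                   min_score: float = 50.0,
                   min_aln_len: int = 100,
                   both_strands: bool = True) -> list[ChunkHit]:
    """Align sequential query sections against the full target.

    Each section is locally aligned on both strands against the whole target;
    at most one best hit per section is reported.  Sections whose best
    alignment fails the identity/score/length thresholds are returned with
    ``significant=False`` (best identity still recorded) so a complete
    per-section table can be written.
    """
    if chunk_len < 50:
        raise ValueError("chunk_len must be >= 50")
    hits: list[ChunkHit] = []
    for idx, (qs, qe) in enumerate(split_chunks(len(query), chunk_len)):
        chunk = query.sequence[qs - 1:qe]
        hit = local_align(chunk, target.sequence, scheme,
                          both_strands=both_strands,
                          seq_id_a=query.id, seq_id_b=target.id,
                          chunk_index=idx, query_offset=qs - 1)
        if hit is None:
            hits.append(ChunkHit(
                chunk_index=idx,
                query_span=GenomicInterval(query.id, qs, qe),
                target_span=None, percent_identity=0.0, alignment_length=0,
                strand="+", score=0.0, significant=False))
            continue
        hit.significant = (hit.percent_identity >= min_identity
                           and hit.score >= min_score
                           and hit.alignment_length >= min_aln_len)
        hits.append(hit)
    return hits


def chunk_table(hits: list[ChunkHit]) -> pd.DataFrame:
    """Per-section report: one row per query chunk."""
    rows = []
    for h in hits:
        rows.append({
            "chunk_index": h.chunk_index,
            "query_start": h.query_span.start,
            "query_end": h.query_span.end,
            "target_start": h.target_span.start if h.target_span else np.nan,
            "target_end": h.target_span.end if h.target_span else np.nan,
            "strand": h.strand,
            "percent_identity": h.percent_identity,
            "alignment_length": h.alignment_length,
            "score": h.score,
            "significant": h.significant,
        })
    return pd.DataFrame(rows)
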