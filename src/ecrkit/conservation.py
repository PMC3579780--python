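"""Sliding-window identity profiling and conserved-block (ECR) calling.

The profile slides a window of fixed *reference* length along the reference
row of a pairwise alignment (step 1 by default) and records, for each window
anchor, the fraction of matching columns among all alignment columns the
window spans.  Gaps in either row count against identity, as do N-containing
columns.  Windows are anchored in reference-sequence coordinates, not
alignment columns, so called blocks are directly reportable on the reference
genome.

Block calling assigns each reference position the identity of the window
*centered* on it (window anchors near the profile edges are clamped, so a
fully conserved alignment yields one block covering the whole profiled
extent); a conserved block is a maximal run of positions at or above the
identity threshold.  The CoreECR caller additionally refines the boundaries
of its single best block by a maximum-scoring-segment pass over per-position
match scores, which localizes the conserved/diverged changepoints to within
a few nucleotides instead of half a window.

Two presets are used throughout the package: ECR calling at >= 75% identity
in a 100-nt window, and CoreECR calling at >= 77% identity in a 350-nt
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairwise import PairwiseAlignment
from .seqcoords import GenomicInterval

ECR_PRESET = (100, 0.75)
CORE_ECR_PRESET = (350, 0.77)


@dataclass(frozen=True)
class ProfileParams:
    window: int = 100
    min_identity: float = 0.75
    step: int = 1

    def __post_init__(self) -> None:
        if self.window < 10:
            raise ValueError("window must be >= 10")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (1 <= self.step <= self.window):
            raise ValueError("step must satisfy 1 <= step <= window")


@dataclass
class ConservationProfile:
    """Windowed identities along the reference sequence.

    ``ref_positions`` are the 1-based reference coordinates of each window's
    first position; ``identities`` is the parallel array of fractions.
    """

    ref_positions: np.ndarray
    identities: np.ndarray
    params: ProfileParams
    aln: PairwiseAlignment | None = None

    def __post_init__(self) -> None:
        if len(self.ref_positions) != len(self.identities):
            raise ValueError("ref_positions and identities must be parallel")
        if len(self.ref_positions) > 1 and np.any(np.diff(self.ref_positions) <= 0):
            raise ValueError("ref_positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ref_positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.ref_positions,
                             "identity": self.identities})


@dataclass
class ConservedBlock:
    interval: GenomicInterval
    mean_identity: float
    label: str = "ECR"


def _ref_col_index(aln: PairwiseAlignment) -> np.ndarray:
    """Column index of each reference (row_a non-gap) position, 0-based."""
    return np.flatnonzero(
        np.frombuffer(aln.row_a.encode(), dtype="S1") != b"-")


def windowed_identity(aln: PairwiseAlignment,
                      params: ProfileParams) -> ConservationProfile:
    """Sliding-window identity along the reference row of an alignment.

    Each window covers ``params.window`` consecutive reference positions; its
    identity is (matching columns) / (alignment columns spanned), so
    insertions in the other species dilute identity.
    """
    cols = _ref_col_index(aln)
    nref = len(cols)
    w = params.window
    if nref < w:
        raise ValueError(
            f"alignment has {nref} reference positions, fewer than window {w}")
    match = aln.match_mask.astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(match)])
    starts = np.arange(0, nref - w + 1, params.step)
    lo = cols[starts]
    hi = cols[starts + w - 1]
    ncols = hi - lo + 1
    ident = (csum[hi + 1] - csum[lo]) / ncols
    ref_positions = aln.a_span.start + starts
    return ConservationProfile(ref_positions, ident, params, aln=aln)


def _recount_identity(aln: PairwiseAlignment, start: int, end: int) -> float:
    """Identity over the reference extent [start, end] (1-based, closed)."""
    cols = _ref_col_index(aln)
    i0 = start - aln.a_span.start
    i1 = end - aln.a_span.start
    lo, hi = cols[i0], cols[i1]
    return float(aln.match_mask[lo:hi + 1].mean())


def call_blocks(profile: ConservationProfile, label: str = "ECR") -> list[ConservedBlock]:
    """Maximal runs of reference positions whose centered window passes.

    Each passing window marks its center position conserved; a block spans
    the centers of a maximal run of consecutive passing windows.  Runs that
    reach the first/last window are extended to the profiled extent's edge
    (edge positions have no centered window of their own).  Block mean
    identity is the mean over the run's passing windows, so it always
    satisfies the calling threshold.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    p = profile.params
    passing = profile.identities >= p.min_identity
    if not passing.any():
        return []
    half = p.window // 2
    seq_id = profile.aln.a_span.seq_id if profile.aln is not None else "ref"
    extent_start = int(profile.ref_positions[0])
    extent_end = int(profile.ref_positions[-1]) + p.window - 1
    blocks: list[ConservedBlock] = []
    idx = np.flatnonzero(passing)
    run_bounds = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in run_bounds:
        first, last = int(run[0]), int(run[-1])
        start = int(profile.ref_positions[first]) + half
        end = int(profile.ref_positions[last]) + half
        if first == 0:
            start = extent_start
        if last == len(profile) - 1:
            end = extent_end
        # a block's identity is the mean over its passing windows (the
        # windowed evidence); this is always >= the threshold and does not
        # over-credit short runs the way a recount over a narrow center
        # extent would
        mean_id = float(profile.identities[run].mean())
        blocks.append(ConservedBlock(
            GenomicInterval(seq_id, start, end), mean_id, label))
    return blocks


def _position_scores(aln: PairwiseAlignment, threshold: float) -> np.ndarray:
    """Per-reference-position score: matches - threshold * columns charged.

    Each reference position is charged its own column plus any following
    insertion columns (gaps in the reference row), so segment sums agree
    with windowed identity numerators/denominators.
    """
    nmatch, ncols = _position_counts(aln)
    return nmatch - threshold * ncols


def _position_counts(aln: PairwiseAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-reference-position (match count, column count) arrays."""
    cols = _ref_col_index(aln)
    match = aln.match_mask.astype(np.float64)
    csum = np.concatenate([[0.0], np.cumsum(match)])
    nref = len(cols)
    ends = np.empty(nref, dtype=np.int64)
    ends[:-1] = cols[1:] - 1
    ends[-1] = len(aln) - 1
    nmatch = csum[ends + 1] - csum[cols]
    ncols = ends - cols + 1
    return nmatch, ncols


def _max_sum_segment(scores: np.ndarray) -> tuple[int, int]:
    """Kadane's algorithm; returns (start, end) 0-based inclusive indices.

    Ties are broken in favor of the earliest, then shortest, segment.
    """
    best = -np.inf
    best_span = (0, 0)
    cur = 0.0
    cur_start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = float(s)
            cur_start = i
        else:
            cur += float(s)
        if cur > best:
            best = cur
            best_span = (cur_start, i)
    return best_span


def refine_block(aln: PairwiseAlignment, block: ConservedBlock,
                 threshold: float, window: int,
                 label: str | None = None) -> ConservedBlock:
    """Sharpen block boundaries by a maximum-scoring-segment pass.

    The refined block is the maximal-sum segment (within the candidate
    extent padded by one window per side) of per-position scores.  Matches
    and mismatches are weighted by the log-likelihood ratio between the
    block's identity rate and the background rate, both estimated from the
    alignment itself - the maximum-likelihood changepoint estimate under a
    two-state (conserved/background) Bernoulli model.  When the two rates
    are too close to estimate reliably, scores fall back to match indicators
    minus the calling threshold.  Either way this removes the half-window
    boundary blur of the sliding window.
    """
    nmatch, ncols = _position_counts(aln)
    a0 = aln.a_span.start
    lo = max(0, block.interval.start - window - a0)
    hi = min(len(nmatch) - 1, block.interval.end + window - a0)
    b0 = block.interval.start - a0
    b1 = block.interval.end - a0
    inside = slice(b0, b1 + 1)
    n_in_match, n_in_cols = nmatch[inside].sum(), ncols[inside].sum()
    out_mask = np.ones(len(nmatch), dtype=bool)
    out_mask[max(0, b0 - window):b1 + window + 1] = False
    n_out_match, n_out_cols = nmatch[out_mask].sum(), ncols[out_mask].sum()
    p_in = n_in_match / n_in_cols if n_in_cols else threshold
    p_out = n_out_match / n_out_cols if n_out_cols else 0.0
    p_in = min(p_in, 1 - 1e-6)
    p_out = max(p_out, 1e-6)
    if p_in - p_out > 0.05:
        w_match = np.log(p_in / p_out)
        w_mismatch = np.log((1 - p_in) / (1 - p_out))
        scores = nmatch * w_match + (ncols - nmatch) * w_mismatch
    else:
        scores = nmatch - threshold * ncols
    s, e = _max_sum_segment(scores[lo:hi + 1])
    start = a0 + lo + s
    end = a0 + lo + e
    return ConservedBlock(
        GenomicInterval(aln.a_span.seq_id, start, end),
        _recount_identity(aln, start, end),
        label or block.label)


def core_ecr(aln: PairwiseAlignment,
             window: int = CORE_ECR_PRESET[0],
             min_identity: float = CORE_ECR_PRESET[1]) -> ConservedBlock | None:
    """Call the single best long, highly conserved block (CoreECR preset).

    Applies the 350-nt / 77% preset, keeps the highest-mean-identity block
    (ties: longer, then smaller start), and refines its boundaries.  Returns
    None when no window passes.
    """
    profile = windowed_identity(aln, ProfileParams(window, min_identity))
    blocks = call_blocks(profile, label="CoreECR")
    if not blocks:
        return None
    best = max(blocks, key=lambda b: (b.mean_identity, b.interval.length,
                                      -b.interval.start))
    return refine_block(aln, best, min_identity, window, label="CoreECR")


def blocks_to_bed_fields(blocks: list[ConservedBlock]):
    """(intervals, names, scores) triple for seqcoords.write_bed."""
    return ([b.interval for b in blocks],
            [b.label for b in blocks],
            [min(1.0, b.mean_identity) for b in blocks])
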