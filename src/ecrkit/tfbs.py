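"""PWM scanning, cross-species conserved-TFBS calling, and affinity scoring.

A putative transcription-factor binding site is a position-weight-matrix
match whose log2 odds (site vs background) reaches a relative-score
threshold.  A site on a reference sequence is called *conserved* when its
aligned image in a second species overlaps a same-matrix, same-orientation
hit there and the 20 alignment columns centered on the site retain a minimum
identity - the flank-conservation filter that separates shared regulatory
sites from coincidental matrix matches.

Occupancy-style affinity follows the biophysical two-state model: each
offset contributes p = R0*exp(-E/lambda) / (1 + R0*exp(-E/lambda)), where E
is the site's mismatch energy relative to the matrix's best site (natural
log ratio form), lambda = 0.7 and R0 = exp(0.584*W - 5.66) (the model's
published defaults as a function of matrix width W), summed over both
strands.

PWMs are read from JASPAR-style count files; multiple-testing correction is
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from statsmodels.stats.multitest import multipletests

from .conservation import ConservedBlock
from .pairwise import PairwiseAlignment, encode
from .seqcoords import GenomicInterval, reverse_complement

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class PWM:
    """Position count/frequency matrix with background and pseudocount.

    ``matrix`` is 4 x W (rows A, C, G, T).  Columns are normalized to
    probabilities after adding ``pseudocount`` distributed by background, so
    every cell is strictly positive.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray | None = None
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM matrix must be 4 x W with W >= 4")
        if (self.matrix < 0).any():
            raise ValueError("PWM counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=np.float64)
        if not math.isclose(self.background.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        col_tot = self.matrix.sum(axis=0)
        return ((self.matrix + self.pseudocount * self.background[:, None])
                / (col_tot + self.pseudocount))

    @property
    def log_odds(self) -> np.ndarray:
        """5 x W log2(f/b); the fifth row (N) contributes 0 at every position."""
        lom = np.log2(self.probabilities / self.background[:, None])
        return np.vstack([lom, np.zeros(self.width)])

    @property
    def score_range(self) -> tuple[float, float]:
        lom = self.log_odds[:4]
        return float(lom.min(axis=0).sum()), float(lom.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probabilities.argmax(axis=0))


@dataclass
class TFBSHit:
    pwm_name: str
    interval: GenomicInterval
    strand: str
    log_odds: float
    relative_score: float


@dataclass
class ConservedTFBS:
    """A reference-species site with its conserved counterpart."""

    hit_ref: TFBSHit
    hit_other: TFBSHit
    flank_identity: float
    in_block: str | None = None


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read one or more JASPAR-format count matrices."""
    path = Path(path)
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in _BASES], dtype=np.float64)
        pwms.append(PWM(name=m.name or m.matrix_id or path.stem, matrix=counts))
    if not pwms:
        raise ValueError(f"no matrices found in {path}")
    return pwms


def read_pwm_dir(directory: str | Path) -> list[PWM]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.jaspar")) + sorted(directory.glob("*.pfm"))
    if not paths:
        raise ValueError(f"no PWM files (*.jaspar, *.pfm) in {directory}")
    pwms: list[PWM] = []
    for p in paths:
        pwms.extend(read_jaspar(p))
    return pwms


def _scan_one_strand(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Log-odds score at every offset (vectorized over offsets)."""
    lom = pwm.log_odds
    W = pwm.width
    n_off = len(codes) - W + 1
    scores = np.zeros(n_off)
    for j in range(W):
        scores += lom[codes[j:j + n_off], j]
    return scores


def pwm_scan(seq: str, pwm: PWM, min_relative_score: float = 0.85,
             both_strands: bool = True, seq_id: str = "seq") -> list[TFBSHit]:
    """All PWM matches at or above ``min_relative_score``, sorted by position.

    The relative score normalizes the summed log2 odds between the matrix's
    minimum and maximum attainable scores; N bases contribute the background
    expectation (zero log odds).
    """
    seq = seq.upper()
    if pwm.width > len(seq):
        logger.warning("PWM %s (W=%d) wider than sequence (%d nt): no hits",
                       pwm.name, pwm.width, len(seq))
        return []
    smin, smax = pwm.score_range
    span = smax - smin
    hits: list[TFBSHit] = []
    L = len(seq)
    W = pwm.width
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", reverse_complement(seq)))
    for strand, s in strands:
        scores = _scan_one_strand(encode(s), pwm)
        rel = (scores - smin) / span
        for off in np.flatnonzero(rel >= min_relative_score):
            off = int(off)
            if strand == "+":
                start = off + 1
            else:
                start = L - off - W + 1
            hits.append(TFBSHit(
                pwm_name=pwm.name,
                interval=GenomicInterval(seq_id, start, start + W - 1,
                                         strand=strand),
                strand=strand,
                log_odds=float(scores[off]),
                relative_score=float(rel[off])))
    hits.sort(key=lambda h: (h.interval.start, h.strand, h.pwm_name))
    return hits


def _flank_identity(aln: PairwiseAlignment, mid_col: int, flank: int) -> float:
    half = flank // 2
    lo = max(0, mid_col - half)
    hi = min(len(aln) - 1, mid_col + half - 1)
    return float(aln.match_mask[lo:hi + 1].mean())


def conserved_sites(aln: PairwiseAlignment,
                    hits_a: list[TFBSHit], hits_b: list[TFBSHit],
                    flank: int = 20, min_flank_identity: float = 0.80,
                    blocks: list[ConservedBlock] | None = None
                    ) -> list[ConservedTFBS]:
    """Cross-species conserved-site filter.

    A reference hit is conserved iff (i) its aligned image in the second
    species overlaps a hit of the same matrix with the same orientation
    relative to the alignment, and (ii) the ``flank`` alignment columns
    centered on the site midpoint reach ``min_flank_identity``.  Sites are
    annotated with the label of the containing conserved block, if supplied.
    """
    out: list[ConservedTFBS] = []
    for hit in hits_a:
        cols = [aln.a_to_col.get(p) for p in
                (hit.interval.start, hit.interval.end)]
        if cols[0] is None or cols[1] is None:
            logger.warning("hit %s at %d-%d outside the aligned span: skipped",
                           hit.pwm_name, hit.interval.start, hit.interval.end)
            continue
        c0, c1 = sorted(cols)
        bpos = [p for p in aln.col_to_b[c0:c1 + 1] if p]
        if not bpos:
            continue
        b_lo, b_hi = min(bpos), max(bpos)
        # orientation relative to the alignment: on a '-'-strand alignment a
        # conserved site appears on opposite sequence strands
        def _same_orientation(other: TFBSHit) -> bool:
            if aln.strand_b == "+":
                return other.strand == hit.strand
            return other.strand != hit.strand

        partners = [o for o in hits_b
                    if o.pwm_name == hit.pwm_name
                    and _same_orientation(o)
                    and not (o.interval.end < b_lo or o.interval.start > b_hi)]
        if not partners:
            continue
        partner = max(
            partners,
            key=lambda o: (min(o.interval.end, b_hi) - max(o.interval.start, b_lo),
                           o.log_odds))
        mid = (c0 + c1 + 1) // 2
        fid = _flank_identity(aln, mid, flank)
        if fid < min_flank_identity:
            continue
        label = None
        if blocks:
            for blk in blocks:
                if (blk.interval.start <= hit.interval.start
                        and hit.interval.end <= blk.interval.end):
                    label = blk.label
                    break
        out.append(ConservedTFBS(hit, partner, fid, label))
    return out


def occupancy_affinity(seq: str, pwm: PWM, lam: float = 0.7) -> float:
    """Expected occupancy summed over all offsets and both strands.

    E at an offset is the natural-log probability ratio between the matrix's
    best site and the observed site; N bases contribute the expected
    background energy at their position.
    """
    seq = seq.upper()
    W = pwm.width
    if len(seq) < W:
        raise ValueError("sequence shorter than the PWM width")
    probs = pwm.probabilities
    best = probs.max(axis=0)
    em = np.log(best[None, :] / probs)  # 4 x W mismatch energies
    em_n = (pwm.background[:, None] * em).sum(axis=0)  # expected background energy
    em5 = np.vstack([em, em_n])
    r0 = math.exp(0.584 * W - 5.66)
    total = 0.0
    for s in (seq, reverse_complement(seq)):
        codes = encode(s)
        n_off = len(codes) - W + 1
        energy = np.zeros(n_off)
        for j in range(W):
            energy += em5[codes[j:j + n_off], j]
        q = r0 * np.exp(-energy / lam)
        total += float((q / (1.0 + q)).sum())
    return total


def benjamini_hochberg(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values); adjusted values are monotone
    non-decreasing in rank and rejections are {adjusted <= alpha}.
    """
    p = np.asarray(list(pvalues), dtype=np.float64)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, adjusted


def site_block_partition(sites, blocks: list[ConservedBlock]) -> dict:
    """Count sites falling fully inside vs outside conserved blocks.

    ``sites`` may be ConservedTFBS (the reference hit's interval is used) or
    plain TFBSHit objects.
    """
    inside = outside = 0
    for site in sites:
        iv = site.hit_ref.interval if isinstance(site, ConservedTFBS) else site.interval
        if any(b.interval.start <= iv.start and iv.end <= b.interval.end
               for b in blocks):
            inside += 1
        else:
            outside += 1
    total = inside + outside
    return {"inside": inside, "outside": outside,
            "fraction_inside": inside / total if total else 0.0}


def hits_frame(hits: list[TFBSHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pwm": h.pwm_name, "start": h.interval.start, "end": h.interval.end,
        "strand": h.strand, "log_odds": h.log_odds,
        "relative_score": h.relative_score} for h in hits])


def conserved_frame(sites: list[ConservedTFBS]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pwm": s.hit_ref.pwm_name,
        "ref_start": s.hit_ref.interval.start,
        "ref_end": s.hit_ref.interval.end,
        "ref_strand": s.hit_ref.strand,
        "other_start": s.hit_other.interval.start,
        "other_end": s.hit_other.interval.end,
        "flank_identity": s.flank_identity,
        "in_block": s.in_block or ""} for s in sites])
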