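"""Independent reference implementations used to check the package.

These deliberately avoid the package's dynamic-programming and vectorized
code paths: alignment scores come from exhaustive enumeration of every
gapped alignment, window identities and PWM scores from direct per-column
recounts.
"""

from __future__ import annotations

import math

from ecrkit.pairwise import ScoringScheme


def enumerate_global_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Maximum global alignment score by exhaustive enumeration.

    Walks every monotone path through the alignment lattice (diagonal /
    gap-in-b / gap-in-a steps), carrying the affine-gap state, and returns
    the best total score.  Exponential - only for strings of length <= ~8.
    """
    best = -math.inf
    la, lb = len(a), len(b)

    def step(i: int, j: int, score: float, last: str | None) -> None:
        nonlocal best
        if i == la and j == lb:
            if score > best:
                best = score
            return
        if i < la and j < lb:
            s = scheme.match if (a[i] == b[j] and a[i] != "N") else scheme.mismatch
            step(i + 1, j + 1, score + s, "M")
        if i < la:
            g = scheme.gap_extend if last == "X" else scheme.gap_open
            step(i + 1, j, score + g, "X")
        if j < lb:
            g = scheme.gap_extend if last == "Y" else scheme.gap_open
            step(i, j + 1, score + g, "Y")

    step(0, 0, 0.0, None)
    return best


def recount_window_identity(aln, ref_start_index: int, window: int) -> float:
    """Window identity by direct column counting, independent of prefix sums.

    ``ref_start_index`` is the 0-based index of the window's first reference
    (non-gap in row_a) position.
    """
    ref_cols = [i for i, c in enumerate(aln.row_a) if c != "-"]
    lo = ref_cols[ref_start_index]
    hi = ref_cols[ref_start_index + window - 1]
    matches = sum(
        1 for i in range(lo, hi + 1)
        if aln.row_a[i] == aln.row_b[i] and aln.row_a[i] not in "-N")
    return matches / (hi - lo + 1)


def rescore_pwm_offsets(seq: str, pwm) -> list[float]:
    """Forward-strand log-odds at every offset by per-position lookup."""
    lom = pwm.log_odds
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    W = pwm.width
    return [sum(lom[idx[seq[o + j]], j] for j in range(W))
            for o in range(len(seq) - W + 1)]


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recipe."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * n / rank_from_top)
        adjusted[i] = running
    return adjusted
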