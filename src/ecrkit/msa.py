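"""Progressive multiple alignment, shared-span extraction, and consensus.

The aligner is a deterministic progressive profile-profile method: a UPGMA
guide tree is built from 6-mer count distances, then profiles are merged up
the tree with the same affine-gap dynamic program used for pairwise global
alignment (for two sequences the result is identical to ``global_align``).
It implements the alignment *contract* needed downstream - it does not
reproduce any particular production aligner's objective function.

The consensus follows the classic case-encoded convention: an uppercase
letter marks a unanimous column, lowercase a strict-majority nucleotide,
'n' a column with no strict majority, and '.' a column where gaps dominate.
Per-row identity to the consensus is computed over residue-consensus columns
only ('n' and '.' columns are excluded); a row gap at a residue-consensus
column counts as a mismatch.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .pairwise import DEFAULT_SCHEME, PairwiseAlignment, ScoringScheme, global_align
from .seqcoords import SequenceRecord

_SYM = "ACGTN-"
_SYM_INDEX = {c: i for i, c in enumerate(_SYM)}


@dataclass
class MultipleAlignment:
    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows must be parallel")
        ncols = {len(r) for r in self.rows}
        if len(ncols) > 1:
            raise ValueError("all rows must have equal length")
        for j in range(self.ncols):
            if all(row[j] == "-" for row in self.rows):
                raise ValueError(f"all-gap column at {j + 1}")

    @property
    def nrows(self) -> int:
        return len(self.rows)

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def col_to_seqpos(self, i: int) -> np.ndarray:
        """Per column: 1-based position on row i's sequence, or 0 at gaps."""
        out = np.zeros(self.ncols, dtype=np.int64)
        pos = 0
        for j, c in enumerate(self.rows[i]):
            if c != "-":
                pos += 1
                out[j] = pos
        return out


@dataclass
class ConsensusResult:
    """Case/'n'/'.'-encoded consensus with per-species identity."""

    consensus: str
    span_columns: tuple[int, int]  # 1-based inclusive columns of the MSA
    per_species_identity: dict[str, float]
    consensus_length: int  # columns with consensus != '.'
    alignment_length: int  # all span columns


# ---------------------------------------------------------------------------
# guide tree

def _kmer_counts(seq: str, k: int = 6) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def kmer_distance(a: str, b: str, k: int = 6) -> float:
    """1 - (shared k-mer count / smaller k-mer total); crude but monotone
    in divergence, which is all a guide tree needs."""
    ca, cb = _kmer_counts(a, k), _kmer_counts(b, k)
    shared = sum(min(ca[m], cb[m]) for m in ca.keys() & cb.keys())
    denom = min(sum(ca.values()), sum(cb.values()))
    return 1.0 - shared / denom if denom else 1.0


def upgma_merge_order(dist: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA agglomeration order on a condensed-free square distance matrix.

    Returns the sequence of cluster-index pairs merged; ties are broken by
    the smallest pair of cluster indices (hence by input order), making the
    guide tree deterministic.
    """
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}
    d = {frozenset((i, j)): float(dist[i, j])
         for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = min(
            ((d[frozenset((i, j))], i, j)
             for i in active for j in active if i < j),
            key=lambda t: (t[0], t[1], t[2]))
        _, i, j = best
        merges.append((i, j))
        members = active[i] + active[j]
        for k in active:
            if k in (i, j):
                continue
            dik = d[frozenset((i, k))]
            djk = d[frozenset((j, k))]
            wi, wj = len(active[i]), len(active[j])
            d[frozenset((next_id, k))] = (wi * dik + wj * djk) / (wi + wj)
        del active[i], active[j]
        active[next_id] = members
        next_id += 1
    return merges


# ---------------------------------------------------------------------------
# profile-profile alignment

def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(6, ncols) symbol frequencies (A,C,G,T,N,-) over the profile's rows."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(
        len(rows), -1)
    freqs = np.zeros((6, arr.shape[1]), dtype=np.float64)
    for i, c in enumerate(_SYM):
        freqs[i] = (arr == ord(c)).mean(axis=0)
    return freqs


def _profile_score_matrix(fa: np.ndarray, fb: np.ndarray,
                          scheme: ScoringScheme) -> np.ndarray:
    """Expected sum-of-pairs column score between two profiles.

    Residue-residue pairs score match/mismatch (N never matches); a residue
    opposite an existing internal gap is charged gap_extend; gap-gap pairs
    score zero.
    """
    sub = np.full((5, 5), scheme.mismatch, dtype=np.float64)
    for i in range(4):
        sub[i, i] = scheme.match
    ra, ga = fa[:5], fa[5]
    rb, gb = fb[:5], fb[5]
    smat = ra.T @ sub @ rb
    smat += np.outer(ga, rb.sum(axis=0)) * scheme.gap_extend
    smat += np.outer(ra.sum(axis=0), gb) * scheme.gap_extend
    return smat.astype(np.float32)


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    smat = _profile_score_matrix(fa, fb, scheme)
    _, end_state, pM, pX, pY = _kernels.gotoh_global(
        smat, np.float32(scheme.gap_open), np.float32(scheme.gap_extend))
    # traceback
    i, j, state = smat.shape[0], smat.shape[1], end_state
    moves = []
    while not (i == 0 and j == 0):
        if state == 0:
            prev = pM[i, j]; moves.append((True, True)); i -= 1; j -= 1
        elif state == 1:
            prev = pX[i, j]; moves.append((True, False)); i -= 1
        else:
            prev = pY[i, j]; moves.append((False, True)); j -= 1
        state = prev
    moves.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for ca, cb in moves:
        for r, row in enumerate(rows_a):
            out_a[r].append(row[ia] if ca else "-")
        for r, row in enumerate(rows_b):
            out_b[r].append(row[ib] if cb else "-")
        ia += ca
        ib += cb
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(seqs: list[SequenceRecord],
                    scheme: ScoringScheme = DEFAULT_SCHEME) -> MultipleAlignment:
    """Progressive multiple alignment along a UPGMA (6-mer distance) guide tree.

    Deterministic for a fixed input order; for exactly two sequences the
    result equals pairwise ``global_align``.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    for s in seqs:
        if len(s) < 50:
            raise ValueError(f"sequence {s.id} shorter than 50 nt")
    if len(seqs) == 2:
        aln = global_align(seqs[0].sequence, seqs[1].sequence, scheme,
                           seq_id_a=seqs[0].id, seq_id_b=seqs[1].id)
        return MultipleAlignment([seqs[0].id, seqs[1].id],
                                 [aln.row_a, aln.row_b])
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kmer_distance(seqs[i].sequence,
                                                    seqs[j].sequence)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([s.id], [s.sequence]) for i, s in enumerate(seqs)}
    next_id = n
    for i, j in upgma_merge_order(dist):
        ids_a, rows_a = clusters.pop(i)
        ids_b, rows_b = clusters.pop(j)
        rows_a, rows_b = _merge_profiles(rows_a, rows_b, scheme)
        clusters[next_id] = (ids_a + ids_b, rows_a + rows_b)
        next_id += 1
    (ids, rows), = clusters.values()
    # restore input row order
    order = sorted(range(len(ids)), key=lambda k: [s.id for s in seqs].index(ids[k]))
    return MultipleAlignment([ids[k] for k in order], [rows[k] for k in order])


# ---------------------------------------------------------------------------
# shared span / consensus

def shared_span(msa: MultipleAlignment) -> tuple[int, int]:
    """Columns (1-based, inclusive) covered by every row's aligned extent.

    A row's extent runs from its first to its last non-gap column; the shared
    span is the intersection across rows - the minimal region present in all
    species.
    """
    starts, ends = [], []
    for row in msa.rows:
        nz = [j for j, c in enumerate(row) if c != "-"]
        starts.append(nz[0])
        ends.append(nz[-1])
    lo, hi = max(starts), min(ends)
    if lo > hi:
        raise ValueError("no shared span: rows have disjoint coverage")
    return lo + 1, hi + 1


def consensus_char(column: str) -> str:
    """Consensus symbol for one MSA column.

    Gap rule first: '.' when gaps are >= 50% of all rows.  Otherwise, over
    non-gap unambiguous residues: unanimous -> uppercase, strict majority
    (> 50%) -> lowercase, no strict majority -> 'n'.  N residues are treated
    as missing data (they neither vote nor block unanimity).
    """
    nrows = len(column)
    gaps = column.count("-")
    if gaps * 2 >= nrows:
        return "."
    votes = Counter(c for c in column if c in "ACGT")
    if not votes:
        return "n"
    base, count = max(votes.items(), key=lambda kv: (kv[1], -"ACGT".index(kv[0])))
    total = sum(votes.values())
    if count == total:
        return base.upper()
    if count * 2 > total:
        return base.lower()
    return "n"


def build_consensus(msa: MultipleAlignment,
                    span: tuple[int, int] | None = None) -> ConsensusResult:
    """Case-encoded consensus over the shared span (or an explicit span)."""
    if msa.nrows < 2:
        raise ValueError("consensus requires >= 2 rows")
    if span is None:
        span = shared_span(msa)
    lo, hi = span
    if lo > hi:
        raise ValueError("empty span")
    cols = ["".join(row[j] for row in msa.rows) for j in range(lo - 1, hi)]
    consensus = "".join(consensus_char(c) for c in cols)
    if any(c in "ACGTacgt" for c in consensus):
        per_species = {
            rid: identity_to_consensus(row[lo - 1:hi], consensus)
            for rid, row in zip(msa.row_ids, msa.rows)}
    else:
        # degenerate consensus (every column 'n' or '.'): identity undefined
        per_species = {rid: float("nan") for rid in msa.row_ids}
    return ConsensusResult(
        consensus=consensus,
        span_columns=(lo, hi),
        per_species_identity=per_species,
        consensus_length=sum(1 for c in consensus if c != "."),
        alignment_length=hi - lo + 1)


def identity_to_consensus(row: str, consensus: str,
                          identity_mode: str = "exclude_n") -> float:
    """Fraction of residue-consensus columns where the row matches.

    Columns whose consensus is 'n' or '.' are excluded from numerator and
    denominator under the default mode; ``identity_mode='strict'`` counts
    them as comparable (and never matching, except row-gap at '.').  A row
    gap at a residue-consensus column is a mismatch.
    """
    if len(row) != len(consensus):
        raise ValueError("row and consensus must have equal length")
    matches = comparable = 0
    for rc, cc in zip(row.upper(), consensus.upper()):
        if cc in "N.":
            if identity_mode == "strict":
                comparable += 1
                if cc == "." and rc == "-":
                    matches += 1
            continue
        comparable += 1
        if rc == cc:
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    return matches / comparable


def identity_summary(per_species_identity: dict[str, float]) -> dict[str, float]:
    """Mean / median / min / max of per-species identities.

    The median of an even count is the midpoint of the two central values.
    """
    vals = list(per_species_identity.values())
    if not vals:
        raise ValueError("no identities to summarize")
    return {
        "mean": statistics.fmean(vals),
        "median": statistics.median(vals),
        "min": min(vals),
        "max": max(vals),
    }


def msa_to_fasta(msa: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.row_ids, msa.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i:i + 60] + "\n")


def consensus_to_fasta(result: ConsensusResult, path, name: str = "consensus") -> None:
    """Write the consensus preserving its case/'n'/'.' encoding bit-exactly."""
    with open(path, "w") as fh:
        fh.write(f">{name} consensus_length={result.consensus_length} "
                 f"alignment_length={result.alignment_length}\n")
        for i in range(0, len(result.consensus), 60):
            fh.write(result.consensus[i:i + 60] + "\n")


def identity_frame(result: ConsensusResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"species": list(result.per_species_identity),
         "identity": list(result.per_species_identity.values())})
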