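# Methods

This note documents the models, conventions, parameter choices, and known
limitations of ecrkit. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and records

All internal coordinates are 1-based and fully closed: an interval
(start, end) contains end − start + 1 bases, matching the convention of
accession coordinate listings (a 505-nt element spans −1642..−1138).
TSS-relative numbering counts −1, −2, … moving 5′ of the transcription
start site, with no position 0; for a gene on the plus strand, relative
−n maps to tss_abs − n, and on the minus strand to tss_abs + n.
Reverse-strand table listings with descending coordinates are normalized
to ascending minus-strand intervals. BED export alone converts to the
standard 0-based half-open form.

FASTA input is uppercased; IUPAC ambiguity codes other than N are coerced
to N with a warning (draft genomes contain them; rejecting them would
block real-data runs), while characters outside the IUPAC nucleotide set
are errors naming the offending record. N never matches anything: it
scores as a mismatch in alignment, counts only in identity denominators,
contributes the background expectation (zero log-odds) to PWM scores, and
casts no vote in consensus columns.

## Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment use the
three-state affine-gap (Gotoh) dynamic program, implemented as
numba-compiled kernels over a precomputed position-score matrix; a gap of
length L costs gap_open + (L−1)·gap_extend. The default scheme
(+2 match, −3 mismatch, −5 open, −2 extend) mirrors classic
nucleotide-BLAST-style scoring. No heuristic seeding is used: inputs are
promoter-scale (≤ ~10 kb), so full O(n·m) DP is affordable and exact.
Traceback ties are broken deterministically — diagonal, then gap in the
second sequence, then gap in the first — and the local traceback always
ends on a match column (trailing gaps cannot improve a local score).
Scores are accumulated in float32; integer-valued schemes are therefore
exact. Correctness is checked against exhaustive enumeration of every
gapped alignment for short strings.

There is no E-value machinery. The chunked search splits the query into
sequential non-overlapping sections (default 500 nt; a final remainder
shorter than half a section merges into the previous one) and reports at
most one best local alignment per section against the full target, both
strands. A section is significant when identity ≥ 0.60, score ≥ 50, and
alignment length ≥ 100 columns; failing sections are reported with their
best identity and a flag, so the per-section table is complete. The
length condition exists because short perfect matches in random sequence
would otherwise pass the identity condition vacuously.

Percent identity is always (columns with equal non-gap, non-N
nucleotides) / (all alignment columns): gaps and N dilute identity.

## Conservation profile and block calling

Windows are anchored in reference-sequence coordinates, not alignment
columns, so profile positions and block coordinates are directly
reportable on the reference. A window of w reference positions spans all
alignment columns from its first to its last reference position;
insertions in the other species fall inside that span and lower identity.
The two built-in presets are 100 nt at 75% (ECR) and 350 nt at 77%
(CoreECR).

Block calling marks the *center* position of every passing window and
takes maximal runs of marked positions as blocks; runs reaching the
first/last window are extended to the profiled extent's edges, since edge
positions have no centered window of their own. Center-marking, rather
than merging whole window extents, keeps block boundaries within about
half a window of the true conservation changepoint instead of a full
window, at the price that an isolated passing window yields a very short
block (such single-window calls are near-threshold noise and are
out-ranked in CoreECR selection). A block's mean identity is the mean
over its passing windows' identities, which by construction satisfies the
calling threshold; recounting identity over the merged extent instead
would double-count the overlap structure and can fall below the threshold
even when every window passes.

The CoreECR caller keeps the single best block (highest mean identity,
ties broken by length then by smaller start) and refines its boundaries
by a maximum-scoring-segment pass over per-position scores. Each
reference position is charged its own column plus any following
insertion columns. Match and mismatch weights are the log-likelihood
ratios log(p_in/p_out) and log((1−p_in)/(1−p_out)), with p_in estimated
from the candidate block and p_out from the profiled extent outside the
block padded by one window — the maximum-likelihood changepoint estimate
under a two-state Bernoulli model. If the two estimates are within 0.05
the refinement falls back to match-minus-threshold scoring. Kadane's
maximum-subarray (earliest segment on ties) is run within the candidate
extent padded by one window per side, so a second conserved region
elsewhere cannot capture the segment. Boundary error is then governed by
the excursion statistics of a negative-drift walk — typically a few
nucleotides — rather than by window geometry. The residual failure mode,
visible in the simulator studies, is a background flank that is
conserved by chance at a level near the block's own identity; no
identity-based rule can exclude such flanks.

## Progressive alignment and consensus

The multiple aligner is a deterministic progressive method: pairwise
6-mer count distances (1 − shared/min total), a UPGMA guide tree with
ties broken by input order, and profile–profile alignment up the tree
using the same affine DP kernel as pairwise alignment. Column scores
between profiles are expected sum-of-pairs values (residue frequencies
against the substitution matrix; a residue opposite an existing internal
gap is charged gap_extend; gap–gap pairs score zero). For exactly two
sequences the result is identical to pairwise global alignment. The
aligner implements the alignment contract the downstream statistics need;
it does not emulate any production aligner's objective function, and no
tree output or bootstrap support is provided.

The minECR (minimal shared element) is the intersection of per-row
aligned extents: the maximal run of columns past every row's leading
terminal gaps and before its trailing ones. Disjoint coverage is an
error ("no shared span").

Consensus encoding per column, gap rule first: '.' when gaps are ≥50% of
all rows; otherwise, over non-gap A/C/G/T residues, unanimous →
uppercase, strict majority (>50%) → lowercase, else 'n' (plurality ties
are 'n', not lowercase). Input N is missing data: it neither votes nor
blocks unanimity, avoiding any collision with the 'n' output symbol.
Consensus length counts non-'.' characters; alignment length counts all
span columns, so the difference is exactly the gap-dominated columns
created by species-specific insertions.

Identity to the consensus compares a row to residue-consensus columns
only ('n' and '.' columns are excluded from numerator and denominator);
a row gap at a residue column is a mismatch. The alternative of counting
'n'/'.' columns as comparable is available as identity_mode="strict".
If a consensus has no residue columns at all (possible for degenerate
random alignments), identities are reported as NaN. Summaries use the
arithmetic mean and the midpoint median for even counts; text output
rounds to whole percent, TSV output does not round.

## TFBS scanning and conservation filtering

PWMs are JASPAR-style count matrices; columns are normalized with a
total pseudocount of 0.8 distributed by the background composition
(uniform by default), so every cell is positive. Scanning sums log2
odds over positions at every offset on both strands; the relative score
normalizes between the matrix's minimum and maximum attainable scores,
with a default calling threshold of 0.85 (match-score thresholds of the
reference tools are unpublished; 0.85 is a conventional stringent
choice).

A reference site is conserved when (i) the alignment columns it occupies
map to positions in the second species that overlap a hit of the same
matrix with the same orientation relative to the alignment (same strand
on a plus-strand alignment, opposite on a minus-strand one), and (ii) the
20 alignment columns centered on the site midpoint have identity ≥ 0.80.
The 20-column flank window follows the published practice of conditioning
site calls on the conservation of the immediate surroundings; the 0.80
cutoff is this package's choice, as the reference tools do not state
theirs. Tightening either threshold can only shrink the conserved set.
The inside/outside partition counts a site inside only when its full
interval lies within a conserved block.

Occupancy affinity follows the two-state binding model: at each offset
the mismatch energy E is the natural-log probability ratio between the
matrix's best site and the observed site, and the offset contributes
p = R₀e^(−E/λ)/(1+R₀e^(−E/λ)), summed over all offsets and both strands,
with λ = 0.7 and R₀ = exp(0.584·W − 5.66) (the model's published defaults
as a function of matrix width W). N bases contribute the
background-expected energy at their position. The score is invariant
under reverse complementation and monotone in site quality.

Multiple-testing correction is the Benjamini–Hochberg step-up procedure
(via statsmodels), applied to user- or simulator-supplied p-values; the
package computes no p-values for PWM hits itself.

## Simulator

The generator's defaults define the package's standard study conditions:
an ancestor of 5000 nt at GC 0.45; per-branch substitution probability
0.15 and indel initiation probability 0.02 (equiprobable
insertion/deletion, geometric lengths of mean 3, i.i.d. inserted bases);
a 400-nt constrained element at positions 3300–3699 whose mutation
probabilities are multiplied by 1/6. For a two-species pair this yields
roughly 30% pairwise substitution divergence in the background and 5%
inside the element — a mammal-scale promoter comparison with a strongly
constrained regulatory element. Probabilities are per branch, not rates
with time: simpler, and sufficient for truth-known benchmarking.

Every mutation pass returns a strictly monotone old→new coordinate map;
truth intervals (element, motifs) are pushed through composed maps, so
their simulated coordinates are exact. Star trees evolve each species
independently from the ancestor (optionally with per-branch rate scales,
giving unequal divergences with known ordering); balanced trees bisect
the species list recursively with one mutation pass per edge, so
same-subtree species share derived mutations. All randomness derives
from a single seed through spawned substreams; outputs (FASTA, BED,
newick) are byte-reproducible.

Motif planting writes a PWM's consensus string at non-overlapping
positions: inside motifs are chosen in ancestral element coordinates and
written at the coordinate-mapped homologous position in every species
(hence conserved by construction, emulating sites preserved by
selection); outside motifs are placed at species-specific random
background positions and are not homologous across species. A candidate
inside position is used only if it maps cleanly in every species.

What the simulator does not model: context-dependent mutation (e.g. CpG
hypermutability), an empirical indel length spectrum, repeat-element
insertion, selection beyond a uniform constraint factor, and
rearrangements. Passing the simulator-based tests therefore demonstrates
correct recovery of the statistical structure the analysis assumes —
a conserved element in a diverging background — not performance on every
property of real genomes.

## Problem sizes and numerical choices

The test suite and acceptance script run at "desk scale": 5-kb pairs,
50 replicate pairs for element recovery, 20 replicates for the TFBS
partition, a 16-species clade for the consensus statistics, and 500
random short-string pairs for the alignment-enumeration oracle. These
sizes give stable statistics while keeping a full run to a couple of
minutes on one CPU. Alignment kernels allocate O(n·m) float32/uint8
matrices (~0.5 GB transiently for a 5 kb × 5 kb global alignment).
Profile windows advance by step 1 by default; larger steps are an
approximation for speed and are documented as such. Determinism
throughout: fixed seeds, deterministic tie-breaks in DP traceback, guide
trees, and block selection.

## Known limitations

* Absolute identity values from the chunked search approximate, but do
  not reproduce, values computed by heuristic seeded aligners with
  unpublished filter settings; comparisons should be made on this
  package's own outputs.
* Published block boundaries from browser-based conservation tools use
  undocumented boundary rules; this package's block coordinates are
  defined by the center-marking and changepoint-refinement rules above
  and may differ from theirs by tens of nucleotides.
* The progressive aligner is adequate for the short, highly similar ECR
  sequences it is applied to; for long or deeply diverged inputs a
  dedicated MSA tool will produce better alignments.
* PWM hit calling reports relative scores and affinity ranks, not
  p-values.
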