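# ecrkit

Detection and analysis of **evolutionarily conserved regions (ECRs)** in
promoter sequences — the comparative-genomics workflow used to localize
cis-regulatory elements upstream of a gene by their conservation across
species, exercised here on the kind of data behind the mouse *Bmp3*
upstream ECR: ~5 kb upstream regions from a mammalian clade, anchored at
the annotated transcription start site (TSS).

It is written for researchers who have upstream-region FASTA files (one per
species) and want to (i) profile pairwise conservation and call conserved
blocks, (ii) search for homologous segments across distant species despite
insertions/deletions, (iii) reduce a set of full-length ECRs to the minimal
shared element and its case-encoded consensus, and (iv) identify
transcription-factor binding sites (TFBSs) that are conserved between
species. A bundled evolution simulator generates clades with known truth
so every stage can be validated without downloading genomes.

## Methods at a glance

* **Conservation profile.** A pairwise global alignment (Needleman–Wunsch
  with affine gaps, default +2/−3 match/mismatch, −5/−2 gap open/extend) is
  scanned with a sliding window of *w* reference nucleotides; window
  identity is (matching columns)/(alignment columns spanned), so gaps count
  against identity. Two presets are built in: ECR calling at ≥75% identity
  in a 100-nt window and **CoreECR** calling at ≥77% in a 350-nt window.
  A conserved block is a maximal run of positions whose centered window
  passes; the CoreECR caller then sharpens its best block's boundaries with
  a maximum-scoring-segment changepoint pass (match/mismatch scores
  weighted by the log-likelihood ratio between the block's and the
  background's identity rates).
* **Chunked homology search.** The query is cut into sequential 500-nt
  sections, each locally aligned (Smith–Waterman, affine gaps, both
  strands) against the full-length target. Sections downstream of a
  genomic insertion or deletion simply map at an offset, so indels between
  species do not break the scan. Significance is by identity/score/length
  thresholds (defaults 0.60 / 50 / 100 columns); sub-threshold sections are
  still reported, flagged, so a complete per-section table can be written.
* **minECR and consensus.** Full-length ECRs are aligned progressively
  (UPGMA guide tree on 6-mer distances, profile–profile affine-gap DP); the
  **minECR** is the run of columns covered by every species (intersection
  of aligned extents). Its consensus uses the classic case encoding:
  UPPERCASE = unanimous, lowercase = strict majority, `n` = no consensus,
  `.` = gap-dominated column. Per-species identity to the consensus is
  reported with mean/median/range.
* **Conserved TFBS.** Position-weight-matrix (PWM) log-odds scanning
  (JASPAR-style count matrices, relative score ≥ 0.85 by default) in both
  species; a site is *conserved* when its aligned image overlaps a
  same-matrix, same-orientation hit in the other species and the 20
  alignment columns centered on the site keep ≥80% identity. Sites are
  partitioned inside/outside conserved blocks. Occupancy-style binding
  affinity follows the biophysical two-state model
  p = R₀e^(−E/λ)/(1+R₀e^(−E/λ)) with λ = 0.7, R₀ = exp(0.584·W − 5.66);
  Benjamini–Hochberg correction is available for user-supplied p-values.
* **Simulator.** An i.i.d. ancestor (GC 45% by default) evolves along a
  star or balanced tree with per-branch substitution and indel
  probabilities; a planted element mutates at a reduced rate (constraint
  factor), and PWM consensus motifs can be planted homologously inside the
  element or species-specifically outside it. Coordinate maps track every
  truth interval through the mutations.

Coordinates are 1-based and fully closed throughout (TSS-relative
numbering has no position 0; −1 abuts the TSS); only BED export is 0-based
half-open.

## Worked example

Simulate a two-species pair with a constrained element, then profile it:

```bash
$ ecrkit simulate --out sim --n-species 2 --seed 11
wrote 2-species clade to sim
$ # split sim/clade.fasta into sp01.fa / sp02.fa, then:
$ ecrkit profile --query sp01.fa --target sp02.fa --out prof
blocks: 43; core ECR: 3300-3702 (identity 0.953)
```

The called CoreECR (sp01:3300–3702, mean identity 0.953) recovers the
planted element, whose true location in this replicate is sp01:3303–3702
(`sim/truth_elements.bed`). The 43 blocks are the 100-nt/75% preset's
calls; most are short near-threshold runs in the diverged background, which
is why the stricter 350-nt/77% CoreECR preset is used to pinpoint the
element.

Reducing a clade's ECR sequences to the minimal shared element:

```bash
$ ecrkit minecr --fasta ecrs.fa --out mine
minECR: consensus length 400 nt (402 nt with insertions); mean identity 97% (range: 96%-98%, median: 97%)
```

`mine/consensus.fasta` holds the case-encoded consensus — e.g.
`GGCTGGAaGGtaTGTTTATaGAGTT...`, where `G` is unanimous across species and
`a` is a majority call — and `mine/identity.tsv` the per-species
identities (here 0.96–0.98; six species at modest divergence). The
"with insertions" length counts gap (`.`) columns created by
species-specific insertions inside the shared span.

Other subcommands: `ecrkit chunkscan` (per-500-nt-section identity matrix
against many targets), `ecrkit tfbs` (conserved-site calls and the
inside/outside-block partition). All thresholds can be set per run via
flags or a YAML config; every run directory contains `config.yaml` and
`run.log` with input digests.

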