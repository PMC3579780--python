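"""Promoter-clade evolution simulator with known ground truth.

Generates an ancestral upstream region, evolves it along a star or balanced
binary tree with per-branch substitution and indel probabilities, and tracks
the coordinates of a planted constrained element (the synthetic ECR) through
every mutation, so that detection pipelines can be scored against truth.
Selection is modeled as a single constraint factor multiplying both mutation
probabilities inside masked intervals.  Motif instances (a PWM's consensus
string) can be planted at homologous positions inside the element - these
survive by construction, emulating conserved binding sites - and at
species-specific background positions, which do not correspond across
species.

The branch process uses per-branch probabilities rather than rates with
time: simpler, and sufficient for truth-known benchmarking.  All operations
are deterministic for a fixed seed; per-operation streams are spawned from
the single clade seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqcoords import GenomicInterval, SequenceRecord, write_bed, write_fasta
from .tfbs import PWM

_BASES = "ACGT"


@dataclass(frozen=True)
class EvolutionParams:
    """Per-branch mutation probabilities.

    Defaults emulate a mammal-scale promoter comparison: each branch of a
    two-branch (pair) comparison at the defaults accumulates ~15%
    substitutions and ~2% indel initiations (geometric lengths, mean 3 nt),
    i.e. ~30% substitution divergence between the pair, with the constrained
    element mutating at one sixth of the background rate (~5% pairwise).
    """

    sub_prob: float = 0.15
    indel_prob: float = 0.02
    indel_mean_len: float = 3.0
    constraint_factor: float = 1.0 / 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_prob", "indel_prob"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0 <= self.constraint_factor <= 1):
            raise ValueError("constraint_factor must be in [0, 1]")
        if self.indel_mean_len < 1:
            raise ValueError("indel_mean_len must be >= 1")


@dataclass
class PlantedMotif:
    interval: GenomicInterval
    inside: bool


@dataclass
class CladeTruth:
    """Simulated species set with true element/motif coordinates."""

    records: list[SequenceRecord]
    element_intervals: dict[str, GenomicInterval]
    motif_intervals: dict[str, list[PlantedMotif]]
    tree: str
    ancestor: SequenceRecord
    ancestor_element: GenomicInterval | None
    maps: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def record(self, species: str) -> SequenceRecord:
        return next(r for r in self.records if r.id == species)


def simulate_ancestor(length: int, gc: float = 0.45,
                      seed: int = 0) -> SequenceRecord:
    """I.i.d. ancestral sequence with P(G) = P(C) = gc/2."""
    if length < 100:
        raise ValueError("length must be >= 100")
    if not (0 < gc < 1):
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))
    return SequenceRecord(id="ancestor", sequence=seq)


def _site_factors(length: int, masks, factor: float) -> np.ndarray:
    f = np.ones(length)
    for iv in masks:
        if iv.start < 1 or iv.end > length:
            raise ValueError("constraint mask outside the sequence")
        f[iv.start - 1:iv.end] = factor
    return f


def evolve_branch(rec: SequenceRecord, params: EvolutionParams,
                  constraint_mask=(), rng: np.random.Generator | None = None,
                  frozen_mask=(), out_id: str | None = None
                  ) -> tuple[SequenceRecord, np.ndarray]:
    """Mutate a sequence along one branch; returns (child, coordinate map).

    Substitutions hit each site with ``sub_prob`` (scaled by
    ``constraint_factor`` inside ``constraint_mask`` intervals, and by zero
    inside ``frozen_mask``); indels initiate per site with ``indel_prob``
    (same scaling), equiprobably an insertion (new i.i.d. bases placed before
    the site) or a deletion (the next L sites removed), with geometric
    lengths of mean ``indel_mean_len``.

    The coordinate map is an array over the parent's 0-based positions
    holding each surviving base's 0-based child position, or -1 for deleted
    sites; it is strictly increasing over surviving sites.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = len(rec)
    factors = _site_factors(L, constraint_mask, params.constraint_factor)
    for iv in frozen_mask:
        factors[iv.start - 1:iv.end] = 0.0
    p_sub = params.sub_prob * factors
    p_indel = params.indel_prob * factors
    sub_draw = rng.random(L)
    indel_draw = rng.random(L)
    base_shift = rng.integers(1, 4, size=L)
    codes = {c: k for k, c in enumerate(_BASES)}
    geo_p = 1.0 / params.indel_mean_len
    out: list[str] = []
    cmap = np.full(L, -1, dtype=np.int64)
    i = 0
    while i < L:
        if indel_draw[i] < p_indel[i]:
            ln = int(rng.geometric(geo_p))
            if rng.random() < 0.5:  # deletion of sites i .. i+ln-1
                i += ln
                continue
            out.extend(_BASES[k] for k in rng.integers(0, 4, size=ln))
        c = rec.sequence[i]
        if c != "N" and sub_draw[i] < p_sub[i]:
            c = _BASES[(codes[c] + int(base_shift[i])) % 4]
        cmap[i] = len(out)
        out.append(c)
        i += 1
    child = SequenceRecord(id=out_id or rec.id, sequence="".join(out),
                           species=rec.species if out_id is None else out_id)
    return child, cmap


def remap_interval(iv: GenomicInterval, cmap: np.ndarray,
                   seq_id: str | None = None) -> GenomicInterval | None:
    """Push a 1-based interval through a coordinate map; None if fully deleted."""
    surv = cmap[iv.start - 1:iv.end]
    surv = surv[surv >= 0]
    if surv.size == 0:
        return None
    return GenomicInterval(seq_id or iv.seq_id, int(surv.min()) + 1,
                           int(surv.max()) + 1, strand=iv.strand)


def compose_maps(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Coordinate map of applying ``first`` then ``second``."""
    out = np.full(len(first), -1, dtype=np.int64)
    alive = first >= 0
    out[alive] = second[first[alive]]
    return out


def _species_names(n: int) -> list[str]:
    return [f"sp{k + 1:02d}" for k in range(n)]


def simulate_clade(n_species: int = 10, tree_shape: str = "star",
                   ancestor_len: int = 5000,
                   element: tuple[int, int] | None = (3300, 3699),
                   params: EvolutionParams = EvolutionParams(),
                   gc: float = 0.45,
                   branch_scales: list[float] | None = None) -> CladeTruth:
    """Evolve an ancestor into a clade with a planted constrained element.

    ``star`` evolves each species independently from the ancestor;
    ``balanced`` recursively bisects the species set along a balanced binary
    tree, applying one branch of evolution per edge (so species in the same
    subtree share derived mutations).  ``branch_scales`` (star only)
    multiplies both mutation probabilities on individual branches, producing
    unequal divergences with known ordering.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if tree_shape not in ("star", "balanced"):
        raise ValueError(f"unknown tree_shape {tree_shape!r}")
    seed_seq = np.random.SeedSequence(params.seed)
    anc_seed, *branch_seeds = seed_seq.spawn(1 + 2 * n_species)
    ancestor = simulate_ancestor(ancestor_len, gc,
                                 seed=np.random.default_rng(anc_seed).integers(2**31))
    mask = []
    anc_element = None
    if element is not None:
        anc_element = GenomicInterval("ancestor", element[0], element[1])
        mask = [anc_element]
    names = _species_names(n_species)
    records: list[SequenceRecord] = []
    maps: dict[str, np.ndarray] = {}
    if tree_shape == "star":
        scales = branch_scales or [1.0] * n_species
        if len(scales) != n_species:
            raise ValueError("branch_scales must have one entry per species")
        for name, scale, bseed in zip(names, scales, branch_seeds):
            bp = replace(params, sub_prob=params.sub_prob * scale,
                         indel_prob=params.indel_prob * scale)
            child, cmap = evolve_branch(
                ancestor, bp, constraint_mask=mask,
                rng=np.random.default_rng(bseed), out_id=name)
            records.append(child)
            maps[name] = cmap
        branches = ",".join(f"{n}:{params.sub_prob * s:.4f}"
                            for n, s in zip(names, scales))
        tree = f"({branches});"
    else:
        if branch_scales is not None:
            raise ValueError("branch_scales applies to star trees only")
        seed_iter = iter(branch_seeds)

        def _mask_for(cmap: np.ndarray):
            if anc_element is None:
                return []
            iv = remap_interval(anc_element, cmap)
            return [iv] if iv is not None else []

        def _descend(seq: SequenceRecord, cmap: np.ndarray,
                     leaves: list[str]) -> str:
            if len(leaves) == 1:
                records.append(replace(seq, id=leaves[0], species=leaves[0]))
                maps[leaves[0]] = cmap
                return f"{leaves[0]}:{params.sub_prob:.4f}"
            half = (len(leaves) + 1) // 2
            subtrees = []
            for part in (leaves[:half], leaves[half:]):
                child, edge_map = evolve_branch(
                    seq, params, constraint_mask=_mask_for(cmap),
                    rng=np.random.default_rng(next(seed_iter)))
                subtrees.append(_descend(child, compose_maps(cmap, edge_map), part))
            return f"({subtrees[0]},{subtrees[1]}):{params.sub_prob:.4f}"

        cmap_identity = np.arange(ancestor_len, dtype=np.int64)
        tree = _descend(ancestor, cmap_identity, names)[: -len(f":{params.sub_prob:.4f}")] + ";"
    element_intervals = {}
    if anc_element is not None:
        for name in names:
            iv = remap_interval(anc_element, maps[name], seq_id=name)
            if iv is None:
                raise RuntimeError(
                    f"planted element fully deleted in {name}; "
                    "lower indel_prob or raise the constraint")
            element_intervals[name] = iv
    return CladeTruth(records=records, element_intervals=element_intervals,
                      motif_intervals={n: [] for n in names}, tree=tree,
                      ancestor=ancestor, ancestor_element=anc_element,
                      maps=maps)


def plant_motifs(clade: CladeTruth, pwm: PWM, n_inside: int = 0,
                 n_outside: int = 0, seed: int = 0) -> CladeTruth:
    """Write PWM consensus instances into a simulated clade.

    Inside motifs are placed at non-overlapping positions of the ancestral
    element and written at the homologous (coordinate-mapped) position of
    every species, so they are perfectly conserved - the synthetic analogue
    of binding sites preserved by selection.  Outside motifs are placed at
    species-specific random background positions and are not shared across
    species.  Truth intervals are recorded per species; the clade is
    modified in place and returned.
    """
    rng = np.random.default_rng(seed)
    W = pwm.width
    cons = pwm.consensus
    seqs = {r.id: list(r.sequence) for r in clade.records}
    if n_inside:
        if clade.ancestor_element is None:
            raise ValueError("clade has no planted element to put motifs inside")
        elem = clade.ancestor_element
        if elem.length < n_inside * (W + 2):
            raise ValueError("element too short for the requested inside motifs")
        starts: list[int] = []
        candidates = rng.permutation(np.arange(elem.start, elem.end - W + 2))
        for cand in candidates:
            cand = int(cand)
            if all(abs(cand - s) >= W + 1 for s in starts):
                # the site must survive (map cleanly) in every species
                spots = {}
                ok = True
                for r in clade.records:
                    m = clade.maps[r.id]
                    new0 = int(m[cand - 1])
                    if new0 < 0 or new0 + W > len(seqs[r.id]):
                        ok = False
                        break
                    spots[r.id] = new0
                if ok:
                    starts.append(cand)
                    for rid, new0 in spots.items():
                        seqs[rid][new0:new0 + W] = cons
                        clade.motif_intervals[rid].append(PlantedMotif(
                            GenomicInterval(rid, new0 + 1, new0 + W), True))
            if len(starts) == n_inside:
                break
        if len(starts) < n_inside:
            raise ValueError("could not place all inside motifs without overlap")
    if n_outside:
        for r in clade.records:
            elem_iv = clade.element_intervals.get(r.id)
            placed: list[int] = []
            tries = 0
            L = len(seqs[r.id])
            while len(placed) < n_outside:
                tries += 1
                if tries > 10000:
                    raise ValueError("could not place outside motifs")
                cand = int(rng.integers(1, L - W + 2))
                if elem_iv is not None and not (
                        cand + W - 1 < elem_iv.start - W or cand > elem_iv.end + W):
                    continue
                if any(abs(cand - p) < W + 1 for p in placed):
                    continue
                placed.append(cand)
                seqs[r.id][cand - 1:cand - 1 + W] = cons
                clade.motif_intervals[r.id].append(PlantedMotif(
                    GenomicInterval(r.id, cand, cand + W - 1), False))
    for r in clade.records:
        r.sequence = "".join(seqs[r.id])
    return clade


def write_clade(clade: CladeTruth, directory) -> None:
    """Emit FASTA, truth BED files, and the newick tree."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(clade.records, directory / "clade.fasta")
    if clade.element_intervals:
        ivs = list(clade.element_intervals.values())
        write_bed(ivs, directory / "truth_elements.bed",
                  names=["element"] * len(ivs))
    motifs = [(m.interval, "inside" if m.inside else "outside")
              for lst in clade.motif_intervals.values() for m in lst]
    if motifs:
        write_bed([m[0] for m in motifs], directory / "truth_motifs.bed",
                  names=[m[1] for m in motifs])
    (directory / "tree.nwk").write_text(clade.tree + "\n")
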