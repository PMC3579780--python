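import numpy as np
import pytest
from scipy.stats import binom

from conftest import make_pwm

from ecrkit.seqcoords import GenomicInterval, SequenceRecord, gc_content
from ecrkit.simulate import (
    CladeTruth,
    EvolutionParams,
    evolve_branch,
    plant_motifs,
    remap_interval,
    simulate_ancestor,
    simulate_clade,
    write_clade,
)


class TestAncestor:
    def test_deterministic(self):
        assert simulate_ancestor(500, seed=7).sequence == \
            simulate_ancestor(500, seed=7).sequence

    def test_gc_within_binomial_bounds(self):
        seq = simulate_ancestor(10000, gc=0.45, seed=1).sequence
        lo, hi = binom.ppf([0.005, 0.995], 10000, 0.45) / 10000
        assert lo <= gc_content(seq) <= hi

    def test_degenerate_gc_rejected(self):
        with pytest.raises(ValueError):
            simulate_ancestor(500, gc=0.0)
        with pytest.raises(ValueError):
            simulate_ancestor(50)


class TestEvolveBranch:
    def test_zero_rates_identity(self):
        rec = simulate_ancestor(1000, seed=0)
        child, cmap = evolve_branch(rec, EvolutionParams(sub_prob=0, indel_prob=0))
        assert child.sequence == rec.sequence
        assert np.array_equal(cmap, np.arange(1000))

    def test_substitution_count_binomial(self):
        rec = simulate_ancestor(10000, seed=3)
        child, cmap = evolve_branch(
            rec, EvolutionParams(sub_prob=0.1, indel_prob=0.0, seed=11))
        subs = sum(1 for i, j in enumerate(cmap)
                   if rec.sequence[i] != child.sequence[j])
        lo, hi = binom.ppf([0.005, 0.995], 10000, 0.1)
        assert lo <= subs <= hi

    def test_coordinate_map_strictly_monotone(self):
        rec = simulate_ancestor(3000, seed=5)
        for seed in range(10):
            _, cmap = evolve_branch(
                rec, EvolutionParams(sub_prob=0.2, indel_prob=0.05, seed=seed))
            surviving = cmap[cmap >= 0]
            assert np.all(np.diff(surviving) > 0)

    def test_constraint_suppresses_divergence(self):
        """Constrained interval must diverge less than background in
        essentially every replicate."""
        rec = simulate_ancestor(2000, seed=1)
        mask = [GenomicInterval("ancestor", 801, 1200)]
        wins = 0
        for seed in range(50):
            child, cmap = evolve_branch(
                rec, EvolutionParams(sub_prob=0.2, indel_prob=0.02,
                                     constraint_factor=0.1, seed=seed),
                constraint_mask=mask)
            def div(lo, hi):
                idx = range(lo - 1, hi)
                changed = sum(1 for i in idx
                              if cmap[i] < 0
                              or rec.sequence[i] != child.sequence[cmap[i]])
                return changed / len(list(idx))
            inside = div(801, 1200)
            outside = (div(1, 800) + div(1201, 2000)) / 2
            wins += inside < outside
        assert wins >= 49

    def test_remap_interval_tracks_element(self):
        rec = simulate_ancestor(2000, seed=2)
        iv = GenomicInterval("ancestor", 801, 1200)
        child, cmap = evolve_branch(
            rec, EvolutionParams(sub_prob=0.15, indel_prob=0.03, seed=4),
            constraint_mask=[iv])
        out = remap_interval(iv, cmap)
        assert out is not None
        assert 1 <= out.start <= out.end <= len(child)


class TestSimulateClade:
    def test_zero_rates_identical_species(self):
        clade = simulate_clade(
            n_species=2, ancestor_len=500, element=(200, 299),
            params=EvolutionParams(sub_prob=0, indel_prob=0))
        assert clade.records[0].sequence == clade.records[1].sequence \
            == clade.ancestor.sequence

    def test_outputs_deterministic(self, tmp_path):
        for d in ("a", "b"):
            clade = simulate_clade(n_species=4, ancestor_len=600,
                                   element=(200, 399),
                                   params=EvolutionParams(seed=13))
            plant_motifs(clade, make_pwm("TGACTACG"), n_inside=2,
                         n_outside=2, seed=14)
            write_clade(clade, tmp_path / d)
        for name in ("clade.fasta", "truth_elements.bed", "truth_motifs.bed",
                     "tree.nwk"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_truth_intervals_inside_sequences(self):
        clade = simulate_clade(n_species=6, params=EvolutionParams(seed=8))
        for rec in clade.records:
            iv = clade.element_intervals[rec.id]
            assert 1 <= iv.start <= iv.end <= len(rec)

    def test_balanced_tree_depth_orders_divergence(self):
        """Sibling species must be less diverged than cross-subtree pairs."""
        def pairwise_div(r1, r2, clade):
            m1, m2 = clade.maps[r1.id], clade.maps[r2.id]
            shared = [(i, j) for i, j in zip(m1, m2) if i >= 0 and j >= 0]
            same = sum(1 for i, j in shared
                       if r1.sequence[i] == r2.sequence[j])
            return 1 - same / len(shared)

        sib, cross = [], []
        for seed in range(10):
            clade = simulate_clade(
                n_species=4, tree_shape="balanced", ancestor_len=800,
                element=None, params=EvolutionParams(sub_prob=0.06,
                                                     indel_prob=0.005,
                                                     seed=seed))
            recs = {r.id: r for r in clade.records}
            sib.append(pairwise_div(recs["sp01"], recs["sp02"], clade))
            cross.append(pairwise_div(recs["sp01"], recs["sp03"], clade))
        assert np.mean(sib) < np.mean(cross)

    def test_constraint_factor_monotonicity(self):
        """Lowering the constraint factor raises element conservation."""
        mean_ident = []
        for factor in (1.0, 0.5, 0.1):
            vals = []
            for seed in range(10):
                clade = simulate_clade(
                    n_species=2, ancestor_len=1500, element=(500, 899),
                    params=EvolutionParams(sub_prob=0.2, indel_prob=0.02,
                                           constraint_factor=factor,
                                           seed=seed))
                # element identity between the two species via ancestor maps
                r1, r2 = clade.records
                m1, m2 = clade.maps[r1.id], clade.maps[r2.id]
                idx = range(499, 899)
                shared = [(m1[i], m2[i]) for i in idx if m1[i] >= 0 and m2[i] >= 0]
                same = sum(1 for i, j in shared
                           if r1.sequence[i] == r2.sequence[j])
                vals.append(same / len(shared))
            mean_ident.append(np.mean(vals))
        assert mean_ident[0] < mean_ident[1] < mean_ident[2]


class TestPlantMotifs:
    def test_inside_motifs_identical_across_species(self, toy_pwm):
        clade = simulate_clade(n_species=3, ancestor_len=1000,
                               element=(400, 699),
                               params=EvolutionParams(seed=21))
        plant_motifs(clade, toy_pwm, n_inside=3, seed=5)
        for rec in clade.records:
            motifs = clade.motif_intervals[rec.id]
            assert len(motifs) == 3
            for m in motifs:
                assert rec.sequence[m.interval.start - 1:m.interval.end] == \
                    toy_pwm.consensus

    def test_outside_motifs_avoid_element(self, toy_pwm):
        clade = simulate_clade(n_species=2, ancestor_len=1500,
                               element=(500, 899),
                               params=EvolutionParams(seed=22))
        plant_motifs(clade, toy_pwm, n_outside=5, seed=6)
        for rec in clade.records:
            elem = clade.element_intervals[rec.id]
            for m in clade.motif_intervals[rec.id]:
                assert m.interval.end < elem.start or m.interval.start > elem.end

    def test_insufficient_room_rejected(self, toy_pwm):
        clade = simulate_clade(n_species=2, ancestor_len=500,
                               element=(200, 229),
                               params=EvolutionParams(sub_prob=0, indel_prob=0))
        with pytest.raises(ValueError):
            plant_motifs(clade, toy_pwm, n_inside=10)
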