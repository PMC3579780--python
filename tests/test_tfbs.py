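import math

import numpy as np
import pytest

from conftest import make_pwm, random_seq
from oracles import bh_adjust, rescore_pwm_offsets

from ecrkit.pairwise import GenomicInterval, PairwiseAlignment, global_align
from ecrkit.seqcoords import reverse_complement
from ecrkit.tfbs import (
    PWM,
    benjamini_hochberg,
    conserved_sites,
    hits_frame,
    occupancy_affinity,
    pwm_scan,
    read_jaspar,
    site_block_partition,
)
from ecrkit.conservation import ConservedBlock


class TestPwm:
    def test_invariants(self):
        with pytest.raises(ValueError):
            PWM("bad", np.ones((4, 3)))  # too narrow
        with pytest.raises(ValueError):
            PWM("bad", -np.ones((4, 6)))

    def test_probabilities_positive_and_normalized(self, toy_pwm):
        p = toy_pwm.probabilities
        assert (p > 0).all()
        assert np.allclose(p.sum(axis=0), 1.0)

    def test_jaspar_roundtrip(self, tmp_path, toy_pwm):
        p = tmp_path / "toy.jaspar"
        lines = [">MA0000.1 toy"]
        for base, row in zip("ACGT", toy_pwm.matrix):
            lines.append(f"{base} [ " + " ".join(str(int(v)) for v in row) + " ]")
        p.write_text("\n".join(lines) + "\n")
        (back,) = read_jaspar(p)
        assert np.allclose(back.matrix, toy_pwm.matrix)
        assert back.consensus == toy_pwm.consensus


class TestPwmScan:
    def test_consensus_site_scores_one(self, toy_pwm):
        hits = pwm_scan(toy_pwm.consensus, toy_pwm, both_strands=False)
        (hit,) = hits
        assert hit.interval.start == 1
        assert hit.relative_score == pytest.approx(1.0)

    def test_threshold_one_rejects_single_mismatch(self, toy_pwm):
        seq = "A" + toy_pwm.consensus[1:]
        assert pwm_scan(seq, toy_pwm, min_relative_score=1.0,
                        both_strands=False) == []

    def test_reverse_strand_coordinates(self, toy_pwm):
        seq = "A" * 20 + reverse_complement(toy_pwm.consensus) + "A" * 20
        hits = [h for h in pwm_scan(seq, toy_pwm, min_relative_score=0.99)
                if h.strand == "-"]
        (hit,) = hits
        assert (hit.interval.start, hit.interval.end) == (21, 28)

    def test_matches_exhaustive_rescoring(self, rng, toy_pwm):
        """Hit set and scores equal an independent per-offset recount."""
        for _ in range(20):
            seq = random_seq(rng, 500)
            scores = rescore_pwm_offsets(seq, toy_pwm)
            smin, smax = toy_pwm.score_range
            expected = {o + 1 for o, s in enumerate(scores)
                        if (s - smin) / (smax - smin) >= 0.8}
            got = {h.interval.start
                   for h in pwm_scan(seq, toy_pwm, 0.8, both_strands=False)}
            assert got == expected

    def test_wider_pwm_than_sequence_warns_empty(self, toy_pwm):
        assert pwm_scan("ACGT", toy_pwm) == []

    def test_n_contributes_background_expectation(self, toy_pwm):
        hit_n = pwm_scan("N" * 8, toy_pwm, min_relative_score=0.0,
                         both_strands=False)
        assert hit_n[0].log_odds == pytest.approx(0.0)


class TestConservedSites:
    def _identity_alignment(self, seq):
        return PairwiseAlignment(seq, seq,
                                 a_span=GenomicInterval("a", 1, len(seq)),
                                 b_span=GenomicInterval("b", 1, len(seq)))

    def test_identical_sequences_conserve_everything(self, rng, toy_pwm):
        seq = random_seq(rng, 200) + toy_pwm.consensus + random_seq(rng, 200)
        aln = self._identity_alignment(seq)
        hits = pwm_scan(seq, toy_pwm, seq_id="a")
        sites = conserved_sites(aln, hits, hits)
        assert len(sites) == len(hits)
        assert all(s.flank_identity == 1.0 for s in sites)

    def test_site_in_one_species_only_not_conserved(self, rng, toy_pwm):
        bg = random_seq(rng, 400)
        a = bg[:200] + toy_pwm.consensus + bg[200:]
        b = bg[:200] + "A" * 8 + bg[200:]
        aln = global_align(a, b)
        sites = conserved_sites(aln, pwm_scan(a, toy_pwm, seq_id="a"),
                                pwm_scan(b, toy_pwm, seq_id="b"))
        assert not any(201 <= s.hit_ref.interval.start <= 208 for s in sites)

    def test_degraded_flank_excluded(self, rng, toy_pwm):
        # motif shared, but every flank base differs between the species
        bg = random_seq(rng, 300)
        flank_a = "A" * 20
        flank_b = "C" * 20
        a = bg[:150] + flank_a + toy_pwm.consensus + flank_a + bg[150:]
        b = bg[:150] + flank_b + toy_pwm.consensus + flank_b + bg[150:]
        aln = global_align(a, b)
        sites = conserved_sites(aln, pwm_scan(a, toy_pwm, seq_id="a"),
                                pwm_scan(b, toy_pwm, seq_id="b"),
                                min_flank_identity=0.8)
        assert not any(s.hit_ref.interval.start == 171 for s in sites)

    def test_flank_threshold_monotonicity(self, rng, toy_pwm):
        from ecrkit.simulate import EvolutionParams, simulate_clade, plant_motifs
        clade = simulate_clade(n_species=2, ancestor_len=2000,
                               element=(800, 1199),
                               params=EvolutionParams(seed=3))
        plant_motifs(clade, toy_pwm, n_inside=4, n_outside=3, seed=7)
        r1, r2 = clade.records
        aln = global_align(r1.sequence, r2.sequence, seq_id_a=r1.id,
                           seq_id_b=r2.id)
        ha = pwm_scan(r1.sequence, toy_pwm, seq_id=r1.id)
        hb = pwm_scan(r2.sequence, toy_pwm, seq_id=r2.id)
        sizes = [len(conserved_sites(aln, ha, hb, min_flank_identity=t))
                 for t in (0.0, 0.5, 0.8, 0.95, 1.0)]
        assert sizes == sorted(sizes, reverse=True)
        refs = {id(s.hit_ref) for s in conserved_sites(aln, ha, hb)}
        assert refs <= {id(h) for h in ha}


class TestOccupancyAffinity:
    def test_perfect_site_beats_degraded(self, rng, toy_pwm):
        bg = random_seq(rng, 100)
        good = bg[:50] + toy_pwm.consensus + bg[50:]
        degraded = bg[:50] + "".join(
            "ACGT"[(("ACGT".index(c)) + 2) % 4] for c in toy_pwm.consensus
        ) + bg[50:]
        assert occupancy_affinity(good, toy_pwm) > occupancy_affinity(degraded, toy_pwm)

    def test_reverse_complement_invariant(self, rng, toy_pwm):
        seq = random_seq(rng, 300)
        assert occupancy_affinity(seq, toy_pwm) == pytest.approx(
            occupancy_affinity(reverse_complement(seq), toy_pwm))

    def test_concatenation_additivity(self, rng, toy_pwm):
        """Affinity decomposes over offsets; concatenation adds interior
        contributions plus the boundary-spanning offsets."""
        s1, s2 = random_seq(rng, 80), random_seq(rng, 80)
        joint = occupancy_affinity(s1 + s2, toy_pwm)
        assert joint >= occupancy_affinity(s1, toy_pwm) + \
            occupancy_affinity(s2, toy_pwm) - 1e-9

    def test_all_n_equals_background_baseline(self, toy_pwm):
        W = toy_pwm.width
        probs = toy_pwm.probabilities
        em = np.log(probs.max(axis=0)[None, :] / probs)
        e_bg = float((toy_pwm.background[:, None] * em).sum())
        r0 = math.exp(0.584 * W - 5.66)
        q = r0 * math.exp(-e_bg / 0.7)
        expected = 2 * q / (1 + q)  # one offset per strand
        assert occupancy_affinity("N" * W, toy_pwm) == pytest.approx(expected)

    def test_too_short_sequence_rejected(self, toy_pwm):
        with pytest.raises(ValueError):
            occupancy_affinity("ACG", toy_pwm)


class TestBenjaminiHochberg:
    def test_all_ones_no_rejections(self):
        reject, adj = benjamini_hochberg([1.0] * 10, alpha=0.05)
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_single_p_unchanged(self):
        reject, adj = benjamini_hochberg([0.03], alpha=0.05)
        assert adj[0] == pytest.approx(0.03) and reject[0]

    def test_textbook_stepup(self):
        reject, adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])
        assert list(reject) == [True, True, True, False]

    def test_matches_hand_stepup_and_dominates_bonferroni(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            p = rng.random(n)
            reject, adj = benjamini_hochberg(p, alpha=0.1)
            assert np.allclose(adj, bh_adjust(list(p)))
            bonferroni = p * n <= 0.1
            assert (reject | ~bonferroni).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestPartition:
    def _site(self, start, end):
        from ecrkit.tfbs import TFBSHit
        return TFBSHit("m", GenomicInterval("a", start, end), "+", 1.0, 0.9)

    def test_no_blocks_fraction_zero(self):
        part = site_block_partition([self._site(5, 12)], [])
        assert part == {"inside": 0, "outside": 1, "fraction_inside": 0.0}

    def test_blocks_cover_everything(self):
        blocks = [ConservedBlock(GenomicInterval("a", 1, 1000), 0.9)]
        part = site_block_partition([self._site(5, 12), self._site(700, 707)],
                                    blocks)
        assert part["fraction_inside"] == 1.0

    def test_straddling_site_counts_outside(self):
        blocks = [ConservedBlock(GenomicInterval("a", 100, 200), 0.9)]
        part = site_block_partition([self._site(195, 205)], blocks)
        assert part["inside"] == 0
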