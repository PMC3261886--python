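import math

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from coaldelta.coalsim import simulate_gene_genealogy
from coaldelta.design import (MarkerProfile, SpeciesTree, build_focal_tree,
                              mitochondrial_profile, nuclear_profile)
from coaldelta.genetrees import (EstimatedGeneTree, GeneTreeEstimator,
                                 estimate_gene_tree, kscore_rescale,
                                 langley_fitch_clock, ml_pairwise_distance,
                                 tau_prior_mean, tmrca_sp1_sp2)
from coaldelta.seqsim import Alignment, evolve_alignment


def jc_profile(L=1000):
    return MarkerProfile("nuclear", 1.0, 1.0, kappa=1.0, gamma_shape=1.0,
                         n_categories=1, length=L, per_lineage_rate=0.001)


class TestPairwiseDistance:
    def test_jc_closed_form(self):
        """kappa=1 limit: d = -(3/4) ln(1 - 4p/3) at p = 0.1."""
        n = 10000
        n_diff = 1000
        d, sat = ml_pairwise_distance(n - n_diff, n_diff // 2,
                                      n_diff - n_diff // 2, kappa=1.0,
                                      gamma_shape=1.0, n_categories=1)
        assert not sat
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3),
                                  rel=1e-4)

    def test_saturation_capped_and_flagged(self):
        d, sat = ml_pairwise_distance(200, 400, 400, kappa=2.0,
                                      gamma_shape=1.0, max_distance=5.0)
        assert sat and d == 5.0

    def test_zero_divergence(self):
        d, sat = ml_pairwise_distance(1000, 0, 0, 2.0, 1.0)
        assert d == 0.0 and not sat

    def test_gamma_correction_increases_distance(self):
        # same counts, rate heterogeneity implies more multiple hits
        d1, _ = ml_pairwise_distance(800, 100, 100, 2.0, 1.0, 1)
        d4, _ = ml_pairwise_distance(800, 100, 100, 2.0, 1.0, 4)
        assert d4 > d1


class TestEstimation:
    def test_nj_recovers_topology_and_lengths_from_long_sequences(self):
        """Statistical consistency on near-exact distances (L=200k)."""
        # fixed 4-tip genealogy with known branch lengths
        g_parent = [4, 4, 5, 6, 5, 6, -1]
        ages = [0.0, 0.0, 0.0, 0.0, 0.01, 0.03, 0.08]
        from coaldelta.coalsim import GeneTree
        g = GeneTree(["sp1_1", "sp2_1", "sp3_1", "sp4_1"], [0, 1, 2, 3],
                     g_parent, ages)
        prof = jc_profile(L=200000)
        aln = evolve_alignment(g, prof, 3)
        tree = estimate_gene_tree([aln])
        # topology: sp1,sp2 form a cherry
        ch = tree.children()
        cherries = [{tree.labels[c] for c in ch[v]}
                    for v in range(tree.n_nodes)
                    if ch[v] and all(c < tree.n_tips for c in ch[v])]
        assert {"sp1_1", "sp2_1"} in cherries
        # patristic sp1-sp2 distance ~ 0.02 within 2%
        est = GeneTreeEstimator(clock=False).fit([aln])
        i, j = aln.labels.index("sp1_1"), aln.labels.index("sp2_1")
        assert est.distance_matrix_[i, j] == pytest.approx(0.02, rel=0.02)

    def test_zero_divergence_flagged(self):
        data = np.zeros((4, 100), dtype=np.int8)
        aln = Alignment(["sp1_1", "sp2_1", "sp3_1", "sp4_1"], data,
                        jc_profile(100))
        est = GeneTreeEstimator().fit([aln])
        assert "zero_divergence" in est.flags_
        assert np.all(est.tree_.length == 0)

    def test_requires_outgroup(self):
        data = np.zeros((4, 10), dtype=np.int8)
        aln = Alignment(["sp1_1", "sp1_2", "sp2_1", "sp3_1"], data,
                        jc_profile(10))
        with pytest.raises(ValueError):
            GeneTreeEstimator(outgroup="sp9").fit([aln])


class TestLangleyFitch:
    def test_two_taxon_root_age_is_mean(self):
        t = EstimatedGeneTree(["sp1_1", "sp2_1"], [2, 2, -1],
                              [0.1, 0.2, 0.0])
        out = langley_fitch_clock(t, 1000.0)
        assert out.age[out.root] == pytest.approx(0.15, rel=1e-8)

    def test_ultrametric_input_unchanged(self):
        # balanced 4-tip ultrametric tree
        t = EstimatedGeneTree(
            ["sp1_1", "sp2_1", "sp3_1", "sp4_1"],
            [4, 4, 5, 5, 6, 6, -1],
            [0.01, 0.01, 0.03, 0.03, 0.04, 0.02, 0.0])
        out = langley_fitch_clock(t, 1000.0)
        assert out.age[4] == pytest.approx(0.01, abs=1e-8)
        assert out.age[5] == pytest.approx(0.03, abs=1e-8)
        assert out.age[6] == pytest.approx(0.05, abs=1e-8)

    def test_matches_brute_force_three_taxon(self):
        """Coordinate-ascent optimum equals a direct numeric optimum."""
        lengths = np.array([0.12, 0.05, 0.33, 0.08, 0.0])
        t = EstimatedGeneTree(["sp1_1", "sp2_1", "sp3_1"],
                              [3, 3, 4, 4, -1], lengths)
        L = 500.0
        out = langley_fitch_clock(t, L)

        def negll(x):
            a3, a4 = x
            if not (0 < a3 < a4):
                return 1e9
            mus = np.array([a3, a3, (2 * a4 - a3 - 0.0)]) * L
            ns = np.array([0.12, 0.05, 0.33 + 0.08]) * L
            return -(np.sum(ns * np.log(mus) - mus))

        best = min((minimize(negll, x0, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12})
                    for x0 in ([0.1, 0.2], [0.05, 0.3], [0.2, 0.25])),
                   key=lambda r: r.fun)
        assert out.age[3] == pytest.approx(best.x[0], rel=1e-5)
        assert out.age[4] == pytest.approx(best.x[1], rel=1e-5)

    def test_unrooted_input_raises(self):
        with pytest.raises(ValueError):
            langley_fitch_clock(
                EstimatedGeneTree(["a", "b"], [1, 0], [0.1, 0.0]))


class TestKScore:
    def _clock_pair(self):
        ref = EstimatedGeneTree(
            ["sp1_1", "sp2_1", "sp3_1", "sp4_1"],
            [4, 4, 5, 5, 6, 6, -1],
            [0.02, 0.01, 0.05, 0.06, 0.01, 0.02, 0.0])
        clk = langley_fitch_clock(ref, 1000.0)
        return ref, clk

    def test_identity_when_reference_is_clock(self):
        _, clk = self._clock_pair()
        out = kscore_rescale(clk, clk)
        assert out.scale_factor == pytest.approx(1.0, rel=1e-12)

    def test_exact_proportionality(self):
        ref, clk = self._clock_pair()
        doubled = clk.copy()
        doubled.length = clk.length * 2
        out = kscore_rescale(doubled, clk)
        assert out.scale_factor == pytest.approx(0.5, rel=1e-12)

    def test_matches_scalar_least_squares(self):
        ref, clk = self._clock_pair()
        out = kscore_rescale(clk, ref)
        rc = clk.children()[clk.root]
        b_clk = [clk.length[v] for v in range(clk.n_nodes)
                 if v != clk.root and v not in rc]
        b_ref = [ref.length[v] for v in range(ref.n_nodes)
                 if v != ref.root and v not in rc]
        b_clk.append(sum(clk.length[v] for v in rc))
        b_ref.append(sum(ref.length[v] for v in rc))
        b_clk, b_ref = np.array(b_clk), np.array(b_ref)
        res = minimize_scalar(lambda k: np.sum((b_ref - k * b_clk) ** 2),
                              bounds=(0.0, 10.0), method="bounded",
                              options={"xatol": 1e-12})
        assert out.scale_factor == pytest.approx(res.x, abs=1e-9)

    def test_zero_clock_tree_raises(self):
        ref, clk = self._clock_pair()
        zero = clk.copy()
        zero.length = np.zeros_like(zero.length)
        with pytest.raises(ValueError):
            kscore_rescale(zero, ref)


class TestTmrcaSummaries:
    def _ultra(self, age12=0.027):
        t = EstimatedGeneTree(
            ["sp1_1", "sp2_1", "sp3_1", "sp4_1"],
            [4, 4, 5, 5, 6, 6, -1],
            np.zeros(7))
        t.age = np.array([0, 0, 0, 0, age12, 0.1, 0.2])
        # note: topology (sp1,sp2),(sp3,sp4); sp1+sp2 MRCA at node 4
        return t

    def test_published_conversion_example(self):
        """MRCA age 0.027 at 0.01 subs/site/Myr reads as 2.7 Myr."""
        assert tmrca_sp1_sp2(self._ultra(0.027), 0.01) == pytest.approx(2.7)

    def test_zero_age(self):
        assert tmrca_sp1_sp2(self._ultra(0.0), 0.02) == 0.0

    def test_missing_species_raises(self):
        t = self._ultra()
        t.labels = ["sp1_1", "sp1_2", "sp3_1", "sp4_1"]
        with pytest.raises(ValueError):
            tmrca_sp1_sp2(t, 0.01)

    def test_true_tree_shortcut(self, plain_profile):
        """theta -> 0: clock-free tMRCA equals tau1 exactly."""
        tree = build_focal_tree(2.5e-9, 0.01, 0.5)
        g = simulate_gene_genealogy(tree, plain_profile,
                                    {"sp1": 2, "sp2": 2}, 8)
        assert g.mrca_age(["sp1", "sp2"], tree.labels) / 0.001 == \
            pytest.approx(0.5, rel=1e-3)


class TestTauPriorMean:
    def _tree_with_pairs(self, ages):
        """Caterpillar over sp1_1, sp1_2, sp2_1 with given node ages."""
        t = EstimatedGeneTree(["sp1_1", "sp1_2", "sp2_1"],
                              [3, 3, 4, 4, -1], np.zeros(5))
        t.age = np.array([0.0, 0.0, 0.0, ages[0], ages[1]])
        return t

    def test_mito_rescaling(self):
        t = self._tree_with_pairs([0.002, 0.008])
        assert tau_prior_mean([t], rate_ratio=10.0) == pytest.approx(0.0008)

    def test_average_over_trees(self):
        a = self._tree_with_pairs([0.001, 0.002])
        b = self._tree_with_pairs([0.003, 0.004])
        assert tau_prior_mean([a, b]) == pytest.approx(0.003)

    def test_minimum_below_mean_pairwise(self, focal_tree, mito_profile):
        """Min cross pair <= mean over all cross pairs (brute force)."""
        g = simulate_gene_genealogy(focal_tree, mito_profile,
                                    {"sp1": 4, "sp2": 4}, 21)
        est = EstimatedGeneTree(g.labels, g.parent,
                                np.zeros(g.n_nodes))
        est.age = g.age.copy()
        mn = tau_prior_mean([est])
        pairs = []
        for i in range(4):
            for j in range(4, 8):
                pairs.append(est.age[est.mrca([i, j])])
        assert mn <= np.mean(pairs) + 1e-15
        assert mn == pytest.approx(min(pairs))

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            tau_prior_mean([])


class TestEndToEndCalibration:
    def test_estimated_tmrca_tracks_true_tmrca(self):
        """Estimation noise must not bias the coalescent signal (10%)."""
        tree = build_focal_tree(0.025, 0.01, 1.0)
        prof = mitochondrial_profile(0.01)
        true_t, est_t = [], []
        for rep in range(25):
            g = simulate_gene_genealogy(
                tree, prof, {"sp1": 5, "sp2": 5, "sp3": 1, "sp4": 1},
                1000 + rep)
            aln = evolve_alignment(g, prof, 2000 + rep)
            true_t.append(g.mrca_age(["sp1", "sp2"], tree.labels) / 0.01)
            est_t.append(GeneTreeEstimator().fit([aln]).tmrca_myr())
        assert np.mean(est_t) == pytest.approx(np.mean(true_t), rel=0.10)
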