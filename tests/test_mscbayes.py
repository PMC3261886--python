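import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coaldelta.design import (MarkerProfile, SpeciesTree, build_focal_tree,
                              marker_strategy)
from coaldelta.experiments import simulate_replicate
from coaldelta.genetrees import EstimatedGeneTree
from coaldelta.mscbayes import (MSCDivergenceSampler, MSCPosteriorTrace,
                                PriorSpec, derive_theta_prior,
                                estimate_rate_ratios_external,
                                sample_msc_posterior,
                                summarize_percent_error)


class TestDeriveThetaPrior:
    def test_published_prior_settings(self):
        """mean 0.025, CI (0.003, 0.07) -> Gamma(~2, ~0.0125)."""
        shape, scale = derive_theta_prior(0.025, (0.003, 0.07))
        assert shape == pytest.approx(2.0, rel=0.15)
        assert shape * scale == pytest.approx(0.025, rel=1e-9)
        q = stats.gamma.ppf([0.025, 0.975], shape, scale=scale)
        assert q[0] == pytest.approx(0.003, rel=0.10)
        assert q[1] == pytest.approx(0.07, rel=0.10)

    @pytest.mark.parametrize("k", [0.5, 2.0, 8.0])
    def test_self_consistency(self, k):
        """CI taken from a known Gamma(k, m/k) recovers (k, m/k)."""
        m = 0.025
        q = stats.gamma.ppf([0.025, 0.975], k, scale=m / k)
        shape, scale = derive_theta_prior(m, tuple(q))
        assert shape == pytest.approx(k, rel=0.01)
        assert scale == pytest.approx(m / k, rel=0.01)

    def test_infeasible_interval_raises(self):
        with pytest.raises(ValueError, match="best candidate"):
            derive_theta_prior(0.025, (0.024, 0.026))

    def test_bad_interval_ordering(self):
        with pytest.raises(ValueError):
            derive_theta_prior(0.025, (0.03, 0.07))


class TestTraceAndSummaries:
    def _trace(self, tau1_values):
        df = pd.DataFrame({"tau_sp1sp2": tau1_values,
                           "theta_n0": np.full(len(tau1_values), 0.01)})
        return MSCPosteriorTrace(df, sampling_interval=2, burn_in=10)

    def test_percent_error_arithmetic(self):
        tr = self._trace([0.012] * 10)
        assert summarize_percent_error(tr, 0.01) == pytest.approx(20.0)
        assert summarize_percent_error(self._trace([0.01] * 5), 0.01) == \
            pytest.approx(0.0)

    def test_percent_error_antisymmetry(self):
        up = summarize_percent_error(self._trace([0.012] * 8), 0.01)
        down = summarize_percent_error(self._trace([0.008] * 8), 0.01)
        assert up == pytest.approx(-down)

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            summarize_percent_error(self._trace([]), 0.01)

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(ValueError):
            self._trace([0.01, -0.002])

    def test_hpd_contains_bulk(self):
        rng = np.random.default_rng(0)
        tr = self._trace(rng.gamma(5.0, 0.002, size=4000))
        lo, hi = tr.hpd("tau_sp1sp2", 0.9)
        inside = np.mean((tr.tau1 >= lo) & (tr.tau1 <= hi))
        assert 0.89 <= inside <= 0.92


class TestExternalRates:
    def _tree(self, total, n=4):
        t = EstimatedGeneTree([f"sp{i+1}_1" for i in range(n)],
                              [4, 4, 5, 5, 6, 6, -1][:2 * n - 1],
                              np.full(2 * n - 1, total / (2 * n - 2)))
        t.length[t.root] = 0.0
        return t

    def test_equal_lengths_give_unit_multipliers(self):
        trees = [self._tree(1.0), self._tree(1.0)]
        assert np.allclose(estimate_rate_ratios_external(trees), 1.0)

    def test_tenfold_mito(self):
        trees = [self._tree(1.0)] * 4 + [self._tree(10.0)]
        m = estimate_rate_ratios_external(trees)
        assert m[4] / m[0] == pytest.approx(10.0)
        assert m.mean() == pytest.approx(1.0)

    def test_permutation_equivariance(self):
        trees = [self._tree(x) for x in (1.0, 2.0, 4.0)]
        m = estimate_rate_ratios_external(trees)
        m_perm = estimate_rate_ratios_external(trees[::-1])
        assert np.allclose(m[::-1], m_perm)

    def test_zero_length_tree_raises(self):
        with pytest.raises(ValueError):
            estimate_rate_ratios_external([self._tree(1.0),
                                           self._tree(0.0)])


class TestSamplerBasics:
    def test_zero_information_data_reproduces_prior(self):
        """Constant sites: the tau1 posterior collapses to its prior."""
        st = build_focal_tree(0.025, 0.01, 1.0)
        prof = MarkerProfile("nuclear", 1.0, 1.0, kappa=1.0, gamma_shape=1.0,
                             n_categories=1, length=40,
                             per_lineage_rate=0.001)
        from coaldelta.seqsim import Alignment
        labels = ["sp1_1", "sp1_2", "sp2_1", "sp2_2", "sp3_1", "sp4_1"]
        aln = Alignment(labels, np.zeros((6, 40), dtype=np.int8), prof)
        pr = PriorSpec(tau_mean=0.002)
        est = MSCDivergenceSampler(topology=st, priors=pr, n_iter=12000,
                                   burn_in=1000, thin=6, seed=4)
        est.fit([aln], profiles=[prof])
        tau1 = est.trace_.tau1
        # Exp(0.002) has mean 0.002 and sd 0.002
        assert tau1.mean() == pytest.approx(0.002, rel=0.25)
        assert tau1.std() == pytest.approx(0.002, rel=0.3)

    def test_trace_bookkeeping(self):
        st = build_focal_tree(0.025, 0.01, 1.0)
        profs = marker_strategy("1mit", 0.01)
        alns = simulate_replicate(st, profs,
                                  {"sp1": 2, "sp2": 2, "sp3": 1, "sp4": 1},
                                  5, 0)
        tr = sample_msc_posterior(alns, st, PriorSpec(tau_mean=0.001),
                                  loci=profs,
                                  mcmc={"n_iter": 60, "burn_in": 20,
                                        "thin": 4},
                                  rng_seed=1)
        assert len(tr) == 10  # (60 - 20) / 4
        assert (tr.samples.filter(like="theta") > 0).all().all()

    def test_single_population_grid_posterior_oracle(self):
        """2 sequences, 1 population: MCMC theta posterior vs brute force.

        The reduction has likelihood P(D | t) under JC with divergence
        2 t and MSC density (2/theta) exp(-2t/theta); the brute-force
        posterior integrates t on a grid.
        """
        theta_true = 0.02
        st = SpeciesTree(["sp1"], [-1], [0.0], [theta_true])
        prof = MarkerProfile("nuclear", 1.0, 1.0, kappa=1.0, gamma_shape=1.0,
                             n_categories=1, length=500,
                             per_lineage_rate=0.001)
        alns = simulate_replicate(st, [prof], {"sp1": 2}, 77, 0)
        pr = PriorSpec(tau_mean=0.001)
        est = MSCDivergenceSampler(topology=st, priors=pr, n_iter=24000,
                                   burn_in=2000, thin=8, seed=6)
        est.fit(alns, profiles=[prof])
        theta_samples = est.trace_.samples["theta_n0"].to_numpy()

        # brute-force posterior on a (theta, t) grid with the same data
        a, b = aln0, aln1 = alns[0].data[0], alns[0].data[1]
        n_diff = int(np.sum(a != b))
        n_same = a.shape[0] - n_diff
        thetas = np.linspace(1e-4, 0.2, 400)
        ts = np.linspace(1e-6, 0.3, 1200)
        p_diff = 0.75 * (1 - np.exp(-8.0 * ts / 3.0))  # divergence 2t
        loglik_t = (n_diff * np.log(p_diff / 3) +
                    n_same * np.log(1 - p_diff))
        post = np.zeros_like(thetas)
        for i, th in enumerate(thetas):
            logmsc = math.log(2.0 / th) - 2.0 * ts / th
            logprior = stats.gamma.logpdf(th, 2.0, scale=0.0125)
            w = np.exp(loglik_t + logmsc - loglik_t.max())
            post[i] = math.exp(logprior) * np.trapezoid(w, ts)
        cdf = np.cumsum(post)
        cdf /= cdf[-1]
        ks = stats.kstest(theta_samples[::6],
                          lambda x: np.interp(x, thetas, cdf))
        assert ks.statistic < 0.05

    def test_non_matching_tips_raise(self):
        st = build_focal_tree(0.025, 0.01, 1.0)
        prof = marker_strategy("1mit", 0.01)[0]
        from coaldelta.seqsim import Alignment
        aln = Alignment(["spX_1", "spY_1", "spZ_1", "spW_1"],
                        np.zeros((4, 10), dtype=np.int8), prof)
        est = MSCDivergenceSampler(topology=st, priors=PriorSpec(
            tau_mean=0.001))
        with pytest.raises(ValueError):
            est.fit([aln], profiles=[prof])

    def test_sklearn_param_interface(self):
        est = MSCDivergenceSampler(n_iter=123, seed=9)
        assert est.get_params()["n_iter"] == 123
        est.set_params(thin=7)
        assert est.thin == 7


class TestPrecisionOrderings:
    """Information content vs whisker width of the Bayesian estimates."""

    def test_whisker_width_shrinks_with_more_nuclear_loci(self):
        """1 -> 5 -> 10 nuclear loci: strictly narrower error whiskers."""
        from coaldelta.design import StudyCondition, nuclear_profile
        from coaldelta.experiments import run_mb_grid

        def cond(nloci):
            prof = [nuclear_profile(0.001, name=f"nuc{i}")
                    for i in range(nloci)]
            return StudyCondition(0.025, 0.01, 3.0, prof, 5, 10,
                                  f"{nloci}nuc")

        out = run_mb_grid([cond(1), cond(5), cond(10)], seed=17,
                          mcmc={"n_iter": 1800, "burn_in": 600, "thin": 3})
        w = (out["whisker_high"] - out["whisker_low"]).to_numpy()
        assert w[0] > w[1] > w[2]

    def test_single_sequence_per_species_is_unsatisfactory(self):
        """n=1 vs n=5 per species (mixed strategy, 0.5 Myr): one sequence
        per species gives both wider whiskers and larger bias."""
        from coaldelta.design import StudyCondition
        from coaldelta.experiments import run_mb_grid

        grid = [StudyCondition(0.025, 0.01, 0.5,
                               marker_strategy("1mit+4nuc", 0.01), n, 16,
                               f"mix_n{n}") for n in (1, 5)]
        out = run_mb_grid(grid, seed=17,
                          mcmc={"n_iter": 1800, "burn_in": 600, "thin": 3})
        w = (out["whisker_high"] - out["whisker_low"]).to_numpy()
        b = out["mean_percent_error"].abs().to_numpy()
        assert w[0] > w[1]
        assert b[0] > b[1]
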