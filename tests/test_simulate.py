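"""Simulator tests: Kingman checks, analytic agreement, demography effects.

Monte-Carlo assertions use fixed seeds and tolerances of at least four
standard errors at the chosen replicate counts.
"""

import math

import numpy as np
import pytest

from twotwo import (
    AdmixturePulse,
    Bottleneck,
    DemographyConfig,
    ModelError,
    OutgroupConfig,
    TTParams,
    ancestral_t4,
    estimate_alpha_ascertained,
    estimate_tt,
    genealogy_config_probs,
    simulate_counts,
    simulate_genealogy,
    treeness_tests,
    true_alpha,
    tt_forward_probs,
)

MU = 1.25e-8


def constant_cfg(**kw):
    base = dict(N1=17000, N2=17000, NA=17000, t_split=10000, mu=MU,
                m_tot=1e9, R=100_000, seed=42)
    base.update(kw)
    return DemographyConfig(**base)


class TestConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ModelError):
            constant_cfg(N1=-5)
        with pytest.raises(ModelError):
            constant_cfg(admixture=AdmixturePulse(gamma=1.5, delta=0))
        with pytest.raises(ModelError):
            constant_cfg(admixture=AdmixturePulse(gamma=0.5, delta=20000))
        with pytest.raises(ModelError):
            constant_cfg(outgroup=OutgroupConfig(t_out=5000, N_out=1000))
        with pytest.raises(ModelError):
            constant_cfg(mode="bogus")
        with pytest.raises(ModelError):
            Bottleneck(lam=0.0, tau_b=10)
        with pytest.raises(ModelError):
            simulate_counts(constant_cfg(R=500))


class TestSingleGenealogy:
    def test_zero_split_is_single_population_coalescent(self):
        # mean pairwise TMRCA ~ 2N generations
        cfg = constant_cfg(t_split=0, N1=500, N2=500, NA=500)
        rng = np.random.default_rng(1)
        pair_times = []
        for _ in range(4000):
            g = simulate_genealogy(cfg, rng)
            # time of the merge creating the population-1 pair's ancestor
            t12 = next(t for t, a, b in g.merges
                       if (a[0] + b[0]) == 2 and a[0] and b[0])
            pair_times.append(t12)
        assert np.mean(pair_times) == pytest.approx(2 * 500, rel=0.1)

    def test_h_indicator_matches_exponential_survival(self):
        cfg = constant_cfg(R=30_000)
        rng = np.random.default_rng(2)
        h1 = sum(simulate_genealogy(cfg, rng).H1 for _ in range(30_000))
        # P(no coalescence) = exp(-t/(2N)) = exp(-10000/34000) ~ 0.745
        assert 1 - h1 / 30_000 == pytest.approx(math.exp(-10000 / 34000), abs=0.01)

    def test_config_probs_sum_to_one_and_scale_with_mu(self):
        cfg = constant_cfg()
        g = simulate_genealogy(cfg, np.random.default_rng(3))
        p = genealogy_config_probs(g, MU)
        assert p.p.sum() == pytest.approx(1.0)
        p0 = genealogy_config_probs(g, 0.0)
        assert p0.polymorphic_sum == 0.0
        with pytest.raises(ModelError, match="linear"):
            genealogy_config_probs(g, 1.0)

    def test_both_early_coalescences_kill_shared_polymorphism(self):
        # force tiny daughters so both pairs coalesce before the split
        cfg = constant_cfg(N1=10, N2=10)
        rng = np.random.default_rng(4)
        g = simulate_genealogy(cfg, rng)
        assert g.H1 and g.H2
        p = genealogy_config_probs(g, MU)
        assert p[1, 1] == 0.0


class TestKingman:
    def test_t4_ratios_and_scale(self):
        cfg = constant_cfg()
        t4 = ancestral_t4(cfg, R=200_000, rng=np.random.default_rng(5))
        assert t4["T42"] == pytest.approx(34000, rel=0.02)
        assert t4["T43"] / t4["T42"] == pytest.approx(1 / 3, rel=0.02)
        assert t4["T44"] / t4["T43"] == pytest.approx(1 / 2, rel=0.02)

    def test_bottleneck_t4_matches_numeric_integration(self):
        """Independent two-epoch oracle: expected stage durations by dense
        grid integration of the piecewise-exponential process."""
        tau_b, NB, NA = 500.0, 1500.0, 17000.0

        def wait_mean(d, r1, r2):
            return (1 - np.exp(-r1 * d)) / r1 + np.exp(-r1 * d) / r2

        r4 = (6 / (2 * NB), 6 / (2 * NA))
        r3 = (3 / (2 * NB), 3 / (2 * NA))
        et44 = wait_mean(np.array([tau_b]), *r4)[0]
        s = np.linspace(0, tau_b, 20001)
        f_in = r4[0] * np.exp(-r4[0] * s)
        et43 = (np.trapezoid(f_in * wait_mean(tau_b - s, *r3), s)
                + math.exp(-r4[0] * tau_b) / r3[1])
        cfg = constant_cfg(bottleneck=Bottleneck(lam=NB / NA, tau_b=tau_b))
        t4 = ancestral_t4(cfg, R=400_000, rng=np.random.default_rng(6))
        assert t4["T44"] == pytest.approx(et44, rel=0.02)
        assert t4["T43"] == pytest.approx(et43, rel=0.02)


class TestSimulateCounts:
    def test_matches_analytic_forward_model(self):
        """Expected configuration probabilities under constant-everything
        demography match the closed-form model at the analytic
        (alpha, V, T, theta)."""
        cfg = constant_cfg(R=500_000)
        res = simulate_counts(cfg)
        tr = res.truth
        params = TTParams(tr.alpha1, tr.alpha2, tr.T1, tr.T2, tr.V1, tr.V2,
                          tr.theta, mu=MU)
        p_model = tt_forward_probs(params)
        p_sim = res.counts.m / res.counts.m_tot
        for ij in ((1, 0), (0, 1), (2, 0), (0, 2), (1, 1), (2, 1), (1, 2)):
            assert p_sim[ij] == pytest.approx(p_model[ij], rel=0.02)

    def test_expected_counts_are_linear_in_m_tot(self):
        a = simulate_counts(constant_cfg(R=2000, m_tot=1e8, seed=7))
        b = simulate_counts(constant_cfg(R=2000, m_tot=2e8, seed=7))
        np.testing.assert_allclose(2 * a.counts.m, b.counts.m, rtol=1e-12)

    def test_same_seed_is_bit_for_bit_reproducible(self):
        a = simulate_counts(constant_cfg(R=2000, seed=11))
        b = simulate_counts(constant_cfg(R=2000, seed=11))
        np.testing.assert_array_equal(a.counts.m, b.counts.m)
        assert a.truth.tau2 == b.truth.tau2

    def test_multinomial_mode_gives_integer_counts(self):
        res = simulate_counts(constant_cfg(R=2000, m_tot=1e6, mode="multinomial"))
        assert res.counts.m.sum() == 1e6
        np.testing.assert_array_equal(res.counts.m, np.round(res.counts.m))

    def test_fast_and_generic_paths_agree(self):
        """The vectorized state-enumeration path and the event-driven
        per-genealogy path are independent implementations of the same
        process; their expected probabilities must agree within MC error."""
        bott = Bottleneck(lam=1500 / 17000, tau_b=500, phi=100)
        fast = simulate_counts(constant_cfg(R=400_000, seed=8, bottleneck=bott))
        cfg = constant_cfg(R=40_000, seed=9, bottleneck=bott,
                           admixture=AdmixturePulse(gamma=1e-12, delta=0))
        with pytest.warns(RuntimeWarning):
            slow = simulate_counts(cfg)  # generic path (pulse is a no-op)
        pf = fast.counts.m / fast.counts.m_tot
        ps = slow.counts.m / slow.counts.m_tot
        for ij in ((1, 0), (0, 1), (2, 0), (0, 2), (1, 1), (2, 1), (1, 2)):
            assert pf[ij] == pytest.approx(ps[ij], rel=0.06)

    def test_bottleneck_bias_is_monotone_in_duration(self):
        t_hats = []
        for tau_b in (100, 500, 1000):
            cfg = constant_cfg(R=300_000, seed=10,
                               bottleneck=Bottleneck(lam=1500 / 17000, tau_b=tau_b))
            est = estimate_tt(simulate_counts(cfg).counts)
            t_hats.append(est.t1_generations)
        assert t_hats[0] > t_hats[1] > t_hats[2]


class TestTrueAlpha:
    def test_closed_forms(self):
        assert true_alpha(constant_cfg(t_split=0)) == (1.0, 1.0)
        a1, a2 = true_alpha(constant_cfg())
        assert a1 == pytest.approx(math.exp(-10000 / 34000))
        # full replacement: both recipient lineages ride in the donor
        cfg = constant_cfg(N1=5000, admixture=AdmixturePulse(gamma=1.0, delta=0.0))
        _, a2 = true_alpha(cfg)
        assert a2 == pytest.approx(math.exp(-10000 / (2 * 5000)))

    def test_closed_form_matches_monte_carlo_under_admixture(self):
        cfg = constant_cfg(R=60_000, seed=12,
                           admixture=AdmixturePulse(gamma=0.4, delta=3000))
        res = simulate_counts(cfg)
        assert res.truth.alpha2_mc == pytest.approx(res.truth.alpha2, abs=0.01)
        assert res.truth.alpha1_mc == pytest.approx(res.truth.alpha1, abs=0.01)


class TestOutgroup:
    @pytest.fixture(scope="class")
    def outgroup_sim(self):
        cfg = DemographyConfig(
            N1=17000, N2=9000, NA=17000, t_split=10000, mu=MU, m_tot=1e9,
            R=100_000, seed=13,
            outgroup=OutgroupConfig(t_out=40000, N_out=17000))
        return simulate_counts(cfg)

    def test_ascertained_counts_are_a_subset(self, outgroup_sim):
        assert np.all(outgroup_sim.counts_star.m <= outgroup_sim.counts.m + 1e-9)
        assert outgroup_sim.counts_star.m_tot < outgroup_sim.counts.m_tot

    def test_ascertained_alpha_recovers_truth(self, outgroup_sim):
        a1, a2 = estimate_alpha_ascertained(outgroup_sim.counts_star)
        assert a1 == pytest.approx(outgroup_sim.truth.alpha1, abs=0.02)
        assert a2 == pytest.approx(outgroup_sim.truth.alpha2, abs=0.02)

    def test_treeness_near_zero_under_true_outgroup(self, outgroup_sim):
        y1, y2 = treeness_tests(outgroup_sim.counts_star)
        assert abs(y1) < 0.03
        assert abs(y2) < 0.005

    def test_outgroup_gene_flow_breaks_treeness_with_signed_y2(self):
        vals = {}
        for rec in (1, 2):
            cfg = DemographyConfig(
                N1=17000, N2=17000, NA=17000, t_split=10000, mu=MU, m_tot=1e9,
                R=30_000, seed=14,
                outgroup=OutgroupConfig(t_out=40000, N_out=17000),
                admixture=AdmixturePulse(gamma=0.3, delta=2000,
                                         recipient=rec, donor="outgroup"))
            _, y2 = treeness_tests(simulate_counts(cfg).counts_star)
            vals[rec] = y2
        assert vals[1] > 0.1      # flow into pop 1 -> excess pop1/outgroup sharing
        assert vals[2] < -0.1
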