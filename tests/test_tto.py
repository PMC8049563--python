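"""TTo estimator and tree-ness test unit tests.

The starred (ascertained) configuration probabilities used as oracles here
are built directly from the no-new-mutation equations: with drift
parameters ``a1, a2`` and an arbitrary ascertained ancestral spectrum
``(b1, b2, b3)``,

    p10* = (a1/2) b1 + (a1/3)(1-a2) b2
    p20* = ((1-a1)/4) b1 + (1/6)(2-a1-a2+a1*a2) b2 + ((1-a2)/4) b3
    p11* = (2/3) a1 a2 b2
    p21* = ((1-a1)/3) a2 b2 + (a2/2) b3
    p12* = (a1/3)(1-a2) b2 + (a1/2) b3

(and the population-swapped p01*, p02*).  Any exact ascertained-drift
estimator must recover ``a1, a2`` from these for every spectrum.
"""

import math

import numpy as np
import pytest

from twotwo import (
    ConfigCounts,
    EstimationError,
    estimate_alpha_ascertained,
    estimate_tt,
    estimate_tto,
    treeness_tests,
    tt_forward_probs,
)


def starred_counts(a1, a2, b1, b2, b3, m_tot=1e8):
    m = np.zeros((3, 3))
    m[1, 0] = (a1 / 2) * b1 + (a1 / 3) * (1 - a2) * b2
    m[0, 1] = (a2 / 2) * b1 + (a2 / 3) * (1 - a1) * b2
    m[2, 0] = ((1 - a1) / 4) * b1 + (2 - a1 - a2 + a1 * a2) / 6 * b2 + ((1 - a2) / 4) * b3
    m[0, 2] = ((1 - a2) / 4) * b1 + (2 - a1 - a2 + a1 * a2) / 6 * b2 + ((1 - a1) / 4) * b3
    m[1, 1] = (2 / 3) * a1 * a2 * b2
    m[2, 1] = ((1 - a1) / 3) * a2 * b2 + (a2 / 2) * b3
    m[1, 2] = (a1 / 3) * (1 - a2) * b2 + (a1 / 2) * b3
    m *= m_tot
    m[0, 0] = m_tot - m.sum()
    return ConfigCounts(m=m, m_tot=m_tot)


class TestAscertainedAlpha:
    @pytest.mark.parametrize("a1, a2", [(0.745, 0.574), (0.3, 0.9), (1.0, 1.0)])
    @pytest.mark.parametrize("b", [(2e-3, 1e-3, 6.67e-4), (5e-4, 8e-4, 3e-4)])
    def test_exact_recovery_for_any_ancestral_spectrum(self, a1, a2, b):
        c = starred_counts(a1, a2, *b)
        e1, e2 = estimate_alpha_ascertained(c)
        assert e1 == pytest.approx(a1, rel=1e-9)
        assert e2 == pytest.approx(a2, rel=1e-9)

    def test_no_drift_limit_gives_one(self):
        c = starred_counts(1.0, 1.0, 1e-3, 5e-4, 3e-4)
        assert estimate_alpha_ascertained(c) == pytest.approx((1.0, 1.0))

    def test_empty_denominator_is_an_error(self):
        c = ConfigCounts.from_cells(100, m22=5)
        with pytest.raises(EstimationError, match="denominator"):
            estimate_alpha_ascertained(c)


class TestTreeness:
    def test_symmetric_counts_give_zero(self):
        c = ConfigCounts.from_cells(
            1e6, m10=100, m01=100, m20=40, m02=40, m21=30, m12=30, m11=50)
        y1, y2 = treeness_tests(c)
        assert y1 == 0.0
        assert y2 == 0.0

    def test_exactly_zero_on_asymmetric_drift_with_true_outgroup(self):
        # drift asymmetry alone must not fail the tests
        c = starred_counts(0.9, 0.3, 2e-3, 1e-3, 6.67e-4)
        y1, y2 = treeness_tests(c)
        assert y1 == pytest.approx(0.0, abs=1e-12)
        assert y2 == pytest.approx(0.0, abs=1e-15)

    def test_scale_invariance(self):
        c = ConfigCounts.from_cells(
            1e6, m10=120, m01=80, m20=40, m02=70, m21=30, m12=55, m11=50)
        y = treeness_tests(c)
        y_scaled = treeness_tests(c.scale(7.5))
        assert y_scaled == pytest.approx(y)

    def test_zero_denominator_names_the_cell(self):
        c = ConfigCounts.from_cells(1e6, m10=10, m20=5)
        with pytest.raises(EstimationError, match="m01"):
            treeness_tests(c)


class TestTToEstimates:
    def test_constant_ancestor_recovery_with_true_alpha(self, const_params):
        """On constant-model expected counts, tau* recover (theta, theta/3,
        theta/6) — the tau4 ratio approximation is exact here — and the
        time estimates match truth and the TT estimates to machine
        precision."""
        th = const_params.theta
        counts = tt_forward_probs(const_params).expected_counts(1e9)
        est = estimate_tto(counts, const_params.alpha1, const_params.alpha2)
        assert est.tau2_star == pytest.approx(th, rel=1e-9)
        assert est.tau3_star == pytest.approx(th / 3, rel=1e-9)
        assert est.tau4_star == pytest.approx(th / 6, rel=1e-9)
        assert est.B1_star == pytest.approx(const_params.T1 + th / 6, rel=1e-9)
        assert est.T1_star == pytest.approx(const_params.T1, rel=1e-8)
        assert est.T2_star == pytest.approx(const_params.T2, rel=1e-8)
        assert est.V1_star == pytest.approx(const_params.V1, rel=1e-8)
        assert est.V2_star == pytest.approx(const_params.V2, rel=1e-8)
        tt = estimate_tt(counts)
        assert est.T1_star == pytest.approx(tt.T1_hat, rel=1e-9)
        assert est.T2_star == pytest.approx(tt.T2_hat, rel=1e-9)

    def test_no_drift_limit_tau2_is_three_p21(self):
        # alpha1 = alpha2 = 1: (m11, m21, m12) proportional to
        # (2/3, 1/3, 1/3) theta and tau2* = 3 p21 = theta
        th = 1e-3
        from twotwo import TTParams
        counts = tt_forward_probs(TTParams(1, 1, 0, 0, 0, 0, th)).expected_counts(1e9)
        est = estimate_tto(counts, 1.0, 1.0)
        assert est.tau2_star == pytest.approx(3 * counts[2, 1] / counts.m_tot, rel=1e-9)
        assert est.tau2_star == pytest.approx(th, rel=1e-9)
        assert math.isnan(est.V1_star)
        assert any("alpha = 1" in f for f in est.flags)

    def test_variant_averages_agree_on_symmetric_model(self):
        from twotwo import TTParams
        params = TTParams(0.7, 0.7, 1e-4, 1e-4, 3e-5, 3e-5, 1e-3)
        counts = tt_forward_probs(params).expected_counts(1e9)
        est = estimate_tto(counts, 0.7, 0.7)
        a, b = est.tau2_star_variants
        assert a == pytest.approx(b, rel=1e-9)
        a, b = est.tau3_star_variants
        assert a == pytest.approx(b, rel=1e-9)

    def test_swapping_populations_swaps_estimates(self, const_params):
        counts = tt_forward_probs(const_params).expected_counts(1e9)
        est = estimate_tto(counts, const_params.alpha1, const_params.alpha2)
        swapped = estimate_tto(counts.transpose(), const_params.alpha2,
                               const_params.alpha1)
        assert swapped.T1_star == pytest.approx(est.T2_star, rel=1e-9)
        assert swapped.B2_star == pytest.approx(est.B1_star, rel=1e-9)
        assert swapped.tau2_star == pytest.approx(est.tau2_star, rel=1e-9)

    def test_error_paths(self, expected_counts):
        with pytest.raises(EstimationError, match="alpha"):
            estimate_tto(expected_counts, 0.0, 0.5)
        with pytest.raises(EstimationError, match="shared polymorphism"):
            estimate_tto(ConfigCounts.from_cells(100, m10=5), 0.5, 0.5)
        # tau2* <= 0: engineered counts with huge m11
        c = ConfigCounts.from_cells(1e6, m11=1000, m21=10, m12=10)
        with pytest.warns(RuntimeWarning, match="tau2"):
            est = estimate_tto(c, 0.9, 0.9)
        assert math.isnan(est.tau4_star)
        assert math.isnan(est.T1_star)
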