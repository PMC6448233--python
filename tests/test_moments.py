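"""Moment calculations: closed-form exponential oracles vs quadrature, and the
Monte-Carlo counting-process oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surv2stage import (
    CensoringProfile,
    HypothesisPair,
    WeibullSurvival,
    alt_moments,
    monte_carlo_moment_oracle,
    null_moments,
)


def exp_null_moments(h0: float, t1: float, t_c: float = 1.0):
    """Closed-form exponential (k=1) null moments; independent of the package path.

    sigma02^2 = 1 - e^(-h0*tc);
    sigma01^2 = sigma02^2 - (1/t1) * int_0^u t h0 e^(-h0 t) dt  for u=min(t1,tc),
    minus the vanished-G1 region handled when t1 < tc.
    """
    s02 = 1.0 - math.exp(-h0 * t_c)
    u = min(t1, t_c)
    # int_0^u (1 - t/t1) h0 e^(-h0 t) dt
    cdf_u = 1.0 - math.exp(-h0 * u)
    int_t_f = (1.0 - (1.0 + h0 * u) * math.exp(-h0 * u)) / h0  # int_0^u t f(t) dt
    s01 = cdf_u - int_t_f / t1
    return s01, s02


def exp_p_quantities(h0: float, h1: float, t_c: float = 1.0):
    """Closed-form exponential final-look p-integrals (G = 1 on [0, tc])."""
    e1 = math.exp(-h1 * t_c)
    p1 = 1.0 - e1
    p0 = (h0 / h1) * p1
    int_te = (1.0 - (1.0 + h1 * t_c) * e1) / h1**2  # int_0^tc t e^(-h1 t) dt
    p00 = h0**2 * int_te
    p01 = h0 * h1 * int_te
    return p1, p0, p00, p01


def wu_var(p1, p0, p00, p01):
    return p1 - p1**2 - p0**2 + 2 * p0 * p1 + 2 * p00 - 2 * p01


class TestCensoringProfile:
    def test_final_profile_is_indicator(self):
        g = CensoringProfile(1.0)
        assert g(0.0) == 1.0 and g(1.0) == 1.0 and g(1.0001) == 0.0

    def test_interim_profile_below_final(self):
        g = CensoringProfile(1.0)
        g1 = CensoringProfile(1.0, interim_time=44 / 24)
        ts = np.linspace(0, 1.5, 301)
        vals = np.array([g1(t) for t in ts])
        assert g1(0.0) == 1.0
        assert np.all(np.diff(vals) <= 1e-12)  # non-increasing
        assert all(g1(t) <= g(t) for t in ts)

    def test_interim_before_tc_vanishes(self):
        g1 = CensoringProfile(2.0, interim_time=0.5)
        assert g1(0.75) == 0.0
        assert g1.upper_limit == 0.5


class TestNullMoments:
    def test_final_variance_telescopes(self, pancreatic_pair):
        nm = null_moments(pancreatic_pair, t1=0.7)
        assert nm.sigma02_sq == pytest.approx(0.65, abs=1e-12)

    def test_interim_variance_closed_form(self, pancreatic_pair):
        h0 = 1.0 / pancreatic_pair.null.scale
        s01, s02 = exp_null_moments(h0, t1=44 / 24)
        nm = null_moments(pancreatic_pair, t1=44 / 24)
        assert s01 == pytest.approx(0.5032, abs=1e-4)  # frozen closed-form value
        assert nm.sigma01_sq == pytest.approx(s01, abs=1e-8)
        assert nm.rho0 == pytest.approx(math.sqrt(s01 / s02), abs=1e-8)
        assert nm.rho0 == pytest.approx(0.880, abs=1e-3)

    def test_late_interim_recovers_full_information(self, pancreatic_pair):
        nm = null_moments(pancreatic_pair, t1=1e9)
        assert nm.rho0 == pytest.approx(1.0, abs=1e-6)


class TestAltMoments:
    def test_final_p1_is_event_probability(self, pancreatic_pair):
        am = alt_moments(pancreatic_pair, t1=44 / 24)
        assert am.p1 == pytest.approx(0.5, abs=1e-10)

    def test_exponential_closed_forms(self, pancreatic_pair):
        h0 = 1.0 / pancreatic_pair.null.scale
        h1 = 1.0 / pancreatic_pair.alt.scale
        p1, p0, p00, p01 = exp_p_quantities(h0, h1)
        am = alt_moments(pancreatic_pair, t1=44 / 24)
        assert p0 == pytest.approx(0.75729, abs=1e-5)     # frozen closed-form values
        assert wu_var(p1, p0, p00, p01) == pytest.approx(0.6730, abs=1e-4)
        assert am.p0 == pytest.approx(p0, abs=1e-8)
        assert am.p00 == pytest.approx(p00, abs=1e-8)
        assert am.p01 == pytest.approx(p01, abs=1e-8)
        assert am.omega == pytest.approx(p1 - p0, abs=1e-8)
        assert am.sigma12_sq == pytest.approx(wu_var(p1, p0, p00, p01), abs=1e-8)

    def test_null_equals_alt_degenerates(self):
        m = WeibullSurvival(1.0, 1.4427)
        pair = HypothesisPair(null=m, alt=m, t_c=1.0)
        am = alt_moments(pair, t1=1.5)
        nm = null_moments(pair, t1=1.5)
        assert am.omega == pytest.approx(0.0, abs=1e-10)
        assert am.omega1 == pytest.approx(0.0, abs=1e-10)
        assert am.sigma12_sq == pytest.approx(nm.sigma02_sq, abs=1e-8)
        assert am.sigma11_sq == pytest.approx(nm.sigma01_sq, abs=1e-8)
        assert am.rho1 == pytest.approx(nm.rho0, abs=1e-7)

    def test_weibull_half_shape_drift_negative(self, weibull_half_pair):
        am = alt_moments(weibull_half_pair, t1=1.2)
        assert am.omega < 0 and am.omega1 < 0
        assert 0 < am.sigma11_sq <= am.sigma12_sq
        assert 0 < am.rho1 <= 1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    s0=st.floats(0.15, 0.8),
    gap=st.floats(0.05, 0.19),
    k=st.sampled_from([0.5, 1.0, 2.0]),
    t1=st.floats(0.2, 3.0),
)
def test_stage1_information_never_exceeds_final(s0, gap, k, t1):
    """G1 <= G pointwise forces every stage-1 moment below its final analogue."""
    pair = HypothesisPair.from_probabilities(s0, s0 + gap, 1.0, k0=k)
    nm = null_moments(pair, t1)
    am = alt_moments(pair, t1)
    assert nm.sigma01_sq <= nm.sigma02_sq + 1e-10
    assert am.p1f <= am.p1 + 1e-10
    assert am.p0f <= am.p0 + 1e-10
    assert am.p00f <= am.p00 + 1e-10
    assert am.p01f <= am.p01 + 1e-10
    assert am.omega < 0  # better survival under H1: fewer events than expected


@pytest.mark.parametrize("t1", [0.4, 44 / 24, 5.0])
def test_exponential_quadrature_matches_closed_form(t1, exp_hr_pair):
    h0 = 1.0 / exp_hr_pair.null.scale
    s01, s02 = exp_null_moments(h0, t1)
    nm = null_moments(exp_hr_pair, t1)
    assert nm.sigma01_sq == pytest.approx(s01, abs=1e-8)
    assert nm.sigma02_sq == pytest.approx(s02, abs=1e-12)


class TestMonteCarloOracle:
    """The Appendix integrals against direct simulation of the counting processes."""

    def test_alternative_moments_recovered(self, pancreatic_pair):
        t1, n1, n = 44 / 24, 44, 73
        am = alt_moments(pancreatic_pair, t1)
        out = monte_carlo_moment_oracle(
            pancreatic_pair, t1, n1, n, theta=24.0, reps=100_000, seed=101
        )
        assert out["mean_W"] == pytest.approx(
            math.sqrt(n) * am.omega, abs=4 * out["se_mean_W"]
        )
        assert out["mean_W1"] == pytest.approx(
            math.sqrt(n1) * am.omega1, abs=4 * out["se_mean_W1"]
        )
        assert out["var_W"] == pytest.approx(am.sigma12_sq, abs=4 * out["se_var_W"])
        assert out["var_W1"] == pytest.approx(am.sigma11_sq, abs=4 * out["se_var_W1"])

    def test_null_moments_recovered(self, pancreatic_pair):
        t1, n1, n = 44 / 24, 44, 73
        nm = null_moments(pancreatic_pair, t1)
        out = monte_carlo_moment_oracle(
            pancreatic_pair, t1, n1, n, theta=24.0, reps=100_000, seed=102,
            hypothesis="null",
        )
        assert abs(out["mean_W"]) < 4 * out["se_mean_W"]
        assert out["var_W1"] == pytest.approx(nm.sigma01_sq, abs=4 * out["se_var_W1"])
        assert out["var_W"] == pytest.approx(nm.sigma02_sq, abs=4 * out["se_var_W"])
        # the observed correlation of (W1, W) carries the information fraction
        # sqrt(n1/n); the design calculus deliberately uses rho0 = s01/s02 alone
        assert out["corr"] == pytest.approx(
            nm.rho0 * math.sqrt(n1 / n), abs=0.01
        )

    def test_same_seed_reproduces(self, pancreatic_pair):
        a = monte_carlo_moment_oracle(pancreatic_pair, 1.0, 10, 20, 10.0,
                                      reps=10_000, seed=7)
        b = monte_carlo_moment_oracle(pancreatic_pair, 1.0, 10, 20, 10.0,
                                      reps=10_000, seed=7)
        assert a == b

    def test_rejects_tiny_rep_count(self, pancreatic_pair):
        with pytest.raises(ValueError):
            monte_carlo_moment_oracle(pancreatic_pair, 1.0, 10, 20, 10.0, reps=100)

    def test_rejects_inconsistent_accrual_window(self, pancreatic_pair):
        with pytest.raises(ValueError, match="accrual"):
            monte_carlo_moment_oracle(pancreatic_pair, 1.0, 10, 20, 24.0,
                                      reps=10_000, seed=7)
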