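"""First-passage-time kernel: normalization, closed forms, series consistency,
and agreement with an independent Euler–Maruyama simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from driftlearn import wiener as W


def _quad_total(p):
    t0 = p[3]
    up = quad(lambda t: W.fpt_density(t, "upper", p), t0 + 1e-6, t0 + 60, limit=400)[0]
    lo = quad(lambda t: W.fpt_density(t, "lower", p), t0 + 1e-6, t0 + 60, limit=400)[0]
    return up, lo


class TestDensity:
    def test_defective_densities_sum_to_one(self, param_sets):
        for p in param_sets:
            up, lo = _quad_total(p)
            assert up + lo == pytest.approx(1.0, abs=1e-4)

    def test_quadrature_matches_choice_probability(self, param_sets):
        for p in param_sets[:5]:
            up, _ = _quad_total(p)
            assert up == pytest.approx(W.choice_probability(p), abs=1e-5)

    def test_rt_at_or_below_t0_is_impossible(self):
        p = (1.0, 1.5, 0.5, 0.30)
        assert W.fpt_logdensity(0.25, "upper", p) == -np.inf
        assert W.fpt_logdensity(0.30, "lower", p) == -np.inf
        with pytest.raises(ValueError):
            W.fpt_logdensity(0.25, "upper", p, on_invalid_rt="raise")

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            W.fpt_logdensity(0.5, "upper", (1.0, -1.0, 0.5, 0.1))
        with pytest.raises(ValueError):
            W.fpt_logdensity(0.5, "upper", (1.0, 1.5, 1.2, 0.1))
        with pytest.raises(ValueError):
            W.choice_probability((np.nan, 1.5, 0.5, 0.1))
        with pytest.raises(ValueError):
            W.WienerParams(1.0, 1.5, 0.5, -0.1)

    def test_reflection_symmetry_exact(self, param_sets):
        # density(rt, upper; v, z) == density(rt, lower; -v, 1-z)
        for v, a, z, t0 in param_sets:
            for rt in (t0 + 0.05, t0 + 0.4, t0 + 2.0):
                assert W.fpt_logdensity(rt, "upper", (v, a, z, t0)) == \
                    W.fpt_logdensity(rt, "lower", (-v, a, 1 - z, t0))

    def test_stable_over_wide_decision_times(self):
        p = (1.0, 1.5, 0.5, 0.0)
        t = np.array([1e-4, 1e-3, 1e-2, 0.1, 1.0, 5.0, 10.0])
        ld = W.fpt_logdensity(t, "upper", p)
        assert np.all(np.isfinite(ld))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        rt = rng.uniform(0.4, 2.0, 50)
        p = (0.8, 1.6, 0.45, 0.25)
        vec = W.fpt_logdensity(rt, "upper", p)
        scl = np.array([W.fpt_logdensity(float(t), "upper", p) for t in rt])
        np.testing.assert_allclose(vec, scl, atol=1e-9)


class TestClosedForms:
    def test_zero_drift_choice_probability_equals_bias(self):
        assert W.choice_probability((0.0, 1.5, 0.5, 0.1)) == pytest.approx(0.5, abs=1e-12)
        assert W.choice_probability((0.0, 1.5, 0.3, 0.1)) == pytest.approx(0.3, abs=1e-9)

    def test_choice_probability_continuous_in_drift(self):
        a, z = 1.5, 0.4
        eps = 1e-9
        below = W.choice_probability((-eps, a, z, 0.1))
        above = W.choice_probability((eps, a, z, 0.1))
        assert abs(above - below) < 1e-6

    def test_zero_drift_mean_decision_time(self):
        # a^2 z (1-z): the diffusive limit
        assert W.mean_decision_time((0.0, 2.0, 0.5, 0.1)) == pytest.approx(1.0, abs=1e-3)
        assert W.mean_decision_time((0.0, 1.0, 0.3, 0.0)) == pytest.approx(0.21, abs=1e-3)

    def test_diffusive_scaling_quadruples_with_boundary(self):
        m1 = W.mean_decision_time((0.0, 1.0, 0.5, 0.0))
        m2 = W.mean_decision_time((0.0, 2.0, 0.5, 0.0))
        assert m2 == pytest.approx(4.0 * m1, rel=1e-9)

    def test_mean_decision_time_matches_quadrature(self):
        p = (1.0, 1.5, 0.5, 0.3)
        m = quad(lambda t: t * W.fpt_density(t + 0.3, "upper", p), 1e-6, 50, limit=400)[0] \
            + quad(lambda t: t * W.fpt_density(t + 0.3, "lower", p), 1e-6, 50, limit=400)[0]
        assert W.mean_decision_time(p) == pytest.approx(m, abs=1e-6)


class TestCdf:
    def test_zero_at_t0_and_limit_is_choice_probability(self):
        p = (0.0, 1.5, 0.4, 0.2)
        assert W.fpt_cdf(0.2, "upper", p) == 0.0
        assert W.fpt_cdf(500.0, "upper", p) == pytest.approx(0.4, abs=1e-9)
        assert W.fpt_cdf(500.0, "lower", p) == pytest.approx(0.6, abs=1e-9)

    def test_matches_density_quadrature(self, param_sets):
        for p in param_sets[:4]:
            t0 = p[3]
            for t in (t0 + 0.3, t0 + 1.0):
                ref = quad(lambda s: W.fpt_density(s, "lower", p), t0 + 1e-9, t,
                           limit=300)[0]
                assert W.fpt_cdf(t, "lower", p) == pytest.approx(ref, abs=1e-7)

    def test_derivative_matches_density(self, param_sets):
        h = 1e-5
        for p in param_sets[:6]:
            t = p[3] + 0.6
            num = (W.fpt_cdf(t + h, "upper", p) - W.fpt_cdf(t - h, "upper", p)) / (2 * h)
            assert num == pytest.approx(W.fpt_density(t, "upper", p), abs=1e-5)

    def test_nondecreasing(self):
        p = (0.7, 1.8, 0.45, 0.25)
        t = np.linspace(0.26, 8.0, 300)
        c = W.fpt_cdf(t, "upper", p)
        assert np.all(np.diff(c) >= -1e-12)


class TestSimulationOracle:
    """Euler–Maruyama (with bridge crossing correction) is an independent
    discretization of the same process; series density, closed-form choice
    probability and mean must all agree with it."""

    @pytest.mark.parametrize("p", [(1.0, 1.5, 0.5, 0.3),
                                   (-0.5, 1.2, 0.35, 0.2),
                                   (2.0, 2.0, 0.6, 0.25)])
    def test_series_density_matches_euler_histogram(self, p):
        rng = np.random.default_rng(42)
        n = 30_000
        rt, up = W.simulate_euler(n, p, rng, dt=2e-4)
        pu = W.choice_probability(p)
        # choice probability within binomial CI
        se = np.sqrt(pu * (1 - pu) / n)
        assert abs(up.mean() - pu) < 4 * se + 2e-3
        # mean decision time within Monte-Carlo error
        m = W.mean_decision_time(p)
        sd = np.std(rt - p[3])
        assert abs((rt - p[3]).mean() - m) < 4 * sd / np.sqrt(n) + 2e-3
        # chi-square goodness of fit of the upper-boundary RT distribution
        ru = rt[up]
        qs = np.linspace(0.05, 0.95, 13)
        edges = np.quantile(ru, qs)
        edges = np.concatenate([[p[3]], edges, [np.inf]])
        cdf_vals = np.array([W.fpt_cdf(e, "upper", p) / pu if np.isfinite(e) else 1.0
                             for e in edges])
        probs = np.diff(cdf_vals)
        counts = np.histogram(ru, bins=np.concatenate([edges[:-1], [1e9]]))[0]
        chi2 = stats.chisquare(counts, probs / probs.sum() * counts.sum())
        assert chi2.pvalue > 0.01

    def test_inverse_cdf_sampler_ks(self):
        p = (1.0, 1.5, 0.5, 0.3)
        rng = np.random.default_rng(5)
        rt, up = W.sample_fpt(5000, p, rng)
        pu = W.choice_probability(p)
        ks = stats.kstest(rt[up], lambda x: np.asarray(W.fpt_cdf(x, "upper", p)) / pu)
        assert ks.pvalue > 0.01
        assert np.all(rt > p[3])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(v=st.floats(-2.5, 2.5), a=st.floats(0.7, 2.5), z=st.floats(0.15, 0.85))
def test_choice_probability_in_open_interval(v, a, z):
    pu = W.choice_probability((v, a, z, 0.1))
    assert 0.0 < pu < 1.0
    # upper-boundary probability increases with drift
    assert W.choice_probability((v + 0.5, a, z, 0.1)) > pu
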