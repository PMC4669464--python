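"""Analytical TF model: delay density, Laplace functional, moments, occupancy."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.integrate import solve_ivp

import vcmm as V


# -- maturation delay -------------------------------------------------------


def test_delay_density_single_exponential():
    d = V.MaturationDelay((0.5,))
    t = np.array([-1.0, 0.0, 1.0, 3.0])
    expected = np.where(t >= 0, 0.5 * np.exp(-0.5 * t), 0.0)
    assert np.allclose(V.delay_density(d, t), expected, atol=1e-15)


def test_delay_density_equal_rates_erlang():
    delta = 0.2
    d = V.MaturationDelay((delta, delta))
    t = np.linspace(0, 40, 9)
    assert np.allclose(
        V.delay_density(d, t), delta**2 * t * np.exp(-delta * t), rtol=1e-12
    )


def test_delay_density_distinct_rates_closed_form():
    d1, d2 = 0.1, 0.3
    d = V.MaturationDelay((d1, d2))
    t = np.linspace(0.1, 50, 7)
    expected = d1 * d2 / (d2 - d1) * (np.exp(-d1 * t) - np.exp(-d2 * t))
    assert np.allclose(V.delay_density(d, t), expected, rtol=1e-12)


def test_delay_density_confluent_branch_continuity():
    """Near-equal rates (phase-type branch) agree with the Erlang limit."""
    t = np.linspace(0.5, 30, 5)
    near = V.delay_density(V.MaturationDelay((0.2, 0.2 * (1 + 1e-8), 0.3)), t)
    # independent oracle: Erlang(2, 0.2) convolved numerically with Exp(0.3)
    d, mu = 0.2, 0.3
    ref = np.array(
        [
            integrate.quad(
                lambda x, tv=tv: d**2 * x * math.exp(-d * x) * mu * math.exp(-mu * (tv - x)),
                0.0,
                tv,
            )[0]
            for tv in t
        ]
    )
    assert np.allclose(near, ref, rtol=1e-6)


@pytest.mark.parametrize("rates", [(0.02,), (0.02, 0.02), (0.01, 0.02, 0.04)])
def test_delay_density_normalised(rates):
    d = V.MaturationDelay(rates)
    val, _ = integrate.quad(
        lambda x: V.delay_density(d, x), 0, d.cutoff, limit=200
    )
    assert val == pytest.approx(1.0, abs=1e-9)


def test_delay_density_invalid_inputs():
    with pytest.raises(ValueError):
        V.MaturationDelay((0.0,))
    with pytest.raises(ValueError):
        V.delay_density(V.MaturationDelay(()), 1.0)


# -- Laplace functional -----------------------------------------------------


def test_laplace_normalisation(tf_params):
    assert V.laplace_transform(0.0, 500.0, tf_params) == 1.0
    assert V.laplace_transform(0.7, 0.0, tf_params) == 1.0
    with pytest.raises(ValueError):
        V.laplace_transform(-0.1, 10.0, tf_params)


def test_laplace_monotone_convex_in_lambda(tf_params):
    lams = np.linspace(0.0, 0.4, 9)
    vals = V.laplace_transform(lams, 900.0, tf_params)
    assert np.all(vals > 0) and np.all(vals <= 1.0)
    d1 = np.diff(vals)
    assert np.all(d1 < 0)
    assert np.all(np.diff(d1) > 0)  # convexity


def test_laplace_matches_monte_carlo(genereg_nobind, tf_params):
    """<e^{-lambda rho}> agrees with the SSA ensemble (3 SE, 4000 runs)."""
    grid = np.array([0.0, 450.0, 900.0])
    ens = V.run_ensemble(genereg_nobind, 900.0, 4000, 42, grid)
    data = ens.data
    for ti, t in ((1, 450.0), (2, 900.0)):
        rho = (data[:, ti, 2] + data[:, ti, 3]) / genereg_nobind.volume
        for lam in (0.02, 0.1):
            emp = np.exp(-lam * rho)
            se = emp.std(ddof=1) / math.sqrt(len(emp))
            assert V.laplace_transform(lam, t, tf_params) == pytest.approx(
                emp.mean(), abs=3 * se
            )


# -- moments ----------------------------------------------------------------


def test_mean_concentration_zero_at_zero(tf_params):
    assert V.mean_concentration(0.0, tf_params) == 0.0
    with pytest.raises(ValueError):
        V.mean_concentration(-1.0, tf_params)


def test_mean_concentration_matches_ode_cascade(tf_params):
    """The triple convolution equals the (independent) linear ODE cascade."""
    spec = V.fixture("fig1b_like")
    a, gm, v, gp = spec.a_tf, spec.gamma_m, spec.v_tf, spec.gamma_p
    d1, d2 = spec.maturation_rates

    def rhs(_, y):
        M, i1, i2, P = y
        return [a - gm * M, v * M - d1 * i1, d1 * i1 - d2 * i2, d2 * i2 - gp * P]

    sol = solve_ivp(rhs, (0, 1800), [0] * 4, rtol=1e-11, atol=1e-14, dense_output=True)
    for t in (120.0, 600.0, 1800.0):
        assert V.mean_concentration(t, tf_params) == pytest.approx(
            float(sol.sol(t)[3]), rel=1e-8
        )


def test_mean_stationary_limit(tf_params):
    spec = V.fixture("fig1b_like")
    closed = spec.a_tf * spec.burst_size / (spec.gamma_p * spec.volume)
    assert V.mean_concentration(math.inf, tf_params) == pytest.approx(closed, rel=1e-9)


def test_small_time_growth_exponent_single_step(tf_params):
    p = dataclasses.replace(tf_params, delay=V.MaturationDelay((0.02,)))
    assert V.growth_exponent(p) == pytest.approx(3.0, abs=0.05)


def test_variance_zero_at_zero(tf_params):
    assert V.variance_concentration(0.0, tf_params) == 0.0


def test_moment_consistency_with_laplace_derivatives(tf_params):
    """Finite-difference derivatives of the Laplace functional reproduce the
    direct convolution formulas for mean and variance (rel. 1e-4)."""
    for t in (600.0, 1800.0):
        mf, vf = V.laplace_moments_fd(t, tf_params)
        assert mf == pytest.approx(V.mean_concentration(t, tf_params), rel=1e-4)
        assert vf == pytest.approx(V.variance_concentration(t, tf_params), rel=1e-4)


def test_variance_matches_ssa(genereg_nobind, tf_params):
    ens = V.run_ensemble(genereg_nobind, 900.0, 4000, 7, np.array([0.0, 900.0]))
    rho = (ens.data[:, -1, 2] + ens.data[:, -1, 3]) / genereg_nobind.volume
    c = rho - rho.mean()
    se_var = math.sqrt(((c**4).mean() - rho.var(ddof=1) ** 2) / len(rho))
    assert V.variance_concentration(900.0, tf_params) == pytest.approx(
        rho.var(ddof=1), abs=3 * se_var
    )


def test_variance_instantaneous_burst_limit():
    """gamma_m, v_tf -> inf at fixed burst size, no delay: the variance
    approaches the concave shot-noise form a b (2b + 1) int phi^2."""
    kern = V.homogeneous_kernel(1 / 1800.0, 1.0)
    b, t = 6.0, 900.0
    p = V.TFModelParams(
        a_tf=1 / 300.0, gamma_m=5.0, v_tf=5.0 * b, delay=V.MaturationDelay(()),
        kernel=kern, volume=1.0, binding_constant=1 / 3.0,
    )
    limit = (1 / 300.0) * b * (2 * b + 1) * integrate.quad(
        lambda s: kern(s) ** 2, 0, t
    )[0]
    assert V.variance_concentration(t, p) == pytest.approx(limit, rel=2e-3)


def test_stationary_variance_burst_size_squared_scaling(tf_params):
    """At fixed transcription rate the burst-covariance term scales as b^2:
    doubling b multiplies the stationary variance by (8b^2+2b)/(2b^2+b)."""
    p2 = dataclasses.replace(tf_params, v_tf=2 * tf_params.v_tf)
    v1 = V.variance_concentration(math.inf, tf_params)
    v2 = V.variance_concentration(math.inf, p2)
    b = tf_params.burst_size
    assert v2 / v1 == pytest.approx((8 * b**2 + 2 * b) / (2 * b**2 + b), rel=0.02)


# -- occupancy --------------------------------------------------------------


def test_occupancy_zero_at_zero(tf_params):
    assert V.occupancy_exact(0.0, tf_params) == 0.0
    assert V.occupancy_mme(0.0, tf_params) == 0.0
    assert math.isnan(V.correction_ratio(0.0, tf_params))


def test_occupancy_integral_degenerate_closed_form(tf_params):
    """With the functional replaced by a point mass exp(-lambda rho0), the
    occupancy integral must return K rho0/(1 + K rho0)."""
    from vcmm.core import _Z_NODES, _Z_WEIGHTS

    K = tf_params.binding_constant
    for rho0 in (0.5, 5.0, 40.0):
        val = 1.0 - float(np.dot(_Z_WEIGHTS, np.exp(K * np.log(_Z_NODES) * rho0)))
        assert val == pytest.approx(K * rho0 / (1 + K * rho0), abs=1e-8)


def test_occupancy_monotone_in_binding_constant(tf_params):
    weaker = dataclasses.replace(tf_params, binding_constant=0.1)
    t = 900.0
    assert V.occupancy_exact(t, weaker) < V.occupancy_exact(t, tf_params)


def test_occupancy_vcmme_below_mme(tf_params):
    for t in (240.0, 600.0, 1800.0):
        assert V.occupancy_vcmme(t, tf_params) <= V.occupancy_mme(t, tf_params)


def test_occupancy_exact_within_rate_law_bounds(tf_params):
    """<p0> lies between the optimal lower bound and the MME upper bound
    evaluated at the analytic moments with K_M = 1/K."""
    rp = V.RateParameters(michaelis_constant=1.0 / tf_params.binding_constant)
    for t in (300.0, 900.0, 2400.0):
        m = V.mean_concentration(t, tf_params)
        v = V.variance_concentration(t, tf_params)
        mom = V.ConcentrationMoments(mean=m, variance=v)
        occ = V.occupancy_exact(t, tf_params)
        assert V.optimal_lower_bound(mom, rp) - 1e-6 <= occ
        assert occ <= V.jensen_upper_bound(mom, rp) + 1e-6


def test_poisson_occupancy_dual_route_and_strong_binding_limit(tf_params):
    for t in (300.0, 900.0):
        a = V.occupancy_poisson(t, tf_params, method="integral")
        b = V.occupancy_poisson(t, tf_params, method="sum")
        assert a == pytest.approx(b, abs=1e-10)
    strong = dataclasses.replace(tf_params, binding_constant=1e9)
    for m in (0.5, 4.0):
        val = V.occupancy_poisson(10.0, strong, mean_count=m)
        assert val == pytest.approx(1 - math.exp(-m), abs=1e-6)
    with pytest.raises(ValueError):
        V.occupancy_poisson(10.0, tf_params, method="bogus")


def test_unapproximated_binding_form(tf_params):
    """Finite K_SP lowers the occupancy relative to the strong-binding law."""
    t = 900.0
    full = V.occupancy_exact(t, tf_params, strong_binding=False)
    approx = V.occupancy_exact(t, tf_params, strong_binding=True)
    assert full < approx
    assert full == pytest.approx(approx, rel=0.05)  # K_SP = 100 is strong


def test_correction_difference_nonnegative_and_ratio_bounded(tf_params):
    for t in (120.0, 600.0, 2400.0):
        d = V.correction_difference(t, tf_params)
        r = V.correction_ratio(t, tf_params)
        assert d >= 0.0
        assert 0.0 <= r <= 1.0


def test_occupancy_matches_binding_ssa_at_late_times(tf_params):
    """Sequential-binding SSA occupancy agrees with the equilibrium analytics
    once the TF concentration is no longer tiny (here t >= 300 s)."""
    spec = V.fixture("fig1b_like")
    grid = np.array([0.0, 300.0, 900.0, 1800.0])
    ens = V.run_ensemble(spec, 1800.0, 800, 5, grid)
    st = V.ensemble_stats(ens)
    for i, t in ((1, 300.0), (2, 900.0), (3, 1800.0)):
        occ_a = V.occupancy_exact(t, tf_params)
        se = math.sqrt(max(st.occupancy[i] * (1 - st.occupancy[i]), 1e-9) / 800)
        assert st.occupancy[i] == pytest.approx(occ_a, abs=3 * se + 0.015)
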