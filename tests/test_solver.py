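"""ABM fractional integrator: weights, oracles, convergence, divergence."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fracstress.model import TABLE1, params_vector, rhs, stress_field
from fracstress.solver import (
    DIVERGENCE_THRESHOLD,
    FractionalOrders,
    SolverConfig,
    Trajectory,
    caputo_derivative_oracle,
    corrector_weight,
    empirical_convergence_order,
    integrate,
    mittag_leffler,
    predictor_weight,
)

CHAOTIC = TABLE1.replace(B=2.2, rho=11.0, omega=1.5)


def linear_field(t, y):
    """Scalar test problem D^q y = -y, y(0)=1, exact y = E_q(-t^q)."""
    return -y


class TestConfigTypes:
    def test_orders_broadcast(self):
        o = FractionalOrders(0.9)
        assert o.commensurate
        np.testing.assert_allclose(o.as_array(), [0.9, 0.9, 0.9])

    def test_orders_incommensurate(self):
        o = FractionalOrders(0.9, 0.95, 1.0)
        assert not o.commensurate

    def test_orders_bounds(self):
        with pytest.raises(ValueError):
            FractionalOrders(0.0)
        with pytest.raises(ValueError):
            FractionalOrders(1.1)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(h=0.0)
        with pytest.raises(ValueError):
            SolverConfig(memory_horizon=50)
        with pytest.raises(ValueError):
            SolverConfig(corrector_iterations=0)

    def test_trajectory_columns(self):
        t = Trajectory(
            times=np.arange(3.0),
            states=np.arange(9.0).reshape(3, 3),
            orders=np.ones(3),
        )
        np.testing.assert_allclose(t.column("Y"), [1.0, 4.0, 7.0])
        assert len(t) == 3


class TestWeights:
    def test_corrector_endpoint(self):
        assert corrector_weight(5, 4, 0.7) == 1.0

    def test_corrector_interior_formula(self):
        q, n, j = 0.6, 10, 4
        m = n - j
        expected = (m + 2) ** (q + 1) + m ** (q + 1) - 2 * (m + 1) ** (q + 1)
        assert corrector_weight(j, n, q) == pytest.approx(expected)

    def test_corrector_bounds(self):
        with pytest.raises(IndexError):
            corrector_weight(7, 5, 0.5)

    def test_predictor_is_kernel_integral(self):
        # beta_{j,n+1} must equal the exact integral of (t_{n+1}-s)^{q-1}
        # over [t_j, t_{j+1}]
        q, h, n, j = 0.75, 0.1, 12, 3
        from scipy.integrate import quad

        val, _ = quad(lambda s: ((n + 1) * h - s) ** (q - 1.0), j * h, (j + 1) * h)
        assert predictor_weight(j, n, q, h) == pytest.approx(val, rel=1e-10)

    def test_predictor_positive(self):
        assert all(predictor_weight(j, 9, 0.4, 0.01) > 0 for j in range(10))


class TestOracles:
    def test_mittag_leffler_reduces_to_exp(self):
        for z in (-2.0, -0.5, 0.3, 1.7):
            assert mittag_leffler(1.0, z) == pytest.approx(np.exp(z), rel=1e-12)

    def test_caputo_oracle_power_function(self):
        # exact Caputo derivative of t^2 is 2 t^(2-q) / Gamma(3-q)
        from math import gamma

        for q in (0.3, 0.5, 0.9):
            t = 1.7
            exact = 2.0 * t ** (2.0 - q) / gamma(3.0 - q)
            assert caputo_derivative_oracle(lambda s: s * s, q, t) == pytest.approx(
                exact, rel=1e-4
            )

    def test_linear_problem_matches_mittag_leffler(self):
        q = 0.6
        cfg = SolverConfig(h=1e-3, t_end=1.0, initial_state=(1.0,))
        traj = integrate(linear_field, q, cfg)
        exact = mittag_leffler(q, -1.0)  # E_q(-t^q) at t=1
        assert abs(traj.states[-1, 0] - exact) < 1e-4

    def test_q1_matches_classical_integrator(self):
        cfg = SolverConfig(h=0.005, t_end=10.0, initial_state=(1.0, 1.0, 1.0))
        traj = integrate(
            stress_field, FractionalOrders(1.0), cfg, params_vector=params_vector(CHAOTIC)
        )
        ref = solve_ivp(
            lambda t, y: rhs(y, t, CHAOTIC),
            (0.0, 10.0),
            [1.0, 1.0, 1.0],
            rtol=1e-10,
            atol=1e-12,
            t_eval=traj.times,
            method="RK45",
        )
        assert np.max(np.abs(traj.states - ref.y.T)) < 1e-3


class TestConvergence:
    H_LIST = (0.02, 0.01, 0.005, 0.0025)

    def test_order_half(self):
        q = 0.5
        slope = empirical_convergence_order(
            linear_field, q, mittag_leffler(q, -1.0), self.H_LIST, t_end=1.0
        )
        assert slope == pytest.approx(1.5, abs=0.2)

    def test_order_one(self):
        slope = empirical_convergence_order(
            linear_field, 1.0, np.exp(-1.0), self.H_LIST, t_end=1.0
        )
        assert slope == pytest.approx(2.0, abs=0.2)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            empirical_convergence_order(linear_field, 0.5, 1.0, (0.1, 0.05), t_end=1.0)


class TestIntegrationPaths:
    def test_compiled_and_python_paths_agree(self):
        cfg = SolverConfig(h=0.01, t_end=20.0, initial_state=(1.0, 1.0, 1.0))
        orders = FractionalOrders(0.95)
        fast = integrate(stress_field, orders, cfg, params_vector=params_vector(CHAOTIC))
        slow = integrate(lambda t, y: rhs(y, t, CHAOTIC), orders, cfg)
        assert np.max(np.abs(fast.states - slow.states)) < 1e-9

    def test_extra_corrector_sweeps_consistent(self):
        base = SolverConfig(h=0.01, t_end=10.0)
        more = SolverConfig(h=0.01, t_end=10.0, corrector_iterations=3)
        orders = FractionalOrders(0.9)
        pv = params_vector(CHAOTIC)
        t1 = integrate(stress_field, orders, base, params_vector=pv)
        t3 = integrate(stress_field, orders, more, params_vector=pv)
        # extra sweeps change the result only at the local-truncation level
        assert np.max(np.abs(t1.states - t3.states)) < 1e-2
        assert np.all(np.isfinite(t3.states))

    def test_incommensurate_orders_run(self):
        cfg = SolverConfig(h=0.02, t_end=5.0)
        traj = integrate(
            stress_field,
            FractionalOrders(0.9, 0.95, 1.0),
            cfg,
            params_vector=params_vector(TABLE1),
        )
        assert not traj.diverged
        assert np.all(np.isfinite(traj.states))

    def test_divergence_truncates_and_flags(self):
        # small fractional orders legitimately produce unbounded solutions;
        # the sweep contract is truncate-and-flag, not raise
        cfg = SolverConfig(h=0.01, t_end=100.0)
        traj = integrate(
            stress_field, FractionalOrders(0.3), cfg, params_vector=params_vector(CHAOTIC)
        )
        assert traj.diverged
        assert len(traj) < int(100.0 / 0.01) + 1
        assert np.all(np.isfinite(traj.states))
        assert np.max(np.abs(traj.states)) <= DIVERGENCE_THRESHOLD * 1.01

    def test_short_memory_truncation_is_invalid_near_q_one(self):
        """Short-memory truncation fails in the chaotic regime.

        At q near 1 the Volterra kernel (t-s)^(q-1) barely decays, so
        the truncated history carries order-one weight; a 1000-step
        horizon visibly corrupts the chaotic-regime solution on
        t in [0, 50] while the full-memory run stays accurate.  This
        test pins down that failure mode: truncation must not be used
        for chaotic-regime work.
        """
        orders = FractionalOrders(0.99)
        pv = params_vector(CHAOTIC)
        full = integrate(
            stress_field, orders, SolverConfig(h=0.01, t_end=50.0), params_vector=pv
        )
        cut = integrate(
            stress_field,
            orders,
            SolverConfig(h=0.01, t_end=50.0, memory_horizon=1000),
            params_vector=pv,
        )
        assert not full.diverged
        n = min(len(full), len(cut))
        discrepancy = np.max(np.abs(full.states[:n] - cut.states[:n]))
        assert cut.diverged or discrepancy > 1e-3
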