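"""Forward-model unit tests: areas, pressures, forces, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from voicefold import (ModelParameters, SimulationConfig, SimulationDiverged,
                       StateVector, apply_asymmetry, integrate)
from voicefold.model import (collision_forces, derivatives, driving_pressure,
                             glottal_areas, glottal_flow, heaviside,
                             smooth_switch)


class TestPieces:
    def test_areas_at_rest_and_initial_condition(self, std_params):
        a1, a2, amin = glottal_areas(np.zeros(8), std_params)
        assert a1 == a2 == amin == pytest.approx(0.05)
        a1, a2, amin = glottal_areas(StateVector(), std_params)  # x = 0.01
        assert a1 == pytest.approx(0.05 + 1.4 * 0.02)
        assert amin == pytest.approx(0.078)

    def test_area_collision_sign(self, std_params):
        y = np.zeros(8)
        y[0] = -0.05  # x1l
        a1, _, amin = glottal_areas(y, std_params)
        assert a1 == pytest.approx(0.05 - 1.4 * 0.05)
        assert a1 < 0 and amin == a1

    def test_heaviside_convention(self):
        assert heaviside(0.1) == 1.0
        assert heaviside(-0.1) == 0.0
        assert heaviside(0.0) == 0.0  # glottis closed at exact contact

    def test_smooth_switch(self):
        assert smooth_switch(0.05, 0.05) == pytest.approx(np.tanh(50.0))
        assert smooth_switch(-1e-6, 0.05) == 0.0
        assert smooth_switch(1e-12, 0.05) == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            smooth_switch(0.1, -1.0)

    def test_driving_pressure_hand_value(self, std_params):
        # a1 = 0.1, amin = 0.05: P1 = Ps (1 - 1/4) with tanh factors ~ 1
        p1 = driving_pressure(0.1, 0.05, std_params)
        assert p1 == pytest.approx(0.006, rel=1e-6)

    def test_driving_pressure_degenerate(self, std_params):
        assert driving_pressure(0.05, 0.05, std_params) == pytest.approx(0.0, abs=1e-9)
        assert driving_pressure(-0.01, -0.01, std_params) == 0.0

    def test_glottal_flow_value_and_gate(self, std_params):
        ug = glottal_flow(0.05, std_params)
        assert ug == pytest.approx(np.sqrt(2 * 0.008 / 0.00113) * 0.05, rel=1e-12)
        assert ug == pytest.approx(0.188, rel=5e-3)
        assert glottal_flow(0.0, std_params) == 0.0
        assert glottal_flow(-0.1, std_params) == 0.0
        # linear in amin
        assert glottal_flow(0.1, std_params) == pytest.approx(2 * ug)

    def test_collision_hand_value(self, std_params):
        left, right = apply_asymmetry(std_params)
        I1l, I2l, I1r, I2r = collision_forces(-0.01, 0.02, left, right,
                                              beta=1.0, L=1.4)
        # c1/m1 * 0.01/(2 L) = (0.24/0.125)*(0.01/2.8)
        assert I1l == pytest.approx((3 * 0.08 / 0.125) * (0.01 / 2.8), rel=1e-9)
        assert I1l == pytest.approx(6.857e-3, rel=1e-3)
        assert I2l == I2r == 0.0

    def test_collision_zero_when_open(self, std_params):
        left, right = apply_asymmetry(std_params)
        assert collision_forces(0.02, 0.02, left, right, 1.0, 1.4) == (0, 0, 0, 0)

    @given(a1=st.floats(-0.1, 0.1), a2=st.floats(-0.1, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_asymmetric_reduces_to_symmetric_at_beta_1(self, a1, a2):
        p = ModelParameters()
        left, right = apply_asymmetry(p)
        asym = collision_forces(a1, a2, left, right, 1.0, p.L)
        sym = collision_forces(a1, a2, left, right, 1.0, p.L,
                               symmetric_form=True)
        assert asym == pytest.approx(sym)

    @given(a1=st.floats(-0.1, -1e-4), beta=st.floats(0.41, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_collision_momentum_ratio(self, a1, beta):
        """Force (not acceleration) on left vs right is in ratio β."""
        p = ModelParameters(beta=beta)
        left, right = apply_asymmetry(p)
        I1l, _, I1r, _ = collision_forces(a1, 0.01, left, right, beta, p.L)
        F_left = I1l * left.m1
        F_right = I1r * right.m1
        # c_il = c_i, c_ir = beta c_i; weights beta/(b+1), 1/(b+1):
        # F_l / F_r = (c * b/(b+1)) / (b c * 1/(b+1)) = 1  -> equal and
        # opposite-in-role contact forces; the *weighted* forms keep the
        # impulse balance independent of the mass asymmetry.
        assert F_left == pytest.approx(F_right, rel=1e-9)


class TestDerivatives:
    def test_rest_without_pressure_is_equilibrium(self):
        p = ModelParameters(Ps=1e-300)
        dy = derivatives(np.zeros(8), p)
        assert np.allclose(dy, 0.0, atol=1e-250)

    def test_symmetric_state_gives_symmetric_derivatives(self, std_params):
        y = StateVector(x1l=0.02, x2l=-0.01, x1r=0.02, x2r=-0.01,
                        v1l=0.003, v2l=-0.002, v1r=0.003, v2r=-0.002)
        dy = derivatives(y, std_params)
        assert np.allclose(dy[[0, 1, 4, 5]], dy[[2, 3, 6, 7]])

    def test_non_finite_state_rejected(self, std_params):
        y = np.zeros(8)
        y[3] = np.nan
        with pytest.raises(ValueError):
            derivatives(y, std_params)

    def test_kernel_matches_reference_derivatives(self, std_params):
        """The jitted vector field equals the NumPy reference pointwise."""
        from voicefold._rk4 import _deriv
        from voicefold.model import _pack
        rng = np.random.default_rng(7)
        p = _pack(std_params, hard_switch=False)
        for _ in range(25):
            y = rng.uniform(-0.06, 0.06, 8)
            out = np.empty(8)
            _deriv(y, p, out)
            assert np.allclose(out, derivatives(y, std_params), rtol=1e-12)


class TestIntegration:
    def test_symmetric_trajectories_coincide(self, sym_result):
        assert np.array_equal(sym_result.states[:, 0], sym_result.states[:, 2])
        assert np.array_equal(sym_result.states[:, 1], sym_result.states[:, 3])

    def test_flow_nonnegative_and_zero_iff_closed(self, sym_result):
        assert np.all(sym_result.Ug >= 0)
        closed = sym_result.amin <= 0
        assert np.all(sym_result.Ug[closed] == 0)
        assert np.all(sym_result.Ug[~closed] > 0)
        assert closed.any() and (~closed).any()

    def test_f0_converged_in_dt(self):
        from voicefold import estimate_f0
        f = {}
        for dt in (0.04, 0.02):
            res = integrate(ModelParameters(), SimulationConfig(dt=dt))
            f[dt] = estimate_f0(res.signal("Ug"), res.fs)
        assert abs(f[0.04] - f[0.02]) < 0.5

    def test_one_step_matches_fine_step_oracle(self, std_params):
        """A single RK4 step from the standard initial condition agrees
        with a very-small-step integration to 1e-6 relative."""
        dt = 0.04
        y = StateVector().as_array()
        k1 = derivatives(y, std_params)
        k2 = derivatives(y + 0.5 * dt * k1, std_params)
        k3 = derivatives(y + 0.5 * dt * k2, std_params)
        k4 = derivatives(y + dt * k3, std_params)
        one_step = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        fine = y.copy()
        n = 64
        h = dt / n
        for _ in range(n):
            f1 = derivatives(fine, std_params)
            f2 = derivatives(fine + 0.5 * h * f1, std_params)
            f3 = derivatives(fine + 0.5 * h * f2, std_params)
            f4 = derivatives(fine + h * f3, std_params)
            fine = fine + h / 6.0 * (f1 + 2 * f2 + 2 * f3 + f4)
        assert np.max(np.abs(one_step - fine)) <= 1e-6 * np.max(np.abs(fine))

    def test_rk4_against_adaptive_oracle(self, std_params):
        """Trajectory matches a high-accuracy adaptive integrator; the
        error contracts with the step size (collisions make the vector
        field nonsmooth, so the finest step carries the tight bound)."""

        def f(t, y):
            return derivatives(y, std_params)

        sol = solve_ivp(f, (0.0, 200.0), StateVector().as_array(),
                        rtol=1e-10, atol=1e-12, dense_output=True,
                        max_step=0.5)
        err = {}
        for dt in (0.04, 0.01):
            res = integrate(std_params, SimulationConfig(dt=dt,
                                                         duration=200.0))
            ref = sol.sol(res.t).T
            num = res.states[:, :4]
            rms_err = np.sqrt(np.mean((num - ref[:, :4]) ** 2))
            rms_sig = np.sqrt(np.mean(ref[:, :4] ** 2))
            err[dt] = rms_err / rms_sig
        assert err[0.01] < 1.5e-4
        assert err[0.04] < 2.5e-3
        assert err[0.01] < err[0.04] / 4.0

    def test_energy_decays_without_driving(self, std_params):
        """With Ps ~ 0 and damping on, mechanical energy only decreases."""
        p = ModelParameters(Ps=1e-300)
        res = integrate(p, SimulationConfig(duration=100.0, transient=0.0))
        y = res.states
        left, right = apply_asymmetry(p)
        E = 0.0
        for (x1, x2, v1, v2, side) in ((y[:, 0], y[:, 1], y[:, 4], y[:, 5], left),
                                       (y[:, 2], y[:, 3], y[:, 6], y[:, 7], right)):
            E = E + 0.5 * (side.m1 * v1 ** 2 + side.m2 * v2 ** 2
                           + side.k1 * x1 ** 2 + side.k2 * x2 ** 2
                           + side.kc * (x1 - x2) ** 2)
        # no collisions happen in free decay from the small initial state
        assert np.all(res.amin > 0)
        assert np.all(np.diff(E) <= 1e-12)

    def test_divergence_guard(self, std_params):
        with pytest.raises(SimulationDiverged):
            integrate(std_params, SimulationConfig(divergence_bound=0.005))

    def test_result_dataframe_roundtrip(self, sym_result, tmp_path):
        path = tmp_path / "run.csv"
        sym_result.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns[:5]) == ["t", "x1l", "x2l", "x1r", "x2r"]
        assert len(df) == len(sym_result.t)


class TestAsymmetryScaling:
    def test_beta_one_identity(self, std_params):
        left, right = apply_asymmetry(std_params)
        assert left == right

    def test_beta_scaling_values(self):
        p = ModelParameters(beta=0.5)
        left, right = apply_asymmetry(p)
        assert right.m1 == pytest.approx(0.25)
        assert right.k1 == pytest.approx(0.04)
        assert right.c1 == pytest.approx(0.5 * 3 * 0.08)
        assert right.r1 == left.r1  # damping is not scaled

    def test_invalid_beta_rejected(self):
        for bad in (0.4, 0.39, 1.01, -1.0):
            with pytest.raises(ValueError):
                ModelParameters(beta=bad)

    def test_positive_constants_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(m1=-0.1)
        with pytest.raises(ValueError):
            ModelParameters(Ps=0.0)
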