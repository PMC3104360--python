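"""Single-neuron dynamics: gating curves, derivatives, Euler step, gate kinetics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from dbsnet.neurons import (
    GateParams,
    IzhParams,
    IzhState,
    MLParams,
    MLState,
    gate_derivative,
    gate_steady,
    izh_derivatives,
    izh_step,
    ml_derivatives,
    ml_gating_curves,
)


@pytest.fixture
def ml():
    return MLParams()


@pytest.fixture
def gate():
    return GateParams()


class TestMLGating:
    def test_half_activation_points(self, ml):
        m_inf, _, _ = ml_gating_curves(ml.v1, ml)
        assert m_inf == pytest.approx(0.5)
        _, w_inf, tau_w = ml_gating_curves(ml.v3, ml)
        assert w_inf == pytest.approx(0.5)
        assert tau_w == pytest.approx(1.0)

    def test_saturation(self, ml):
        m_inf, w_inf, _ = ml_gating_curves(50.0, ml)
        assert m_inf == pytest.approx(1.0)
        assert w_inf == pytest.approx(1.0)

    def test_bounded_and_monotone_on_dense_grid(self, ml):
        v = np.linspace(-2.0, 2.0, 4001)
        m_inf, w_inf, tau_w = ml_gating_curves(v, ml)
        for curve in (m_inf, w_inf):
            assert np.all((curve >= 0.0) & (curve <= 1.0))
            assert np.all(np.diff(curve) >= 0.0)
        assert np.all(tau_w > 0.0)


class TestMLDerivatives:
    def test_matches_closed_form_at_origin(self, ml, gate):
        # all currents zero, v = w = 0: only the Ca and leak/K terms at v=0 remain
        state = MLState(v=0.0, w=0.0, I_slow=0.0, s=0.0)
        d = ml_derivatives(state, v_delayed=0.0, I_syn=0.0, I_noise=0.0,
                           I_stim=0.0, X1=0.0, params=ml, gate=gate)
        m_inf = 0.5 * (1.0 + np.tanh((0.0 - ml.v1) / ml.v2))
        expected = (
            -ml.g_ca * m_inf * (0.0 - ml.v_ca) - ml.g_l * (0.0 - ml.v_l)
        ) / ml.C
        assert d.dv == pytest.approx(expected, rel=1e-12)

    def test_slow_current_setpoint_equilibrium(self, gate):
        p = MLParams(alpha=0.0)
        state = MLState(v=0.0, w=0.2, I_slow=0.005, s=0.1)
        d = ml_derivatives(state, v_delayed=p.v_star, I_syn=0.0, I_noise=0.0,
                           I_stim=0.0, X1=0.0, params=p, gate=gate)
        assert d.dI_slow == pytest.approx(0.0, abs=1e-15)

    def test_full_rhs_against_independent_oracle(self, ml, gate):
        # independent transcription of the four equations, random inputs
        rng = np.random.default_rng(7)
        for _ in range(50):
            v, w, islow, s = rng.uniform([-0.4, 0, -0.01, 0], [0.2, 1, 0.01, 1])
            v_del, i_syn, i_noise, i_stim = rng.uniform(-0.3, 0.3, 4)
            x1 = rng.integers(0, 2)
            d = ml_derivatives(MLState(v, w, islow, s), v_del, i_syn, i_noise,
                               i_stim, x1, ml, gate)
            m = 0.5 * (1 + np.tanh((v - ml.v1) / ml.v2))
            wi = 0.5 * (1 + np.tanh((v - ml.v3) / ml.v4))
            tw = 1 / np.cosh((v - ml.v3) / (2 * ml.v4))
            dv = (-ml.g_ca * m * (v - ml.v_ca) - ml.g_k * w * (v - ml.v_k)
                  - ml.g_l * (v - ml.v_l) + islow + i_syn + i_noise
                  + ml.s1 * x1 * i_stim) / ml.C
            assert d.dv == pytest.approx(dv, rel=1e-12)
            assert d.dw == pytest.approx(ml.phi * (wi - w) / tw, rel=1e-12)
            assert d.dI_slow == pytest.approx(ml.eps_j * (ml.v_star - v_del), rel=1e-12)
            h = 1 / (1 + np.exp(-(v - gate.theta_s) / gate.sigma_s))
            assert d.ds == pytest.approx(gate.alpha_s * h * (1 - s) - gate.beta_s * s, rel=1e-12)


class TestIzhStep:
    def test_reset_on_spike_crossing(self):
        p = IzhParams()
        state = IzhState(v=29.9, u=0.0, s=0.0)
        new, spiked = izh_step(state, I_total=50.0, dt=0.1, params=p)
        assert spiked
        assert new.v == p.c_reset == -50.0
        assert new.u == pytest.approx(state.u + 0.1 * p.a * (p.b * state.v - state.u) + p.d)

    def test_rest_fixed_point_is_stationary(self):
        # solve 0.04 v^2 + 5 v + 140 - b v + I = 0 for the stable (lower) root
        p = IzhParams(drive=0.0)
        f = lambda v: 0.04 * v**2 + 5 * v + 140 - p.b * v
        v_rest = brentq(f, -90.0, -60.0)
        dt = 1e-3
        state = IzhState(v=v_rest, u=p.b * v_rest, s=0.0)
        new, spiked = izh_step(state, I_total=0.0, dt=dt, params=p)
        assert not spiked
        assert new.v == pytest.approx(v_rest, abs=10 * dt**2)
        assert new.u == pytest.approx(p.b * v_rest, abs=10 * dt**2)

    def test_matches_scalar_euler_oracle_exactly(self):
        p = IzhParams()
        rng = np.random.default_rng(3)
        v, u = -60.0, -12.0
        dt = 0.1
        state = IzhState(v=v, u=u, s=0.0)
        for _ in range(200):
            i_ext = float(rng.uniform(-5, 15))
            state, spiked = izh_step(state, i_ext, dt, p)
            # independently coded scalar update
            v_new = v + dt * (0.04 * v * v + 5 * v + 140 - u + i_ext + p.drive)
            u_new = u + dt * p.a * (p.b * v - u)
            if v_new >= p.spike_cut:
                v_new, u_new = p.c_reset, u_new + p.d
            # association order of the oracle's sum differs, so agreement is
            # to rounding error rather than bit-exact
            assert state.v == pytest.approx(v_new, rel=1e-13, abs=1e-13)
            assert state.u == pytest.approx(u_new, rel=1e-13, abs=1e-13)
            v, u = state.v, state.u

    def test_divergent_step_raises(self):
        p = IzhParams()
        state = IzhState(v=1e200, u=0.0, s=0.0)
        with pytest.raises(FloatingPointError):
            izh_step(state, 0.0, 0.1, p)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            izh_step(IzhState(), 0.0, -0.1, IzhParams())


class TestGate:
    def test_steady_state_fraction_when_fully_open(self, gate):
        # ds/dt = 0 with H_inf = 1 gives s* = alpha/(alpha+beta) = 2/3
        s_star = gate.alpha_s / (gate.alpha_s + gate.beta_s)
        assert s_star == pytest.approx(2.0 / 3.0)
        assert gate_derivative(s_star, 10.0, gate) == pytest.approx(0.0, abs=1e-12)

    def test_closed_gate_far_below_threshold_is_stationary(self, gate):
        assert gate_derivative(0.0, -1e6, gate) == pytest.approx(0.0, abs=1e-12)

    def test_half_activation_rate(self, gate):
        assert gate_derivative(0.0, gate.theta_s, gate) == pytest.approx(gate.alpha_s / 2)

    def test_s_stays_in_unit_interval_for_random_voltage_traces(self, gate):
        # Euler-integrate the gate against wild bounded voltage excursions
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = float(rng.uniform(0, 1))
            v_trace = rng.uniform(-5, 5, size=2000)
            dt = 0.5
            for v in v_trace:
                s = s + dt * gate_derivative(s, v, gate)
                assert -1e-9 <= s <= 1.0 + 1e-9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GateParams(alpha_s=-1.0)
        with pytest.raises(ValueError):
            MLParams(C=0.0)
        with pytest.raises(ValueError):
            IzhParams(a=-0.1)
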