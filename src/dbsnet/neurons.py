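"""Single-neuron dynamics: Morris-Lecar bursting STN neuron and Izhikevich chattering neuron.

Two backends share the same first-order synaptic gating variable ``s`` with
Terman-style kinetics.  The Morris-Lecar (ML) neuron is the biophysical
reference: a dimensionless spike generator augmented with a slowly varying
current that integrates the delayed membrane potential, standing in for the
inhibitory STN<->GPe feedback loop and turning tonic spiking into periodic
bursts.  The Izhikevich neuron is the reduced-order stand-in used for larger
populations: a quadratic integrate-and-fire model with after-spike resets,
parameterized in the chattering regime so bursts carry a comparable number of
spikes at a tremor-like rate.

All ML quantities are dimensionless; one ML time unit is identified with 1 ms
so that pulse-train bookkeeping, burst rates and spectral readouts share a
single time base across backends.  Izhikevich voltages are in mV and time in
ms by construction of the model's canonical fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GateParams",
    "MLParams",
    "MLState",
    "MLDerivative",
    "IzhParams",
    "IzhState",
    "gate_steady",
    "gate_derivative",
    "ml_gating_curves",
    "ml_derivatives",
    "izh_derivatives",
    "izh_step",
]


@dataclass(frozen=True)
class GateParams:
    """Kinetics of the synaptic gating variable s.

    ds/dt = alpha_s * H_inf(v) * (1 - s) - beta_s * s, with H_inf a logistic
    activation of the presynaptic potential.  The defaults give a gate that
    opens during spikes (H_inf ~ 1 above threshold) with a 20 ms closing time.
    """

    alpha_s: float = 0.1
    beta_s: float = 0.05
    theta_s: float = 0.2
    sigma_s: float = 0.02

    def __post_init__(self) -> None:
        if self.alpha_s <= 0 or self.beta_s <= 0 or self.sigma_s <= 0:
            raise ValueError("alpha_s, beta_s and sigma_s must be positive")


def gate_steady(v, gate: GateParams):
    """Steady-state activation H_inf(v) of the synaptic gate."""
    z = np.clip(-(np.asarray(v, dtype=float) - gate.theta_s) / gate.sigma_s, -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def gate_derivative(s, v, gate: GateParams):
    """Right-hand side of the synaptic gate ODE; keeps s in [0, 1] for any v."""
    h = gate_steady(v, gate)
    return gate.alpha_s * h * (1.0 - s) - gate.beta_s * s


@dataclass(frozen=True)
class MLParams:
    """Morris-Lecar STN neuron parameters (dimensionless).

    The slow current integrates the delayed membrane potential towards the
    set point ``v_star``: dI_slow/dt = eps_j * (v_star - v(t - tau_j)
    - alpha * I_slow).  ``eps_j`` sets the burst rate and is drawn per neuron
    (Gaussian, mean 2e-3, sd 2e-5) so natural frequencies disperse slightly;
    ``alpha`` modulates the inhibitory (GPe-like) response and is 0 in the
    reference configuration.  ``s1`` weights the local effectiveness of
    somatic stimulation.
    """

    g_ca: float = 1.0
    g_k: float = 2.0
    g_l: float = 0.5
    v_ca: float = 1.0
    v_k: float = -0.7
    v_l: float = -0.5
    v1: float = -0.01
    v2: float = 0.15
    v3: float = 0.1
    v4: float = 0.145
    C: float = 1.0
    phi: float = 1.15
    v_star: float = -0.22
    alpha: float = 0.0
    tau_j: float = 10.0
    eps_j: float = 2e-3
    eps_sd: float = 2e-5
    s1: float = 1.0

    def __post_init__(self) -> None:
        if min(self.g_ca, self.g_k, self.g_l) <= 0:
            raise ValueError("channel conductances must be positive")
        if self.C <= 0:
            raise ValueError("membrane capacitance must be positive")
        if self.tau_j < 0:
            raise ValueError("feedback delay must be nonnegative")
        if self.eps_j <= 0:
            raise ValueError("slow-current rate eps_j must be positive")


@dataclass
class MLState:
    v: float = -0.25
    w: float = 0.0
    I_slow: float = 0.0
    s: float = 0.0


@dataclass
class MLDerivative:
    dv: float
    dw: float
    dI_slow: float
    ds: float


def ml_gating_curves(v, params: MLParams):
    """Ca/K channel activation curves of the Morris-Lecar spike generator.

    Returns ``(m_inf, w_inf, tau_w)`` with the canonical hyperbolic forms
    m_inf = (1 + tanh((v - v1)/v2))/2, w_inf = (1 + tanh((v - v3)/v4))/2 and
    tau_w = 1/cosh((v - v3)/(2 v4)).  Both activations are monotone in v and
    bounded in [0, 1]; tau_w is strictly positive.
    """
    m_inf = 0.5 * (1.0 + np.tanh((v - params.v1) / params.v2))
    w_inf = 0.5 * (1.0 + np.tanh((v - params.v3) / params.v4))
    tau_w = 1.0 / np.cosh((v - params.v3) / (2.0 * params.v4))
    return m_inf, w_inf, tau_w


def ml_derivatives(
    state: MLState,
    v_delayed: float,
    I_syn: float,
    I_noise: float,
    I_stim: float,
    X1: float,
    params: MLParams,
    gate: GateParams,
) -> MLDerivative:
    """Full right-hand side of the four delayed ODEs of one ML neuron.

    ``v_delayed`` is this neuron's membrane potential ``tau_j`` time units in
    the past (the caller owns the history buffer).  ``X1`` switches the
    somatic stimulation term on or off.
    """
    v, w = state.v, state.w
    m_inf, w_inf, tau_w = ml_gating_curves(v, params)
    i_ion = (
        -params.g_ca * m_inf * (v - params.v_ca)
        - params.g_k * w * (v - params.v_k)
        - params.g_l * (v - params.v_l)
    )
    dv = (i_ion + state.I_slow + I_syn + I_noise + params.s1 * X1 * I_stim) / params.C
    dw = params.phi * (w_inf - w) / tau_w
    dI_slow = params.eps_j * (params.v_star - v_delayed - params.alpha * state.I_slow)
    ds = gate_derivative(state.s, v, gate)
    return MLDerivative(dv, dw, dI_slow, ds)


@dataclass(frozen=True)
class IzhParams:
    """Izhikevich quadratic model in the chattering (bursting) regime.

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I, du/dt = a (b v - u); on reaching
    ``spike_cut`` the state resets v <- c_reset, u <- u + d.  ``drive`` is the
    constant tonic current that places the neuron in the repetitive-bursting
    regime; the default 4.0 yields 8-9 spikes per burst at ~6.5 Hz, matching
    the ML reference neuron's burst statistics (see docs/methods.md for how
    this value was fixed).  In a population the drive is drawn per neuron
    from N(drive, drive_sd) (clipped to the bursting band), dispersing the
    natural burst frequencies the same way the ML neuron's Gaussian eps_j
    does; identical oscillators would otherwise lock trivially to any
    common input.
    """

    a: float = 0.02
    b: float = 0.2
    c_reset: float = -50.0
    d: float = 0.7
    drive: float = 4.0
    drive_sd: float = 0.05
    spike_cut: float = 30.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("recovery rate a must be positive")
        if self.spike_cut <= self.c_reset:
            raise ValueError("spike_cut must exceed the reset potential")


@dataclass
class IzhState:
    v: float = -65.0
    u: float = -13.0
    s: float = 0.0


def izh_derivatives(v, u, I_total, params: IzhParams):
    """Continuous part of the Izhikevich model (reset handled by izh_step)."""
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I_total
    du = params.a * (params.b * v - u)
    return dv, du


def izh_step(
    state: IzhState,
    I_total: float,
    dt: float,
    params: IzhParams,
    gate: GateParams | None = None,
) -> tuple[IzhState, bool]:
    """One forward-Euler step with after-spike reset.

    ``I_total`` is the full input current excluding the tonic ``drive``,
    which is added here.  Returns the new state and whether a spike (reset)
    occurred during this step.  Raises on non-finite state, the signature of
    a divergent step size.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dv, du = izh_derivatives(state.v, state.u, I_total + params.drive, params)
    v = state.v + dt * dv
    u = state.u + dt * du
    if not (np.isfinite(v) and np.isfinite(u)):
        raise FloatingPointError("Izhikevich state diverged; reduce dt")
    s = state.s
    if gate is not None:
        s = min(1.0, max(0.0, s + dt * gate_derivative(s, state.v, gate)))
    spiked = v >= params.spike_cut
    if spiked:
        v = params.c_reset
        u = u + params.d
    return IzhState(v=v, u=u, s=s), bool(spiked)


def draw_eps(n: int, params: MLParams, rng: np.random.Generator) -> np.ndarray:
    """Per-neuron slow-current rates: Gaussian around eps_j, clipped positive."""
    eps = rng.normal(params.eps_j, params.eps_sd, size=n)
    return np.clip(eps, 1e-6, None)


def draw_drive(n: int, params: IzhParams, rng: np.random.Generator) -> np.ndarray:
    """Per-neuron tonic drives: Gaussian around drive, clipped to the bursting band."""
    drv = rng.normal(params.drive, params.drive_sd, size=n)
    return np.clip(drv, 3.6, 5.5)
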