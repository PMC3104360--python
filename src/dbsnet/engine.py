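"""Scenario configuration and network integration.

`run_scenario` integrates a single lattice population (Morris-Lecar via RK4
with a delay ring buffer, Izhikevich via forward Euler with after-spike
resets); `run_two_population` integrates the pacemaker->driven pair used to
study how stimulating one nucleus desynchronizes a downstream area.  All
randomness is controlled by four explicit seeds (lattice jitter, noise,
initial conditions, inter-population weights), derivable from one master
seed; identical configuration and seeds give bit-identical traces.

User-facing durations and windows are in seconds; internally everything runs
in milliseconds (one Morris-Lecar dimensionless time unit = 1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .neurons import GateParams, IzhParams, MLParams, draw_drive, draw_eps
from .noise import NoiseParams, ou_noise_trace
from .stimulation import PulseTrain, electrode_layout, stim_profile
from .topology import (
    CouplingParams,
    InterPopCoupling,
    Lattice,
    build_interpop_coupling,
    build_lattice,
    coupling_matrix,
)

__all__ = [
    "Seeds",
    "StimProtocol",
    "ScenarioConfig",
    "SimulationTrace",
    "run_scenario",
    "run_two_population",
]

NOISE_HOLD_MS = 1.0  # OU noise is pre-generated on this grid and held constant


@dataclass(frozen=True)
class Seeds:
    lattice: int = 1
    noise: int = 2
    init: int = 3
    interpop: int = 4

    @classmethod
    def from_master(cls, seed: int) -> "Seeds":
        states = np.random.SeedSequence(seed).generate_state(4) % (2**31)
        return cls(*(int(x) for x in states))


@dataclass(frozen=True)
class StimProtocol:
    """Electrode layout plus pulse train plus onset/offset window.

    ``weight`` is the backend's somatic stimulation weight (s1 for ML, the
    printed s = 50 for Izhikevich).  ``slow_weight`` (s2) couples the
    magnitude of the stimulation current into the Morris-Lecar slow current,
    modeling co-activation of inhibitory afferent fibres alongside the
    direct somatic excitation; 0 disables the pathway (Izhikevich runs,
    which have no slow current, ignore it).
    """

    mode: str = "center"  # "center" or "quad"
    train: PulseTrain = field(default_factory=PulseTrain)
    window_s: tuple[float, float] = (4.5, 9.0)
    c_s: float = 0.1
    decay_len: float = 0.5
    weight: float = 1.0
    slow_weight: float = 0.0


@dataclass(frozen=True)
class ScenarioConfig:
    backend: str  # "morris_lecar" or "izhikevich"
    n_neurons: int
    duration_s: float
    dt_ms: float
    dl: float = 0.1
    jitter_sd: float = 0.0
    record_stride_ms: float = 1.0
    neuron: MLParams | IzhParams = field(default_factory=MLParams)
    gate: GateParams = field(default_factory=GateParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    stimulation: StimProtocol | None = None
    seeds: Seeds = field(default_factory=Seeds)
    # initial membrane potentials are drawn uniformly from this range
    # (backend default when None); a degenerate range gives identical
    # initial states, useful for symmetry checks
    init_v_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.backend not in ("morris_lecar", "izhikevich"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.duration_s <= 0 or self.dt_ms <= 0:
            raise ValueError("duration and dt must be positive")
        if self.stimulation is not None and self.duration_s < self.stimulation.window_s[1]:
            raise ValueError("duration must cover the stimulation window")

    def with_seed(self, master_seed: int) -> "ScenarioConfig":
        return replace(self, seeds=Seeds.from_master(master_seed))


@dataclass
class SimulationTrace:
    """Recorded run: voltages, non-stimulation currents, spikes, provenance."""

    times_ms: np.ndarray  # (T,)
    V: np.ndarray  # (N, T)
    I_ion: np.ndarray  # (N, T) total currents excluding stimulation
    spike_times: list[np.ndarray]  # per neuron, ms; empty arrays for ML
    lattice: Lattice
    config: ScenarioConfig

    @property
    def n_neurons(self) -> int:
        return self.V.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.times_ms / 1000.0


def _stim_arrays(config: ScenarioConfig, lattice: Lattice):
    stim = config.stimulation
    n = lattice.n
    if stim is None:
        prof = np.zeros(n)
        train = PulseTrain()
        return prof, np.zeros(n), train, -1.0, -1.0, 1.0
    array = electrode_layout(stim.mode, lattice, c_s=stim.c_s, decay_len=stim.decay_len)
    prof = stim_profile(lattice, array)
    t_on, t_off = (1000.0 * w for w in stim.window_s)
    return prof, stim.slow_weight * prof, stim.train, t_on, t_off, stim.weight


def _noise_matrix(config: ScenarioConfig, n: int, seed: int) -> tuple[np.ndarray, int]:
    n_cols = int(np.ceil(config.duration_s * 1000.0 / NOISE_HOLD_MS)) + 1
    params = replace(config.noise, seed=seed)
    noise = ou_noise_trace(n, n_cols, NOISE_HOLD_MS, params)
    stride = max(1, int(round(NOISE_HOLD_MS / config.dt_ms)))
    return noise, stride


def _init_ml(config: ScenarioConfig, n: int, rng: np.random.Generator):
    lo, hi = config.init_v_range or (-0.3, 0.14)
    v = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
    w = np.zeros(n)
    islow = np.zeros(n)
    s = np.zeros(n)
    return v, w, islow, s


def _init_izh(config: ScenarioConfig, n: int, rng: np.random.Generator):
    p: IzhParams = config.neuron  # type: ignore[assignment]
    lo, hi = config.init_v_range or (-65.0, -50.0)
    v = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
    u = p.b * v
    s = np.zeros(n)
    return v, u, s


def _check_status(status, backend: str) -> None:
    code, step, neuron = status
    if code != 0:
        raise FloatingPointError(
            f"{backend} integration diverged at step {step}, neuron {neuron} "
            f"(population {code}); reduce dt or input amplitudes"
        )


def run_scenario(config: ScenarioConfig) -> SimulationTrace:
    """Integrate one lattice population and record its trace.

    Morris-Lecar runs fourth-order Runge-Kutta with the delayed membrane
    potential read from a ring-buffer history (constant initial history);
    Izhikevich runs forward Euler with post-step reset and exact spike-time
    logging.  Voltages and total non-stimulation currents are recorded every
    ``record_stride_ms``.
    """
    lattice = build_lattice(config.n_neurons, config.dl, config.jitter_sd, config.seeds.lattice)
    w_mat = coupling_matrix(lattice, config.coupling.sigma_g)
    n = lattice.n
    dt = config.dt_ms
    n_steps = int(round(config.duration_s * 1000.0 / dt))
    rec_stride = max(1, int(round(config.record_stride_ms / dt)))
    n_rec = (n_steps + rec_stride - 1) // rec_stride
    noise, noise_stride = _noise_matrix(config, n, config.seeds.noise)
    prof, slow_prof, train, t_on, t_off, stim_weight = _stim_arrays(config, lattice)
    rng = np.random.default_rng(config.seeds.init)
    cp = config.coupling
    gp = config.gate
    v_rec = np.empty((n, n_rec))
    iion_rec = np.empty((n, n_rec))

    if config.backend == "morris_lecar":
        p: MLParams = config.neuron  # type: ignore[assignment]
        v, w, islow, s = _init_ml(config, n, rng)
        eps = draw_eps(n, p, rng)
        delay_steps = int(round(p.tau_j / dt))
        status = _kernels.ml_network(
            v, w, islow, s, eps, w_mat,
            cp.g_bar_s / cp.c_n, cp.v_rev_syn,
            prof * stim_weight, slow_prof, train.amp_pos, train.amp_neg,
            train.t_pos_ms, train.t_neg_ms, train.period_ms, t_on, t_off,
            noise, noise_stride,
            p.g_ca, p.g_k, p.g_l, p.v_ca, p.v_k, p.v_l,
            p.v1, p.v2, p.v3, p.v4, p.C, p.phi, p.v_star, p.alpha, p.s1,
            gp.alpha_s, gp.beta_s, gp.theta_s, gp.sigma_s,
            dt, n_steps, delay_steps, rec_stride,
            v_rec, iion_rec,
        )
        _check_status(status, "morris_lecar")
        spikes: list[np.ndarray] = [np.empty(0) for _ in range(n)]
    else:
        p: IzhParams = config.neuron  # type: ignore[assignment]
        v, u, s = _init_izh(config, n, rng)
        drives = draw_drive(n, p, rng)
        max_spk = int(config.duration_s * 1000.0)  # ISI floor ~2 ms: generous cap
        spike_times = np.empty((n, max_spk))
        spike_counts = np.zeros(n, dtype=np.int64)
        status = _kernels.izh_network(
            v, u, s, w_mat,
            cp.g_bar_s / cp.c_n, cp.v_rev_syn, cp.v_scale, cp.i_scale,
            prof, stim_weight, train.amp_pos, train.amp_neg,
            train.t_pos_ms, train.t_neg_ms, train.period_ms, t_on, t_off,
            noise, noise_stride,
            p.a, p.b, p.c_reset, p.d, drives, p.spike_cut,
            gp.alpha_s, gp.beta_s, gp.theta_s, gp.sigma_s,
            dt, n_steps, rec_stride,
            v_rec, iion_rec, spike_times, spike_counts,
        )
        _check_status(status, "izhikevich")
        spikes = [spike_times[j, : spike_counts[j]].copy() for j in range(n)]

    times_ms = np.arange(n_rec) * rec_stride * dt
    return SimulationTrace(
        times_ms=times_ms, V=v_rec, I_ion=iion_rec, spike_times=spikes,
        lattice=lattice, config=config,
    )


def run_two_population(
    pacemaker_config: ScenarioConfig,
    driven_config: ScenarioConfig,
    coupling: InterPopCoupling | None = None,
    ff_rel_sd: float = 0.2,
) -> tuple[SimulationTrace, SimulationTrace]:
    """Integrate the pacemaker->driven pair (Izhikevich backend).

    Stimulation (if configured) targets the pacemaker only; the driven
    population keeps its own (weak) intra-coupling and receives the
    feedforward Gaussian-random synaptic current from the pacemaker gates.
    When ``coupling`` is omitted it is built with its mean pinned to the mean
    intra-pacemaker weight (the strong-driving condition).
    """
    c1, c2 = pacemaker_config, driven_config
    if c1.backend != "izhikevich" or c2.backend != "izhikevich":
        raise ValueError("the two-population experiment is defined for the izhikevich backend")
    if c1.dt_ms != c2.dt_ms or c1.duration_s != c2.duration_s:
        raise ValueError("both populations must share dt and duration")
    if c2.stimulation is not None:
        raise ValueError("stimulation targets the pacemaker population only")

    lat1 = build_lattice(c1.n_neurons, c1.dl, c1.jitter_sd, c1.seeds.lattice)
    lat2 = build_lattice(c2.n_neurons, c2.dl, c2.jitter_sd, c2.seeds.lattice)
    w1 = coupling_matrix(lat1, c1.coupling.sigma_g)
    w2 = coupling_matrix(lat2, c2.coupling.sigma_g)
    if coupling is None:
        coupling = build_interpop_coupling(
            lat1, lat2, c1.coupling.sigma_g, rel_sd=ff_rel_sd, seed=c1.seeds.interpop
        )
    if coupling.weights.shape != (lat2.n, lat1.n):
        raise ValueError("inter-population coupling has mismatched shape")

    dt = c1.dt_ms
    n_steps = int(round(c1.duration_s * 1000.0 / dt))
    rec_stride = max(1, int(round(c1.record_stride_ms / dt)))
    n_rec = (n_steps + rec_stride - 1) // rec_stride
    noise1, noise_stride = _noise_matrix(c1, lat1.n, c1.seeds.noise)
    noise2, _ = _noise_matrix(c2, lat2.n, c2.seeds.noise)
    prof, _slow, train, t_on, t_off, stim_weight = _stim_arrays(c1, lat1)
    rng1 = np.random.default_rng(c1.seeds.init)
    rng2 = np.random.default_rng(c2.seeds.init)
    p: IzhParams = c1.neuron  # type: ignore[assignment]
    gp = c1.gate
    cp1, cp2 = c1.coupling, c2.coupling
    v1, u1, s1 = _init_izh(c1, lat1.n, rng1)
    v2, u2, s2 = _init_izh(c2, lat2.n, rng2)
    drives1 = draw_drive(lat1.n, p, rng1)
    drives2 = draw_drive(lat2.n, c2.neuron, rng2)  # type: ignore[arg-type]
    max_spk = int(c1.duration_s * 1000.0)
    st1 = np.empty((lat1.n, max_spk)); sc1 = np.zeros(lat1.n, dtype=np.int64)
    st2 = np.empty((lat2.n, max_spk)); sc2 = np.zeros(lat2.n, dtype=np.int64)
    vr1 = np.empty((lat1.n, n_rec)); ir1 = np.empty((lat1.n, n_rec))
    vr2 = np.empty((lat2.n, n_rec)); ir2 = np.empty((lat2.n, n_rec))

    status = _kernels.izh_two_populations(
        v1, u1, s1, w1, v2, u2, s2, w2, coupling.weights,
        cp1.g_bar_s / cp1.c_n, cp2.g_bar_s / cp2.c_n, cp1.g_bar_s / cp1.c_n,
        cp1.v_rev_syn, cp1.v_scale, cp1.i_scale,
        prof, stim_weight, train.amp_pos, train.amp_neg,
        train.t_pos_ms, train.t_neg_ms, train.period_ms, t_on, t_off,
        noise1, noise2, noise_stride,
        p.a, p.b, p.c_reset, p.d, drives1, drives2, p.spike_cut,
        gp.alpha_s, gp.beta_s, gp.theta_s, gp.sigma_s,
        dt, n_steps, rec_stride,
        vr1, ir1, st1, sc1, vr2, ir2, st2, sc2,
    )
    _check_status(status, "izhikevich two-population")

    times_ms = np.arange(n_rec) * rec_stride * dt
    tr1 = SimulationTrace(times_ms, vr1, ir1,
                          [st1[j, : sc1[j]].copy() for j in range(lat1.n)], lat1, c1)
    tr2 = SimulationTrace(times_ms, vr2, ir2,
                          [st2[j, : sc2[j]].copy() for j in range(lat2.n)], lat2, c2)
    return tr1, tr2
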