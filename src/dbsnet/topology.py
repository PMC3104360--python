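"""Lattice geometry and synaptic coupling.

Neurons sit on a square lattice with spacing ``dl``.  Excitatory synaptic
interaction is local: each pair is weighted by a Gaussian kernel of the
pairwise distance, optionally jittered (a zero-mean Gaussian added to the
distances themselves, not the positions, to emulate a disordered "random
network").  The feedforward pacemaker->driven pathway replaces the distance
kernel with Gaussian-random weights whose mean matches the mean intra-
pacemaker weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Lattice",
    "CouplingParams",
    "InterPopCoupling",
    "build_lattice",
    "spatial_weight",
    "coupling_matrix",
    "synaptic_current",
    "synaptic_currents",
    "build_interpop_coupling",
    "interpop_current",
    "interpop_currents",
]


@dataclass(frozen=True)
class Lattice:
    """Square lattice of neuron positions with (possibly jittered) distances."""

    positions: np.ndarray  # (N, 2) lattice units
    distances: np.ndarray  # (N, N), diagonal 0, >= 0
    dl: float
    jitter_sd: float
    seed: int

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def side(self) -> int:
        return int(round(np.sqrt(self.n)))

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        return self.positions.min(axis=0), self.positions.max(axis=0)


@dataclass(frozen=True)
class CouplingParams:
    """Synaptic coupling constants.

    I_syn_j = (g_bar_s / c_n) * sum_{k != j} w(D_jk) * s_k * (v_j - v_rev_syn)
    with w the spatial kernel of width ``sigma_g``.  The reversal potential
    ``v_rev_syn`` sits below the entire bursting voltage range, so the
    driving force (v_j - v_rev_syn) is positive whenever the neuron is
    active and the coupling is excitatory (glutamatergic), which is what
    synchronizes the lattice.  ``c_n`` is a fixed normalization constant
    (reference values: 2.0584 for the 100-neuron ML lattice, 2.1765 for the
    225-neuron Izhikevich lattice); :func:`auto_c_n` offers a size-consistent
    alternative.  ``v_scale`` maps the postsynaptic membrane potential into
    the (dimensionless) voltage scale the synaptic driving force is
    expressed in: 1 for the ML backend, 0.01 for the Izhikevich backend,
    whose potentials are in mV but whose synaptic dynamics are inherited
    unchanged from the dimensionless formulation; ``i_scale`` converts the
    resulting dimensionless current into the backend's current units.
    """

    g_bar_s: float = 0.4
    v_rev_syn: float = -0.85
    sigma_g: float = 0.5
    c_n: float = 2.0584
    v_scale: float = 1.0
    i_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.g_bar_s < 0:
            raise ValueError("g_bar_s must be nonnegative")
        if self.sigma_g <= 0 or self.c_n <= 0:
            raise ValueError("sigma_g and c_n must be positive")


def build_lattice(n: int, dl: float = 0.1, jitter_sd: float = 0.0, seed: int = 0) -> Lattice:
    """Regular square lattice of ``n`` neurons with optional distance jitter.

    ``n`` must be a perfect square.  Positions are a regular grid with spacing
    ``dl``; the pairwise distance matrix gets an independent N(0, jitter_sd)
    draw added per ordered pair (clamped at 0), so it is symmetric only for
    ``jitter_sd = 0``.  The diagonal stays exactly 0.
    """
    side = int(round(np.sqrt(n)))
    if side * side != n:
        raise ValueError(f"neuron count {n} is not a perfect square")
    if dl <= 0:
        raise ValueError("lattice spacing dl must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    xs = np.arange(side) * dl
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    positions = np.column_stack([gx.ravel(), gy.ravel()])
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        dist = dist + rng.normal(0.0, jitter_sd, size=dist.shape)
        dist = np.clip(dist, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return Lattice(positions=positions, distances=dist, dl=dl, jitter_sd=jitter_sd, seed=seed)


def spatial_weight(d, sigma_g: float):
    """Distance-dependent synaptic kernel w(d) = exp(-d^2 / (2 sigma_g^2))."""
    d = np.asarray(d, dtype=float)
    return np.exp(-(d**2) / (2.0 * sigma_g**2))


def coupling_matrix(lattice: Lattice, sigma_g: float) -> np.ndarray:
    """Pairwise weight matrix w(D) with zero diagonal (no self-coupling)."""
    w = spatial_weight(lattice.distances, sigma_g)
    np.fill_diagonal(w, 0.0)
    return w


def auto_c_n(lattice: Lattice, sigma_g: float) -> float:
    """Mean over neurons of the summed incoming kernel weight.

    A size-consistent normalization for lattices whose printed constant is
    unknown; not used by the packaged default scenarios, which keep the
    printed c_n values.
    """
    return float(coupling_matrix(lattice, sigma_g).sum(axis=1).mean())


def synaptic_current(v_j: float, gates: np.ndarray, weights_row: np.ndarray, params: CouplingParams) -> float:
    """Synaptic input to one neuron from the gates of all others."""
    gates = np.asarray(gates, dtype=float)
    weights_row = np.asarray(weights_row, dtype=float)
    if gates.shape != weights_row.shape:
        raise ValueError("gates and weights row have mismatched shapes")
    drive = params.v_scale * v_j - params.v_rev_syn
    return float(params.i_scale * (params.g_bar_s / params.c_n) * (weights_row @ gates) * drive)


def synaptic_currents(v: np.ndarray, gates: np.ndarray, weights: np.ndarray, params: CouplingParams) -> np.ndarray:
    """Vectorized synaptic input for the whole population."""
    if weights.shape[1] != gates.shape[0]:
        raise ValueError("gates and weight matrix have mismatched shapes")
    drive = params.v_scale * np.asarray(v, dtype=float) - params.v_rev_syn
    return params.i_scale * (params.g_bar_s / params.c_n) * (weights @ gates) * drive


@dataclass(frozen=True)
class InterPopCoupling:
    """Directed pacemaker->driven weights, Gaussian-distributed.

    ``weights[i, k]`` couples pacemaker neuron k onto driven neuron i.  The
    draw is calibrated so the realized mean weight stays within 5% of the
    mean intra-pacemaker coupling weight (the stated strong-driving regime).
    """

    weights: np.ndarray  # (N_driven, N_pacemaker)
    mean_weight: float
    seed: int


def build_interpop_coupling(
    pacemaker: Lattice,
    driven: Lattice,
    sigma_g: float,
    rel_sd: float = 0.2,
    seed: int = 0,
) -> InterPopCoupling:
    """Random feedforward coupling with mean pinned to the pacemaker's mean weight.

    The mean of the Gaussian weight distribution equals the mean off-diagonal
    intra-pacemaker kernel weight; ``rel_sd`` is the coefficient of variation
    of the draw (the source text states only the Gaussian form and the mean).
    Weights are clipped at 0 and the realized matrix is rescaled to hit the
    target mean exactly, which keeps the <=5% mean invariant for any seed.
    """
    w_intra = coupling_matrix(pacemaker, sigma_g)
    n_p = pacemaker.n
    mean_w = float(w_intra.sum() / (n_p * (n_p - 1)))
    rng = np.random.default_rng(seed)
    weights = rng.normal(mean_w, rel_sd * mean_w, size=(driven.n, pacemaker.n))
    weights = np.clip(weights, 0.0, None)
    weights *= mean_w / weights.mean()
    return InterPopCoupling(weights=weights, mean_weight=mean_w, seed=seed)


def interpop_current(
    v_j: float, pacemaker_gates: np.ndarray, weights_row: np.ndarray, params: CouplingParams
) -> float:
    """Feedforward synaptic input to one driven neuron (same form, random weights)."""
    return synaptic_current(v_j, pacemaker_gates, weights_row, params)


def interpop_currents(
    v_driven: np.ndarray, pacemaker_gates: np.ndarray, coupling: InterPopCoupling, params: CouplingParams
) -> np.ndarray:
    """Vectorized feedforward input to the driven population; strictly one-way."""
    if coupling.weights.shape[1] != pacemaker_gates.shape[0]:
        raise ValueError("pacemaker gates and coupling matrix have mismatched shapes")
    drive = params.v_scale * np.asarray(v_driven, dtype=float) - params.v_rev_syn
    return params.i_scale * (params.g_bar_s / params.c_n) * (coupling.weights @ pacemaker_gates) * drive
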