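"""Charge-balanced high-frequency pulse-train stimulation.

The DBS waveform W(t) is a 130 Hz train of biphasic pulses: a short positive
phase (0.2 ms) followed by a longer negative phase (3.0 ms) whose amplitude is
derived so the net charge per period is exactly zero.  Stimulation reaches
each neuron through one or four electrodes, decaying exponentially with
distance; a layout normalization keeps the total delivered stimulation
independent of the electrode count.  All times are in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import Lattice

__all__ = [
    "PulseTrain",
    "ElectrodeArray",
    "StimWindow",
    "pulse_waveform",
    "stim_window_indicator",
    "stim_current",
    "stim_profile",
    "electrode_layout",
]


@dataclass(frozen=True)
class PulseTrain:
    """Periodic charge-balanced biphasic pulse.

    ``amp_neg`` is derived, not set: amp_pos*t_pos + amp_neg*t_neg = 0.
    """

    freq_hz: float = 130.0
    t_pos_ms: float = 0.2
    t_neg_ms: float = 3.0
    amp_pos: float = 1.0

    def __post_init__(self) -> None:
        if self.freq_hz <= 0 or self.t_pos_ms <= 0 or self.t_neg_ms <= 0:
            raise ValueError("frequency and phase widths must be positive")
        if self.t_pos_ms + self.t_neg_ms > self.period_ms:
            raise ValueError("biphasic pulse does not fit in one period")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.freq_hz

    @property
    def amp_neg(self) -> float:
        return -self.amp_pos * self.t_pos_ms / self.t_neg_ms


def pulse_waveform(t_ms, train: PulseTrain):
    """W(t): amp_pos on [0, t_pos), amp_neg on [t_pos, t_pos+t_neg), 0 after.

    Periodic with period 1/freq; vectorized over ``t_ms``.
    """
    phase = np.mod(np.asarray(t_ms, dtype=float), train.period_ms)
    out = np.where(
        phase < train.t_pos_ms,
        train.amp_pos,
        np.where(phase < train.t_pos_ms + train.t_neg_ms, train.amp_neg, 0.0),
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class StimWindow:
    """Onset/offset of stimulation (the step function X1), in ms."""

    t_on_ms: float
    t_off_ms: float

    def __post_init__(self) -> None:
        if not self.t_on_ms < self.t_off_ms:
            raise ValueError("stimulation window requires t_on < t_off")


def stim_window_indicator(t_ms, window: StimWindow | None):
    """X1(t): 1 inside [t_on, t_off), else 0; identically 0 without a window."""
    t = np.asarray(t_ms, dtype=float)
    if window is None:
        out = np.zeros_like(t)
    else:
        out = ((t >= window.t_on_ms) & (t < window.t_off_ms)).astype(float)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ElectrodeArray:
    """Stimulation electrode layout with spatial decay and count normalization.

    Per-neuron stimulation current:
    I_stim_j(t) = (c_s / c_n_stim) * sum_k exp(-||y_j - y^k|| / decay_len)
                  * X1(t) * W(t).
    ``c_n_stim`` is chosen by :func:`electrode_layout` so that
    sum_j sum_k exp(-d_jk/decay_len) / c_n_stim is the same for every layout
    on the same lattice (total delivered stimulation independent of the
    number of electrodes).
    """

    positions: np.ndarray  # (K, 2)
    c_s: float = 0.1
    decay_len: float = 0.5
    c_n_stim: float = 1.0

    def __post_init__(self) -> None:
        if self.positions.ndim != 2 or self.positions.shape[0] == 0:
            raise ValueError("electrode array must hold at least one position")
        if self.c_s < 0 or self.decay_len <= 0 or self.c_n_stim <= 0:
            raise ValueError("invalid electrode array constants")


def _decay_sum(neuron_pos: np.ndarray, array: ElectrodeArray) -> np.ndarray:
    pos = np.atleast_2d(np.asarray(neuron_pos, dtype=float))
    d = np.linalg.norm(pos[:, None, :] - array.positions[None, :, :], axis=2)
    return np.exp(-d / array.decay_len).sum(axis=1)


def stim_profile(lattice: Lattice, array: ElectrodeArray) -> np.ndarray:
    """Static per-neuron spatial factor (c_s/c_n_stim) * sum_k exp(-d/lambda)."""
    return (array.c_s / array.c_n_stim) * _decay_sum(lattice.positions, array)


def stim_current(
    neuron_pos,
    t_ms,
    array: ElectrodeArray,
    train: PulseTrain,
    window: StimWindow | None,
):
    """Stimulation current at a neuron position and time (both vectorizable)."""
    spatial = _decay_sum(neuron_pos, array)
    if spatial.size == 1:
        spatial = float(spatial[0])
    wt = pulse_waveform(t_ms, train) * stim_window_indicator(t_ms, window)
    return (array.c_s / array.c_n_stim) * spatial * wt


def electrode_layout(
    mode: str,
    lattice: Lattice,
    c_s: float = 0.1,
    decay_len: float = 0.5,
) -> ElectrodeArray:
    """Build the one-electrode (``center``) or four-electrode (``quad``) layout.

    ``center`` places a single electrode at the lattice centroid; ``quad``
    places four electrodes at the centroids of the four equal quadrants of
    the lattice bounding box.  ``c_n_stim`` normalizes the summed exponential
    reach over the lattice against the single-center layout, so the total
    delivered stimulation matches the one-electrode protocol exactly.
    """
    lo, hi = lattice.bbox
    center = lattice.centroid
    if mode == "center":
        positions = center[None, :]
    elif mode == "quad":
        q1 = lo + 0.25 * (hi - lo)
        q3 = lo + 0.75 * (hi - lo)
        positions = np.array([[q1[0], q1[1]], [q1[0], q3[1]], [q3[0], q1[1]], [q3[0], q3[1]]])
    else:
        raise ValueError(f"unknown electrode layout mode: {mode!r}")
    ref = ElectrodeArray(positions=center[None, :], c_s=c_s, decay_len=decay_len, c_n_stim=1.0)
    arr = ElectrodeArray(positions=positions, c_s=c_s, decay_len=decay_len, c_n_stim=1.0)
    total_ref = _decay_sum(lattice.positions, ref).sum()
    total = _decay_sum(lattice.positions, arr).sum()
    return ElectrodeArray(
        positions=positions, c_s=c_s, decay_len=decay_len, c_n_stim=float(total / total_ref)
    )
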