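"""Synthetic ground-truth generators for testing the metrics stack.

These fixtures exercise burst detection, phase reconstruction and the order
parameter without running the network simulator: periodic burst trains with
controlled Gaussian onset jitter (whose expected order parameter is known in
closed form), and voltage traces with stereotyped bursts injected at known
onsets.  Times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sync import BurstTrain

__all__ = [
    "SyntheticBurstSpec",
    "expected_R",
    "make_burst_population",
    "burst_template",
    "make_voltage_with_bursts",
]


@dataclass(frozen=True)
class SyntheticBurstSpec:
    n_neurons: int = 50
    burst_rate_hz: float = 5.0
    phase_dispersion_ms: float = 0.0  # sd of per-onset Gaussian jitter
    duration_ms: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_rate_hz <= 0:
            raise ValueError("burst_rate_hz must be positive")
        if self.phase_dispersion_ms < 0:
            raise ValueError("phase_dispersion_ms must be nonnegative")


def expected_R(spec: SyntheticBurstSpec) -> float:
    """Analytic order parameter for Gaussian onset jitter.

    Onset jitter of sd ``sigma`` ms at burst period T maps to phase jitter of
    sd 2*pi*sigma/T; the modulus of the mean phasor of a Gaussian phase
    distribution is its characteristic function exp(-sd_phi^2 / 2).
    """
    sd_phi = 2.0 * np.pi * spec.burst_rate_hz * spec.phase_dispersion_ms / 1000.0
    return float(np.exp(-(sd_phi**2) / 2.0))


def make_burst_population(spec: SyntheticBurstSpec) -> list[BurstTrain]:
    """Per-neuron burst trains: a common periodic grid plus Gaussian jitter.

    Jitter is drawn independently per neuron per onset; onsets are sorted so
    each train stays strictly increasing.  For dispersion small against the
    period the sort is a no-op and the measured order parameter follows the
    Gaussian characteristic function (:func:`expected_R`); for dispersion
    much larger than the period the onsets decorrelate across neurons and
    the order parameter collapses to the finite-size floor.
    """
    period = 1000.0 / spec.burst_rate_hz
    grid = np.arange(period, spec.duration_ms, period)
    rng = np.random.default_rng(spec.seed)
    trains = []
    for _ in range(spec.n_neurons):
        t = np.sort(grid + rng.normal(0.0, spec.phase_dispersion_ms, size=grid.size))
        keep = np.concatenate([[True], np.diff(t) > 1e-9])
        trains.append(BurstTrain(t[keep]))
    return trains


def burst_template(
    n_spikes: int = 6,
    spike_width_ms: float = 4.0,
    isi_ms: float = 10.0,
    amplitude: float = 1.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Stereotyped burst: ``n_spikes`` clipped sinusoid humps.

    The shape is irrelevant to the metrics by design; it only has to cross a
    detection threshold once per spike.
    """
    t = np.arange(0.0, n_spikes * isi_ms, dt)
    phase = np.mod(t, isi_ms)
    hump = np.where(
        phase < spike_width_ms, np.sin(np.pi * phase / spike_width_ms), 0.0
    )
    return amplitude * hump


def make_voltage_with_bursts(
    onsets: BurstTrain,
    template: np.ndarray,
    duration_ms: float,
    dt: float = 1.0,
    baseline: float = -1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Baseline trace with template copies at the onsets plus Gaussian noise.

    Raises when templates would overlap (template longer than the minimum
    inter-onset gap).
    """
    n = int(round(duration_ms / dt))
    t_on = onsets.onset_times
    if t_on.size > 1 and template.size * dt >= np.min(np.diff(t_on)):
        raise ValueError("burst template overlaps consecutive onsets")
    v = np.full(n, baseline)
    for t0 in t_on:
        i0 = int(round(t0 / dt))
        i1 = min(i0 + template.size, n)
        if i0 < n:
            v[i0:i1] = baseline + template[: i1 - i0]
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return v
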