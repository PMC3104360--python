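"""Trace-level analysis: burst trains, order parameter series, LFP, spectra.

Thin glue between :class:`~dbsnet.engine.SimulationTrace` and the metric
modules.  Burst onsets come from threshold crossings of the recorded voltage
for the Morris-Lecar backend and from the exact logged spike times for the
Izhikevich backend (whose 1 ms voltage record undersamples individual
spikes).  Windows at this level are in seconds.
"""

from __future__ import annotations

import numpy as np

from .engine import SimulationTrace
from .lfp import LFPTrace, Spectrogram, band_power_ratio, lfp_from_currents, spectrogram_db
from .sync import (
    BurstTrain,
    SyncSeries,
    bursts_from_spikes,
    compute_sync_series,
    detect_burst_onsets,
    mean_R,
    spikes_per_burst,
)

__all__ = [
    "burst_trains",
    "sync_series",
    "mean_r_window",
    "lfp_trace",
    "lfp_spectrogram",
    "band_fraction",
    "burst_spike_counts",
]

# Burst-onset detection defaults per backend.  The quiescence gaps sit well
# above the largest intra-burst pauses (tens of ms, including the stutter at
# burst tails) and well below the inter-burst intervals (>150 ms).
ML_THRESHOLD = -0.05
ML_MIN_GAP_MS = 100.0       # quiescence gap for burst-onset (phase) detection
ML_SPIKE_GAP_MS = 40.0      # tighter gap for grouping spikes into bursts
IZH_MIN_GAP_MS = 30.0  # gap rule for grouping logged Izhikevich spikes


def burst_trains(trace: SimulationTrace, min_gap_ms: float | None = None) -> list[BurstTrain]:
    """Per-neuron burst onsets for a recorded run."""
    if trace.config.backend == "morris_lecar":
        dt = float(trace.times_ms[1] - trace.times_ms[0])
        gap = ML_MIN_GAP_MS if min_gap_ms is None else min_gap_ms
        return [
            detect_burst_onsets(trace.V[j], dt, ML_THRESHOLD, min_gap=gap)
            for j in range(trace.n_neurons)
        ]
    gap = IZH_MIN_GAP_MS if min_gap_ms is None else min_gap_ms
    return [bursts_from_spikes(st, min_gap=gap) for st in trace.spike_times]


def sync_series(
    trace: SimulationTrace,
    min_gap_ms: float | None = None,
    extrapolate: bool = True,
) -> SyncSeries:
    """Time-resolved burst-phase order parameter on the trace's record grid.

    Phases are extrapolated past each neuron's covered onset interval at its
    nearest observed burst rate (see :func:`dbsnet.sync.phase_from_onsets`),
    so neurons whose bursting is suppressed by stimulation stay in the order
    parameter instead of being dropped, which would bias R toward the
    still-bursting (and typically still-synchronized) remainder.
    """
    trains = burst_trains(trace, min_gap_ms=min_gap_ms)
    return compute_sync_series(trains, trace.times_ms, extrapolate=extrapolate)


def mean_r_window(series: SyncSeries, window_s: tuple[float, float]) -> float:
    """Time-averaged R over a window given in seconds."""
    return mean_R(series, (window_s[0] * 1000.0, window_s[1] * 1000.0))


def lfp_trace(trace: SimulationTrace, electrode_pos=None) -> LFPTrace:
    """Simulated LFP at a recording electrode (default: lattice centroid).

    Uses the recorded total non-stimulation currents; the distance floor is
    half the lattice spacing.
    """
    pos = trace.lattice.centroid if electrode_pos is None else np.asarray(electrode_pos)
    return lfp_from_currents(
        trace.I_ion,
        trace.lattice.positions,
        pos,
        trace.times_ms,
        dist_floor=trace.lattice.dl / 2.0,
    )


def lfp_spectrogram(
    trace: SimulationTrace, window_len_s: float = 1.0, overlap: float = 0.75
) -> Spectrogram:
    return spectrogram_db(lfp_trace(trace), window_len_s=window_len_s, overlap=overlap)


def band_fraction(
    spec: Spectrogram, band_hz: tuple[float, float] = (5.0, 20.0),
    window_s: tuple[float, float] | None = None,
) -> float:
    """Fraction of LFP power in a band (default the pathological 5-20 Hz)."""
    return band_power_ratio(spec, band_hz, window=window_s)


def burst_spike_counts(trace: SimulationTrace, min_gap_ms: float | None = None) -> list[np.ndarray]:
    """Spikes-per-burst arrays per neuron (Izhikevich: from logged spikes)."""
    if trace.config.backend == "morris_lecar":
        # count spike-level upward crossings of a spike threshold between onsets
        dt = float(trace.times_ms[1] - trace.times_ms[0])
        gap = ML_SPIKE_GAP_MS if min_gap_ms is None else min_gap_ms
        out = []
        for j in range(trace.n_neurons):
            v = trace.V[j]
            up = np.flatnonzero((v[:-1] < 0.0) & (v[1:] >= 0.0))
            out.append(spikes_per_burst((up + 1) * dt, min_gap=gap))
        return out
    gap = IZH_MIN_GAP_MS if min_gap_ms is None else min_gap_ms
    return [spikes_per_burst(st, min_gap=gap) for st in trace.spike_times]
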