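"""Simulated local field potential and spectral readouts.

The LFP at a virtual recording electrode is the point-source sum of every
neuron's total ionic current weighted by the inverse distance to the
electrode, LFP(t) = R_e * sum_j I_j(t) / r_j, with homogeneous extracellular
resistivity R_e = 1.  The stimulation current is excluded from I_j by the
caller.  Spectrograms (short-time power in dB, Hann window) expose the
pathological low-frequency (5-20 Hz) concentration of power and its spreading
under stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "LFPTrace",
    "Spectrogram",
    "lfp_from_currents",
    "spectrogram_db",
    "band_power_ratio",
]


@dataclass(frozen=True)
class LFPTrace:
    times: np.ndarray  # (T,) ms, uniform
    lfp: np.ndarray  # (T,)
    electrode_pos: np.ndarray
    R_e: float = 1.0

    @property
    def fs_hz(self) -> float:
        dt_ms = float(self.times[1] - self.times[0])
        return 1000.0 / dt_ms


@dataclass(frozen=True)
class Spectrogram:
    freqs: np.ndarray  # (F,) Hz
    times: np.ndarray  # (W,) s
    power: np.ndarray  # (F, W) linear power

    @property
    def db(self) -> np.ndarray:
        return 10.0 * np.log10(np.maximum(self.power, 1e-300))


def lfp_from_currents(
    currents: np.ndarray,
    positions: np.ndarray,
    electrode_pos: np.ndarray,
    times: np.ndarray,
    R_e: float = 1.0,
    dist_floor: float = 0.05,
) -> LFPTrace:
    """1/r-weighted sum of per-neuron currents at the recording electrode.

    ``currents`` is (N, T) and must exclude the stimulation current.
    Distances below ``dist_floor`` (default half the reference lattice
    spacing) are floored to avoid the point-source singularity when the
    electrode coincides with a neuron.
    """
    electrode_pos = np.asarray(electrode_pos, dtype=float)
    r = np.linalg.norm(np.asarray(positions, dtype=float) - electrode_pos, axis=1)
    r = np.maximum(r, dist_floor)
    lfp = R_e * (currents / r[:, None]).sum(axis=0)
    return LFPTrace(times=np.asarray(times, dtype=float), lfp=lfp, electrode_pos=electrode_pos, R_e=R_e)


def spectrogram_db(trace: LFPTrace, window_len_s: float = 1.0, overlap: float = 0.75) -> Spectrogram:
    """Short-time power spectrum of the LFP (Hann window).

    Defaults (1 s window, 75% overlap) resolve the 5-20 Hz band where the
    synchronized network concentrates its power.  The mean is removed first
    so the DC bin does not mask the low-frequency content.
    """
    nper = int(round(window_len_s * trace.fs_hz))
    if nper > trace.lfp.size:
        raise ValueError("spectrogram window longer than trace")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    x = trace.lfp - trace.lfp.mean()
    f, t, sxx = signal.spectrogram(
        x,
        fs=trace.fs_hz,
        window="hann",
        nperseg=nper,
        noverlap=int(round(overlap * nper)),
        scaling="density",
        mode="psd",
    )
    return Spectrogram(freqs=f, times=t, power=sxx)


def band_power_ratio(
    spec: Spectrogram,
    band: tuple[float, float],
    window: tuple[float, float] | None = None,
) -> float:
    """Fraction of total power that falls inside ``band`` over a time window.

    mean power in [f1, f2] x [t_a, t_b] divided by total power in the same
    time window; 1 when the band spans the full frequency axis.
    """
    f1, f2 = band
    if not f1 < f2:
        raise ValueError("empty frequency band")
    in_band = (spec.freqs >= f1) & (spec.freqs <= f2)
    if not np.any(in_band):
        raise ValueError("band outside resolved frequency range")
    if window is None:
        in_t = np.ones(spec.times.size, dtype=bool)
    else:
        in_t = (spec.times >= window[0]) & (spec.times <= window[1])
        if not np.any(in_t):
            raise ValueError("empty time window")
    p = spec.power[:, in_t]
    total = p.sum()
    if total == 0:
        return 0.0
    return float(p[in_band, :].sum() / total)
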