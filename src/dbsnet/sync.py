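"""Burst-phase synchronization metrics.

The population's prominent dynamics is bursting, so each neuron's phase is
anchored to its burst onsets: the phase grows linearly by 2*pi between
consecutive onsets.  Population synchrony is the Kuramoto order parameter of
these burst phases, R(t) e^{i Theta(t)} = mean_j e^{i phi_j(t)}: R = 1 is
perfect in-phase bursting, R = 0 complete desynchronization.  Samples outside
a neuron's covered onset interval are invalid and excluded from R rather than
extrapolated, which avoids biasing R at window edges.  Times are in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BurstTrain",
    "SyncSeries",
    "detect_burst_onsets",
    "bursts_from_spikes",
    "spikes_per_burst",
    "phase_from_onsets",
    "order_parameter",
    "compute_sync_series",
    "mean_R",
]


@dataclass(frozen=True)
class BurstTrain:
    """Strictly increasing burst-onset times of one neuron (ms)."""

    onset_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.onset_times, dtype=float)
        object.__setattr__(self, "onset_times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("burst onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onset_times.size


@dataclass
class SyncSeries:
    """Time-resolved order parameter on a uniform sample grid."""

    times: np.ndarray  # (T,) ms
    phases: np.ndarray  # (N, T), NaN where invalid
    R: np.ndarray  # (T,), NaN where no valid phase
    Theta: np.ndarray  # (T,) in [-pi, pi)
    n_valid: np.ndarray  # (T,) number of neurons entering R


def _auto_min_gap(crossing_times: np.ndarray) -> float:
    """Gap threshold = 3x the median inter-crossing interval.

    Within a burst the inter-spike interval dominates the median, so three
    times it separates intra-burst spikes from inter-burst pauses.
    """
    if crossing_times.size < 2:
        return np.inf
    return 3.0 * float(np.median(np.diff(crossing_times)))


def detect_burst_onsets(
    v_trace: np.ndarray,
    dt: float,
    threshold: float,
    min_gap: float | None = None,
) -> BurstTrain:
    """Burst onsets from a voltage trace: threshold crossings after quiescence.

    An onset is an upward crossing of ``threshold`` preceded by a
    sub-threshold interval of at least ``min_gap`` ms (auto-estimated from
    the crossing statistics when omitted).  Returns an empty train when the
    trace never crosses.
    """
    v = np.asarray(v_trace, dtype=float)
    if v.size < 2:
        raise ValueError("trace needs at least 2 samples")
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    if up.size == 0:
        return BurstTrain(np.empty(0))
    t_cross = (up + 1) * dt
    gap = _auto_min_gap(t_cross) if min_gap is None else float(min_gap)
    onsets = bursts_from_spikes(t_cross, min_gap=gap)
    return onsets


def bursts_from_spikes(spike_times: np.ndarray, min_gap: float | None = None) -> BurstTrain:
    """Group spike (or crossing) times into bursts; the onset is the first spike.

    A new burst starts whenever the gap since the previous spike is at least
    ``min_gap`` ms.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        return BurstTrain(np.empty(0))
    gap = _auto_min_gap(st) if min_gap is None else float(min_gap)
    if not np.isfinite(gap):
        return BurstTrain(st[:1])
    breaks = np.flatnonzero(np.diff(st) >= gap)
    onsets = st[np.concatenate([[0], breaks + 1])]
    return BurstTrain(onsets)


def spikes_per_burst(spike_times: np.ndarray, min_gap: float | None = None) -> np.ndarray:
    """Spike counts of each burst under the same gap rule."""
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        return np.empty(0, dtype=int)
    gap = _auto_min_gap(st) if min_gap is None else float(min_gap)
    if not np.isfinite(gap):
        return np.array([st.size])
    breaks = np.flatnonzero(np.diff(st) >= gap)
    edges = np.concatenate([[0], breaks + 1, [st.size]])
    return np.diff(edges).astype(int)


def phase_from_onsets(train: BurstTrain, t, extrapolate: bool = False) -> np.ndarray:
    """Piecewise-linear burst phase phi(t) = 2 pi k + 2 pi (t - t_k)/(t_{k+1} - t_k).

    By default valid only on [first onset, last onset]; samples outside are
    NaN and downstream metrics exclude them.  With ``extrapolate=True`` the
    phase continues past the covered interval at the rate of the nearest
    observed inter-onset interval: a neuron whose bursting is suppressed
    keeps advancing at its last (stimulation-lengthened) burst rate instead
    of silently leaving the order parameter.  Trains with fewer than two
    onsets carry no rate information and stay invalid.  Vectorized over
    ``t``.
    """
    t = np.asarray(t, dtype=float)
    onsets = train.onset_times
    out = np.full(t.shape, np.nan)
    if len(train) < 2:
        return out if out.ndim else float(out)
    k = np.searchsorted(onsets, t, side="right") - 1
    kk = np.clip(k, 0, onsets.size - 2)
    frac = (t - onsets[kk]) / (onsets[kk + 1] - onsets[kk])
    phi = 2.0 * np.pi * (kk + frac)
    if extrapolate:
        out[:] = phi
    else:
        valid = (k >= 0) & (t <= onsets[-1])
        out[valid] = phi[valid]
        at_end = valid & (t == onsets[-1])
        out[at_end] = 2.0 * np.pi * (onsets.size - 1)
    return out if out.ndim else float(out)


def order_parameter(phases: np.ndarray) -> tuple[float, float]:
    """Kuramoto order parameter of one phase snapshot, ignoring NaN entries.

    R e^{i Theta} = mean_j e^{i phi_j}.  Raises when no valid phase remains.
    """
    phi = np.asarray(phases, dtype=float)
    phi = phi[np.isfinite(phi)]
    if phi.size == 0:
        raise ValueError("order parameter undefined: no valid phases")
    z = np.exp(1j * phi).mean()
    return float(np.abs(z)), float(np.angle(z))


def compute_sync_series(
    trains: list[BurstTrain], times: np.ndarray, extrapolate: bool = False
) -> SyncSeries:
    """Phases and time-resolved (R, Theta) for a population of burst trains."""
    times = np.asarray(times, dtype=float)
    phases = np.vstack([phase_from_onsets(tr, times, extrapolate=extrapolate) for tr in trains])
    z = np.exp(1j * phases)
    valid = np.isfinite(phases)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        zsum = np.where(valid, z, 0).sum(axis=0)
        zmean = np.where(n_valid > 0, zsum / np.maximum(n_valid, 1), np.nan)
    R = np.abs(zmean)
    R[n_valid == 0] = np.nan
    Theta = np.angle(zmean)
    return SyncSeries(times=times, phases=phases, R=R, Theta=Theta, n_valid=n_valid)


def mean_R(series: SyncSeries, window: tuple[float, float]) -> float:
    """Time-averaged R over [t_a, t_b] ms, excluding invalid samples."""
    t_a, t_b = window
    sel = (series.times >= t_a) & (series.times <= t_b)
    if not np.any(sel):
        raise ValueError("empty averaging window")
    r = series.R[sel]
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no valid R samples in window")
    return float(r.mean())
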