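"""Study-level experiment protocols.

Each function runs one of the reference protocols end-to-end — simulate,
detect bursts, reduce to the quantities the study reports — over a list of
master seeds, and returns plain floats.  The acceptance script and the
regression tests are thin callers of these functions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import presets
from .analysis import band_fraction, burst_spike_counts, lfp_spectrogram, mean_r_window, sync_series
from .engine import run_scenario, run_two_population

__all__ = [
    "single_population_R",
    "two_population_R",
    "isolated_izh_burst_sizes",
    "isolated_ml_burst_sizes",
    "band_fraction_change",
]


def _windows(backend: str) -> tuple[tuple[float, float], tuple[float, float]]:
    if backend == "morris_lecar":
        on = presets.ML_STIM_WINDOW_S
    else:
        on = presets.IZH_STIM_WINDOW_S
    return (0.0, on[0]), on


def single_population_R(backend: str, stim_mode: str | None, seeds) -> dict:
    """Mean burst-phase R before and (if stimulated) during stimulation.

    Returns ``{"pre": [...], "during": [...]}`` with one entry per seed;
    ``during`` equals the post-onset window average also for unstimulated
    runs, where no stimulation is applied.
    """
    make = presets.ml_lattice if backend == "morris_lecar" else presets.izh_lattice
    pre_w, stim_w = _windows(backend)
    out = {"pre": [], "during": []}
    for seed in seeds:
        trace = run_scenario(make(stim_mode, master_seed=int(seed)))
        series = sync_series(trace)
        out["pre"].append(mean_r_window(series, pre_w))
        out["during"].append(mean_r_window(series, stim_w))
    return out


def two_population_R(stim_mode: str | None, seeds) -> dict:
    """Pacemaker/driven mean R before and during the stimulation window."""
    pre_w, stim_w = _windows("izhikevich")
    out = {"pop1_pre": [], "pop1_during": [], "pop2_pre": [], "pop2_during": []}
    for seed in seeds:
        pac, drv = presets.two_population_pair(stim_mode, master_seed=int(seed))
        tr1, tr2 = run_two_population(pac, drv)
        s1, s2 = sync_series(tr1), sync_series(tr2)
        out["pop1_pre"].append(mean_r_window(s1, pre_w))
        out["pop1_during"].append(mean_r_window(s1, stim_w))
        out["pop2_pre"].append(mean_r_window(s2, pre_w))
        out["pop2_during"].append(mean_r_window(s2, stim_w))
    return out


def isolated_izh_burst_sizes(seeds, duration_s: float = 20.0) -> list[np.ndarray]:
    """Spikes-per-burst of a single noise-driven Izhikevich neuron per seed.

    The first and last (possibly truncated) bursts are dropped.
    """
    out = []
    for seed in seeds:
        cfg = presets.izh_lattice(None, master_seed=int(seed),
                                  duration_s=duration_s, n_neurons=1)
        counts = burst_spike_counts(run_scenario(cfg))[0]
        out.append(counts[1:-1] if counts.size > 2 else counts)
    return out


def isolated_ml_burst_sizes(seeds, duration_s: float = 10.0) -> list[np.ndarray]:
    """Spikes-per-burst of a single noise-driven Morris-Lecar neuron per seed."""
    out = []
    for seed in seeds:
        cfg = replace(presets.ml_lattice(None, master_seed=int(seed),
                                         duration_s=duration_s), n_neurons=1)
        counts = burst_spike_counts(run_scenario(cfg))[0]
        out.append(counts[1:-1] if counts.size > 2 else counts)
    return out


def band_fraction_change(stim_mode: str, seeds, band=(5.0, 20.0)) -> dict:
    """Low-frequency LFP band-power fraction before vs during stimulation.

    Izhikevich lattice; the pre window trims the first 0.5 s transient and
    the during window trims 0.5 s after onset.
    """
    on = presets.IZH_STIM_WINDOW_S
    out = {"pre": [], "during": []}
    for seed in seeds:
        trace = run_scenario(presets.izh_lattice(stim_mode, master_seed=int(seed)))
        spec = lfp_spectrogram(trace)
        out["pre"].append(band_fraction(spec, band, window_s=(0.5, on[0])))
        out["during"].append(band_fraction(spec, band, window_s=(on[0] + 0.5, on[1])))
    return out
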