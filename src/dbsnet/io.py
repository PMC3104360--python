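"""Scenario serialization and trace export.

Scenario configurations round-trip through flat nested-dict YAML; the
packaged reference scenarios live under ``dbsnet/scenarios/``.  Trace
directories hold a config echo (YAML), the recorded arrays (compressed npz),
spike times, and analysis products as delimited text tables.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .engine import ScenarioConfig, Seeds, SimulationTrace, StimProtocol
from .neurons import GateParams, IzhParams, MLParams
from .noise import NoiseParams
from .stimulation import PulseTrain
from .sync import SyncSeries
from .topology import CouplingParams

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "dump_scenario",
    "load_scenario",
    "load_packaged_scenario",
    "packaged_scenario_names",
    "write_trace_dir",
    "read_trace_dir",
    "write_sync_table",
]

_SECTIONS = {
    "neuron_ml": MLParams,
    "neuron_izh": IzhParams,
    "gate": GateParams,
    "coupling": CouplingParams,
    "noise": NoiseParams,
    "seeds": Seeds,
}


def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    d: dict = {
        "backend": cfg.backend,
        "n_neurons": cfg.n_neurons,
        "duration_s": cfg.duration_s,
        "dt_ms": cfg.dt_ms,
        "dl": cfg.dl,
        "jitter_sd": cfg.jitter_sd,
        "record_stride_ms": cfg.record_stride_ms,
        "gate": dataclasses.asdict(cfg.gate),
        "coupling": dataclasses.asdict(cfg.coupling),
        "noise": dataclasses.asdict(cfg.noise),
        "seeds": dataclasses.asdict(cfg.seeds),
    }
    key = "neuron_ml" if cfg.backend == "morris_lecar" else "neuron_izh"
    d[key] = dataclasses.asdict(cfg.neuron)
    if cfg.stimulation is not None:
        stim = dataclasses.asdict(cfg.stimulation)
        stim["train"] = dataclasses.asdict(cfg.stimulation.train)
        stim["window_s"] = list(cfg.stimulation.window_s)
        d["stimulation"] = stim
    if cfg.init_v_range is not None:
        d["init_v_range"] = list(cfg.init_v_range)
    return d


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    backend = d["backend"]
    key = "neuron_ml" if backend == "morris_lecar" else "neuron_izh"
    neuron_cls = _SECTIONS[key]
    neuron = neuron_cls(**d.pop(key))
    stim = None
    if "stimulation" in d:
        sd = dict(d.pop("stimulation"))
        train = PulseTrain(**sd.pop("train"))
        sd["window_s"] = tuple(sd["window_s"])
        stim = StimProtocol(train=train, **sd)
    init_v = d.pop("init_v_range", None)
    return ScenarioConfig(
        backend=backend,
        n_neurons=d["n_neurons"],
        duration_s=d["duration_s"],
        dt_ms=d["dt_ms"],
        dl=d.get("dl", 0.1),
        jitter_sd=d.get("jitter_sd", 0.0),
        record_stride_ms=d.get("record_stride_ms", 1.0),
        neuron=neuron,
        gate=GateParams(**d.get("gate", {})),
        coupling=CouplingParams(**d.get("coupling", {})),
        noise=NoiseParams(**d.get("noise", {})),
        stimulation=stim,
        seeds=Seeds(**d.get("seeds", {})),
        init_v_range=tuple(init_v) if init_v is not None else None,
    )


def dump_scenario(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(cfg), sort_keys=False))


def load_scenario(path: str | Path) -> ScenarioConfig:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))


def packaged_scenario_names() -> list[str]:
    root = resources.files("dbsnet") / "scenarios"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_packaged_scenario(name: str) -> ScenarioConfig:
    path = resources.files("dbsnet") / "scenarios" / f"{name}.yaml"
    if not path.is_file():
        raise FileNotFoundError(
            f"unknown packaged scenario {name!r}; available: {packaged_scenario_names()}"
        )
    return scenario_from_dict(yaml.safe_load(path.read_text()))


def write_trace_dir(trace: SimulationTrace, out_dir: str | Path) -> Path:
    """One directory per run: config echo, arrays, spike times."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_scenario(trace.config, out / "config.yaml")
    np.savez_compressed(
        out / "trace.npz",
        times_ms=trace.times_ms,
        V=trace.V,
        I_ion=trace.I_ion,
        positions=trace.lattice.positions,
        distances=trace.lattice.distances,
        **{f"spikes_{j}": st for j, st in enumerate(trace.spike_times)},
    )
    return out


def read_trace_dir(run_dir: str | Path) -> SimulationTrace:
    run_dir = Path(run_dir)
    cfg = load_scenario(run_dir / "config.yaml")
    with np.load(run_dir / "trace.npz") as z:
        n = z["V"].shape[0]
        from .topology import Lattice

        lattice = Lattice(
            positions=z["positions"], distances=z["distances"],
            dl=cfg.dl, jitter_sd=cfg.jitter_sd, seed=cfg.seeds.lattice,
        )
        return SimulationTrace(
            times_ms=z["times_ms"], V=z["V"], I_ion=z["I_ion"],
            spike_times=[z[f"spikes_{j}"] for j in range(n)],
            lattice=lattice, config=cfg,
        )


def write_sync_table(series: SyncSeries, path: str | Path) -> None:
    """R(t) and mean phase as a tab-separated table (time_ms, R, Theta, n_valid)."""
    data = np.column_stack([series.times, series.R, series.Theta, series.n_valid])
    np.savetxt(
        path, data, delimiter="\t", fmt=["%.3f", "%.6f", "%.6f", "%d"],
        header="time_ms\tR\tTheta\tn_valid", comments="",
    )
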