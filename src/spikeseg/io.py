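"""Configuration schema, serialization, and run manifests.

All physical quantities carry their unit in the config key
(``refractory_ms``, ``f0_hz``, ``width_2sigma_deg``, ...); the in-memory
representation is SI (seconds, Hz, degrees) with voltages in mV.
Configs load from YAML or JSON; grids and spike trains round-trip
through labeled CSV and JSON.
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .metrics import DiscriminabilityGrid
from .neurons import DepressionParams, NeuronParams
from .spatial import ChannelBank, TuningCurve, DEFAULT_AZIMUTHS
from .spikes import SpikeTrainSet, SpikeTrain
from .stimuli import Spectrogram, TFGrid
from .strf import STRFParams
from .network import NetworkConfig

__all__ = [
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "config_hash",
    "RunManifest",
    "write_manifest",
    "grid_to_csv",
    "grid_from_csv",
    "spectrogram_to_csv",
    "spectrogram_from_csv",
    "spiketrains_to_csv",
    "spiketrains_to_json",
]


class ConfigError(ValueError):
    """Schema violation, naming the offending field."""


def _ms(seconds: float) -> float:
    """Seconds -> milliseconds, rounded so unit conversion round-trips."""
    return round(seconds * 1e3, 9)


def _neuron_to_dict(p: NeuronParams) -> dict:
    return {
        "v_rest_mv": p.v_rest, "v_thresh_mv": p.v_thresh,
        "e_exc_mv": p.e_exc, "e_inh_mv": p.e_inh,
        "refractory_ms": _ms(p.refractory), "tau_mem_ms": _ms(p.tau_mem),
        "adapt_strength": p.adapt_strength, "adapt_tau_ms": _ms(p.adapt_tau),
        "e_adapt_mv": p.e_adapt,
    }


def _neuron_from_dict(d: dict, path: str) -> NeuronParams:
    try:
        return NeuronParams(
            v_rest=d.get("v_rest_mv", -60.0), v_thresh=d.get("v_thresh_mv", -40.0),
            e_exc=d.get("e_exc_mv", 0.0), e_inh=d.get("e_inh_mv", -70.0),
            refractory=d.get("refractory_ms", 3.0) * 1e-3,
            tau_mem=d.get("tau_mem_ms", 20.0) * 1e-3,
            adapt_strength=d.get("adapt_strength", 0.0),
            adapt_tau=d.get("adapt_tau_ms", 400.0) * 1e-3,
            e_adapt=d.get("e_adapt_mv", -70.0),
        )
    except (ValueError, TypeError) as e:
        raise ConfigError(f"{path}: {e}") from e


def _strf_to_dict(p: STRFParams) -> dict:
    return {
        "f0_hz": p.f0, "sigma_f_hz": p.sigma_f, "omega_f_cyc_per_hz": p.omega_f,
        "t0_ms": _ms(p.t0), "sigma_t_ms": _ms(p.sigma_t), "omega_t_hz": p.omega_t,
        "p_t_rad": p.p_t, "a": p.a,
    }


def _strf_from_dict(d: dict, path: str) -> STRFParams:
    if "strf_no" in d:
        over = {}
        try:
            return STRFParams.from_preset(d["strf_no"], **over)
        except KeyError as e:
            raise ConfigError(f"{path}.strf_no: {e}") from e
    try:
        return STRFParams(
            f0=d.get("f0_hz", 4300.0), sigma_f=d.get("sigma_f_hz", 2000.0),
            omega_f=d.get("omega_f_cyc_per_hz", 5e-5),
            t0=d.get("t0_ms", 7.0) * 1e-3, sigma_t=d.get("sigma_t_ms", 4.5) * 1e-3,
            omega_t=d.get("omega_t_hz", 56.0),
            p_t=d.get("p_t_rad", float(np.pi / 2)), a=d.get("a", 0.1),
        )
    except (ValueError, TypeError) as e:
        raise ConfigError(f"{path}: {e}") from e


def config_to_dict(cfg: NetworkConfig) -> dict:
    curve0 = cfg.bank.channels[0][0]
    return {
        "bank": {
            "centers_deg": [c.center for c, _ in cfg.bank.channels],
            "width_2sigma_deg": curve0.width_2sigma,
            "strf": _strf_to_dict(cfg.bank.channels[0][1]),
        },
        "ff_weight_r": cfg.ff_weight_r.tolist(),
        "ff_weight_i": cfg.ff_weight_i.tolist(),
        "lateral": cfg.lateral.tolist(),
        "rc_weight": cfg.rc_weight.tolist(),
        "depression": {"d": cfg.depression.d, "tau_d_ms": _ms(cfg.depression.tau_d)},
        "relay": _neuron_to_dict(cfg.relay),
        "inter": _neuron_to_dict(cfg.inter),
        "cortical": _neuron_to_dict(cfg.cortical),
        "adapt_all": cfg.adapt_all,
        "input_refractory_ms": _ms(cfg.input_refractory),
        "dt_ms": _ms(cfg.dt),
        "strf_no": cfg.strf_no,
        "unit": cfg.unit,
    }


def config_from_dict(d: dict) -> NetworkConfig:
    if "unit" in d and d["unit"] is not None and "cortical" not in d:
        # unit preset: resolve STRF variant and adaptation conductance
        base = NetworkConfig.for_unit(int(d["unit"]))
    else:
        base = None
    bank_d = d.get("bank", {})
    strf = _strf_from_dict(bank_d.get("strf", {"strf_no": d["strf_no"]}
                                      if d.get("strf_no") else {}), "bank.strf")
    if base is not None:
        strf = base.bank.channels[0][1]
    centers = bank_d.get("centers_deg", list(DEFAULT_AZIMUTHS))
    width = bank_d.get("width_2sigma_deg", 10.0)
    try:
        bank = ChannelBank([(TuningCurve(c, width), strf) for c in centers])
    except ValueError as e:
        raise ConfigError(f"bank: {e}") from e
    dep_d = d.get("depression", {})
    try:
        depression = DepressionParams(d=dep_d.get("d", 0.95),
                                      tau_d=dep_d.get("tau_d_ms", 80.0) * 1e-3)
    except ValueError as e:
        raise ConfigError(f"depression: {e}") from e
    cortical = (_neuron_from_dict(d["cortical"], "cortical") if "cortical" in d
                else (base.cortical if base is not None
                      else NeuronParams(adapt_strength=0.04)))
    try:
        return NetworkConfig(
            bank=bank,
            ff_weight_r=d.get("ff_weight_r"),
            ff_weight_i=d.get("ff_weight_i"),
            lateral=d.get("lateral"),
            rc_weight=d.get("rc_weight"),
            depression=depression,
            relay=_neuron_from_dict(d.get("relay", {}), "relay"),
            inter=_neuron_from_dict(d.get("inter", {}), "inter"),
            cortical=cortical,
            adapt_all=bool(d.get("adapt_all", False)),
            input_refractory=d.get("input_refractory_ms", 6.0) * 1e-3,
            dt=d.get("dt_ms", 0.1) * 1e-3,
            strf_no=d.get("strf_no", base.strf_no if base else None),
            unit=d.get("unit"),
        )
    except ValueError as e:
        raise ConfigError(str(e)) from e


def load_config(path) -> NetworkConfig:
    """Load and validate a network config from YAML or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return config_from_dict(d)


def save_config(cfg: NetworkConfig, path) -> None:
    path = Path(path)
    d = config_to_dict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True))


def config_hash(cfg: NetworkConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


class RunManifest:
    """Reproducibility record written before a run's results."""

    def __init__(self, cfg: NetworkConfig, seed: int, outputs: list[str]):
        from . import __version__

        self.data = {
            "config_hash": config_hash(cfg),
            "seed": int(seed),
            "spikeseg_version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "outputs": list(outputs),
        }


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(manifest.data, indent=2, sort_keys=True))


# -- grids -------------------------------------------------------------------


def grid_to_csv(grid: DiscriminabilityGrid, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["masker_az \\ target_az"] + [f"{a:g}" for a in grid.azimuths])
        w.writerow(["clean"] + [f"{v:.6g}" for v in grid.clean])
        for m, az in enumerate(grid.azimuths):
            w.writerow([f"{az:g}"] + [f"{v:.6g}" for v in grid.masked[m]])


def grid_from_csv(path) -> DiscriminabilityGrid:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    azimuths = tuple(float(x) for x in rows[0][1:])
    clean = np.array([float(x) for x in rows[1][1:]])
    masked = np.array([[float(x) for x in r[1:]] for r in rows[2:]])
    return DiscriminabilityGrid(clean, masked, azimuths)


# -- spectrograms ------------------------------------------------------------


def spectrogram_to_csv(spec: Spectrogram, path) -> None:
    """Dense CSV of power values plus a JSON sidecar with the grid."""
    path = Path(path)
    np.savetxt(path, spec.values, delimiter=",")
    sidecar = {
        "time_step_s": spec.grid.time_step,
        "duration_s": spec.grid.duration,
        "freq_bins_hz": spec.grid.freq_bins.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def spectrogram_from_csv(path) -> Spectrogram:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = TFGrid(meta["time_step_s"], np.asarray(meta["freq_bins_hz"]),
                  meta["duration_s"])
    return Spectrogram(grid, np.loadtxt(path, delimiter=","))


# -- spike trains ------------------------------------------------------------


def spiketrains_to_csv(trains: SpikeTrainSet, path) -> None:
    """Two-column (trial, time_s) CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "time_s"])
        for i, tr in enumerate(trains.trains):
            for t in tr.spike_times:
                w.writerow([i, f"{t:.6f}"])


def spiketrains_to_json(trains: SpikeTrainSet, path) -> None:
    d = {
        "label": trains.label,
        "duration_s": trains.duration,
        "trains": [tr.spike_times.tolist() for tr in trains.trains],
    }
    Path(path).write_text(json.dumps(d))


def spiketrains_from_json(path) -> SpikeTrainSet:
    d = json.loads(Path(path).read_text())
    return SpikeTrainSet(
        [SpikeTrain(np.asarray(ts), d["duration_s"]) for ts in d["trains"]],
        label=d.get("label", ""),
    )
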