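"""The three-layer spatial-segregation network.

Architecture: four spatial input channels (midbrain-like STRF neurons at
azimuths -90, 0, 45, 90 degrees) each excite one relay neuron (R) and
one interneuron (I); interneurons send lateral inhibition onto relay
neurons of *other* channels per a configurable connectivity matrix; all
relay neurons converge onto a single cortical output neuron (C) through
depressing synapses.  Lateral inhibition lets a driven channel's target
response suppress another channel's masker response, creating the
discriminability "hotspots" the model exists to explain.

The graph is feedforward in layers (inputs -> I -> R -> C), so each
layer is integrated to completion before the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from ._seeding import child_rng
from .neurons import (
    SIM_DT,
    DepressionParams,
    NeuronParams,
    SynapseParams,
    conductance_from_spikes,
    depression_trace,
    lif_batch,
    psc_kernel,
)
from .spatial import ChannelBank, Scene, scene_to_channel_stimuli
from .spikes import DEFAULT_INPUT_REFRACTORY, SpikeTrain, SpikeTrainSet, poisson_spikes
from .strf import build_strf, encode_rate
from .tables import unit_preset

__all__ = [
    "NetworkConfig",
    "TrialRecord",
    "Network",
    "build_network",
    "preset",
    "PRESET_NAMES",
    "DEFAULT_FF_WEIGHT",
    "DEFAULT_RC_WEIGHT",
    "DEFAULT_LATERAL_WEIGHT",
]

# Default synaptic weights (peak conductance, leak units).  Chosen once so
# that with the default STRF and unit-mean-power song stimuli a single
# channel relays song syllables faithfully, the cortical neuron runs at
# ~10-15 spikes/s (sparse enough that a competing masker genuinely
# degrades template discriminability), and an active channel's lateral
# inhibition holds a masker-driven relay below threshold even across
# inter-syllable gaps.  Input->I is twice input->R so the brief alpha
# EPSC delivers the same synaptic charge as the relay's slower EPSC.
DEFAULT_FF_WEIGHT = 5.0
DEFAULT_FF_I_FACTOR = 2.0
DEFAULT_RC_WEIGHT = 3.0
DEFAULT_LATERAL_WEIGHT = 30.0
DEFAULT_CORTICAL_ADAPT = 0.04


@dataclass
class NetworkConfig:
    bank: ChannelBank = field(default_factory=ChannelBank.default)
    ff_weight_r: np.ndarray | None = None   # input -> relay, per channel
    ff_weight_i: np.ndarray | None = None   # input -> interneuron, per channel
    lateral: np.ndarray | None = None       # [j, k]: I_j -> R_k weight
    rc_weight: np.ndarray | None = None     # relay -> cortical, per channel
    depression: DepressionParams = field(default_factory=DepressionParams)
    relay: NeuronParams = field(default_factory=NeuronParams)
    inter: NeuronParams = field(default_factory=NeuronParams)
    cortical: NeuronParams = field(
        default_factory=lambda: NeuronParams(adapt_strength=DEFAULT_CORTICAL_ADAPT)
    )
    adapt_all: bool = False          # apply cortical adaptation strength everywhere
    input_refractory: float = DEFAULT_INPUT_REFRACTORY
    dt: float = SIM_DT
    strf_no: int | None = None       # preset bookkeeping
    unit: int | None = None

    def __post_init__(self):
        n = self.bank.n_channels
        if self.ff_weight_r is None:
            self.ff_weight_r = np.full(n, DEFAULT_FF_WEIGHT)
        if self.ff_weight_i is None:
            self.ff_weight_i = DEFAULT_FF_I_FACTOR * np.asarray(self.ff_weight_r, float)
        if self.rc_weight is None:
            self.rc_weight = np.full(n, DEFAULT_RC_WEIGHT)
        if self.lateral is None:
            self.lateral = np.zeros((n, n))
        self.ff_weight_r = np.asarray(self.ff_weight_r, float)
        self.ff_weight_i = np.asarray(self.ff_weight_i, float)
        self.rc_weight = np.asarray(self.rc_weight, float)
        self.lateral = np.asarray(self.lateral, float)
        for name in ("ff_weight_r", "ff_weight_i", "rc_weight"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"config.{name}: expected {n} per-channel weights")
            if np.any(arr < 0):
                raise ValueError(f"config.{name}: weights must be nonnegative")
        if self.lateral.shape != (n, n):
            raise ValueError(f"config.lateral: expected shape ({n}, {n})")
        if np.any(self.lateral < 0):
            raise ValueError("config.lateral: weights must be nonnegative")
        if np.any(np.diag(self.lateral) != 0):
            raise ValueError("config.lateral: diagonal (self-inhibition) must be zero")

    @classmethod
    def for_unit(cls, unit: int, **kwargs) -> "NetworkConfig":
        """Config preset for a tabulated simulated unit: its STRF variant
        and cortical adaptation conductance."""
        from .strf import STRFParams

        strf_no, adapt = unit_preset(unit)
        bank = kwargs.pop("bank", None) or ChannelBank.default(
            STRFParams.from_preset(strf_no)
        )
        cortical = kwargs.pop("cortical", None) or NeuronParams(adapt_strength=adapt)
        return cls(bank=bank, cortical=cortical, strf_no=strf_no, unit=unit, **kwargs)


@dataclass
class TrialRecord:
    """Per-trial spikes of every neuron, plus optional traces."""

    input_spikes: list[SpikeTrain]
    inter_spikes: list[SpikeTrain]
    relay_spikes: list[SpikeTrain]
    cortical_spikes: SpikeTrain
    traces: dict | None = None
    seed: int | None = None
    condition: str = ""


class Network:
    """Runnable realization of a NetworkConfig."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        dt = config.dt
        self._k_epsc = psc_kernel(SynapseParams(kind="diff_exp", tau_rise=1e-3,
                                                tau_fall=3e-3), dt)
        self._k_alpha = psc_kernel(SynapseParams(kind="alpha", tau_alpha=1e-3), dt)
        self._k_ipsc = psc_kernel(SynapseParams(kind="diff_exp", tau_rise=4e-3,
                                                tau_fall=50e-3, sign="inhibitory"), dt)
        self._strfs = {}

    # -- input stage ----------------------------------------------------
    def channel_rates(self, scene: Scene):
        """Per-channel STRF-encoded rate traces for a scene."""
        stimuli = scene_to_channel_stimuli(scene, self.config.bank)
        rates = []
        for (curve, params), stim in zip(self.config.bank.channels, stimuli):
            key = (params, stim.grid.time_step, stim.grid.duration,
                   len(stim.grid.freq_bins))
            if key not in self._strfs:
                self._strfs[key] = build_strf(params, stim.grid)
            rates.append(encode_rate(self._strfs[key], stim))
        return rates

    def input_spikes_for_scene(self, scene: Scene, n_trials: int, seed: int):
        """Refractory-Poisson input spikes: trials x channels SpikeTrains.

        Keyed only by (scene rates, seed): identical across wirings."""
        return self.input_spikes_for_scenes([scene] * n_trials, seed)

    def input_spikes_for_scenes(self, scenes: list[Scene], seed: int):
        """As `input_spikes_for_scene` but with one scene per trial (e.g.
        a fresh masker-noise token each presentation)."""
        out = []
        rate_cache = {}
        for trial, scene in enumerate(scenes):
            key = id(scene)
            if key not in rate_cache:
                rate_cache[key] = self.channel_rates(scene)
            row = []
            for ch, rate in enumerate(rate_cache[key]):
                rng = child_rng(seed, "input", trial, ch)
                st = poisson_spikes(rate, self.config.input_refractory,
                                    n_trials=1, rng=rng)
                row.append(st.trains[0])
            out.append(row)
        return out

    # -- network integration --------------------------------------------
    def run_from_input_spikes(self, input_spikes, record_traces: bool = False):
        """Integrate I, R, C layers given per-trial per-channel input spikes."""
        cfg = self.config
        dt = cfg.dt
        n_trials = len(input_spikes)
        n_ch = cfg.bank.n_channels
        duration = input_spikes[0][0].duration
        n_steps = int(round(duration / dt))

        relay_adapt = cfg.cortical.adapt_strength if cfg.adapt_all else cfg.relay.adapt_strength
        inter_adapt = cfg.cortical.adapt_strength if cfg.adapt_all else cfg.inter.adapt_strength
        relay_p = replace(cfg.relay, adapt_strength=relay_adapt)
        inter_p = replace(cfg.inter, adapt_strength=inter_adapt)

        g_in_r = np.zeros((n_trials, n_ch, n_steps))
        g_in_i = np.zeros((n_trials, n_ch, n_steps))
        for t in range(n_trials):
            for c in range(n_ch):
                times = input_spikes[t][c].spike_times
                g_in_r[t, c] = conductance_from_spikes(
                    times, self._k_epsc, n_steps, dt, cfg.ff_weight_r[c])
                g_in_i[t, c] = conductance_from_spikes(
                    times, self._k_alpha, n_steps, dt, cfg.ff_weight_i[c])

        i_spikes, i_v, _ = lif_batch(inter_p, g_in_i, None, dt, record=record_traces)

        # lateral inhibition: I_j spikes filtered by the slow IPSC kernel,
        # combined through the connectivity matrix onto each relay
        if np.any(cfg.lateral > 0):
            ipsc = np.maximum(
                fftconvolve(i_spikes.astype(float),
                            self._k_ipsc[None, None, :], axes=-1)[..., :n_steps], 0.0)
            g_inh_r = np.einsum("jk,tjn->tkn", cfg.lateral, ipsc)
        else:
            g_inh_r = None
        r_spikes, r_v, _ = lif_batch(relay_p, g_in_r, g_inh_r, dt,
                                     record=record_traces)

        g_c = np.zeros((n_trials, n_steps))
        relay_trains = [[None] * n_ch for _ in range(n_trials)]
        for t in range(n_trials):
            for c in range(n_ch):
                times = np.nonzero(r_spikes[t, c])[0] * dt
                train = SpikeTrain(times, duration)
                relay_trains[t][c] = train
                eff = depression_trace(train, cfg.depression)
                g_c[t] += conductance_from_spikes(
                    times, self._k_epsc, n_steps, dt, cfg.rc_weight[c], eff)
        c_spikes, c_v, c_a = lif_batch(cfg.cortical, g_c, None, dt,
                                       record=record_traces)

        records = []
        for t in range(n_trials):
            traces = None
            if record_traces:
                traces = {
                    "inter_v": i_v[t], "relay_v": r_v[t], "cortical_v": c_v[t],
                    "cortical_adapt": c_a[t],
                    "relay_g_exc": g_in_r[t],
                    "relay_g_inh": (g_inh_r[t] if g_inh_r is not None
                                    else np.zeros_like(g_in_r[t])),
                }
            records.append(TrialRecord(
                input_spikes=list(input_spikes[t]),
                inter_spikes=[SpikeTrain(np.nonzero(i_spikes[t, c])[0] * dt, duration)
                              for c in range(n_ch)],
                relay_spikes=relay_trains[t],
                cortical_spikes=SpikeTrain(np.nonzero(c_spikes[t])[0] * dt, duration),
                traces=traces,
            ))
        return records

    def run_condition(self, scene: Scene, n_trials: int = 10, seed: int = 0,
                      record_traces: bool = False):
        """Full pipeline for one stimulus condition.

        Returns (SpikeTrainSet of the cortical neuron, list of TrialRecord);
        bit-reproducible given (config, scene, seed).
        """
        return self.run_trials([scene] * n_trials, seed, record_traces=record_traces)

    def run_trials(self, scenes: list[Scene], seed: int = 0,
                   record_traces: bool = False):
        """Full pipeline with one scene per trial (trial-varying maskers)."""
        inputs = self.input_spikes_for_scenes(scenes, seed)
        records = self.run_from_input_spikes(inputs, record_traces=record_traces)
        for rec in records:
            rec.seed = seed
        c_set = SpikeTrainSet([rec.cortical_spikes for rec in records])
        return c_set, records


def build_network(config: NetworkConfig) -> Network:
    """Validate a config and realize the runnable network."""
    return Network(config)


PRESET_NAMES = ("no_inhibition", "fig2b", "fig2c", "contralateral", "beamformer")


def preset(name: str, base: NetworkConfig,
           weight: float = DEFAULT_LATERAL_WEIGHT) -> NetworkConfig:
    """Named lateral-inhibition wirings on a 4-channel base config.

    no_inhibition: empty lateral matrix (broadly tuned, no hotspots).
    fig2b:         single connection, 0-degree channel inhibits -90.
    fig2c:         0-degree channel inhibits -90 and +90 (the example
                   unit's fitted wiring).
    contralateral: every channel inhibits all channels at smaller azimuth
                   (targets right of maskers are segregable).
    beamformer:    the frontal (0-degree) channel inhibits all others.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    bank = base.bank
    n = bank.n_channels
    lat = np.zeros((n, n))
    if name == "fig2b":
        lat[bank.channel_index(0.0), bank.channel_index(-90.0)] = weight
    elif name == "fig2c":
        j = bank.channel_index(0.0)
        lat[j, bank.channel_index(-90.0)] = weight
        lat[j, bank.channel_index(90.0)] = weight
    elif name == "contralateral":
        centers = bank.centers
        for j in range(n):
            for k in range(n):
                if centers[k] < centers[j]:
                    lat[j, k] = weight
    elif name == "beamformer":
        j = bank.channel_index(0.0)
        lat[j, :] = weight
        lat[j, j] = 0.0
    return NetworkConfig(
        bank=base.bank, ff_weight_r=base.ff_weight_r.copy(),
        ff_weight_i=base.ff_weight_i.copy(), lateral=lat,
        rc_weight=base.rc_weight.copy(), depression=base.depression,
        relay=base.relay, inter=base.inter, cortical=base.cortical,
        adapt_all=base.adapt_all, input_refractory=base.input_refractory,
        dt=base.dt, strf_no=base.strf_no, unit=base.unit,
    )
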