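"""Conductance-based leaky integrate-and-fire dynamics.

All neurons share the same membrane equation, with conductances in units
of the leak conductance:

    tau_m dV/dt = -(V - V_rest) - g_E (V - E_exc) - g_I (V - E_inh)
                  - g_A (V - E_adapt)

A spike is emitted when V crosses threshold; V resets to rest and is
clamped there for an absolute refractory period of 3 ms.  Spike-rate
adaptation is a hyperpolarizing conductance g_A incremented at each of
the neuron's own spikes and decaying exponentially (tau = 400 ms).
Synaptic conductances are peak-normalized kernels (alpha function for
interneuron EPSCs; difference of exponentials, 1/3 ms for EPSCs and
4/50 ms for IPSCs, elsewhere) scaled by the synaptic weight, with
optional short-term depression (per-spike factor 0.95, recovery 80 ms)
on the relay-to-cortical synapses.

The membrane time constant is not constrained by the reference
physiology; the default is the common cortical value of 20 ms, and all
weights are expressed relative to leak so this is a documented scale
choice.  Integration is forward Euler at dt = 0.1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .spikes import SpikeTrain

try:  # optional acceleration of the integration loop
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "DepressionParams",
    "psc_kernel",
    "depression_trace",
    "simulate_neuron",
    "lif_batch",
    "conductance_from_spikes",
    "SIM_DT",
]

SIM_DT = 1e-4  # s


@dataclass(frozen=True)
class NeuronParams:
    v_rest: float = -60.0        # mV
    v_thresh: float = -40.0      # mV
    e_exc: float = 0.0           # mV
    e_inh: float = -70.0         # mV
    refractory: float = 3e-3     # s
    tau_mem: float = 20e-3       # s (documented default; not a measured value)
    adapt_strength: float = 0.0  # conductance increment per spike, leak units
    adapt_tau: float = 400e-3    # s
    e_adapt: float = -70.0       # mV

    def __post_init__(self):
        if not self.v_rest < self.v_thresh:
            raise ValueError("v_rest must be below v_thresh")
        if self.tau_mem <= 0 or self.adapt_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.adapt_strength < 0:
            raise ValueError("adapt_strength must be nonnegative")


@dataclass(frozen=True)
class DepressionParams:
    d: float = 0.95       # per-spike efficacy factor
    tau_d: float = 80e-3  # recovery time constant, s

    def __post_init__(self):
        if not 0 < self.d <= 1:
            raise ValueError("depression factor d must be in (0, 1]")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")


@dataclass(frozen=True)
class SynapseParams:
    kind: str = "diff_exp"       # "alpha" | "diff_exp"
    tau_alpha: float = 1e-3      # alpha-function time constant, s
    tau_rise: float = 1e-3       # s
    tau_fall: float = 3e-3       # s
    weight: float = 1.0          # peak conductance, leak units
    sign: str = "excitatory"     # "excitatory" | "inhibitory"
    depression: DepressionParams | None = None

    def __post_init__(self):
        if self.kind not in ("alpha", "diff_exp"):
            raise ValueError("kind must be 'alpha' or 'diff_exp'")
        if self.kind == "diff_exp" and not self.tau_rise < self.tau_fall:
            raise ValueError("diff_exp requires tau_rise < tau_fall")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")


# Standard synapse types used throughout the network
EPSC_FAST = dict(kind="diff_exp", tau_rise=1e-3, tau_fall=3e-3)   # onto R, C
EPSC_ALPHA = dict(kind="alpha", tau_alpha=1e-3)                   # onto I
IPSC_SLOW = dict(kind="diff_exp", tau_rise=4e-3, tau_fall=50e-3)  # I -> R


def psc_kernel(params: SynapseParams, dt: float, span: float | None = None) -> np.ndarray:
    """Peak-normalized postsynaptic conductance kernel sampled at dt.

    alpha:    k(t) = (t/tau) exp(1 - t/tau), peak 1 at t = tau
    diff_exp: k(t) proportional to exp(-t/tau_fall) - exp(-t/tau_rise),
              normalized to peak 1 at
              t* = tau_r tau_f / (tau_f - tau_r) * ln(tau_f / tau_r)
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.kind == "alpha":
        tau = params.tau_alpha
        if tau <= 0:
            raise ValueError("tau_alpha must be positive")
        if span is None:
            span = 10 * tau
        t = np.arange(int(round(span / dt))) * dt
        return (t / tau) * np.exp(1 - t / tau)
    tau_r, tau_f = params.tau_rise, params.tau_fall
    t_peak = tau_r * tau_f / (tau_f - tau_r) * np.log(tau_f / tau_r)
    peak = np.exp(-t_peak / tau_f) - np.exp(-t_peak / tau_r)
    if span is None:
        span = t_peak + 8 * tau_f
    t = np.arange(int(round(span / dt))) * dt
    return (np.exp(-t / tau_f) - np.exp(-t / tau_r)) / peak


def depression_trace(
    presynaptic: SpikeTrain,
    params: DepressionParams,
    return_state: bool = False,
):
    """Delivered synaptic efficacy at each presynaptic spike.

    The depression state D starts at 1 and recovers between spikes as
    dD/dt = (1 - D)/tau_d; each spike delivers the pre-spike D and then
    multiplies the state by d.  With `return_state`, also returns the
    state immediately after the last spike (e.g. 0.95 after one isolated
    spike at the default depression factor).
    """
    times = presynaptic.spike_times
    eff = np.empty(len(times))
    d_state = 1.0
    last = None
    for i, t in enumerate(times):
        if last is not None:
            d_state = 1.0 - (1.0 - d_state) * np.exp(-(t - last) / params.tau_d)
        eff[i] = d_state
        d_state *= params.d
        last = t
    if return_state:
        return eff, d_state
    return eff


def conductance_from_spikes(
    spike_times: np.ndarray,
    kernel: np.ndarray,
    n_steps: int,
    dt: float,
    weight: float = 1.0,
    efficacies: np.ndarray | None = None,
) -> np.ndarray:
    """Conductance trace from a spike train: scaled impulses convolved
    with a peak-normalized kernel."""
    imp = np.zeros(n_steps)
    if len(spike_times):
        idx = np.minimum(np.round(np.asarray(spike_times) / dt).astype(int), n_steps - 1)
        amps = weight * (efficacies if efficacies is not None else np.ones(len(idx)))
        np.add.at(imp, idx, amps)
    if not np.any(imp):
        return imp
    # FFT round-off can leave ~1e-17 negatives; conductances are >= 0
    return np.maximum(fftconvolve(imp, kernel)[:n_steps], 0.0)


def _lif_loop_numpy(g_exc, g_inh, v_rest, v_thresh, e_exc, e_inh, e_adapt,
                    refr_steps, a_decay, k, adapt_strength, record):
    nb, n_steps = g_exc.shape
    v = np.full(nb, v_rest)
    g_a = np.zeros(nb)
    refr = np.zeros(nb, dtype=np.int64)
    spikes = np.zeros((nb, n_steps), dtype=np.bool_)
    v_trace = np.empty((nb, n_steps if record else 0), dtype=np.float32)
    a_trace = np.empty((nb, n_steps if record else 0), dtype=np.float32)
    ok = True
    for n in range(n_steps):
        ge = g_exc[:, n]
        gi = g_inh[:, n]
        dv = k * (
            -(v - v_rest) - ge * (v - e_exc) - gi * (v - e_inh)
            - g_a * (v - e_adapt)
        )
        in_refr = refr > 0
        v = np.where(in_refr, v_rest, v + dv)
        refr = np.maximum(refr - 1, 0)
        sp = (v >= v_thresh) & ~in_refr
        spikes[:, n] = sp
        v = np.where(sp, v_rest, v)
        refr = np.where(sp, refr_steps, refr)
        g_a = g_a * a_decay + adapt_strength * sp
        if record:
            v_trace[:, n] = v
            a_trace[:, n] = g_a
        if not np.all(np.isfinite(v)):
            ok = False
            break
    return spikes, v_trace, a_trace, ok


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _lif_loop_jit(g_exc, g_inh, v_rest, v_thresh, e_exc, e_inh, e_adapt,
                      refr_steps, a_decay, k, adapt_strength, record):
        nb, n_steps = g_exc.shape
        v = np.full(nb, v_rest)
        g_a = np.zeros(nb)
        refr = np.zeros(nb, dtype=np.int64)
        spikes = np.zeros((nb, n_steps), dtype=np.bool_)
        v_trace = np.empty((nb, n_steps if record else 0), dtype=np.float32)
        a_trace = np.empty((nb, n_steps if record else 0), dtype=np.float32)
        ok = True
        for n in range(n_steps):
            for b in range(nb):
                if refr[b] > 0:
                    v[b] = v_rest
                else:
                    dv = k * (
                        -(v[b] - v_rest)
                        - g_exc[b, n] * (v[b] - e_exc)
                        - g_inh[b, n] * (v[b] - e_inh)
                        - g_a[b] * (v[b] - e_adapt)
                    )
                    v[b] = v[b] + dv
                sp = v[b] >= v_thresh and refr[b] == 0
                if refr[b] > 0:
                    refr[b] -= 1
                if sp:
                    spikes[b, n] = True
                    v[b] = v_rest
                    refr[b] = refr_steps
                    g_a[b] = g_a[b] * a_decay + adapt_strength
                else:
                    g_a[b] = g_a[b] * a_decay
                if record:
                    v_trace[b, n] = v[b]
                    a_trace[b, n] = g_a[b]
                if not np.isfinite(v[b]):
                    ok = False
            if not ok:
                break
        return spikes, v_trace, a_trace, ok


def lif_batch(
    params: NeuronParams,
    g_exc: np.ndarray,
    g_inh: np.ndarray | None,
    dt: float = SIM_DT,
    record: bool = False,
):
    """Integrate a batch of independent LIF neurons (forward Euler).

    g_exc, g_inh: arrays (..., n_steps) of nonnegative conductances in
    leak units.  Returns (spikes bool array (..., n_steps), v_trace,
    adapt_trace); traces are None unless `record`.  The step loop runs
    through a jitted kernel when numba is available, with an equivalent
    numpy fallback.
    """
    g_exc = np.atleast_2d(np.asarray(g_exc, float))
    batch = g_exc.shape[:-1]
    n_steps = g_exc.shape[-1]
    if g_inh is None:
        g_inh = np.zeros_like(g_exc)
    else:
        g_inh = np.atleast_2d(np.asarray(g_inh, float))
    if np.any(g_exc < 0) or np.any(g_inh < 0):
        raise ValueError("conductances must be nonnegative")

    ge = np.ascontiguousarray(g_exc.reshape(-1, n_steps))
    gi = np.ascontiguousarray(g_inh.reshape(-1, n_steps))
    loop = _lif_loop_jit if _HAVE_NUMBA else _lif_loop_numpy
    spikes, v_trace, a_trace, ok = loop(
        ge, gi, params.v_rest, params.v_thresh, params.e_exc, params.e_inh,
        params.e_adapt, int(round(params.refractory / dt)),
        1.0 - dt / params.adapt_tau, dt / params.tau_mem,
        params.adapt_strength, record,
    )
    if not ok:
        raise FloatingPointError(
            "non-finite membrane potential during integration; "
            "check conductance magnitudes vs dt"
        )
    spikes = spikes.reshape(batch + (n_steps,))
    if record:
        return (spikes, v_trace.reshape(batch + (n_steps,)),
                a_trace.reshape(batch + (n_steps,)))
    return spikes, None, None


def simulate_neuron(
    params: NeuronParams,
    exc_conductance: np.ndarray,
    inh_conductance: np.ndarray | None = None,
    dt: float = SIM_DT,
    duration: float | None = None,
):
    """Single-neuron convenience wrapper around `lif_batch`.

    Returns (SpikeTrain, voltage trace mV, adaptation-conductance trace).
    """
    g_exc = np.asarray(exc_conductance, float)
    if duration is not None:
        n_steps = int(round(duration / dt))
        if len(g_exc) < n_steps:
            g_exc = np.pad(g_exc, (0, n_steps - len(g_exc)))
        else:
            g_exc = g_exc[:n_steps]
        if inh_conductance is not None:
            gi = np.asarray(inh_conductance, float)
            gi = np.pad(gi, (0, max(0, n_steps - len(gi))))[:n_steps]
            inh_conductance = gi
    spikes, v, g_a = lif_batch(params, g_exc[None, :],
                               None if inh_conductance is None
                               else np.asarray(inh_conductance, float)[None, :],
                               dt=dt, record=True)
    times = np.nonzero(spikes[0])[0] * dt
    dur = len(g_exc) * dt
    return SpikeTrain(times, dur), v[0].astype(float), g_a[0].astype(float)
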