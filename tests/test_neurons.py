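"""Conductance LIF dynamics, synaptic kernels, depression, adaptation."""

import numpy as np
import pytest

from spikeseg import DepressionParams, NeuronParams, SynapseParams
from spikeseg.neurons import (
    SIM_DT,
    depression_trace,
    lif_batch,
    psc_kernel,
    simulate_neuron,
)
from spikeseg.spikes import SpikeTrain


class TestPscKernel:
    def test_alpha_peaks_at_tau(self):
        k = psc_kernel(SynapseParams(kind="alpha", tau_alpha=1e-3), dt=1e-5)
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        assert k.argmax() * 1e-5 == pytest.approx(1e-3, abs=1e-5)

    @pytest.mark.parametrize(
        "tau_r,tau_f,t_peak",
        [
            # t* = tau_r tau_f / (tau_f - tau_r) * ln(tau_f / tau_r)
            (1e-3, 3e-3, 1.5e-3 * np.log(3)),
            (4e-3, 50e-3, (4e-3 * 50e-3 / 46e-3) * np.log(12.5)),
        ],
    )
    def test_diff_exp_peak_location_and_height(self, tau_r, tau_f, t_peak):
        k = psc_kernel(SynapseParams(kind="diff_exp", tau_rise=tau_r,
                                     tau_fall=tau_f), dt=1e-5)
        assert k.max() == pytest.approx(1.0, abs=1e-4)
        assert k.argmax() * 1e-5 == pytest.approx(t_peak, abs=2e-5)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams(kind="diff_exp", tau_rise=3e-3, tau_fall=1e-3)


class TestDepression:
    def test_single_spike_delivers_full_then_depresses(self):
        eff = depression_trace(SpikeTrain([0.1], 1.0), DepressionParams())
        assert eff[0] == 1.0
        # immediately following spike sees the depressed state 0.95
        eff2 = depression_trace(SpikeTrain([0.1, 0.1001], 1.0), DepressionParams())
        assert eff2[1] == pytest.approx(0.95, abs=1e-3)

    def test_recovery_after_one_time_constant(self):
        # second spike 80 ms later: 1 - 0.05 e^-1
        eff = depression_trace(SpikeTrain([0.1, 0.18], 1.0), DepressionParams())
        assert eff[1] == pytest.approx(1 - 0.05 * np.exp(-1), abs=1e-9)

    def test_full_recovery_at_long_intervals(self):
        times = np.arange(5) * 0.8  # 10 tau_d apart
        eff = depression_trace(SpikeTrain(times, 5.0), DepressionParams())
        assert np.all(eff > 0.999)

    def test_bounded_and_monotone_in_burst(self):
        burst = np.arange(20) * 2e-3  # ISI << tau_d
        eff = depression_trace(SpikeTrain(burst, 1.0), DepressionParams())
        assert np.all((eff > 0) & (eff <= 1))
        assert np.all(np.diff(eff) <= 1e-12)


class TestLif:
    def test_rest_is_fixed_point(self):
        train, v, _ = simulate_neuron(NeuronParams(), np.zeros(5000))
        assert train.n_spikes == 0
        assert v.min() == v.max() == -60.0

    def test_saturating_drive_respects_refractory(self):
        g = np.full(50000, 50.0)  # 5 s of strong drive
        train, _, _ = simulate_neuron(NeuronParams(), g)
        assert train.n_spikes > 100
        assert train.isis().min() >= 3e-3 - 1e-12

    def test_adaptation_reduces_rate(self):
        g = np.full(20000, 2.0)  # 2 s suprathreshold drive
        t0, _, _ = simulate_neuron(NeuronParams(adapt_strength=0.0), g)
        t1, _, _ = simulate_neuron(NeuronParams(adapt_strength=0.2), g)
        assert t1.n_spikes < t0.n_spikes
        # instantaneous rate decreases over the first 400 ms
        early = np.sum(t1.spike_times < 0.2)
        late = np.sum((t1.spike_times >= 0.2) & (t1.spike_times < 0.4))
        assert late <= early

    def test_voltage_bounded(self):
        g_e = np.abs(np.sin(np.arange(20000) / 500.0)) * 3.0
        g_i = np.abs(np.cos(np.arange(20000) / 300.0)) * 2.0
        p = NeuronParams(adapt_strength=0.1)
        _, v, _ = simulate_neuron(p, g_e, g_i)
        lo = min(p.e_inh, p.e_adapt, p.v_rest)
        assert v.min() >= lo - 1e-9
        assert v.max() <= p.v_thresh + 1e-9

    def test_rate_monotone_in_excitation(self):
        counts = []
        for g in (0.8, 1.5, 3.0):
            t, _, _ = simulate_neuron(NeuronParams(), np.full(10000, g))
            counts.append(t.n_spikes)
        assert counts[0] <= counts[1] <= counts[2]

    def test_dt_convergence(self):
        # halving dt changes the spike count by < 2% on a fixed input
        rng = np.random.default_rng(0)
        base = np.repeat(rng.uniform(0, 2.5, 2000), 10)  # 2 s at 0.1 ms
        t1, _, _ = simulate_neuron(NeuronParams(), base, dt=1e-4)
        t2, _, _ = simulate_neuron(NeuronParams(), np.repeat(base, 2), dt=5e-5)
        assert abs(t2.n_spikes - t1.n_spikes) <= 0.02 * t1.n_spikes

    def test_adaptation_decay_recovers_time_constant(self):
        p = NeuronParams(adapt_strength=0.1)
        g = np.zeros(20000)
        g[100:125] = 50.0  # 2.5 ms pulse -> exactly one spike
        train, _, g_a = simulate_neuron(p, g)
        assert train.n_spikes == 1
        i0 = int(round(train.spike_times[0] / SIM_DT)) + 1
        seg = g_a[i0 : i0 + 15000]
        t = np.arange(len(seg)) * SIM_DT
        tau = -1.0 / np.polyfit(t, np.log(seg), 1)[0]
        assert tau == pytest.approx(0.4, rel=0.01)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            lif_batch(NeuronParams(), -np.ones((1, 100)), None)
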