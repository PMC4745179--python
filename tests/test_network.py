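"""Network assembly, presets, and lateral-inhibition behavior."""

import numpy as np
import pytest

from spikeseg import (
    NetworkConfig,
    Scene,
    SceneSource,
    build_network,
    preset,
)


@pytest.fixture(scope="module")
def base_config():
    return NetworkConfig()


class TestPresets:
    def test_no_inhibition_is_zero_matrix(self, base_config):
        cfg = preset("no_inhibition", base_config)
        assert np.all(cfg.lateral == 0)

    def test_fig2b_single_connection(self, base_config):
        cfg = preset("fig2b", base_config)
        bank = cfg.bank
        j, k = bank.channel_index(0.0), bank.channel_index(-90.0)
        assert np.count_nonzero(cfg.lateral) == 1
        assert cfg.lateral[j, k] > 0

    def test_fig2c_inhibits_both_flanks(self, base_config):
        cfg = preset("fig2c", base_config)
        j = cfg.bank.channel_index(0.0)
        nz = set(zip(*np.nonzero(cfg.lateral)))
        assert nz == {(j, cfg.bank.channel_index(-90.0)),
                      (j, cfg.bank.channel_index(90.0))}

    def test_beamformer_three_entries_in_frontal_row(self, base_config):
        cfg = preset("beamformer", base_config)
        j = cfg.bank.channel_index(0.0)
        assert np.count_nonzero(cfg.lateral) == 3
        assert np.count_nonzero(cfg.lateral[j]) == 3
        assert cfg.lateral[j, j] == 0

    def test_contralateral_six_ordered_pairs(self, base_config):
        cfg = preset("contralateral", base_config)
        assert np.count_nonzero(cfg.lateral) == 6
        centers = cfg.bank.centers
        for j, k in zip(*np.nonzero(cfg.lateral)):
            assert centers[k] < centers[j]

    def test_unknown_preset_rejected(self, base_config):
        with pytest.raises(ValueError, match="preset"):
            preset("everything", base_config)


class TestConfigValidation:
    def test_nonzero_diagonal_rejected(self):
        lat = np.zeros((4, 4))
        lat[1, 1] = 1.0
        with pytest.raises(ValueError, match="diagonal"):
            NetworkConfig(lateral=lat)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="lateral"):
            NetworkConfig(lateral=-np.ones((4, 4)) + np.eye(4))
        with pytest.raises(ValueError, match="ff_weight_r"):
            NetworkConfig(ff_weight_r=np.array([1.0, -1.0, 1.0, 1.0]))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="per-channel"):
            NetworkConfig(rc_weight=np.ones(3))

    def test_unit_preset_resolves_tables(self):
        cfg = NetworkConfig.for_unit(15)
        assert cfg.strf_no == 2
        assert cfg.cortical.adapt_strength == 0.0
        cfg = NetworkConfig.for_unit(5)
        assert cfg.strf_no == 7 and cfg.cortical.adapt_strength == 0.2


class TestSimulation:
    def test_silence_produces_no_output(self, grid):
        net = build_network(NetworkConfig())
        c_set, recs = net.run_condition(Scene([], grid_=grid), n_trials=2, seed=0)
        assert all(t.n_spikes == 0 for t in c_set.trains)
        assert all(s.n_spikes == 0 for r in recs for s in r.relay_spikes)

    def test_deterministic_given_seed(self, song_pair):
        s1, _ = song_pair
        net = build_network(NetworkConfig())
        scene = Scene([SceneSource(s1, 0.0, "target")])
        a, _ = net.run_condition(scene, n_trials=2, seed=9)
        b, _ = net.run_condition(scene, n_trials=2, seed=9)
        for ta, tb in zip(a.trains, b.trains):
            np.testing.assert_array_equal(ta.spike_times, tb.spike_times)

    def test_lateral_connection_suppresses_masker_relay(self, song_pair, masker):
        # target at 0 deg, masker at -90: the 0-deg channel's interneuron
        # inhibits the -90 relay only in the wired network, on shared inputs
        s1, _ = song_pair
        scene = Scene([SceneSource(s1, 0.0, "target"),
                       SceneSource(masker, -90.0, "masker")])
        cfg = NetworkConfig()
        net0 = build_network(preset("no_inhibition", cfg))
        netb = build_network(preset("fig2b", cfg))
        _, r0 = net0.run_condition(scene, n_trials=4, seed=21)
        _, rb = netb.run_condition(scene, n_trials=4, seed=21)
        im = cfg.bank.channel_index(-90.0)
        count0 = sum(r.relay_spikes[im].n_spikes for r in r0)
        countb = sum(r.relay_spikes[im].n_spikes for r in rb)
        assert count0 > 0
        assert countb < count0

    def test_reversed_locations_leave_target_relay_untouched(self, song_pair, masker):
        # masker at 0, target at -90: fig2b has no connection protecting -90,
        # and the 0-deg channel's relay is never inhibited
        s1, _ = song_pair
        scene = Scene([SceneSource(s1, -90.0, "target"),
                       SceneSource(masker, 0.0, "masker")])
        cfg = NetworkConfig()
        net0 = build_network(preset("no_inhibition", cfg))
        netb = build_network(preset("fig2b", cfg))
        _, r0 = net0.run_condition(scene, n_trials=4, seed=22)
        _, rb = netb.run_condition(scene, n_trials=4, seed=22)
        i0 = cfg.bank.channel_index(0.0)
        count0 = sum(r.relay_spikes[i0].n_spikes for r in r0)
        countb = sum(r.relay_spikes[i0].n_spikes for r in rb)
        assert countb == count0

    def test_relay_count_monotone_in_lateral_weight(self, song_pair, masker):
        s1, _ = song_pair
        scene = Scene([SceneSource(s1, 0.0, "target"),
                       SceneSource(masker, -90.0, "masker")])
        counts = []
        for w in (0.0, 5.0, 30.0):
            cfg = preset("fig2b", NetworkConfig(), weight=w) if w else NetworkConfig()
            net = build_network(cfg)
            _, recs = net.run_condition(scene, n_trials=4, seed=23)
            im = cfg.bank.channel_index(-90.0)
            counts.append(sum(r.relay_spikes[im].n_spikes for r in recs))
        assert counts[0] >= counts[1] >= counts[2]

    def test_cortical_response_invariant_under_channel_permutation(self, song_pair):
        # with no lateral inhibition and equal weights, C only sees the
        # multiset of channel spike trains: permuting channels is a no-op
        s1, _ = song_pair
        net = build_network(NetworkConfig())
        scene = Scene([SceneSource(s1, 0.0, "target")])
        inputs = net.input_spikes_for_scene(scene, n_trials=3, seed=31)
        permuted = [[row[1], row[0], row[3], row[2]] for row in inputs]
        out_a = net.run_from_input_spikes(inputs)
        out_b = net.run_from_input_spikes(permuted)
        for ra, rb in zip(out_a, out_b):
            np.testing.assert_array_equal(
                ra.cortical_spikes.spike_times, rb.cortical_spikes.spike_times
            )

    def test_interneurons_never_inhibited(self, song_pair, masker):
        # I spikes identical with and without lateral wiring on shared inputs
        s1, _ = song_pair
        scene = Scene([SceneSource(s1, 0.0, "target"),
                       SceneSource(masker, -90.0, "masker")])
        net0 = build_network(NetworkConfig())
        netc = build_network(preset("contralateral", NetworkConfig()))
        _, r0 = net0.run_condition(scene, n_trials=2, seed=24)
        _, rc = netc.run_condition(scene, n_trials=2, seed=24)
        for a, b in zip(r0, rc):
            for ia, ib in zip(a.inter_spikes, b.inter_spikes):
                np.testing.assert_array_equal(ia.spike_times, ib.spike_times)

    def test_traces_recorded_on_request(self, song_pair):
        s1, _ = song_pair
        net = build_network(NetworkConfig())
        scene = Scene([SceneSource(s1, 0.0, "target")])
        _, recs = net.run_condition(scene, n_trials=1, seed=1, record_traces=True)
        tr = recs[0].traces
        assert set(tr) >= {"cortical_v", "relay_v", "cortical_adapt",
                           "relay_g_exc", "relay_g_inh"}
        n_steps = int(round(s1.grid.duration / net.config.dt))
        assert tr["cortical_v"].shape == (n_steps,)
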