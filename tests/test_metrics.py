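"""van Rossum distance, discriminability index, goodness of fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeseg import DiscriminabilityGrid, discriminability, goodness_of_fit, van_rossum
from spikeseg.metrics import van_rossum_grid
from spikeseg.spikes import SpikeTrain, SpikeTrainSet

TAU = 0.01


def train(times, duration=1.0):
    return SpikeTrain(np.asarray(times, float), duration)


spike_trains = st.lists(
    st.floats(0.0, 0.99), min_size=0, max_size=8
).map(lambda ts: train(sorted(ts)))


class TestVanRossum:
    def test_identity(self):
        t = train([0.1, 0.4, 0.7])
        assert van_rossum(t, t, TAU) == 0.0

    def test_empty_vs_single_spike(self):
        # closed form: sqrt(1/tau * int e^{-2t/tau}) = 1/sqrt(2)
        assert van_rossum(train([]), train([0.5]), TAU) == pytest.approx(
            1 / np.sqrt(2)
        )

    def test_far_separated_singles(self):
        # non-overlapping kernels: D^2 = 1/2 + 1/2
        assert van_rossum(train([0.1]), train([0.9]), TAU) == pytest.approx(
            1.0, abs=1e-6
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=spike_trains, b=spike_trains, c=spike_trains)
    def test_metric_axioms(self, a, b, c):
        dab = van_rossum(a, b, TAU)
        assert dab >= 0
        assert dab == pytest.approx(van_rossum(b, a, TAU), abs=1e-9)
        assert dab <= van_rossum(a, c, TAU) + van_rossum(c, b, TAU) + 1e-9

    def test_grid_summation_converges_to_closed_form(self, rng):
        for _ in range(5):
            a = train(np.sort(rng.uniform(0, 0.8, 6)))
            b = train(np.sort(rng.uniform(0, 0.8, 5)))
            exact = van_rossum(a, b, TAU)
            approx = van_rossum_grid(a, b, TAU, dt=1e-6)
            assert approx == pytest.approx(exact, abs=5e-4)


class TestDiscriminability:
    def test_perfect_for_offset_regular_trains(self):
        base = np.arange(0.025, 2.0, 0.05)
        s1 = SpikeTrainSet([train(base, 2.0)] * 10)
        s2 = SpikeTrainSet([train(base + 0.025, 2.0)] * 10)
        assert discriminability(s1, s2, tau=TAU) == 100.0

    def test_identical_sets_are_chance_by_tie_break(self):
        base = np.arange(0.05, 1.0, 0.05)
        s = SpikeTrainSet([train(base)] * 10)
        vals = [discriminability(s, s, tau=TAU, seed=k) for k in range(20)]
        assert np.mean(vals) == pytest.approx(50.0, abs=3.0)

    def test_symmetric_under_label_swap(self, rng):
        s1 = SpikeTrainSet([train(np.sort(rng.uniform(0, 1, 10))) for _ in range(5)])
        s2 = SpikeTrainSet([train(np.sort(rng.uniform(0, 1, 14))) for _ in range(5)])
        assert discriminability(s1, s2, tau=TAU, seed=1) == pytest.approx(
            discriminability(s2, s1, tau=TAU, seed=1)
        )

    def test_invariant_to_common_time_shift(self, rng):
        t1 = [np.sort(rng.uniform(0.1, 0.5, 8)) for _ in range(4)]
        t2 = [np.sort(rng.uniform(0.1, 0.5, 8)) for _ in range(4)]
        a = discriminability(
            SpikeTrainSet([train(t) for t in t1]),
            SpikeTrainSet([train(t) for t in t2]), tau=TAU, seed=2)
        b = discriminability(
            SpikeTrainSet([train(t + 0.3) for t in t1]),
            SpikeTrainSet([train(t + 0.3) for t in t2]), tau=TAU, seed=2)
        assert a == pytest.approx(b, abs=1e-9)

    def test_monotone_in_divergence(self, rng):
        # two sets of jittered copies of a common pattern: discriminability
        # grows as the second set's pattern drifts away from the first's
        base = np.sort(rng.uniform(0, 1.8, 20))

        def jittered_set(pattern):
            return SpikeTrainSet([
                train(np.clip(np.sort(pattern + rng.normal(0, 0.005, len(pattern))),
                              0, 1.999), 2.0)
                for _ in range(10)
            ])

        s1 = jittered_set(base)
        vals = [
            discriminability(s1, jittered_set(base + shift), tau=TAU, seed=3)
            for shift in (0.0, 0.01, 0.05)
        ]
        assert vals[0] <= vals[1] <= vals[2]

    def test_singleton_sets_rejected(self):
        s = SpikeTrainSet([train([0.1])])
        with pytest.raises(ValueError):
            discriminability(s, s, tau=TAU)

    def test_random_draws_subsample_templates(self, rng):
        s1 = SpikeTrainSet([train(np.sort(rng.uniform(0, 1, 10))) for _ in range(6)])
        s2 = SpikeTrainSet([train(np.sort(rng.uniform(0, 1, 10))) for _ in range(6)])
        full = discriminability(s1, s2, tau=TAU, seed=4)
        sub = discriminability(s1, s2, tau=TAU, n_draws=10, seed=4)
        assert 0 <= sub <= 100
        assert abs(sub - full) < 40  # noisy but same scale


class TestGoodnessOfFit:
    def _grid(self, values):
        v = np.asarray(values, float)
        return DiscriminabilityGrid(v[:4], v[4:].reshape(4, 4))

    def test_identical_grids(self, rng):
        g = self._grid(rng.uniform(50, 100, 20))
        dev, corr = goodness_of_fit(g, g)
        assert dev == 0.0 and corr == pytest.approx(1.0)

    def test_constant_offset(self, rng):
        v = rng.uniform(50, 90, 20)
        dev, corr = goodness_of_fit(self._grid(v), self._grid(v + 5))
        assert dev == pytest.approx(5.0)
        assert corr == pytest.approx(1.0)

    def test_pearson_matches_textbook_formula(self, rng):
        a = rng.uniform(40, 100, 20)
        b = rng.uniform(40, 100, 20)
        dev, corr = goodness_of_fit(self._grid(a), self._grid(b))
        # independent manual computation
        exp_dev = sum(abs(x - y) for x, y in zip(a, b)) / 20
        am, bm = a - a.mean(), b - b.mean()
        exp_corr = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert dev == pytest.approx(exp_dev)
        assert corr == pytest.approx(exp_corr)

    def test_zero_variance_grid_flags_missing_correlation(self, rng):
        flat = self._grid(np.full(20, 60.0))
        other = self._grid(rng.uniform(50, 90, 20))
        dev, corr = goodness_of_fit(flat, other)
        assert np.isnan(corr) and dev > 0

    def test_grid_value_range_enforced(self):
        with pytest.raises(ValueError):
            self._grid(np.full(20, 120.0))
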