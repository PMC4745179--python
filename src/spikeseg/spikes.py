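"""Spike-train containers and the refractory Poisson input generator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeding import child_rng
from .strf import RateTrace

__all__ = ["SpikeTrain", "SpikeTrainSet", "poisson_spikes", "DEFAULT_INPUT_REFRACTORY"]

DEFAULT_INPUT_REFRACTORY = 6e-3  # s
_SIM_DT = 1e-4  # Bernoulli sampling step for the Poisson generator, s


@dataclass
class SpikeTrain:
    """Sorted spike times (s) on [0, duration)."""

    spike_times: np.ndarray
    duration: float

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, float)
        if self.spike_times.size and (
            np.any(np.diff(self.spike_times) < 0)
            or self.spike_times[0] < 0
            or self.spike_times[-1] >= self.duration + 1e-12
        ):
            raise ValueError("spike times must be sorted and within [0, duration)")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclass
class SpikeTrainSet:
    """Trial-structured collection of spike trains for one condition."""

    trains: list[SpikeTrain]
    label: str = ""

    def __post_init__(self):
        if self.trains:
            d0 = self.trains[0].duration
            if any(abs(t.duration - d0) > 1e-12 for t in self.trains):
                raise ValueError("all trains in a set must share one duration")

    @property
    def n_trials(self) -> int:
        return len(self.trains)

    @property
    def duration(self) -> float:
        return self.trains[0].duration if self.trains else 0.0


def _thin_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Greedy deletion of spikes closer than `refractory` to the last kept."""
    if refractory <= 0 or times.size == 0:
        return times
    kept = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= refractory:
            kept.append(t)
            last = t
    return np.asarray(kept)


def poisson_spikes(
    rate: RateTrace,
    refractory: float = DEFAULT_INPUT_REFRACTORY,
    n_trials: int = 10,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> SpikeTrainSet:
    """Inhomogeneous Poisson samples of a rate trace with an absolute
    refractory period.

    Per-bin Bernoulli sampling at a 0.1 ms step (p = rate * dt), followed
    by greedy deletion of spikes closer than `refractory` to the previous
    accepted spike.  For a constant rate r this yields the renewal-process
    rate r / (1 + r * refractory).
    """
    if refractory < 0:
        raise ValueError("refractory must be nonnegative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = child_rng(seed, "poisson")
    # upsample the rate trace to the sampling step by zero-order hold
    factor = max(int(round(rate.time_step / _SIM_DT)), 1)
    dt = rate.time_step / factor
    r = np.repeat(rate.rates, factor)
    p = np.clip(r * dt, 0.0, 1.0)
    duration = rate.duration
    trains = []
    for _ in range(n_trials):
        idx = np.nonzero(rng.random(len(p)) < p)[0]
        times = _thin_refractory(idx * dt, refractory)
        trains.append(SpikeTrain(times, duration))
    return SpikeTrainSet(trains)
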