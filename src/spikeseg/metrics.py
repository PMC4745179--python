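"""Spike-train discriminability: van Rossum distance, template-matching
discriminability index, spatial grids and goodness of fit.

The discriminability index is the percent-correct of a nearest-template
classifier: one template train is drawn from each of two response sets,
every remaining train is assigned to the closer template under the van
Rossum distance, and the percentage of correct assignments is averaged
over template draws (exhaustively over all template pairs by default).
50% is chance (indiscriminable responses), 100% is perfect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeding import child_int, child_rng
from .spikes import SpikeTrain, SpikeTrainSet
from .stimuli import Spectrogram
from .spatial import DEFAULT_AZIMUTHS, Scene, SceneSource

__all__ = [
    "van_rossum",
    "van_rossum_grid",
    "discriminability",
    "DiscriminabilityGrid",
    "spatial_grid",
    "goodness_of_fit",
    "DEFAULT_TAU",
]

DEFAULT_TAU = 10e-3  # s; van Rossum kernel time constant

# Masker level relative to song (power gain on a unit-mean-power token).
# 2x power makes masker-evoked input rates comparable to song-evoked ones,
# i.e. a masker that competes on equal terms at the input stage.
DEFAULT_MASKER_GAIN = 2.0


def _cross_sum(a: np.ndarray, b: np.ndarray, tau: float) -> float:
    """sum_ij exp(-|a_i - b_j| / tau)."""
    if len(a) == 0 or len(b) == 0:
        return 0.0
    return float(np.exp(-np.abs(a[:, None] - b[None, :]) / tau).sum())


def van_rossum(train_a: SpikeTrain, train_b: SpikeTrain, tau: float = DEFAULT_TAU) -> float:
    """van Rossum distance with causal exponential kernel exp(-t/tau).

    D = sqrt((1/tau) * integral (f_a - f_b)^2 dt), evaluated exactly via
    the pairwise-exponential closed form (the kernel tails are integrated
    to infinity).  A single spike against an empty train gives
    1/sqrt(2); two far-separated single spikes give ~1.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    a, b = train_a.spike_times, train_b.spike_times
    d2 = 0.5 * (_cross_sum(a, a, tau) + _cross_sum(b, b, tau)) - _cross_sum(a, b, tau)
    return float(np.sqrt(max(d2, 0.0)))


def van_rossum_grid(
    train_a: SpikeTrain, train_b: SpikeTrain, tau: float = DEFAULT_TAU, dt: float = 1e-5
) -> float:
    """Time-grid evaluation of the van Rossum distance (O(dt) accurate);
    kept as an independent numerical route alongside the closed form."""
    pad = 10 * tau
    n = int(round((max(train_a.duration, train_b.duration) + pad) / dt))
    t = np.arange(n) * dt

    def filtered(train):
        f = np.zeros(n)
        for s in train.spike_times:
            m = t >= s
            f[m] += np.exp(-(t[m] - s) / tau)
        return f

    diff = filtered(train_a) - filtered(train_b)
    return float(np.sqrt((diff**2).sum() * dt / tau))


def _distance_matrix(trains: list[SpikeTrain], tau: float) -> np.ndarray:
    """Squared van Rossum distances between all train pairs."""
    n = len(trains)
    self_sums = [_cross_sum(t.spike_times, t.spike_times, tau) for t in trains]
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = 0.5 * (self_sums[i] + self_sums[j]) - _cross_sum(
                trains[i].spike_times, trains[j].spike_times, tau
            )
            d2[i, j] = d2[j, i] = max(v, 0.0)
    return d2


def discriminability(
    set_1: SpikeTrainSet,
    set_2: SpikeTrainSet,
    tau: float = DEFAULT_TAU,
    n_draws: int | None = None,
    seed: int = 0,
) -> float:
    """Template-matching discriminability index, percent in [0, 100].

    Exhaustive over all template pairs when `n_draws` is None or at least
    n1*n2; ties between templates are broken by a fair coin from the
    seeded generator.
    """
    n1, n2 = set_1.n_trials, set_2.n_trials
    if n1 < 2 or n2 < 2:
        raise ValueError("discriminability needs >= 2 trains per set")
    trains = list(set_1.trains) + list(set_2.trains)
    labels = np.array([0] * n1 + [1] * n2)
    d2 = _distance_matrix(trains, tau)
    rng = child_rng(seed, "disc")

    if n_draws is None or n_draws >= n1 * n2:
        pairs = [(i, n1 + j) for i in range(n1) for j in range(n2)]
    else:
        pairs = [
            (int(rng.integers(n1)), n1 + int(rng.integers(n2))) for _ in range(n_draws)
        ]

    scores = []
    for t1, t2 in pairs:
        others = [k for k in range(len(trains)) if k not in (t1, t2)]
        da = d2[others, t1]
        db = d2[others, t2]
        lab = labels[others]
        tie = da == db
        assign = np.where(da < db, 0, 1)
        if tie.any():
            assign = np.where(tie, (rng.random(len(others)) < 0.5).astype(int), assign)
        scores.append(100.0 * np.mean(assign == lab))
    return float(np.mean(scores))


@dataclass
class DiscriminabilityGrid:
    """1x4 clean row plus 4x4 masked grid of discriminability percent.

    masked[m, i] is the condition with the masker at azimuths[m] and the
    target at azimuths[i] (rows = masker location, columns = target).
    """

    clean: np.ndarray
    masked: np.ndarray
    azimuths: tuple = DEFAULT_AZIMUTHS

    def __post_init__(self):
        self.clean = np.asarray(self.clean, float)
        self.masked = np.asarray(self.masked, float)
        n = len(self.azimuths)
        if self.clean.shape != (n,) or self.masked.shape != (n, n):
            raise ValueError("grid shapes inconsistent with azimuth labels")
        allv = self.all_values()
        if np.any((allv < 0) | (allv > 100)):
            raise ValueError("discriminability values must lie in [0, 100]")

    def all_values(self) -> np.ndarray:
        """Clean row followed by the masked grid, flattened (20 values)."""
        return np.concatenate([self.clean, self.masked.ravel()])

    def to_dict(self) -> dict:
        return {
            "azimuths": list(self.azimuths),
            "clean": self.clean.tolist(),
            "masked": self.masked.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminabilityGrid":
        return cls(np.asarray(d["clean"]), np.asarray(d["masked"]), tuple(d["azimuths"]))


def masker_tokens(
    masker: Spectrogram,
    n_trials: int,
    seed: int,
    gain: float = DEFAULT_MASKER_GAIN,
    refresh: bool = True,
) -> list[Spectrogram]:
    """Per-trial masker spectrograms at the working level.

    With `refresh` (default) each trial gets a fresh noise realization at
    the level of the supplied token, as when a new noise token is
    generated per presentation; otherwise the supplied (frozen) token is
    reused on every trial."""
    from .stimuli import make_masker

    level = gain * float(masker.values.mean())
    if not refresh:
        tok = Spectrogram(masker.grid, level * masker.values / masker.values.mean())
        return [tok] * n_trials
    out = []
    for trial in range(n_trials):
        tok = make_masker(masker.grid, child_int(seed, "masker_token", trial))
        out.append(Spectrogram(tok.grid, level * tok.values))
    return out


def spatial_grid(
    network,
    song1: Spectrogram,
    song2: Spectrogram,
    masker: Spectrogram,
    azimuths=DEFAULT_AZIMUTHS,
    n_trials: int = 10,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
    masker_gain: float = DEFAULT_MASKER_GAIN,
    masker_refresh: bool = True,
) -> DiscriminabilityGrid:
    """Simulate all clean and masked target/masker location combinations
    and score the cortical neuron's song discriminability for each.

    Input-spike randomness and masker tokens are keyed by the condition
    and trial (not the network), so grids from different wirings on one
    seed share identical inputs.
    """
    azimuths = tuple(float(a) for a in azimuths)
    n = len(azimuths)
    clean = np.zeros(n)
    masked = np.zeros((n, n))
    tokens = masker_tokens(masker, n_trials, seed, masker_gain, masker_refresh)

    def respond(song_id, song, az_t, az_m):
        key = ("clean", song_id, az_t) if az_m is None else ("masked", song_id, az_t, az_m)
        cond_seed = child_int(seed, "grid", *key)
        if az_m is None:
            scenes = [Scene([SceneSource(song, az_t, "target")])] * n_trials
        else:
            scenes = [
                Scene([SceneSource(song, az_t, "target"),
                       SceneSource(tokens[trial], az_m, "masker")])
                for trial in range(n_trials)
            ]
        c_set, _ = network.run_trials(scenes, seed=cond_seed)
        return c_set

    for i, az_t in enumerate(azimuths):
        r1 = respond(1, song1, az_t, None)
        r2 = respond(2, song2, az_t, None)
        clean[i] = discriminability(r1, r2, tau=tau,
                                    seed=child_int(seed, "disc", "clean", az_t))
        for m, az_m in enumerate(azimuths):
            r1m = respond(1, song1, az_t, az_m)
            r2m = respond(2, song2, az_t, az_m)
            masked[m, i] = discriminability(
                r1m, r2m, tau=tau, seed=child_int(seed, "disc", "masked", az_t, az_m))
    return DiscriminabilityGrid(clean, masked, azimuths)


def goodness_of_fit(
    grid_a: DiscriminabilityGrid, grid_b: DiscriminabilityGrid
) -> tuple[float, float]:
    """(mean absolute deviation in percentage points, Pearson correlation)
    over the 20 clean+masked values.

    Returns NaN correlation when either grid has zero variance (a
    perfectly uniform grid has no pattern to correlate).
    """
    a = grid_a.all_values()
    b = grid_b.all_values()
    if a.shape != b.shape:
        raise ValueError("grids must have matching shapes")
    mean_dev = float(np.mean(np.abs(a - b)))
    if np.std(a) == 0 or np.std(b) == 0:
        return mean_dev, float("nan")
    corr = float(np.corrcoef(a, b)[0, 1])
    return mean_dev, corr
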