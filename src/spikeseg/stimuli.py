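"""Synthetic song and masker spectrograms.

The model is driven by time-frequency power spectrograms of two
song-like broadband stimuli ("song 1" and "song 2") and a stationary
broadband noise masker, all sampled on one common grid.  The songs are
sequences of harmonic-stack syllables with amplitude and frequency
modulation, loosely emulating zebra-finch song structure; the masker is
frozen (seed-fixed) broadband noise.  Both are normalized to unit mean
power so that mixing gains are signal-to-noise ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import child_rng

__all__ = ["TFGrid", "Spectrogram", "make_song", "make_masker", "mix"]


@dataclass(frozen=True)
class TFGrid:
    """Common time-frequency sampling grid.

    time_step in seconds (default 1 ms), freq_bins in Hz (strictly
    ascending), duration in seconds.
    """

    time_step: float = 1e-3
    freq_bins: np.ndarray = field(
        default_factory=lambda: np.linspace(250.0, 8000.0, 64)
    )
    duration: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "freq_bins", np.asarray(self.freq_bins, float))
        if not self.time_step > 0:
            raise ValueError("time_step must be positive")
        if self.freq_bins.ndim != 1 or len(self.freq_bins) < 2:
            raise ValueError("freq_bins must be a 1-D array with >= 2 bins")
        if not np.all(np.diff(self.freq_bins) > 0):
            raise ValueError("freq_bins must be strictly increasing")
        if self.duration < 10 * self.time_step:
            raise ValueError("duration must be at least 10 time steps")

    @property
    def n_times(self) -> int:
        return int(round(self.duration / self.time_step))

    @property
    def n_freqs(self) -> int:
        return len(self.freq_bins)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) * self.time_step

    def __eq__(self, other):
        if not isinstance(other, TFGrid):
            return NotImplemented
        return (
            self.time_step == other.time_step
            and self.duration == other.duration
            and np.array_equal(self.freq_bins, other.freq_bins)
        )


@dataclass
class Spectrogram:
    """Nonnegative time x frequency power matrix on a TFGrid."""

    grid: TFGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.grid.n_times, self.grid.n_freqs):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with grid "
                f"({self.grid.n_times}, {self.grid.n_freqs})"
            )
        if np.any(self.values < 0):
            raise ValueError("power values must be nonnegative")


# Syllable statistics: ~5-6 syllables/s of 50-150 ms with the short
# inter-syllable gaps of natural motifs, 3-5 harmonic partials.
_SYL_DUR = (0.09, 0.15)
_GAP_DUR = (0.03, 0.07)
_F0_RANGE = (500.0, 1800.0)
_N_HARMONICS = (3, 5)
_FM_FRAC = 0.2          # max fractional frequency sweep per syllable
_PARTIAL_BW = 150.0     # Hz, spectral width of each partial


def make_song(grid: TFGrid, song_id: int, seed: int) -> Spectrogram:
    """Generate a deterministic song-like spectrogram.

    Songs 1 and 2 use disjoint random streams from the same seed so they
    differ in syllable timing and spectral content while remaining
    reproducible.  Output has unit mean power.
    """
    if song_id not in (1, 2):
        raise ValueError(f"song_id must be 1 or 2, got {song_id!r}")
    rng = child_rng(seed, "song", song_id)
    n_t, n_f = grid.n_times, grid.n_freqs
    t = grid.times
    f = grid.freq_bins
    values = np.zeros((n_t, n_f))

    onset = rng.uniform(*_GAP_DUR)
    while onset < grid.duration - _SYL_DUR[0]:
        dur = rng.uniform(*_SYL_DUR)
        dur = min(dur, grid.duration - onset)
        f0 = rng.uniform(*_F0_RANGE)
        n_h = rng.integers(_N_HARMONICS[0], _N_HARMONICS[1] + 1)
        sweep = rng.uniform(-_FM_FRAC, _FM_FRAC)
        amp = rng.uniform(0.5, 1.0)

        i0 = int(round(onset / grid.time_step))
        i1 = min(int(round((onset + dur) / grid.time_step)), n_t)
        if i1 <= i0:
            break
        frac = (t[i0:i1] - t[i0]) / max(dur, grid.time_step)
        env = amp * np.sin(np.pi * np.clip(frac, 0, 1)) ** 2  # raised-cosine-like
        inst_f0 = f0 * (1.0 + sweep * frac)  # linear FM sweep
        for h in range(1, n_h + 1):
            fc = h * inst_f0[:, None]  # (time, 1)
            values[i0:i1] += (
                env[:, None]
                / h
                * np.exp(-0.5 * ((f[None, :] - fc) / _PARTIAL_BW) ** 2)
            )
        onset += dur + rng.uniform(*_GAP_DUR)

    mean_power = values.mean()
    if mean_power > 0:
        values /= mean_power
    return Spectrogram(grid, values)


def make_masker(grid: TFGrid, seed: int) -> Spectrogram:
    """Frozen stationary broadband noise spectrogram, unit mean power.

    Power values are i.i.d. exponential per time-frequency bin, so the
    time-marginal power is near-constant (CV ~ 1/sqrt(n_freqs)).
    """
    rng = child_rng(seed, "masker")
    values = rng.exponential(1.0, size=(grid.n_times, grid.n_freqs))
    values /= values.mean()
    return Spectrogram(grid, values)


def mix(spectrograms: list[tuple[Spectrogram, float]]) -> Spectrogram:
    """Element-wise power sum of gain-weighted spectrograms on one grid."""
    if not spectrograms:
        raise ValueError("mix requires at least one spectrogram")
    grid = spectrograms[0][0].grid
    total = np.zeros((grid.n_times, grid.n_freqs))
    for spec, gain in spectrograms:
        if spec.grid != grid:
            raise ValueError("all spectrograms must share one grid")
        if gain < 0:
            raise ValueError("gains must be nonnegative")
        total += gain * spec.values
    return Spectrogram(grid, total)
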