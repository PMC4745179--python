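"""Gabor spectrotemporal receptive fields and the rate-encoding stage.

The midbrain-like input neurons are modeled as separable Gabor STRFs,
STRF(t, f) = G(f) * H(t), with

    G(f) = exp(-0.5 ((f - f0)/sigma_f)^2) * cos(2 pi Omega_f (f - f0))
    H(t) = exp(-0.5 ((t - t0)/sigma_t)^2) * cos(2 pi Omega_t (t - t0) + P_t)

An input neuron's instantaneous firing rate is the stimulus spectrogram
convolved (causally in time) with its STRF, half-wave rectified, and
scaled by the per-neuron normalization factor ``a``:  r(t) = a * r0(t).

Note on units: the best spectral modulation Omega_f is quoted in the
source physiology as "50 us"; spectral modulation has units of cycles
per Hz (= seconds), i.e. Omega_f = 5e-5 cycles/Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .stimuli import Spectrogram, TFGrid
from .tables import strf_preset_values

__all__ = [
    "STRFParams",
    "STRF",
    "RateTrace",
    "build_strf",
    "encode_rate",
    "STIMULUS_SCALE",
]

# Global stimulus scale constant mapping unit-mean-power spectrograms to
# convolution outputs such that the tabulated normalization factors a
# (0.05-0.17) put song-driven mean input rates in the 10-20 spikes/s
# range (sparse, cortical-like coding).  This single constant defines the
# (arbitrary) stimulus power unit; the relative meaning of a across
# input-filter variants is preserved.
STIMULUS_SCALE = 12.0


@dataclass(frozen=True)
class STRFParams:
    """Gabor STRF parameters (defaults are the broadband midbrain fit)."""

    f0: float = 4300.0          # best frequency, Hz
    sigma_f: float = 2000.0     # spectral bandwidth, Hz
    omega_f: float = 5e-5       # best spectral modulation, cycles/Hz
    t0: float = 7e-3            # temporal latency, s
    sigma_t: float = 4.5e-3     # temporal bandwidth, s
    omega_t: float = 56.0       # best temporal modulation, Hz
    p_t: float = np.pi / 2      # temporal phase, rad
    a: float = 0.1              # rate normalization factor

    def __post_init__(self):
        if self.sigma_f <= 0 or self.sigma_t <= 0:
            raise ValueError("sigma_f and sigma_t must be positive")
        if self.a < 0:
            raise ValueError("normalization factor a must be nonnegative")

    @classmethod
    def from_preset(cls, strf_no: int, **overrides) -> "STRFParams":
        a, p_t = strf_preset_values(strf_no)
        kwargs = {"a": a, "p_t": p_t}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class STRF:
    """Realized filter matrix; time axis is filter lag starting at 0."""

    grid: TFGrid
    values: np.ndarray  # (n_lags, n_freqs)
    params: STRFParams

    @property
    def n_lags(self) -> int:
        return self.values.shape[0]


@dataclass
class RateTrace:
    """Nonnegative instantaneous firing rate, spikes/s per time bin."""

    time_step: float
    rates: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def duration(self) -> float:
        return len(self.rates) * self.time_step


def gabor_freq(params: STRFParams, f: np.ndarray) -> np.ndarray:
    """Spectral Gabor G(f)."""
    f = np.asarray(f, float)
    return np.exp(-0.5 * ((f - params.f0) / params.sigma_f) ** 2) * np.cos(
        2 * np.pi * params.omega_f * (f - params.f0)
    )


def gabor_time(params: STRFParams, t: np.ndarray) -> np.ndarray:
    """Temporal Gabor H(t)."""
    t = np.asarray(t, float)
    return np.exp(-0.5 * ((t - params.t0) / params.sigma_t) ** 2) * np.cos(
        2 * np.pi * params.omega_t * (t - params.t0) + params.p_t
    )


def build_strf(params: STRFParams, grid: TFGrid, lag_span: float | None = None) -> STRF:
    """Sample STRF(t, f) = G(f) H(t) on the grid's frequency bins and a
    causal lag axis [0, lag_span)."""
    if lag_span is None:
        lag_span = params.t0 + 4 * params.sigma_t
    if lag_span < params.t0 + 3 * params.sigma_t:
        raise ValueError(
            f"lag_span {lag_span:g} s too short; need >= t0 + 3 sigma_t = "
            f"{params.t0 + 3 * params.sigma_t:g} s"
        )
    lags = np.arange(int(round(lag_span / grid.time_step))) * grid.time_step
    values = np.outer(gabor_time(params, lags), gabor_freq(params, grid.freq_bins))
    return STRF(grid, values, params)


def encode_rate(strf: STRF, stim: Spectrogram, a: float | None = None) -> RateTrace:
    """Rate-encode a stimulus: causal convolution, rectification, scaling.

    r0(t) = max(0, sum_f sum_tau STRF(tau, f) stim(t - tau, f)), with the
    stimulus implicitly zero-padded before onset; r(t) = a * r0(t).
    """
    if stim.grid != strf.grid:
        raise ValueError("stimulus and STRF must share one time-frequency grid")
    if a is None:
        a = strf.params.a
    # full convolution along time per frequency bin, summed over frequency
    conv = fftconvolve(stim.values, strf.values, mode="full", axes=0)
    r0 = np.maximum(conv[: stim.grid.n_times].sum(axis=1), 0.0)
    return RateTrace(stim.grid.time_step, a * STIMULUS_SCALE * r0)
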