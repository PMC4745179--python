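# spikeseg

A spiking-network model of how auditory cortex could solve the spatial
"cocktail party" problem: why a cortical neuron encodes a target song
equally well from any direction when the song is alone, yet develops
sharp location-dependent "hotspots" of song discriminability the moment
a competing noise masker is present.

The package is aimed at computational neuroscientists and hearing
researchers who want to simulate, analyze, and fit this class of
three-layer lateral-inhibition circuits on synthetic song/masker scenes.

## The model

**Input stage.** Four spatial channels, tuned to azimuths −90°, 0°, 45°
and 90° by Gaussian curves of width 2σ (below 15° there is no crosstalk
between channels 45° apart). Each channel contains a midbrain-like
neuron modeled as a separable Gabor spectrotemporal receptive field,

    STRF(t, f) = G(f) · H(t)
    G(f) = exp(−½((f−f₀)/σ_f)²) · cos(2π·Ω_f·(f−f₀))
    H(t) = exp(−½((t−t₀)/σ_t)²) · cos(2π·Ω_t·(t−t₀) + P_t)

with f₀ = 4300 Hz, σ_f = 2000 Hz, Ω_f = 5·10⁻⁵ cycles/Hz, t₀ = 7 ms,
σ_t = 4.5 ms, Ω_t = 56 Hz; the temporal phase P_t and a normalization
factor *a* vary across thirteen tabulated filter variants. A stimulus
spectrogram is convolved with the STRF, half-wave rectified, scaled
(r(t) = a·r₀(t)), and turned into spikes by a Poisson generator with a
6 ms refractory period.

**Network.** Each channel's input excites a relay neuron (R, EPSC =
difference of exponentials, 1/3 ms) and an interneuron (I, alpha EPSC,
τ = 1 ms). Interneurons send *lateral* inhibition (IPSC 4/50 ms) onto
relay neurons of other channels; all relays converge through depressing
synapses (per-spike factor 0.95, recovery 80 ms) onto one cortical
output neuron (C) with spike-rate adaptation (τ = 400 ms). All neurons
are conductance-based leaky integrate-and-fire units (rest −60 mV,
threshold −40 mV, E_exc = 0 mV, E_inh = −70 mV, 3 ms refractory) solved
by forward Euler at 0.1 ms.

**Readout.** Song coding is scored with a template-matching
discriminability index built on the van Rossum spike distance
(D = √((1/τ)∫(f_a−f_b)² dt), causal exponential kernel, τ = 10 ms):
50% is chance, 100% perfect. A *spatial grid* collects this index for
every target/masker location combination (1×4 clean row + 4×4 masked
grid), and grids are compared by mean absolute deviation and Pearson
correlation.

Because one active channel's interneuron can veto another channel's
relay, a target at the inhibiting location suppresses a masker at the
inhibited location — producing a hotspot — while the clean (no-masker)
response is untouched.

## Worked example

```python
import numpy as np
from spikeseg import ExperimentSpec, run_fig2_suite

spec = ExperimentSpec(seed=1)          # 2 s stimuli, 10 trials, 4 azimuths
grids, report = run_fig2_suite(spec)

print("clean row (no masker):", np.round(grids["no_inhibition"].clean, 1))
print("masked grid, no inhibition (rows = masker az, cols = target az):")
print(np.round(grids["no_inhibition"].masked, 1))
print("masked grid, one lateral connection (0 deg inhibits -90 deg):")
print(np.round(grids["fig2b"].masked, 1))
print("hotspot gain at (target 0, masker -90):",
      round(report["hotspot_gain_fig2b"], 1), "points")
```

Output (about half a minute on one core):

```
clean row (no masker): [99.6 99.7 93.7 97.9]
masked grid, no inhibition (rows = masker az, cols = target az):
[[95.8 87.6 90.7 91.9]
 [92.8 97.5 94.4 97.2]
 [92.3 91.6 95.7 92.6]
 [95.9 85.2 92.6 91.8]]
masked grid, one lateral connection (0 deg inhibits -90 deg):
[[95.8 97.9 90.7 91.9]
 [49.5 97.5 94.4 97.2]
 [92.3 91.6 95.7 92.6]
 [95.9 85.2 92.6 91.8]]
hotspot gain at (target 0, masker -90): 10.3 points
```

Reading the numbers: with no lateral inhibition the masked grid is
nearly uniform (SD ≈ 3 points) — the network is broadly tuned and no
location combination is special. Adding a single inhibitory connection
from the 0° channel onto the −90° relay raises the (target 0°, masker
−90°) cell from 87.6% to 97.9% (a hotspot: the target vetoes the
masker), drops the reversed combination (target −90°, masker 0°) to
chance (49.5%: now the masker vetoes the target), and leaves the clean
row byte-identical. `run_width_sweep` shows the same grid degrading
gracefully as input tuning widens to 40/80/120°, and `run_multimasker`
and the `contralateral`/`beamformer` presets explore engineered wirings
that stay robust under several simultaneous maskers.

A CLI mirrors the library: `spikeseg stimuli|simulate|grid|experiments|fit`
(see `spikeseg --help`); network configs are YAML/JSON with unit-suffixed
keys, and every run writes a manifest with the config hash and seed.

## Fitting

`fit_to_grid` fits a network to a target spatial grid in three
deterministic coordinate-wise stages — cortical adaptation strength
against the mean clean level, per-channel feedforward weights against
the clean row, then the two lateral weights of each channel pair jointly
against its pair of masked cells — using frozen input spike trains so
the objective is noise-free.

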