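# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, what the synthetic stimuli do and do not
emulate, the numerical choices, and the design decisions taken where the
problem was genuinely open.

## Model structure and assumptions

The network is a three-layer, purely feedforward graph per stimulus
condition: four spatial input channels → per-channel relay (R) and
interneuron (I) → one cortical output neuron (C), with cross-channel
lateral inhibition I_j → R_k as the only interaction between channels.
Because no connection feeds back (no R→I, I→I, or C→anything), each
layer is integrated to completion before the next, which is both exact
and fast. One R and one I per channel stand in for whatever population
implements them biologically; interneurons are never themselves
inhibited.

Spatial selectivity enters only through the Gaussian azimuth tuning of
the input channels. Azimuth is treated as a linear coordinate on
[−90°, 90°] (a frontal speaker arc), not a circular variable, and
channel gains are not normalized across channels — each channel's curve
is an independent unit-height Gaussian. At the default tuning width
(2σ = 10°) a source on one channel's center contributes < 10⁻⁷ of its
power to the neighbors 45° away, so scenes route one source per channel;
widths of 40–120° produce deliberate crosstalk.

Concurrent sources combine by **power addition of their spectrograms**
at each channel, weighted by the channel's gain at each source azimuth.
This is the simplest physically sensible rule for level-matched
incoherent sources; mixing at the rate or spike level would be
alternatives, but spectrogram addition keeps the nonlinearity (the
rectified STRF) downstream of the mixture, as in a real ear.

## Neurons and synapses

All neurons share one conductance-based leaky integrate-and-fire
equation with conductances in units of the leak:

τ_m dV/dt = −(V−V_rest) − g_E(V−E_exc) − g_I(V−E_inh) − g_A(V−E_adapt)

| parameter | value | notes |
|---|---|---|
| V_rest / V_thresh | −60 / −40 mV | reset to rest on spike |
| E_exc / E_inh | 0 / −70 mV | |
| refractory | 3 ms | absolute; V clamped at rest |
| τ_m | 20 ms | not constrained by the source physiology; a common cortical value. All weights are in leak units, so this is a scale choice, not a hidden degree of freedom |
| adaptation | ΔG per spike 0–0.2, τ = 400 ms, E = −70 mV | reversal unstated in the source; set to the inhibitory reversal since the term is hyperpolarizing |
| depression (R→C) | d = 0.95 per spike, τ_D = 80 ms | delivered efficacy is the pre-spike state |

Synaptic kernels are peak-normalized so a weight *is* the peak
conductance: alpha function (τ = 1 ms) onto interneurons; difference of
exponentials 1/3 ms (EPSC onto R and C) and 4/50 ms (IPSC onto R).
Adaptation is configured per layer; by default only the cortical neuron
has a nonzero strength (the tabulated per-unit value), with an
`adapt_all` switch that applies the cortical strength to every neuron —
the source description is ambiguous between the two readings, and the
switch exposes rather than hides that.

Integration is forward Euler at dt = 0.1 ms (halving dt changes spike
counts on a 2 s input by < 2%; there is a test for this). The step loop
runs through a numba-jitted kernel when numba is importable, with a
bit-identical numpy fallback.

## Input encoding

The STRF is the separable Gabor product G(f)·H(t) sampled on the
stimulus grid with a causal lag axis (lag span t₀ + 4σ_t by default; a
span below t₀ + 3σ_t is rejected). Convolution is causal in time with
implicit zero-padding before stimulus onset. One printed quirk is worth
flagging: the best spectral modulation is quoted in the source
physiology as "50 μs"; spectral modulation has units of cycles/Hz =
seconds, so Ω_f = 5·10⁻⁵ cycles/Hz.

The rectified convolution r₀(t) is multiplied by the per-variant
normalization factor *a* and by one global constant
`STIMULUS_SCALE = 12`, which defines the (arbitrary) power unit of the
synthetic spectrograms. It was chosen once so that the tabulated *a*
values (0.05–0.17) put song-driven input rates around 10–20 spikes/s —
sparse, cortical-like firing. Whether r₀ should be normalized per
stimulus before applying *a* is unstated in the source; a single global
scale preserves the relative meaning of *a* across filter variants and
is our resolution of that question.

Spikes are drawn per 0.1 ms bin with probability r·dt and thinned by
greedy deletion of any spike closer than 6 ms to the last accepted one;
for constant rate r this realizes a dead-time renewal process with rate
r/(1 + 0.006·r) (checked against that closed form in tests).

## Synthetic stimuli

`make_song` builds song-like spectrograms: sequences of 3–5-harmonic
stacks (fundamental 500–1800 Hz, Gaussian partial width 150 Hz) with
per-syllable amplitude envelopes and linear FM sweeps up to ±20%.
Syllables last 90–150 ms and are separated by short 30–70 ms gaps, the
timing of natural motifs — at 2 s this yields roughly 10–12 syllables.
`make_masker` draws i.i.d. exponential power per time–frequency bin, so
its time-marginal power is stationary (CV ≈ 1/√64 ≈ 0.13). Both are
normalized to unit mean power, so mixing gains are power ratios.

What the generator emulates: two spectrally and temporally distinct
broadband songs (flattened-spectrogram correlation ≈ 0.2) and a
stationary broadband competitor on a shared 1 ms × 64-bin grid. What it
does not: real birdsong syntax, harmonicity fine structure, room
acoustics, binaural cues, or any neural variability beyond Poisson
spiking. Passing tests therefore show that the *circuit mechanism*
behaves as described under controlled drive, not that the model
quantitatively predicts responses to natural recordings.

Two stimulus-level choices matter for the masked conditions and were
fixed at design time:

- **Masker level** defaults to 2× song power. Unit-mean-power maskers
  drive the temporally band-pass STRF weakly (a stationary stimulus has
  little energy at the filter's preferred modulation); 2× makes
  masker-evoked input rates comparable to song-evoked ones, i.e. a
  masker that competes on equal terms, as the strong masker responses in
  the reference data indicate.
- **Masker noise is refreshed per trial** by default (seed-derived, so
  runs remain bit-reproducible), with a flag to freeze one token. With a
  frozen token and Poisson spiking as the only noise source, the masker
  contributes a *repeatable* temporal pattern that a template classifier
  simply absorbs — masked grids sit at ceiling and no hotspot contrast
  can exist. Trial-varying tokens make the masker a genuine source of
  trial-to-trial variability, which is the regime in which lateral
  inhibition visibly rescues discriminability.

## Network operating point

Default weights (leak units): input→R 5, input→I 10, R→C 3, lateral 30,
cortical adaptation 0.04. These were set once, before the behavioral
suites were frozen, by three requirements: a relay should follow its
channel's song spikes roughly one-for-one; the cortical neuron should
run at ~10–15 spikes/s, sparse enough that a competing masker genuinely
degrades template discriminability; and an active channel's inhibition
should hold a masker-driven relay below threshold *across inter-syllable
gaps*, which the 50 ms IPSC tail can only do if the relay's EPSC is not
so strong that single input spikes always win (hence input→R of 5, not
higher, and a large lateral weight — suppression saturates in that
weight). Input→I is twice input→R so the brief alpha kernel delivers the
same synaptic charge as the relay's slower EPSC; the two remain
independently configurable since their ratio is not constrained by the
source.

## Discriminability

`van_rossum` evaluates the distance exactly through the
pairwise-exponential closed form (kernel tails integrated beyond the
recording window); a time-grid summation (`van_rossum_grid`, O(dt)
accurate) is kept as an independent numerical route and cross-checked in
tests. The index classifies, for every template pair, the remaining
2(n−1) trains to the nearer template; with 10-trial sets the 100
template pairs are enumerated exhaustively by default (random draws are
available for large sets), and distance ties are broken by a fair coin
from the seeded generator. τ defaults to 10 ms, a standard choice for
song discrimination at syllable timescales; larger τ blurs syllable
timing and compresses the index toward chance.

Grids are always serialized with their azimuth labels; rows are masker
location, columns target location. `goodness_of_fit` returns mean
absolute deviation over the 20 cells plus Pearson correlation, and
returns NaN correlation for a zero-variance grid (a perfectly uniform
grid has no pattern to correlate — the source study likewise had one
unfittable, very uniform unit).

## Seeding and reproducibility

Every random stream derives from a root seed plus a tuple of structural
keys (condition, trial, channel, purpose) via `SeedSequence`, so: reruns
are bit-identical; different network wirings given the same root seed
receive identical input spikes (which is why adding a lateral connection
leaves the clean row byte-identical); and per-trial masker tokens are
reproducible. CLI runs write a manifest (config hash, seed, version,
outputs) before results.

## Fitting

`fit_to_grid` mirrors the staged, per-connection character of the
original fitting procedure with a deterministic coordinate search
(coarse grid plus local refinement) per parameter: (1) cortical
adaptation strength in [0, 0.2] against the mean clean level; (2) each
channel's feedforward weight against its clean value; (3) the two
lateral weights of each unordered channel pair jointly against that
pair's two masked cells — jointly, because I_j→R_k raises the (masker k,
target j) cell but lowers the reversed cell, so the pair shares its two
knobs. Lateral candidates form a geometric ladder (0–32) since
suppression saturates in the weight. All stages integrate the network on
frozen input spike trains, making the objective deterministic; the
budget counts single-cell simulations and the fitter returns best-so-far
with a warning when it is exhausted. Recovered *weights* can differ from
a hidden generator's (suppression saturates, so weight 8 and weight 30
can produce the same cell), but the discriminability structure is
recovered — which is the fitting target here, as it was in the source
study.

## Problem sizes

Default study conditions are 2 s stimuli, 64 frequency bins, 10 trials
per condition, dt = 0.1 ms. The behavioral test suites run the hotspot
and width-sweep checks at exactly these conditions; structural unit
tests use 0.4–0.5 s stimuli and 2–4 trials, sizes chosen so the full
test run stays in the low minutes on one core. The parameter-recovery
check uses a 400-evaluation budget at the default conditions.

## Known limitations

- No acoustic front end: scenes are spectrograms, not waveforms; there
  are no interaural cues, HRTFs, or elevation.
- Poisson input spiking is the only noise source; real neurons add
  intrinsic and state-dependent variability, so absolute discriminability
  levels here are optimistic.
- The four-channel, one-neuron-per-role architecture is a minimal
  caricature; population effects (pooling, heterogeneous tuning) are out
  of scope.
- Fitted lateral weights are identifiable only up to the saturation of
  suppression (see Fitting).
- The dead-time Poisson thinning is exact only in the small-dt limit;
  at dt = 0.1 ms the bias is < 1% for rates up to several hundred
  spikes/s.
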