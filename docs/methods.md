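# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `ssveplab`.

## Frame-based flicker and duty-cycle bins

A display refreshing at *R* frames/s realizes a flicker frequency *f*
exactly only when the cycle is a whole number of frames, *n = R/f*.
Nominal target frequencies are accepted with 1 % relative tolerance on the
realized frequency *R*/round(*R*/*f*), because the conventional labels
(6.67 Hz for 60/9, 8.57 Hz for 60/7) are themselves rounded. Within one
cycle the ON block leads (the generator only produces contiguous ON
blocks; phase within the cycle does not affect any spectral quantity used
here). Duty cycles are reported as integer percentages rounded half-up —
required so that 3/8 → 38 % and 5/8 → 63 % — and assigned to the four
closed bins [14–25], [28–38], [45–57], [62–72] %. Splits outside every bin
are kept with an empty bin label rather than dropped.

The amplitude spectrum of a duty-*d* unit pulse train is computed in closed
form: DC level *d*, harmonic *n* amplitude (2/*n*π)|sin(*n*π*d*)|. The test
suite checks this against a dense-FFT oracle (one period sampled at
655,360 points, so that every tested duty is an exact sample count and
discretization error is orders of magnitude below the 10⁻⁶ comparison
tolerance).

## Stimulus SNR from a luminance trace

The stimulus-side SNR is 10·log₁₀ of the power at the target bin over the
mean of the six neighboring bins at ±0.25, ±0.5, ±0.75 Hz, reported at the
fundamental and 2nd harmonic. The spectrum is estimated by Welch's method
with **rectangular** segments truncated to the whole number of stimulus
periods nearest 4 s (≈0.25 Hz bin spacing, 50 % overlap). With this choice
a frame-realized tone occupies exactly one bin and does not leak into its
neighbor bins, so ratios of 70 dB and more are measurable; a Hann window
would spread the tone across the very bins used as the noise estimate.
Frequencies incommensurate with the segment length incur scalloping and
are under-reported. With zero noise in the neighbor bins the value is
capped at a documented ceiling of 120 dB. Traces shorter than one segment
are rejected. The low/high classification threshold is 50 dB, between the
two stimulus-quality regimes the pipeline compares (~30 vs ~70 dB).

## Synthetic EEG sessions

The generator emulates a 16-channel (10–20 montage: Fz, Cz, CPz, P1, Pz,
P2, PO3, POz, PO4, PO7, PO8, O1, Oz, O2, TP9, TP10), 500 Hz recording with
cued trials: 3 s inter-trial idle, 2 s cue, 1 s fade, then 5 s of flicker;
stimulation onset is therefore 6 s into each 11 s trial, and the 3 s
immediately before onset contain background activity only. A session is a
sequence of blocks, each presenting every target once in seeded random
order.

Signal components, all in µV:

- **Background**: per-channel 1/f^γ colored noise (inverse-FFT shaping,
  flattened below 1 Hz), γ = 1.5, RMS 10. The log–log PSD slope over
  2–40 Hz recovers γ within ±0.2.
- **Alpha intrusion**: stochastic narrow-band oscillation (Gaussian
  spectral bump, center 10 Hz, bandwidth ≈1 Hz), RMS 4 on occipital
  channels, scaled by the same scalp gain map as the evoked response.
  This reproduces the persistent-10 Hz confound that competes with the
  10 Hz target and degrades short-window decoding.
- **Line interference**: 60 Hz sinusoid, amplitude 2, equal on all
  channels.
- **Evoked response**: during the flicker span only, sinusoids at *f*,
  2*f*, 3*f* with amplitude ratios 1 : 0.5 : 0.25 and fundamental
  amplitude 3 on gain-1 channels. The scalp gain map is 1.0 on the eight
  posterior channels (PO3, POz, PO4, PO7, PO8, O1, Oz, O2), 0.35 on
  P1/Pz/P2/CPz, 0.1 on Fz/Cz/TP9/TP10. Phase is random per trial, common
  across channels up to a per-channel lag ≤10 ms.

The default amplitudes were calibrated once so that the default session
reproduces the operating point reported for this class of system — CCA
accuracy of roughly 65 / 87 / 90+ % at 1.5 / 3 / 5 s analysis windows on
the eight posterior channels — rather than a trivially easy or impossible
decoding problem.

**Stimulus-SNR condition.** The low-SNR condition models imprecise
frequency rendering and ambient modulation: the evoked amplitudes are
scaled by a retention factor (default 0.5 — a weaker, less coherent
stimulus drives a weaker response), the leaked fundamental energy
reappears as an incoherent sideband pair at *f* ± δ with δ ~ U(0.15,
0.35) Hz, and a 10 Hz ambient competitor (amplitude 2, posterior-weighted)
is added during stimulation. At these defaults the mean narrow-band SSVEP
SNR drops by ≈3 dB relative to the high-SNR condition, matching the size
of the condition effect the pipeline is meant to resolve.

**Attention.** Each trial lapses independently with probability
`attention_lapse_prob` (default 0); lapsed trials have every evoked
amplitude multiplied by 0.2 and are flagged in the event table.

**Randomness and pairing.** Every process draws from an independent stream
keyed by (seed, trial index, process id). Identical seed + config is
bit-identical; regenerating a session under a different condition
(`inject_condition`) changes only the condition-specific streams, so
high/low-SNR and attention comparisons are exactly paired at the sample
level. This is also why condition injection regenerates from stored
provenance instead of editing the array in place: an attention lapse
*rescales* the evoked component, which cannot be done post hoc on mixed
data.

What the generator does **not** model: non-stationary artifacts (blinks,
saccades, EMG, motion), volume-conduction correlation between channels
(noise is channel-independent apart from the common line and evoked
components), SSVEP latency (~0.1 s) and amplitude non-linearities in
stimulus contrast, and any dependence of the response on duty cycle,
color, size or eccentricity — those stimulus properties are carried as
metadata, not as response modulators. Passing tests therefore show the
*pipeline* behaves correctly on signals with the assumed structure, not
that it would reach the same numbers on recorded EEG.

## Preprocessing

Filtering is zero-phase (forward–backward) per channel: an IIR notch at
60 Hz (Q = 30) followed by a 4th-order Butterworth band-pass, 4–40 Hz.
Zero phase matters because CCA compares the signal against fixed-phase
templates. Segmentation takes idle = [onset − 3 s, onset) and
stimulation = [onset, onset + L); trials without enough surrounding data
are skipped with a logged warning naming the trial (or raise, on request).

Channel selection computes the narrow-band SNR per channel and trial at
the trial's own target frequency in both windows, averages across trials,
and runs a paired t-test per channel. Channels with p < 0.01 and a
positive mean rise are ranked by the rise, and the top 8 are retained —
matching the eight-channel posterior montage such screening selects on
real data. Both windows are analyzed with equal (3 s) Welch segments so
that, absent a response, idle and stimulation estimates are exchangeable
and the test keeps its nominal false-positive rate.

## Spectral estimation for the SSVEP SNR statistic

The neighbor-bin statistic needs its six noise bins at ±0.25·k Hz to lie
outside the spectral mainlobe of the target component. `welch_psd`
therefore uses Hann segments of 4 s by default (native 0.25 Hz
resolution), zero-padded only to regularize the grid; with 1 s segments
the mainlobe (±1 Hz) would cover all six neighbor bins and clamp the
statistic into [2.0, 3.4] regardless of signal strength, erasing the
multi-dB stimulation and condition effects the statistic exists to
measure. Shorter analysis windows fall back to a single segment of the
window length. The 1 s segment length remains available as a parameter
for broadband spectral estimates. Nominal target frequencies are mapped
to the nearest grid bin.

On a flat spectrum each of the two terms equals exactly 1 (the statistic
is 2.0); when all six neighbor bins are zero the per-term ratio is capped
at 10¹². Note the target bin contains its own noise floor, so an injected
tone with power equal to the noise reads ≈3 dB, not 0.

## CCA and FBCCA

The canonical correlation is computed by orthonormalizing the centered
channel matrix and template matrix (SVD with a rank tolerance; null
directions are dropped with a logged warning on rank-deficient input) and
taking the largest singular value of the cross-product of the bases. This
is numerically stabler than the normal-equations route, which the test
suite uses as an independent oracle. ρ is invariant to per-channel affine
rescaling by construction. Templates use 3 harmonics with
t = 1/fs … N/fs. Ties in the argmax resolve to the lowest candidate
frequency, deterministically. Classification windows start at stimulation
onset; no visual-latency offset is applied.

The filter bank uses 5 subbands starting at n·6 Hz (n = 1..5) with a
common 40 Hz upper edge, realized as 4th-order zero-phase Chebyshev
type-I band-passes (0.5 dB ripple) with a 2 Hz transition margin added on
both sides, and combination weights w(n) = n^−1.25 + 0.25 applied to the
squared subband correlations. These are the standard values for this
method family; all are overridable through `FilterBankConfig`. FBCCA's
advantage over plain CCA appears when the fundamental band is corrupted
(strong alpha intrusion, sidebands) while harmonic bands stay clean; on
clean high-SNR sessions the two methods converge.

## Evaluation

Accuracy is tabulated on a 0.5–5 s window grid in 0.5 s steps; dispersion
is the standard deviation across blocks (one block = one presentation of
all four targets). The ITR uses the analysis window length as the
selection time T, with no gaze-shift or cue overhead (a deliberate,
configurable convention — published ITRs sometimes include overheads).
The p·log₂p terms are handled by their limits at p = 0 and 1; the rate's
minimum is exactly 0 at chance p = 1/N. Condition comparisons test the
paired differences for normality (Shapiro–Wilk at 0.05) and use a paired
t-test when normal, a Wilcoxon signed-rank test otherwise; exactly
constant differences are rejected as degenerate rather than assigned a
p-value. Stars follow the convention of the analyses this package
supports: * for p < 0.01, ** for p < 0.05.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
sessions of 32–200 trials (8–50 blocks of 4 targets), which is enough to
resolve every effect they assert: binomial confidence bands at these sizes
are a few percentage points wide, and the condition effects built into the
generator are an order of magnitude larger. The square-wave oracle uses
655,360 samples per period; the permutation null for CCA uses 200 draws.

## Known limitations

- The EDF reader requires MNE and annotations of the form
  `ssvep/<frequency>`; there is no EDF writer, so the round-trip tests
  cover the delimited-text and HDF5 containers.
- PSDA at analysis windows shorter than ~2 s uses a single short Welch
  segment; its variance grows accordingly and CCA should be preferred
  there (as it is on real systems).
- The per-channel significance screen is uncorrected for multiple
  comparisons, as is conventional for this selection step; with 16
  channels at α = 0.01 an occasional false positive is expected and the
  top-k rule bounds its impact.
- The generator's stimulus-property metadata (color, size, location) do
  not modulate the response; studying those effects requires setting the
  response parameters per condition explicitly.
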