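# Methods

This note documents the model implemented by `pyzapline`, its assumptions,
the tunable parameters, the synthetic data used to validate it, and the
numerical choices made where the design was genuinely open.

## Signal model and assumptions

A recording is a channels × samples matrix `X` with sampling rate `srate`.
The method assumes `X = B + Σ_j w_j s_j(t)ᵀ`: broadband background activity
`B` plus a small number of narrowband noise sources, each a near-sinusoidal
time course `s_j` at frequency `f_j` projected through a spatial topography
`w_j`.  Two failure modes of plain spatial filtering motivate the design:
the topography may change over the recording (movement, equipment
repositioning), and the exact noise frequency may be unknown or drift.
Spatial filtering needs at least two channels; everything below assumes a
multichannel recording.

All spectral quantities are Welch PSDs (Hann taper, 50 % overlap, constant
detrend) in 10·log₁₀ units, summarized across channels by the arithmetic
mean of the log spectra — the log of the geometric mean of the linear PSDs.
This choice keeps a few very noisy channels from masking the rest; it is
always ≤ the log of the arithmetic mean (checked as a test invariant).

## Detection

**Coarse.** The full-recording spectrum is computed with a window of
`srate × min_chunk_length` samples (7500 at 250 Hz → 1/30 Hz resolution).
A 6 Hz window walks bin by bin across `[minfreq, maxfreq]` = [17, 99] Hz.
The *center power* at a bin is the mean log power of the flanking thirds of
the window (the middle third, where a peak would sit, is excluded).  A bin
whose excess over the center power is > `coarse_freq_detect_power_diff`
(4 dB ≙ 2.5× power) triggers a detection; the contiguous region with excess
> 1.76 dB (≙ 1.5×) around it is delineated and the region's power maximum is
the noise frequency.  17 Hz keeps alpha-band peaks and low subharmonics out;
99 Hz stops below the second line harmonic.

**Fine (per chunk and post-cleaning).** In the same 6 Hz window, the
*deviation* is the center power minus the mean of the lower 5 % quantiles of
the two flanking thirds.  Mean ± SD or MAD measures are dragged upward by
exactly the outliers being sought; the lower quantile is not.  The
detection threshold is `center + 2 × deviation` (`freq_detect_mult_fine`).
A chunk carries the artifact if its spectral peak within ±0.05 Hz of the
target exceeds that threshold; chunk spectra use a single Hann-tapered
segment spanning the whole chunk, so even a 30 s chunk resolves 1/30 Hz.

## Segmentation

The recording is band-passed `f ± 3` Hz (4th-order Butterworth, applied
forward-backward for zero phase), channel covariances are computed in
non-overlapping 1 s epochs, and for every epoch boundary the Frobenius
distance between the norm-scaled mean covariance of the 20 epochs before
and after is recorded.  Norm scaling makes the series invariant to overall
amplitude; the 20 s averaging window is what lifts genuine topography
changes above the estimation noise of single-epoch covariances in a 6 Hz
band (a single-epoch version was measured to miss EEG-level switches
entirely), while staying below the 30 s minimum chunk duration so peak
locations are not displaced.  Local maxima above `median + 3 × IQR` become
chunk boundaries; candidates closer than `min_chunk_length` (30 s) to an
accepted boundary or to either end are skipped, in time order.  A fixed
`chunk_length` bypasses all of this; with no surviving peak the recording is
one chunk.

## The core cleaning operation

Per chunk at frequency `f`:

1. **Split.** `smoothed` is a moving average of length `srate/f` samples
   (fractional lengths by linear interpolation between the two flanking
   integer lengths; reflection padding at the edges).  Its frequency
   response has nulls at `f` and all harmonics.  `residual = chunk −
   smoothed` by definition, so the parts always sum back exactly.
2. **Bias.** `C0` is the residual covariance; `C1` is the covariance of the
   residual reconstructed from only the DFT bins nearest `k·f`
   (k = 1 … ⌊Nyquist/f⌋), averaged over consecutive windows of
   `nfft = 2^round(log2 srate)` samples (capped at the chunk length).
3. **Decompose.** `C0` is whitened through its eigendecomposition
   (eigenvalues < 1e−9 × the largest discarded; at most `nkeep` kept when
   set), the whitened `C1` is eigendecomposed, and components are sorted by
   descending eigenvalue — the *score*, the component's noise-power ratio.
4. **Select.** Outliers in the scores are counted by iterated
   mean + σ·SD thresholding (sample SD, n−1; strict comparison; iteration
   stops when nothing is removed).  The removal count is
   `max(outliers, fixed_nremove)` when the artifact is present (only
   `fixed_nremove` otherwise — removing one component where nothing was
   detected catches missed artifacts at negligible cost), finally capped at
   ⌊components/5⌋.
5. **Remove and recombine.** The selected component time courses are
   regressed out of every channel of the residual (least squares), and
   `smoothed` is added back.  Only the residual is spatially reduced, so the
   output keeps full rank and untouched spectrum away from the noise bands.
   Removing zero components is implemented as the exact identity.

## Adaptation loop

After each pass the cleaned full-recording spectrum is re-checked with the
fine threshold: if > 0.5 % of the bins within ±0.05 Hz of the target lie
above `center + 2·deviation`, the cleaning was **too weak**; if > 0.5 % of
the bins within [−0.4, +0.1] Hz lie below `center − 2·deviation`, it was
**too strong** (an overcleaning notch sits slightly below the noise
frequency, hence the asymmetric band).  Too weak: σ decreases 0.25 (floor
2.5) and the fixed minimum removal increases 1.  Too strong: σ increases
0.25 (ceiling 4.0) and the fixed minimum decreases 1 (floor: its configured
initial value).  Too strong takes precedence and latches — once the
cleaning has overshot it is never strengthened again.  The pass re-runs
until no parameter changes, with a hard cap of 10 iterations per frequency
(the bounded σ/fixed lattice converges well before; the cap guards
pathological oscillation).  Each new noise frequency starts from the
configured initial σ and fixed removal, and is searched on the
already-cleaned data from 0.05 Hz above the previous frequency.

The whole pipeline contains no random number generation, so identical input
and configuration reproduce the output bit for bit; the report's
`final_config` (the configuration with all detected frequencies filled in)
replays a run exactly.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `noisefreqs` | empty | Hz | frequencies to clean; empty = detect automatically |
| `minfreq`, `maxfreq` | 17, 99 | Hz | automatic search range |
| `detection_winsize` | 6 | Hz | detection window (thirds define center power) |
| `coarse_freq_detect_power_diff` | 4 | dB | coarse detection margin (2.5×) |
| `coarse_freq_detect_lower_power_diff` | 1.76 | dB | region-growing margin (1.5×) |
| `freq_detect_mult_fine` | 2 | – | fine-threshold multiplier |
| `detailed_freq_bounds_upper` | [−0.05, 0.05] | Hz | peak band / too-weak check |
| `detailed_freq_bounds_lower` | [−0.4, 0.1] | Hz | notch band / too-strong check |
| `max_proportion_above_upper` / `_below_lower` | 0.005 | – | tolerated violating bins |
| `noise_comp_detect_sigma` | 3.0 | SD | initial outlier threshold |
| `min_sigma`, `max_sigma` | 2.5, 4.0 | SD | adaptation bounds |
| `adaptive_nremove`, `adaptive_sigma` | on | – | component / strength adaptation |
| `fixed_nremove` | 1 | count | minimum components removed per chunk |
| `search_individual_noise` | on | – | per-chunk peak fine-tuning |
| `chunk_length` | 0 | s | fixed chunking (0 = adaptive) |
| `min_chunk_length` | 30 | s | minimum chunk duration |
| `win_size_complete_spectrum` | 0 | samples | Welch window (0 → srate × chunk length, using `min_chunk_length` when chunking is adaptive) |
| `nkeep` | 0 | count | PCA dimension cap inside the decomposition (0 = none) |
| `plot_results` | on | – | write diagnostic figures |

The `win_size_complete_spectrum` auto rule needs a chunk length, but the
default chunk length is 0 (adaptive); the minimum chunk length is
substituted in that case, which yields the long windows (high frequency
resolution) the detectors need.

## Synthetic data

The generator produces what the algorithm assumes: independent 1/f Gaussian
background per channel (frequency-domain shaping of white noise with a
1/√f amplitude profile, DC removed, each channel rescaled to exactly unit
variance) plus sinusoidal sources with constant or linearly drifting
frequency and amplitude, optional activity intervals, and topographies that
switch abruptly at stated change points.  Source amplitudes are calibrated
so the raw noise/surroundings ratio (band power ±0.05 Hz over the 6 Hz
center power) hits a requested contamination level: the standard fixtures
use ratio ≈ 7 for the EEG-like cases (24 channels) and ≈ 500 for the
MEG-like case (64 channels), all 300 s at 250 Hz.  Everything regenerates
bit-identically from a seed.

What the generator does *not* emulate: correlated background across
channels (no head-model forward projection), non-sinusoidal artifact
waveforms, transient artifacts (blinks, muscle), and line-noise sidebands.
Passing tests therefore demonstrate correct mechanics and calibration of
the pipeline under its own model assumptions, not performance on any real
recording — real data add harmonics structure, correlated background and
channel-specific noise floors that can only weaken, not change the meaning
of, the analytics reported.

## Numerical choices

* Welch: Hann taper, 50 % overlap, constant detrend; PSD floored at 1e−300
  before the log.
* Quantiles: linear-interpolation empirical quantile; argmax ties break
  toward the lowest frequency; all threshold comparisons are strict (`>`).
* Whitening rank cut at 1e−9 × the largest eigenvalue of `C0`; scores
  clipped at 0 against round-off.
* The moving-average smoother uses reflection padding, so the complement
  identity holds over the whole chunk including edges.
* Epochs for segmentation are non-overlapping 1 s, final partial epoch
  dropped; a fixed-chunk remainder shorter than the minimum chunk length is
  merged into its predecessor.
* Resampling (CLI `--resample`) is zero-phase polyphase; lower rates mean
  fewer harmonics below Nyquist and an easier cleaning problem.

## Problem sizes

The test suite and the acceptance script run on 300 s, 24–64 channel,
250 Hz synthetic recordings — enough for ≥ 10 chunks at the minimum chunk
length, sub-0.04 Hz spectral resolution, and stable covariance statistics —
and on 60 s, 6-channel recordings for I/O and CLI round trips.  A full
automatic cleaning of a 300 s / 24-channel fixture takes on the order of a
second on a laptop-class CPU.

## Known limitations

* A topography change and a frequency close to a chunk boundary are
  resolved at 1 s epoch granularity; boundaries are accurate to ~1–2 s.
* Very strong contamination (MEG-like, ratio ≫ 100) can leave the
  below-noise spectrum slightly distorted, as the spatial projection also
  removes some background in the noise direction; the below-noise
  removed-power analytic in the report makes this visible.
* With fewer than 10 channels the ⌊n/5⌋ cap limits removal to one
  component; heavily contaminated low-channel-count recordings may stay
  under-cleaned.
* The EDF writer stores 16-bit samples (EDF's native precision); use the
  binary-float format for lossless round trips.
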