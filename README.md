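# pyzapline

Automatic, adaptive removal of frequency-specific noise — power-line
interference and other narrowband oscillatory artifacts — from continuous
multichannel electrophysiological recordings (EEG, MEG and similar).

## The problem

Line noise at 50/60 Hz (and artifacts from lab equipment at other
frequencies) contaminates M/EEG recordings.  Notch filters carve a hole in
the spectrum; regression methods assume constant artifact amplitude; plain
spatial filtering assumes one fixed artifact topography and needs manual
tuning of the target frequency and the number of components to remove.

`pyzapline` combines spectral and spatial filtering and automates every
tuning decision:

1. **Detection.** The Welch log-spectrum (Hann taper, 10·log₁₀ PSD,
   geometric mean over channels) is scanned with a 6 Hz window between 17
   and 99 Hz; a frequency whose power exceeds the window's *center power*
   (mean of the flanking thirds) by > 4 dB (a 2.5× power increase) marks a
   noise frequency.
2. **Segmentation.** The data are narrowband-filtered ±3 Hz around the noise
   frequency and channel covariance matrices are tracked in 1 s epochs;
   peaks in the covariance distance series split the recording into chunks
   of spatially stable noise topography (minimum 30 s).
3. **Cleaning.** Each chunk is split into a spectrally clean part and a
   noise-band residual by a period-matched moving average (nulls at *f* and
   its harmonics, `smoothed + residual == chunk`).  The residual is
   decomposed by joint decorrelation (DSS): solving the generalized
   eigenproblem of the baseline covariance **C₀** and a covariance **C₁**
   biased toward the DFT bins at *k·f* ranks spatial components by noise
   power.  The leading components — chosen by an iterative mean + σ·SD
   outlier count, capped at ⅕ of the components — are regressed out of the
   residual only, and the clean part is added back.  No spectral notch, no
   rank reduction.
4. **Adaptation.** The cleaned spectrum is checked against quantile-derived
   thresholds for a remaining peak (*too weak*) or an introduced notch
   (*too strong*); σ and the fixed minimum removal are nudged and the pass
   re-runs until the result is acceptable.  Subsequent noise frequencies are
   then searched on the already-cleaned data.

## Worked example

```python
from pyzapline import run
from pyzapline.synthetic import standard_fixture, measure_noise_ratio

fx = standard_fixture("stationary-50Hz", seed=0)   # 24 ch, 300 s, 250 Hz
print(round(measure_noise_ratio(fx.combined, 50.0), 2))

cleaned, report = run(fx.combined)
r = report.frequencies[0]
print(round(r.frequency, 2), r.n_removed_per_chunk,
      round(r.ratio_noise_to_surroundings_clean, 2))
```

prints

```
7.16
50.0 [1] 1.03
```

The synthetic recording carries a 50 Hz source whose power in the ±0.05 Hz
band is 7.16× the surrounding spectrum (an EEG-like contamination level).
The pipeline detects 50.0 Hz automatically, removes one spatial component in
the single stationary chunk, and leaves a noise/surroundings ratio of 1.03 —
a ratio of 1 means no residual peak and no notch.

From the shell:

```bash
pyzapline --input rec.edf --output out/ --resample 250
```

writes the cleaned recording, a `report.json` holding every analytics value
plus the exact configuration used (re-running with it replays the cleaning
bit-identically), and one eight-panel diagnostic figure per cleaned
frequency.

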