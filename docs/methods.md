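# Methods

`phonmeter` distils a reference model of time-varying loudness (the
*teacher*) into a small multilayer perceptron (the *student*) that maps a
61-band short-term spectrum directly to instantaneous loudness level in
phons.  This note records the model, the synthetic study material, the
numerical choices, and what the desk-scale experiments do and do not
show.

## Spectral front end

Audio is mono at 16 kHz, calibrated so that a unit-RMS waveform
corresponds to 94 dB SPL (the 1-Pa microphone reference; configurable).
Frames of 1024 samples are windowed with a periodic Hann window and
transformed with a 1024-point DFT; successive frames are shifted by 560
samples when building training corpora and by 16 samples (1 ms) for
loudness traces.  Band powers are normalised by the window energy
(`2 / (N * sum(w^2))`) so that a steady sinusoid's banded level equals
its calibrated SPL and broadband power is conserved up to window
leakage.

The 512 positive-frequency bins (DC excluded) are grouped into 61
bands: every bin with centre frequency below 200 Hz forms its own band
(12 bands, 15.625–187.5 Hz), and from the upper edge of the last single
bin (195.3125 Hz) onward the band edges grow by exactly `2^(1/9)` per
band (ninth-octave bands, centre = geometric mean of the edges), the
last band being truncated at the 8-kHz Nyquist limit.  This produces
12 + 49 = 61 bands; the first ninth-octave band happens to contain
exactly one bin, centred at 203 Hz, so "one bin per band up to 0.2 kHz"
holds at bin resolution.  Note that exactly ninth-octave bands *from
200 Hz to 8 kHz* could only ever number 48 (log2(40) ≈ 5.32 octaves);
continuing the edges from the single-bin boundary and truncating at
Nyquist is the only contiguous reading that yields the canonical count
of 61.  Per-band levels are floored at −30 dB SPL so the network sees
bounded inputs; the floor is far below any audible level.

## The teacher

The teacher follows the classic loudness-model cascade (Glasberg-and-
Moore-style time-varying loudness):

1. **Outer/middle ear.**  Free-field-to-eardrum (frontal incidence) and
   middle-ear gain tables, interpolated on a log-frequency axis and
   applied at the band centres.  The tables reproduce the standard
   features: ear-canal resonance near 3 kHz, strong low-frequency
   attenuation by the middle ear.
2. **Excitation pattern.**  Each band is treated as one sinusoidal
   component at its centre.  150 channels are spaced 0.25 Cam apart at
   Cam 1.75–39 on the ERB_N-number scale
   (`Cam(f) = 21.4 log10(4.37 f/1000 + 1)`,
   `ERB(f) = 24.7 (4.37 f/1000 + 1)` Hz).  Components pass through
   rounded-exponential filters `W(g) = (1 + p|g|) e^{-p|g|}` with
   `p = 4 fc / ERB(fc)` on the upper side and a lower side that
   flattens by 0.35 of its 51-dB value per dB of component level
   (upward spread of excitation); component intensities add in power.
3. **Specific loudness.**  A compressive transform per channel:
   `N' = C[(G E + A)^α − A^α]` in the mid range (C = 0.047), a
   continuous rapidly shrinking branch below the threshold excitation,
   and a square-root branch above E = 1e10.  The threshold excitation
   is 3.63 dB from 500 Hz up and rises toward low frequencies (less
   cochlear gain); `α` and `A` are interpolated smoothly between the
   published anchors (0.2, 4.72) at full gain and (0.267, 8.8) at
   −25 dB gain.  Published tables quantise these constants in 5-dB
   steps of gain; smooth interpolation between the anchors changes
   third-decimal values only and keeps the transform monotone, which is
   what the behaviour-level checks rely on.
4. **Summation and phon conversion.**  Instantaneous loudness in sones
   is `0.25 * Σ N'`.  The sone-to-phon mapping is *self-calibrated*: the
   complete pipeline (including the front end) is run on 1-kHz pure
   tones from 0 to 110 dB SPL in 0.25-dB steps and the strictly
   monotone level-to-sone curve is inverted by interpolation on
   log-sones.  The phon scale therefore satisfies its definition at
   1 kHz *by construction*, and quantities like "white noise at 60 dB
   SPL is ~20 phons louder than a 60-dB tone" are genuine model
   predictions, not calibration artefacts.  Phons are clipped at 0 for
   reporting; sones below the 0-dB-SPL calibration point map to 0 phons.
5. **Temporal smoothing.**  Two cascaded one-pole smoothers with
   asymmetric attack/release coefficients per 1-ms step, operating on
   sones (the quantity the ear integrates) and converted back to phons:
   short-term attack 0.045 / release 0.02, long-term attack 0.01 /
   release 0.0005 — the published values of the time-varying loudness
   model.  The maximum of the long-term trace is the overall loudness.

Constants not fixed by behavioural checks (exact transfer-table
entries, threshold curve) are taken from the published model
literature at the precision recalled there; the package's contract is
the behaviour suite: phon identity at 1 kHz (±0.5 phons from 20 to
100 dB SPL), strict monotonicity with level, spectral loudness
summation that shrinks at high levels, non-decreasing loudness with
noise bandwidth at fixed level, and smoother fixed-point/asymmetry
properties.

## Synthetic study material

No external corpora are used.  The generator emulates the full-scale
training material:

* **Artificial sounds** — pure tones (15–110 dB SPL, 20–8000 Hz,
  optionally with white or pink background noise from 60 dB below up to
  10 dB below the tone), bandpass noises (bandwidth log-uniform 0.1–5
  octaves, spectral slope uniform −6…+6 dB/octave), spectrally notched
  broadband noises (notch uniform 0–2 octaves), and white/pink noise,
  noise levels uniform 20–100 dB SPL.  The distributions cover the
  stated ranges evenly; the exact full-scale distributions were not
  recorded, so these are package choices.  Each artificial sound is a
  *single analysis frame* (1024 samples): one generated sound
  contributes one independently drawn spectrum, mirroring a corpus in
  which "spectra were generated".
* **Speech surrogate** — amplitude-modulated harmonic complexes with a
  wandering fundamental (80–280 Hz), three slowly moving formant-like
  resonances, syllabic modulation with true silent gaps, and weak gated
  high-frequency noise bursts, scaled to 60 dB SPL RMS like the
  full-scale speech material.  Its instantaneous-loudness distribution
  spans more than 40 phons and reaches near-silence in the gaps, the
  features of running speech that matter for distillation.  It does not
  contain linguistic structure, realistic formant dynamics, or
  recording-channel effects; passing tests therefore show that the
  pipeline distils *a* speech-like broadband nonstationary class, not
  that the student meets any benchmark on real speech.

Corpora are described by a seeded manifest (every sound carries its own
integer seed) and are bit-reproducible.  Frames are labelled with the
teacher's instantaneous loudness level and split 90/10 into training
and validation sets by a seeded shuffle of rows.

## The student and its training

The student is the 61-150-150-150-1 perceptron with rectified-linear
hidden units and a linear output, implemented directly on numpy arrays
(He-scaled seeded initialisation, zero biases).  Inputs (dB) and output
(phons) share the rough 0–110 scale, so the network maps spectra to
phons without feature engineering.  Training minimises mean squared
error (reported as RMS in phons) with Adam at its standard defaults
(step 0.001, decays 0.9/0.999, epsilon 1e-8), batch size 128, for 400
epochs by default.

Two numerical aids are used, neither of which changes the represented
function family:

* inputs are standardised with training-split statistics during
  optimisation and the affine change of variables is folded back into
  the first layer on return, so the deployed network consumes raw dB
  spectra;
* the Adam step size follows a cosine decay to 1e-5 over the run.  The
  full-scale protocol anneals minibatch noise by sheer step count
  (millions of steps); at desk scale (~10^5 steps) a constant step
  leaves the optimiser bouncing at a ~1-phon noise floor, and the decay
  substitutes for that annealing (training RMS 0.32 instead of 0.8 on
  the 30k-row artificial corpus).

Weights are persisted in an HDF5 container with named arrays, a format
version, the layer sizes, the training seed and the corpus-manifest
hash; loading is bit-exact and validates format and shapes.

## What desk scale can and cannot reproduce

The full-scale study trains on ~1.7 million spectra; the desk-scale
corpora here contain ~30,000 rows (the package default; built in ~15 s
and trained in ~4 minutes on one CPU core).  The qualitative results
reproduce cleanly at this scale: the student tracks the teacher far
better than bias-corrected A-weighted SPL, a student trained only on
speech surrogates fails catastrophically on tones and notched noises
(tens of phons RMS) while the artificial-sounds student stays moderate
everywhere, error decreases with corpus size, and long training on a
small corpus shows the late-checkpoint overfitting uptick.

The *absolute* sub-phon accuracy of the full-scale study is a
data-volume result and does not reproduce at 1/50th of the data: with
~27k independent training spectra the held-out RMS error of the
artificial-sounds student plateaus near 1.2–1.3 phons (median absolute
error ~0.4 phons), dominated by tone-in-noise and bandpass-noise
spectra.  The error follows an almost exact `n^(-1/2)` law in the
corpus size (0.69 phons at 100k rows), which extrapolates to the
0.3–0.4-phon regime at around a million spectra — the full-scale
corpus size.  Weight decay and longer training do not close the gap,
which identifies it as sample complexity of the 61-dimensional input
manifold rather than optimisation.  The acceptance script reports the
honestly computed desk-scale values.

## Numerical choices and degenerate inputs

* Percentiles of absolute error use linear interpolation between order
  statistics.
* A-weighting is evaluated from the standard analytic pole formula at
  the 61 band centres (not per bin), consistent with the
  representation the student sees; its RMS error is computed after
  removing the per-set mean offset to the teacher labels.
* The stationary-loudness baseline applies the teacher once to each
  sound's power-averaged band spectrum and compares with the overall
  (maximum long-term) loudness of the time-varying run.
* Digital silence maps every band to the −30-dB floor, which yields
  0 sones and 0 phons.  All-zero signals cannot be RMS-scaled and are
  rejected.  Bandpass noise with vanishing bandwidth degenerates to a
  tone at the centre frequency.
* The sone-to-phon inversion fails loudly (raises) if the calibration
  sweep is not strictly monotone, which would indicate an inconsistent
  teacher configuration.
* Smoothing at a 560-sample hop would be wrong (coefficients are per
  1-ms step); traces always use the 16-sample hop.

## Known limitations

* The teacher is monaural/diotic free-field only; no binaural stages.
* The front end is single-resolution (one 1024-point DFT), the design
  the distillation study targets, not the multi-resolution front end of
  the original time-varying loudness implementation; very low
  frequencies are under-resolved accordingly.
* Ear-transfer and threshold tables are interpolated from published
  anchor values at reduced precision; absolute loudness levels for
  extreme spectra may deviate from the reference implementation by a
  few tenths of a phon, within the tolerance of every behavioural
  contract the package states.
* The speech surrogate is a statistical stand-in; results on real
  speech corpora are out of scope.
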