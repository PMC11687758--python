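# Methods

## The problem and the two nasalance measures

Hypernasality — excessive nasal resonance during oral speech, typical of
velopharyngeal dysfunction and cleft palate — is assessed instrumentally
with a nasometer: two microphones separated by a plate record the nose and
mouth signals on separate channels.  The classic **eNasalance** score is a
band-limited energy ratio: both channels are restricted to a 300 Hz band
centered at 600 Hz (450–750 Hz, where the nasal murmur concentrates) and

```
eNasalance = 100 · RMS(nose) / (RMS(nose) + RMS(mouth))   [percent]
```

is computed per utterance; a speaker's score is the unweighted mean over
utterances.  The filter is pinned as a 4th-order Butterworth band-pass
applied forward–backward (zero phase), so scores are bit-reproducible.

**mfccNasalance** replaces the fixed band with a learned classifier.  Each
recording is cut into 250 ms windows, one starting every 100 ms; each
window becomes a 2 × 39 × 26 tensor (2 channels × 39 cepstral coefficients
× 26 frames) fed to a small CNN that outputs the posterior probability that
the window is nasal.  A speaker's mfccNasalance is the arithmetic mean of
those nasal posteriors over all their windows, a value in [0, 1].  When
cross-validation produces several fold models, the released posterior is
the mean over folds; by linearity this equals averaging per-fold speaker
scores.

Either score can be recoded to the 4-level clinical scale (0 oral, 1 mild,
2 moderate, 3 severe) by rank, preserving the group sizes of a reference
distribution (normally the perceptual classification of the same cohort).
This transform inherits the reference's distribution by construction — it
cannot detect a cohort-wide shift — which is a documented limitation of the
approach, not of the implementation.

## Feature front-end

Per channel and window: 25 ms frames with a 10 ms hop and centered
(reflect-padded) framing — the only convention that yields exactly 26
frames from 250 ms — Hann window, power spectrum, a 40-filter Slaney-style
mel filterbank, a 10·log10 compression with a 1e-10 power floor (silent
input stays finite), and an orthonormal DCT-II keeping 13 coefficients.
First and second time-derivatives from a 9-frame linear regression with
edge replication complete the 39 rows; a pure 39-static variant exists
behind `FeatureConfig(n_static=39, include_deltas=False)`.  No per-speaker
or corpus normalization is applied; raw stacks are fed to the network.
Milliseconds are converted to samples with round-half-to-even; intervals
are half-open `[start, end)`; the default working rate is 44.1 kHz
(nasometer hardware rates vary, so this is configurable, as is the channel
order, default nose = channel 0).

## Labels from alignments

Training labels come from phone alignments, not manual annotation.  Nasal
consonants (/m/, /n/, /ɲ/ by default) are nasal in full.  A vowel sharing a
boundary with a nasal consonant is partially nasalized, the section
abutting that boundary: the whole vowel if shorter than 60 ms, 50% of it
between 60 and 90 ms (boundaries inclusive), 30% above 90 ms.  A window is
labeled nasal when its accumulated nasal time reaches 30% of the window —
at least 75 ms of 250 ms, read inclusively since 75/250 = 0.30.  Unknown
phone symbols are logged and treated as oral; silence contributes nothing.
Windows overlapping utterance-final silence are kept.

## The window classifier

Two convolution blocks — conv (16 filters, stride 1, same padding, linear
activation), batch normalization, leaky ReLU (slope 0.01), 2×2 stride-1
same-padded max pooling (which does not downsample; implemented exactly as
specified although unusual) — then a 128-unit linear dense layer and a
2-way softmax.  The kernel shape `i × j` (coefficient × time axes) is the
object of study: `j = 1` kernels are *spectral*, `i = 1` *temporal*,
otherwise *spectral-temporal*.  The grid is all shapes with
1 ≤ i, j ≤ 8 except 1 × 1, each used either in both layers or with a
pointwise 1 × 1 first layer that mixes the nose and mouth channels per
cell — 126 configurations; with 5-fold cross-validation a full campaign
trains 630 models, and averaging the per-fold correlations over 3 utterance
types yields 378 aggregated measures.

Training uses categorical cross-entropy (the standard companion of
softmax; no loss is mandated otherwise), Adam, Glorot-uniform
initialization, batch 64, and keeps the final-epoch weights (no early
stopping).  Class imbalance is not re-weighted.  Cross-validation splits
are speaker-disjoint: speakers are partitioned into 5 seeded folds and no
speaker's windows appear on both sides of any split.  Full-scale defaults
are 100 epochs at learning rate 1e-5; the desk-scale *reduced* regime
(`TrainConfig.reduced()`) uses 20 epochs at 1e-3, a standard Adam step for
small corpora, so a configuration trains in minutes on one CPU.  Batch
normalization uses running statistics at inference.

The CNN stack itself is implemented in this package on numpy (convolution
as a sum of shifted per-offset channel mixes, gradients verified against
finite differences and the forward pass against an independent correlation
routine in the tests), driven entirely by explicit seeded generators: the
same seed gives bit-identical weights and training trajectories.

## Synthetic cohorts

No clinical recordings ship with the package; the generator produces the
signal structure the method exploits, deliberately schematically.  Oral
vowels are harmonic sources with formant-like mid-frequency emphasis on the
mouth channel (nose at a 0.1 leakage gain); oral consonants are 1–4 kHz
noise bursts; nasal consonants are low-frequency harmonic murmurs whose
envelope peaks at 500 Hz (covering the 450–750 Hz analysis band) on the
nose channel (mouth at 0.1 leakage); vowel sections adjacent to nasals are
cross-faded toward the murmur over exactly the durations the labeling rules
nasalize.  A speaker's nasality level in [0, 1] is the probability that any
phone slot is a nasal consonant, so the realized nasal phone-time fraction
tracks the level; per-speaker fundamental frequency (170–250 Hz) and gain
variation keep folds non-trivially different.  Annotations tile each
utterance exactly and are correct by construction.

What passing tests on this material shows: the pipeline recovers a known
nasality ranking from the channel-balance/low-frequency cues it is designed
to read, with no speaker leakage.  What it does not show: robustness to
real vocal tracts, dialectal nasality differences, room acoustics,
microphone bleed beyond a scalar gain, or pathological voice quality — the
generator has none of these.

## Validation experiments

`nasalkit.experiments` pins the desk-scale study conditions used by the
test suite and `scripts/acceptance.py`: a training cohort of 10 speakers ×
3 utterances (~2.6 s of speech each, ~780 windows) with overlapping
nasality levels 0.15–0.55 (both classes present in every fold), a test
cohort of 10 speakers graded 0.0–0.9, and the pointwise-first 3 × 3
configuration trained in the reduced regime with 5-fold speaker-disjoint
cross-validation.  These sizes make the whole experiment a few minutes of
single-CPU work while leaving comfortable margins on the checks:
validation accuracy clears 0.9 and the Spearman correlation between
mfccNasalance and the generated nasality level clears 0.8.  A leakage
guard re-runs the same cross-validation with labels randomly permuted
(10 epochs) and checks that validation accuracy stays within 0.1 of the
majority-class prior.

## Numerical choices and edge cases

- "Same" padding with even kernel extents puts the extra padded position
  after (the common framework convention); max-pool tie-breaks route the
  gradient to the first matching candidate.
- An all-zero audio window is valid and yields a finite, frame-constant
  stack (decibel floor).  Recordings shorter than one window yield an
  empty window list, not an error.
- `scale_transform` breaks score ties by stable input order, so reference
  counts are honored exactly even when all scores coincide.
- Spearman correlation uses average ranks for ties and requires n ≥ 3 with
  variation in both vectors.
- eNasalance is exactly invariant to a common gain on both channels;
  mfccNasalance is only approximately so (the classifier sees loudness
  through the energy coefficient), checked empirically on synthetic data
  with a 0.1 tolerance on the speaker score for a 6 dB attenuation.
- Vowel nasalization at exactly 60 and 90 ms falls in the 50% class; the
  window threshold is inclusive (exactly 75 ms is nasal).

## Known limitations

Full-grid training (126 × 5 models) is supported but slow on CPU — the
grid exists for completeness and for small-scale kernel-shape studies; the
reduced grid is the tested path.  The scale transform requires a reference
distribution and therefore external perceptual ratings.  The TextGrid
reader handles long-format interval tiers only.  Perceptual adjudication
implements the adjudicator-wins rule; other consensus schemes must be
resolved upstream.
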