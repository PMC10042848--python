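# Methods

This note documents the models, parameter choices and numerical
conventions behind `easim`, and what the synthetic components do and do
not establish about real listeners.

## Place map and frequency allocations

The Greenwood function `F(x) = A(10^{ax} − k)` is used with the
standard human parameterization (A = 165.4 Hz, a = 0.06 /mm, k = 0.88)
on a 35-mm cochlear duct, place measured from the apex. This
parameterization is validated internally by a printed-number anchor:
the extreme contacts of the default array (16 electrodes over 20 mm,
most apical contact 24 mm from the base) must round to CFs of 610 and
11,837 Hz, which they do (610.47 / 11,836.62 Hz). Constructors accept
the insertion-depth convention (mm from the base) and convert.

Analysis-band edges are the CFs of `n+1` linearly spaced places
spanning the place image of the input range, so bands partition the
input range exactly in place coordinates (equal place widths, no gaps
or overlaps). Carriers are the CFs of `n` linearly spaced places
spanning the place image of the output range, endpoints included; with
16 channels and the electrode-matched output range the carriers
therefore fall exactly on the 16 electrode CFs. (A per-band
*midpoint* carrier rule was considered and rejected: it cannot
reproduce the anchored 610/11,837-Hz extremes.)

No spiral-ganglion correction is applied; the plain organ-of-Corti
Greenwood map reproduces the anchored endpoints, so a second map would
be unconstrained freedom.

## Sine-wave vocoder

Chain: first-order Butterworth high-pass pre-emphasis at 1200 Hz
(6 dB/oct); per-channel Butterworth band-pass analysis filters of
design order 4 per skirt (`scipy.signal.butter(4, (lo, hi))`, the
MATLAB `butter(4,[w1 w2])` convention, 24 dB/oct skirts); half-wave
rectification and 4th-order 160-Hz low-pass envelope extraction;
amplitude modulation of one sine carrier per channel; summation.

* Sample rate: 44.1 kHz by default (must exceed twice the 11,837-Hz
  top carrier; the audio-heavy tests run at 32 kHz, which still leaves
  a 4-kHz margin above the top carrier).
* Filtering is causal (forward-only) by default, mirroring real-time
  processing; every stage accepts a zero-phase option for analysis.
* Carrier phases default to zero (deterministic); a seeded random
  phase policy is available.
* Level restoration: the vocoded output is rescaled so its long-term
  RMS equals the pre-vocoder ear input's RMS, with a floor — if the
  raw vocoded output is more than 60 dB below the input (i.e. the
  input carried essentially no in-band energy), no gain is applied, so
  out-of-band inputs stay silent instead of being amplified into noise.
  The experiment's fixed 65 dBA presentation level is represented by a
  configurable digital reference RMS (0.05 full scale); only relative
  levels matter anywhere in the pipeline.
* The envelope cutoff (160 Hz) intentionally exceeds half the lowest
  analysis bandwidth in some conditions; no constraint is imposed.

## Residual acoustic hearing

Residual hearing is a steep band-pass only — no audiogram shaping,
recruitment or compression — hence a best-case acoustic path. The
240 dB/oct slope is realized as a 40th-order Butterworth high-pass
cascaded with a 40th-order low-pass, both designed directly in
second-order sections (a direct-form realization of this order is
numerically unusable; every biquad's poles are checked inside the unit
circle). Measured steady-state rejection one octave beyond each cutoff
exceeds 200 dB in float64, far beyond the 60-dB acceptance floor.
Electric + acoustic summation within the BiEAS ear is plain addition;
each path carries its own level reference and no EAS weighting is
applied.

**Path-disjointness metric.** For the matched allocation the acoustic
(≤ 600 Hz) and electric (≥ 610 Hz) designed bands are adjacent, so any
instantaneous PSD-overlap metric is dominated by the ~20-Hz junction
where the two transition skirts touch and cannot fall below roughly
−25 dB for any realizable filter pair. Overlap is therefore defined as
the peak magnitude of the normalized cross-correlation between the two
paths' outputs for a common input — zero exactly when the output
spectra are disjoint — and measures ≤ −55 dB here (bound tested:
−40 dB). This captures the quantity that matters for electric-acoustic
fusion: how much common signal component the two modes share.

## Binaural rendering

The default renderer is a parametric spherical head (radius 8.75 cm,
c = 343 m/s): Woodworth ITD `a(θ + sin θ)/c` applied to the
contralateral ear as an exact fractional delay (frequency-domain phase
shift after zero-padding), and a one-pole/one-zero head-shadow filter
per ear, `H(s) = (αs + β)/(s + β)` with `β = 2c/a` and
`α = 1 + cos(θ_ear)` (flat at broadside, −6 dB/oct shadow at the far
ear, +6 dB high-shelf at the near ear). The model is exactly mirror
symmetric and diotic at 0°; ITD and broadband ILD grow monotonically
with |azimuth|. Measured HRIRs can replace it (`HRIRRenderer`, stereo
WAV per azimuth) for exact replication of a particular HRTF set.

TMR is defined and applied at the source, pre-spatialization, on
long-term RMS, with the two maskers first equalized to a common RMS;
per-ear effective TMR (head shadow) is emergent. Silent maskers pass
through as the target-alone limit rather than raising the
silent-masker error reserved for explicit TMR scaling.

## Synthetic corpus

The corpus emulates a closed-set matrix test: 5 categories × 10
monosyllabic words × 3 male talkers (150 tokens), target-talker mean
F0 106 Hz, maskers 97 and 128 Hz. Target sentences always start with
the fixed Name cue token; within every category a trial's three
sentences use three distinct words.

Tokens are source-filter synthesis: a harmonic source at the talker F0
(per-token mean drawn ±2% around nominal, linear glide ±2% across the
token, random harmonic phases), shaped by a word-identity spectral
envelope (sum of four formant resonances drawn once per word from
speech-plausible ranges, broadband floor, gentle high-frequency tilt,
energy out to 8 kHz) and a word-identity coarse energy contour (five
control points, monotone-cubic interpolated) with raised-cosine
onset/offset. Word identity (formants + contour) depends only on
(category, index), so the "same word" is recognizable across talkers
and corpus seeds; realization detail (F0, duration, phases) is
deterministic in (seed, category, index, talker). Durations are
uniform on 0.35–0.50 s — the real corpus' duration statistics are not
published, so this is a convention, as is every other synthesis
parameter not fixed by the stated talker F0s.

Masker sentences are duration-normalized to the target by WSOLA
time-scale modification (50-ms Hann frames, 50% synthesis overlap,
±8 ms similarity search), which changes duration without affecting
pitch; the F0-invariance is tested (< 2% shift). Stretch ratios
outside [0.5, 2] are rejected as non-physical for this corpus.

F0 estimation (used for corpus validation) is frame-wise normalized
autocorrelation (40-ms frames, parabolic peak interpolation, voicing
threshold 0.3, median over voiced frames).

What the corpus is not: intelligible English speech. Consequences:
masking here is energetic plus target/masker confusion within the
closed set; linguistic informational masking is absent. Passing tests
establish the signal chain and procedure, not human-level percepts.

## Simulated listeners

`PsychometricOracle` is an audio-free logistic test double for the
both-keywords-correct event, `P = g + (1 − g − lapse)·σ(s(TMR − T))`
with guess floor g = 0.01 (10 alternatives per keyword, two keywords).
It validates the staircase against a known ground truth.

`TemplateObserver` listens: a 30-channel ERB-spaced band-pass front
end (gammatone-like selectivity, one ERB about each center, 80 Hz–8
kHz), half-wave rectification, 50-Hz envelope smoothing, 200-Hz frame
rate, log compression. Templates are the front-end images of each
candidate Number/Color token of the target talker rendered at 0° and
processed through the observer's own listening condition. Decision:
per keyword, the template with the highest normalized
cross-correlation against the corresponding segment of the processed
mixture, maximized over time alignments (segment extracted with 40 ms
of context), summed across the two ears. The observer knows the
target's word timing — defensible for a cued closed-set task where the
fixed cue word anchors attention, and deliberately generous. With the
target alone it is errorless in every condition; its psychometric
function is monotone in TMR but several dB less sensitive than human
listeners, and no claim is made that its SRTs or SRM pattern
reproduce the human group means.

## Adaptive procedure

1-up/1-down staircase on TMR: start +10 dB (above the entire published
SRT range), 4-dB steps until the second reversal, 2-dB steps after,
SRT = mean TMR of the last six reversals, converging on the 50% point
of the both-keywords psychometric function. Reversal levels are the
track extremes (the level presented on the trial whose response
reversed the step direction).

Termination defaults to 10 total reversals (trial cap 60, tracks that
hit the cap are flagged and their SRT uses the reversals available
with a warning). The choice of 10 rather than the minimal 8 leaves two
settling reversals between the step-size change and the averaged six:
with only 8, the averaged window still carries the descent from the
supra-threshold start and the track's converged percent-correct sits
≈ 2.3 points above the 50% target; with 10 it is statistically
indistinguishable from 50% (verified against logistic oracles across
seeds, estimator bias < 0.1 dB at 1,000 tracks).

Experiments randomize the condition × masker-configuration cells
within each block with a seeded generator and average SRTs across
blocks; results are tidy tables (one row per track).

## Analysis

SRM = SRT(co-located) − SRT(separated); positive SRM means separation
helps. `summarize` aggregates per-cell means/SDs and appends SRM;
missing cells yield explicit NaN markers, never silent drops. The
published group-mean SRT table of the simulated study is shipped as
reference input; reconstructing the published per-condition SRM values
from it agrees to ±0.01 dB (one condition prints −0.38 where the
table means give −0.39, a rounding artifact of the published means).
Inferential statistics (RM ANOVA, post hocs) are out of scope; the
tidy CSV exports feed any external stats tool.

## Problem sizes and determinism

The audio-heavy validation (template-observer psychometric points,
clean-identification checks) runs at 32 kHz with tens of trials per
point; staircase validation uses 1,000 audio-free oracle tracks; the
corpus fidelity check synthesizes the full 150-token inventory at
44.1 kHz. All randomness flows through `numpy` `SeedSequence`
namespacing, so every pipeline stage is bit-reproducible for a fixed
seed, which the determinism tests assert end to end.

## Known limitations

* No hearing-loss, recruitment or channel-interaction modeling (the
  steep-filter, no-overlap construction is itself a best case).
* The parametric head model approximates measured HRTFs; ILD spectra
  are first-order caricatures (supply HRIRs for fidelity).
* The synthetic corpus and observer support *relative* and
  *qualitative* conclusions about the processing chain; absolute SRTs
  and the size of condition effects do not transfer to humans.
* The observer's segment-level timing knowledge overestimates a real
  listener's segregation ability at very low TMR.
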