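# Methods

This note documents the models, parameters and numerical choices behind
`strokeprosody`, and what the synthetic cohort does and does not emulate.

## Epoch detection and instantaneous F0

Zero-frequency filtering exploits the fact that the glottal closure imposes
an impulse-like discontinuity on the speech signal whose effect survives a
resonator centred at 0 Hz, while vocal-tract resonances do not. The
implementation:

1. first difference of the input (removes recording-chain bias),
2. two cascaded double-pole resonators at z = 1,
3. after each resonator stage, trend removal by subtracting a centred moving
   average (window 10 ms, edges reflected), applied three times in
   succession per stage. A single pass leaves a dominant slow residual
   because the resonator amplifies low frequencies roughly as 1/omega^2; the
   iterated subtraction is the standard cure and affects nothing above the
   ~100 Hz transition band.

Epochs are the negative-to-positive zero crossings, linearly interpolated to
sub-sample precision (this removes most of the 16 kHz grid quantization from
the per-cycle F0 estimates). The strength of excitation is the slope of the
filtered signal at the crossing. Defaults: trend window 0.010 s, strength
gate 5% of the mean strength (computed once, not iteratively), F0 gate
[50, 300] Hz. Contours are never resampled; all statistics operate on raw
per-cycle values.

The fixed 10 ms trend window is appropriate for roughly 100–250 Hz voices
(one to two pitch periods). Below ~90 Hz the window undersamples the period
and epoch doubling appears; a pitch-adaptive window would fix this but is
deliberately not used, for determinism and because the analysis targets the
adult 100–220 Hz range.

## Vocal tract length normalization

Formants are per-frame peaks of the order-18 linear-prediction spectrum
(25 ms frames, 10 ms shift, pre-emphasis 0.97, frames restricted to voiced
stretches judged by epoch density >= 2 per frame; the three lowest peaks
above 90 Hz are taken as F1–F3, and the track is median-smoothed over 5
frames to suppress single-frame peak-picking outliers). Formant dispersion
is the mean of F3 − F1 over frames; the per-gender reference (mu, sigma,
sample sd with n − 1) comes from healthy speakers only, and

    alpha = 1 + (1/20) (D_f − mu) / sigma.

No clipping is applied for extreme dispersions; alpha stays in roughly
[0.85, 1.15] for |z| <= 3. The spectral warp is the common piecewise-linear
VTLN map, f -> f/alpha below a knee at 0.85 x Nyquist, continued linearly to
preserve the endpoint, with linear interpolation between bins; alpha = 1 is
exactly the identity.

Accuracy: at male-range F0 the dispersion estimate lands within ~100 Hz of
truth at 20 dB SNR. At female-range F0 (~205 Hz) the LP peaks can only
sample the envelope at harmonic spacing, which biases F3 low by up to
~150 Hz. This bias is common to all speakers of a gender, so it cancels in
the standardized quantity (D_f − mu)/sigma that alpha actually uses; the
absolute-dispersion tolerance is correspondingly looser for female-range
voices in the tests.

## MFCC front end and transition features

Per frame (20 ms / 10 ms, Hamming): pre-emphasis 0.97, 512-point power
spectrum, VTLN warp, 26 triangular mel filters on [0, 8 kHz], log, optional
RASTA band-pass of each log-mel trajectory (numerator 0.1·[2,1,0,−1,−2],
pole 0.98, first four frames used only to seed the filter state so the slow
startup transient is suppressed), orthonormal DCT, coefficients 1–13 (c0
excluded). Frame energies are measured on the raw waveform frames; frames
below 6% of the maximum frame energy are discarded as silence before any
cepstral-difference computation (the 6%-of-total-energy reading is not
usable: no single frame of a long utterance can carry 6% of a sum over
hundreds of frames).

The cepstral difference with K = 2 is computed for interior frames and
normalized by its utterance maximum (peak 1; the maximum is retained as
`scale`). Segmentation thresholds the normalized curve at 0.5 — exactly the
"50% of the utterance maximum" rule — and discards runs shorter than 2
frames (no minimum is published; one-frame regions are almost always noise).
Edge frames without a value join the adjacent steady region.

The relative-area features are evaluated on the raw-scale curve with the
absolute threshold 0.5, matching the printed definition of RTA and the
magnitude of published group means (order 10, impossible on a peak-1 curve).
`rta_mode="excess"` subtracts the threshold before summing, an alternative
reading of the accompanying prose; the default is the literal formula.
RTD, TR and RSSD = 1 − RTD are scale-free. Group summaries are unweighted
means over utterances (S0 and S1 pooled); MSSTR defaults to the printed
definition MSSD/MTD (ratio of means), with a mean-of-ratios variant
available.

## F0 statistics

Per-utterance summaries use sd with n − 1, biased-moment skewness, and plain
(not excess) kurtosis. Group-level F0 statistics pool per-cycle values
within a (vowel, gender, group) cell by default (`f0_pooling="speakers"`
switches to per-utterance medians). Pooled z-scoring standardizes both
groups of a gender together. The one-way ANOVA is the closed-form
fixed-effects F with p from the F distribution; because F is invariant under
affine maps, raw and z-normalized data give identical p-values, which the
pipeline reports as two columns as a consistency check. The 2-D embedding of
per-speaker (mean, median, sd) vectors uses standardized features and
seeded t-SNE with perplexity capped at (n − 1)/3.

## Synthetic cohort

Source-filter synthesis with fully known ground truth:

- **Source:** impulse train, one pulse per glottal cycle, gaps
  `round(fs/f0)` samples (the realized F0 is grid-quantized, e.g.
  16000/120 = 133.33 Hz), negative polarity (the glottal flow derivative at
  closure is a negative spike — with positive pulses the ZFF crossing
  convention inverts). A zero-phase −12 dB/oct glottal tilt (real pole pair
  at 800 Hz, applied forward–backward so pulse timing is preserved) gives
  the source a realistic fundamental-dominant spectrum; without it, white
  recording noise near 100–150 Hz overwhelms epoch detection above ~180 Hz
  at 20 dB SNR because the raw impulse train carries almost no energy at the
  fundamental.
- **Filter:** cascade of three 2nd-order resonators at Peterson–Barney-style
  vowel formants (female targets ×1.17), bandwidths (80, 90, 120) Hz.
- **Sentences:** three steady vowel segments (0.35 s) joined by linear
  formant/F0 interpolation windows (60 ms control); the interpolation
  windows are the ground-truth transition regions. The cascade runs
  blockwise (2 ms) with carried filter state, and segment loudness is
  equalized (a speaker holds roughly constant effort; otherwise the energy
  gate can mistake a weakly resonant vowel for silence).
- **Noise:** white Gaussian at 20 dB SNR over the voiced portion, plus 50 ms
  of leading/trailing low-level silence per utterance to exercise the
  silence gate.

Cohort structure (defaults): 25 speakers per (group, gender) cell, five
vowels (0.8 s) and two sentences each. Speaker baseline F0 is lognormal
around the gender base (male 130 Hz, female 205 Hz; inter-speaker sd 7%)
drawn by quantile-stratified sampling so that small cohorts cover the
speaker range representatively and group contrasts reflect the configured
effects rather than speaker-sampling luck. Vocal-tract scale varies by
±3% sd per speaker (this is what VTLN must undo). Group effects:

| effect | default | emulates |
| --- | --- | --- |
| male stroke F0 shift | ×1.05 | raised male median F0 |
| female stroke F0 shift | ×0.85 | lowered female median F0 |
| stroke transition scale | ×0.6 | shorter transition regions |
| stroke F0 variability scale | ×1.2 | wider F0 spread / IQR |
| articulatory instability | 0.5% control, ×4 stroke | formant wander (tremor band, ≤8 Hz) |
| source HNR | 25 dB control, 15 dB stroke | breathy dysarthric phonation |

The instability and breathiness effects are what raise the stroke group's
relative transition area: transition-duration compression alone *lowers*
measured RTA slightly (a transition's cepstral-difference mass is nearly
invariant to its duration), so the higher published stroke MTA must come
from steeper spectral dynamics, which these two effects supply. The
recovered MTA contrast is a direction (a few percent), not the several-fold
magnitude seen in clinical data — the generator encodes the sign structure
of the group differences, not dysarthric articulation itself.

What the generator does **not** emulate: real phonotactics and coarticulation,
aperiodic/voiceless segments, room reverberation, non-white hospital noise,
pathological voice breaks, and severity gradations. Passing tests therefore
show that the pipeline recovers known signal structure and the configured
group contrasts under realistic noise — not that it reproduces clinical
effect sizes.

## Problem sizes and runtime

Defaults are desk-scale: 0.8 s vowels, ~1.25 s sentences, 700 utterances in
the default cohort; the full double pipeline runs in ~15 s on one CPU, the
complete test suite in under a minute. Longer sustained vowels (≥1.5 s)
improve formant-dispersion estimates and are used where that accuracy is
asserted.

## Known limitations

- Epoch recovery degrades below ~90 Hz (fixed 10 ms trend window) and the
  female-range formant bias noted above is inherent to LP-peak picking at
  wide harmonic spacing.
- The ANOVA treats per-cycle F0 values as independent observations (the
  published tables imply per-cycle pooling); a mixed-effects model with
  speaker random effects would be the statistically stricter choice and is
  out of scope.
- RTA magnitudes depend on the RASTA flag and the mel floor; comparisons are
  meaningful within a configuration, not across configurations.
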