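# strokeprosody

Prosodic analysis of stroke-affected (dysarthric) speech. The package
implements two complementary acoustic analyses used to contrast speech from
stroke patients with that of healthy controls, plus a synthetic-speech cohort
generator with fully known ground truth so every stage is testable without
clinical recordings.

**Who it is for:** speech scientists and clinical-speech researchers who want
a reproducible, scriptable pipeline for epoch-based F0 statistics and
transition/steady-state duration features on sustained vowels and short read
sentences.

## The methods

**Epoch-based instantaneous F0.** Glottal closure instants (epochs) are
detected by zero-frequency filtering (ZFF): the speech signal is passed
through a cascade of two resonators at 0 Hz and the local mean (10 ms window)
is removed after each stage; negative-to-positive zero crossings of the
result are the epochs, and the slope at each crossing is the strength of
excitation. Epochs weaker than 5% of the mean strength are discarded. The
instantaneous F0 contour is the reciprocal of the interval between successive
epochs, gated to [50, 300] Hz. Group statistics compare pooled per-cycle F0
values per (vowel, gender, group) cell via the relative deviation

    zeta = (F0_stroke - F0_control) / F0_control

together with pooled z-scoring, IQR, and one-way ANOVA (raw and z-normalized
p-values agree exactly because the F statistic is affine-invariant).

**Transition / steady-state durations.** Each sentence is summarized by 13
MFCCs per 20 ms frame (10 ms shift, energy coefficient excluded, optional
RASTA filtering), after a per-speaker vocal-tract-length normalization
(VTLN): the warp factor

    alpha_i = 1 + (1/20) * (D_f_i - mu) / sigma,    D_f = mean(F3 - F1)

uses formant dispersion from the sustained /A/ vowels, referenced to healthy
speakers of the same gender. The cepstral difference

    dC(l) = sum_{m=1..13} sum_{k=1..2} k |C(m, l+k) - C(m, l-k)|

marks spectral transitions: frame runs above 50% of the utterance maximum are
transition regions, the rest steady-state. Five features follow per
utterance — relative transition duration (RTD), relative transition area
(RTA), transition rate (TR), and the steady-state counterparts RSSD and
RSSA — and are averaged per (group, gender) cell into MTD, MTA, MTR, MSSD and
MSSTR = MSSD/MTD.

**Synthetic cohort.** `make_cohort` builds a two-group, two-gender cohort
(default 25 speakers per cell; five vowels and two three-segment "sentences"
each) from impulse-train source-filter synthesis with known epochs, formants
and transition windows. Group effects mirror the clinical contrast
structure: male stroke F0 raised (+5%), female lowered (−15%), stroke
transition windows compressed (×0.6), and stroke phonation/articulation less
stable (wider F0 spread, formant wander, breathier source).

## Worked example

```python
import strokeprosody as sp

cohort = sp.make_cohort(sp.CohortSpec(n_per_cell=4, seed=0))
pairs = sp.pairs_from_cohort(cohort)

f0res = sp.run_f0_analysis(pairs)
print(f0res.zeta.round(3).to_string(index=False))

dres = sp.run_duration_analysis(pairs)
print(dres.summary.round(3).to_string(index=False))
```

prints

```
vowel gender  zeta_median  zeta_mean  zeta_sd
    A   male        0.039      0.045    0.321
    A female       -0.067     -0.038   -0.499
    E   male        0.054      0.053    0.098
    E female       -0.103     -0.102   -0.461
    I   male        0.052      0.054    0.052
    I female       -0.118     -0.115   -0.359
    O   male        0.059      0.052    0.043
    O female       -0.113     -0.085   -0.408
    U   male        0.048      0.047    0.347
    U female       -0.135     -0.125   -0.301

  group gender   mtd    mta   mtr  mssd  msstr  n_utterances
control female 0.099 12.503 2.013 0.901  9.151             8
control   male 0.100 12.655 2.015 0.900  9.033             8
 stroke female 0.091 14.249 2.448 0.909  9.963             8
 stroke   male 0.089 14.300 2.539 0.911 10.184             8
```

Reading the output: `zeta_median` is positive for every vowel in the male
cells (stroke males phonate ~5% higher than controls) and negative in the
female cells (stroke females ~7–14% lower) — the configured cohort effects,
recovered from the audio alone. In the duration summary the stroke rows show
lower MTD (shorter transitions), higher MTA (steeper spectral change) and
higher MSSTR (relatively longer steady states) than the matching control
rows.

A command-line interface mirrors the library:

```sh
strokeprosody synth --spec cohort.json --out cohort/
strokeprosody f0 run cohort/manifest.csv --out f0_results/
strokeprosody duration run cohort/manifest.csv --out duration_results/
strokeprosody f0 extract some_vowel.wav --out contour.csv
```

Clinical recordings are analysed the same way: write a CSV manifest with
columns `path, speaker_id, group, gender, age, utterance_type` (vowels
`A E I O U`, sentences `S0 S1 ...`, optional `take` and `complete` columns)
pointing at mono WAV files at 16 kHz or above; 44.1 kHz input is resampled.

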