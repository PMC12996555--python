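"""Synthetic voiced-speech generator with fully known ground truth.

Source-filter synthesis: an impulse train with one pulse per glottal cycle
(the pulse instants are the ground-truth epochs) excites a cascade of three
second-order all-pole resonators at the vowel formants.  Sequences of vowel
segments joined by linear formant/F0 interpolation windows emulate short read
sentences; the interpolation windows are the ground-truth transition regions.

``make_cohort`` builds a two-group (stroke / control), two-gender cohort with
configurable gender-specific F0 shifts, F0-variability scaling and
transition-duration compression, mirroring the contrast structure of a
clinical stroke-speech corpus: male stroke speakers raised in F0, female
lowered, stroke transitions compressed and stroke phonation less stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, lfilter
from scipy.stats import norm

from .datatypes import ANALYSIS_RATE, GroundTruth, Waveform

# Reference (adult male) formant targets in Hz and shared bandwidths.
VOWEL_FORMANTS = {
    "A": (730.0, 1090.0, 2440.0),
    "E": (530.0, 1840.0, 2480.0),
    "I": (390.0, 1990.0, 2550.0),
    "O": (570.0, 840.0, 2410.0),
    "U": (440.0, 1020.0, 2240.0),
}
DEFAULT_BANDWIDTHS = (80.0, 90.0, 120.0)
GLOTTAL_TILT_HZ = 800.0  # cutoff of the -12 dB/oct source spectral tilt
# Intrinsic vowel pitch: high vowels sit slightly above the speaker baseline.
VOWEL_F0_FACTOR = {"A": 1.00, "E": 1.02, "I": 1.05, "O": 1.00, "U": 1.04}
FEMALE_FORMANT_SCALE = 1.17
SENTENCE_SEGMENTS = {"S0": ("A", "I", "U"), "S1": ("E", "O", "A")}
VOWELS = tuple(VOWEL_FORMANTS)
SENTENCES = tuple(SENTENCE_SEGMENTS)


@dataclass
class VowelSpec:
    """Specification of one sustained-vowel utterance.

    ``f0`` is either a scalar (Hz) or a trajectory sampled uniformly over the
    duration; ``jitter`` is the fractional cycle-to-cycle period perturbation.
    """

    f0: float | np.ndarray
    formants: tuple
    duration: float
    bandwidths: tuple = DEFAULT_BANDWIDTHS
    sample_rate: int = ANALYSIS_RATE
    snr_db: float = math.inf
    jitter: float = 0.0
    formant_wander: float = 0.0  # fractional sd of slow (2-8 Hz) formant modulation
    hnr_db: float = math.inf     # source harmonics-to-noise ratio (aspiration noise)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        f0 = np.atleast_1d(np.asarray(self.f0, dtype=float))
        nyquist = self.sample_rate / 2.0
        if np.any(f0 <= 0) or np.any(f0 >= nyquist):
            raise ValueError(f"f0 must lie in (0, {nyquist}) Hz")
        f1, f2, f3 = self.formants
        if not (0 < f1 < f2 < f3):
            raise ValueError(f"formants must satisfy 0 < F1 < F2 < F3, got {self.formants}")
        if f3 >= nyquist:
            raise ValueError(f"formants must lie below the Nyquist rate {nyquist} Hz")
        if self.jitter < 0:
            raise ValueError(f"jitter must be >= 0, got {self.jitter}")
        if self.formant_wander < 0:
            raise ValueError(f"formant_wander must be >= 0, got {self.formant_wander}")


@dataclass
class SequenceSpec:
    """Vowel segments joined by linear formant/F0 interpolation windows."""

    segments: list  # of VowelSpec
    transition_durations: list  # seconds, len = len(segments) - 1

    def __post_init__(self) -> None:
        if len(self.transition_durations) != len(self.segments) - 1:
            raise ValueError(
                "transition_durations must have one entry fewer than segments "
                f"({len(self.transition_durations)} vs {len(self.segments)})"
            )
        for i, tr in enumerate(self.transition_durations):
            if tr <= 0:
                raise ValueError(f"transition_durations[{i}] must be > 0")
            if tr >= self.segments[i].duration or tr >= self.segments[i + 1].duration:
                raise ValueError(
                    f"transition_durations[{i}]={tr} must be shorter than both "
                    "flanking segment durations"
                )
        rates = {s.sample_rate for s in self.segments}
        if len(rates) != 1:
            raise ValueError("all segments must share one sample_rate")

    @property
    def sample_rate(self) -> int:
        return self.segments[0].sample_rate


@dataclass
class CohortSpec:
    """Two-group, two-gender synthetic cohort.

    Group effects: ``stroke_f0_shift`` multiplies the stroke speakers' F0
    baseline per gender (> 1 male, < 1 female by default);
    ``stroke_transition_scale`` (< 1) compresses stroke transition windows;
    ``stroke_f0_sd_scale`` (> 1) widens both the stroke inter-speaker F0
    spread and the within-utterance instability (drift and jitter);
    ``stroke_instability_scale`` widens the stroke formant wander and
    ``stroke_hnr_db`` makes the stroke source breathier — the articulatory
    and phonatory instability of moderate dysarthria.
    """

    n_per_cell: int = 25
    gender_f0_base: dict = field(default_factory=lambda: {"male": 130.0, "female": 205.0})
    stroke_f0_shift: dict = field(default_factory=lambda: {"male": 1.05, "female": 0.85})
    stroke_transition_scale: float = 0.6
    stroke_f0_sd_scale: float = 1.2
    seed: int = 0
    vowel_duration: float = 0.8
    segment_duration: float = 0.35
    transition_duration: float = 0.06
    snr_db: float = 20.0
    sample_rate: int = ANALYSIS_RATE
    speaker_f0_sd: float = 0.07        # lognormal sd of speaker baseline F0
    formant_scale_sd: float = 0.03     # sd of per-speaker vocal-tract scale
    contour_drift: float = 0.02        # fractional slow F0 drift within utterance
    jitter: float = 0.005              # cycle-to-cycle period perturbation
    articulatory_instability: float = 0.005  # fractional formant wander (tremor band)
    stroke_instability_scale: float = 4.0    # multiplier on wander for the stroke group
    hnr_db: float = 25.0                     # source harmonics-to-noise ratio, control
    stroke_hnr_db: float = 15.0              # breathier source for the stroke group
    silence_pad_s: float = 0.05        # leading/trailing silence per utterance

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        for name in ("stroke_transition_scale", "stroke_f0_sd_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for g, v in self.stroke_f0_shift.items():
            if v <= 0:
                raise ValueError(f"stroke_f0_shift[{g}] must be > 0")


def _f0_at(f0, duration: float, t: np.ndarray | float):
    """Evaluate a scalar-or-sampled F0 trajectory at time ``t``."""
    arr = np.atleast_1d(np.asarray(f0, dtype=float))
    if arr.size == 1:
        return np.full_like(np.atleast_1d(t), arr[0]) if np.ndim(t) else float(arr[0])
    grid = np.linspace(0.0, duration, arr.size)
    return np.interp(t, grid, arr)


def generate_pulse_train(
    f0,
    duration: float,
    sample_rate: int = ANALYSIS_RATE,
    jitter: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Waveform, GroundTruth]:
    """Impulse excitation with one unit pulse per glottal cycle.

    Pulse gaps are ``round(fs / f0)`` samples (the realized F0 is therefore
    quantized to the sample grid), optionally perturbed by a fractional
    Gaussian jitter per cycle.  The pulse instants are returned as
    ground-truth epoch times together with the realized per-cycle F0.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    f0_arr = np.atleast_1d(np.asarray(f0, dtype=float))
    if np.any(f0_arr <= 0):
        raise ValueError("f0 must be > 0")
    if np.any(f0_arr >= sample_rate / 2):
        raise ValueError(f"f0 must be below the Nyquist rate {sample_rate / 2} Hz")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_total = int(round(duration * sample_rate))
    pulses = []
    gaps = []
    n = 0
    while n < n_total:
        pulses.append(n)
        f_here = float(_f0_at(f0, duration, n / sample_rate))
        period = sample_rate / f_here
        if jitter > 0:
            period *= 1.0 + jitter * rng.standard_normal()
        gap = max(2, int(round(period)))
        gaps.append(gap)
        n += gap
    # negative polarity: the glottal flow derivative at closure is a negative
    # spike, which is what makes the ZFF output rise through zero at the epoch
    x = np.zeros(n_total)
    x[np.asarray(pulses)] = -1.0
    pulses = np.asarray(pulses, dtype=float)
    realized = sample_rate / np.asarray(gaps[: len(pulses) - 1], dtype=float)
    gt = GroundTruth(
        epoch_times=pulses / sample_rate,
        segment_boundaries=[(0.0, duration, "steady")],
        f0_realized=realized,
    )
    return Waveform(x, sample_rate, source_id="pulse_train"), gt


def _glottal_tilt(x: np.ndarray, fs: int, fc: float = GLOTTAL_TILT_HZ) -> np.ndarray:
    """Zero-phase -12 dB/oct low-pass emulating the glottal flow spectrum.

    Real glottal flow falls off ~-12 dB/oct, which concentrates energy at the
    fundamental; a raw impulse train has an unrealistically flat source
    spectrum and starves the low-frequency band that zero-frequency filtering
    relies on.  The filter is applied forward-backward so the excitation
    energy stays centred on the pulse instants (the ground-truth epochs).
    """
    r = math.exp(-2.0 * math.pi * fc / fs)
    return filtfilt([1.0 - r], [1.0, -r], x)


def _aspiration(exc: np.ndarray, hnr_db: float, rng: np.random.Generator) -> np.ndarray:
    """Add source aspiration noise at the given harmonics-to-noise ratio.

    Breathy/hoarse phonation mixes turbulence noise into the glottal source;
    the noise is added before the formant cascade so it is vocal-tract shaped
    like real aspiration.
    """
    if math.isinf(hnr_db):
        return exc
    p = float(np.mean(exc**2))
    if p == 0:
        return exc
    sd = math.sqrt(p / (10.0 ** (hnr_db / 10.0)))
    return exc + sd * rng.standard_normal(exc.size)


def _resonator_coeffs(f: float, bw: float, fs: int):
    r = math.exp(-math.pi * bw / fs)
    a = np.array([1.0, -2.0 * r * math.cos(2.0 * math.pi * f / fs), r * r])
    # unit gain at the resonance frequency
    b = np.array([(1.0 - r) * math.sqrt(1.0 - 2.0 * r * math.cos(4.0 * math.pi * f / fs) + r * r)])
    return b, a


def apply_formant_filter(
    excitation: Waveform,
    formants,
    bandwidths=DEFAULT_BANDWIDTHS,
) -> Waveform:
    """Shape an excitation with a cascade of all-pole formant resonators."""
    f1, f2, f3 = formants
    if not (0 < f1 < f2 < f3):
        raise ValueError(f"formants must satisfy 0 < F1 < F2 < F3, got {tuple(formants)}")
    if f3 >= excitation.sample_rate / 2:
        raise ValueError(
            f"formants must lie below the Nyquist rate {excitation.sample_rate / 2} Hz"
        )
    y = excitation.samples
    for f, bw in zip(formants, bandwidths):
        b, a = _resonator_coeffs(f, bw, excitation.sample_rate)
        y = lfilter(b, a, y)
    return Waveform(y, excitation.sample_rate, source_id=excitation.source_id)


def _wander(total_s: float, times: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slow multiplicative formant modulation (tremor band, up to ~8 Hz).

    Gaussian knots at 16 Hz linearly interpolated; returns a factor per
    requested time.  sd = 0 gives exactly 1.
    """
    if sd == 0:
        return np.ones_like(times)
    knots_t = np.linspace(0.0, total_s, max(2, int(total_s * 16) + 2))
    knots = rng.normal(0.0, sd, knots_t.size)
    return 1.0 + np.interp(times, knots_t, knots)


def _add_noise(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    if math.isinf(snr_db):
        return x
    p_signal = float(np.mean(x**2))
    if p_signal == 0:
        return x
    p_noise = p_signal / (10.0 ** (snr_db / 10.0))
    return x + math.sqrt(p_noise) * rng.standard_normal(x.size)


def synthesize_vowel(spec: VowelSpec, seed: int | None = None) -> tuple[Waveform, GroundTruth]:
    """Sustained vowel: pulse train -> formant cascade -> additive noise."""
    rng = np.random.default_rng(seed)
    exc, gt = generate_pulse_train(
        spec.f0, spec.duration, spec.sample_rate, jitter=spec.jitter, rng=rng
    )
    exc = Waveform(
        _aspiration(_glottal_tilt(exc.samples, spec.sample_rate), spec.hnr_db, rng),
        spec.sample_rate,
    )
    if spec.formant_wander > 0:
        fs = spec.sample_rate
        block = max(1, int(round(0.002 * fs)))
        n = exc.samples.size
        starts = np.arange(0, n, block)
        factors = _wander(spec.duration, (starts + 0.5 * block) / fs, spec.formant_wander, rng)
        y = np.empty(n)
        zis = [np.zeros(2) for _ in range(3)]
        base = np.asarray(spec.formants, dtype=float)
        for start, fac in zip(starts, factors):
            nb = min(block, n - start)
            seg = exc.samples[start : start + nb]
            for s_idx, (f, bw) in enumerate(zip(base * fac, spec.bandwidths)):
                b, a = _resonator_coeffs(float(f), float(bw), fs)
                seg, zis[s_idx] = lfilter(b, a, seg, zi=zis[s_idx])
            y[start : start + nb] = seg
    else:
        y = apply_formant_filter(exc, spec.formants, spec.bandwidths).samples
    y = _normalize_rms(y)
    y = _add_noise(y, spec.snr_db, rng)
    gt.true_dispersion = spec.formants[2] - spec.formants[0]
    return Waveform(y, spec.sample_rate, source_id="vowel"), gt


def _normalize_rms(x: np.ndarray, target: float = 0.1) -> np.ndarray:
    rms = math.sqrt(float(np.mean(x**2))) if x.size else 0.0
    return x if rms == 0 else x * (target / rms)


def synthesize_sequence(spec: SequenceSpec, seed: int | None = None) -> tuple[Waveform, GroundTruth]:
    """Vowel segments joined by linear formant/F0 interpolation windows.

    The excitation is a single pulse train following the piecewise F0
    trajectory; the resonator cascade is updated blockwise (2 ms steps inside
    transitions) with filter state carried across blocks, so the output is
    continuous.  Ground truth records the steady/transition tiling.
    """
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate
    segs = spec.segments
    n_seg = len(segs)

    # time plan: steady_0, trans_0, steady_1, ..., steady_{n-1}
    boundaries = []
    plan = []  # (n_samples, kind, index)
    t = 0.0
    for i, seg in enumerate(segs):
        n_samples = int(round(seg.duration * fs))
        plan.append((n_samples, "steady", i))
        boundaries.append((t, t + n_samples / fs, "steady"))
        t += n_samples / fs
        if i < n_seg - 1:
            n_tr = int(round(spec.transition_durations[i] * fs))
            plan.append((n_tr, "transition", i))
            boundaries.append((t, t + n_tr / fs, "transition"))
            t += n_tr / fs
    total = sum(n for n, _, _ in plan)
    duration = total / fs

    seg_f0 = [float(np.mean(np.atleast_1d(s.f0))) for s in segs]
    f0_of_t = np.empty(total)
    pos = 0
    for n_samples, kind, i in plan:
        if kind == "steady":
            f0_of_t[pos : pos + n_samples] = seg_f0[i]
        else:
            f0_of_t[pos : pos + n_samples] = np.linspace(
                seg_f0[i], seg_f0[i + 1], n_samples, endpoint=False
            )
        pos += n_samples

    jitter = max(s.jitter for s in segs)
    exc, gt = generate_pulse_train(f0_of_t, duration, fs, jitter=jitter, rng=rng)
    hnr = min(s.hnr_db for s in segs)
    exc = Waveform(_aspiration(_glottal_tilt(exc.samples, fs), hnr, rng), fs)

    # blockwise time-varying formant cascade with carried state
    y = np.empty(total)
    zis = [np.zeros(2) for _ in range(3)]
    block = max(1, int(round(0.002 * fs)))
    wander_sd = max(s.formant_wander for s in segs)
    n_blocks = total // block + 1
    block_factors = _wander(
        duration, (np.arange(n_blocks) + 0.5) * block / fs, wander_sd, rng
    )
    pos = 0
    for n_samples, kind, i in plan:
        chunks = []
        if kind == "steady":
            base = np.asarray(segs[i].formants, dtype=float)
            for off in range(0, n_samples, block):
                nb = min(block, n_samples - off)
                chunks.append((pos + off, nb, base, segs[i].bandwidths))
        else:
            f_from = np.asarray(segs[i].formants, dtype=float)
            f_to = np.asarray(segs[i + 1].formants, dtype=float)
            for off in range(0, n_samples, block):
                nb = min(block, n_samples - off)
                frac = (off + 0.5 * nb) / n_samples
                chunks.append((pos + off, nb, f_from + frac * (f_to - f_from), segs[i].bandwidths))
        pos += n_samples
        factors = [block_factors[start // block] for start, _, _, _ in chunks]
        for (start, nb, formants, bws), fac in zip(chunks, factors):
            seg_out = exc.samples[start : start + nb]
            for s_idx, (f, bw) in enumerate(zip(formants * fac, bws)):
                b, a = _resonator_coeffs(float(f), float(bw), fs)
                seg_out, zis[s_idx] = lfilter(b, a, seg_out, zi=zis[s_idx])
            y[start : start + nb] = seg_out

    # equalize segment loudness (a speaker holds roughly constant effort);
    # without this the energy gate can mistake a weakly resonant vowel for
    # silence.  Gain is constant over steadies, linear across transitions.
    anchors_t, anchors_g = [], []
    pos = 0
    for n_samples, kind, i in plan:
        if kind == "steady":
            rms = math.sqrt(float(np.mean(y[pos : pos + n_samples] ** 2)))
            anchors_t.extend([pos, pos + n_samples - 1])
            anchors_g.extend([1.0 / max(rms, 1e-12)] * 2)
        pos += n_samples
    y = y * np.interp(np.arange(total), anchors_t, anchors_g)

    y = _normalize_rms(y)
    snr = min(s.snr_db for s in segs)
    y = _add_noise(y, snr, rng)
    gt.segment_boundaries = boundaries
    gt.true_dispersion = float(np.mean([s.formants[2] - s.formants[0] for s in segs]))
    return Waveform(y, fs, source_id="sequence"), gt


@dataclass
class CohortUtterance:
    """One synthetic utterance with its manifest row and ground truth."""

    path: str
    speaker_id: str
    group: str
    gender: str
    age: int
    utterance_type: str
    take: int
    complete: bool
    waveform: Waveform
    ground_truth: GroundTruth


@dataclass
class Cohort:
    spec: CohortSpec
    utterances: list

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "path": u.path,
                "speaker_id": u.speaker_id,
                "group": u.group,
                "gender": u.gender,
                "age": u.age,
                "utterance_type": u.utterance_type,
                "take": u.take,
                "complete": u.complete,
            }
            for u in self.utterances
        ]
        return pd.DataFrame(rows)

    def write(self, outdir) -> str:
        """Write WAVs, manifest.csv and a JSON ground-truth sidecar per utterance."""
        import os

        os.makedirs(outdir, exist_ok=True)
        for u in self.utterances:
            wav_path = os.path.join(outdir, u.path)
            u.waveform.write(wav_path)
            sidecar = {
                "epoch_times": u.ground_truth.epoch_times.tolist(),
                "segment_boundaries": [list(b) for b in u.ground_truth.segment_boundaries],
                "true_dispersion": u.ground_truth.true_dispersion,
            }
            with open(wav_path.replace(".wav", ".json"), "w") as fh:
                json.dump(sidecar, fh)
        manifest_path = os.path.join(outdir, "manifest.csv")
        self.manifest().to_csv(manifest_path, index=False)
        return manifest_path


def _stratified_normal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quantile-stratified standard-normal draws, shuffled.

    Small cells then cover the speaker-variability range representatively, so
    group contrasts reflect the configured effects rather than sampling noise.
    """
    z = norm.ppf((np.arange(n) + 0.5) / n)
    return rng.permutation(z)


def _pad_silence(w: Waveform, gt: GroundTruth, pad_s: float, snr_db: float,
                 rng: np.random.Generator) -> tuple[Waveform, GroundTruth]:
    n_pad = int(round(pad_s * w.sample_rate))
    if n_pad == 0:
        return w, gt
    p_signal = float(np.mean(w.samples**2))
    noise_sd = math.sqrt(p_signal / (10.0 ** (snr_db / 10.0))) if math.isfinite(snr_db) else 0.0
    pad = noise_sd * rng.standard_normal(n_pad)
    samples = np.concatenate([pad, w.samples, noise_sd * rng.standard_normal(n_pad)])
    shift = n_pad / w.sample_rate
    boundaries = [(0.0, shift, "silence")]
    boundaries += [(a + shift, b + shift, lab) for a, b, lab in gt.segment_boundaries]
    boundaries.append((shift + w.duration, shift + w.duration + n_pad / w.sample_rate, "silence"))
    gt2 = GroundTruth(
        epoch_times=gt.epoch_times + shift,
        segment_boundaries=boundaries,
        true_dispersion=gt.true_dispersion,
        f0_realized=gt.f0_realized,
    )
    return Waveform(samples, w.sample_rate, source_id=w.source_id), gt2


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group cohort: five vowels + two sentences per speaker.

    Deterministic given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    utterances = []
    for group in ("stroke", "control"):
        for gender in ("male", "female"):
            n = spec.n_per_cell
            z_f0 = _stratified_normal(n, rng)
            z_vt = _stratified_normal(n, rng)
            ages = rng.integers(35, 66, size=n)
            sd_scale = spec.stroke_f0_sd_scale if group == "stroke" else 1.0
            f0_shift = spec.stroke_f0_shift[gender] if group == "stroke" else 1.0
            tr_scale = spec.stroke_transition_scale if group == "stroke" else 1.0
            fmt_base = FEMALE_FORMANT_SCALE if gender == "female" else 1.0
            for i in range(n):
                sid = f"{group[:2]}_{gender[0]}_{i:02d}"
                base_f0 = (
                    spec.gender_f0_base[gender]
                    * f0_shift
                    * math.exp(spec.speaker_f0_sd * sd_scale * z_f0[i])
                )
                fmt_scale = fmt_base * (1.0 + spec.formant_scale_sd * z_vt[i])
                drift_sd = spec.contour_drift * sd_scale
                jit = spec.jitter * sd_scale
                wander = spec.articulatory_instability * (
                    spec.stroke_instability_scale if group == "stroke" else 1.0
                )
                hnr = spec.stroke_hnr_db if group == "stroke" else spec.hnr_db
                for vowel in VOWELS:
                    f0_target = base_f0 * VOWEL_F0_FACTOR[vowel]
                    drift = drift_sd * rng.standard_normal(8)
                    contour = f0_target * (1.0 + drift - drift.mean())
                    vspec = VowelSpec(
                        f0=contour,
                        formants=tuple(f * fmt_scale for f in VOWEL_FORMANTS[vowel]),
                        duration=spec.vowel_duration,
                        sample_rate=spec.sample_rate,
                        snr_db=spec.snr_db,
                        jitter=jit,
                        formant_wander=wander,
                        hnr_db=hnr,
                    )
                    w, gt = synthesize_vowel(vspec, seed=rng.integers(2**31))
                    w, gt = _pad_silence(w, gt, spec.silence_pad_s, spec.snr_db, rng)
                    utterances.append(
                        CohortUtterance(
                            path=f"{sid}_{vowel}.wav", speaker_id=sid, group=group,
                            gender=gender, age=int(ages[i]), utterance_type=vowel,
                            take=1, complete=True, waveform=w, ground_truth=gt,
                        )
                    )
                for sent in SENTENCES:
                    decl = (1.04, 1.0, 0.96)  # mild F0 declination across the sentence
                    segs = [
                        VowelSpec(
                            f0=base_f0 * d,
                            formants=tuple(f * fmt_scale for f in VOWEL_FORMANTS[v]),
                            duration=spec.segment_duration,
                            sample_rate=spec.sample_rate,
                            snr_db=spec.snr_db,
                            jitter=jit,
                            formant_wander=wander,
                            hnr_db=hnr,
                        )
                        for v, d in zip(SENTENCE_SEGMENTS[sent], decl)
                    ]
                    sspec = SequenceSpec(
                        segments=segs,
                        transition_durations=[spec.transition_duration * tr_scale] * 2,
                    )
                    w, gt = synthesize_sequence(sspec, seed=rng.integers(2**31))
                    w, gt = _pad_silence(w, gt, spec.silence_pad_s, spec.snr_db, rng)
                    utterances.append(
                        CohortUtterance(
                            path=f"{sid}_{sent}.wav", speaker_id=sid, group=group,
                            gender=gender, age=int(ages[i]), utterance_type=sent,
                            take=1, complete=True, waveform=w, ground_truth=gt,
                        )
                    )
    return Cohort(spec=spec, utterances=utterances)
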