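"""Synthetic speech generator: ground-truth integrity and determinism."""

import numpy as np
import pytest
from scipy.signal import find_peaks, welch

import strokeprosody as sp
from strokeprosody.synth import VOWEL_FORMANTS


class TestPulseTrain:
    def test_constant_f0_pulse_count_and_gaps(self):
        w, gt = sp.generate_pulse_train(100.0, 1.0, 16000, jitter=0.0, seed=0)
        assert len(gt.epoch_times) == 100
        gaps = np.diff(np.round(gt.epoch_times * 16000).astype(int))
        assert set(gaps) == {160}

    def test_sample_grid_quantization(self):
        # 133.33 Hz target realized on the grid: gap 120 samples -> 16000/120
        w, gt = sp.generate_pulse_train(133.33, 1.0, 16000, jitter=0.0, seed=0)
        gaps = np.diff(np.round(gt.epoch_times * 16000).astype(int))
        assert set(gaps) == {120}
        assert np.all(gt.f0_realized == 16000.0 / 120.0)

    @pytest.mark.parametrize("f0,duration", [(100.0, 0.0), (100.0, -1.0), (0.0, 1.0), (-5.0, 1.0)])
    def test_invalid_inputs_rejected(self, f0, duration):
        with pytest.raises(ValueError):
            sp.generate_pulse_train(f0, duration, 16000)

    @pytest.mark.parametrize("f0", [80.0, 133.33, 220.0])
    def test_epoch_count_matches_duration_times_f0(self, f0):
        _, gt = sp.generate_pulse_train(f0, 1.0, 16000, jitter=0.0, seed=0)
        assert abs(len(gt.epoch_times) - int(1.0 * f0)) <= 1

    def test_realized_f0_within_one_grid_step(self):
        f0 = 177.0
        _, gt = sp.generate_pulse_train(f0, 1.0, 16000, jitter=0.0, seed=0)
        n = round(16000 / f0)
        step = 16000 / (n * (n - 1))
        assert np.all(np.abs(gt.f0_realized - f0) <= step)


class TestFormantFilter:
    def test_spectral_peaks_at_formants(self, rng):
        exc = sp.Waveform(rng.standard_normal(32000), 16000)
        out = sp.apply_formant_filter(exc, (500, 1500, 2500))
        f, p = welch(out.samples, fs=16000, nperseg=4096)
        peaks, _ = find_peaks(p)
        for target in (500, 1500, 2500):
            assert np.min(np.abs(f[peaks] - target)) <= 50.0

    def test_zero_excitation_gives_zero_output(self):
        exc = sp.Waveform(np.zeros(1000), 16000)
        out = sp.apply_formant_filter(exc, (500, 1500, 2500))
        assert np.all(out.samples == 0.0)

    def test_formants_above_nyquist_rejected(self):
        exc = sp.Waveform(np.zeros(1000), 16000)
        with pytest.raises(ValueError):
            sp.apply_formant_filter(exc, (500, 1500, 8001))

    def test_output_length_preserved(self, rng):
        exc = sp.Waveform(rng.standard_normal(777), 16000)
        out = sp.apply_formant_filter(exc, (700, 1200, 2600))
        assert out.samples.size == 777


class TestSynthesizeVowel:
    def test_true_dispersion_is_f3_minus_f1(self):
        spec = sp.VowelSpec(f0=120.0, formants=(700, 1200, 2600), duration=0.3)
        _, gt = sp.synthesize_vowel(spec, seed=0)
        assert gt.true_dispersion == 1900.0

    def test_deterministic_given_seed(self):
        spec = sp.VowelSpec(f0=150.0, formants=(730, 1090, 2440), duration=0.3, snr_db=20.0)
        w1, _ = sp.synthesize_vowel(spec, seed=5)
        w2, _ = sp.synthesize_vowel(spec, seed=5)
        assert np.array_equal(w1.samples, w2.samples)

    def test_rising_contour_gives_shrinking_epoch_gaps(self):
        spec = sp.VowelSpec(f0=np.linspace(100.0, 140.0, 32), formants=(730, 1090, 2440),
                            duration=1.0)
        _, gt = sp.synthesize_vowel(spec, seed=0)
        gaps = np.diff(gt.epoch_times)
        assert np.all(np.diff(gaps) <= 1.0 / 16000 + 1e-12)  # non-increasing on the grid
        assert gaps[-1] < gaps[0]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            sp.VowelSpec(f0=100.0, formants=(730, 1090, 2440), duration=0.0)
        with pytest.raises(ValueError, match="formants"):
            sp.VowelSpec(f0=100.0, formants=(1090, 730, 2440), duration=1.0)
        with pytest.raises(ValueError, match="f0"):
            sp.VowelSpec(f0=-1.0, formants=(730, 1090, 2440), duration=1.0)


class TestSynthesizeSequence:
    def test_two_segments_one_transition(self):
        segs = [sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS[v], duration=0.5)
                for v in ("A", "I")]
        w, gt = sp.synthesize_sequence(sp.SequenceSpec(segs, [0.05]), seed=2)
        assert w.duration == pytest.approx(1.05, abs=1e-6)
        assert gt.transition_intervals == [(0.5, 0.55)]

    def test_single_segment_no_transitions(self):
        segs = [sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS["A"], duration=0.4)]
        _, gt = sp.synthesize_sequence(sp.SequenceSpec(segs, []), seed=0)
        assert gt.transition_intervals == []

    def test_three_segments_two_transitions(self):
        segs = [sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS[v], duration=0.35)
                for v in ("A", "I", "U")]
        _, gt = sp.synthesize_sequence(sp.SequenceSpec(segs, [0.04, 0.06]), seed=0)
        lengths = [round(b - a, 6) for a, b in gt.transition_intervals]
        assert lengths == [0.04, 0.06]

    def test_boundaries_tile_duration(self):
        segs = [sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS[v], duration=0.3)
                for v in ("A", "E", "O")]
        w, gt = sp.synthesize_sequence(sp.SequenceSpec(segs, [0.05, 0.05]), seed=1)
        bounds = sorted(gt.segment_boundaries)
        assert bounds[0][0] == 0.0
        for (a0, b0, _), (a1, b1, _) in zip(bounds, bounds[1:]):
            assert b0 == pytest.approx(a1, abs=1e-9)
        assert bounds[-1][1] == pytest.approx(w.duration, abs=1e-6)

    def test_transition_longer_than_segment_rejected(self):
        segs = [sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS[v], duration=0.2)
                for v in ("A", "I")]
        with pytest.raises(ValueError, match="transition"):
            sp.SequenceSpec(segs, [0.25])

    def test_transition_count_mismatch_rejected(self):
        segs = [sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS[v], duration=0.3)
                for v in ("A", "I")]
        with pytest.raises(ValueError):
            sp.SequenceSpec(segs, [0.05, 0.05])


class TestCohort:
    def test_counts(self, small_cohort):
        manifest = small_cohort.manifest()
        assert manifest["speaker_id"].nunique() == 8  # 2 per (group, gender) cell
        assert len(manifest) == 8 * 7               # five vowels + two sentences each

    def test_manifest_deterministic(self, small_cohort):
        again = sp.make_cohort(sp.CohortSpec(n_per_cell=2, seed=7))
        assert small_cohort.manifest().to_csv(index=False) == again.manifest().to_csv(index=False)
        w0 = small_cohort.utterances[0].waveform.samples
        w1 = again.utterances[0].waveform.samples
        assert np.array_equal(w0, w1)

    def test_epoch_ground_truth_strictly_increasing(self, small_cohort):
        for u in small_cohort.utterances[:10]:
            assert np.all(np.diff(u.ground_truth.epoch_times) > 0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sp.CohortSpec(n_per_cell=0)
        with pytest.raises(ValueError):
            sp.CohortSpec(stroke_transition_scale=-1.0)

    def test_write_roundtrip(self, tmp_path, small_cohort):
        manifest_path = small_cohort.write(tmp_path)
        records = sp.load_manifest(manifest_path)
        assert len(records) == len(small_cohort.utterances)
        w = sp.Waveform.read(records[0].path)
        assert w.sample_rate == 16000
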