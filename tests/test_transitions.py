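"""MFCC front end, cepstral difference, region segmentation and duration features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import strokeprosody as sp
from strokeprosody import transitions as tr
from strokeprosody.synth import VOWEL_FORMANTS


def _mfcc_from_matrix(coeffs, shift_s=0.01, energies=None):
    coeffs = np.asarray(coeffs, dtype=float)
    L = coeffs.shape[0]
    if energies is None:
        energies = np.ones(L)
    return tr.MFCCMatrix(coeffs, np.arange(L) * shift_s, np.asarray(energies, float), shift_s)


def _curve(values, scale=1.0):
    return tr.CepstralDifferenceCurve(np.asarray(values, float), K=2, scale=scale)


def brute_force_delta_c(C, K):
    """Triple-loop oracle for the cepstral difference."""
    L, M = C.shape
    out = np.full(L, np.nan)
    for l in range(K, L - K):
        acc = 0.0
        for m in range(M):
            for k in range(1, K + 1):
                acc += k * abs(C[l + k, m] - C[l - k, m])
        out[l] = acc
    return out


class TestComputeMFCC:
    def test_frame_count_for_one_second(self):
        w = sp.Waveform(np.sin(2 * np.pi * 220 * np.arange(16000) / 16000), 16000)
        m = tr.compute_mfcc(w)
        assert m.n_frames == 99  # floor((16000 - 320) / 160) + 1
        assert m.coefficients.shape == (99, 13)

    def test_deterministic(self):
        w = sp.Waveform(np.sin(2 * np.pi * 300 * np.arange(8000) / 16000), 16000)
        m1 = tr.compute_mfcc(w, rasta=False)
        m2 = tr.compute_mfcc(w, rasta=False)
        assert np.array_equal(m1.coefficients, m2.coefficients)

    def test_different_vowels_differ(self):
        specs = [sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS[v], duration=0.3)
                 for v in ("A", "I")]
        ws = [sp.synthesize_vowel(s, seed=1)[0] for s in specs]
        means = [tr.compute_mfcc(w, rasta=False).coefficients.mean(axis=0) for w in ws]
        assert np.linalg.norm(means[0] - means[1]) > 0

    def test_too_short_rejected(self):
        w = sp.Waveform(np.zeros(100), 16000)
        with pytest.raises(ValueError):
            tr.compute_mfcc(w)

    def test_vtln_alpha_changes_coefficients(self):
        spec = sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS["A"], duration=0.3)
        w, _ = sp.synthesize_vowel(spec, seed=1)
        m1 = tr.compute_mfcc(w, vtln_alpha=1.0, rasta=False)
        m2 = tr.compute_mfcc(w, vtln_alpha=1.1, rasta=False)
        assert not np.allclose(m1.coefficients, m2.coefficients)


class TestDiscardSilence:
    def test_low_energy_frame_dropped(self):
        m = _mfcc_from_matrix(np.zeros((3, 13)), energies=[1.0, 0.5, 0.03])
        out = tr.discard_silence(m, energy_frac=0.06)
        assert out.n_frames == 2
        assert np.array_equal(out.kept_indices, [0, 1])

    def test_equal_energies_none_dropped(self):
        m = _mfcc_from_matrix(np.zeros((5, 13)), energies=np.ones(5))
        assert tr.discard_silence(m).n_frames == 5

    def test_zero_fraction_is_identity(self):
        m = _mfcc_from_matrix(np.zeros((4, 13)), energies=[1.0, 1e-9, 1.0, 1.0])
        assert tr.discard_silence(m, energy_frac=0.0).n_frames == 4

    def test_all_dropped_rejected(self):
        m = _mfcc_from_matrix(np.zeros((0, 13)), energies=[])
        with pytest.raises(ValueError):
            tr.discard_silence(m)


class TestCepstralDifference:
    def test_constant_matrix_gives_zero(self):
        m = _mfcc_from_matrix(np.full((20, 13), 3.7))
        c = tr.cepstral_difference(m)
        interior = c.values[2:-2]
        assert np.all(interior == 0.0)
        assert np.all(np.isnan(c.values[:2])) and np.all(np.isnan(c.values[-2:]))

    def test_single_coefficient_step_example(self):
        # sequence (0,0,0,1,1,1,1): at the fourth frame (0-based l=3),
        # dC = 1*|C(4)-C(2)| + 2*|C(5)-C(1)| = 1 + 2 = 3 before normalization
        m = _mfcc_from_matrix(np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0], [1.0]]))
        c = tr.cepstral_difference(m, K=2)
        assert c.raw[3] == pytest.approx(3.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        C = rng.standard_normal((50, 13))
        m = _mfcc_from_matrix(C)
        c = tr.cepstral_difference(m, K=2)
        expected = brute_force_delta_c(C, 2)
        assert np.nanmax(np.abs(c.raw - expected)) < 1e-10

    def test_normalized_peak_is_one(self, rng):
        m = _mfcc_from_matrix(rng.standard_normal((30, 13)))
        c = tr.cepstral_difference(m)
        assert np.nanmax(c.values) == pytest.approx(1.0)
        assert c.scale > 0

    def test_too_few_frames_rejected(self):
        m = _mfcc_from_matrix(np.zeros((4, 13)))
        with pytest.raises(ValueError):
            tr.cepstral_difference(m, K=2)


class TestFindRegions:
    def test_single_peak_run(self):
        r = tr.find_regions(_curve([0.2, 0.6, 1.0, 0.6, 0.2]))
        assert r.transitions == [(1, 4)]
        assert r.steadies == [(0, 1), (4, 5)]

    def test_min_length_discards_single_frame_run(self):
        r = tr.find_regions(_curve([0.1, 0.2, 1.0, 0.2, 0.1]), min_len_frames=2)
        assert r.transitions == []
        assert r.steadies == [(0, 5)]

    def test_two_runs_three_steadies(self):
        r = tr.find_regions(_curve([0.1, 0.8, 0.9, 0.1, 0.1, 0.7, 0.8, 0.1]))
        assert r.transitions == [(1, 3), (5, 7)]
        assert r.steadies == [(0, 1), (3, 5), (7, 8)]

    def test_nan_edges_join_steady(self):
        v = np.array([np.nan, np.nan, 0.9, 0.9, 0.1, np.nan])
        r = tr.find_regions(_curve(v))
        assert r.transitions == [(2, 4)]
        assert sum(e - s for s, e in r.transitions + r.steadies) == 6


class TestTransitionFeatures:
    def test_worked_example(self):
        c = _curve([0.2, 0.6, 1.0, 0.6, 0.2])
        r = tr.find_regions(c)
        f = tr.transition_features(r, c, frame_shift_s=0.01)
        assert f.rtd == pytest.approx(0.6)
        assert f.rta == pytest.approx(0.44)   # (0.6 + 1.0 + 0.6) / 5
        assert f.tr == pytest.approx(20.0)    # 1 / (5 * 0.01)
        assert f.rssd == pytest.approx(0.4)

    def test_excess_mode_subtracts_threshold(self):
        c = _curve([0.2, 0.6, 1.0, 0.6, 0.2])
        r = tr.find_regions(c)
        f = tr.transition_features(r, c, rta_mode="excess")
        assert f.rta == pytest.approx((0.1 + 0.5 + 0.1) / 5)

    def test_no_transitions(self):
        c = _curve([0.1, 0.2, 0.3, 0.2, 0.1])
        r = tr.find_regions(c)
        f = tr.transition_features(r, c)
        assert (f.rtd, f.rta, f.tr, f.rssd) == (0.0, 0.0, 0.0, 1.0)

    def test_empty_rejected(self):
        r = tr.RegionSet([], [], 0)
        with pytest.raises(ValueError):
            tr.transition_features(r, _curve([]))

    def test_unknown_mode_rejected(self):
        c = _curve([0.2, 0.6, 1.0, 0.6, 0.2])
        with pytest.raises(ValueError):
            tr.transition_features(tr.find_regions(c), c, rta_mode="bogus")

    @given(hnp.arrays(np.float64, st.integers(5, 60),
                      elements=st.floats(0.0, 1.0, allow_nan=False)))
    @settings(max_examples=100, deadline=None)
    def test_rtd_plus_rssd_is_one(self, values):
        c = _curve(values)
        f = tr.transition_features(tr.find_regions(c), c)
        assert f.rtd + f.rssd == pytest.approx(1.0, abs=1e-12)


class TestSequenceRecovery:
    def _estimate(self, tdur, seed=5):
        segs = [sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS[v], duration=0.35)
                for v in ("A", "I", "U")]
        w, _ = sp.synthesize_sequence(sp.SequenceSpec(segs, [tdur, tdur]), seed=seed)
        m = tr.discard_silence(tr.compute_mfcc(w))
        c = tr.cepstral_difference(m)
        r = tr.find_regions(c)
        return tr.transition_features(r, c), r.total_frames

    def test_known_transition_duration_recovered(self):
        segs = [sp.VowelSpec(f0=120.0, formants=VOWEL_FORMANTS[v], duration=0.5)
                for v in ("A", "I")]
        w, _ = sp.synthesize_sequence(sp.SequenceSpec(segs, [0.05]), seed=2)
        m = tr.discard_silence(tr.compute_mfcc(w))
        c = tr.cepstral_difference(m)
        r = tr.find_regions(c)
        f = tr.transition_features(r, c)
        assert len(r.transitions) == 1
        assert abs(f.rtd - 0.05 / 1.05) <= 2.0 / r.total_frames

    def test_shrinking_transition_never_increases_rtd(self):
        rtds = []
        for tdur in (0.04, 0.06, 0.08, 0.10):
            f, L = self._estimate(tdur)
            rtds.append((f.rtd, L))
        for (r_small, L), (r_large, _) in zip(rtds, rtds[1:]):
            assert r_small <= r_large + 2.0 / L


class TestGroupSummary:
    def _features(self, rows):
        return pd.DataFrame(rows)

    def test_single_utterance_cells(self):
        rows = []
        for group in ("stroke", "control"):
            for gender in ("male", "female"):
                rows.append(dict(group=group, gender=gender, rtd=0.2, rta=5.0,
                                 tr=3.0, rssd=0.8, complete=True))
        out = tr.group_summary(self._features(rows)).set_index(["group", "gender"])
        assert out.loc[("stroke", "male"), "mtd"] == 0.2
        assert out.loc[("stroke", "male"), "msstr"] == pytest.approx(4.0)

    def test_mean_over_utterances(self):
        rows = [dict(group="control", gender="male", rtd=v, rta=1.0, tr=1.0,
                     rssd=1 - v, complete=True) for v in (0.2, 0.4)]
        out = tr.group_summary(self._features(rows))
        assert out.loc[0, "mtd"] == pytest.approx(0.3)
        assert out.loc[0, "msstr"] == pytest.approx(0.7 / 0.3)

    def test_mean_of_ratios_mode(self):
        rows = [dict(group="control", gender="male", rtd=v, rta=1.0, tr=1.0,
                     rssd=1 - v, complete=True) for v in (0.2, 0.5)]
        out = tr.group_summary(self._features(rows), msstr_mode="mean_of_ratios")
        assert out.loc[0, "msstr"] == pytest.approx((0.8 / 0.2 + 0.5 / 0.5) / 2)

    def test_incomplete_excluded_and_empty_cell_rejected(self):
        rows = [dict(group="stroke", gender="male", rtd=0.2, rta=1.0, tr=1.0,
                     rssd=0.8, complete=False),
                dict(group="control", gender="male", rtd=0.2, rta=1.0, tr=1.0,
                     rssd=0.8, complete=True)]
        with pytest.raises(ValueError, match="stroke"):
            tr.group_summary(self._features(rows))
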