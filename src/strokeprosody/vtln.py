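"""Vocal tract length normalization via formant dispersion.

Formant dispersion — the mean spacing of the low formants, here the average
of F3 − F1 over voiced frames — correlates inversely with vocal tract
length.  Each speaker's spectral envelope is warped by a factor

    alpha = 1 + (1/20) * (D_f - mu) / sigma

where mu and sigma are the mean and sample standard deviation of dispersion
over the *healthy* speakers of the same gender.  A speaker at the reference
dispersion is untouched (alpha = 1); one sigma above maps to alpha = 1.05.
The warp itself is the common piecewise-linear convention: frequencies below
a knee at 0.85 x Nyquist move as f -> f/alpha, with a continuous,
endpoint-preserving linear segment above the knee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, freqz

from . import zff
from .datatypes import Waveform

DEFAULT_FRAME_S = 0.025
DEFAULT_SHIFT_S = 0.010
DEFAULT_KNEE_FRAC = 0.85
MIN_FORMANT_HZ = 90.0
WARP_SLOPE = 1.0 / 20.0


@dataclass
class FormantTrack:
    """Per-frame ordered (F1, F2, F3) estimates in Hz."""

    formants: np.ndarray  # (n_frames, 3)
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.formants = np.atleast_2d(np.asarray(self.formants, dtype=float))
        self.frame_times = np.asarray(self.frame_times, dtype=float)

    def __len__(self) -> int:
        return self.formants.shape[0]


@dataclass
class ReferenceStats:
    """Healthy-group dispersion baseline for one gender."""

    mu: float
    sigma: float
    gender: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class WarpFactor:
    alpha: float
    speaker_id: str = ""

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


def _lpc(frame: np.ndarray, order: int) -> np.ndarray | None:
    """Autocorrelation-method LPC; returns the full coefficient vector [1, a1..ap]."""
    n = frame.size
    r = np.correlate(frame, frame, mode="full")[n - 1 : n + order]
    if r[0] <= 0:
        return None
    r = r + 1e-9 * r[0] * (np.arange(order + 1) == 0)  # tiny regularization
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return None
    return np.concatenate([[1.0], a])


def estimate_formants(
    w: Waveform,
    lp_order: int | None = None,
    frame_s: float = DEFAULT_FRAME_S,
    shift_s: float = DEFAULT_SHIFT_S,
    preemphasis: float = 0.97,
    min_epochs_per_frame: int = 2,
) -> FormantTrack:
    """Per-frame formants from linear-prediction spectrum peaks.

    Frames are restricted to voiced stretches, judged by epoch density
    (at least ``min_epochs_per_frame`` detected epochs per frame).  In each
    voiced frame the three lowest-frequency LP-spectrum peaks above 90 Hz are
    taken as (F1, F2, F3); frames with fewer than three peaks are dropped.
    The track is then smoothed with a 5-frame running median per formant,
    the standard guard against single-frame peak-picking outliers.
    """
    fs = w.sample_rate
    if lp_order is None:
        lp_order = 2 + fs // 1000
    n_frame = int(round(frame_s * fs))
    n_shift = int(round(shift_s * fs))
    if w.samples.size < n_frame:
        raise ValueError("signal shorter than one analysis frame")
    epochs = zff.filter_epochs(zff.detect_epochs(zff.zero_frequency_filter(w), w))
    x = np.append(w.samples[0], w.samples[1:] - preemphasis * w.samples[:-1])
    window = np.hamming(n_frame)
    formants, times = [], []
    for start in range(0, x.size - n_frame + 1, n_shift):
        t0, t1 = start / fs, (start + n_frame) / fs
        n_ep = int(np.count_nonzero((epochs.times >= t0) & (epochs.times < t1)))
        if n_ep < min_epochs_per_frame:
            continue
        a = _lpc(x[start : start + n_frame] * window, lp_order)
        if a is None:
            continue
        freq, h = freqz(1.0, a, worN=1024, fs=fs)
        mag = np.abs(h)
        peaks, _ = find_peaks(mag)
        cand = freq[peaks]
        cand = cand[cand > MIN_FORMANT_HZ]
        if cand.size < 3:
            continue
        formants.append(cand[:3])
        times.append(0.5 * (t0 + t1))
    if not formants:
        raise ValueError("no voiced formant frames")
    track = np.asarray(formants)
    if track.shape[0] >= 3:
        track = median_filter(track, size=(min(5, track.shape[0]), 1), mode="nearest")
    return FormantTrack(track, np.asarray(times))


def formant_dispersion(track: FormantTrack) -> float:
    """Mean over frames of F3 - F1, in Hz."""
    if len(track) == 0:
        raise ValueError("empty formant track")
    return float(np.mean(track.formants[:, 2] - track.formants[:, 0]))


def reference_stats(dispersions, genders, groups) -> dict:
    """Per-gender mean/sd of dispersion over healthy (control) speakers only.

    ``dispersions``, ``genders`` and ``groups`` are parallel sequences, one
    entry per speaker.  sigma uses the n-1 normalization.  Requires at least
    two healthy speakers per gender present in the data.
    """
    d = np.asarray(dispersions, dtype=float)
    genders = np.asarray(genders)
    groups = np.asarray(groups)
    out = {}
    for gender in np.unique(genders):
        healthy = d[(genders == gender) & (groups == "control")]
        if healthy.size < 2:
            raise ValueError(
                f"need >= 2 healthy speakers of gender {gender!r}, got {healthy.size}"
            )
        out[str(gender)] = ReferenceStats(
            mu=float(np.mean(healthy)), sigma=float(np.std(healthy, ddof=1)),
            gender=str(gender),
        )
    return out


def warp_factor(dispersion: float, ref: ReferenceStats, speaker_id: str = "") -> WarpFactor:
    """alpha = 1 + (1/20) (D_f - mu) / sigma."""
    return WarpFactor(
        alpha=1.0 + WARP_SLOPE * (dispersion - ref.mu) / ref.sigma, speaker_id=speaker_id
    )


def warp_frequencies(f: np.ndarray, alpha: float, f_max: float,
                     knee_frac: float = DEFAULT_KNEE_FRAC) -> np.ndarray:
    """Source frequency looked up for each output frequency under the warp.

    A spectral feature at frequency g appears at g/alpha in the warped
    spectrum (for g below the knee), so the output at frequency f reads the
    input at alpha*f; above the knee the map continues linearly to fix the
    endpoint (f_max -> f_max).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    f = np.asarray(f, dtype=float)
    knee = knee_frac * f_max
    src = np.where(f <= knee, alpha * f,
                   alpha * knee + (f_max - alpha * knee) * (f - knee) / (f_max - knee))
    return np.clip(src, 0.0, f_max)


def warp_spectrum(spectrum: np.ndarray, alpha: float,
                  knee_frac: float = DEFAULT_KNEE_FRAC) -> np.ndarray:
    """Warp a single magnitude/power spectrum sampled on a uniform [0, Nyquist] grid.

    alpha = 1 is the identity; band count and non-negativity are preserved;
    energy is linearly interpolated between bins.
    """
    s = np.asarray(spectrum, dtype=float)
    bins = np.arange(s.size, dtype=float)
    src = warp_frequencies(bins, alpha, f_max=float(s.size - 1), knee_frac=knee_frac)
    return np.interp(src, bins, s)
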