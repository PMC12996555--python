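"""Zero-frequency-filtering epoch detection and instantaneous F0 extraction.

Glottal closure instants (epochs) are the moments of significant excitation in
each glottal cycle.  Passing speech through a cascade of resonators centred at
0 Hz and removing the local mean leaves a smooth oscillation whose
negative-to-positive zero crossings coincide with the epochs; the slope of the
filtered signal at a crossing is the strength of excitation.  The
instantaneous F0 contour is the reciprocal of the interval between successive
epochs, one value per glottal cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import lfilter

from .datatypes import Waveform

DEFAULT_TREND_WINDOW_S = 0.010
DEFAULT_MIN_STRENGTH_FRAC = 0.05
DEFAULT_F0_MIN = 50.0
DEFAULT_F0_MAX = 300.0


@dataclass
class EpochSequence:
    """Glottal closure instants with excitation strengths."""

    times: np.ndarray      # seconds, strictly increasing
    strengths: np.ndarray  # nonnegative, one per epoch

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.times.shape != self.strengths.shape:
            raise ValueError("times and strengths must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("epoch times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class F0Contour:
    """Per-cycle fundamental frequency values at epoch-interval midpoints."""

    times: np.ndarray
    values: np.ndarray  # Hz, > 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return self.values.size


def zero_frequency_filter(w: Waveform, trend_window_s: float = DEFAULT_TREND_WINDOW_S) -> np.ndarray:
    """Zero-frequency-filter a waveform.

    The signal is differenced once (removes slowly varying bias from the
    recording chain), then passed through two cascaded double-pole resonators
    at 0 Hz.  After each resonator stage the local trend — a centred moving
    average of ``trend_window_s`` seconds, edges padded by reflection — is
    subtracted, which both removes the polynomial growth of the integrator
    output and keeps the computation well conditioned.

    Returns an array of the same length as the input.
    """
    if trend_window_s <= 0:
        raise ValueError(f"trend_window_s must be > 0, got {trend_window_s}")
    n_win = int(round(trend_window_s * w.sample_rate))
    if n_win < 1 or n_win > w.samples.size:
        raise ValueError(
            f"trend window of {trend_window_s} s ({n_win} samples) does not fit "
            f"a signal of {w.samples.size} samples"
        )
    x = np.diff(w.samples, prepend=w.samples[:1])
    y = x
    for _ in range(2):
        # double pole at z = 1: y[n] = x[n] + 2 y[n-1] - y[n-2]
        y = lfilter([1.0], [1.0, -2.0, 1.0], y)
        # the integrator amplifies low frequencies ~1/omega^2, so a single
        # mean subtraction leaves a dominant slow residual; three successive
        # passes flatten it
        for _ in range(3):
            y = y - uniform_filter1d(y, size=n_win, mode="reflect")
    return y


def detect_epochs(zff_signal: np.ndarray, w: Waveform) -> EpochSequence:
    """Locate epochs as negative-to-positive zero crossings of the ZFF signal.

    Crossing instants are linearly interpolated to sub-sample precision.  The
    strength of excitation at each epoch is the slope of the ZFF signal there
    (difference of the adjacent samples divided by the sample period).

    An unvoiced or empty signal yields an empty sequence, not an error.
    """
    z = np.asarray(zff_signal, dtype=float)
    if z.size < 2:
        return EpochSequence(np.empty(0), np.empty(0))
    idx = np.nonzero((z[:-1] < 0) & (z[1:] >= 0))[0]
    if idx.size == 0:
        return EpochSequence(np.empty(0), np.empty(0))
    rise = z[idx + 1] - z[idx]
    frac = np.where(rise > 0, -z[idx] / np.where(rise > 0, rise, 1.0), 0.0)
    times = (idx + frac) / w.sample_rate
    strengths = rise * w.sample_rate
    return EpochSequence(times, strengths)


def filter_epochs(e: EpochSequence, min_strength_frac: float = DEFAULT_MIN_STRENGTH_FRAC) -> EpochSequence:
    """Discard weak epochs.

    Epochs whose strength falls below ``min_strength_frac`` times the mean
    strength of the input sequence are removed; the mean is computed once over
    the input, not iteratively.
    """
    if not 0.0 <= min_strength_frac <= 1.0:
        raise ValueError(f"min_strength_frac must be in [0, 1], got {min_strength_frac}")
    if len(e) == 0 or min_strength_frac == 0.0:
        return EpochSequence(e.times.copy(), e.strengths.copy())
    threshold = min_strength_frac * float(np.mean(e.strengths))
    keep = e.strengths >= threshold
    return EpochSequence(e.times[keep], e.strengths[keep])


def instantaneous_f0(
    e: EpochSequence,
    f0_min: float = DEFAULT_F0_MIN,
    f0_max: float = DEFAULT_F0_MAX,
) -> F0Contour:
    """Per-cycle F0: reciprocal of the interval between successive epochs.

    Values outside [``f0_min``, ``f0_max``] Hz are discarded (they arise from
    noisy silence stretches).  Contour times are interval midpoints.  Fewer
    than two epochs yield an empty contour.
    """
    if len(e) < 2:
        return F0Contour(np.empty(0), np.empty(0))
    intervals = np.diff(e.times)
    values = 1.0 / intervals
    mids = 0.5 * (e.times[:-1] + e.times[1:])
    keep = (values >= f0_min) & (values <= f0_max)
    return F0Contour(mids[keep], values[keep])


def extract_f0(
    w: Waveform,
    trend_window_s: float = DEFAULT_TREND_WINDOW_S,
    min_strength_frac: float = DEFAULT_MIN_STRENGTH_FRAC,
    f0_min: float = DEFAULT_F0_MIN,
    f0_max: float = DEFAULT_F0_MAX,
) -> F0Contour:
    """Full chain: ZFF -> epoch detection -> strength gate -> gated contour."""
    z = zero_frequency_filter(w, trend_window_s)
    e = filter_epochs(detect_epochs(z, w), min_strength_frac)
    return instantaneous_f0(e, f0_min, f0_max)
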