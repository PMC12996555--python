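"""Cepstral-difference transition/steady-state segmentation and duration features.

The spectral envelope of each utterance is summarized per frame by 13 MFCCs
(energy coefficient excluded, optional RASTA band-pass of the log-mel
trajectories, optional VTLN warp of the power spectrum).  The cepstral
difference

    dC(l) = sum_m sum_{k=1..K} k * | C(m, l+k) - C(m, l-k) |

measures the local slope of the cepstral trajectory; frame runs where dC
exceeds 50% of its utterance maximum are transition regions, the complement
steady-state regions.  Five per-utterance features follow: relative
transition duration (RTD), relative transition area (RTA), transition rate
(TR), and the steady-state counterparts RSSD and RSSA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from scipy.signal import lfilter

from .datatypes import Waveform
from .vtln import DEFAULT_KNEE_FRAC, warp_frequencies

DEFAULT_FRAME_S = 0.020
DEFAULT_SHIFT_S = 0.010
DEFAULT_N_COEFF = 13
DEFAULT_ENERGY_FRAC = 0.06
DEFAULT_K = 2
DEFAULT_THRESHOLD_FRAC = 0.5
DEFAULT_MIN_LEN_FRAMES = 2
RTA_THRESHOLD = 0.5  # absolute threshold on dC in the relative-area features


@dataclass
class MFCCMatrix:
    """Frame-wise cepstral coefficients (frames x coefficients, c0 excluded)."""

    coefficients: np.ndarray
    frame_times: np.ndarray
    frame_energies: np.ndarray
    frame_shift_s: float
    rasta: bool = False
    kept_indices: np.ndarray | None = None  # map to pre-silence-removal frames

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class CepstralDifferenceCurve:
    """dC(l) per frame, normalized to peak 1; edge frames are NaN.

    ``scale`` is the raw-curve maximum used for the normalization, so
    ``raw = values * scale`` recovers the unnormalized curve.
    """

    values: np.ndarray
    K: int = DEFAULT_K
    normalized: bool = True
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def raw(self) -> np.ndarray:
        return self.values * self.scale

    def __len__(self) -> int:
        return self.values.size


@dataclass
class RegionSet:
    """Half-open frame intervals labelled transition / steady."""

    transitions: list
    steadies: list
    total_frames: int


@dataclass
class TransitionFeatures:
    rtd: float
    rta: float
    tr: float
    rssd: float
    rssa: float
    utterance_id: str = ""


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int, n_fft: int, fs: int) -> np.ndarray:
    """Triangular filters on the mel scale spanning [0, fs/2]."""
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(fs / 2.0), n_mels + 2))
    bin_freqs = np.arange(n_fft // 2 + 1) * fs / n_fft
    fb = np.zeros((n_mels, bin_freqs.size))
    for i in range(n_mels):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bin_freqs - lo) / (mid - lo)
        down = (hi - bin_freqs) / (hi - mid)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def _rasta_filter(logmel: np.ndarray) -> np.ndarray:
    """Classic RASTA band-pass along the frame axis.

    H(z) = 0.1 (2 + z^-1 - z^-3 - 2 z^-4) / (1 - 0.98 z^-1); the first four
    frames are run through the FIR part only (output discarded) to seed the
    filter state, which suppresses the slow startup transient.
    """
    b = 0.1 * np.array([2.0, 1.0, 0.0, -1.0, -2.0])
    a = np.array([1.0, -0.98])
    L = logmel.shape[0]
    out = np.zeros_like(logmel)
    if L <= 4:
        return out
    warm, zf = lfilter(b, [1.0], logmel[:4], axis=0, zi=np.zeros((4, logmel.shape[1])))
    out[4:], _ = lfilter(b, a, logmel[4:], axis=0, zi=zf)
    return out


def compute_mfcc(
    w: Waveform,
    vtln_alpha: float = 1.0,
    frame_s: float = DEFAULT_FRAME_S,
    shift_s: float = DEFAULT_SHIFT_S,
    n_coeff: int = DEFAULT_N_COEFF,
    rasta: bool = True,
    n_mels: int = 26,
    n_fft: int = 512,
    preemphasis: float = 0.97,
    knee_frac: float = DEFAULT_KNEE_FRAC,
) -> MFCCMatrix:
    """MFCC front end with optional VTLN spectral warp and RASTA filtering.

    Per frame: pre-emphasis, Hamming window, power spectrum, VTLN warp,
    mel filterbank, log, RASTA (when enabled), DCT; coefficients 1..n_coeff
    are kept (the energy coefficient c0 is excluded).  Frame energies are
    measured on the raw (un-pre-emphasized) waveform frames.
    """
    fs = w.sample_rate
    n_frame = int(round(frame_s * fs))
    n_shift = int(round(shift_s * fs))
    if w.samples.size < n_frame:
        raise ValueError("utterance shorter than one analysis frame")
    starts = np.arange(0, w.samples.size - n_frame + 1, n_shift)
    idx = starts[:, None] + np.arange(n_frame)[None, :]
    raw_frames = w.samples[idx]
    energies = np.sum(raw_frames**2, axis=1)
    x = np.append(w.samples[0], w.samples[1:] - preemphasis * w.samples[:-1])
    frames = x[idx] * np.hamming(n_frame)
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    if vtln_alpha != 1.0:
        bins = np.arange(power.shape[1], dtype=float)
        src = warp_frequencies(bins, vtln_alpha, f_max=float(power.shape[1] - 1),
                               knee_frac=knee_frac)
        lo = np.clip(np.floor(src).astype(int), 0, power.shape[1] - 1)
        hi = np.clip(lo + 1, 0, power.shape[1] - 1)
        frac = src - lo
        power = power[:, lo] * (1.0 - frac) + power[:, hi] * frac
    fb = _mel_filterbank(n_mels, n_fft, fs)
    logmel = np.log(np.maximum(power @ fb.T, 1e-12))
    if rasta:
        logmel = _rasta_filter(logmel)
    cep = dct(logmel, type=2, norm="ortho", axis=1)
    coeffs = cep[:, 1 : n_coeff + 1]
    frame_times = (starts + 0.5 * n_frame) / fs
    return MFCCMatrix(coeffs, frame_times, energies, shift_s, rasta=rasta)


def discard_silence(
    m: MFCCMatrix,
    w: Waveform | None = None,
    energy_frac: float = DEFAULT_ENERGY_FRAC,
) -> MFCCMatrix:
    """Drop frames below ``energy_frac`` of the maximum frame energy.

    Remaining frames are re-indexed contiguously; ``kept_indices`` maps back
    to the original frame axis.  ``energy_frac = 0`` is the identity.
    """
    if not 0.0 <= energy_frac <= 1.0:
        raise ValueError(f"energy_frac must be in [0, 1], got {energy_frac}")
    e = m.frame_energies
    keep = e >= energy_frac * float(np.max(e)) if e.size else np.zeros(0, bool)
    if not np.any(keep):
        raise ValueError("utterance below energy floor")
    return MFCCMatrix(
        m.coefficients[keep], m.frame_times[keep], e[keep], m.frame_shift_s,
        rasta=m.rasta, kept_indices=np.nonzero(keep)[0],
    )


def cepstral_difference(m: MFCCMatrix, K: int = DEFAULT_K) -> CepstralDifferenceCurve:
    """Weighted across-frame cepstral slope, normalized to peak 1.

    dC(l) = sum_m sum_{k=1..K} k |C(m, l+k) - C(m, l-k)| for the interior
    frames l in [K, L-K); the K edge frames on either side carry NaN.  The
    curve is divided by its maximum (stored as ``scale``) so the 50%-of-max
    segmentation threshold becomes the constant 0.5.
    """
    C = m.coefficients
    L = C.shape[0]
    if L <= 2 * K:
        raise ValueError(f"need more than 2K={2 * K} frames, got {L}")
    dc = np.zeros(L - 2 * K)
    for k in range(1, K + 1):
        dc += k * np.sum(np.abs(C[K + k : L - K + k] - C[K - k : L - K - k]), axis=1)
    values = np.full(L, np.nan)
    scale = float(np.max(dc)) if dc.size and np.max(dc) > 0 else 1.0
    values[K : L - K] = dc / scale
    return CepstralDifferenceCurve(values, K=K, normalized=True, scale=scale)


def find_regions(
    c: CepstralDifferenceCurve,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_len_frames: int = DEFAULT_MIN_LEN_FRAMES,
) -> RegionSet:
    """Segment the frame axis into transition and steady regions.

    Maximal runs of frames with normalized dC above ``threshold_frac`` are
    transitions; runs shorter than ``min_len_frames`` are re-labelled steady.
    Edge frames without a dC value join the adjacent steady region.
    """
    v = c.values
    L = v.size
    mask = np.zeros(L, dtype=bool)
    defined = ~np.isnan(v)
    mask[defined] = v[defined] > threshold_frac
    transitions = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_len_frames:
            transitions.append((int(s), int(e)))
    steadies = []
    prev = 0
    for s, e in transitions:
        if s > prev:
            steadies.append((prev, s))
        prev = e
    if prev < L:
        steadies.append((prev, L))
    return RegionSet(transitions=transitions, steadies=steadies, total_frames=L)


def transition_features(
    r: RegionSet,
    c: CepstralDifferenceCurve,
    frame_shift_s: float = DEFAULT_SHIFT_S,
    rta_mode: str = "literal",
    utterance_id: str = "",
) -> TransitionFeatures:
    """Five duration features of one utterance.

    RTD = transition frames / L; TR = transition regions per second;
    RSSD = 1 - RTD.  RTA sums, over all frames, the raw-scale dC values
    exceeding the absolute threshold 0.5 and divides by L ("literal" mode;
    "excess" mode sums dC - 0.5 instead).  RSSA is the steady-state
    counterpart: sub-threshold dC restricted to steady frames, divided by L.
    """
    L = r.total_frames
    if L == 0:
        raise ValueError("empty region set (L = 0)")
    if rta_mode not in ("literal", "excess"):
        raise ValueError(f"rta_mode must be 'literal' or 'excess', got {rta_mode!r}")
    n_trans_frames = sum(e - s for s, e in r.transitions)
    rtd = n_trans_frames / L
    raw = np.nan_to_num(c.raw, nan=0.0)
    over = raw > RTA_THRESHOLD
    if rta_mode == "literal":
        rta = float(np.sum(raw[over])) / L
    else:
        rta = float(np.sum(raw[over] - RTA_THRESHOLD)) / L
    steady_mask = np.zeros(L, dtype=bool)
    for s, e in r.steadies:
        steady_mask[s:e] = True
    under = steady_mask & ~over
    rssa = float(np.sum(raw[under])) / L
    tr = len(r.transitions) / (L * frame_shift_s)
    return TransitionFeatures(
        rtd=rtd, rta=rta, tr=tr, rssd=1.0 - rtd, rssa=rssa, utterance_id=utterance_id
    )


def group_summary(features: pd.DataFrame, msstr_mode: str = "ratio_of_means") -> pd.DataFrame:
    """Per-(group, gender) means of the duration features.

    ``features`` needs columns rtd, rta, tr, rssd (and optionally rssa),
    plus group and gender labels; rows flagged ``complete == False`` are
    excluded.  MTD/MTA/MTR/MSSD are unweighted means over utterances;
    MSSTR = MSSD / MTD (``msstr_mode='mean_of_ratios'`` averages per-utterance
    rssd/rtd instead).
    """
    if msstr_mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown msstr_mode {msstr_mode!r}")
    df = features
    if "complete" in df.columns:
        df = df[df["complete"].astype(bool)]
    for group in features["group"].unique():
        for gender in features["gender"].unique():
            if df[(df["group"] == group) & (df["gender"] == gender)].empty:
                raise ValueError(f"empty cell (group={group}, gender={gender})")
    rows = []
    for (group, gender), cell in df.groupby(["group", "gender"], sort=True):
        mtd = float(cell["rtd"].mean())
        mssd = float(cell["rssd"].mean())
        if msstr_mode == "ratio_of_means":
            msstr = mssd / mtd
        else:
            msstr = float((cell["rssd"] / cell["rtd"]).mean())
        rows.append(
            {
                "group": group, "gender": gender, "mtd": mtd,
                "mta": float(cell["rta"].mean()), "mtr": float(cell["tr"].mean()),
                "mssd": mssd, "msstr": msstr, "n_utterances": int(len(cell)),
            }
        )
    return pd.DataFrame(rows)
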