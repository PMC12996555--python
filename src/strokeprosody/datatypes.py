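"""Core signal containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

ANALYSIS_RATE = 16_000  # Hz; all analyses run at this rate


@dataclass
class Waveform:
    """Mono audio signal with its sampling rate.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence (float). Finite values only.
    sample_rate : int
        Sampling rate in Hz, > 0.
    source_id : str
        Provenance tag (file path, synthetic utterance id, ...).
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate

    @classmethod
    def read(cls, path) -> "Waveform":
        """Load a mono WAV file. Integer PCM is scaled to [-1, 1)."""
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
        else:
            data = data.astype(float)
        return cls(samples=data, sample_rate=int(rate), source_id=str(path))

    def write(self, path) -> None:
        """Write as 16-bit PCM WAV, peak-normalized to 0.5 if needed."""
        x = self.samples
        peak = np.max(np.abs(x)) if x.size else 0.0
        if peak > 1.0:
            x = 0.5 * x / peak
        wavfile.write(path, self.sample_rate, np.round(x * 32767.0).astype(np.int16))


@dataclass
class GroundTruth:
    """Known generation parameters of a synthetic utterance (test oracle).

    ``segment_boundaries`` is a list of ``(start_s, end_s, label)`` with label
    in {"steady", "transition"}, tiling [0, duration] without overlap.
    """

    epoch_times: np.ndarray
    segment_boundaries: list = field(default_factory=list)
    true_dispersion: float = float("nan")
    f0_realized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epoch_times = np.asarray(self.epoch_times, dtype=float)
        if self.epoch_times.size > 1 and not np.all(np.diff(self.epoch_times) > 0):
            raise ValueError("epoch_times must be strictly increasing")

    @property
    def transition_intervals(self) -> list:
        return [(a, b) for a, b, lab in self.segment_boundaries if lab == "transition"]

    @property
    def steady_intervals(self) -> list:
        return [(a, b) for a, b, lab in self.segment_boundaries if lab == "steady"]
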