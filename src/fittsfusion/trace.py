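"""Uniformly sampled signal container shared by all channel types.

A :class:`SignalTrace` holds one sensor channel of a trial: a dense array of
samples (scalar per sample, or a fixed-dimension vector such as a 3-axis
gyroscope reading), the sampling rate, and a units label.  It is deliberately
minimal — feature extractors operate on the raw array and the rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalTrace"]


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled channel.

    Parameters
    ----------
    samples
        Array of shape ``(N,)`` for scalar channels or ``(N, d)`` for
        vector channels (e.g. 3-axis IMU).  All samples must be finite.
    sampling_rate
        Sampling frequency in Hz, strictly positive.
    units
        Free-text physical units label (e.g. ``"mV"``, ``"uS"``, ``"mm"``).
    """

    samples: np.ndarray
    sampling_rate: float
    units: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (scalar) or 2-D (vector) per sample")
        if arr.shape[0] < 1:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trace contains non-finite samples")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Trace duration in seconds (N / rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate
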