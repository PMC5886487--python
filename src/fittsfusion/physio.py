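"""Physiological feature extraction: EMG, GSR, PPG and EEG-state metrics.

EMG channels are conditioned with a zero-phase 20-450 Hz band-pass, a 60 Hz
notch, and DC removal, then summarized by two time-domain amplitude features,
each normalized by the subject's MVIC reference:

* weighted mean absolute value (MAV, second type): mean of the rectified
  signal under a trapezoidal weight that ramps up over the first quarter of
  the window, is 1 on the middle half, and ramps down over the last quarter;
* RMS of the rectified envelope after a 2 ms moving average.

Skin conductance is low-pass filtered at 5 Hz and summarized by SCvr, the
trial's max-min conductance range over the subject's baseline-session range.
Heart rate comes from the mean peak-to-peak interval (PPI) of the PPG pulse
train, normalized by the resting heart rate.  The five EEG cognitive-state
probabilities are validated and passed through unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .trace import SignalTrace
from .synthetic import EEG_STATES, TrialRecord

__all__ = [
    "preprocess_emg",
    "emg_mav",
    "emg_rms",
    "mvic_normalize",
    "gsr_variance",
    "heart_rate_from_ppg",
    "eeg_state_metrics",
    "EmgFeatureResult",
]

EMG_BAND = (20.0, 450.0)
NOTCH_HZ = 60.0


@dataclass(frozen=True)
class EmgFeatureResult:
    """MVIC-normalized MAV and RMS for one muscle ("PectM" or "PostD")."""

    mav: float
    rms: float
    muscle: str

    def __post_init__(self) -> None:
        if self.mav < 0 or self.rms < 0:
            raise ValueError("EMG amplitude features must be non-negative")


@lru_cache(maxsize=8)
def _bandpass_fir(rate: float) -> np.ndarray:
    # Linear-phase FIR; ~10 Hz transition gives >=40 dB stopband with a
    # Hamming window while staying short enough for sub-second trials.
    numtaps = int(3.3 * rate / 10.0) | 1
    ny = rate / 2
    return sps.firwin(
        numtaps, [EMG_BAND[0], min(EMG_BAND[1], 0.98 * ny)], pass_zero=False, fs=rate
    )


def preprocess_emg(raw: SignalTrace) -> SignalTrace:
    """Condition a raw EMG trace: 20-450 Hz band-pass, 60 Hz notch, DC removal.

    Both filters are applied forward-backward, so the output is zero-phase.
    Requires a sampling rate above 900 Hz so the upper band edge sits below
    Nyquist.
    """
    if raw.sampling_rate <= 900.0:
        raise ValueError(
            f"EMG sampling rate {raw.sampling_rate} Hz too low for a "
            f"{EMG_BAND[1]} Hz band edge"
        )
    x = raw.samples
    if x.ndim != 1:
        raise ValueError("EMG trace must be a scalar channel")
    n = x.shape[0]
    taps = _bandpass_fir(raw.sampling_rate)
    padlen = min(3 * len(taps), n - 1)
    y = sps.filtfilt(taps, [1.0], x, padlen=padlen)
    # moderate Q: a narrower notch rings for hundreds of samples at the
    # trace edges, which sub-second trials cannot afford
    bn, an = sps.iirnotch(NOTCH_HZ, Q=10.0, fs=raw.sampling_rate)
    y = sps.filtfilt(bn, an, y, padlen=min(int(raw.sampling_rate), n - 1))
    y = y - y.mean()
    return SignalTrace(y, sampling_rate=raw.sampling_rate, units=raw.units)


def _mav_weights(n: int, printed_form: bool = False) -> np.ndarray:
    """Trapezoidal MAV weights for 1-indexed samples i = 1..N.

    w_i = 1 on 0.25N <= i <= 0.75N, 4i/N on the leading quarter and the
    symmetric ramp 4(N-i)/N on the trailing quarter.  ``printed_form``
    switches the trailing branch to 4(i-N)/N, which is negative — kept only
    for compatibility with sources that carry that sign.
    """
    i = np.arange(1, n + 1, dtype=float)
    w = np.ones(n)
    lead = i < 0.25 * n
    trail = i > 0.75 * n
    w[lead] = 4.0 * i[lead] / n
    w[trail] = (4.0 * (i[trail] - n) / n) if printed_form else (4.0 * (n - i[trail]) / n)
    return w


def emg_mav(x: SignalTrace, printed_weights: bool = False) -> float:
    """Weighted mean absolute value: ``(1/N) sum w_i |x_i|``.

    In the continuous limit the weight function integrates to 0.75, so a
    rectified-constant signal of amplitude 1 maps to 0.75.
    """
    if x.n_samples < 4:
        raise ValueError("MAV needs at least 4 samples")
    s = np.abs(np.asarray(x.samples, dtype=float))
    if s.ndim != 1:
        raise ValueError("MAV expects a scalar channel")
    w = _mav_weights(s.shape[0], printed_form=printed_weights)
    return float(np.mean(w * s))


def emg_rms(x: SignalTrace, envelope_smoothing: bool = True) -> float:
    """RMS of the rectified envelope: rectify, 2 ms moving average, then
    ``sqrt((1/N) sum e_i^2)`` over the smoothed envelope.

    The moving-average window is ``round(0.002 * rate)`` samples; windows
    shorter than 2 samples or not shorter than the trace are degenerate and
    skipped (the RMS is then taken over the raw rectified signal).
    ``envelope_smoothing=False`` applies the quadratic-mean formula directly
    to the rectified samples.
    """
    s = np.abs(np.asarray(x.samples, dtype=float))
    if s.ndim != 1:
        raise ValueError("RMS expects a scalar channel")
    w = int(round(0.002 * x.sampling_rate))
    if envelope_smoothing and 2 <= w < s.shape[0]:
        # edge-replicating average so boundary samples are not zero-padded
        s = uniform_filter1d(s, size=w, mode="nearest")
    return float(math.sqrt(np.mean(s**2)))


def mvic_normalize(value: float, mvic: float) -> float:
    """Express an EMG amplitude as a fraction of the MVIC reference."""
    if not mvic > 0:
        raise ValueError(f"MVIC reference must be > 0, got {mvic}")
    return value / mvic


def _lowpass_linear_phase(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    """Zero-phase low-pass used for GSR conditioning and PPG envelopes."""
    if x.shape[0] < 12 or cutoff >= rate / 2:
        return x
    b, a = sps.butter(2, cutoff / (rate / 2))
    return sps.filtfilt(b, a, x, padlen=min(12, x.shape[0] - 1))


def gsr_variance(gsr: SignalTrace, baseline_range: float) -> float:
    """SCvr: max-min range of the 5 Hz low-passed conductance trace, divided
    by the subject's baseline-session range (both in uS)."""
    if not baseline_range > 0:
        raise ValueError(f"baseline range must be > 0, got {baseline_range}")
    x = np.asarray(gsr.samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("GSR trace must be a scalar channel")
    y = _lowpass_linear_phase(x, gsr.sampling_rate, 5.0)
    return float((y.max() - y.min()) / baseline_range)


def detect_ppg_peaks(ppg: SignalTrace) -> np.ndarray:
    """Indices of systolic peaks on the low-passed PPG envelope.

    Minimum peak spacing 0.33 s (a ~180 bpm physiological ceiling) and a
    prominence floor relative to the envelope spread suppress noise peaks.
    """
    x = np.asarray(ppg.samples, dtype=float)
    env = _lowpass_linear_phase(x, ppg.sampling_rate, 8.0)
    spread = env.max() - env.min()
    peaks, _ = sps.find_peaks(
        env,
        distance=max(1, int(round(0.33 * ppg.sampling_rate))),
        prominence=0.2 * spread if spread > 0 else None,
    )
    return peaks


def heart_rate_from_ppg(ppg: SignalTrace, rest_heart_rate: float) -> float:
    """Heart rate from mean peak-to-peak interval, over the resting rate.

    ``HR = 60 / mean(PPI)`` bpm; returns ``HR / rest_heart_rate``.  Raises if
    fewer than two pulse peaks are detectable.
    """
    if not rest_heart_rate > 0:
        raise ValueError("resting heart rate must be > 0")
    peaks = detect_ppg_peaks(ppg)
    if peaks.shape[0] < 2:
        raise ValueError("fewer than 2 pulse peaks detected; trace unusable")
    ppi = np.diff(peaks) / ppg.sampling_rate
    hr = 60.0 / float(np.mean(ppi))
    return hr / rest_heart_rate


def eeg_state_metrics(record: TrialRecord) -> dict:
    """Validated pass-through of the five cognitive-state probabilities."""
    out = {}
    for name in EEG_STATES:
        p = record.eeg_states.get(name)
        if p is None:
            raise ValueError(f"EEG state {name} missing from record")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"EEG state {name} outside [0, 1]: {p}")
        out[name] = float(p)
    return out


def extract_emg_features(
    raw: SignalTrace, mvic: float, muscle: str, printed_weights: bool = False
) -> EmgFeatureResult:
    """Condition one EMG channel and return its MVIC-normalized MAV and RMS."""
    conditioned = preprocess_emg(raw)
    return EmgFeatureResult(
        mav=mvic_normalize(emg_mav(conditioned, printed_weights=printed_weights), mvic),
        rms=mvic_normalize(emg_rms(conditioned), mvic),
        muscle=muscle,
    )
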