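"""Kinematic motion metrics in task space and user (limb) space.

Task-space metrics come from the tool trajectory: path straight deviation
(mean perpendicular distance of samples from the start-to-end line) and path
efficiency (traveled path length over straight-line distance).  User-space
metrics come from the limb IMUs: mean angular-velocity magnitude, mean
gravity-removed linear-acceleration magnitude, and the RMS magnitude of jerk

    J = sqrt(x'''(t)^2 + y'''(t)^2 + z'''(t)^2),

a movement-smoothness measure.  Derivatives are taken with Savitzky-Golay
local-polynomial filters (polyorder 5), which differentiate and low-pass in
one step and are exact for polynomial trajectories up to degree 5 —
including at the trace boundaries, where plain central differences degrade.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import savgol_filter

from .trace import SignalTrace

__all__ = [
    "path_straight_deviation",
    "path_efficiency",
    "jerk_rms",
    "jerk_rms_from_acceleration",
    "mean_angular_velocity",
    "mean_linear_acceleration",
]


def _positions(traj) -> np.ndarray:
    pos = traj.samples if isinstance(traj, SignalTrace) else np.asarray(traj, float)
    if pos.ndim != 2 or pos.shape[1] not in (2, 3):
        raise ValueError("trajectory must be (n, 2) or (n, 3) positions")
    if pos.shape[0] < 2:
        raise ValueError("trajectory needs at least 2 samples")
    if pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(pos.shape[0])])
    return pos


def path_straight_deviation(traj) -> float:
    """Mean perpendicular distance of samples from the start-to-end line.

    ``(1/n) * sum_{i=1..n} ||p0pi x a|| / ||a||`` with reach axis
    ``a = p_n - p_0``; the start point is the reference and is excluded from
    the average, the endpoint contributes its identically-zero deviation.
    Raises when start and end coincide (undefined axis).
    """
    pos = _positions(traj)
    axis = pos[-1] - pos[0]
    norm = float(np.linalg.norm(axis))
    if norm == 0.0:
        raise ValueError("zero reach axis: start and end positions coincide")
    rel = pos[1:] - pos[0]
    dists = np.linalg.norm(np.cross(rel, axis), axis=-1) / norm
    return float(np.mean(dists))


def path_efficiency(traj) -> float:
    """Traveled path length over straight-line start-to-end distance (>= 1)."""
    pos = _positions(traj)
    straight = float(np.linalg.norm(pos[-1] - pos[0]))
    if straight == 0.0:
        raise ValueError("zero straight-line distance: ratio undefined")
    seglen = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(seglen.sum() / straight)


def _time_mean(values: np.ndarray, rate: float) -> float:
    """Trapezoidal time average (1/T) * integral, so the half-weighted
    endpoints do not bias short traces."""
    n = values.shape[0]
    return float(np.trapezoid(values, dx=1.0 / rate) / ((n - 1) / rate))


def _savgol_window(n: int, rate: float) -> int:
    # ~0.15 s of support, at least 7 samples, odd, and within the trace.
    w = max(7, int(round(0.15 * rate)) | 1)
    if w > n:
        w = n if n % 2 == 1 else n - 1
    return w


def jerk_rms(traj: SignalTrace) -> float:
    """RMS magnitude of jerk (third position derivative) over a trajectory.

    Units follow the position units per s^3 (mm/s^3 for tool paths).
    Requires at least 7 samples.
    """
    pos = _positions(traj)
    n = pos.shape[0]
    if n < 7:
        raise ValueError("jerk needs at least 7 samples")
    rate = traj.sampling_rate
    w = _savgol_window(n, rate)
    third = np.column_stack(
        [
            savgol_filter(pos[:, k], w, polyorder=5, deriv=3, delta=1.0 / rate)
            for k in range(3)
        ]
    )
    j2 = np.sum(third**2, axis=1)
    return float(math.sqrt(_time_mean(j2, rate)))


def jerk_rms_from_acceleration(imu: SignalTrace) -> float:
    """RMS jerk magnitude from a 3-axis accelerometer trace (m/s^3).

    Jerk is the first time derivative of the gravity-removed acceleration;
    the per-axis trial mean (gravity plus static bias) is subtracted first.
    """
    acc = np.asarray(imu.samples, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("accelerometer trace must be (n, 3)")
    n = acc.shape[0]
    if n < 7:
        raise ValueError("jerk needs at least 7 samples")
    acc = acc - acc.mean(axis=0, keepdims=True)
    rate = imu.sampling_rate
    w = _savgol_window(n, rate)
    order = min(5, w - 2)
    deriv = np.column_stack(
        [
            savgol_filter(acc[:, k], w, polyorder=order, deriv=1, delta=1.0 / rate)
            for k in range(3)
        ]
    )
    j2 = np.sum(deriv**2, axis=1)
    return float(math.sqrt(_time_mean(j2, rate)))


def mean_angular_velocity(imu: SignalTrace) -> float:
    """Mean magnitude of the 3-axis gyroscope reading, rad/s."""
    w = np.asarray(imu.samples, dtype=float)
    if w.ndim != 2 or w.shape[1] != 3:
        raise ValueError("gyroscope trace must be (n, 3)")
    return float(np.mean(np.linalg.norm(w, axis=1)))


def mean_linear_acceleration(imu: SignalTrace) -> float:
    """Mean magnitude of gravity-removed linear acceleration, m/s^2.

    The per-axis mean over the trial (gravity plus static sensor bias, for a
    roughly constant limb orientation) is subtracted before taking
    magnitudes, so the result is invariant to any constant offset vector.
    """
    acc = np.asarray(imu.samples, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("accelerometer trace must be (n, 3)")
    resid = acc - acc.mean(axis=0, keepdims=True)
    return float(np.mean(np.linalg.norm(resid, axis=1)))
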