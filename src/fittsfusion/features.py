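"""Per-trial feature extraction into the 20-metric feature table.

One row per trial: identifier columns (subject, block, repetition, D, W,
ID) followed by the candidate metrics — EMG MAV/RMS per muscle relative to
MVIC, the five EEG state probabilities, SCvr, normalized heart rate, the
eight motion-kinematic metrics, and movement time.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from . import kinematics as kin
from . import physio
from .screening import ALL_METRICS
from .synthetic import TrialRecord

__all__ = ["extract_trial_features", "build_feature_table", "ID_COLUMNS"]

ID_COLUMNS = ("subject", "block", "repetition", "D", "W", "ID")


def extract_trial_features(record: TrialRecord) -> dict:
    """Compute all candidate metrics for one trial."""
    b = record.baselines
    pectm = physio.extract_emg_features(record.emg_pectm, b.mvic_pectm, "PectM")
    postd = physio.extract_emg_features(record.emg_postd, b.mvic_postd, "PostD")
    eeg = physio.eeg_state_metrics(record)

    row = {
        "subject": record.subject_id,
        "block": record.block,
        "repetition": record.repetition,
        "D": record.condition.distance,
        "W": record.condition.width,
        "ID": record.condition.difficulty,
        "PostD_rms": postd.rms,
        "PectM_rms": pectm.rms,
        "PostD_MAV": postd.mav,
        "PectM_MAV": pectm.mav,
        **eeg,
        "SC_vr": physio.gsr_variance(record.gsr, b.sc_baseline_range),
        "HR": physio.heart_rate_from_ppg(record.ppg, b.rest_heart_rate),
        "AngVel_FA": kin.mean_angular_velocity(record.imu_forearm_gyro),
        "AngVel_UA": kin.mean_angular_velocity(record.imu_upperarm_gyro),
        "LinAcc_FA": kin.mean_linear_acceleration(record.imu_forearm_accel),
        "LinAcc_UA": kin.mean_linear_acceleration(record.imu_upperarm_accel),
        "Jerk_FA": kin.jerk_rms_from_acceleration(record.imu_forearm_accel),
        "Jerk_UA": kin.jerk_rms_from_acceleration(record.imu_upperarm_accel),
        "PathStrDev": kin.path_straight_deviation(record.trajectory),
        "PathEff": kin.path_efficiency(record.trajectory),
        "MT": record.movement_time,
    }
    return row


def build_feature_table(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Feature rows for a trial collection, columns in canonical order."""
    rows = [extract_trial_features(r) for r in records]
    df = pd.DataFrame(rows)
    return df[list(ID_COLUMNS) + list(ALL_METRICS)]
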