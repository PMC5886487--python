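"""Delimited-text persistence for trial datasets and pipeline tables.

Each trial writes one CSV file per channel group (trajectory, forearm IMU,
upper-arm IMU, EMG, GSR, PPG) with ``#``-prefixed header lines stating the
channel names, sampling rate, and units, followed by the sample rows.  A
dataset manifest table ties the files to subject/block/repetition, the
condition geometry (D, W, ID), movement time, EEG state probabilities, and
the subject baselines, so a dataset on disk round-trips into the same
in-memory records the extractors consume.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .synthetic import (
    EEG_STATES,
    FittsCondition,
    SubjectBaselines,
    SynthConfig,
    TrialRecord,
)
from .trace import SignalTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_dataset",
    "read_dataset",
    "write_config",
    "read_config",
]

# channel-group name -> (record attribute(s), column names)
_CHANNEL_GROUPS = {
    "trajectory": (("trajectory",), ("x", "y", "z")),
    "imu_fa": (("imu_forearm_gyro", "imu_forearm_accel"),
               ("gx", "gy", "gz", "ax", "ay", "az")),
    "imu_ua": (("imu_upperarm_gyro", "imu_upperarm_accel"),
               ("gx", "gy", "gz", "ax", "ay", "az")),
    "emg": (("emg_pectm", "emg_postd"), ("PectM", "PostD")),
    "gsr": (("gsr",), ("gsr",)),
    "ppg": (("ppg",), ("ppg",)),
}


def write_trace(path: Path, traces: list[SignalTrace], columns: list[str]) -> None:
    """Write one channel-group file: header comments + CSV sample rows."""
    arrays = []
    for t in traces:
        a = t.samples
        arrays.append(a[:, None] if a.ndim == 1 else a)
    data = np.hstack(arrays)
    if data.shape[1] != len(columns):
        raise ValueError("column names do not match trace dimensions")
    rate = traces[0].sampling_rate
    units = ";".join(t.units for t in traces)
    with open(path, "w") as fh:
        fh.write(f"# channels: {','.join(columns)}\n")
        fh.write(f"# sampling_rate_hz: {rate!r}\n")
        fh.write(f"# units: {units}\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.10g")


def read_trace(path: Path) -> tuple[np.ndarray, float, list[str], list[str]]:
    """Read a channel-group file -> (data, rate, column names, units)."""
    header: dict[str, str] = {}
    with open(path) as fh:
        body_start = 0
        lines = fh.readlines()
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, val = line.lstrip("# ").partition(":")
        header[key.strip()] = val.strip()
    data = np.loadtxt(_io.StringIO("".join(lines[body_start:])), delimiter=",")
    data = np.atleast_2d(data)
    if data.shape[0] == 1 and data.shape[1] > len(header["channels"].split(",")):
        data = data.T
    return (
        data,
        float(header["sampling_rate_hz"].strip("'\"")),
        header["channels"].split(","),
        header["units"].split(";"),
    )


def _trial_stem(r: TrialRecord) -> str:
    return f"s{r.subject_id:02d}_b{r.block}_r{r.repetition}_d{int(r.condition.distance)}"


def write_dataset(records: Iterable[TrialRecord], outdir: str | Path) -> pd.DataFrame:
    """Write per-trial channel files plus ``manifest.csv``; returns the manifest."""
    outdir = Path(outdir)
    trials = outdir / "trials"
    trials.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        stem = _trial_stem(r)
        paths = {}
        for group, (attrs, cols) in _CHANNEL_GROUPS.items():
            path = trials / f"{stem}_{group}.csv"
            write_trace(path, [getattr(r, a) for a in attrs], list(cols))
            paths[group] = str(path.relative_to(outdir))
        rows.append(
            {
                "subject": r.subject_id,
                "block": r.block,
                "repetition": r.repetition,
                "D": r.condition.distance,
                "W": r.condition.width,
                "ID": r.condition.difficulty,
                "MT": r.movement_time,
                **{name: r.eeg_states[name] for name in EEG_STATES},
                "mvic_pectm": r.baselines.mvic_pectm,
                "mvic_postd": r.baselines.mvic_postd,
                "rest_heart_rate": r.baselines.rest_heart_rate,
                "sc_baseline_range": r.baselines.sc_baseline_range,
                **{f"file_{g}": p for g, p in paths.items()},
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_dataset(outdir: str | Path) -> list[TrialRecord]:
    """Rebuild TrialRecords from a written dataset directory."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        traces = {}
        for group, (attrs, cols) in _CHANNEL_GROUPS.items():
            data, rate, _, units = read_trace(outdir / row[f"file_{group}"])
            ulist = units + [""] * len(attrs)
            if len(attrs) == 2 and len(cols) == 6:  # gyro + accel triplets
                traces[attrs[0]] = SignalTrace(data[:, :3], rate, ulist[0])
                traces[attrs[1]] = SignalTrace(data[:, 3:], rate, ulist[1])
            elif len(attrs) == 2:  # two scalar EMG channels
                traces[attrs[0]] = SignalTrace(data[:, 0], rate, ulist[0])
                traces[attrs[1]] = SignalTrace(data[:, 1], rate, ulist[1])
            elif data.shape[1] == 1:
                traces[attrs[0]] = SignalTrace(data[:, 0], rate, ulist[0])
            else:
                traces[attrs[0]] = SignalTrace(data, rate, ulist[0])
        records.append(
            TrialRecord(
                subject_id=int(row["subject"]),
                block=int(row["block"]),
                repetition=int(row["repetition"]),
                condition=FittsCondition(float(row["D"]), float(row["W"])),
                movement_time=float(row["MT"]),
                eeg_states={name: float(row[name]) for name in EEG_STATES},
                baselines=SubjectBaselines(
                    mvic_pectm=float(row["mvic_pectm"]),
                    mvic_postd=float(row["mvic_postd"]),
                    rest_heart_rate=float(row["rest_heart_rate"]),
                    sc_baseline_range=float(row["sc_baseline_range"]),
                ),
                **traces,
            )
        )
    return records


def write_config(config: SynthConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_config(path: str | Path) -> SynthConfig:
    with open(path) as fh:
        return SynthConfig.from_dict(yaml.safe_load(fh))
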