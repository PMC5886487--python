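"""Synthetic multimodal Fitts-task trial generator.

Emulates a bivariate target-reaching study on a haptic interface: 14 subjects
perform reaches to targets of width W = 5 mm at distances D in
{10, 20, 40, 80, 180, 320} mm, five repetitions per condition in randomized
blocks, giving indices of difficulty ID = log2(2D/W) from 2 to 7 bits.
Every trial carries the full multimodal record the downstream feature
extractors consume:

* movement time following Fitts' law MT = a + b*ID plus noise,
* a 2-D tool trajectory (minimum-jerk backbone plus low-pass perturbation
  whose amplitude grows with ID, so straightness degrades with difficulty),
* forearm / upper-arm IMU channels (3-axis angular velocity and linear
  acceleration including gravity) derived from the reach profile,
* two surface-EMG channels (pectoralis major, posterior deltoid) whose
  envelope amplitude rises with ID, expressed relative to per-subject MVIC,
* a skin-conductance (GSR) drift whose max-min range rises with ID,
* a quasi-periodic fingertip PPG pulse train at a heart rate rising with ID,
* five EEG cognitive-state probabilities (pass-through metrics), and
* per-subject baselines (MVIC per muscle, resting HR, baseline SC range).

The whole dataset is a pure function of (config, master seed): one master
seed spawns per-subject and per-trial child seeds by a fixed splitting rule,
so any subset regenerates identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .trace import SignalTrace

__all__ = [
    "index_of_difficulty",
    "sample_movement_time",
    "minimum_jerk_trajectory",
    "synth_ppg",
    "generate_trial",
    "generate_dataset",
    "make_subject",
    "FittsCondition",
    "FittsLawParams",
    "SamplingRates",
    "ResponseSlopes",
    "SubjectVariation",
    "SynthConfig",
    "SubjectBaselines",
    "SubjectProfile",
    "TrialRecord",
    "EEG_STATES",
]

EEG_STATES = ("Engagement", "Workload", "Distraction", "SleepOnset", "HeadMvL")

#: standard gravity, m/s^2
G = 9.80665


# ---------------------------------------------------------------------------
# Fitts geometry and movement-time law
# ---------------------------------------------------------------------------

def index_of_difficulty(distance: float, width: float) -> float:
    """Fitts index of difficulty ID = log2(2D/W) in bits.

    Parameters
    ----------
    distance
        Centre-to-centre target distance D, mm (or any unit shared with W).
    width
        Target width W, same unit.
    """
    if not distance > 0:
        raise ValueError(f"target distance must be > 0, got {distance}")
    if not width > 0:
        raise ValueError(f"target width must be > 0, got {width}")
    return math.log2(2.0 * distance / width)


@dataclass(frozen=True)
class FittsCondition:
    """One task-difficulty condition: target distance D and width W (mm)."""

    distance: float
    width: float

    def __post_init__(self) -> None:
        if not self.distance > 0 or not self.width > 0:
            raise ValueError("FittsCondition requires positive D and W")

    @property
    def difficulty(self) -> float:
        """Index of difficulty in bits, log2(2D/W)."""
        return index_of_difficulty(self.distance, self.width)


@dataclass(frozen=True)
class FittsLawParams:
    """Parameters of MT = a + b*ID: intercept a (s), slope b (s/bit), and
    the SD of the zero-mean Gaussian trial noise on MT (s)."""

    intercept: float = 0.35
    slope: float = 0.22
    mt_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("Fitts slope b must be > 0")
        if self.mt_noise_sd < 0:
            raise ValueError("mt_noise_sd must be >= 0")


def sample_movement_time(
    params: FittsLawParams, difficulty: float, rng: np.random.Generator
) -> float:
    """Draw one movement time MT = a + b*ID + eps, truncated to stay positive.

    ``eps ~ Normal(0, mt_noise_sd^2)``; draws are clipped from below at a
    small positive floor (0.1 s) so downstream traces are never empty.
    """
    if not difficulty > 0:
        raise ValueError(f"difficulty must be > 0, got {difficulty}")
    mt = params.intercept + params.slope * difficulty
    if params.mt_noise_sd > 0:
        mt += params.mt_noise_sd * rng.standard_normal()
    return max(mt, 0.1)


# ---------------------------------------------------------------------------
# Minimum-jerk reach backbone
# ---------------------------------------------------------------------------

def minimum_jerk_trajectory(
    p0: Sequence[float], pf: Sequence[float], movement_time: float, rate: float
) -> SignalTrace:
    """Straight point-to-point reach with the minimum-jerk time profile.

    Position follows ``p(tau) = p0 + (pf - p0)(10 tau^3 - 15 tau^4 + 6 tau^5)``
    with ``tau = t / MT``: endpoints are met exactly and endpoint velocity and
    acceleration vanish.  Coincident endpoints yield a constant trace.
    """
    if not movement_time > 0:
        raise ValueError("movement_time must be > 0")
    if not rate > 0:
        raise ValueError("rate must be > 0")
    p0 = np.asarray(p0, dtype=float)
    pf = np.asarray(pf, dtype=float)
    n = max(int(round(movement_time * rate)) + 1, 2)
    tau = np.linspace(0.0, 1.0, n)
    s = 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5
    pos = p0[None, :] + s[:, None] * (pf - p0)[None, :]
    return SignalTrace(pos, sampling_rate=(n - 1) / movement_time, units="mm")


def _minjerk_speed_shape(tau: np.ndarray) -> np.ndarray:
    """ds/dtau of the minimum-jerk profile: 30 tau^2 - 60 tau^3 + 30 tau^4."""
    return 30.0 * tau**2 - 60.0 * tau**3 + 30.0 * tau**4


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingRates:
    """Per-channel sampling rates in Hz (EMG and GSR/PPG rates follow the
    wireless acquisition units; the haptic trajectory rate is configurable)."""

    emg: float = 1024.0
    gsr: float = 512.0
    ppg: float = 512.0
    imu: float = 100.0
    trajectory: float = 100.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not v > 0:
                raise ValueError(f"sampling rate {name} must be > 0")


@dataclass(frozen=True)
class ResponseSlopes:
    """How each synthetic channel responds to the index of difficulty.

    EMG activation (fraction of MVIC) is affine in ID per muscle; the
    trajectory perturbation amplitude is ``base * (1 + gamma * ID)`` mm;
    the GSR range (units of the subject baseline range) and heart rate
    (fraction of resting HR) are affine in ID; EEG states are affine in ID
    clipped to [0, 1], with Distraction/SleepOnset/HeadMvL given near-zero
    slope so a correlation screen typically drops them.
    """

    emg_base: float = 0.05
    emg_slope_pectm: float = 0.020
    emg_slope_postd: float = 0.016
    emg_trial_jitter: float = 0.15

    traj_noise_base_mm: float = 0.6
    traj_noise_gamma: float = 0.35
    traj_noise_cutoff_hz: float = 3.0

    gsr_base: float = 0.4
    gsr_slope: float = 0.10
    gsr_jitter: float = 0.45

    hr_slope: float = 0.012
    hr_jitter: float = 0.05
    ppg_beat_jitter: float = 0.02

    # (baseline probability, slope per bit, trial noise SD) per EEG state
    eeg: dict = field(
        default_factory=lambda: {
            "Engagement": (0.35, 0.015, 0.10),
            "Workload": (0.40, 0.016, 0.10),
            "Distraction": (0.20, 0.001, 0.08),
            "SleepOnset": (0.15, 0.000, 0.06),
            "HeadMvL": (0.25, 0.001, 0.09),
        }
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "eeg", {k: tuple(v) for k, v in self.eeg.items()}
        )


@dataclass(frozen=True)
class SubjectVariation:
    """Between-subject heterogeneity: additive SD on the Fitts intercept and
    log-normal multiplicative SDs per metric family, plus baseline spreads."""

    mt_intercept_sd: float = 0.08
    emg_sd: float = 0.25
    imu_sd: float = 0.15
    path_sd: float = 0.20
    mvic_mean_mv: float = 1.5
    mvic_sd: float = 0.30
    rest_hr_mean: float = 68.0
    rest_hr_sd: float = 7.0
    sc_baseline_mean_us: float = 1.0
    sc_baseline_sd: float = 0.30


@dataclass(frozen=True)
class SynthConfig:
    """Full generator configuration; the defaults are the study conditions
    (14 subjects x 6 distances x 5 repetitions, W = 5 mm)."""

    n_subjects: int = 14
    repetitions: int = 5
    distances: tuple = (10.0, 20.0, 40.0, 80.0, 180.0, 320.0)
    target_width: float = 5.0
    rates: SamplingRates = field(default_factory=SamplingRates)
    fitts: FittsLawParams = field(default_factory=FittsLawParams)
    slopes: ResponseSlopes = field(default_factory=ResponseSlopes)
    subject_variation: SubjectVariation = field(default_factory=SubjectVariation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.repetitions < 1:
            raise ValueError("n_subjects and repetitions must be >= 1")
        if len(self.distances) < 1:
            raise ValueError("at least one target distance is required")
        if not self.target_width > 0:
            raise ValueError("target_width must be > 0")
        object.__setattr__(self, "distances", tuple(float(d) for d in self.distances))

    @property
    def conditions(self) -> list[FittsCondition]:
        return [FittsCondition(d, self.target_width) for d in self.distances]

    @property
    def n_trials(self) -> int:
        return self.n_subjects * len(self.distances) * self.repetitions

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distances"] = list(self.distances)
        d["slopes"]["eeg"] = {k: list(v) for k, v in d["slopes"]["eeg"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key, sub in (
            ("rates", SamplingRates),
            ("fitts", FittsLawParams),
            ("slopes", ResponseSlopes),
            ("subject_variation", SubjectVariation),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "distances" in d:
            d["distances"] = tuple(d["distances"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Subjects and trial records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectBaselines:
    """Per-subject calibration session outputs: reference MVIC amplitude per
    muscle (mV), resting heart rate (bpm), and the max-min range of the
    baseline skin-conductance recording (uS)."""

    mvic_pectm: float
    mvic_postd: float
    rest_heart_rate: float
    sc_baseline_range: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not v > 0:
                raise ValueError(f"baseline {name} must be > 0, got {v}")


@dataclass(frozen=True)
class SubjectProfile:
    """A subject's random effects, drawn once per subject: Fitts intercept
    offset and multiplicative (log-normal) factors per metric family."""

    subject_id: int
    baselines: SubjectBaselines
    mt_intercept_offset: float
    emg_factor: float
    imu_factor: float
    path_factor: float


@dataclass(frozen=True)
class TrialRecord:
    """One reaching trial: geometry, movement time, all channel traces, the
    five EEG state probabilities, and the subject's baselines."""

    subject_id: int
    block: int
    repetition: int
    condition: FittsCondition
    movement_time: float
    trajectory: SignalTrace
    imu_forearm_gyro: SignalTrace
    imu_forearm_accel: SignalTrace
    imu_upperarm_gyro: SignalTrace
    imu_upperarm_accel: SignalTrace
    emg_pectm: SignalTrace
    emg_postd: SignalTrace
    gsr: SignalTrace
    ppg: SignalTrace
    eeg_states: dict
    baselines: SubjectBaselines

    def __post_init__(self) -> None:
        if not self.movement_time > 0:
            raise ValueError("movement_time must be > 0")
        for name in EEG_STATES:
            p = self.eeg_states.get(name)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValueError(f"EEG state {name} missing or outside [0, 1]: {p}")


def make_subject(
    config: SynthConfig, subject_id: int, rng: np.random.Generator
) -> SubjectProfile:
    """Draw one subject's baselines and random effects."""
    sv = config.subject_variation
    baselines = SubjectBaselines(
        mvic_pectm=sv.mvic_mean_mv * math.exp(sv.mvic_sd * rng.standard_normal()),
        mvic_postd=sv.mvic_mean_mv * math.exp(sv.mvic_sd * rng.standard_normal()),
        rest_heart_rate=max(40.0, sv.rest_hr_mean + sv.rest_hr_sd * rng.standard_normal()),
        sc_baseline_range=sv.sc_baseline_mean_us
        * math.exp(sv.sc_baseline_sd * rng.standard_normal()),
    )
    return SubjectProfile(
        subject_id=subject_id,
        baselines=baselines,
        mt_intercept_offset=sv.mt_intercept_sd * rng.standard_normal(),
        emg_factor=math.exp(sv.emg_sd * rng.standard_normal()),
        imu_factor=math.exp(sv.imu_sd * rng.standard_normal()),
        path_factor=math.exp(sv.path_sd * rng.standard_normal()),
    )


# ---------------------------------------------------------------------------
# Channel synthesis helpers
# ---------------------------------------------------------------------------

def _lowpass_noise(
    rng: np.random.Generator, n: int, rate: float, cutoff: float
) -> np.ndarray:
    """Unit-SD Gaussian noise low-passed at ``cutoff`` Hz (zero-phase)."""
    x = rng.standard_normal(n)
    if n < 12 or cutoff >= rate / 2:
        return x
    b, a = sps.butter(2, cutoff / (rate / 2))
    y = sps.filtfilt(b, a, x, padlen=min(3 * max(len(a), len(b)), n - 1))
    sd = y.std()
    return y / sd if sd > 0 else y


def synth_ppg(
    heart_rate: float,
    duration: float,
    rate: float,
    rng: np.random.Generator,
    beat_jitter: float = 0.02,
    noise_sd: float = 0.02,
) -> SignalTrace:
    """Quasi-periodic fingertip pulse waveform.

    Gaussian systolic pulses at beat times whose intervals are
    ``(60/hr) * (1 + jitter * N(0,1))``; mean peak-to-peak interval 60/hr.
    Raises if the duration cannot contain at least two beats.
    """
    if not heart_rate > 0:
        raise ValueError("heart rate must be > 0")
    period = 60.0 / heart_rate
    if duration < 2.0 * period:
        raise ValueError(
            f"duration {duration:.2f}s holds fewer than two beats at {heart_rate} bpm"
        )
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    beats = []
    tb = 0.55 * period  # first systolic peak away from the trace edge
    while tb < duration - 0.45 * period:
        beats.append(tb)
        iv = period * (1.0 + beat_jitter * rng.standard_normal())
        tb += max(iv, 0.33)  # physiological cap at ~180 bpm
    beats = np.asarray(beats)
    width = 0.12 * period
    x = np.exp(-0.5 * ((t[:, None] - beats[None, :]) / width) ** 2).sum(axis=1)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return SignalTrace(x, sampling_rate=rate, units="a.u.")


def _synth_emg(
    rng: np.random.Generator,
    movement_time: float,
    rate: float,
    amplitude_mv: float,
) -> SignalTrace:
    """Band-limited (20-450 Hz) stochastic carrier shaped by the reach speed
    profile, normalized so the whole-trial RMS equals ``amplitude_mv``."""
    n = max(int(round(movement_time * rate)) + 1, 64)
    carrier = rng.standard_normal(n)
    ny = rate / 2
    b, a = sps.butter(4, [20.0 / ny, min(450.0, 0.95 * ny) / ny], btype="band")
    carrier = sps.filtfilt(b, a, carrier, padlen=min(3 * 9, n - 1))
    tau = np.linspace(0.0, 1.0, n)
    envelope = 0.25 + _minjerk_speed_shape(tau)  # tonic floor + phasic burst
    x = carrier * envelope
    rms = math.sqrt(float(np.mean(x**2)))
    x *= amplitude_mv / rms
    return SignalTrace(x, sampling_rate=rate, units="mV")


def _synth_gsr(
    rng: np.random.Generator,
    duration: float,
    rate: float,
    rng_range_us: float,
    noise_sd_us: float = 0.005,
) -> SignalTrace:
    """Slow tonic drift whose max-min range equals ``rng_range_us``."""
    n = int(round(duration * rate))
    t = np.linspace(0.0, 1.0, n)
    shape = np.sin(np.pi * t)  # rises and recovers within the trial window
    x = 2.0 + rng_range_us * shape
    if noise_sd_us > 0:
        x = x + noise_sd_us * _lowpass_noise(rng, n, rate, 1.0)
    return SignalTrace(x, sampling_rate=rate, units="uS")


def _synth_imu(
    rng: np.random.Generator,
    trajectory: SignalTrace,
    rate: float,
    scale: float,
    arm_length_m: float = 0.35,
    gyro_noise_sd: float = 0.01,
    accel_noise_sd: float = 0.0025,
) -> tuple[SignalTrace, SignalTrace]:
    """Limb IMU pair (gyro rad/s, accel m/s^2) tracking the tool trajectory.

    The limb follows the (perturbed) end-effector path scaled by ``scale``,
    so corrective submovements carry into limb acceleration and jerk.
    Angular velocity is tangential speed over an effective arm length;
    acceleration is the second derivative of limb position plus gravity on
    z.  Both channels carry low-passed sensor noise.
    """
    t_src = trajectory.times
    duration = t_src[-1]
    n = max(int(round(duration * rate)) + 1, 8)
    t = np.linspace(0.0, duration, n)
    pos = np.column_stack(
        [np.interp(t, t_src, trajectory.samples[:, k]) for k in range(3)]
    )
    pos_m = scale * pos / 1000.0
    vel = np.gradient(pos_m, t, axis=0)
    acc_dyn = np.gradient(vel, t, axis=0)

    gyro = np.zeros((n, 3))
    gyro[:, 2] = np.linalg.norm(vel, axis=1) / arm_length_m
    gyro += gyro_noise_sd * np.column_stack(
        [_lowpass_noise(rng, n, rate, 8.0) for _ in range(3)]
    )

    acc = acc_dyn.copy()
    acc[:, 2] += G
    acc += accel_noise_sd * np.column_stack(
        [_lowpass_noise(rng, n, rate, 8.0) for _ in range(3)]
    )
    return (
        SignalTrace(gyro, sampling_rate=rate, units="rad/s"),
        SignalTrace(acc, sampling_rate=rate, units="m/s^2"),
    )


# ---------------------------------------------------------------------------
# Trial and dataset generation
# ---------------------------------------------------------------------------

def generate_trial(
    config: SynthConfig,
    subject: SubjectProfile,
    condition: FittsCondition,
    rng: np.random.Generator,
    block: int = 0,
    repetition: int = 0,
) -> TrialRecord:
    """Synthesize one complete multimodal trial for one subject/condition."""
    sl = config.slopes
    rates = config.rates
    difficulty = condition.difficulty

    params = FittsLawParams(
        intercept=config.fitts.intercept + subject.mt_intercept_offset,
        slope=config.fitts.slope,
        mt_noise_sd=config.fitts.mt_noise_sd,
    )
    mt = sample_movement_time(params, difficulty, rng)

    # --- tool trajectory: minimum-jerk backbone + orthogonal perturbation
    backbone = minimum_jerk_trajectory(
        (0.0, 0.0, 0.0), (condition.distance, 0.0, 0.0), mt, rates.trajectory
    )
    pos = backbone.samples.copy()
    n = pos.shape[0]
    amp = sl.traj_noise_base_mm * (1.0 + sl.traj_noise_gamma * difficulty)
    amp *= subject.path_factor
    if amp > 0:
        tau = np.linspace(0.0, 1.0, n)
        wiggle = _lowpass_noise(rng, n, backbone.sampling_rate, sl.traj_noise_cutoff_hz)
        pos[:, 1] += amp * np.sin(np.pi * tau) * wiggle  # endpoints stay exact
    trajectory = SignalTrace(pos, sampling_rate=backbone.sampling_rate, units="mm")

    # --- limb IMUs: forearm follows the tool closely, upper arm moves less
    fa_scale = 0.9 * subject.imu_factor * math.exp(0.05 * rng.standard_normal())
    ua_scale = 0.45 * subject.imu_factor * math.exp(0.05 * rng.standard_normal())
    fa_gyro, fa_acc = _synth_imu(rng, trajectory, rates.imu, fa_scale)
    ua_gyro, ua_acc = _synth_imu(rng, trajectory, rates.imu, ua_scale)

    # --- EMG: activation affine in ID, relative to the subject's MVIC
    def activation(slope: float) -> float:
        jit = math.exp(sl.emg_trial_jitter * rng.standard_normal()) if sl.emg_trial_jitter else 1.0
        return (sl.emg_base + slope * difficulty) * subject.emg_factor * jit

    emg_pectm = _synth_emg(
        rng, mt, rates.emg, activation(sl.emg_slope_pectm) * subject.baselines.mvic_pectm
    )
    emg_postd = _synth_emg(
        rng, mt, rates.emg, activation(sl.emg_slope_postd) * subject.baselines.mvic_postd
    )

    # --- physiological slow channels span the reach plus surrounding rest
    physio_window = mt + 4.0
    gsr_jit = math.exp(sl.gsr_jitter * rng.standard_normal()) if sl.gsr_jitter else 1.0
    gsr_range = (sl.gsr_base + sl.gsr_slope * difficulty) * gsr_jit
    gsr = _synth_gsr(
        rng, physio_window, rates.gsr, gsr_range * subject.baselines.sc_baseline_range
    )

    hr = subject.baselines.rest_heart_rate * (
        1.0 + sl.hr_slope * difficulty + sl.hr_jitter * rng.standard_normal()
    )
    hr = max(hr, 40.0)
    ppg = synth_ppg(hr, physio_window, rates.ppg, rng, beat_jitter=sl.ppg_beat_jitter)

    eeg = {
        name: float(np.clip(base + slope * difficulty + sd * rng.standard_normal(), 0, 1))
        for name, (base, slope, sd) in sl.eeg.items()
    }

    return TrialRecord(
        subject_id=subject.subject_id,
        block=block,
        repetition=repetition,
        condition=condition,
        movement_time=mt,
        trajectory=trajectory,
        imu_forearm_gyro=fa_gyro,
        imu_forearm_accel=fa_acc,
        imu_upperarm_gyro=ua_gyro,
        imu_upperarm_accel=ua_acc,
        emg_pectm=emg_pectm,
        emg_postd=emg_postd,
        gsr=gsr,
        ppg=ppg,
        eeg_states=eeg,
        baselines=subject.baselines,
    )


def _subject_seed(config: SynthConfig, subject_idx: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(config.seed, spawn_key=(subject_idx,))


def _trial_seed(
    config: SynthConfig, subject_idx: int, block: int, slot: int
) -> np.random.SeedSequence:
    return np.random.SeedSequence(config.seed, spawn_key=(subject_idx, block, slot))


def generate_dataset(config: SynthConfig) -> list[TrialRecord]:
    """Generate the full trial collection for a configuration.

    ``n_subjects * len(distances) * repetitions`` records; each repetition is
    one randomized block containing every condition once (randomized, blocked
    design).  Reproducible byte-for-byte under a fixed master seed: subject
    profiles and trial channels draw from child seeds keyed by
    (subject, block, within-block slot).
    """
    records: list[TrialRecord] = []
    conditions = config.conditions
    for s_idx in range(config.n_subjects):
        subj_rng = np.random.default_rng(_subject_seed(config, s_idx))
        subject = make_subject(config, s_idx, subj_rng)
        for block in range(config.repetitions):
            order = subj_rng.permutation(len(conditions))
            for slot, c_idx in enumerate(order):
                trial_rng = np.random.default_rng(
                    _trial_seed(config, s_idx, block, slot)
                )
                records.append(
                    generate_trial(
                        config,
                        subject,
                        conditions[int(c_idx)],
                        trial_rng,
                        block=block,
                        repetition=block,
                    )
                )
    return records
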