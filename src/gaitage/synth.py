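"""Synthetic trunk-IMU cohorts with ground truth.

The generator emulates the study design the pipeline targets: an elderly
cohort (default 136 subjects aged 60-90, 36/64/36 in their 60s/70s/80s,
33 M / 103 F) in which each subject performs three timed-up-and-go (TUG)
trials and one six-minute walk test (6MWT), recorded by a single trunk IMU
at 100 Hz.

Gait acceleration is a harmonic-sum model.  With step frequency
``f_step = 1/step_time`` and stride frequency ``f_step / 2``:

    acc_vt(t) = A * [ sin(2 pi f_step t)
                      + beta  * sin(pi f_step t)          (asymmetry)
                      + gamma * sin(3 pi f_step t) ]      (roughness)
                + N(0, noise_sd)

``beta`` injects stride-frequency energy that makes alternating (left/right)
steps unequal, which suppresses the step-lag autocorrelation peak and any
even-harmonic dominance; ``gamma`` injects a higher odd stride harmonic that
lowers the harmonic ratio of the vertical axis.  Mediolateral acceleration
is dominated by the stride frequency, as in real trunk accelerometry.

TUG trials are built from half-sine angular-velocity pulses: two pitch
pulses (chair rise/sit) and two yaw pulses (the two turns), with gait
acceleration in between.  Ground-truth event intervals are the analytic
spans where the noise-free pulse exceeds the detection threshold, so the
segmentation stage can be scored against them directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .io_config import ImuRecording, SubjectMeta, TestType, TUG_SUBTASKS

#: detection thresholds the generated pulses must clear, deg/s
PITCH_THRESHOLD = 25.0
YAW_THRESHOLD = 32.0


@dataclass
class GaitModelParams:
    """Latent gait parameters of one subject.

    step_time         time between successive (left/right) steps, s
    acc_amp           amplitude of the vertical step harmonic, m/s^2
    asymmetry         beta in [0, 1): relative stride-frequency amplitude
    roughness         gamma >= 0: relative high-harmonic amplitude
    noise_sd          white acceleration noise, m/s^2
    gyro_noise_sd     white angular-velocity noise, deg/s
    gait_speed        over-ground speed used for TUG walk durations, m/s
    turn_peak_yaw     peak yaw rate of TUG turns, deg/s (must exceed 32)
    chair_peak_pitch  peak pitch rate of chair transfers, deg/s (must exceed 25)
    """

    step_time: float = 0.55
    acc_amp: float = 1.3
    asymmetry: float = 0.10
    roughness: float = 0.10
    noise_sd: float = 0.08
    gyro_noise_sd: float = 0.5
    gait_speed: float = 1.05
    turn_peak_yaw: float = 75.0
    chair_peak_pitch: float = 60.0

    def __post_init__(self) -> None:
        if self.step_time <= 0:
            raise ParameterError(f"step_time must be positive, got {self.step_time}")
        if not 0 <= self.asymmetry < 1:
            raise ParameterError(f"asymmetry must be in [0, 1), got {self.asymmetry}")
        if self.roughness < 0 or self.noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ParameterError("roughness and noise levels must be non-negative")
        if self.gait_speed <= 0:
            raise ParameterError("gait_speed must be positive")


@dataclass
class GroundTruth:
    """What the generator actually put into a recording."""

    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    step_times: np.ndarray | None = None
    params: GaitModelParams | None = None


@dataclass
class CohortSpec:
    """Cohort composition; defaults emulate the target study population."""

    n_subjects: int = 136
    group_counts: tuple[int, int, int] = (36, 64, 36)  # 60s / 70s / 80s
    sex_counts: tuple[int, int] = (33, 103)            # M / F
    tug_trials_per_subject: int = 3
    sixmwt_duration_s: float = 360.0
    fs: float = 100.0
    height_mean_cm: dict[str, float] = field(
        default_factory=lambda: {"M": 166.0, "F": 153.0})
    height_sd_cm: float = 5.5

    def __post_init__(self) -> None:
        if sum(self.group_counts) != self.n_subjects:
            raise ParameterError(
                f"group counts {self.group_counts} must sum to {self.n_subjects}")
        if sum(self.sex_counts) != self.n_subjects:
            raise ParameterError(
                f"sex counts {self.sex_counts} must sum to {self.n_subjects}")


@dataclass
class AgeCoupling:
    """Linear age -> gait-parameter maps with subject-level scatter.

    Each entry is (value at age 60, change per year).  ``noise_sd`` gives
    the between-subject standard deviation of each parameter around its
    age trend; ``noise_scale`` rescales all of them at once (0 disables
    subject-level scatter).
    """

    slopes: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "step_time":        (0.50, 0.005),    # slows with age
        "acc_amp":          (1.55, -0.015),   # weaker push-off with age
        "asymmetry":        (0.05, 0.006),    # gait becomes less symmetric
        "roughness":        (0.05, 0.006),    # gait becomes less smooth
        "gait_speed":       (1.25, -0.015),   # m/s
        "turn_peak_yaw":    (90.0, -1.0),     # slower turning
        "chair_peak_pitch": (72.0, -0.8),     # slower chair transfer
    })
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "step_time": 0.02, "acc_amp": 0.08, "asymmetry": 0.02,
        "roughness": 0.02, "gait_speed": 0.05,
        "turn_peak_yaw": 4.0, "chair_peak_pitch": 3.0,
    })
    noise_scale: float = 1.0
    noise_sd_acc: float = 0.08       # measurement noise, constant across ages
    gyro_noise_sd: float = 0.5

    _BOUNDS = {
        "step_time": (0.35, 1.0), "acc_amp": (0.3, 3.0),
        "asymmetry": (0.0, 0.6), "roughness": (0.0, 0.6),
        "gait_speed": (0.4, 2.0), "turn_peak_yaw": (40.0, 150.0),
        "chair_peak_pitch": (32.0, 120.0),
    }

    def params_for_age(self, age: float, rng: np.random.Generator) -> GaitModelParams:
        values = {}
        for name, (base, slope) in self.slopes.items():
            v = base + slope * (age - 60.0)
            if self.noise_scale > 0:
                v += rng.normal(0.0, self.noise_scale * self.noise_sd[name])
            lo, hi = self._BOUNDS[name]
            values[name] = float(np.clip(v, lo, hi))
        return GaitModelParams(noise_sd=self.noise_sd_acc,
                               gyro_noise_sd=self.gyro_noise_sd, **values)


DEFAULT_COUPLING = AgeCoupling()


# ---------------------------------------------------------------------------
# gait acceleration model
# ---------------------------------------------------------------------------

def _gait_acc(t: np.ndarray, p: GaitModelParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free harmonic-sum gait acceleration on the three axes."""
    w_step = 2.0 * math.pi / p.step_time     # step angular frequency
    a = p.acc_amp
    vt = a * (np.sin(w_step * t)
              + p.asymmetry * np.sin(0.5 * w_step * t)
              + p.roughness * np.sin(1.5 * w_step * t))
    ap = 0.6 * a * (np.sin(w_step * t + 0.7)
                    + p.asymmetry * np.sin(0.5 * w_step * t + 0.4)
                    + p.roughness * np.sin(1.5 * w_step * t + 0.2))
    # mediolateral sway alternates left/right, i.e. at the stride frequency
    ml = 0.5 * a * (np.sin(0.5 * w_step * t)
                    + p.roughness * np.sin(2.0 * w_step * t))
    return vt, ml, ap


def simulate_6mwt(params: GaitModelParams, duration_s: float = 360.0,
                  fs: float = 100.0, seed: int = 0,
                  subject_id: str = "synthetic") -> tuple[ImuRecording, GroundTruth]:
    """Simulate a six-minute-walk trunk-IMU trace.

    Ground-truth step times are the peak times of the vertical step
    harmonic, ``step_time * (k + 1/4)`` for every step inside the walk.
    """
    if duration_s <= 10 * params.step_time:
        raise ParameterError("walk duration must exceed ten step times")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    vt, ml, ap = _gait_acc(t, params)
    vt = vt + rng.normal(0.0, params.noise_sd, n)
    ml = ml + rng.normal(0.0, params.noise_sd, n)
    ap = ap + rng.normal(0.0, params.noise_sd, n)
    gyro = [rng.normal(0.0, params.gyro_noise_sd, n) for _ in range(3)]
    rec = ImuRecording(subject_id=subject_id, test=TestType.SIXMWT, trial_index=1,
                       fs=fs, t=t, acc_vt=vt, acc_ml=ml, acc_ap=ap,
                       yaw=gyro[0], pitch=gyro[1], roll=gyro[2])
    k = np.arange(int(math.floor(duration_s / params.step_time)))
    step_times = params.step_time * (k + 0.25)
    step_times = step_times[step_times < duration_s]
    truth = GroundTruth(step_times=step_times, params=params)
    return rec, truth


# ---------------------------------------------------------------------------
# TUG trial
# ---------------------------------------------------------------------------

#: half-sine pulse widths, s
CHAIR_PULSE_S = 1.5
TURN_PULSE_S = 2.0

#: quiet sitting/standing margins around the trial, s
_LEAD_S = 1.0

#: coupling from chair pitch rate to anterior-posterior trunk acceleration,
#: (m/s^2) per (deg/s) — makes chair-transfer vigour visible in the
#: acceleration statistics, as it is in real trunk recordings
_CHAIR_ACC_PER_DEGS = 0.02


def _half_sine(t: np.ndarray, t0: float, width: float, peak: float) -> np.ndarray:
    x = np.zeros_like(t)
    m = (t >= t0) & (t <= t0 + width)
    x[m] = peak * np.sin(math.pi * (t[m] - t0) / width)
    return x


def _threshold_span(t0: float, width: float, peak: float, thr: float) -> tuple[float, float]:
    """Analytic span where a half-sine pulse exceeds a threshold."""
    dt = width / math.pi * math.asin(thr / peak)
    return t0 + dt, t0 + width - dt


def simulate_tug_trial(params: GaitModelParams, fs: float = 100.0, seed: int = 0,
                       subject_id: str = "synthetic", trial_index: int = 1,
                       walkway_m: float = 3.0) -> tuple[ImuRecording, GroundTruth]:
    """Simulate one TUG trial: chair rise, 3 m walk, turn, walk back, turn, sit.

    Pitch carries two chair pulses and yaw two turn pulses (half-sines);
    the ground truth records, for each of the six sub-tasks, the interval
    where the noise-free pulse exceeds its detection threshold (chair: 25
    deg/s on pitch; turn: 32 deg/s on yaw), with the two gait intervals
    defined as the gaps between consecutive events.
    """
    if params.chair_peak_pitch <= PITCH_THRESHOLD:
        raise ParameterError(
            f"chair_peak_pitch {params.chair_peak_pitch} must exceed the "
            f"{PITCH_THRESHOLD} deg/s detection threshold")
    if params.turn_peak_yaw <= YAW_THRESHOLD:
        raise ParameterError(
            f"turn_peak_yaw {params.turn_peak_yaw} must exceed the "
            f"{YAW_THRESHOLD} deg/s detection threshold")

    walk_s = walkway_m / params.gait_speed
    # event onset times (pulse starts)
    t_sts = _LEAD_S
    t_turn1 = t_sts + CHAIR_PULSE_S + walk_s
    t_turn2 = t_turn1 + TURN_PULSE_S + walk_s
    t_sit = t_turn2 + TURN_PULSE_S
    total_s = t_sit + CHAIR_PULSE_S + _LEAD_S

    rng = np.random.default_rng(seed)
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    pitch = (_half_sine(t, t_sts, CHAIR_PULSE_S, params.chair_peak_pitch)
             - _half_sine(t, t_sit, CHAIR_PULSE_S, params.chair_peak_pitch))
    yaw = (_half_sine(t, t_turn1, TURN_PULSE_S, params.turn_peak_yaw)
           - _half_sine(t, t_turn2, TURN_PULSE_S, params.turn_peak_yaw))
    roll = np.zeros(n)

    # gait acceleration between the chair events
    vt = np.zeros(n)
    ml = np.zeros(n)
    ap = np.zeros(n)
    walking = (t >= t_sts + CHAIR_PULSE_S) & (t <= t_sit)
    gvt, gml, gap = _gait_acc(t[walking] - (t_sts + CHAIR_PULSE_S), params)
    vt[walking], ml[walking], ap[walking] = gvt, gml, gap
    # trunk lean during chair transfers shows up on the AP axis
    ap = ap + _CHAIR_ACC_PER_DEGS * np.abs(pitch)

    vt = vt + rng.normal(0.0, params.noise_sd, n)
    ml = ml + rng.normal(0.0, params.noise_sd, n)
    ap = ap + rng.normal(0.0, params.noise_sd, n)
    yaw = yaw + rng.normal(0.0, params.gyro_noise_sd, n)
    pitch = pitch + rng.normal(0.0, params.gyro_noise_sd, n)
    roll = roll + rng.normal(0.0, params.gyro_noise_sd, n)

    rec = ImuRecording(subject_id=subject_id, test=TestType.TUG,
                       trial_index=trial_index, fs=fs, t=t,
                       acc_vt=vt, acc_ml=ml, acc_ap=ap,
                       yaw=yaw, pitch=pitch, roll=roll)

    sts = _threshold_span(t_sts, CHAIR_PULSE_S, params.chair_peak_pitch, PITCH_THRESHOLD)
    turn1 = _threshold_span(t_turn1, TURN_PULSE_S, params.turn_peak_yaw, YAW_THRESHOLD)
    turn2 = _threshold_span(t_turn2, TURN_PULSE_S, params.turn_peak_yaw, YAW_THRESHOLD)
    sit = _threshold_span(t_sit, CHAIR_PULSE_S, params.chair_peak_pitch, PITCH_THRESHOLD)
    intervals = {
        "sit_to_stand": sts,
        "forward_gait": (sts[1], turn1[0]),
        "mid_turn": turn1,
        "backward_gait": (turn1[1], turn2[0]),
        "end_turn": turn2,
        "stand_to_sit": sit,
    }
    assert list(intervals) == list(TUG_SUBTASKS)
    return rec, GroundTruth(intervals=intervals, params=params)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _draw_cohort_meta(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectMeta]:
    ages = []
    for decade, count in zip((60, 70, 80), spec.group_counts):
        ages.extend(rng.uniform(decade, decade + 10, count))
    sexes = np.array(["M"] * spec.sex_counts[0] + ["F"] * spec.sex_counts[1])
    rng.shuffle(sexes)
    metas = []
    for i, (age, sex) in enumerate(zip(ages, sexes)):
        height = rng.normal(spec.height_mean_cm[str(sex)], spec.height_sd_cm)
        metas.append(SubjectMeta(subject_id=f"S{i + 1:03d}", age=float(age),
                                 height_cm=float(max(height, 120.0)), sex=str(sex)))
    return metas


def iter_cohort(spec: CohortSpec, coupling: AgeCoupling, seed: int):
    """Yield per-subject data without holding the whole cohort in memory.

    Yields ``(meta, tug_recordings, tug_truths, sixmwt_recording,
    sixmwt_truth)`` tuples, one per subject, deterministically in subject
    order for a given ``(spec, coupling, seed)``.
    """
    rng = np.random.default_rng(seed)
    metas = _draw_cohort_meta(spec, rng)
    for meta in metas:
        p = coupling.params_for_age(meta.age, rng)
        tug_recs, tug_truths = [], []
        for trial in range(1, spec.tug_trials_per_subject + 1):
            rec, truth = simulate_tug_trial(
                p, fs=spec.fs, seed=int(rng.integers(2**31)),
                subject_id=meta.subject_id, trial_index=trial)
            tug_recs.append(rec)
            tug_truths.append(truth)
        walk_rec, walk_truth = simulate_6mwt(
            p, duration_s=spec.sixmwt_duration_s, fs=spec.fs,
            seed=int(rng.integers(2**31)), subject_id=meta.subject_id)
        yield meta, tug_recs, tug_truths, walk_rec, walk_truth


def simulate_cohort(spec: CohortSpec, coupling: AgeCoupling | None = None,
                    seed: int = 0):
    """Materialise a full cohort.

    Returns ``(metas, recordings, truths)`` where ``recordings`` maps
    subject id to ``{"tug": [...], "6mwt": rec}`` and ``truths`` mirrors it.
    """
    coupling = coupling or DEFAULT_COUPLING
    metas, recordings, truths = [], {}, {}
    for meta, tug_recs, tug_truths, walk_rec, walk_truth in iter_cohort(
            spec, coupling, seed):
        metas.append(meta)
        recordings[meta.subject_id] = {"tug": tug_recs, "6mwt": walk_rec}
        truths[meta.subject_id] = {"tug": tug_truths, "6mwt": walk_truth}
    return metas, recordings, truths
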