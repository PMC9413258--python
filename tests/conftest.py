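"""Shared fixtures: canonical subjects, recordings and scaled cohorts.

Multi-seed model checks run on scaled-down cohorts (36 subjects with the
same 1:2:1 decade structure as the full 136-subject design, 60 s walks) so
the whole suite stays within an ordinary CI budget; the full-size study
conditions are exercised once by the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pytest

import gaitage as ga


@pytest.fixture(scope="session")
def meta() -> ga.SubjectMeta:
    return ga.SubjectMeta(subject_id="S001", age=72.0, height_cm=160.0, sex="F")


@pytest.fixture()
def default_params() -> ga.GaitModelParams:
    return ga.GaitModelParams()


@pytest.fixture()
def quiet_params() -> ga.GaitModelParams:
    """Noise-free gait parameters for deterministic ground-truth checks."""
    return ga.GaitModelParams(noise_sd=0.0, gyro_noise_sd=0.0)


@pytest.fixture(scope="session")
def walk_recording() -> ga.ImuRecording:
    rec, _ = ga.simulate_6mwt(ga.GaitModelParams(), duration_s=60.0, seed=7)
    return rec


@pytest.fixture(scope="session")
def walk_features(walk_recording, meta) -> dict[str, float]:
    return ga.extract_6mwt_features(walk_recording, meta)


@pytest.fixture(scope="session")
def tug_recording() -> tuple[ga.ImuRecording, ga.GroundTruth]:
    return ga.simulate_tug_trial(ga.GaitModelParams(), seed=5)


def scaled_cohort_spec(n: int = 36) -> ga.CohortSpec:
    """A cohort with the study's 1:2:1 decade and ~1:3 sex structure."""
    q = n // 4
    return ga.CohortSpec(n_subjects=n, group_counts=(q, n - 2 * q, q),
                         sex_counts=(n // 4, n - n // 4),
                         sixmwt_duration_s=60.0)


def split_signal_coupling(noise_scale: float = 1.0) -> ga.AgeCoupling:
    """Age drives TUG-side and walk-side parameters through separate channels.

    TUG carries age through transfer/turn vigour and over-ground speed;
    the walk test carries it through cadence, asymmetry and roughness.
    """
    return ga.AgeCoupling(slopes={
        "step_time": (0.50, 0.005),
        "acc_amp": (1.55, 0.0),
        "asymmetry": (0.05, 0.006),
        "roughness": (0.05, 0.006),
        "gait_speed": (1.25, -0.015),
        "turn_peak_yaw": (90.0, -1.0),
        "chair_peak_pitch": (72.0, -0.8),
    }, noise_scale=noise_scale)


def planted_speed_turn_coupling() -> ga.AgeCoupling:
    """Age linearly drives only walking speed (cadence + over-ground speed)
    and turn angular velocity; all other parameters are age-flat."""
    return ga.AgeCoupling(slopes={
        "step_time": (0.50, 0.005),
        "acc_amp": (1.55, 0.0),
        "asymmetry": (0.10, 0.0),
        "roughness": (0.10, 0.0),
        "gait_speed": (1.25, -0.015),
        "turn_peak_yaw": (90.0, -1.0),
        "chair_peak_pitch": (72.0, 0.0),
    })


#: feature names that should respond to the planted speed/turn signal
PLANTED_FEATURES = {
    "6mwt.gp.number_of_steps", "6mwt.gp.steps_per_s", "6mwt.gp.step_time",
    "6mwt.gp.gait_distance", "6mwt.gp.average_gait_speed",
    "tug.time.total", "tug.time.gait", "tug.time.mid_turn", "tug.time.end_turn",
    "tug.mid_turn.yaw.rms", "tug.mid_turn.yaw.max",
    "tug.end_turn.yaw.rms", "tug.end_turn.yaw.max",
}


@pytest.fixture(scope="session")
def small_feature_table() -> ga.FeatureTable:
    """One scaled synthetic cohort feature table (36 subjects, 60 s walks)."""
    return ga.cohort_feature_table(scaled_cohort_spec(), seed=11)


@pytest.fixture(scope="session")
def multiseed_comparison() -> list[tuple[float, dict]]:
    """OT/OS/AG comparison on ten seeded split-signal cohorts.

    Returns one ``(label_sd, results)`` pair per seed; shared by the model
    ordering and skill checks so the cohorts are only built once.
    """
    out = []
    for seed in range(10):
        table = ga.cohort_feature_table(scaled_cohort_spec(),
                                        split_signal_coupling(), seed=100 + seed)
        results = ga.compare_feature_sets(
            table, ga.SplitSpec(seed=seed),
            ga.SearchSpec(n_trials=8, method="random"), seed=seed)
        out.append((float(table.df["age"].std()), results))
    return out
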