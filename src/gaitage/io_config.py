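"""On-disk formats and core in-memory containers.

A recording is a single trunk-worn IMU trace: three linear-acceleration
axes (vertical, mediolateral, anterior-posterior, in m/s^2) and three
angular-velocity axes (yaw, pitch, roll, in deg/s) sampled uniformly,
nominally at 100 Hz.  Recordings are stored as plain CSV with a small
``# key=value`` comment header carrying the subject id, test type, trial
index, sampling rate and acceleration units.

A feature table is a pandas DataFrame keyed by subject id with an ``age``
label column plus 132 named gait features: 111 from the timed-up-and-go
test (prefix ``tug.``) and 21 from the six-minute walk test (prefix
``6mwt.``).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, IntegrityError, SamplingError, SchemaError

#: CSV column order for IMU traces.
IMU_COLUMNS = ["time_s", "acc_vt", "acc_ml", "acc_ap", "yaw", "pitch", "roll"]

ACC_CHANNELS = ("acc_vt", "acc_ml", "acc_ap")
GYRO_CHANNELS = ("yaw", "pitch", "roll")

_G = 9.80665  # m/s^2 per g, used when a file declares acc_units=g

TIME_TOL = 1e-9  # allowed deviation of timestamp spacing from 1/fs, seconds


class TestType(str, enum.Enum):
    TUG = "TUG"
    SIXMWT = "6MWT"


@dataclass
class ImuRecording:
    """Uniformly sampled 6-channel trunk IMU trace."""

    subject_id: str
    test: TestType
    trial_index: int
    fs: float
    t: np.ndarray
    acc_vt: np.ndarray
    acc_ml: np.ndarray
    acc_ap: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray

    def __post_init__(self) -> None:
        self.test = TestType(self.test)
        arrays = [self.t, *self.channels().values()]
        n = len(self.t)
        if n < 2:
            raise SamplingError("recording must contain at least 2 samples")
        if any(len(a) != n for a in arrays):
            raise SamplingError("all channels must have the same length")
        if self.fs <= 0:
            raise SamplingError(f"sampling rate must be positive, got {self.fs}")
        if self.trial_index < 1:
            raise FormatError(f"trial_index must be >= 1, got {self.trial_index}")
        dt = np.diff(self.t)
        if np.any(np.abs(dt - 1.0 / self.fs) > 100 * TIME_TOL):
            worst = float(np.max(np.abs(dt - 1.0 / self.fs)))
            raise SamplingError(
                f"timestamps deviate from uniform 1/fs spacing by {worst:.3g} s"
            )

    def channels(self) -> dict[str, np.ndarray]:
        """All six signal channels by name, in canonical order."""
        return {
            "acc_vt": self.acc_vt,
            "acc_ml": self.acc_ml,
            "acc_ap": self.acc_ap,
            "yaw": self.yaw,
            "pitch": self.pitch,
            "roll": self.roll,
        }

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata; age is the regression label."""

    subject_id: str
    age: float
    height_cm: float
    sex: str  # "M" or "F"

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise FormatError(f"height must be positive, got {self.height_cm}")
        if self.sex not in ("M", "F"):
            raise FormatError(f"sex must be 'M' or 'F', got {self.sex!r}")


# ---------------------------------------------------------------------------
# feature naming scheme
# ---------------------------------------------------------------------------

TUG_SUBTASKS = ("sit_to_stand", "forward_gait", "mid_turn", "backward_gait",
                "end_turn", "stand_to_sit")
#: sub-task groups used for descriptive statistics (forward and backward
#: gait are averaged into a single ``gait`` group)
TUG_STAT_GROUPS = ("sit_to_stand", "gait", "mid_turn", "end_turn", "stand_to_sit")
TUG_SIGNALS = ("acc_vt", "acc_ml", "acc_ap", "acc_res", "yaw", "pitch", "roll")
TUG_STATS = ("rms", "min", "max")


def tug_feature_names() -> list[str]:
    """The 111 TUG feature names: 6 durations + 3 stats x 7 signals x 5 groups."""
    names = ["tug.time.total"] + [f"tug.time.{s}" for s in
                                  ("sit_to_stand", "gait", "mid_turn",
                                   "end_turn", "stand_to_sit")]
    for group in TUG_STAT_GROUPS:
        for sig in TUG_SIGNALS:
            for stat in TUG_STATS:
                names.append(f"tug.{group}.{sig}.{stat}")
    return names


def sixmwt_feature_names() -> list[str]:
    """The 21 6MWT feature names: 6 gait parameters, 9 symmetry, 3 HR, 3 ApEn."""
    gp = ["number_of_steps", "steps_per_s", "step_time", "stride_length",
          "gait_distance", "average_gait_speed"]
    names = [f"6mwt.gp.{n}" for n in gp]
    for stat in ("sr", "str", "si"):
        for axis in ("acc_vt", "acc_ap", "acc_res"):
            names.append(f"6mwt.{stat}.{axis}")
    for stat in ("hr", "apen"):
        for axis in ("acc_vt", "acc_ml", "acc_ap"):
            names.append(f"6mwt.{stat}.{axis}")
    return names


TUG_FEATURE_NAMES = tug_feature_names()
SIXMWT_FEATURE_NAMES = sixmwt_feature_names()
ALL_FEATURE_NAMES = TUG_FEATURE_NAMES + SIXMWT_FEATURE_NAMES

assert len(TUG_FEATURE_NAMES) == 111
assert len(SIXMWT_FEATURE_NAMES) == 21


def feature_tag(name: str) -> str:
    """Feature-set tag for a column name: ``TUG`` or ``SIXMWT``."""
    if name.startswith("tug."):
        return "TUG"
    if name.startswith("6mwt."):
        return "SIXMWT"
    raise SchemaError(f"unrecognised feature name {name!r}")


class FeatureTable:
    """Per-subject feature matrix with the age label.

    Thin wrapper around a DataFrame indexed by ``subject_id`` whose first
    column is ``age`` followed by the 132 feature columns in canonical
    order.  ``validate()`` enforces the (111, 21) column census.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate subject ids: {dups}")
        self.df = df
        if validate:
            self.validate()

    def validate(self) -> None:
        if "age" not in self.df.columns:
            raise SchemaError("feature table must contain an 'age' column")
        feats = [c for c in self.df.columns if c != "age"]
        n_tug = sum(1 for c in feats if feature_tag(c) == "TUG")
        n_six = len(feats) - n_tug
        if n_tug != 111 or n_six != 21:
            raise SchemaError(
                f"feature census mismatch: found {n_tug} TUG (expected 111) "
                f"and {n_six} 6MWT (expected 21) columns"
            )
        if self.df[feats].isna().any().any():
            bad = self.df[feats].columns[self.df[feats].isna().any()].tolist()
            raise SchemaError(f"missing values in feature columns: {bad[:5]}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c != "age"]

    def census(self) -> tuple[int, int]:
        feats = self.feature_names
        n_tug = sum(1 for c in feats if feature_tag(c) == "TUG")
        return n_tug, len(feats) - n_tug

    def subset(self, tag: str) -> pd.DataFrame:
        """Feature columns belonging to one tag ('TUG' or 'SIXMWT')."""
        cols = [c for c in self.feature_names if feature_tag(c) == tag]
        if not cols:
            raise SchemaError(f"no columns tagged {tag!r}")
        return self.df[cols]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FeatureTable) and self.df.equals(other.df)

    @classmethod
    def from_rows(cls, rows: dict[str, dict[str, float]],
                  ages: dict[str, float]) -> "FeatureTable":
        """Build a table from per-subject feature dicts plus age labels."""
        df = pd.DataFrame.from_dict(rows, orient="index")
        df = df.reindex(columns=ALL_FEATURE_NAMES)
        df.insert(0, "age", pd.Series(ages))
        df.index.name = "subject_id"
        return cls(df)


# ---------------------------------------------------------------------------
# IMU CSV I/O
# ---------------------------------------------------------------------------

def write_imu_csv(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording as CSV with a ``# key=value`` metadata header."""
    path = Path(path)
    header = (
        f"# subject_id={rec.subject_id}\n"
        f"# test={rec.test.value}\n"
        f"# trial_index={rec.trial_index}\n"
        f"# fs={rec.fs!r}\n"
        f"# acc_units=m/s2\n"
        f"# gyro_units=deg/s\n"
    )
    df = pd.DataFrame({"time_s": rec.t, **rec.channels()})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_imu_csv(path: str | Path) -> ImuRecording:
    """Read an IMU trace CSV written by :func:`write_imu_csv`.

    Acceleration declared in ``g`` in the header is converted to m/s^2;
    gyro channels are always taken as deg/s.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=n_meta)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    fs = float(meta.get("fs", 100.0))
    acc_scale = _G if meta.get("acc_units", "m/s2") == "g" else 1.0
    return ImuRecording(
        subject_id=meta.get("subject_id", path.stem),
        test=TestType(meta.get("test", "TUG")),
        trial_index=int(meta.get("trial_index", 1)),
        fs=fs,
        t=df["time_s"].to_numpy(float),
        acc_vt=df["acc_vt"].to_numpy(float) * acc_scale,
        acc_ml=df["acc_ml"].to_numpy(float) * acc_scale,
        acc_ap=df["acc_ap"].to_numpy(float) * acc_scale,
        yaw=df["yaw"].to_numpy(float),
        pitch=df["pitch"].to_numpy(float),
        roll=df["roll"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# manifest and feature-table I/O
# ---------------------------------------------------------------------------

def write_manifest(metas: Iterable[SubjectMeta], files: dict[str, dict[str, list[str]]],
                   path: str | Path) -> None:
    """Write a cohort manifest CSV.

    ``files[subject_id]`` maps ``"tug"`` to the list of TUG trial CSVs and
    ``"6mwt"`` to a single-element list with the walk CSV.
    """
    rows = []
    for m in metas:
        f = files.get(m.subject_id, {})
        rows.append({
            "subject_id": m.subject_id, "age": m.age,
            "height_cm": m.height_cm, "sex": m.sex,
            "tug_files": ";".join(f.get("tug", [])),
            "sixmwt_file": ";".join(f.get("6mwt", [])),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str | Path) -> tuple[list[SubjectMeta], dict[str, dict[str, list[str]]]]:
    df = pd.read_csv(path)
    required = {"subject_id", "age", "height_cm", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing column(s) {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise IntegrityError("duplicate subject_id in manifest")
    metas, files = [], {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        metas.append(SubjectMeta(sid, float(row["age"]),
                                 float(row["height_cm"]), str(row["sex"])))
        files[sid] = {
            "tug": [p for p in str(row.get("tug_files", "")).split(";") if p and p != "nan"],
            "6mwt": [p for p in str(row.get("sixmwt_file", "")).split(";") if p and p != "nan"],
        }
    return metas, files


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table to CSV (full float precision, stable order)."""
    table.validate()
    table.df.to_csv(path, index=True)


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, index_col="subject_id")
    df.index = df.index.astype(str)
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# config and results
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def save_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_default)
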