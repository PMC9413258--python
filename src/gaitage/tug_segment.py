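"""TUG sub-task segmentation from thresholded angular velocity.

Chair transfers (sit-to-stand, stand-to-sit) are found where the rectified,
low-pass-filtered pitch rate exceeds 25 deg/s; turns where the rectified,
filtered yaw rate exceeds 32 deg/s.  A valid trial contains exactly two
chair events bracketing exactly two turns; the two gait phases are the gaps
between consecutive events:

    sit-to-stand | forward gait | mid-turn | backward gait | end-turn | stand-to-sit

Event boundaries are the first/last samples of the thresholded run.  Runs
separated by less than ``merge_gap_s`` are merged and runs shorter than
``min_event_s`` are discarded before counting, which de-bounces threshold
chatter near the crossing points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SegmentationError
from .io_config import ImuRecording
from .preprocess import FilterSpec, TUG_FILTER, lowpass, rectify


@dataclass(frozen=True)
class ThresholdSpec:
    """Segmentation thresholds and de-bounce settings (deg/s, seconds)."""

    pitch_thresh: float = 25.0
    yaw_thresh: float = 32.0
    min_event_s: float = 0.3
    merge_gap_s: float = 0.3
    filter_spec: FilterSpec = field(default=TUG_FILTER)

    def __post_init__(self) -> None:
        if self.pitch_thresh <= 0 or self.yaw_thresh <= 0:
            raise ParameterError("thresholds must be positive")


@dataclass(frozen=True)
class Interval:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TugSegmentation:
    """Six ordered, non-overlapping labelled sub-task intervals."""

    intervals: dict[str, Interval]

    _ORDER = ("sit_to_stand", "forward_gait", "mid_turn",
              "backward_gait", "end_turn", "stand_to_sit")

    def __post_init__(self) -> None:
        if list(self.intervals) != list(self._ORDER):
            raise SegmentationError(
                f"expected sub-tasks {self._ORDER}, got {tuple(self.intervals)}")
        prev_end = -np.inf
        for iv in self.intervals.values():
            if iv.duration_s <= 0:
                raise SegmentationError(f"{iv.label} has non-positive duration")
            if iv.start_s < prev_end:
                raise SegmentationError(f"{iv.label} overlaps its predecessor")
            prev_end = iv.end_s

    def __getitem__(self, label: str) -> Interval:
        return self.intervals[label]

    def to_dict(self) -> dict[str, tuple[float, float]]:
        return {k: (v.start_s, v.end_s) for k, v in self.intervals.items()}


def detect_events(series: np.ndarray, threshold: float, min_event_s: float,
                  merge_gap_s: float, fs: float) -> list[tuple[float, float]]:
    """Maximal above-threshold runs of a rectified, filtered series.

    Returns ``(start_s, end_s)`` pairs ordered by start time, after merging
    runs separated by less than ``merge_gap_s`` and dropping runs shorter
    than ``min_event_s``.
    """
    x = np.asarray(series, float)
    above = x > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(x)]
    runs = [[s / fs, (e - 1) / fs] for s, e in zip(starts, ends)]
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_event_s]


def segment_tug(recording: ImuRecording, spec: ThresholdSpec | None = None) -> TugSegmentation:
    """Segment one TUG trial into its six sub-tasks.

    Pitch and yaw are rectified, low-pass filtered, and thresholded; the
    trial is rejected with a :class:`SegmentationError` (reporting the
    counts found) unless exactly two chair events bracket exactly two turns.
    """
    spec = spec or ThresholdSpec()
    fs = recording.fs
    pitch = lowpass(rectify(recording.pitch), spec.filter_spec, fs)
    yaw = lowpass(rectify(recording.yaw), spec.filter_spec, fs)
    chair = detect_events(pitch, spec.pitch_thresh, spec.min_event_s,
                          spec.merge_gap_s, fs)
    turns = detect_events(yaw, spec.yaw_thresh, spec.min_event_s,
                          spec.merge_gap_s, fs)
    if len(chair) != 2 or len(turns) != 2:
        raise SegmentationError(
            f"{len(chair)} chair event(s), expected 2; "
            f"{len(turns)} turn event(s), expected 2")
    if not (chair[0][1] < turns[0][0] and turns[0][1] < turns[1][0]
            and turns[1][1] < chair[1][0]):
        raise SegmentationError(
            "events not in chair-turn-turn-chair order: "
            f"chair={chair}, turns={turns}")
    iv = {
        "sit_to_stand": Interval("sit_to_stand", *chair[0]),
        "forward_gait": Interval("forward_gait", chair[0][1], turns[0][0]),
        "mid_turn": Interval("mid_turn", *turns[0]),
        "backward_gait": Interval("backward_gait", turns[0][1], turns[1][0]),
        "end_turn": Interval("end_turn", *turns[1]),
        "stand_to_sit": Interval("stand_to_sit", *chair[1]),
    }
    return TugSegmentation(iv)


def tug_time_features(seg: TugSegmentation) -> dict[str, float]:
    """The six TUG duration features (seconds).

    ``tug.time.total`` spans first chair-event onset to last chair-event
    offset; ``tug.time.gait`` is the mean of the forward and backward gait
    durations; the remaining four are their interval durations.
    """
    return {
        "tug.time.total": seg["stand_to_sit"].end_s - seg["sit_to_stand"].start_s,
        "tug.time.sit_to_stand": seg["sit_to_stand"].duration_s,
        "tug.time.gait": 0.5 * (seg["forward_gait"].duration_s
                                + seg["backward_gait"].duration_s),
        "tug.time.mid_turn": seg["mid_turn"].duration_s,
        "tug.time.end_turn": seg["end_turn"].duration_s,
        "tug.time.stand_to_sit": seg["stand_to_sit"].duration_s,
    }
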