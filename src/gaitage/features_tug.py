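"""The 111 TUG features.

Six duration features (see :func:`gaitage.tug_segment.tug_time_features`)
plus RMS / min / max of seven signals — the three filtered acceleration
axes, their resultant, and the three filtered angular-velocity axes — over
five sub-task groups.  Forward and backward gait are averaged into a single
``gait`` group at the feature level: the statistic is computed on each gait
interval separately and the two values are averaged.
"""

from __future__ import annotations

import numpy as np

from .errors import ExtractionError, SchemaError
from .io_config import (ImuRecording, TUG_FEATURE_NAMES, TUG_SIGNALS,
                        TUG_STAT_GROUPS, TUG_STATS)
from .preprocess import FilterSpec, TUG_FILTER, lowpass, resultant_acceleration
from .tug_segment import TugSegmentation, tug_time_features


def descriptive_stats(series: np.ndarray) -> tuple[float, float, float]:
    """(rms, min, max) of a non-empty series; rms = sqrt(mean(x^2))."""
    x = np.asarray(series, float)
    if x.size == 0:
        raise ExtractionError("cannot compute statistics of an empty series")
    return (float(np.sqrt(np.mean(x**2))), float(x.min()), float(x.max()))


def _filtered_signals(recording: ImuRecording,
                      filter_spec: FilterSpec) -> dict[str, np.ndarray]:
    """The seven analysis signals, low-pass filtered.

    The resultant is computed from the filtered acceleration components.
    """
    fs = recording.fs
    out = {name: lowpass(ch, filter_spec, fs)
           for name, ch in recording.channels().items()}
    out["acc_res"] = resultant_acceleration(out["acc_vt"], out["acc_ml"],
                                            out["acc_ap"])
    return out


def extract_tug_features(recording: ImuRecording, seg: TugSegmentation,
                         filter_spec: FilterSpec = TUG_FILTER) -> dict[str, float]:
    """All 111 TUG features of one trial.

    Raises :class:`ExtractionError` naming the sub-task if any interval
    holds fewer than two samples.
    """
    fs = recording.fs
    signals = _filtered_signals(recording, filter_spec)

    def window(label: str) -> slice:
        iv = seg[label]
        i0 = int(np.ceil(iv.start_s * fs))
        i1 = int(np.floor(iv.end_s * fs)) + 1
        if i1 - i0 < 2:
            raise ExtractionError(
                f"sub-task {label!r} spans fewer than 2 samples")
        return slice(i0, i1)

    windows = {label: window(label) for label in
               ("sit_to_stand", "forward_gait", "mid_turn", "backward_gait",
                "end_turn", "stand_to_sit")}

    feats = dict(tug_time_features(seg))
    for group in TUG_STAT_GROUPS:
        for sig_name in TUG_SIGNALS:
            sig = signals[sig_name]
            if group == "gait":
                fwd = descriptive_stats(sig[windows["forward_gait"]])
                bwd = descriptive_stats(sig[windows["backward_gait"]])
                stats = tuple(0.5 * (a + b) for a, b in zip(fwd, bwd))
            else:
                stats = descriptive_stats(sig[windows[group]])
            for stat_name, value in zip(TUG_STATS, stats):
                feats[f"tug.{group}.{sig_name}.{stat_name}"] = value
    assert list(feats) == TUG_FEATURE_NAMES
    return feats


def aggregate_trials(trials: list[dict[str, float]]) -> dict[str, float]:
    """Elementwise mean of per-trial feature sets (the per-subject value)."""
    if not trials:
        raise SchemaError("need at least one trial to aggregate")
    names = list(trials[0])
    for tr in trials[1:]:
        if list(tr) != names:
            raise SchemaError("trials have inconsistent feature names")
    return {name: float(np.mean([tr[name] for tr in trials])) for name in names}
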