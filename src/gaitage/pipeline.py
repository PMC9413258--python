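"""End-to-end glue: recordings -> per-subject feature rows -> feature table."""

from __future__ import annotations

from dataclasses import dataclass, field

from .features_6mwt import SixMwtConfig, extract_6mwt_features
from .features_tug import aggregate_trials, extract_tug_features
from .io_config import FeatureTable, ImuRecording, SubjectMeta
from .preprocess import FilterSpec, TUG_FILTER
from .synth import AgeCoupling, CohortSpec, DEFAULT_COUPLING, iter_cohort
from .tug_segment import ThresholdSpec, segment_tug


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the extraction pipeline in one place."""

    tug_filter: FilterSpec = field(default=TUG_FILTER)
    thresholds: ThresholdSpec = field(default_factory=ThresholdSpec)
    sixmwt: SixMwtConfig = field(default_factory=SixMwtConfig)


def subject_features(tug_recordings: list[ImuRecording],
                     sixmwt_recording: ImuRecording, meta: SubjectMeta,
                     config: PipelineConfig | None = None) -> dict[str, float]:
    """The full 132-feature row of one subject.

    TUG trials are segmented and extracted individually, then averaged
    elementwise; the walk-test features come from the single 6MWT record.
    """
    cfg = config or PipelineConfig()
    per_trial = []
    for rec in tug_recordings:
        seg = segment_tug(rec, cfg.thresholds)
        per_trial.append(extract_tug_features(rec, seg, cfg.tug_filter))
    feats = aggregate_trials(per_trial)
    feats.update(extract_6mwt_features(sixmwt_recording, meta, cfg.sixmwt))
    return feats


def cohort_feature_table(spec: CohortSpec, coupling: AgeCoupling | None = None,
                         seed: int = 0,
                         config: PipelineConfig | None = None) -> FeatureTable:
    """Simulate a cohort and extract its feature table, one subject at a time.

    Recordings are discarded as soon as their features are computed, so a
    full cohort never needs to be resident in memory.
    """
    coupling = coupling or DEFAULT_COUPLING
    rows: dict[str, dict[str, float]] = {}
    ages: dict[str, float] = {}
    for meta, tug_recs, _tug_truths, walk_rec, _walk_truth in iter_cohort(
            spec, coupling, seed):
        rows[meta.subject_id] = subject_features(tug_recs, walk_rec, meta, config)
        ages[meta.subject_id] = meta.age
    return FeatureTable.from_rows(rows, ages)
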