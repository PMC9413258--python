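"""Generator contracts: determinism, census, ground truth, responsiveness."""

import numpy as np
import pytest

import gaitage as ga
from gaitage.features_6mwt import regularity, unbiased_autocorr

from conftest import scaled_cohort_spec


class TestSimulate6mwt:
    def test_same_seed_identical(self):
        p = ga.GaitModelParams()
        a, _ = ga.simulate_6mwt(p, duration_s=30, seed=9)
        b, _ = ga.simulate_6mwt(p, duration_s=30, seed=9)
        for name in a.channels():
            np.testing.assert_array_equal(a.channels()[name], b.channels()[name])

    def test_step_count_ground_truth(self):
        p = ga.GaitModelParams(step_time=0.5, noise_sd=0.0)
        _, truth = ga.simulate_6mwt(p, duration_s=360, seed=0)
        assert len(truth.step_times) == 720

    def test_nonpositive_step_time_rejected(self):
        with pytest.raises(ga.ParameterError):
            ga.GaitModelParams(step_time=0.0)

    def test_too_short_walk_rejected(self):
        with pytest.raises(ga.ParameterError):
            ga.simulate_6mwt(ga.GaitModelParams(step_time=1.0), duration_s=5.0)

    def test_symmetric_gait_gives_equal_regularity(self, meta):
        p = ga.GaitModelParams(asymmetry=0.0, noise_sd=0.0, gyro_noise_sd=0.0)
        rec, _ = ga.simulate_6mwt(p, duration_s=60, seed=1)
        feats = ga.extract_6mwt_features(rec, meta)
        for axis in ("acc_vt", "acc_ap", "acc_res"):
            assert abs(feats[f"6mwt.si.{axis}"]) < 0.05
            assert feats[f"6mwt.sr.{axis}"] == pytest.approx(
                feats[f"6mwt.str.{axis}"], abs=0.05)


class TestSimulateTug:
    def test_truth_has_six_ordered_intervals(self, quiet_params):
        _, truth = ga.simulate_tug_trial(quiet_params, seed=3)
        labels = list(truth.intervals)
        assert labels == ["sit_to_stand", "forward_gait", "mid_turn",
                          "backward_gait", "end_turn", "stand_to_sit"]
        spans = list(truth.intervals.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a0 < a1 <= b0

    @pytest.mark.parametrize("kwargs", [
        {"chair_peak_pitch": 24.0}, {"turn_peak_yaw": 31.0}])
    def test_subthreshold_pulses_rejected(self, kwargs):
        p = ga.GaitModelParams(**kwargs)
        with pytest.raises(ga.ParameterError):
            ga.simulate_tug_trial(p)

    def test_pulses_exceed_thresholds(self, quiet_params):
        rec, _ = ga.simulate_tug_trial(quiet_params, seed=0)
        assert (np.abs(rec.pitch) > 25).any()
        assert (np.abs(rec.yaw) > 32).any()


class TestCohort:
    def test_census_and_structure(self):
        spec = scaled_cohort_spec(36)
        metas, recs, truths = ga.simulate_cohort(spec, seed=4)
        assert len(metas) == 36
        ages = np.array([m.age for m in metas])
        assert ((ages >= 60) & (ages < 70)).sum() == spec.group_counts[0]
        assert ((ages >= 70) & (ages < 80)).sum() == spec.group_counts[1]
        assert ((ages >= 80) & (ages < 90)).sum() == spec.group_counts[2]
        assert sum(m.sex == "M" for m in metas) == spec.sex_counts[0]
        for m in metas:
            assert len(recs[m.subject_id]["tug"]) == 3
            assert recs[m.subject_id]["6mwt"].test == ga.TestType.SIXMWT

    def test_default_spec_matches_study_design(self):
        spec = ga.CohortSpec()
        assert spec.n_subjects == 136
        assert spec.group_counts == (36, 64, 36)
        assert spec.sex_counts == (33, 103)
        assert spec.tug_trials_per_subject == 3

    def test_bad_group_counts_rejected(self):
        with pytest.raises(ga.ParameterError):
            ga.CohortSpec(n_subjects=10, group_counts=(5, 5, 5))

    def test_two_seeds_differ_same_census(self):
        spec = scaled_cohort_spec(12)
        m1, r1, _ = ga.simulate_cohort(spec, seed=1)
        m2, r2, _ = ga.simulate_cohort(spec, seed=2)
        assert [m.subject_id for m in m1] == [m.subject_id for m in m2]
        a = r1[m1[0].subject_id]["6mwt"].acc_vt
        b = r2[m2[0].subject_id]["6mwt"].acc_vt
        assert not np.array_equal(a, b)

    def test_gait_speed_feature_monotone_in_age(self, meta):
        """With zero subject scatter and fixed stature, measured walking
        speed decreases strictly with age by construction of the coupling."""
        spec = ga.CohortSpec(n_subjects=9, group_counts=(3, 3, 3),
                             sex_counts=(3, 6), sixmwt_duration_s=360.0,
                             height_mean_cm={"M": 160.0, "F": 160.0},
                             height_sd_cm=0.0)
        coupling = ga.AgeCoupling(noise_scale=0.0, noise_sd_acc=0.0,
                                  gyro_noise_sd=0.0)
        speeds, ages = [], []
        for m, _, _, walk, _ in ga.iter_cohort(spec, coupling, seed=6):
            x = ga.lowpass(walk.acc_vt, ga.SIXMWT_FILTER, walk.fs)
            steps = ga.detect_steps(x, walk.fs)
            gp = ga.gait_parameters(steps, m.height_cm, walk.duration_s)
            ages.append(m.age)
            speeds.append(gp["average_gait_speed"])
        order = np.argsort(ages)
        ages_sorted = np.array(ages)[order]
        speeds_sorted = np.array(speeds)[order]
        # step counts are integers, so subjects closer in age than the count
        # resolution (~0.15 y at this cadence slope) can tie exactly
        assert (np.diff(speeds_sorted) <= 0).all()
        for i in range(len(order) - 1):
            if ages_sorted[i + 1] - ages_sorted[i] > 0.5:
                assert speeds_sorted[i + 1] < speeds_sorted[i]


class TestResponsiveness:
    """3-point parameter sweeps, noise-free: SR falls with asymmetry,
    vertical-axis HR falls with roughness."""

    def _walk(self, **kwargs):
        p = ga.GaitModelParams(noise_sd=0.0, gyro_noise_sd=0.0, **kwargs)
        rec, _ = ga.simulate_6mwt(p, duration_s=60, seed=0)
        return rec, p

    def test_asymmetry_decreases_step_regularity(self):
        srs = []
        for beta in (0.0, 0.2, 0.4):
            rec, p = self._walk(asymmetry=beta)
            x = ga.lowpass(rec.acc_vt, ga.SIXMWT_FILTER, rec.fs)
            ac = unbiased_autocorr(x, int(2.6 * p.step_time * rec.fs))
            sr, _ = regularity(ac, rec.fs, (0.5 * p.step_time, 1.5 * p.step_time),
                               (1.5 * p.step_time, 2.5 * p.step_time))
            srs.append(sr)
        assert srs[0] > srs[1] > srs[2]

    def test_roughness_decreases_vertical_hr(self, meta):
        hrs = []
        for gamma in (0.05, 0.2, 0.4):
            rec, _ = self._walk(roughness=gamma)
            feats = ga.extract_6mwt_features(rec, meta)
            hrs.append(feats["6mwt.hr.acc_vt"])
        assert hrs[0] > hrs[1] > hrs[2]
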