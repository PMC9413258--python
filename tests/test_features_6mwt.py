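"""Walk-test features against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

import gaitage as ga
from gaitage.features_6mwt import HR_CAP, SixMwtConfig
from gaitage.io_config import SIXMWT_FEATURE_NAMES


class TestDetectSteps:
    def test_noise_free_walk_exact_count(self):
        p = ga.GaitModelParams(step_time=0.5, noise_sd=0.0, gyro_noise_sd=0.0)
        rec, truth = ga.simulate_6mwt(p, duration_s=360, seed=0)
        x = ga.lowpass(rec.acc_vt, ga.SIXMWT_FILTER, rec.fs)
        steps = ga.detect_steps(x, rec.fs)
        assert len(steps) == len(truth.step_times) == 720

    def test_interstep_times_match_generator(self):
        p = ga.GaitModelParams(step_time=0.6, asymmetry=0.0, noise_sd=0.0,
                               gyro_noise_sd=0.0)
        rec, _ = ga.simulate_6mwt(p, duration_s=60, seed=0)
        x = ga.lowpass(rec.acc_vt, ga.SIXMWT_FILTER, rec.fs)
        steps = ga.detect_steps(x, rec.fs)
        # first/last peaks carry zero-phase filter edge transients
        np.testing.assert_allclose(np.diff(steps)[1:-1], 0.6, atol=1.01 / rec.fs)

    def test_constant_signal_no_steps(self):
        assert len(ga.detect_steps(np.zeros(1000), 100.0)) == 0


class TestGaitParameters:
    def test_formula_arithmetic(self):
        steps = np.arange(720) * 0.5
        gp = ga.gait_parameters(steps, height_cm=160.0, duration_s=360.0,
                                k_height=0.83)
        assert gp["steps_per_s"] == pytest.approx(2.0)
        assert gp["step_time"] == pytest.approx(0.5)
        assert gp["stride_length"] == pytest.approx(1.328)
        assert gp["gait_distance"] == pytest.approx(478.08)
        assert gp["average_gait_speed"] == pytest.approx(1.328)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ga.ExtractionError):
            ga.gait_parameters(np.array([1.0]), 160.0, 360.0)


class TestUnbiasedAutocorr:
    def test_zero_lag_is_one(self):
        rng = np.random.default_rng(0)
        ac = ga.unbiased_autocorr(rng.normal(size=200), 50)
        assert ac[0] == pytest.approx(1.0)

    def test_sinusoid_peak_at_period(self):
        fs, f = 100.0, 2.0
        t = np.arange(0, 30, 1 / fs)
        ac = ga.unbiased_autocorr(np.sin(2 * np.pi * f * t), 100)
        assert ac[int(fs / f)] == pytest.approx(1.0, abs=1e-3)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        ac = ga.unbiased_autocorr(x, 119)
        xc = x - x.mean()
        a0 = sum(v * v for v in xc) / len(xc)
        for m in range(120):
            n = len(xc) - m
            expected = sum(xc[i] * xc[i + m] for i in range(n)) / n / a0
            assert ac[m] == pytest.approx(expected, abs=1e-9)

    def test_excessive_lag_rejected(self):
        with pytest.raises(ga.ParameterError):
            ga.unbiased_autocorr(np.zeros(10), 10)


class TestRegularity:
    fs = 100.0

    def _autocorr_of(self, x, max_lag=260):
        return ga.unbiased_autocorr(x, max_lag)

    def test_periodic_signal_sr_equals_str(self):
        t = np.arange(0, 60, 1 / self.fs)
        ac = self._autocorr_of(np.sin(2 * np.pi * 2.0 * t))
        sr, strr = ga.regularity(ac, self.fs, (0.25, 0.75), (0.75, 1.25))
        assert sr == pytest.approx(strr, abs=1e-3)
        assert sr == pytest.approx(1.0, abs=1e-2)

    def test_asymmetric_generator_sr_below_str(self):
        p = ga.GaitModelParams(asymmetry=0.4, noise_sd=0.0, gyro_noise_sd=0.0)
        rec, _ = ga.simulate_6mwt(p, duration_s=60, seed=0)
        x = ga.lowpass(rec.acc_vt, ga.SIXMWT_FILTER, rec.fs)
        ac = self._autocorr_of(x, int(2.6 * p.step_time * rec.fs))
        sr, strr = ga.regularity(ac, rec.fs,
                                 (0.5 * p.step_time, 1.5 * p.step_time),
                                 (1.5 * p.step_time, 2.5 * p.step_time))
        assert sr < strr

    def test_matches_brute_force_peak_scan(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 40, 1 / self.fs)
        x = np.sin(2 * np.pi * 1.8 * t) + 0.3 * np.sin(2 * np.pi * 0.9 * t) \
            + 0.1 * rng.normal(size=len(t))
        ac = self._autocorr_of(x)
        sr, strr = ga.regularity(ac, self.fs, (0.3, 0.8), (0.8, 1.4))
        for (lo, hi), got in (((0.3, 0.8), sr), ((0.8, 1.4), strr)):
            best = -np.inf
            for i in range(int(lo * self.fs), int(hi * self.fs) + 1):
                if ac[i] > ac[i - 1] and ac[i] > ac[i + 1]:
                    best = max(best, ac[i])
            assert got == pytest.approx(min(best, 1.0), abs=1e-12)

    def test_no_peak_raises(self):
        ac = np.linspace(1.0, 0.0, 200)  # monotone: no local maxima
        with pytest.raises(ga.RegularityError):
            ga.regularity(ac, self.fs, (0.3, 0.8), (0.8, 1.4))


class TestSymmetryIndex:
    @pytest.mark.parametrize("sr,strr,expected", [
        (0.9, 0.9, 0.0), (0.6, 0.8, -0.25), (0.8, 0.6, 0.25)])
    def test_examples(self, sr, strr, expected):
        assert ga.symmetry_index(sr, strr) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ga.ExtractionError):
            ga.symmetry_index(0.0, 0.0)


class TestHarmonicRatio:
    fs = 100.0
    stride_freq = 0.5  # 10 strides = 20 s = 2000 samples

    def _t(self, n=2000):
        return np.arange(n) / self.fs

    def test_pure_odd_harmonic_gives_zero_vt(self):
        x = np.sin(2 * np.pi * self.stride_freq * self._t())
        hr = ga.harmonic_ratio(x, self.fs, self.stride_freq, "acc_vt")
        assert hr == pytest.approx(0.0, abs=1e-6)

    def test_pure_even_harmonic_capped_vt(self):
        x = np.sin(2 * np.pi * 2 * self.stride_freq * self._t())
        hr = ga.harmonic_ratio(x, self.fs, self.stride_freq, "acc_vt")
        assert hr == HR_CAP

    def test_ml_uses_reciprocal_convention(self):
        x = np.sin(2 * np.pi * self.stride_freq * self._t())
        assert ga.harmonic_ratio(x, self.fs, self.stride_freq, "acc_ml") == HR_CAP

    def test_even_energy_strictly_increases_vt_hr(self):
        t = self._t()
        base = np.sin(2 * np.pi * self.stride_freq * t)
        hrs = [ga.harmonic_ratio(base + a * np.sin(2 * np.pi * 2 * self.stride_freq * t),
                                 self.fs, self.stride_freq, "acc_vt")
               for a in (0.2, 0.5, 1.0)]
        assert hrs[0] < hrs[1] < hrs[2]

    def test_matches_fft_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=2000)
        hr = ga.harmonic_ratio(x, self.fs, self.stride_freq, "acc_vt",
                               n_harmonics=20)
        # window length is an integer number of strides, so stride harmonics
        # fall exactly on FFT bins: harmonic k of 0.5 Hz -> bin 10 k
        mags = np.abs(np.fft.rfft(x - x.mean())) * 2.0 / len(x)
        even = sum(mags[10 * k] for k in range(2, 21, 2))
        odd = sum(mags[10 * k] for k in range(1, 21, 2))
        assert hr == pytest.approx(even / odd, abs=1e-9)

    def test_short_segment_rejected(self):
        with pytest.raises(ga.ExtractionError):
            ga.harmonic_ratio(np.zeros(100), self.fs, self.stride_freq, "acc_vt")


def apen_pincus_oracle(x, m, r):
    """Literal Pincus definition: Phi^m - Phi^(m+1), self-matches included."""
    def phi(mm):
        n = len(x) - mm + 1
        pats = [x[i:i + mm] for i in range(n)]
        total = 0.0
        for p in pats:
            c = sum(1 for q in pats
                    if max(abs(a - b) for a, b in zip(p, q)) <= r)
            total += math.log(c / n)
        return total / n
    return phi(m) - phi(m + 1)


class TestApproximateEntropy:
    def test_constant_series_zero(self):
        assert ga.approximate_entropy(np.full(200, 3.0)) == 0.0

    def test_matches_pincus_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        r = 0.2 * float(np.std(x))
        got = ga.approximate_entropy(x, 2, r)
        assert got == pytest.approx(apen_pincus_oracle(list(x), 2, r), abs=1e-9)

    def test_periodic_below_noise(self):
        t = np.arange(500) / 100.0
        periodic = np.sin(2 * np.pi * 2.0 * t)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, np.std(periodic), 500)
            assert (ga.approximate_entropy(periodic, 2, 0.2)
                    < ga.approximate_entropy(noise, 2, 0.2))

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ga.ParameterError):
            ga.approximate_entropy(np.arange(100.0), 2, 0.0)


class TestExtract6mwt:
    def test_exactly_21_named_features(self, walk_features):
        assert list(walk_features) == SIXMWT_FEATURE_NAMES

    def test_all_features_finite(self, walk_features):
        for name, value in walk_features.items():
            assert np.isfinite(value), name

    def test_regularity_bounds(self, walk_features):
        for axis in ("acc_vt", "acc_ap", "acc_res"):
            assert -1 <= walk_features[f"6mwt.sr.{axis}"] <= 1
            assert -1 <= walk_features[f"6mwt.str.{axis}"] <= 1
        for axis in ("acc_vt", "acc_ml", "acc_ap"):
            assert walk_features[f"6mwt.apen.{axis}"] >= 0
            assert walk_features[f"6mwt.hr.{axis}"] >= 0

    def test_symmetric_walk_si_near_zero(self, meta):
        p = ga.GaitModelParams(asymmetry=0.0, noise_sd=0.0, gyro_noise_sd=0.0)
        rec, _ = ga.simulate_6mwt(p, duration_s=60, seed=2)
        feats = ga.extract_6mwt_features(rec, meta)
        for axis in ("acc_vt", "acc_ap", "acc_res"):
            assert abs(feats[f"6mwt.si.{axis}"]) < 0.05
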