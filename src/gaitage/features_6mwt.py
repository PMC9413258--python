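"""The 21 six-minute-walk-test features.

Six gait parameters (step count, cadence, step time, stride length, walk
distance, mean speed) from vertical-acceleration peak detection; step and
stride regularity (SR, STR) and the symmetry index SI from the unbiased
autocorrelation of trunk acceleration on the vertical, anterior-posterior
and resultant axes; the harmonic ratio (HR) of the three acceleration axes
at stride-frequency harmonics; and Pincus approximate entropy (ApEn) of the
three axes.

Conventions
-----------
* The unbiased autocorrelation ``A(m) = (1/(N-m)) sum_i x_i x_{i+m}`` is
  computed on the mean-removed signal and normalised by ``A(0)``, so
  ``A(0) = 1`` and a perfectly periodic signal has peaks near 1.
* SR is the highest autocorrelation peak in a lag window around the step
  time, STR the highest peak in a window around the stride (two-step) time;
  ``SI = (SR - STR) / max(SR, STR)`` is 0 for perfectly symmetric gait.
* HR sums discrete Fourier magnitudes at harmonics 1..n of the stride
  frequency over ten-stride windows: even/odd for the vertical and
  anterior-posterior axes, odd/even for the mediolateral axis (whose
  fundamental is the stride frequency itself).  Smoother gait concentrates
  energy in the dominant harmonics and raises HR.
* ApEn(m, r) follows Pincus (self-matches included, Chebyshev distance),
  evaluated on consecutive epochs and averaged to bound the quadratic cost
  on six-minute records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ExtractionError, ParameterError, RegularityError
from .io_config import ImuRecording, SubjectMeta, SIXMWT_FEATURE_NAMES
from .preprocess import FilterSpec, SIXMWT_FILTER, lowpass, resultant_acceleration

#: sentinel returned when the HR denominator vanishes (pure even or pure
#: odd harmonic content)
HR_CAP = 1e3


# ---------------------------------------------------------------------------
# step detection and gait parameters
# ---------------------------------------------------------------------------

def detect_steps(acc_vt: np.ndarray, fs: float, min_step_s: float = 0.3,
                 height_frac: float = 0.25) -> np.ndarray:
    """Step event times from filtered vertical acceleration.

    Local maxima above ``height_frac`` of the signal's 95th percentile,
    separated by at least ``min_step_s``.  A flat signal yields no steps.
    """
    x = np.asarray(acc_vt, float)
    p95 = np.percentile(x, 95)
    if p95 <= 0:
        return np.array([])
    idx, _ = find_peaks(x, height=height_frac * p95,
                        distance=max(1, int(round(min_step_s * fs))))
    return idx / fs


def gait_parameters(steps: np.ndarray, height_cm: float, duration_s: float,
                    k_height: float = 0.83) -> dict[str, float]:
    """The six spatiotemporal gait parameters.

    Stride length is estimated from stature as ``k_height * height`` (m);
    walk distance is step count times half a stride.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    steps = np.asarray(steps, float)
    if len(steps) < 2:
        raise ExtractionError(f"need at least 2 steps, found {len(steps)}")
    stride_length = k_height * height_cm / 100.0
    n = len(steps)
    gait_distance = 0.5 * stride_length * n
    return {
        "number_of_steps": float(n),
        "steps_per_s": n / duration_s,
        "step_time": float(np.mean(np.diff(steps))),
        "stride_length": stride_length,
        "gait_distance": gait_distance,
        "average_gait_speed": gait_distance / duration_s,
    }


# ---------------------------------------------------------------------------
# regularity and symmetry
# ---------------------------------------------------------------------------

def unbiased_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalised unbiased autocorrelation at lags 0..max_lag.

    ``A(m) = (1/(N-m)) sum_i x_i x_{i+m}`` on the mean-removed signal,
    divided by ``A(0)`` so the zero-lag coefficient is exactly 1.
    """
    x = np.asarray(x, float)
    n = len(x)
    if max_lag >= n:
        raise ParameterError(f"max_lag {max_lag} must be < series length {n}")
    x = x - x.mean()
    ac = np.empty(max_lag + 1)
    for m in range(max_lag + 1):
        ac[m] = np.dot(x[: n - m], x[m:]) / (n - m)
    if ac[0] == 0:
        raise ExtractionError("zero-variance signal has no autocorrelation")
    return ac / ac[0]


def regularity(autocorr: np.ndarray, fs: float,
               step_window_s: tuple[float, float],
               stride_window_s: tuple[float, float]) -> tuple[float, float]:
    """(SR, STR): highest autocorrelation peaks in the step and stride windows."""
    ac = np.asarray(autocorr, float)
    peaks, _ = find_peaks(ac)

    def best(window: tuple[float, float], label: str) -> float:
        lo, hi = (int(np.floor(window[0] * fs)), int(np.ceil(window[1] * fs)))
        sel = peaks[(peaks >= lo) & (peaks <= hi)]
        if sel.size == 0:
            raise RegularityError(
                f"no autocorrelation peak in the {label} window "
                f"{window[0]:.2f}-{window[1]:.2f} s")
        return float(ac[sel].max())

    sr = best(step_window_s, "step")
    strr = best(stride_window_s, "stride")
    return min(sr, 1.0), min(strr, 1.0)


def symmetry_index(sr: float, strr: float) -> float:
    """SI = (SR - STR) / max(SR, STR); 0 for perfectly symmetric gait."""
    denom = max(sr, strr)
    if denom == 0:
        raise ExtractionError("SI undefined: both regularity peaks are zero")
    return (sr - strr) / denom


# ---------------------------------------------------------------------------
# harmonic ratio
# ---------------------------------------------------------------------------

def harmonic_ratio(acc: np.ndarray, fs: float, stride_freq: float,
                   axis: str, n_harmonics: int = 20) -> float:
    """HR of one acceleration segment spanning at least ten strides.

    Fourier magnitudes are evaluated at integer multiples of the stride
    frequency over the first exactly-ten-stride span.  For the vertical
    and anterior-posterior axes HR = even-sum / odd-sum; mediolateral is
    the reciprocal convention.  A vanishing denominator returns ``HR_CAP``.
    """
    if stride_freq <= 0:
        raise ParameterError("stride frequency must be positive")
    if axis not in ("acc_vt", "acc_ml", "acc_ap"):
        raise ParameterError(f"unknown axis {axis!r}")
    x = np.asarray(acc, float)
    n_ten = int(round(10.0 / stride_freq * fs))
    if len(x) < n_ten:
        raise ExtractionError(
            f"segment of {len(x)} samples is shorter than ten strides ({n_ten})")
    x = x[:n_ten] - x[:n_ten].mean()
    t = np.arange(n_ten) / fs
    k = np.arange(1, n_harmonics + 1)
    # DFT magnitudes at exact stride harmonics (k x stride_freq)
    phase = np.exp(-2j * math.pi * stride_freq * np.outer(k, t))
    mags = np.abs(phase @ x) * 2.0 / n_ten
    even = mags[1::2].sum()   # k = 2, 4, ...
    odd = mags[0::2].sum()    # k = 1, 3, ...
    num, den = (odd, even) if axis == "acc_ml" else (even, odd)
    if den <= num / HR_CAP:
        return HR_CAP
    return float(num / den)


# ---------------------------------------------------------------------------
# approximate entropy
# ---------------------------------------------------------------------------

def _phi_numpy(x: np.ndarray, m: int, r: float) -> float:
    """Vectorised Phi^m(r): mean log fraction of r-close embedded vectors."""
    n = len(x) - m + 1
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    dist = np.abs(emb[:, None, 0] - emb[None, :, 0])
    for j in range(1, m):
        np.maximum(dist, np.abs(emb[:, None, j] - emb[None, :, j]), out=dist)
    counts = (dist <= r).sum(axis=1)
    return float(np.mean(np.log(counts / n)))


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _phi_numba(x, m, r):  # type: ignore[misc]
        n = len(x) - m + 1
        total = 0.0
        for i in range(n):
            count = 0
            for j in range(n):
                d = 0.0
                for k in range(m):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                if d <= r:
                    count += 1
            total += math.log(count / n)
        return total / n

    _phi = _phi_numba
except ImportError:  # pragma: no cover
    _phi = _phi_numpy


def approximate_entropy(x: np.ndarray, m_embed: int = 2, r: float | None = None) -> float:
    """Pincus ApEn(m, r) of a series.

    ``r`` defaults to 0.2 times the series standard deviation.  Distances
    are Chebyshev and self-matches are counted, so a constant series (all
    embedded vectors identical) returns exactly 0.
    """
    x = np.asarray(x, float)
    if len(x) < m_embed + 2:
        raise ParameterError("series too short for the embedding dimension")
    if np.ptp(x) == 0:
        return 0.0
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ParameterError(f"tolerance r must be positive, got {r}")
    phi_m = _phi(x, m_embed, r)
    phi_m1 = _phi(x, m_embed + 1, r)
    return max(phi_m - phi_m1, 0.0)


# ---------------------------------------------------------------------------
# full feature set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SixMwtConfig:
    """Tunable parameters of the walk-test feature extraction."""

    filter_spec: FilterSpec = field(default=SIXMWT_FILTER)
    min_step_s: float = 0.3
    peak_height_frac: float = 0.25
    k_height: float = 0.83
    n_harmonics: int = 20
    apen_m: int = 2
    apen_r_frac: float = 0.2
    apen_epoch_s: float = 30.0
    hr_strides: int = 10


def _mean_hr(x: np.ndarray, fs: float, stride_freq: float, axis: str,
             cfg: SixMwtConfig) -> float:
    """HR averaged over consecutive non-overlapping ten-stride windows."""
    n_win = int(round(cfg.hr_strides / stride_freq * fs))
    n_full = len(x) // n_win
    if n_full == 0:
        raise ExtractionError("walk shorter than ten strides; cannot compute HR")
    vals = [harmonic_ratio(x[i * n_win:(i + 1) * n_win], fs, stride_freq,
                           axis, cfg.n_harmonics)
            for i in range(n_full)]
    return float(np.mean(vals))


def _mean_apen(x: np.ndarray, fs: float, cfg: SixMwtConfig) -> float:
    """ApEn averaged over consecutive epochs, with r from the whole series."""
    r = cfg.apen_r_frac * float(np.std(x))
    if r == 0:
        return 0.0
    n_epoch = int(round(cfg.apen_epoch_s * fs))
    n_full = max(len(x) // n_epoch, 1)
    vals = [approximate_entropy(x[i * n_epoch:(i + 1) * n_epoch], cfg.apen_m, r)
            for i in range(n_full)]
    return float(np.mean(vals))


def extract_6mwt_features(recording: ImuRecording, meta: SubjectMeta,
                          config: SixMwtConfig | None = None) -> dict[str, float]:
    """All 21 walk-test features of one recording."""
    cfg = config or SixMwtConfig()
    fs = recording.fs
    duration = recording.duration_s
    sig = {name: lowpass(recording.channels()[name], cfg.filter_spec, fs)
           for name in ("acc_vt", "acc_ml", "acc_ap")}
    sig["acc_res"] = resultant_acceleration(sig["acc_vt"], sig["acc_ml"],
                                            sig["acc_ap"])

    steps = detect_steps(sig["acc_vt"], fs, cfg.min_step_s, cfg.peak_height_frac)
    gp = gait_parameters(steps, meta.height_cm, duration, cfg.k_height)
    step_time = gp["step_time"]
    stride_freq = 1.0 / (2.0 * step_time)

    feats = {f"6mwt.gp.{k}": v for k, v in gp.items()}

    step_win = (0.5 * step_time, 1.5 * step_time)
    stride_win = (1.5 * step_time, 2.5 * step_time)
    max_lag = min(int(math.ceil(2.6 * step_time * fs)), len(recording.t) - 1)
    reg = {}
    for axis in ("acc_vt", "acc_ap", "acc_res"):
        ac = unbiased_autocorr(sig[axis], max_lag)
        reg[axis] = regularity(ac, fs, step_win, stride_win)
    for axis in ("acc_vt", "acc_ap", "acc_res"):
        feats[f"6mwt.sr.{axis}"] = reg[axis][0]
    for axis in ("acc_vt", "acc_ap", "acc_res"):
        feats[f"6mwt.str.{axis}"] = reg[axis][1]
    for axis in ("acc_vt", "acc_ap", "acc_res"):
        feats[f"6mwt.si.{axis}"] = symmetry_index(*reg[axis])

    for axis in ("acc_vt", "acc_ml", "acc_ap"):
        feats[f"6mwt.hr.{axis}"] = _mean_hr(sig[axis], fs, stride_freq, axis, cfg)
    for axis in ("acc_vt", "acc_ml", "acc_ap"):
        feats[f"6mwt.apen.{axis}"] = _mean_apen(sig[axis], fs, cfg)

    assert list(feats) == SIXMWT_FEATURE_NAMES
    return feats
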