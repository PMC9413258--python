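"""Signal conditioning applied before segmentation and feature extraction.

The low-pass step follows the MATLAB-style specification triple
(passband edge in pi rad/sample, steepness, stopband attenuation in dB):
the stopband edge is placed at ``fpass + (1 - steepness) * (fnyq - fpass)``
and the minimal-order Butterworth meeting the attenuation there is applied
forward-backward (zero phase), so event boundaries are not delayed.

Two named specs are provided as defaults: ``TUG_FILTER`` (passband
0.01*pi/sample, steepness 0.83, 60 dB) for the timed-up-and-go channels and
``SIXMWT_FILTER`` (0.02*pi/sample, 0.86, 40 dB) for the walk-test
acceleration.  At 100 Hz these come out as order-4 Butterworth designs with
roughly 0.8 Hz and 1.6 Hz natural frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError

#: passband ripple budget used when picking the minimal filter order, dB
_GPASS_DB = 0.1


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass design parameters.

    passband        passband edge as a fraction of pi rad/sample
                    (0.01 -> 0.5 Hz at 100 Hz sampling)
    steepness       transition sharpness in (0.5, 1); the transition band is
                    ``(1 - steepness)`` of the passband-to-Nyquist span
    stopband_atten  minimum stopband attenuation, dB
    zero_phase      apply forward-backward for zero group delay
    """

    passband: float
    steepness: float
    stopband_atten: float
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.passband < 1:
            raise ParameterError(f"passband must be in (0, 1), got {self.passband}")
        if not 0.5 < self.steepness < 1:
            raise ParameterError(f"steepness must be in (0.5, 1), got {self.steepness}")
        if self.stopband_atten <= 0:
            raise ParameterError("stopband attenuation must be positive")

    def design(self, fs: float):
        """Return (sos, order) of the minimal-order Butterworth design."""
        nyq = fs / 2.0
        fpass = self.passband * nyq
        fstop = fpass + (1.0 - self.steepness) * (nyq - fpass)
        order, wn = signal.buttord(fpass / nyq, fstop / nyq,
                                   _GPASS_DB, self.stopband_atten)
        sos = signal.butter(order, wn, btype="low", output="sos")
        return sos, order


TUG_FILTER = FilterSpec(passband=0.01, steepness=0.83, stopband_atten=60.0)
SIXMWT_FILTER = FilterSpec(passband=0.02, steepness=0.86, stopband_atten=40.0)


def resultant_acceleration(acc_vt: np.ndarray, acc_ml: np.ndarray,
                           acc_ap: np.ndarray) -> np.ndarray:
    """Euclidean norm of the three acceleration axes, per sample."""
    acc_vt = np.asarray(acc_vt, float)
    acc_ml = np.asarray(acc_ml, float)
    acc_ap = np.asarray(acc_ap, float)
    if not (acc_vt.shape == acc_ml.shape == acc_ap.shape):
        raise ParameterError(
            f"axis length mismatch: {acc_vt.shape}, {acc_ml.shape}, {acc_ap.shape}"
        )
    return np.sqrt(acc_vt**2 + acc_ml**2 + acc_ap**2)


def lowpass(series: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a 1-D series.

    Raises a :class:`ParameterError` when the series is too short for the
    filter's edge padding (length must exceed 3x the design order).
    """
    x = np.asarray(series, float)
    sos, order = spec.design(fs)
    if len(x) <= 3 * order:
        raise ParameterError(
            f"series of length {len(x)} too short for order-{order} filter"
        )
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def rectify(series: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(series, float))
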