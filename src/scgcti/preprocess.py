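"""Band-limiting and resampling of the raw channels.

The SCG is conditioned with a zero-phase band-pass Butterworth filter
(third order, 5-40 Hz) applied forward-backward, so the effective
magnitude response is the squared single-pass response and the net phase
is zero.  For R-peak detection the ECG gets its own gentler conditioning
(0.5-40 Hz).  Analysis runs at 1 kHz after polyphase resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps


class InvalidParameterError(ValueError):
    pass


@dataclass
class FilterSpec:
    low_cut: float = 5.0
    high_cut: float = 40.0
    order: int = 3
    zero_phase: bool = True


def bandpass_filter(x, sampling_rate: float, spec: FilterSpec | None = None):
    """Zero-phase Butterworth band-pass.

    Forward-backward application with odd-reflection edge padding of
    length 3 x (2 x order + 1).
    """
    spec = spec or FilterSpec()
    nyq = sampling_rate / 2.0
    if not 0.0 < spec.low_cut < spec.high_cut:
        raise InvalidParameterError("need 0 < low_cut < high_cut")
    if spec.high_cut >= nyq:
        raise InvalidParameterError(
            f"high_cut {spec.high_cut} Hz must be below Nyquist {nyq} Hz")
    x = np.asarray(x, dtype=float)
    b, a = sps.butter(spec.order, [spec.low_cut / nyq, spec.high_cut / nyq],
                      btype="bandpass")
    if spec.zero_phase:
        return sps.filtfilt(b, a, x)  # default padding: odd, 3*(2*order+1)
    return sps.lfilter(b, a, x)


def filter_ecg(x, sampling_rate: float):
    """ECG conditioning for R detection: 0.5-40 Hz, order 3, zero phase."""
    return bandpass_filter(x, sampling_rate,
                           FilterSpec(low_cut=0.5, high_cut=40.0, order=3))


def resample_signal(x, from_rate: float, to_rate: float):
    """Polyphase resampling preserving duration to within one output sample."""
    if from_rate <= 0 or to_rate <= 0:
        raise InvalidParameterError("sampling rates must be positive")
    x = np.asarray(x, dtype=float)
    if from_rate == to_rate:
        return x.copy()
    frac = Fraction(to_rate / from_rate).limit_denominator(10000)
    # work on the mean-removed signal: the anti-alias FIR's DC gain is not
    # exactly 1, and this keeps constants exactly constant
    m = float(np.mean(x)) if len(x) else 0.0
    return sps.resample_poly(x - m, frac.numerator, frac.denominator,
                             padtype="line") + m
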