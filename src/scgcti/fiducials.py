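"""Fiducial-point detection, waveform classification and cardiac time intervals.

The four fiducial points (FPs) of the dorso-ventral SCG — mitral closure
(MC), aortic opening (AO), aortic closure (AC), mitral opening (MO) — are
located on the ensemble-averaged beat as the most topographically
prominent local extremum inside an event-specific search window.
Prominence rather than raw amplitude makes detection invariant to
baseline offset.  A beat is classed traditional (T) when all four FPs are
identifiable with consistent ordering, non-traditional (NT) otherwise;
this is an explicit algorithmic surrogate for the expert visual call that
is the field's current standard, and outputs carry that provenance.

Cardiac time intervals follow the standard definitions: PEP = Q to AO,
IVCT = MC to AO, LVET = AO to AC, IVRT = AC to MO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .beats import AverageBeat

FP_NAMES = ("MC", "AO", "AC", "MO")

#: Default search windows, ms from R.  MO's window is anchored to the
#: detected AC.  Diastolic windows stretch with the mean RR interval.
DEFAULT_WINDOWS = {"MC": (10.0, 60.0), "AO": (45.0, 160.0),
                   "AC": (250.0, 450.0), "MO": (20.0, 180.0)}


class WindowCoverageError(ValueError):
    """The averaged beat does not span the requested search windows."""


@dataclass
class FiducialSet:
    latencies: dict = field(default_factory=dict)     # event -> ms from R
    prominences: dict = field(default_factory=dict)   # event -> a.u.
    found: dict = field(default_factory=dict)         # event -> bool
    windows_used: dict = field(default_factory=dict)  # event -> (lo, hi) ms

    def ordered(self) -> bool:
        """True when all four latencies exist and satisfy MC < AO < AC < MO."""
        if not all(self.found.get(e) for e in FP_NAMES):
            return False
        lat = [self.latencies[e] for e in FP_NAMES]
        return 0.0 < lat[0] < lat[1] < lat[2] < lat[3]


@dataclass
class WaveformClass:
    label: str                               # 'T' | 'NT'
    availability: dict                       # event -> bool
    note: str = ""
    method: str = "algorithmic-prominence-surrogate"


@dataclass
class CTISet:
    PEP: float | None = None
    IVCT: float | None = None
    LVET: float | None = None
    IVRT: float | None = None


def _window_indices(time_ms: np.ndarray, lo: float, hi: float):
    idx = np.flatnonzero((time_ms >= lo) & (time_ms <= hi))
    if len(idx) < 3:
        raise WindowCoverageError(
            f"beat axis [{time_ms[0]:.0f}, {time_ms[-1]:.0f}] ms does not "
            f"cover search window [{lo:.0f}, {hi:.0f}] ms")
    return idx


def _best_peak(samples: np.ndarray, time_ms: np.ndarray, lo: float, hi: float,
               polarity: int = 1):
    """Most prominent local extremum inside [lo, hi]; ties go earlier.

    Prominence is topographic, computed on the whole beat so window edges
    do not inflate it.  Returns (latency_ms, prominence) or (None, 0).
    """
    y = samples * polarity
    y = np.where(np.isfinite(y), y, np.nanmin(y[np.isfinite(y)]) if np.isfinite(y).any() else 0.0)
    peaks, props = sps.find_peaks(y, prominence=0.0)
    idx = _window_indices(time_ms, lo, hi)
    in_win = peaks[(peaks >= idx[0]) & (peaks <= idx[-1])]
    if len(in_win) == 0:
        return None, 0.0
    prom = props["prominences"][np.isin(peaks, in_win)]
    best = np.argmax(prom)          # argmax returns the first (earliest) tie
    return float(time_ms[in_win[best]]), float(prom[best])


def detect_fiducials(beat: AverageBeat, windows: dict | None = None,
                     prominence_frac: float = 0.10,
                     polarity: dict | None = None,
                     noise_factor: float = 5.0) -> FiducialSet:
    """Locate MC, AO, AC and MO on an averaged beat.

    Search proceeds left to right: the AO window is clipped to start
    after a detected MC, and MO is searched relative to the detected AC.
    Diastolic windows (AC, and MO's anchor-relative span) scale with
    ``beat.mean_rr``/1000 when the mean RR is known, since diastole
    shortens at faster rates.  A point counts as found when its
    prominence reaches ``prominence_frac`` of the beat's peak-to-peak
    amplitude and, when the average carries a residual-noise estimate
    (``beat.noise_sem``), also ``noise_factor`` times that level — a
    repeatable pattern must stand clear of what ensemble averaging left
    of the non-repeatable noise, otherwise residual noise wiggles in a
    low-amplitude beat would masquerade as fiducial points.
    """
    win = dict(DEFAULT_WINDOWS)
    if windows:
        win.update(windows)
    pol = {e: 1 for e in FP_NAMES}
    if polarity:
        pol.update(polarity)

    t = beat.time_ms
    y = beat.samples
    finite = np.isfinite(y)
    p2p = float(np.ptp(y[finite])) if finite.any() else 0.0
    thresh = prominence_frac * p2p
    if beat.noise_sem is not None:
        thresh = max(thresh, noise_factor * beat.noise_sem)

    scale = 1.0
    if beat.mean_rr is not None and beat.mean_rr > 0:
        scale = beat.mean_rr / 1000.0

    fps = FiducialSet()

    def record(ev, lo, hi):
        lat, prom = _best_peak(y, t, lo, hi, pol[ev])
        ok = lat is not None and prom >= thresh and thresh > 0
        fps.latencies[ev] = lat if ok else None
        fps.prominences[ev] = prom
        fps.found[ev] = bool(ok)
        fps.windows_used[ev] = (lo, hi)
        return fps.latencies[ev]

    mc = record("MC", *win["MC"])
    ao_lo, ao_hi = win["AO"]
    if mc is not None:
        ao_lo = max(ao_lo, mc + t[1] - t[0])
    ao = record("AO", ao_lo, ao_hi)
    ac_lo, ac_hi = win["AC"][0] * scale, win["AC"][1] * scale
    if ao is not None:
        ac_lo = max(ac_lo, ao + (t[1] - t[0]))
    ac = record("AC", ac_lo, min(ac_hi, t[-1]))
    if ac is not None:
        mo_lo = ac + win["MO"][0] * scale
        mo_hi = min(ac + win["MO"][1] * scale, t[-1])
    else:      # AC missing: span the whole range an AC-anchored window could reach
        mo_lo = ac_lo + win["MO"][0] * scale
        mo_hi = min(ac_hi + win["MO"][1] * scale, t[-1])
    record("MO", mo_lo, mo_hi)
    return fps


def classify_waveform(fps: FiducialSet) -> WaveformClass:
    """Traditional iff all four FPs are found with MC < AO < AC < MO."""
    avail = {e: bool(fps.found.get(e)) for e in FP_NAMES}
    if all(avail.values()):
        if fps.ordered():
            return WaveformClass(label="T", availability=avail)
        return WaveformClass(label="NT", availability=avail,
                             note="ordering violation: latencies not MC<AO<AC<MO")
    return WaveformClass(label="NT", availability=avail)


def compute_ctis(fps: FiducialSet, q_to_r: float) -> CTISet:
    """Cardiac time intervals from FP latencies and the Q-to-R interval.

    Any interval with a missing endpoint is left absent; partial FP sets
    yield partial interval sets.
    """
    if q_to_r < 0:
        raise ValueError("q_to_r must be non-negative")
    lat = {e: (fps.latencies.get(e) if fps.found.get(e) else None)
           for e in FP_NAMES}
    ctis = CTISet()
    if lat["AO"] is not None:
        ctis.PEP = lat["AO"] + q_to_r
        if lat["MC"] is not None:
            ctis.IVCT = lat["AO"] - lat["MC"]
        if lat["AC"] is not None:
            ctis.LVET = lat["AC"] - lat["AO"]
    if lat["AC"] is not None and lat["MO"] is not None:
        ctis.IVRT = lat["MO"] - lat["AC"]
    return ctis
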