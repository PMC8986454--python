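"""R/Q detection, beat-quality screening and ensemble averaging.

The patient's typical SCG waveform is obtained by selecting a window of
at least six good-quality beats and averaging the R-aligned SCG segments
sample-wise.  When no such window exists (frequent ectopy), a single
clean sinus beat stands in for the average, mirroring how patients with
frequent ectopic beats are handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import filter_ecg


class NoUsableBeatsError(RuntimeError):
    """No beat of acceptable quality exists in the record."""


@dataclass
class BeatSeries:
    """Per-beat timing and quality bookkeeping for one record."""

    r_times: np.ndarray                      # ms from record start
    q_times: np.ndarray | None = None        # ms, NaN where undetectable
    quality: list = field(default_factory=list)   # 'good'|'ectopic'|'noisy'

    def __post_init__(self):
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.q_times is not None:
            self.q_times = np.asarray(self.q_times, dtype=float)
        if not self.quality:
            self.quality = ["good"] * len(self.r_times)

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.r_times)

    @property
    def n_beats(self) -> int:
        return len(self.r_times)


@dataclass
class AverageBeat:
    """Ensemble-averaged SCG beat on a ms axis relative to the R peak."""

    time_ms: np.ndarray
    samples: np.ndarray
    n_beats_used: int
    mean_rr: float | None = None
    single_beat: bool = False
    #: residual-noise level of the average: median per-sample standard
    #: error across beats.  None when only one beat was averaged.
    noise_sem: float | None = None

    def __post_init__(self):
        if not (self.time_ms[0] <= 0.0 <= self.time_ms[-1]):
            raise ValueError("average-beat axis must contain the R instant (0 ms)")
        if self.n_beats_used < 1:
            raise ValueError("n_beats_used must be >= 1")


@dataclass
class SelectedWindow:
    beat_indices: np.ndarray
    single_beat: bool = False


def detect_r_peaks(ecg, sampling_rate: float) -> BeatSeries:
    """Detect R peaks with a 200 ms refractory period.

    Detection runs on a 0.5-40 Hz conditioned copy; each peak is then
    refined to the local maximum of the raw ECG within +/-10 ms, so the
    reported time sits on the true R apex.  A flat or peak-free signal
    yields an empty series, not an error.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * sampling_rate:
        raise ValueError("need at least 2 s of ECG")
    if np.ptp(ecg) == 0.0:
        return BeatSeries(r_times=np.empty(0))
    y = filter_ecg(ecg, sampling_rate)
    refractory = int(round(0.2 * sampling_rate))
    height = np.median(y) + 0.5 * (np.percentile(y, 99.5) - np.median(y))
    peaks, _ = sps.find_peaks(y, height=height, distance=refractory)
    if len(peaks) == 0:
        return BeatSeries(r_times=np.empty(0))
    # refine on the raw channel
    half = max(1, int(round(0.010 * sampling_rate)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    return BeatSeries(r_times=refined / sampling_rate * 1000.0)


def detect_q_points(ecg, r_times, sampling_rate: float) -> np.ndarray:
    """Q = ECG minimum in [R-60 ms, R-4 ms]; NaN where the window is cut."""
    ecg = np.asarray(ecg, dtype=float)
    q_times = np.full(len(r_times), np.nan)
    for i, r in enumerate(np.asarray(r_times, dtype=float)):
        lo = int(round((r - 60.0) / 1000.0 * sampling_rate))
        hi = int(round((r - 4.0) / 1000.0 * sampling_rate))
        if lo < 0 or hi >= len(ecg) or hi <= lo:
            continue
        q_idx = lo + int(np.argmin(ecg[lo:hi + 1]))
        q_times[i] = q_idx / sampling_rate * 1000.0
    return q_times


def _running_median5(x: np.ndarray) -> np.ndarray:
    """Centred running median of 5 with edge shrinkage."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - 2), min(n, i + 3)
        out[i] = np.median(x[lo:hi])
    return out


def flag_beat_quality(series: BeatSeries, scg, sampling_rate: float,
                      rr_tol: float = 0.20, rms_factor: float = 3.0) -> BeatSeries:
    """Flag each beat good / ectopic / noisy.

    A beat is ectopic when the RR interval ending on it falls more than
    ``rr_tol`` below the running median of five intervals (premature), or
    rises above it without following a premature interval — the long beat
    after a premature one is the compensatory pause of a sinus beat and
    is kept.  A beat is noisy when its SCG segment RMS exceeds
    ``rms_factor`` times the median beat RMS.
    """
    if series.n_beats == 0:
        raise ValueError("empty beat series")
    scg = np.asarray(scg, dtype=float)
    rr = series.rr_intervals
    quality = ["good"] * series.n_beats
    if len(rr) > 0:
        med = _running_median5(rr)
        dev = (rr - med) / med
        for i in range(len(rr)):       # interval i ends on beat i+1
            if dev[i] < -rr_tol:
                quality[i + 1] = "ectopic"
            elif dev[i] > rr_tol and not (i > 0 and dev[i - 1] < -rr_tol):
                quality[i + 1] = "ectopic"

    # per-beat SCG RMS over a fixed window around R
    rms = np.full(series.n_beats, np.nan)
    for i, r in enumerate(series.r_times):
        lo = int(round((r - 100.0) / 1000.0 * sampling_rate))
        hi = int(round((r + 600.0) / 1000.0 * sampling_rate))
        lo, hi = max(0, lo), min(len(scg), hi)
        if hi > lo:
            rms[i] = np.sqrt(np.mean(scg[lo:hi] ** 2))
    med_rms = np.nanmedian(rms)
    if np.isfinite(med_rms) and med_rms > 0:
        for i in range(series.n_beats):
            if np.isfinite(rms[i]) and rms[i] > rms_factor * med_rms:
                quality[i] = "noisy"
    return BeatSeries(r_times=series.r_times, q_times=series.q_times,
                      quality=quality)


def select_window(series: BeatSeries, min_beats: int = 6) -> SelectedWindow:
    """Earliest contiguous run of >= ``min_beats`` good beats.

    Falls back to the single good beat with the most regular RR when no
    such run exists; raises :class:`NoUsableBeatsError` when every beat
    is flagged.
    """
    good = np.array([q == "good" for q in series.quality])
    if not good.any():
        raise NoUsableBeatsError("no good-quality beats in record")
    run_start, run_len = None, 0
    for i, g in enumerate(good):
        if g:
            if run_start is None:
                run_start = i
            run_len += 1
            if run_len >= min_beats:
                # extend to the full contiguous run
                j = i
                while j + 1 < len(good) and good[j + 1]:
                    j += 1
                return SelectedWindow(np.arange(run_start, j + 1))
        else:
            run_start, run_len = None, 0
    # single-beat fallback: the good beat with smallest RR irregularity
    idx = np.flatnonzero(good)
    rr = series.rr_intervals
    if len(rr) == 0:
        best = idx[0]
    else:
        med = np.median(rr)

        def irregularity(i):
            devs = [abs(rr[j] - med) for j in (i - 1, i) if 0 <= j < len(rr)]
            return min(devs) if devs else np.inf

        best = min(idx, key=irregularity)
    return SelectedWindow(np.array([best]), single_beat=True)


def ensemble_average(scg, series: BeatSeries, sampling_rate: float,
                     window_ms: tuple = (-100.0, 600.0),
                     beat_indices=None) -> AverageBeat:
    """Sample-wise mean of R-aligned SCG segments.

    Each output sample averages only the beats whose window covers it, so
    segments truncated at a record edge drop out of the affected samples
    without biasing the rest of the average.
    """
    scg = np.asarray(scg, dtype=float)
    if beat_indices is None:
        beat_indices = np.arange(series.n_beats)
    beat_indices = np.asarray(beat_indices)
    if len(beat_indices) == 0:
        raise ValueError("no beats to average")
    lo_ms, hi_ms = window_ms
    n_lo = int(round(lo_ms / 1000.0 * sampling_rate))
    n_hi = int(round(hi_ms / 1000.0 * sampling_rate))
    width = n_hi - n_lo + 1
    acc = np.zeros(width)
    acc2 = np.zeros(width)
    cnt = np.zeros(width, dtype=int)
    for bi in beat_indices:
        r_idx = int(round(series.r_times[bi] / 1000.0 * sampling_rate))
        lo, hi = r_idx + n_lo, r_idx + n_hi + 1
        src_lo, src_hi = max(0, lo), min(len(scg), hi)
        if src_hi <= src_lo:
            continue
        dst_lo = src_lo - lo
        seg = scg[src_lo:src_hi]
        acc[dst_lo:dst_lo + len(seg)] += seg
        acc2[dst_lo:dst_lo + len(seg)] += seg ** 2
        cnt[dst_lo:dst_lo + len(seg)] += 1
    if cnt.max() == 0:
        raise ValueError("averaging window lies outside the record for every beat")
    samples = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    time_ms = (np.arange(n_lo, n_hi + 1)) / sampling_rate * 1000.0
    rr = series.rr_intervals
    used = int(cnt.max())
    mean_rr = float(np.mean(rr)) if len(rr) else None

    # residual noise of the mean: per-sample across-beat SD / sqrt(count)
    noise_sem = None
    multi = cnt >= 2
    if multi.any():
        var = (acc2[multi] - acc[multi] ** 2 / cnt[multi]) / (cnt[multi] - 1)
        sem = np.sqrt(np.maximum(var, 0.0) / cnt[multi])
        noise_sem = float(np.median(sem))
    return AverageBeat(time_ms=time_ms, samples=samples, n_beats_used=used,
                       mean_rr=mean_rr, single_beat=(len(beat_indices) == 1),
                       noise_sem=noise_sem)
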