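"""Synthetic ECG + SCG record generation with known ground truth.

The generator emulates the two-channel recordings of a wearable
seismocardiography setup: one ECG lead plus the dorso-ventral chest
acceleration, digitized at 14 bit / 200 Hz.  Each heartbeat contributes a
stylized PQRST complex to the ECG channel and, on the SCG channel, a train
of Gaussian-windowed cosine bumps centred at the latencies of the four
valve events (mitral closure MC, aortic opening AO, aortic closure AC,
mitral opening MO).  "Traditional" (T) morphologies carry all four bumps;
"non-traditional" (NT) morphologies have one to four bumps suppressed and
broadband 5-40 Hz distortion added.  Respiratory amplitude modulation,
white measurement noise, RR variability, occasional ectopic beats and the
2.64 ms/pixel quantization of sonogram-derived annotations are all
modelled, so every downstream stage can be validated against exact ground
truth without any recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as sstats

FP_NAMES = ("MC", "AO", "AC", "MO")

DEFAULT_FP_LATENCIES = {"MC": 30.0, "AO": 80.0, "AC": 380.0, "MO": 460.0}
# AO is typically the most prominent systolic complex of the dorso-ventral SCG.
DEFAULT_FP_AMPLITUDES = {"MC": 1.0, "AO": 2.0, "AC": 1.2, "MO": 0.9}


class InvalidParameterError(ValueError):
    """A generator parameter violates its contract."""


@dataclass
class SynthConfig:
    """Parameters of one synthetic patient recording.

    Latencies are milliseconds from the R peak; amplitudes are relative
    units; ``noise_sd`` is a fraction of the clean beat's peak-to-peak
    amplitude; ``bump_width_ms`` is the full width (~2 sigma) of the
    Gaussian envelope of each valve-event bump.
    """

    sampling_rate: float = 200.0
    duration: float = 300.0
    mean_rr: float = 857.0
    rr_sd: float = 40.0
    ectopic_rate: float = 0.0
    morphology: str = "traditional"
    fp_latencies: dict = field(default_factory=lambda: dict(DEFAULT_FP_LATENCIES))
    fp_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_FP_AMPLITUDES))
    noise_sd: float = 0.05
    resp_mod_depth: float = 0.2
    resp_period: float = 4.0
    quantization_bits: int = 14
    bump_width_ms: float = 20.0
    carrier_hz: float = 15.0
    q_offset_ms: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if not np.isfinite(self.mean_rr) or self.mean_rr <= 0:
            raise InvalidParameterError("mean_rr must be finite and positive")
        if self.rr_sd < 0:
            raise InvalidParameterError("rr_sd must be non-negative")
        if not 0.0 <= self.ectopic_rate <= 1.0:
            raise InvalidParameterError("ectopic_rate must be in [0, 1]")
        if self.morphology not in ("traditional", "non_traditional"):
            raise InvalidParameterError(f"unknown morphology {self.morphology!r}")
        if self.sampling_rate <= 2 * 40.0:
            raise InvalidParameterError("sampling_rate must exceed 80 Hz (2 x 40 Hz band edge)")
        if self.duration * 1000.0 < 3 * self.mean_rr:
            raise InvalidParameterError("duration must cover at least 3 beats")
        if not 0.0 <= self.resp_mod_depth < 1.0:
            raise InvalidParameterError("resp_mod_depth must be in [0, 1)")
        if self.morphology == "traditional":
            lat = [self.fp_latencies[k] for k in FP_NAMES]
            if not (0.0 < lat[0] < lat[1] < lat[2] < lat[3]):
                raise InvalidParameterError(
                    "traditional morphology requires 0 < MC < AO < AC < MO latencies"
                )


@dataclass
class GroundTruth:
    """Exact construction record of a synthetic recording."""

    r_times: np.ndarray            # ms from record start
    q_offsets: np.ndarray          # ms before R, per beat
    valve_times: list              # per beat: {event: ms-from-R} (sinus beats)
    beat_labels: list              # 'sinus' | 'ectopic', per beat
    true_class: str                # 'T' | 'NT'
    suppressed_fps: tuple = ()     # events removed in NT morphology


@dataclass
class EchoAnnotationTruth:
    """Sonogram-style annotation of one valve event over a run of beats."""

    event: str
    start_beat: int
    rr_sequence: np.ndarray         # ms, between the displayed beats
    event_times_from_r: np.ndarray  # ms, pixel-quantized


def generate_rr_series(config: SynthConfig, n_beats: int | None = None,
                       rng: np.random.Generator | None = None):
    """Draw an RR-interval series with sinus/ectopic labels.

    Sinus intervals come from a normal law truncated to
    [0.5, 1.5] x mean_rr.  An ectopic event replaces one interval of
    length r by a premature 0.6 r interval followed by a compensatory
    1.4 r interval; the beat terminating the premature interval is
    labelled ``'ectopic'``.

    Returns ``(rr_ms, labels)`` where ``labels[i]`` describes the beat
    that ends interval ``i``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    target_ms = None if n_beats is not None else config.duration * 1000.0

    lo, hi = 0.5 * config.mean_rr, 1.5 * config.mean_rr
    rrs: list[float] = []
    labels: list[str] = []

    def draw_sinus() -> float:
        if config.rr_sd == 0:
            return config.mean_rr
        a = (lo - config.mean_rr) / config.rr_sd
        b = (hi - config.mean_rr) / config.rr_sd
        return float(sstats.truncnorm.rvs(a, b, loc=config.mean_rr,
                                          scale=config.rr_sd, random_state=rng))

    total = 0.0
    while True:
        if n_beats is not None and len(rrs) >= n_beats:
            break
        if target_ms is not None and total >= target_ms:
            break
        r = draw_sinus()
        if rng.uniform() < config.ectopic_rate:
            rrs.extend([0.6 * r, 1.4 * r])
            labels.extend(["ectopic", "sinus"])
            total += 2.0 * r
        else:
            rrs.append(r)
            labels.append("sinus")
            total += r
    if n_beats is not None:
        rrs, labels = rrs[:n_beats], labels[:n_beats]
    return np.asarray(rrs, dtype=float), labels


def _gauss(t_ms: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)


def _ecg_beat(t_ms: np.ndarray, q_offset: float) -> np.ndarray:
    """Stylized PQRST complex on a ms axis relative to R (R amplitude 1)."""
    y = 0.15 * _gauss(t_ms, -160.0, 20.0)          # P
    y -= 0.12 * _gauss(t_ms, -q_offset, 4.0)       # Q
    y += 1.00 * _gauss(t_ms, 0.0, 7.0)             # R
    y -= 0.20 * _gauss(t_ms, 25.0, 6.0)            # S
    y += 0.30 * _gauss(t_ms, 180.0, 35.0)          # T
    return y


def _scg_beat(t_ms: np.ndarray, latencies: dict, amplitudes: dict,
              sigma_ms: float, carrier_hz: float) -> np.ndarray:
    """Sum of Gaussian-windowed cosine bumps, one per valve event.

    The cosine carrier peaks at the bump centre, so the envelope centre is
    a local maximum of the clean template.
    """
    y = np.zeros_like(t_ms)
    for ev, c in latencies.items():
        a = amplitudes.get(ev, 1.0)
        y += a * _gauss(t_ms, c, sigma_ms) * np.cos(
            2.0 * math.pi * carrier_hz * (t_ms - c) / 1000.0)
    return y


def _quantize(x: np.ndarray, bits: int) -> np.ndarray:
    """Uniform mid-tread quantization to ``bits`` over the signal's range."""
    full = float(np.max(np.abs(x)))
    if full == 0.0:
        return x
    lsb = 2.0 * full / (2 ** bits)
    return np.round(x / lsb) * lsb


def generate_record(config: SynthConfig, patient_id: str = "synth",
                    metadata: dict | None = None):
    """Generate one synchronous ECG+SCG record and its ground truth.

    Returns ``(SignalRecord, GroundTruth)``.
    """
    from .sigio import SignalRecord  # local import avoids a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t_ms = np.arange(n) / fs * 1000.0

    rrs, labels = generate_rr_series(config, rng=rng)
    first_r = 400.0
    r_times = first_r + np.concatenate([[0.0], np.cumsum(rrs)])
    keep = r_times <= t_ms[-1] - 100.0
    r_times = r_times[keep]
    beat_labels = (["sinus"] + labels)[: len(r_times)]
    if len(r_times) < 3:
        raise InvalidParameterError("duration too short: fewer than 3 beats fit")

    suppressed: tuple = ()
    latencies = dict(config.fp_latencies)
    if config.morphology == "non_traditional":
        k = int(rng.integers(1, 5))
        suppressed = tuple(sorted(str(e) for e in
                                  rng.choice(FP_NAMES, size=k, replace=False)))
        latencies = {e: v for e, v in latencies.items() if e not in suppressed}

    sigma = config.bump_width_ms / 2.0
    # amplitude reference: the full (unsuppressed) beat template, so noise
    # levels mean the same thing for T and NT morphologies
    ref_t = np.arange(-100.0, 600.0, 1000.0 / fs)
    full_beat = _scg_beat(ref_t, dict(config.fp_latencies), config.fp_amplitudes,
                          sigma, config.carrier_hz)
    clean_p2p = float(np.ptp(full_beat)) or 1.0
    ecg = np.zeros(n)
    scg = np.zeros(n)
    q_offsets = np.full(len(r_times), config.q_offset_ms)
    valve_times = []
    for i, r in enumerate(r_times):
        rel = t_ms - r
        win = (rel >= -300.0) & (rel <= 700.0)
        ecg[win] += _ecg_beat(rel[win], config.q_offset_ms)
        scg[win] += _scg_beat(rel[win], latencies, config.fp_amplitudes,
                              sigma, config.carrier_hz)
        valve_times.append(dict(latencies))

    if config.morphology == "non_traditional":
        # broadband 5-40 Hz distortion at half the beat amplitude
        white = rng.standard_normal(n)
        ny = fs / 2.0
        b, a = sps.butter(3, [5.0 / ny, 40.0 / ny], btype="bandpass")
        colored = sps.filtfilt(b, a, white)
        colored *= 0.5 * clean_p2p / (2.0 * np.std(colored))
        scg = scg + colored

    if config.resp_mod_depth > 0:
        scg = scg * (1.0 + config.resp_mod_depth
                     * np.sin(2.0 * math.pi * t_ms / 1000.0 / config.resp_period))
    if config.noise_sd > 0:
        scg = scg + rng.standard_normal(n) * config.noise_sd * clean_p2p
        ecg = ecg + rng.standard_normal(n) * 0.02

    ecg = _quantize(ecg, config.quantization_bits)
    scg = _quantize(scg, config.quantization_bits)

    truth = GroundTruth(
        r_times=r_times,
        q_offsets=q_offsets,
        valve_times=valve_times,
        beat_labels=beat_labels,
        true_class="T" if config.morphology == "traditional" else "NT",
        suppressed_fps=suppressed,
    )
    meta = {"diagnosis": None, "ejection_fraction": None}
    if metadata:
        meta.update(metadata)
    rec = SignalRecord(ecg=ecg, scg=scg, sampling_rate=fs,
                       patient_id=patient_id, metadata=meta)
    return rec, truth


def generate_echo_annotation(truth: GroundTruth, event: str, n_beats: int = 4,
                             jitter_sd: float = 2.0, pixel_ms: float = 2.64,
                             seed: int | None = None, start_beat: int | None = None,
                             allow_any_n: bool = False) -> EchoAnnotationTruth:
    """Emulate a sonogram reading of one valve event over 3-5 beats.

    The annotated time-from-R equals ground truth plus N(0, jitter_sd^2)
    reading error, then rounded to the nearest multiple of the sonogram's
    pixel pitch (2.64 ms in the emulated US machine).
    """
    if event not in FP_NAMES:
        raise InvalidParameterError(f"unknown valve event {event!r}")
    if not allow_any_n and not 3 <= n_beats <= 5:
        raise InvalidParameterError("n_beats must be in [3, 5]")
    rng = np.random.default_rng(seed)

    labels = truth.beat_labels
    if start_beat is None:
        start_beat = -1
        run = 0
        for i, lab in enumerate(labels):
            run = run + 1 if lab == "sinus" else 0
            if run >= n_beats:
                start_beat = i - n_beats + 1
                break
        if start_beat < 0:
            raise InvalidParameterError(
                f"no run of {n_beats} consecutive sinus beats in ground truth")
    if start_beat + n_beats > len(truth.r_times):
        raise InvalidParameterError("annotation window exceeds record")

    rr_seq = np.diff(truth.r_times[start_beat:start_beat + n_beats])
    times = []
    for i in range(start_beat, start_beat + n_beats):
        tv = truth.valve_times[i].get(event)
        if tv is None:
            raise InvalidParameterError(f"event {event} absent from beat {i}")
        noisy = tv + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        times.append(np.round(noisy / pixel_ms) * pixel_ms if pixel_ms > 0 else noisy)
    return EchoAnnotationTruth(event=event, start_beat=start_beat,
                               rr_sequence=rr_seq,
                               event_times_from_r=np.asarray(times))


def generate_cohort(n_patients: int, group_mix: dict | None = None,
                    t_prevalence: dict | None = None, seed: int = 0,
                    duration: float = 30.0, base_config: SynthConfig | None = None):
    """Generate a patient cohort with per-group traditional-shape prevalence.

    ``group_mix`` gives diagnosis proportions over {MI, HF, TX} and
    ``t_prevalence`` the probability of a traditional waveform per group;
    defaults mirror a rehabilitation cohort of infarction, failure and
    transplant patients.  Per-patient physiology (heart rate, RR
    variability, valve-event latencies, ejection fraction) is sampled
    within realistic ranges.  Records default to 30 s: downstream analysis
    uses only the earliest window of six good beats, so longer records add
    runtime without information.

    Returns a list of ``(SignalRecord, GroundTruth, metadata)`` triples.
    """
    if n_patients <= 0:
        raise InvalidParameterError("n_patients must be positive")
    group_mix = group_mix or {"MI": 34 / 90, "HF": 49 / 90, "TX": 7 / 90}
    t_prevalence = t_prevalence or {"MI": 26 / 34, "HF": 27 / 49, "TX": 3 / 7}
    if abs(sum(group_mix.values()) - 1.0) > 1e-9 or min(group_mix.values()) < 0:
        raise InvalidParameterError("group_mix must be non-negative proportions summing to 1")
    for g, p in t_prevalence.items():
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError(f"t_prevalence[{g}] outside [0, 1]")

    # mean EF per diagnosis group (%): infarction ~43, failure ~30, transplant ~57
    ef_mean = {"MI": 43.0, "HF": 30.0, "TX": 57.0}
    rng = np.random.default_rng(seed)
    groups = list(group_mix)
    probs = np.array([group_mix[g] for g in groups])
    base = base_config or SynthConfig()

    cohort = []
    for i in range(n_patients):
        g = groups[int(rng.choice(len(groups), p=probs))]
        is_t = rng.uniform() < t_prevalence[g]
        mean_rr = rng.uniform(700.0, 1100.0)
        # diastolic latencies shorten with faster rates (systole much less)
        scale = mean_rr / 1000.0
        lat = {
            "MC": rng.uniform(20.0, 45.0),
            "AO": rng.uniform(65.0, 110.0),
            "AC": rng.uniform(330.0, 420.0) * scale,
        }
        lat["MO"] = lat["AC"] + rng.uniform(60.0, 120.0) * scale
        cfg = replace(
            base,
            duration=duration,
            mean_rr=mean_rr,
            rr_sd=rng.uniform(20.0, 60.0),
            morphology="traditional" if is_t else "non_traditional",
            fp_latencies=lat,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        ef = float(np.clip(rng.normal(ef_mean[g], 8.0), 10.0, 75.0))
        pid = f"P{i:03d}"
        rec, truth = generate_record(cfg, patient_id=pid,
                                     metadata={"diagnosis": g,
                                               "ejection_fraction": round(ef, 1)})
        meta = {"patient_id": pid, "diagnosis": g,
                "ejection_fraction": round(ef, 1), "true_class": truth.true_class}
        cohort.append((rec, truth, meta))
    return cohort
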