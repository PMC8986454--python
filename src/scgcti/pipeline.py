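"""End-to-end study orchestration.

``run_study`` drives every record through conditioning, beat detection,
ensemble averaging, fiducial detection and classification, and — when
echo annotations exist — RR-sequence synchronization and agreement
statistics, then assembles cohort-level prevalence and difference
tables.  Patients failing a stage are reported with the failing stage,
never silently dropped.  ``reproduce_tables`` regenerates the published
agreement and prevalence statistics from the packaged fixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import FilterSpec, bandpass_filter, resample_signal
from .beats import (NoUsableBeatsError, detect_r_peaks, detect_q_points,
                    flag_beat_quality, select_window, ensemble_average)
from .fiducials import FP_NAMES, detect_fiducials, classify_waveform, compute_ctis
from .sync import align_rr_sequences, map_annotation_times
from .agreement import (count_within_range, f_test_variances, g_test_independence,
                        group_stats, load_cohort_fixture, load_reference,
                        load_study_differences, patient_differences, prevalence_table,
                        reference_range, welch_test, KNOWN_COUNT_DISCREPANCIES)

DEFAULT_CONFIG = {
    "filter": {"low_cut": 5.0, "high_cut": 40.0, "order": 3},
    "analysis": {"resample_rate": 1000.0, "window_ms": [-100.0, 600.0],
                 "min_beats": 6},
    "fiducials": {"prominence_frac": 0.10},
    "sync": {"tolerance": 15.0, "min_margin": 10.0},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: dict(v) for k, v in base.items()}
    for k, v in (override or {}).items():
        out.setdefault(k, {}).update(v)
    return out


def analyze_record(record, config: dict | None = None) -> dict:
    """Single-patient analysis: averaged beat, fiducials, class, CTIs.

    Returns a dict with either the results or ``failed_stage`` plus the
    error message.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    fs_out = cfg["analysis"]["resample_rate"]
    result: dict = {"patient_id": record.patient_id,
                    "metadata": dict(record.metadata)}
    try:
        scg_f = bandpass_filter(record.scg, record.sampling_rate,
                                FilterSpec(**cfg["filter"]))
        scg = resample_signal(scg_f, record.sampling_rate, fs_out)
        ecg = resample_signal(record.ecg, record.sampling_rate, fs_out)
    except Exception as exc:
        result.update(failed_stage="preprocess", error=str(exc))
        return result
    try:
        series = detect_r_peaks(ecg, fs_out)
        if series.n_beats < 3:
            raise NoUsableBeatsError("fewer than 3 R peaks detected")
        series.q_times = detect_q_points(ecg, series.r_times, fs_out)
        series = flag_beat_quality(series, scg, fs_out)
        window = select_window(series, min_beats=cfg["analysis"]["min_beats"])
        beat = ensemble_average(scg, series, fs_out,
                                window_ms=tuple(cfg["analysis"]["window_ms"]),
                                beat_indices=window.beat_indices)
    except Exception as exc:
        result.update(failed_stage="beats", error=str(exc))
        return result
    try:
        fps = detect_fiducials(beat,
                               prominence_frac=cfg["fiducials"]["prominence_frac"])
        wclass = classify_waveform(fps)
        q_offsets = series.r_times[window.beat_indices] - \
            series.q_times[window.beat_indices]
        q_to_r = float(np.nanmedian(q_offsets)) if np.isfinite(q_offsets).any() else 0.0
        ctis = compute_ctis(fps, max(q_to_r, 0.0))
    except Exception as exc:
        result.update(failed_stage="fiducials", error=str(exc))
        return result
    result.update(
        series=series, window=window, beat=beat, fiducials=fps,
        waveform_class=wclass.label, availability=wclass.availability,
        classification_method=wclass.method,
        ctis={"PEP": ctis.PEP, "IVCT": ctis.IVCT, "LVET": ctis.LVET,
              "IVRT": ctis.IVRT},
        fp_latencies={e: fps.latencies.get(e) for e in FP_NAMES},
        n_beats_used=beat.n_beats_used, single_beat=beat.single_beat,
    )
    return result


def _patient_echo_differences(result: dict, annotations, cfg: dict) -> dict:
    """Sync each annotation and average repeated measures per event."""
    series = result["series"]
    fps = result["fp_latencies"]
    per_event: dict = {}
    for ann in annotations:
        align = align_rr_sequences(ann.rr_sequence, series.rr_intervals,
                                   tolerance=cfg["sync"]["tolerance"],
                                   min_margin=cfg["sync"]["min_margin"])
        if not align.accepted:
            continue
        glob = map_annotation_times(ann, align, series)
        idx = align.start_index + np.arange(len(glob))
        from_r = glob - series.r_times[idx]
        per_event.setdefault(ann.event, []).extend(from_r.tolist())
    return patient_differences(per_event, fps)


def run_study(records, annotations_by_patient: dict | None = None,
              config: dict | None = None, seed: int | None = None) -> dict:
    """Run the full study flow over a cohort of records.

    ``annotations_by_patient`` maps patient_id to a list of
    EchoAnnotation.  Returns a StudyReport dict: per-patient results,
    prevalence tables by diagnosis and EF, the Echo−FP difference table
    with group statistics, and provenance.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    annotations_by_patient = annotations_by_patient or {}
    patients = []
    diff_rows = []
    for rec in records:
        res = analyze_record(rec, cfg)
        if "failed_stage" not in res:
            anns = annotations_by_patient.get(rec.patient_id, [])
            if anns:
                diffs = _patient_echo_differences(res, anns, cfg)
                res["echo_fp_differences"] = diffs
                if diffs:
                    diff_rows.append({"patient_id": rec.patient_id, **diffs})
        patients.append(res)

    ok = [p for p in patients if "failed_stage" not in p]
    cohort = pd.DataFrame([{
        "patient_id": p["patient_id"],
        "diagnosis": p["metadata"].get("diagnosis"),
        "ejection_fraction": p["metadata"].get("ejection_fraction"),
        "waveform": p["waveform_class"],
    } for p in ok])

    report: dict = {
        "provenance": {"version": __version__, "config": cfg, "seed": seed,
                       "classification": "algorithmic-prominence-surrogate"},
        "patients": [
            {k: v for k, v in p.items()
             if k not in ("series", "window", "beat", "fiducials")}
            for p in patients],
        "n_failed": len(patients) - len(ok),
    }
    if len(cohort):
        report["prevalence_by_diagnosis"] = prevalence_table(
            cohort, "diagnosis").to_dict("records")
        report["prevalence_by_ef"] = prevalence_table(
            cohort, "ef").to_dict("records")
    if diff_rows:
        table = pd.DataFrame(diff_rows).set_index("patient_id")
        report["difference_table"] = table.reset_index().to_dict("records")
        report["difference_stats"] = group_stats(table).to_dict("index")
    return report


def reproduce_tables(mode: str = "printed") -> dict:
    """Regenerate the published agreement and prevalence statistics.

    Uses the packaged per-patient difference table, healthy-subject
    reference statistics and cohort memberships.  ``mode`` selects how
    the 95% reference range is formed ('printed' rounded values or
    'exact' mean ± 1.96·SD); both are reported.
    """
    t4 = load_study_differences()
    ref = load_reference()
    cohort = load_cohort_fixture()
    stats = group_stats(t4)

    out: dict = {"group_stats": stats.round(6).to_dict("index")}

    for m in ("printed", "exact"):
        ranges, counts = {}, {}
        for ev in t4.columns:
            rng = reference_range(ref[ev], mode=m)
            ranges[ev] = rng
            counts[ev] = count_within_range(t4[ev], rng)
        out[f"ranges_{m}"] = ranges
        out[f"counts_within_{m}"] = counts
    out["count_discrepancies"] = KNOWN_COUNT_DISCREPANCIES

    tests = {}
    for ev in t4.columns:
        r = ref[ev]
        w = welch_test(stats.loc[ev, "mean"], stats.loc[ev, "sd"],
                       int(stats.loc[ev, "n"]), r.mean, r.sd, r.n)
        f = f_test_variances(stats.loc[ev, "sd"], int(stats.loc[ev, "n"]),
                             r.sd, r.n)
        tests[ev] = {"welch_p": w.p_value, "welch_t": w.statistic,
                     "f_p": f.p_value, "f": f.statistic,
                     "mean_significant": w.p_value < 0.05,
                     "sd_significant": f.p_value < 0.05}
    out["tests_vs_healthy"] = tests

    prev_diag = prevalence_table(cohort, "diagnosis")
    prev_ef = prevalence_table(cohort, "ef")
    out["prevalence_by_diagnosis"] = prev_diag.to_dict("records")
    out["prevalence_by_ef"] = prev_ef.to_dict("records")

    mi = prev_diag[prev_diag.stratum == "MI"].iloc[0]
    hf = prev_diag[prev_diag.stratum == "HF"].iloc[0]
    g = g_test_independence([
        [mi.n_traditional, mi.n_patients - mi.n_traditional],
        [hf.n_traditional, hf.n_patients - hf.n_traditional]])
    out["g_test_mi_vs_hf"] = {"G": g.statistic, "df": g.df, "p": g.p_value,
                              "significant": g.p_value < 0.05}
    return out
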