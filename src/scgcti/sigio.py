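"""On-disk formats for signal records and echo annotations.

A record is a CSV (columns ``time_s, ecg, scg_z``) plus a JSON sidecar
carrying the sampling rate and patient metadata; annotations are a JSON
array.  Plain-text formats were chosen over a binary container so that
every artefact remains inspectable with standard tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_EVENTS = ("MC", "AO", "AC", "MO")
VALID_DIAGNOSES = ("MI", "HF", "TX")


class FormatError(ValueError):
    """A file does not conform to the record/annotation format."""


@dataclass
class SignalRecord:
    """Synchronous one-lead ECG and dorso-ventral SCG acceleration."""

    ecg: np.ndarray
    scg: np.ndarray
    sampling_rate: float
    patient_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.scg = np.asarray(self.scg, dtype=float)
        if self.ecg.shape != self.scg.shape:
            raise FormatError("ecg and scg must have equal length")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        diag = self.metadata.get("diagnosis")
        if diag is not None and diag not in VALID_DIAGNOSES:
            raise FormatError(f"diagnosis {diag!r} not in {VALID_DIAGNOSES}")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class EchoAnnotation:
    """Sonogram-derived valve-event timings over a run of displayed beats.

    Times are milliseconds from the R peak of the same beat;
    ``rr_sequence`` lists the RR intervals between the displayed beats and
    is what ties the sonogram to the device timeline.
    """

    patient_id: str
    event: str
    rr_sequence: list
    event_times_from_r: list
    image_id: str = ""

    def __post_init__(self):
        if self.event not in VALID_EVENTS:
            raise FormatError(f"event {self.event!r} not in {VALID_EVENTS}")
        self.rr_sequence = [float(x) for x in self.rr_sequence]
        self.event_times_from_r = [float(x) for x in self.event_times_from_r]
        if len(self.rr_sequence) < 2:
            raise FormatError("rr_sequence must contain at least 2 intervals")
        if len(self.event_times_from_r) > len(self.rr_sequence) + 1:
            raise FormatError("more event times than displayed beats")
        if not all(np.isfinite(self.rr_sequence)) or not all(
                np.isfinite(self.event_times_from_r)):
            raise FormatError("annotation times must be finite")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_record(record: SignalRecord, path) -> Path:
    """Write a record as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({"time_s": record.time_s, "ecg": record.ecg,
                       "scg_z": record.scg})
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {"sampling_rate": record.sampling_rate,
               "patient_id": record.patient_id,
               "metadata": record.metadata}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_record(path) -> SignalRecord:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    if "sampling_rate" not in sidecar:
        raise FormatError("sidecar lacks field 'sampling_rate'")
    df = pd.read_csv(path)
    for col in ("time_s", "ecg", "scg_z"):
        if col not in df.columns:
            raise FormatError(f"CSV lacks column '{col}'")
    return SignalRecord(ecg=df["ecg"].to_numpy(), scg=df["scg_z"].to_numpy(),
                        sampling_rate=float(sidecar["sampling_rate"]),
                        patient_id=sidecar.get("patient_id", ""),
                        metadata=sidecar.get("metadata", {}))


def write_annotations(annotations, path) -> Path:
    path = Path(path)
    payload = [{"patient_id": a.patient_id, "event": a.event,
                "rr_sequence": a.rr_sequence,
                "event_times_from_r": a.event_times_from_r,
                "image_id": a.image_id} for a in annotations]
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_annotations(path) -> list:
    path = Path(path)
    payload = json.loads(path.read_text())
    if not isinstance(payload, list):
        raise FormatError("annotation file must contain a JSON array")
    out = []
    for obj in payload:
        try:
            out.append(EchoAnnotation(
                patient_id=obj["patient_id"], event=obj["event"],
                rr_sequence=obj["rr_sequence"],
                event_times_from_r=obj["event_times_from_r"],
                image_id=obj.get("image_id", "")))
        except KeyError as exc:
            raise FormatError(f"annotation object lacks field {exc}") from exc
    return out
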