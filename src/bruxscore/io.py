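"""Recording, manifest and report I/O.

On-disk formats: EDF (primary, via :mod:`mne` for reading and a minimal
built-in writer), a diffable CSV dialect for hand-written fixtures
(``t,<channel>,...`` at a uniform time step), a CSV cohort manifest, a JSON
ground-truth sidecar (``<recording>.truth.json``) and a JSON result report.

All times inside the package are seconds from recording start; sample
indices are 0-based.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EMG_LEFT = "EMG_LEFT"
EMG_RIGHT = "EMG_RIGHT"
ECG = "ECG"

#: case-insensitive channel-name aliases, extendable by callers
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    EMG_LEFT: ("emg_left", "emg_l", "emgl", "emg1", "masseter_left", "left masseter"),
    EMG_RIGHT: ("emg_right", "emg_r", "emgr", "emg2", "masseter_right", "right masseter"),
    ECG: ("ecg", "ekg", "ecg1", "heart", "cardiac"),
}

REPORT_SCHEMA_VERSION = 1


class RecordingError(ValueError):
    """Unreadable, corrupt or structurally invalid recording."""


class ManifestError(ValueError):
    """Invalid cohort manifest."""


@dataclass
class Channel:
    label: str
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise RecordingError(f"channel {self.label}: sampling rate must be > 0")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class Recording:
    """A single overnight EMG/ECG recording in physical units (mV).

    Exactly one ECG channel and one or two masseter-EMG channels; channel
    order is normalized to (EMG_LEFT, EMG_RIGHT?, ECG). ``duration`` is the
    examination length: the time between switching the device on and off.
    """

    subject_id: str
    channels: list[Channel]
    start_time: str | None = None
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            if not self.channels:
                raise RecordingError("recording has no channels")
            self.duration = max(c.duration for c in self.channels)
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise RecordingError(f"duplicate channel labels: {labels}")
        if labels.count(ECG) != 1:
            raise RecordingError(
                f"ECG channel required; found channels {labels}"
            )
        n_emg = sum(lb in (EMG_LEFT, EMG_RIGHT) for lb in labels)
        if not 1 <= n_emg <= 2 or n_emg + 1 != len(labels):
            raise RecordingError(
                f"expected one or two EMG channels plus ECG, found {labels}"
            )
        for c in self.channels:
            if abs(len(c.samples) - round(self.duration * c.sampling_rate)) > 1:
                raise RecordingError(
                    f"channel {c.label}: {len(c.samples)} samples inconsistent "
                    f"with duration {self.duration} s at {c.sampling_rate} Hz"
                )
        order = {EMG_LEFT: 0, EMG_RIGHT: 1, ECG: 2}
        self.channels.sort(key=lambda c: order[c.label])

    @property
    def emg_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.label != ECG]

    @property
    def ecg(self) -> Channel:
        return next(c for c in self.channels if c.label == ECG)


@dataclass
class SubjectManifestRow:
    subject_id: str
    group: str
    sex: str
    age: float
    twi: int
    symptoms_present: bool
    self_report_positive: bool
    recording_path: str

    def __post_init__(self) -> None:
        if self.group not in ("study", "control"):
            raise ManifestError(
                f"{self.subject_id}: invalid group {self.group!r}"
            )
        if self.sex not in ("female", "male"):
            raise ManifestError(f"{self.subject_id}: invalid sex {self.sex!r}")
        self.twi = int(self.twi)
        if not 0 <= self.twi <= 4:
            raise ManifestError(
                f"{self.subject_id}: twi must be in [0, 4], got {self.twi}"
            )


def _canonical_label(name: str, aliases: dict[str, tuple[str, ...]]) -> str | None:
    low = name.strip().lower()
    for canon, alts in aliases.items():
        if low == canon.lower() or low in alts:
            return canon
    return None


def read_recording(
    path: str | Path,
    dialect: str | None = None,
    subject_id: str | None = None,
    aliases: dict[str, tuple[str, ...]] | None = None,
) -> Recording:
    """Read an EDF or CSV-dialect recording into physical units (mV)."""
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "edf"
    if not path.exists():
        raise RecordingError(f"recording file not found: {path}")
    aliases = aliases or DEFAULT_ALIASES
    sid = subject_id or path.stem.removesuffix(".edf")
    if dialect == "edf":
        return _read_edf(path, sid, aliases)
    if dialect == "csv":
        return _read_csv(path, sid, aliases)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_edf(path: Path, subject_id: str, aliases) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise RecordingError(f"unreadable EDF file {path}: {exc}") from exc
    channels: list[Channel] = []
    for name in raw.ch_names:
        canon = _canonical_label(name, aliases)
        if canon is None:
            continue
        idx = raw.ch_names.index(name)
        data = raw.get_data(picks=[idx])[0]
        unit = (getattr(raw, "_orig_units", {}) or {}).get(name, "")
        # mne rescales recognized voltage dimensions to volts
        if unit.lower() in ("mv", "uv", "µv", "v"):
            data = data * 1e3  # volts -> mV
        channels.append(Channel(canon, data, float(raw.info["sfreq"])))
    if not any(c.label == ECG for c in channels):
        raise RecordingError(
            f"ECG channel required; found channels {list(raw.ch_names)}"
        )
    return Recording(subject_id, channels)


def _read_csv(path: Path, subject_id: str, aliases) -> Recording:
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise RecordingError(f"{path}: CSV dialect needs a 't' time column")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise RecordingError(f"{path}: need at least two samples")
    steps = np.diff(t)
    step = float(np.median(steps))
    if step <= 0 or np.any(np.abs(steps - step) > 1e-6 * max(1.0, 1 / step)):
        raise RecordingError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / step
    channels = []
    for col in df.columns:
        if col == "t":
            continue
        canon = _canonical_label(col, aliases)
        if canon is None:
            continue
        channels.append(Channel(canon, df[col].to_numpy(dtype=float), fs))
    if not any(c.label == ECG for c in channels):
        raise RecordingError(
            f"ECG channel required; found columns {list(df.columns)}"
        )
    return Recording(subject_id, channels, duration=len(t) / fs)


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording as EDF (``.edf``) or the CSV dialect (``.csv``).

    The CSV dialect requires all channels to share one sampling rate and is
    lossless at the written precision; EDF quantizes to 16 bits.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rates = {c.sampling_rate for c in recording.channels}
        if len(rates) != 1:
            raise RecordingError("CSV dialect requires a single sampling rate")
        fs = rates.pop()
        n = min(len(c.samples) for c in recording.channels)
        cols = {"t": np.arange(n) / fs}
        for c in recording.channels:
            cols[c.label.lower()] = c.samples[:n]
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
        return path
    from . import _edf

    _edf.write_edf(
        path,
        [c.samples for c in recording.channels],
        [c.sampling_rate for c in recording.channels],
        [c.label for c in recording.channels],
        patient_id=recording.subject_id or "X",
    )
    return path


def truth_sidecar_path(recording_path: str | Path) -> Path:
    p = Path(recording_path)
    return p.with_suffix(p.suffix + ".truth.json")


def write_truth(truth, recording_path: str | Path) -> Path:
    """Write the ground-truth sidecar ``<recording>.truth.json``."""
    out = truth_sidecar_path(recording_path)
    out.write_text(json.dumps(truth.to_dict(), indent=1))
    return out


def read_truth(recording_path: str | Path):
    from .synthetic import GroundTruth

    p = truth_sidecar_path(recording_path)
    if not p.exists():
        raise FileNotFoundError(f"no truth sidecar at {p}")
    return GroundTruth.from_dict(json.loads(p.read_text()))


MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age",
    "twi",
    "symptoms_present",
    "self_report_positive",
    "recording_path",
]


def read_manifest(path: str | Path) -> list[SubjectManifestRow]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ManifestError(f"no subjects in manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} missing columns {missing}")
    if df.empty:
        raise ManifestError(f"no subjects in manifest {path}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ManifestError(f"duplicate subject_id(s): {sorted(set(map(str, dupes)))}")
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            SubjectManifestRow(
                subject_id=str(rec["subject_id"]),
                group=str(rec["group"]),
                sex=str(rec["sex"]),
                age=float(rec["age"]),
                twi=int(rec["twi"]),
                symptoms_present=_as_bool(rec["symptoms_present"]),
                self_report_positive=_as_bool(rec["self_report_positive"]),
                recording_path=str(rec["recording_path"]),
            )
        )
    return rows


def write_manifest(rows: Iterable[SubjectManifestRow], path: str | Path) -> Path:
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ManifestError(f"not a boolean: {v!r}")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return None
    return obj


def write_report(
    summaries: Sequence,
    accuracy,
    stats,
    path: str | Path,
    scoring_config=None,
    extra: dict | None = None,
) -> Path:
    """Write the machine-readable cohort report (JSON, versioned schema)."""
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "scoring_config": _jsonable(scoring_config) if scoring_config else None,
        "subjects": _jsonable(list(summaries)),
        "accuracy": _jsonable(accuracy) if accuracy is not None else None,
        "statistics": _jsonable(stats) if stats is not None else None,
    }
    if extra:
        doc.update(_jsonable(extra))
    out = Path(path)
    out.write_text(json.dumps(doc, indent=1))
    return out


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
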