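"""Minimal EDF (European Data Format) writer.

Writes plain EDF (not EDF+): fixed-width ASCII headers followed by
little-endian int16 data records. Only what the package needs to emit
standard, `mne`-readable overnight recordings; reading is delegated to
``mne.io.read_raw_edf``.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    # shortest decimal representation that fits the fixed-width field
    for fmt in (f"%.{p}g" % value for p in range(8, 0, -1)):
        if len(fmt) <= width:
            return _field(fmt, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(
    path: str | Path,
    signals: list[np.ndarray],
    sampling_rates: list[float],
    labels: list[str],
    physical_dim: str = "mV",
    start_time: _dt.datetime | None = None,
    patient_id: str = "X",
) -> None:
    """Write channels (physical units) to ``path`` as 16-bit EDF.

    Record duration is 1 s, so every sampling rate must be a positive
    integer; signals are zero-padded to a whole number of records.
    """
    if not (len(signals) == len(sampling_rates) == len(labels)):
        raise ValueError("signals, sampling_rates and labels must align")
    rates = []
    for fs in sampling_rates:
        if fs <= 0 or abs(fs - round(fs)) > 1e-9:
            raise ValueError(f"EDF writer needs integer sampling rates, got {fs}")
        rates.append(int(round(fs)))

    n_records = max(
        int(np.ceil(len(x) / fs)) for x, fs in zip(signals, rates)
    )
    start = start_time or _dt.datetime(2000, 1, 1, 22, 0, 0)

    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field("Startdate X", 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + len(signals))), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(len(signals)), 4),
        ]
    )

    phys_min, phys_max, scaled = [], [], []
    for x in signals:
        x = np.asarray(x, dtype=float)
        amp = float(np.max(np.abs(x))) if x.size else 1.0
        amp = amp if amp > 0 else 1.0
        # symmetric physical range, headroom so no sample clips
        pmax = float(f"{amp * 1.001:.6g}")
        phys_min.append(-pmax)
        phys_max.append(pmax)
        gain = _DIG_MAX / pmax
        scaled.append(np.clip(np.round(x * gain), _DIG_MIN, _DIG_MAX).astype("<i2"))

    per_signal = b"".join(
        [
            b"".join(_field(lb, 16) for lb in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field(physical_dim, 8) for _ in labels),
            b"".join(_num(v, 8) for v in phys_min),
            b"".join(_num(v, 8) for v in phys_max),
            b"".join(_field(str(_DIG_MIN), 8) for _ in labels),
            b"".join(_field(str(_DIG_MAX), 8) for _ in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field(str(fs), 8) for fs in rates),
            b"".join(_field("", 32) for _ in labels),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for rec in range(n_records):
            for x, fs in zip(scaled, rates):
                chunk = x[rec * fs : (rec + 1) * fs]
                if len(chunk) < fs:
                    chunk = np.concatenate(
                        [chunk, np.zeros(fs - len(chunk), dtype="<i2")]
                    )
                fh.write(chunk.tobytes())
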