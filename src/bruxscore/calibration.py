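"""MVC calibration: locate the three voluntary clenches and normalize.

A recording starts with a calibration prologue — three maximum voluntary
clenches (MVC) of ~3 s separated by ~10 s of rest — performed by the
patient after switching the device on. The greatest clench amplitude
becomes the normalization constant; scoring thresholds are expressed as
percent of it. Each EMG channel is normalized by its own MVC (left/right
clench asymmetry is physiological).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .preprocess import EnvelopeSeries


class CalibrationError(ValueError):
    """No MVC calibration detected."""


@dataclass
class MvcResult:
    clench_windows: list[tuple[float, float]]
    per_clench_peak: list[float]
    mvc: float
    calibration_span: tuple[float, float]
    #: largest/smallest clench peak; >> 1 flags sub-maximal clench effort
    effort_ratio: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.mvc <= 0:
            raise CalibrationError("MVC must be positive")


def detect_mvc(
    envelope: EnvelopeSeries,
    search_window: float = 60.0,
    min_dur: float = 1.0,
    max_dur: float = 6.0,
    tail: float = 5.0,
) -> MvcResult:
    """Find up to three supra-noise clench segments in the opening window.

    Segments are detected on the raw envelope with an adaptive threshold of
    5x the window median; each clench's amplitude is read from a 0.5 s
    moving average of the envelope, which tames the sampling spread of a
    short-window RMS of stochastic EMG. The calibration span runs to the
    last clench offset plus ``tail`` seconds and is excluded from scoring.
    """
    fs = envelope.sampling_rate
    n = int(round(search_window * fs))
    if len(envelope.values) < n:
        raise CalibrationError(
            f"envelope shorter than the {search_window} s calibration window"
        )
    seg = envelope.values[:n]
    thr = 5.0 * float(np.median(seg))
    above = seg > thr
    # contiguous above-threshold runs
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise CalibrationError("no MVC calibration detected")
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1

    smooth = uniform_filter1d(seg, size=max(3, int(round(0.5 * fs))), mode="nearest")
    clenches = []
    for s, e in zip(run_starts, run_ends):
        dur = (e - s) / fs
        if min_dur <= dur <= max_dur:
            clenches.append((float(np.max(smooth[s:e])), s / fs, e / fs))
    if not clenches:
        raise CalibrationError("no MVC calibration detected")
    clenches.sort(reverse=True)
    top = sorted(clenches[:3], key=lambda c: c[1])
    if len(top) < 3:
        warnings.warn(
            f"only {len(top)} MVC clench(es) found; expected 3", stacklevel=2
        )
    peaks = [c[0] for c in top]
    windows = [(c[1], c[2]) for c in top]
    mvc = max(peaks)
    return MvcResult(
        clench_windows=windows,
        per_clench_peak=peaks,
        mvc=mvc,
        calibration_span=(0.0, windows[-1][1] + tail),
        effort_ratio=mvc / min(peaks),
    )


def normalize(envelope: EnvelopeSeries, mvc: float) -> EnvelopeSeries:
    """Rescale an envelope to percent of MVC: ``100 * values / mvc``."""
    if mvc <= 0:
        raise CalibrationError("MVC must be positive for normalization")
    return EnvelopeSeries(
        100.0 * envelope.values / mvc,
        envelope.sampling_rate,
        envelope.channel,
        units="%MVC",
    )
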