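"""Signal conditioning: EMG envelope extraction and ECG beat detection.

Two derived series feed every scoring rule:

* a moving-RMS envelope of each rectified masseter-EMG channel (later
  normalized to %MVC by :mod:`bruxscore.calibration`), and
* a beat-by-beat heart-rate series from adaptive-threshold R-peak
  detection on the single ECG lead.

No resampling is performed: the envelope keeps the EMG rate and heart
rate is an event series, interpolated by previous-beat hold where needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks


class EcgError(ValueError):
    """ECG unusable for beat detection."""


@dataclass
class EnvelopeSeries:
    """Non-negative EMG amplitude envelope (mV, or %MVC once normalized)."""

    values: np.ndarray
    sampling_rate: float
    channel: str = ""
    units: str = "mV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate


@dataclass
class HeartRateSeries:
    """Beat times (s, strictly increasing) and per-beat rates (bpm).

    ``rates[i] = 60 / (beat_times[i+1] - beat_times[i])`` is the rate of the
    i-th RR interval, so ``len(rates) == len(beat_times) - 1``.
    """

    beat_times: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.rates) != len(self.beat_times) - 1:
            raise ValueError("rates must have one element per RR interval")
        if np.any(self.rates <= 0):
            raise ValueError("heart rates must be positive")


def emg_envelope(
    samples: np.ndarray, fs: float, rms_window: float = 0.05, channel: str = ""
) -> EnvelopeSeries:
    """Moving-RMS envelope of the mean-subtracted EMG, centered window.

    The 50 ms default resolves the shortest scoreable burst (0.25 s) with
    modest edge smearing while suppressing carrier-level fluctuation.
    """
    if fs < 200:
        warnings.warn(
            f"EMG sampling rate {fs} Hz is below the recommended 200 Hz",
            stacklevel=2,
        )
    win = int(round(rms_window * fs))
    if win < 2:
        raise ValueError(f"RMS window {rms_window} s is under 2 samples at {fs} Hz")
    win += win % 2 == 0  # odd length => exactly centered
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    power = uniform_filter1d(x * x, size=win, mode="nearest")
    return EnvelopeSeries(np.sqrt(np.maximum(power, 0.0)), fs, channel)


def detect_r_peaks(
    samples: np.ndarray, fs: float, refractory: float = 0.25
) -> np.ndarray:
    """R-peak times via band-emphasis -> derivative -> squaring -> moving
    integration -> adaptive threshold (Pan-Tompkins-style), 250 ms refractory.

    Operates on the squared signal, so lead polarity is irrelevant.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 10 * fs:
        raise EcgError("need at least 10 s of ECG")
    nyq = fs / 2.0
    b, a = butter(2, [5 / nyq, min(18.0, 0.9 * nyq) / nyq], btype="band")
    bp = filtfilt(b, a, x)
    deriv = np.gradient(bp)
    sq = deriv * deriv
    integ = uniform_filter1d(sq, size=max(3, int(round(0.15 * fs))), mode="nearest")

    dist = max(1, int(round(refractory * fs)))
    cand, _ = find_peaks(integ, distance=dist)
    if len(cand) == 0:
        raise EcgError("unusable ECG: no candidate peaks")

    # adaptive signal/noise running estimates
    lead = integ[: int(2 * fs)]
    spki = float(np.max(lead))
    npki = float(np.mean(lead))
    thr = npki + 0.25 * (spki - npki)
    qrs: list[int] = []
    for p in cand:
        if integ[p] > thr:
            qrs.append(p)
            spki = 0.125 * integ[p] + 0.875 * spki
        else:
            npki = 0.125 * integ[p] + 0.875 * npki
        thr = npki + 0.25 * (spki - npki)
    if not qrs:
        raise EcgError("unusable ECG: no peaks above adaptive threshold")

    # refine each fiducial to the local maximum of the squared band signal
    half = int(round(0.10 * fs))
    sq_bp = bp * bp
    times = []
    for p in qrs:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        times.append((lo + int(np.argmax(sq_bp[lo:hi]))) / fs)
    out = np.array(sorted(set(times)))
    # enforce refractory after refinement
    keep = [0]
    for i in range(1, len(out)):
        if out[i] - out[keep[-1]] >= refractory:
            keep.append(i)
    return out[keep]


def heart_rate_series(beat_times: np.ndarray) -> HeartRateSeries:
    """Per-interval rates (bpm): ``60 / diff(beat_times)``."""
    t = np.asarray(beat_times, dtype=float)
    if len(t) < 2:
        raise EcgError("need at least 2 beats for a heart-rate series")
    rr = np.diff(t)
    if np.any(rr <= 0):
        raise EcgError("beat times must be strictly increasing")
    return HeartRateSeries(t, 60.0 / rr)


def mean_heart_rate(series: HeartRateSeries) -> float:
    """Arithmetic mean of the beat-to-beat rates (bpm)."""
    if len(series.rates) == 0:
        raise EcgError("empty heart-rate series")
    return float(np.mean(series.rates))
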