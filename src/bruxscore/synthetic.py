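"""Synthetic overnight EMG/ECG recordings with planted ground truth.

Emulates an ambulatory-device night: a calibration prologue of three 3 s
maximum voluntary clenches separated by 10 s of rest, then hours of sleep
containing tonic/phasic/mixed masseter events. True sleep-bruxism episodes
are preceded 1-5 s by a heart-rate surge (the micro-arousal cardiac
signature); confounder events carry no surge, and surge-only arousals
carry no EMG activity. Everything planted is recorded in a
:class:`GroundTruth` object so every downstream stage can be tested with
no external data.

The EMG is band-limited (80-250 Hz) Gaussian noise amplitude-modulated by
a burst-envelope profile; the ECG is a 40 ms biphasic QRS impulse train
whose RR intervals follow the configured baseline heart rate with mild
jitter. Surges are step-onset exponential-recovery tachycardias whose
onset coincides with a beat, with the coupled event onset placed exactly
``lag`` seconds later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.stats import truncnorm

from .io import ECG, EMG_LEFT, EMG_RIGHT, Channel, Recording, SubjectManifestRow

CLENCH_DUR = 3.0
CLENCH_REST = 10.0
CLENCH_START = 5.0
CAL_TAIL = 5.0
#: minimum quiet gap from one planted event's offset to the next onset;
#: also guarantees one event's surge cannot fall in another's lag window
EVENT_SEPARATION = 12.0

TYPES = ("tonic", "phasic", "mixed")


@dataclass
class GeneratorConfig:
    seed: int = 0
    night_duration: float = 25200.0   # s (~7 h)
    emg_rate: float = 500.0           # Hz
    ecg_rate: float = 250.0           # Hz
    mvc_amplitude: float = 1.0        # mV
    noise_floor: float = 0.02         # mV resting envelope
    baseline_hr: float = 60.0         # bpm
    episode_rate: float = 6.04        # coupled SB episodes per scored hour
    type_mix: tuple[float, float, float] = (0.60, 0.34, 0.06)  # tonic, phasic, mixed
    confounder_rate: float = 1.0      # uncoupled events per hour
    surge_only_rate: float = 1.0      # surges without EMG per hour
    surge_magnitude: float = 0.30     # fractional HR rise (>= 0.20 scores)
    lag_range: tuple[float, float] = (1.0, 5.0)   # s, surge onset -> event onset
    burst_fraction: float = 0.40      # burst amplitude as fraction of MVC
    amplitude_jitter: float = 0.20    # relative burst-amplitude jitter
    rr_jitter: float = 0.03           # relative RR-interval jitter
    surge_tau: float = 6.0            # s, tachycardia recovery time constant
    ramp: float = 0.05                # s, burst onset/offset ramp

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")
        if min(self.episode_rate, self.confounder_rate, self.surge_only_rate) < 0:
            raise ValueError("event rates must be non-negative")
        lo, hi = self.lag_range
        if not (0 < lo < hi):
            raise ValueError("lag_range must satisfy 0 < low < high")
        if self.night_duration < 120.0:
            raise ValueError(
                "night too short to fit the MVC calibration prologue"
            )


@dataclass
class TruthEvent:
    onset: float
    offset: float
    type: str                      # tonic | phasic | mixed | confounder
    burst_times: list[tuple[float, float]]
    coupled: bool
    surge_onset: float | None = None
    subtype: str | None = None     # tonic/phasic/mixed shape of a confounder


@dataclass
class GroundTruth:
    events: list[TruthEvent]
    surges: list[dict]                       # {"onset": s, "peak_fraction": f}
    mvc_windows: list[tuple[float, float]]
    clench_amplitudes: dict[str, list[float]]
    beat_times: np.ndarray
    calibration_end: float
    night_duration: float
    true_index: float
    baseline_hr: float

    @property
    def coupled_events(self) -> list[TruthEvent]:
        return [e for e in self.events if e.coupled]

    @property
    def scored_length(self) -> float:
        return self.night_duration - self.calibration_end

    def to_dict(self) -> dict:
        return {
            "events": [
                {
                    "onset": e.onset,
                    "offset": e.offset,
                    "type": e.type,
                    "burst_times": [list(bt) for bt in e.burst_times],
                    "coupled": e.coupled,
                    "surge_onset": e.surge_onset,
                    "subtype": e.subtype,
                }
                for e in self.events
            ],
            "surges": self.surges,
            "mvc_windows": [list(w) for w in self.mvc_windows],
            "clench_amplitudes": self.clench_amplitudes,
            "beat_times": np.asarray(self.beat_times).tolist(),
            "calibration_end": self.calibration_end,
            "night_duration": self.night_duration,
            "true_index": self.true_index,
            "baseline_hr": self.baseline_hr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            events=[
                TruthEvent(
                    onset=e["onset"],
                    offset=e["offset"],
                    type=e["type"],
                    burst_times=[tuple(bt) for bt in e["burst_times"]],
                    coupled=e["coupled"],
                    surge_onset=e.get("surge_onset"),
                    subtype=e.get("subtype"),
                )
                for e in d["events"]
            ],
            surges=d["surges"],
            mvc_windows=[tuple(w) for w in d["mvc_windows"]],
            clench_amplitudes=d["clench_amplitudes"],
            beat_times=np.asarray(d["beat_times"], dtype=float),
            calibration_end=d["calibration_end"],
            night_duration=d["night_duration"],
            true_index=d["true_index"],
            baseline_hr=d["baseline_hr"],
        )


def _burst_layout(kind: str, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Relative (onset, offset) pairs for one event of the given shape.

    Durations sit inside the scoring classes but away from their boundaries
    (phasic 0.35-1.5 s within the 0.25-2 s class; tonic 2.5-8 s) so that
    envelope edge smearing of ~±50 ms cannot flip an event's class.
    """
    bursts: list[tuple[float, float]] = []
    t = 0.0
    if kind == "tonic":
        bursts.append((0.0, float(rng.uniform(2.5, 8.0))))
    elif kind == "phasic":
        for k in range(int(rng.integers(3, 7))):
            if k:
                t += float(rng.uniform(0.3, 0.8))
            d = float(rng.uniform(0.35, 1.5))
            bursts.append((t, t + d))
            t += d
    elif kind == "mixed":
        d0 = float(rng.uniform(2.5, 5.0))
        bursts.append((0.0, d0))
        t = d0
        for _ in range(int(rng.integers(3, 5))):
            t += float(rng.uniform(0.3, 0.8))
            d = float(rng.uniform(0.35, 1.5))
            bursts.append((t, t + d))
            t += d
    else:
        raise ValueError(kind)
    return bursts


def _place_events(cfg: GeneratorConfig, cal_end: float, rng: np.random.Generator):
    """Homogeneous-Poisson candidate onsets thinned to enforce quiet
    separation between consecutive events (and hence clean lag windows)."""
    sleep_start = cal_end + 31.0   # clear of the 60 s MVC search window
    sleep_end = cfg.night_duration - 25.0
    hours = (cfg.night_duration - cal_end) / 3600.0
    kinds: list[tuple[float, str]] = []
    for rate, kind in (
        (cfg.episode_rate, "episode"),
        (cfg.confounder_rate, "confounder"),
        (cfg.surge_only_rate, "surge_only"),
    ):
        n = rng.poisson(rate * hours) if rate > 0 else 0
        kinds += [(float(o), kind) for o in rng.uniform(sleep_start, sleep_end, n)]
    kinds.sort()

    placed = []
    last_offset = sleep_start - EVENT_SEPARATION
    for onset, kind in kinds:
        if onset < last_offset + EVENT_SEPARATION:
            continue
        if kind == "surge_only":
            placed.append(
                {"kind": kind, "onset": onset, "layout": [], "span": 0.0}
            )
            last_offset = onset
            continue
        subtype = TYPES[int(rng.choice(3, p=cfg.type_mix))]
        layout = _burst_layout(subtype, rng)
        span = max(e for _, e in layout)
        if onset + span > sleep_end:
            continue
        lag = float(rng.uniform(*cfg.lag_range)) if kind == "episode" else None
        placed.append(
            {
                "kind": kind,
                "onset": onset,
                "layout": layout,
                "span": span,
                "subtype": subtype,
                "lag": lag,
            }
        )
        last_offset = onset + span
    return placed


def _beat_train(cfg: GeneratorConfig, surge_requests, rng: np.random.Generator):
    """Sequential RR generation with surge snapping.

    Each requested surge activates at the first beat at/after its nominal
    time; the activated (snapped) onset is returned so coupled events can
    be anchored exactly ``lag`` seconds after it. While active, a surge
    multiplies the instantaneous rate by ``1 + m * exp(-dt / tau)``.
    """
    hr = cfg.baseline_hr
    tau = cfg.surge_tau
    pending = sorted(surge_requests, key=lambda r: r["time"])
    active: list[tuple[float, float]] = []
    snapped: list[dict] = []
    beats = [float(rng.uniform(0.2, 1.0))]
    t = beats[0]
    pi = 0
    while True:
        f = 1.0
        for s, m in active:
            dt = t - s
            if 0 <= dt < 8 * tau:
                f += m * math.exp(-dt / tau)
        active = [(s, m) for s, m in active if t - s < 8 * tau]
        jitter = float(np.clip(rng.normal(0.0, cfg.rr_jitter), -3 * cfg.rr_jitter, 3 * cfg.rr_jitter))
        rr = (60.0 / (hr * f)) * (1.0 + jitter)
        t_next = t + rr
        if t_next >= cfg.night_duration:
            break
        if pi < len(pending) and pending[pi]["time"] <= t_next:
            req = pending[pi]
            pi += 1
            active.append((t_next, cfg.surge_magnitude))
            snapped.append({"request": req, "onset": t_next})
        beats.append(t_next)
        t = t_next
    return np.array(beats), snapped


def _qrs_template(fs: float) -> np.ndarray:
    """40 ms biphasic pulse; positive lobe peaks 10 ms in."""
    n1 = max(2, int(round(0.020 * fs)))
    n2 = max(2, int(round(0.020 * fs)))
    pos = np.sin(np.pi * np.arange(n1) / n1)
    neg = -0.5 * np.sin(np.pi * np.arange(n2) / n2)
    return np.concatenate([pos, neg])


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise shaped to the 80-250 Hz surface-EMG band."""
    x = rng.standard_normal(n)
    hi = min(245.0, 0.49 * fs)
    b, a = butter(4, [80.0 / (fs / 2), hi / (fs / 2)], btype="band")
    x = filtfilt(b, a, x)
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def _add_trapezoid(profile, fs, onset, offset, amplitude, ramp):
    i0 = int(round(onset * fs))
    i1 = int(round(offset * fs))
    i0, i1 = max(i0, 0), min(i1, len(profile))
    if i1 <= i0:
        return
    nr = max(1, int(round(ramp * fs)))
    shape = np.full(i1 - i0, amplitude)
    k = min(nr, len(shape))
    shape[:k] = np.linspace(0, amplitude, k, endpoint=False)
    shape[-k:] = np.minimum(shape[-k:], np.linspace(amplitude, 0, k, endpoint=False))
    np.maximum(profile[i0:i1], shape, out=profile[i0:i1])


def generate_recording(config: GeneratorConfig) -> tuple[Recording, GroundTruth]:
    """Generate one overnight recording plus its ground truth.

    Deterministic: the same config (seed included) yields bit-identical
    samples and truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- calibration prologue geometry
    mvc_windows = []
    t0 = CLENCH_START
    for _ in range(3):
        mvc_windows.append((t0, t0 + CLENCH_DUR))
        t0 += CLENCH_DUR + CLENCH_REST
    cal_end = mvc_windows[-1][1] + CAL_TAIL

    placed = _place_events(cfg, cal_end, rng)

    # --- beat train with snapped surges
    requests = []
    for ev in placed:
        if ev["kind"] == "episode":
            requests.append({"time": ev["onset"] - ev["lag"], "event": ev})
        elif ev["kind"] == "surge_only":
            requests.append({"time": ev["onset"], "event": None})
    beats, snapped = _beat_train(cfg, requests, rng)

    surges = []
    for sn in snapped:
        req, onset = sn["request"], sn["onset"]
        surges.append({"onset": float(onset), "peak_fraction": cfg.surge_magnitude})
        ev = req["event"]
        if ev is not None:
            # anchor the event exactly `lag` after the snapped surge onset
            ev["onset"] = onset + ev["lag"]
            ev["surge_onset"] = float(onset)
    # episodes whose surge could not be snapped (night ended first): demote
    truth_events = []
    for ev in placed:
        if ev["kind"] == "surge_only":
            continue
        coupled = ev["kind"] == "episode" and "surge_onset" in ev
        bursts = [
            (ev["onset"] + s, ev["onset"] + e) for s, e in ev["layout"]
        ]
        truth_events.append(
            TruthEvent(
                onset=ev["onset"],
                offset=ev["onset"] + ev["span"],
                type=ev["subtype"] if coupled else "confounder",
                burst_times=bursts,
                coupled=coupled,
                surge_onset=ev.get("surge_onset"),
                subtype=ev["subtype"],
            )
        )
    truth_events.sort(key=lambda e: e.onset)

    # --- EMG channels
    n_emg = int(round(cfg.night_duration * cfg.emg_rate))
    channels = []
    clench_amps: dict[str, list[float]] = {}
    side_gain = {EMG_LEFT: 1.0, EMG_RIGHT: float(rng.uniform(0.8, 1.0))}
    burst_amps = [
        cfg.burst_fraction
        * cfg.mvc_amplitude
        * (1.0 + float(rng.uniform(-cfg.amplitude_jitter, cfg.amplitude_jitter)))
        for ev in truth_events
        for _ in ev.burst_times
    ]
    for label in (EMG_LEFT, EMG_RIGHT):
        profile = np.full(n_emg, cfg.noise_floor)
        amps = [
            cfg.mvc_amplitude * float(rng.uniform(0.85, 1.0)) for _ in range(3)
        ]
        clench_amps[label] = [a * side_gain[label] for a in amps]
        for (s, e), a in zip(mvc_windows, clench_amps[label]):
            _add_trapezoid(profile, cfg.emg_rate, s, e, a, cfg.ramp)
        k = 0
        for ev in truth_events:
            for s, e in ev.burst_times:
                _add_trapezoid(
                    profile, cfg.emg_rate, s, e, burst_amps[k] * side_gain[label], cfg.ramp
                )
                k += 1
        carrier = _bandlimited_carrier(n_emg, cfg.emg_rate, rng)
        channels.append(Channel(label, carrier * profile, cfg.emg_rate))

    # --- ECG channel
    n_ecg = int(round(cfg.night_duration * cfg.ecg_rate))
    ecg = 0.01 * rng.standard_normal(n_ecg)
    tpl = _qrs_template(cfg.ecg_rate)
    lead = int(round(0.010 * cfg.ecg_rate))
    for bt in beats:
        i0 = int(round(bt * cfg.ecg_rate)) - lead
        if i0 < 0 or i0 + len(tpl) > n_ecg:
            continue
        ecg[i0 : i0 + len(tpl)] += tpl
    channels.append(Channel(ECG, ecg, cfg.ecg_rate))

    n_coupled = sum(e.coupled for e in truth_events)
    truth = GroundTruth(
        events=truth_events,
        surges=surges,
        mvc_windows=mvc_windows,
        clench_amplitudes=clench_amps,
        beat_times=beats,
        calibration_end=cal_end,
        night_duration=cfg.night_duration,
        true_index=n_coupled / ((cfg.night_duration - cal_end) / 3600.0),
        baseline_hr=cfg.baseline_hr,
    )
    rec = Recording("synthetic", channels, duration=cfg.night_duration)
    return rec, truth


# --- cohort generation -----------------------------------------------------

#: per-group defaults emulating the screening cohort: index distribution,
#: baseline heart rate, age, fraction of women, recording length (s)
GROUP_DEFAULTS = {
    "study": {
        "index": (6.04, 2.55),
        "hr": (59.6, 6.8),
        "age": (29.9, 8.35, 20.0, 56.0),
        "p_female": 23 / 35,
        "night": (25320.0, 4080.0),
    },
    "control": {
        "index": (1.35, 0.86),
        "hr": (63.5, 4.86),
        "age": (35.0, 10.9, 22.0, 66.0),
        "p_female": 20 / 25,
        "night": (25860.0, 4680.0),
    },
}


def draw_index_rates(
    n: int, dist: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Per-subject episode rates: normal(mean, sd) truncated at 0."""
    mu, sd = dist
    if sd <= 0 or n < 0:
        raise ValueError("need sd > 0 and n >= 0")
    return truncnorm.rvs((0 - mu) / sd, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def _trunc(rng, mu, sd, lo, hi):
    return float(truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd, random_state=rng))


def iter_cohort(
    n_study: int,
    n_control: int,
    study_index_dist: tuple[float, float] = GROUP_DEFAULTS["study"]["index"],
    control_index_dist: tuple[float, float] = GROUP_DEFAULTS["control"]["index"],
    seed: int = 0,
    night_duration: float | None = None,
    **overrides,
):
    """Yield ``(SubjectManifestRow, Recording, GroundTruth)`` per subject.

    Study subjects carry the clinical reference labels (symptoms present,
    positive self-report); controls are asymptomatic. ``night_duration``
    fixes the recording length for every subject (useful for scaled-down
    runs); by default lengths are drawn per group.
    """
    if n_study < 0 or n_control < 0:
        raise ValueError("cohort sizes must be non-negative")
    fixed_rate = overrides.pop("episode_rate", None)
    rng = np.random.default_rng(seed)
    specs = [("study", i, study_index_dist) for i in range(n_study)]
    specs += [("control", i, control_index_dist) for i in range(n_control)]
    for group, i, dist in specs:
        gd = GROUP_DEFAULTS[group]
        rate = fixed_rate if fixed_rate is not None else float(draw_index_rates(1, dist, rng)[0])
        hr = _trunc(rng, *gd["hr"], 40.0, 100.0)
        age = _trunc(rng, *gd["age"])
        sex = "female" if rng.random() < gd["p_female"] else "male"
        if group == "study":
            twi = 1 if rng.random() < 30 / 35 else 2
        else:
            twi = 0
        night = night_duration or round(_trunc(rng, *gd["night"], 7200.0, 36000.0))
        sub_seed = int(rng.integers(0, 2**31))
        cfg = GeneratorConfig(
            seed=sub_seed,
            night_duration=float(night),
            baseline_hr=hr,
            episode_rate=rate,
            **overrides,
        )
        sid = f"{'S' if group == 'study' else 'C'}{i + 1:03d}"
        rec, truth = generate_recording(cfg)
        rec.subject_id = sid
        row = SubjectManifestRow(
            subject_id=sid,
            group=group,
            sex=sex,
            age=round(age, 1),
            twi=twi,
            symptoms_present=group == "study",
            self_report_positive=group == "study",
            recording_path="",
        )
        yield row, rec, truth


def generate_cohort(
    n_study: int,
    n_control: int,
    study_index_dist: tuple[float, float] = GROUP_DEFAULTS["study"]["index"],
    control_index_dist: tuple[float, float] = GROUP_DEFAULTS["control"]["index"],
    seed: int = 0,
    **kwargs,
):
    """Materialized cohort: ``(manifest_rows, recordings, truths)``."""
    rows, recs, truths = [], [], []
    for row, rec, truth in iter_cohort(
        n_study, n_control, study_index_dist, control_index_dist, seed, **kwargs
    ):
        rows.append(row)
        recs.append(rec)
        truths.append(truth)
    return rows, recs, truths
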