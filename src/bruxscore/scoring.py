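"""The scoring core: bursts, events, heart-rate surges, SB episodes, index.

The scoring rules mirror the ambulatory-device criteria: an EMG burst
counts when it exceeds 10 %MVC; bursts group into masticatory events
(tonic = a sustained burst of more than 2 s, phasic = three or more
rhythmic bursts of 0.25-2 s, mixed = both); an event is scored as a
sleep-bruxism (SB) episode only when its onset follows the onset of a
>= 20% heart-rate surge by 1-5 s; the bruxism index is the number of SB
episodes per hour of scored (post-calibration) recording, and an index
strictly greater than 2/h is a positive screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import calibration, preprocess
from .io import Recording
from .preprocess import EnvelopeSeries, HeartRateSeries

TONIC = "tonic"
PHASIC = "phasic"
MIXED = "mixed"
UNCLASSIFIED = "unclassified"


@dataclass
class ScoringConfig:
    """Every numeric scoring rule in one place (defaults are the device rules)."""

    burst_threshold: float = 10.0      # %MVC, strict >
    burst_min_dur: float = 0.25        # s
    burst_offset_hysteresis: float = 0.8   # close burst below 0.8 x threshold
    burst_merge_gap: float = 0.05      # s, merge chatter
    event_gap: float = 3.0             # s of sub-threshold quiescence between events
    tonic_min_dur: float = 2.0         # s, strict >
    phasic_burst_bounds: tuple[float, float] = (0.25, 2.0)  # s, inclusive
    phasic_min_bursts: int = 3
    hr_rise: float = 0.20              # fractional surge over baseline
    hr_baseline_beats: int = 10
    lag_window: tuple[float, float] = (1.0, 5.0)  # s, surge onset -> event onset
    diagnostic_cutoff: float = 2.0     # episodes/h, strict >
    bilateral_mode: str = "union"      # union | left | right | max-envelope
    count_unclassified: bool = False   # count 1-2 short-burst activity as contractions
    one_to_one_coupling: bool = True   # one surge licenses at most one episode
    rms_window: float = 0.05           # s, envelope RMS window
    mvc_search_window: float = 60.0    # s

    def __post_init__(self) -> None:
        if self.lag_window[0] >= self.lag_window[1]:
            raise ValueError("lag_window must have low < high")
        if self.burst_min_dur > self.phasic_burst_bounds[0]:
            raise ValueError("burst_min_dur must not exceed the phasic lower bound")
        for name in (
            "burst_threshold",
            "burst_min_dur",
            "event_gap",
            "tonic_min_dur",
            "hr_rise",
            "diagnostic_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Burst:
    onset: float
    offset: float
    peak: float   # %MVC
    channel: str = ""

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class MasticatoryEvent:
    bursts: list[Burst]
    type: str = UNCLASSIFIED

    @property
    def onset(self) -> float:
        return self.bursts[0].onset

    @property
    def offset(self) -> float:
        return max(b.offset for b in self.bursts)


@dataclass
class SBEpisode:
    event: MasticatoryEvent
    surge_onset: float

    @property
    def lag(self) -> float:
        return self.event.onset - self.surge_onset


@dataclass
class SubjectSummary:
    subject_id: str
    bruxism_index: float
    mean_hr: float
    n_total: int
    n_tonic: int
    n_phasic: int
    n_mixed: int
    exam_length: float
    scored_length: float


@dataclass
class ScoringResult:
    """Summary plus the intermediate objects (for reports and recovery tests)."""

    summary: SubjectSummary
    events: list[MasticatoryEvent]
    episodes: list[SBEpisode]
    surge_onsets: list[float]
    mvc: dict[str, calibration.MvcResult]
    config: ScoringConfig


def detect_bursts(
    pct_envelope: EnvelopeSeries, config: ScoringConfig, channel: str | None = None
) -> list[Burst]:
    """Threshold-crossing burst detection on a %MVC envelope.

    A burst opens when the envelope rises above ``burst_threshold`` and
    closes when it falls below ``burst_offset_hysteresis x threshold`` (the
    hysteresis stops threshold-grazing amplitudes from splitting one burst
    into chatter). Bursts closer than ``burst_merge_gap`` merge; bursts
    shorter than ``burst_min_dur`` are discarded.
    """
    env = pct_envelope.values
    fs = pct_envelope.sampling_rate
    thr = config.burst_threshold
    low = config.burst_offset_hysteresis * thr
    ch = channel if channel is not None else pct_envelope.channel

    above = env > thr
    below = env < low
    bursts: list[Burst] = []
    i = 0
    n = len(env)
    rises = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if n and above[0]:
        rises = np.concatenate([[0], rises])
    pos = 0
    while pos < len(rises):
        s = rises[pos]
        if bursts and s / fs <= bursts[-1].offset:
            pos += 1
            continue
        rel = np.flatnonzero(below[s:])
        e = s + rel[0] if rel.size else n
        bursts.append(Burst(s / fs, e / fs, float(np.max(env[s:e])), ch))
        pos += 1

    merged: list[Burst] = []
    for b in bursts:
        if merged and b.onset - merged[-1].offset < config.burst_merge_gap:
            prev = merged[-1]
            merged[-1] = Burst(
                prev.onset, max(prev.offset, b.offset), max(prev.peak, b.peak), ch
            )
        else:
            merged.append(b)
    return [b for b in merged if b.duration >= config.burst_min_dur]


def merge_overlapping(bursts: list[Burst]) -> list[Burst]:
    """Union of bursts across channels: overlapping intervals coalesce."""
    out: list[Burst] = []
    for b in sorted(bursts, key=lambda b: (b.onset, b.offset)):
        if out and b.onset <= out[-1].offset:
            prev = out[-1]
            out[-1] = Burst(
                prev.onset,
                max(prev.offset, b.offset),
                max(prev.peak, b.peak),
                prev.channel if prev.channel == b.channel else "both",
            )
        else:
            out.append(b)
    return out


def group_events(bursts: list[Burst], config: ScoringConfig) -> list[MasticatoryEvent]:
    """Maximal runs of bursts whose sub-threshold gaps are < ``event_gap``."""
    events: list[MasticatoryEvent] = []
    for b in sorted(bursts, key=lambda b: b.onset):
        if events and b.onset - events[-1].offset < config.event_gap:
            events[-1].bursts.append(b)
        else:
            events.append(MasticatoryEvent([b]))
    for ev in events:
        ev.type = classify_event(ev, config)
    return events


def classify_event(event: MasticatoryEvent, config: ScoringConfig) -> str:
    """Tonic / phasic / mixed per burst durations (boundaries: tonic strict
    > 2 s, phasic bounds inclusive). Activity matching neither definition
    (one or two short bursts) is ``unclassified``."""
    lo, hi = config.phasic_burst_bounds
    tonic = any(b.duration > config.tonic_min_dur for b in event.bursts)
    n_phasic = sum(lo <= b.duration <= hi for b in event.bursts)
    phasic = n_phasic >= config.phasic_min_bursts
    if tonic and phasic:
        return MIXED
    if tonic:
        return TONIC
    if phasic:
        return PHASIC
    return UNCLASSIFIED


def detect_hr_surges(hr: HeartRateSeries, config: ScoringConfig) -> list[float]:
    """Onset times of >= ``hr_rise`` heart-rate surges over a trailing baseline.

    The baseline at interval i is the mean of the ``hr_baseline_beats``
    preceding interval rates and is frozen while a surge is open. The
    reported onset is the start of the accelerated run: from the first
    qualifying interval the onset walks back over up to two immediately
    preceding intervals already elevated by half the rise, landing on the
    beat where the RR shortening began.
    """
    nb = config.hr_baseline_beats
    rates = hr.rates
    t = hr.beat_times
    if len(rates) < nb + 1:
        raise preprocess.EcgError(
            f"need more than {nb} RR intervals for surge detection"
        )
    onsets: list[float] = []
    in_surge = False
    frozen = 0.0
    csum = np.concatenate([[0.0], np.cumsum(rates)])
    for i in range(nb, len(rates)):
        baseline = frozen if in_surge else (csum[i] - csum[i - nb]) / nb
        if not in_surge:
            if rates[i] >= (1.0 + config.hr_rise) * baseline:
                j = i
                half = (1.0 + 0.5 * config.hr_rise) * baseline
                while j > max(nb - 1, i - 2) and rates[j - 1] >= half:
                    j -= 1
                onsets.append(float(t[j]))
                in_surge = True
                frozen = baseline
        elif rates[i] < (1.0 + config.hr_rise) * frozen:
            in_surge = False
    return onsets


def score_sb_episodes(
    events: list[MasticatoryEvent],
    surge_onsets: list[float],
    config: ScoringConfig,
) -> list[SBEpisode]:
    """Couple classified events to preceding heart-rate surges.

    An event becomes an SB episode iff some surge onset precedes its onset
    by a lag inside ``lag_window``; with one-to-one coupling (default) each
    surge licenses at most the first qualifying event.
    """
    lo, hi = config.lag_window
    episodes: list[SBEpisode] = []
    used = [False] * len(surge_onsets)
    surges = sorted(range(len(surge_onsets)), key=lambda k: surge_onsets[k])
    for ev in sorted(events, key=lambda e: e.onset):
        if ev.type == UNCLASSIFIED:
            continue
        for k in surges:
            if config.one_to_one_coupling and used[k]:
                continue
            lag = ev.onset - surge_onsets[k]
            if lo <= lag <= hi:
                used[k] = True
                episodes.append(SBEpisode(ev, surge_onsets[k]))
                break
    return episodes


def bruxism_index(episodes: list[SBEpisode], scored_length: float) -> float:
    """SB episodes per hour of scored recording."""
    if scored_length <= 0:
        raise ValueError("scored_length must be positive")
    return len(episodes) * 3600.0 / scored_length


def score_recording(recording: Recording, config: ScoringConfig | None = None) -> ScoringResult:
    """Run the full chain: envelope -> MVC -> %MVC -> bursts -> events ->
    R peaks -> HR surges -> SB episodes -> subject summary."""
    cfg = config or ScoringConfig()

    emg = recording.emg_channels
    if cfg.bilateral_mode == "left":
        emg = [c for c in emg if c.label == "EMG_LEFT"] or emg[:1]
    elif cfg.bilateral_mode == "right":
        emg = [c for c in emg if c.label == "EMG_RIGHT"] or emg[-1:]

    mvc_results: dict[str, calibration.MvcResult] = {}
    all_bursts: list[Burst] = []
    cal_end = 0.0
    envelopes: list[EnvelopeSeries] = []
    for ch in emg:
        env = preprocess.emg_envelope(
            ch.samples, ch.sampling_rate, cfg.rms_window, channel=ch.label
        )
        mvc = calibration.detect_mvc(env, search_window=cfg.mvc_search_window)
        mvc_results[ch.label] = mvc
        cal_end = max(cal_end, mvc.calibration_span[1])
        pct = calibration.normalize(env, mvc.mvc)
        envelopes.append(pct)

    if cfg.bilateral_mode == "max-envelope" and len(envelopes) > 1:
        n = min(len(e.values) for e in envelopes)
        stacked = np.maximum.reduce([e.values[:n] for e in envelopes])
        combined = EnvelopeSeries(
            stacked, envelopes[0].sampling_rate, "max", units="%MVC"
        )
        all_bursts = detect_bursts(combined, cfg)
    else:
        for pct in envelopes:
            all_bursts.extend(detect_bursts(pct, cfg))
        all_bursts = merge_overlapping(all_bursts)

    # clip to the scored span: calibration clenches must not be scored
    scored_bursts = [b for b in all_bursts if b.onset >= cal_end]
    events = group_events(scored_bursts, cfg)

    ecg = recording.ecg
    beats = preprocess.detect_r_peaks(ecg.samples, ecg.sampling_rate)
    hr = preprocess.heart_rate_series(beats)
    surges = detect_hr_surges(hr, cfg)
    episodes = score_sb_episodes(events, surges, cfg)

    exam_length = recording.duration
    scored_length = exam_length - cal_end
    classified = [e for e in events if e.type != UNCLASSIFIED]
    n_counts = {
        TONIC: sum(e.type == TONIC for e in classified),
        PHASIC: sum(e.type == PHASIC for e in classified),
        MIXED: sum(e.type == MIXED for e in classified),
    }
    n_total = len(classified) + (
        sum(e.type == UNCLASSIFIED for e in events) if cfg.count_unclassified else 0
    )
    summary = SubjectSummary(
        subject_id=recording.subject_id,
        bruxism_index=bruxism_index(episodes, scored_length),
        mean_hr=preprocess.mean_heart_rate(hr),
        n_total=n_total,
        n_tonic=n_counts[TONIC],
        n_phasic=n_counts[PHASIC],
        n_mixed=n_counts[MIXED],
        exam_length=exam_length,
        scored_length=scored_length,
    )
    return ScoringResult(summary, events, episodes, surges, mvc_results, cfg)


def summarize_subject(recording: Recording, config: ScoringConfig | None = None) -> SubjectSummary:
    """Convenience wrapper returning only the per-subject summary row."""
    return score_recording(recording, config).summary
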