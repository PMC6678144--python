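"""Burst detection, event grouping/classification, surge coupling, index."""

import dataclasses

import numpy as np
import pytest

from bruxscore import scoring
from bruxscore.preprocess import EnvelopeSeries, HeartRateSeries
from bruxscore.scoring import (
    Burst,
    ScoringConfig,
    bruxism_index,
    classify_event,
    detect_bursts,
    detect_hr_surges,
    group_events,
    merge_overlapping,
    score_recording,
    score_sb_episodes,
)

CFG = ScoringConfig()


def env_from_segments(segments, total=20.0, fs=100.0, floor=2.0):
    """%MVC envelope with rectangular plateaus given as (onset, offset, level)."""
    v = np.full(int(total * fs), float(floor))
    for s, e, level in segments:
        v[int(s * fs) : int(e * fs)] = level
    return EnvelopeSeries(v, fs, "EMG_LEFT", units="%MVC")


def hr_from_rates(rates, start=0.0):
    """Beat times realizing the given per-interval rates (bpm)."""
    times = [start]
    for r in rates:
        times.append(times[-1] + 60.0 / r)
    return HeartRateSeries(np.array(times), np.asarray(rates, dtype=float))


class TestDetectBursts:
    def test_subthreshold_envelope_yields_nothing(self):
        assert detect_bursts(env_from_segments([], floor=8.0), CFG) == []

    def test_plateau_duration_recovered(self):
        bursts = detect_bursts(env_from_segments([(5.0, 7.5, 40.0)]), CFG)
        assert len(bursts) == 1
        assert bursts[0].duration == pytest.approx(2.5, abs=0.1)
        assert bursts[0].peak == pytest.approx(40.0)

    def test_short_spike_discarded(self):
        bursts = detect_bursts(env_from_segments([(5.0, 5.1, 50.0)]), CFG)
        assert bursts == []

    def test_hysteresis_keeps_graze_as_one_burst(self):
        """A dip to 9 %MVC (above 0.8 x 10) must not split the burst."""
        env = env_from_segments([(5.0, 5.4, 15.0), (5.4, 5.6, 9.0), (5.6, 6.0, 15.0)])
        bursts = detect_bursts(env, CFG)
        assert len(bursts) == 1
        assert bursts[0].duration == pytest.approx(1.0, abs=0.1)

    def test_deep_dip_splits_bursts(self):
        env = env_from_segments([(5.0, 5.5, 15.0), (6.0, 6.5, 15.0)])
        assert len(detect_bursts(env, CFG)) == 2

    def test_chatter_merge_gap(self):
        env = env_from_segments([(5.0, 5.5, 15.0), (5.52, 6.0, 15.0)])
        assert len(detect_bursts(env, CFG)) == 1


class TestGroupAndClassify:
    def b(self, onset, dur):
        return Burst(onset, onset + dur, 40.0, "EMG_LEFT")

    def test_bursts_with_small_gaps_form_one_event(self):
        events = group_events([self.b(0, 0.5), self.b(1.5, 0.5), self.b(3.0, 0.5)], CFG)
        assert len(events) == 1
        assert len(events[0].bursts) == 3

    def test_gap_at_event_gap_splits(self):
        events = group_events([self.b(0, 0.5), self.b(5.5, 0.5)], CFG)
        assert len(events) == 2

    def test_tonic_definition(self):
        assert classify_event(group_events([self.b(0, 2.5)], CFG)[0], CFG) == "tonic"

    def test_phasic_definition(self):
        ev = group_events([self.b(0, 0.5), self.b(1, 0.5), self.b(2, 0.5)], CFG)[0]
        assert classify_event(ev, CFG) == "phasic"

    def test_mixed_definition(self):
        bursts = [self.b(0, 3.0), self.b(4, 0.5), self.b(5, 0.5), self.b(6, 0.5)]
        assert classify_event(group_events(bursts, CFG)[0], CFG) == "mixed"

    def test_exactly_two_seconds_is_not_tonic(self):
        """Tonic needs strictly more than 2 s; a lone 2.0 s burst is
        phasic-eligible but alone cannot make a phasic event."""
        ev = group_events([self.b(0, 2.0)], CFG)[0]
        assert classify_event(ev, CFG) == "unclassified"

    def test_quarter_second_burst_is_phasic_eligible(self):
        ev = group_events([self.b(0, 0.25), self.b(1, 0.25), self.b(2, 0.25)], CFG)[0]
        assert classify_event(ev, CFG) == "phasic"

    def test_cross_channel_overlap_merges(self):
        bursts = [
            Burst(0.0, 1.0, 30.0, "EMG_LEFT"),
            Burst(0.5, 1.5, 35.0, "EMG_RIGHT"),
        ]
        merged = merge_overlapping(bursts)
        assert len(merged) == 1
        assert merged[0].offset == 1.5
        assert merged[0].peak == 35.0

    def test_agrees_with_brute_force_oracle(self):
        """Grouping + classification agree with an independent transitive-
        closure grouping and a direct re-statement of the class rules."""
        rng = np.random.default_rng(99)
        for _ in range(60):
            n = int(rng.integers(1, 12))
            onsets = np.sort(rng.uniform(0, 60, n))
            bursts = []
            last_end = 0.0
            for o in onsets:
                o = max(o, last_end + 0.06)
                d = float(rng.choice([0.3, 0.5, 1.0, 2.0, 2.5, 3.5]))
                bursts.append(Burst(o, o + d, 40.0, "EMG_LEFT"))
                last_end = o + d
            got = group_events(bursts, CFG)
            want = oracle_group_classify(bursts, CFG)
            assert [(len(e.bursts), e.type) for e in got] == want


def oracle_group_classify(bursts, cfg):
    """O(n^2) union-find over the 'gap < event_gap' relation, then the
    tonic/phasic/mixed rules re-stated from scratch."""
    n = len(bursts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    srt = sorted(range(n), key=lambda i: bursts[i].onset)
    for ai in range(n):
        for bi in range(n):
            a, b = bursts[srt[ai]], bursts[srt[bi]]
            if a.onset <= b.onset and b.onset - a.offset < cfg.event_gap:
                ra, rb = find(srt[ai]), find(srt[bi])
                parent[rb] = ra
    groups = {}
    for i in srt:
        groups.setdefault(find(i), []).append(bursts[i])
    out = []
    for _, members in sorted(groups.items(), key=lambda kv: kv[1][0].onset):
        durs = [b.offset - b.onset for b in members]
        has_tonic = any(d > 2.0 for d in durs)
        has_phasic = sum(0.25 <= d <= 2.0 for d in durs) >= 3
        if has_tonic and has_phasic:
            typ = "mixed"
        elif has_tonic:
            typ = "tonic"
        elif has_phasic:
            typ = "phasic"
        else:
            typ = "unclassified"
        out.append((len(members), typ))
    return out


class TestDetectHrSurges:
    def test_constant_rate_yields_nothing(self):
        assert detect_hr_surges(hr_from_rates([60.0] * 30), CFG) == []

    def test_single_25_percent_beat_triggers(self):
        """One RR shortened to 0.8 s at 60 bpm is 75 bpm = +25% >= +20%."""
        rates = [60.0] * 15 + [75.0] + [60.0] * 5
        onsets = detect_hr_surges(hr_from_rates(rates), CFG)
        assert len(onsets) == 1
        # the qualifying interval starts at beat 15 -> t = 15 s
        assert onsets[0] == pytest.approx(15.0, abs=0.01)

    def test_19_percent_rise_does_not_trigger(self):
        rates = [60.0] * 15 + [71.0] + [60.0] * 5
        assert detect_hr_surges(hr_from_rates(rates), CFG) == []

    def test_run_of_fast_beats_is_one_surge(self):
        rates = [60.0] * 15 + [78.0, 78.0, 76.0] + [60.0] * 8
        assert len(detect_hr_surges(hr_from_rates(rates), CFG)) == 1

    def test_walk_back_finds_ramp_start(self):
        """With a half-elevated beat before the qualifying one, the onset
        backs up to where the acceleration began."""
        rates = [60.0] * 15 + [68.0, 78.0] + [60.0] * 5
        onsets = detect_hr_surges(hr_from_rates(rates), CFG)
        assert len(onsets) == 1
        assert onsets[0] == pytest.approx(15.0, abs=0.01)

    def test_short_series_rejected(self):
        with pytest.raises(Exception, match="RR intervals"):
            detect_hr_surges(hr_from_rates([60.0] * 5), CFG)

    def test_planted_surges_recovered_within_one_beat(self, short_night):
        from bruxscore import preprocess

        cfg, rec, truth = short_night
        beats = preprocess.detect_r_peaks(rec.ecg.samples, rec.ecg.sampling_rate)
        hr = preprocess.heart_rate_series(beats)
        onsets = detect_hr_surges(hr, CFG)
        beat_period = 60.0 / cfg.baseline_hr
        for surge in truth.surges:
            err = np.min(np.abs(np.asarray(onsets) - surge["onset"]))
            assert err <= beat_period + 0.05


class TestCoupling:
    def ev(self, onset, dur=2.5):
        e = scoring.MasticatoryEvent([Burst(onset, onset + dur, 40.0, "L")])
        e.type = "tonic"
        return e

    def test_lag_inside_window_scores(self):
        eps = score_sb_episodes([self.ev(100.0)], [97.0], CFG)
        assert len(eps) == 1
        assert eps[0].lag == pytest.approx(3.0)

    def test_lag_below_one_second_rejected(self):
        assert score_sb_episodes([self.ev(100.0)], [99.5], CFG) == []

    def test_lag_above_five_seconds_rejected(self):
        assert score_sb_episodes([self.ev(100.0)], [94.0], CFG) == []

    def test_unclassified_events_never_score(self):
        e = self.ev(100.0)
        e.type = "unclassified"
        assert score_sb_episodes([e], [97.0], CFG) == []

    def test_one_surge_licenses_one_episode(self):
        events = [self.ev(100.0), self.ev(102.5)]
        eps = score_sb_episodes(events, [99.0], CFG)
        assert len(eps) == 1
        assert eps[0].event.onset == 100.0

    def test_many_to_many_when_configured(self):
        cfg = dataclasses.replace(CFG, one_to_one_coupling=False)
        events = [self.ev(100.0), self.ev(103.0)]
        assert len(score_sb_episodes(events, [99.0], cfg)) == 2


class TestBruxismIndex:
    def test_twelve_episodes_in_six_hours(self):
        eps = [object()] * 12
        assert bruxism_index(eps, 6 * 3600.0) == pytest.approx(2.0)

    def test_zero_episodes(self):
        assert bruxism_index([], 3600.0) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            bruxism_index([], 0.0)


class TestEndToEnd:
    def test_recovers_planted_episodes_exactly(self, scored_short_night):
        """The headline recovery contract: k planted coupled events among m
        confounders yield exactly k scored episodes."""
        cfg, rec, truth, result = scored_short_night
        assert len(result.episodes) == len(truth.coupled_events)
        for ep in result.episodes:
            assert 1.0 <= ep.lag <= 5.0

    def test_counts_monotone_along_chain(self, scored_short_night):
        _, _, _, result = scored_short_night
        classified = [e for e in result.events if e.type != "unclassified"]
        assert len(result.episodes) <= len(classified) <= len(result.events)

    def test_summary_counts_consistent(self, scored_short_night):
        _, _, _, result = scored_short_night
        s = result.summary
        assert s.n_total == s.n_tonic + s.n_phasic + s.n_mixed
        assert s.scored_length == pytest.approx(s.exam_length - result.mvc["EMG_LEFT"].calibration_span[1], abs=1.0)

    def test_index_tracks_planted_rate(self, scored_short_night):
        _, _, truth, result = scored_short_night
        assert result.summary.bruxism_index == pytest.approx(truth.true_index, rel=0.10)

    def test_gain_invariance(self, short_night):
        """Multiplying the EMG gain by any positive constant leaves scoring
        unchanged (thresholds are %MVC)."""
        _, rec, _ = short_night
        base = score_recording(rec)
        import copy

        scaled = copy.deepcopy(rec)
        for ch in scaled.emg_channels:
            ch.samples = ch.samples * 10.0
        res = score_recording(scaled)
        assert res.summary.bruxism_index == base.summary.bruxism_index
        assert len(res.episodes) == len(base.episodes)
        assert [e.type for e in res.events] == [e.type for e in base.events]

    def test_flat_ecg_propagates_error(self, quiet_night):
        from bruxscore.preprocess import EcgError

        _, rec, _ = quiet_night
        import copy

        broken = copy.deepcopy(rec)
        broken.ecg.samples = np.zeros_like(broken.ecg.samples)
        with pytest.raises(EcgError):
            score_recording(broken)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScoringConfig(lag_window=(5.0, 1.0))
        with pytest.raises(ValueError):
            ScoringConfig(burst_min_dur=0.5)
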