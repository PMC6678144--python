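# Methods

## Scoring model

A recording holds one or two masseter-EMG channels and one ECG lead, in
mV, with times in seconds from device switch-on. The examination length is
the full recording duration; the *scored* length excludes the calibration
prologue.

**Envelope.** Each EMG channel is mean-subtracted and converted to a
moving-RMS envelope with a centered 50 ms window. The window must resolve
the shortest scoreable burst (0.25 s) while suppressing carrier-level
fluctuation; 50 ms smears burst edges by at most ~±25 ms, well under the
class boundaries used later. The envelope is shift-equivariant and keeps
the native EMG rate (no resampling anywhere in the chain).

**MVC calibration.** The prologue is three ~3 s maximum voluntary
clenches separated by ~10 s of rest. Clench segments are found in the
opening 60 s (the protocol needs 29 s; the slack allows for patient delay
in unsupervised home use) as contiguous runs above 5× the window-median
envelope, kept when 1–6 s long; the three with the largest peaks are the
clenches. Each clench's amplitude is read from a 0.5 s moving average of
the RMS envelope rather than the raw 50 ms envelope peak: the short-window
RMS of a stochastic EMG carrier has ~17% sampling spread, so its maximum
over a 3 s clench would overestimate MVC by tens of percent, while the
smoothed read keeps the %MVC scale within ~5%. The largest clench
amplitude is the channel's MVC; each channel is normalized by its own MVC
because left/right clench asymmetry is physiological. The ratio of the
largest to smallest clench peak is reported as an effort-quality flag
(sub-maximal clenching inflates every %MVC value) but is not acted on.
Scoring begins after the last clench offset plus 5 s.

**Bursts and events.** On the %MVC envelope a burst opens above 10 %MVC
and closes below 0.8× threshold — the hysteresis stops threshold-grazing
amplitudes from splitting one contraction into chatter. Bursts shorter
than 0.25 s are discarded; bursts separated by under 50 ms merge. With two
EMG channels, bursts are detected per channel and pooled (union), with
overlapping cross-channel bursts coalesced; union is the most sensitive
defensible combination when the device itself does not document how sides
combine, and `ScoringConfig.bilateral_mode` offers
`union|left|right|max-envelope`. Bursts whose sub-threshold gaps are
under 3 s group into one masticatory event; 3 s of quiescence is the
conventional rhythmic-masticatory-activity separation, configurable via
`event_gap`. An event is *tonic* when any burst exceeds 2 s (strict),
*phasic* when ≥ 3 bursts last 0.25–2 s (inclusive bounds), *mixed* when
both hold. A burst of exactly 2.000 s is therefore phasic-eligible, not
tonic. Events with one or two short bursts match no definition and are
*unclassified*: they are excluded from contraction counts and episode
candidacy by default (the taxonomy is exhaustive over tonic/phasic/mixed,
and counting unclassifiable activity would inflate totals);
`count_unclassified` restores them to the totals for sensitivity
analyses.

**Heart rate and surges.** R peaks come from a Pan-Tompkins-style
pipeline — 5–18 Hz band emphasis, differentiation, squaring, 150 ms
moving integration, adaptive signal/noise thresholds with a 250 ms
refractory — refined to the local maximum of the squared band signal.
Squaring makes detection polarity-invariant. No search-back pass is
implemented; on noisy real recordings this can drop low-amplitude beats,
a known limitation. The rate of RR interval i is 60/RR, an event series
rather than a sample series. A surge opens at the first interval whose
rate reaches 1.2× the trailing mean of the 10 preceding intervals;
consecutive qualifying intervals extend the surge and the baseline is
frozen while it is open. Beat-domain baselining avoids interpolation
artifacts; the vendor's exact baseline definition is undocumented, so
this is a package design decision, not a claimed fact about the device.
The reported surge onset is the start of the accelerated run: from the
first qualifying interval, the onset walks back over up to two preceding
intervals already elevated by half the rise, landing on the beat where
the RR shortening began. Without this, the reported onset lags the true
acceleration by 1–2 beats and events near the lag-window edges would be
systematically lost.

**Episodes, index, diagnosis.** A classified event becomes an SB episode
iff its onset follows some surge onset by 1–5 s (comparison on onsets;
the micro-arousal cascade puts cardiac activation first). Each surge
licenses at most the first qualifying event (`one_to_one_coupling=False`
relaxes this; whether one arousal may license several events is
undocumented for the device). The bruxism index is episodes × 3600 /
scored_length. The calibration denominator choice matters: the prologue
contains deliberate maximal contractions and must not be scored, and true
sleep length is unknowable without EEG, so scored recording time is the
honest denominator. An index strictly greater than 2/h is a positive
screen. Cohort accuracy cross-tabulates device calls against the clinical
reference standard — symptomatic examination AND positive self-report,
mirroring how screening cohorts are assembled — and reports sensitivity
and specificity to one decimal.

**Cohort statistics.** Group descriptives are n, min, max, arithmetic
mean, median, sample SD (n−1) and CV = 100·SD/mean. Group comparisons use
the Mann-Whitney U normal approximation with midranks and tie-corrected
variance and no continuity correction, reported as z with a two-sided p;
ties matter because indices are conventionally rounded to 0.1.
Correlations are Spearman's ρ (Pearson correlation of midranks) with
t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom. Association of binary
factors uses the Pearson chi-square on 2×2 tables without continuity
correction. α = 0.05 two-sided throughout, with no multiple-testing
correction — a deliberate match to common practice in small screening
cohorts and a documented limitation. Normality screening is omitted: the
pipeline always applies the nonparametric tests, which is what a
normality pre-test would select for index-like skewed data anyway.

## Synthetic nights

The generator plants everything the scorer must recover.

* **EMG**: band-limited (80–250 Hz, 4th-order Butterworth, zero-phase)
  unit-RMS Gaussian noise, amplitude-modulated by an envelope profile:
  2% of MVC at rest, trapezoidal bursts with 50 ms ramps at 40% of MVC
  with ±20% per-burst jitter (jitter and ramps prevent degenerate
  square-wave fixtures that would hide envelope-lag bugs). Clench
  amplitudes draw from 0.85–1.0× the configured MVC so the three clenches
  differ realistically; the right channel carries a fixed 0.8–1.0×
  asymmetry gain, which cancels in %MVC. Defaults: 500 Hz EMG, 250 Hz
  ECG — unstated for the device class, chosen to resolve 0.25 s bursts
  and R peaks comfortably.
* **Events**: candidate onsets from a homogeneous Poisson process per
  class (coupled episodes, confounders, surge-only arousals), greedily
  thinned so each event's onset starts ≥ 12 s after the previous event's
  offset. This enforces the ≥ 10 s onset separation a scorer expects
  between distinct events and guarantees one event's surge cannot fall
  into the next event's lag window, so planted coupling is unambiguous.
  Realized counts (not nominal rates) define the planted index. Event
  shapes: tonic one burst of 2.5–8 s; phasic 3–6 bursts of 0.35–1.5 s
  with 0.3–0.8 s gaps; mixed a 2.5–5 s burst plus 3–4 short bursts.
  Durations sit inside the scoring classes but away from the 0.25 s
  minimum and the 2 s tonic boundary so that ±50 ms envelope smearing
  cannot flip a planted class — an identifiability choice, not a claim
  that real events avoid boundaries. The type mix defaults to 60/34/6%
  tonic/phasic/mixed, the proportion observed among scored contractions
  in screening cohorts. Confounders reuse the same shapes (so only the
  cardiac signature separates them), and surge-only arousals plant
  tachycardia without EMG.
* **ECG**: a 40 ms biphasic QRS template on an RR sequence generated
  beat by beat at the configured baseline heart rate with 3% relative RR
  jitter. A surge multiplies the instantaneous rate by
  1 + m·exp(−Δt/6 s), i.e. a step-onset tachycardia recovering over
  ~10 s, with m = 0.30 by default — comfortably above the 20% scoring
  rule, as micro-arousal tachycardia is; a magnitude at exactly 0.20
  would sit on the detection threshold under RR jitter. Each surge
  activates at the first beat at/after its nominal time and the coupled
  event is anchored exactly `lag` seconds (uniform in 1–5 s) after that
  snapped onset, so the planted lag is exact on the beat grid. A ramped
  onset was considered and rejected: it makes the detectable onset lag
  the nominal one by 1–2 beats, which no scorer could undo, and the
  1–5 s coupling geometry — the part that matters — is unaffected by
  onset shape.

What the generator does **not** emulate: sleep-stage architecture, EEG,
apnea, body-movement and swallowing artifacts, electrode detachment,
ECG morphology beyond the R wave, heart-rate variability structure
(only white RR jitter), or sub-maximal calibration effort. Passing
recovery tests therefore demonstrates the scoring logic is correct and
robust to the planted confounders — not that the pipeline is validated
on patients.

## Cohorts and problem sizes

Cohort simulation draws per-subject episode rates from truncated normals
(study mean 6.04, SD 2.55; control mean 1.35, SD 0.86; truncated at 0),
baseline heart rates (59.6 ± 6.8 vs 63.5 ± 4.86 bpm), ages, sex mix and
recording lengths (~7 h ± ~1.1 h) per group, with study subjects carrying
the positive clinical reference labels. Note a consequence worth knowing:
with these distributions a few study subjects legitimately fall under the
2/h cut-off and ~23% of controls exceed it, so a simulated cohort's
sensitivity is typically in the 90s rather than 100% — the generator
models group overlap, not a deterministic label.

The validation suite and `scripts/acceptance.py` use scaled-down problem
sizes chosen as this package's own test-design choice: 3 h nights for the
20-night recovery sweep and 2 h nights for the simulated 35/25 cohort
(the cut-off exceedance probabilities are essentially flat in night
length, so shorter nights change variance, not structure). Generator
defaults remain the full study conditions (7 h nights).

## Numerical and degenerate-input choices

* RMS window forced to an odd sample count so the envelope is exactly
  centered; windows under 2 samples are rejected.
* Envelope and statistics use float64 throughout; EDF output quantizes to
  16 bits over a symmetric per-channel physical range (relative error
  ≤ ~3·10⁻⁵ of full scale).
* Burst state machine: opening is strict `> threshold`, closing strict
  `< 0.8×threshold`; a burst still open at signal end closes there.
* Surge walk-back is capped at two intervals to avoid chasing noise.
* Empty inputs are errors where a statistic is undefined (empty group,
  zero scored length, MVC ≤ 0, sensitivity with no clinical positives)
  and identities where a sum is natural (no bursts → no events → index 0).
* Mann-Whitney with zero pooled variance (all values identical) returns
  z = 0, p = 1 by convention; perfect Spearman monotonicity reports
  t = ±∞ with p = 0.
* All randomness flows from a single integer seed per generator config;
  cohort subjects get child seeds drawn from the cohort seed, so any
  subject is reproducible in isolation.

## Known limitations

* The R-peak detector has no search-back stage and a fixed band; it is
  adequate for template-like single-lead signals, not arrhythmia or
  heavy-artifact ECG (the scoring use case explicitly excludes cardiac
  diagnostics).
* Calibration assumes the patient actually performed the prologue inside
  the opening 60 s; a missed prologue is a hard error rather than a
  silent fallback, and degraded (1–2 clench) prologues only warn.
* The clinical reference in cohort scoring is the manifest's label
  conjunction; no blinded re-examination exists in simulation, so
  simulated accuracy measures the index-distribution overlap, nothing
  more.
* Tie handling and continuity-correction conventions differ between
  statistics packages; this package's choices (midranks, tie-corrected
  variance, no continuity correction) are documented above and verified
  against exact enumeration rather than against any one package's
  defaults.
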