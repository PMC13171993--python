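# Methods note

This document describes, in the package's own terms, the measurement model
implemented by `jointgaze`: what the engine computes, under which
conventions, and why the defaults are what they are.

## 1. Coordinate frame and regions

All positions are screen pixels on a 1920 × 1080 display (`ScreenGeometry`).
A region of interest (ROI) is an axis-aligned rectangle with **half-open
membership**: `(x, y)` is inside iff `x0 ≤ x < x1` and `y0 ≤ y < y1`, so
abutting regions partition the plane without double-counting boundary
points. ROIs within one trial must not overlap; a fixation whose centroid
falls in two regions raises a configuration error rather than guessing.

The attention-getter anchor is inset 15 % from a screen corner
(counterbalanced left/right across trials) because tracker accuracy and
precision degrade near screen borders (the "edge effect"); keeping the
anchor away from the border makes the 100 ms trigger reliable.

## 2. Fixation detection (I-DT)

Raw samples `(t_ms, x_px, y_px, valid)` are parsed into fixation events by
dispersion-threshold identification:

- **dispersion** of a sample window is `(max x − min x) + (max y − min y)`;
- a fixation is a **greedy-left maximal** run of valid samples with
  dispersion ≤ `max_dispersion_px` (default 60 px ≈ 1–1.5° at typical
  viewing distances);
- runs shorter than `min_duration_ms` (default 60 ms) are discarded;
- inter-sample gaps up to `max_gap_ms` (default 75 ms, e.g. blinks or
  dropped frames) are bridged; longer gaps break the run;
- the centroid is the mean of the member samples.

**Offset convention.** A fixation's offset is its last sample time plus one
sampling period (the median inter-sample interval of the stream). An
*n*-sample event at *f* Hz therefore has duration exactly `n/f` seconds:
each sample represents one period of looking. This makes scripted,
noise-free streams round-trip exactly — a scripted 200 ms fixation at
300 Hz is detected as precisely 200 ms — which is what lets the trigger
thresholds below be recovered behaviorally to the millisecond.

`min_duration_ms` is validated to be ≤ 100 ms so that detection can never
silently mask the shortest trigger threshold in the battery.

## 3. The contingency engine

A trial is a chain of numbered phases. Each phase has an optional gaze
trigger, an optional duration (its timeout/timeframe), and next-phase
pointers for the trigger and timeout paths. The engine consumes a fixation
stream plus optional researcher override commands and emits exactly one
transition record per visited phase: cause (`gaze_fixation`,
`gaze_alternation`, `timeout`, `override`), time, and latency from phase
onset.

**Resolution rule.** The earliest candidate ends the phase. At identical
timestamps the precedence is override > gaze > timeout: researcher control
is absolute, and at a timeframe boundary participant-driven data wins over
the scheduled advance. Non-contingent phases (video playback, greeting)
always end with cause `timeout` and are flagged `scheduled`, distinguishing
planned advances from failed contingencies.

**Fixation triggers** fire at `max(fixation onset, phase onset) +
min_fixation_ms`; gaze already resting on the region when the phase starts
gets credit only for its within-phase portion. Fires after the phase
timeframe are suppressed.

**Alternation triggers** implement the joint-attention bid: a two-state
automaton over the phase's fixation labels. A face fixation arms it; an
immediately following fixation on the paired object fires it at that
fixation's offset; a re-fixation on the face keeps it armed; any other
fixation — including off-region gaze — resets the sequence *without* ending
the phase, so the participant may start over within the timeframe. A pair
whose completing fixation ends after the timeframe does not fire.

**Attention-getter.** Phase 0 of every scored trial waits, unbounded by
default, for a 100 ms fixation on the anchor; this standardizes the initial
gaze position. Because an unresponsive stream would wait forever, the
engine raises an explicit `UnboundedWaitError` in that case unless the
researcher sets a cap (`attention_getter_cap_ms`), under which the phase
can also time out. All elapsed-time accounting excludes phase 0, since its
duration reflects the participant, not the stimulus design.

## 4. The battery

| Task | Trials | Trigger logic | Max duration |
|---|---|---|---|
| RJA | 16 | face fixation 200 ms (4 s timeframe) → 1.5 s direct gaze → 4 s cue window | 9.5 s |
| IJA-Request | 8 | face 200 ms → 10 s video → face↔tablet alternation (7 s) → 3.5 s response | 26 s |
| IJA-Comment | 8 | face 200 ms → face↔object alternation (7 s) → 3 s response | 14 s |

RJA cues are gaze shifts or head turns, left or right, fully crossed and
assigned to four object pairs by a Latin square over the four blocks.
Request trials cycle four video pairs and comment trials four objects so
that each block shows one left and one right instance from adjacent set
indices. Each block holds 4 RJA + 2 request + 2 comment trials; a seeded
constrained shuffle forbids three consecutive same-task trials, enforced
across block boundaries. The trial *multiset* is seed-invariant; only the
order varies.

Worst case, the 32 scored trials sum to 472 s (≈ 8 min), 118 s (≈ 2 min)
per block, excluding attention-getters. A 10 s greeting and a training
trial precede block 1, unscored. The training trial is a 26 s demonstration
phase followed by one full request chain, giving a 52 s worst case; the
demonstration phase makes the cap exact rather than merely an upper bound.

## 5. Scoring

- **RJA**: a trial is scorable only if a face fixation *spans the cue
  onset* (the measure is gaze-following *from the face*). The first
  non-face fixation within the 4 s cue window decides: cued target →
  `correct`, any other region → `incorrect`, none → `none`. Latency is
  that fixation's onset minus cue onset.
- **IJA** (request and comment): success iff the construct phase ended with
  cause `gaze_alternation`; a timeout is a valid failure. Latency is the
  alternation completion time minus phase onset.
- Any trial whose relevant phase was ended by researcher override is
  excluded from analysis (`valid_for_analysis = False`), not counted as
  failure. Session proportions are computed over valid trials only and are
  `None` — undefined, never zero — when no valid trials exist.

## 6. Synthetic participant

`ParticipantModel` is a generative model used to close the loop in testing
and for power/pipeline exploration. Per relevant phase it draws compliance
(Bernoulli: `p_initiate` for eye contact, `p_rja`, `p_request`,
`p_comment` for the constructs) and a response latency (lognormal, mean
800 ms, sd 400 ms, truncated to the phase's feasible window). Compliant
behavior produces the intended fixation sequence; non-compliance produces
wandering off-region fixations. Landing error (`jitter_px`, clipped into
the region), per-sample tremor, and dropout corrupt the rasterized 300 Hz
stream. The simulator emits both the intended fixation events (for fast,
exact engine tests) and the raw samples (for full-pipeline tests), plus a
ground-truth record of every intended transition — so tests can assert
that the engine recovers exactly what the participant "meant to do".

All simulator defaults are fixed study conditions; every random draw
derives from the model's single seed, making sessions bit-reproducible.

## 7. Numerical and design decisions

- Times are float milliseconds throughout; no hidden unit conversions.
- CSV round trips are bit-exact: floats are written with 17 significant
  digits and parsed with round-trip precision.
- Chained phase timeouts within a trial are exact sums; only phases
  downstream of a gaze-timed transition can carry one-ulp float error.
- The request-trial alternation pairs the face with the cued-side tablet
  region, and the comment trial instantiates only the cued-side object
  region, so "the target" is unambiguous for the automaton.
- Elapsed-time reports exclude the attention-getter by convention (see §3).

## 8. Limitations

The engine operates on fixations, not raw gaze, so trigger latencies are
quantized by the detector (one sampling period plus minimum duration in the
worst case). The simulator is a testing instrument, not a model of child
behavior: compliance is independent across phases and latencies are
unimodally distributed. Smooth pursuit, saccade kinematics, and calibration
drift are out of scope; drift is handled operationally via the manual
override path.
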