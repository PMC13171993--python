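# jointgaze

An open, hardware-independent engine for **gaze-contingent joint-attention
assessment**. It implements, in plain Python, the full control logic of a
screen-based battery in which stimuli react in real time to where a child is
looking: trials advance when the participant fixates an attention-getter,
makes eye contact with an on-screen partner, follows a gaze or head-turn cue,
or alternates gaze between the partner's face and an object — and time out
gracefully when they do not.

## Why

Joint attention — sharing attentional engagement with a partner on an object
or event — is a core early social-communication skill, and one of the most
studied markers in autism research. Traditional assessments are live and
examiner-dependent; screen-based gaze-contingent paradigms make the
interaction reproducible, but the contingency logic is usually buried inside
proprietary stimulus-presentation software tied to one eye tracker. This
package separates that logic into an open, testable library:

- **declarative trial specifications** — every trial is a chain of phases,
  each with an optional gaze trigger, a timeout, and a manual override path;
- **a deterministic contingency engine** that resolves, for any fixation
  stream, exactly when and why each phase ended;
- **a counterbalanced 32-trial battery** covering responding to joint
  attention (RJA: following gaze-shift and head-turn cues) and initiating
  joint attention (IJA: requesting and commenting via face–object gaze
  alternation);
- **construct scoring** (first-look accuracy, alternation success, latencies)
  and session summaries;
- **a synthetic participant simulator** that closes the loop for testing:
  it produces both intended fixation events and rasterized raw gaze samples
  with noise, jitter and dropout.

Everything is text-based (CSV / JSON-lines / YAML), deterministic under a
seed, and independent of any tracker vendor: any source of `t, x, y, valid`
samples or pre-detected fixation events can drive it.

## The model in brief

- **Fixation detection** is dispersion-threshold identification (I-DT):
  a fixation is a maximal run of valid samples whose bounding-box dispersion
  `(max x − min x) + (max y − min y)` stays within 60 px, lasting at least
  60 ms, with gaps up to 75 ms bridged. A fixation's offset is the last
  sample time plus one sampling period, so an *n*-sample event at *f* Hz has
  duration exactly *n/f*.
- **Triggers** operate on labeled fixations. A *fixation trigger* fires when
  a single fixation on its region accumulates a minimum duration (100 ms on
  the attention-getter, 200 ms on the partner's face); a fixation straddling
  the phase onset contributes only its within-phase portion. An *alternation
  trigger* is a two-state automaton: a face fixation arms it, an immediately
  following fixation on the target object fires it at that fixation's
  offset; any other fixation (including off-region) resets the sequence
  without ending the phase.
- **Phase resolution**: the earliest of override, gaze trigger, and timeout
  ends a phase; at identical timestamps the precedence is
  override > gaze > timeout.
- **Battery**: 4 blocks of 8 trials (4 RJA, 2 requesting, 2 commenting),
  fully counterbalanced over cue type, cue direction, and stimulus sets,
  with a seeded constrained shuffle that never presents the same task three
  times in a row. Worst-case scored duration is 16×9.5 s + 8×26 s + 8×14 s
  = 472 s ≈ 8 min; each block ≈ 2 min. A 10 s greeting and a training trial
  capped at 52 s precede block 1 and are never scored.

## Worked example

Simulate a moderately compliant participant end to end — raw 300 Hz samples
in, construct scores out:

```python
from jointgaze import build_battery, detect_fixations, run_session, simulate_session
from jointgaze.simulator import ParticipantModel

battery = build_battery(seed=7)
model = ParticipantModel(p_rja=0.8, p_request=0.8, p_comment=0.8, seed=7)
session = simulate_session(battery, model)          # raw 300 Hz samples
fixations = detect_fixations(session.samples)       # I-DT event detection
run = run_session(battery, fixations)

s = run.summary
print(f"samples: {len(session.samples)}, fixations: {len(fixations)}")
print(f"RJA correct rate:       {s.rja_correct_rate:.3f}  (n={s.rja_n_valid})")
print(f"Request success rate:   {s.request_success_rate:.3f}  (n={s.request_n_valid})")
print(f"Comment success rate:   {s.comment_success_rate:.3f}  (n={s.comment_n_valid})")
print(f"RJA latency (median):   {s.latency_median_ms['RJA']:.0f} ms")
```

Output:

```text
samples: 115226, fixations: 410
RJA correct rate:       0.750  (n=16)
Request success rate:   0.750  (n=8)
Comment success rate:   0.750  (n=8)
RJA latency (median):   803 ms
```

The same pipeline is available from the command line:

```bash
jointgaze battery build --seed 7 --out battery.yaml
jointgaze simulate --config battery.yaml --seed 7 --out-dir sim/
jointgaze run --config battery.yaml --gaze sim/gaze.csv --out-dir out/
jointgaze report --results out/results.csv
```

`out/` then contains a transition log (`transitions.jsonl`), per-trial
results (`results.csv`), a session summary (`summary.json`), and a run
manifest.

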