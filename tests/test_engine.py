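"""Trigger evaluation, phase resolution, and trial execution."""

import itertools

import pytest

from jointgaze import (
    Cue,
    Direction,
    FixationEvent,
    OverrideCommand,
    PhaseSpec,
    Task,
    TransitionCause,
    TriggerKind,
    TriggerSpec,
    UnboundedWaitError,
    eval_alternation_trigger,
    eval_fixation_trigger,
    make_trial,
    run_phase,
    run_trial,
    trial_elapsed_ms,
)

from oracles import alternation_oracle

FACE_TRIGGER = TriggerSpec(kind=TriggerKind.FIXATION, roi="Face", min_fixation_ms=200.0)
ALT_TRIGGER = TriggerSpec(kind=TriggerKind.ALTERNATION, roi_pair=("Face", "Target"))

# centroids inside the conftest pair_rois regions
CENTER = {"Face": (960, 300), "Target": (400, 675), "Other": (1550, 675), None: (50, 1050)}


def fix_seq(labels, onset=0.0, dur=200.0, gap=50.0):
    """Fixation chain with the given ROI labels (None = off every ROI)."""
    out, t = [], onset
    for lab in labels:
        x, y = CENTER[lab]
        out.append(FixationEvent(t, t + dur, x, y))
        t += dur + gap
    return out


class TestFixationTrigger:
    def test_long_enough_face_fixation_fires_after_threshold(self, pair_rois):
        fx = [FixationEvent(500, 750, 960, 300)]  # 250 ms on the face
        fired, t = eval_fixation_trigger(FACE_TRIGGER, fx, pair_rois, phase_onset=0.0)
        assert fired and t == 700.0  # onset + 200 ms

    def test_short_face_fixation_never_fires(self, pair_rois):
        fx = [FixationEvent(500, 650, 960, 300)]  # 150 ms < 200 ms
        fired, t = eval_fixation_trigger(FACE_TRIGGER, fx, pair_rois, phase_onset=0.0)
        assert not fired and t is None

    def test_fixation_outside_roi_never_fires(self, pair_rois):
        fx = [FixationEvent(500, 900, 50, 1050)]  # 400 ms off every ROI
        fired, _ = eval_fixation_trigger(FACE_TRIGGER, fx, pair_rois, phase_onset=0.0)
        assert not fired

    def test_straddling_fixation_counts_only_within_phase(self, pair_rois):
        """Gaze already on the face at phase onset cannot fire instantly."""
        fx = [FixationEvent(-1_000, 150, 960, 300)]  # only 150 ms inside the phase
        fired, _ = eval_fixation_trigger(FACE_TRIGGER, fx, pair_rois, phase_onset=0.0)
        assert not fired
        fx = [FixationEvent(-1_000, 400, 960, 300)]  # 400 ms inside
        fired, t = eval_fixation_trigger(FACE_TRIGGER, fx, pair_rois, phase_onset=0.0)
        assert fired and t == 200.0  # phase onset + threshold

    def test_fire_beyond_timeframe_suppressed(self, pair_rois):
        fx = [FixationEvent(3_900, 4_300, 960, 300)]
        fired, _ = eval_fixation_trigger(
            FACE_TRIGGER, fx, pair_rois, phase_onset=0.0, timeframe_ms=4_000.0
        )
        assert not fired  # would complete at 4,100 ms, past the 4 s window


class TestAlternationTrigger:
    def test_face_then_target_fires_at_target_offset(self, pair_rois):
        fx = fix_seq(["Face", "Target"])
        fired, t = eval_alternation_trigger(ALT_TRIGGER, fx, pair_rois, 0.0)
        assert fired and t == fx[1].offset

    def test_deviation_resets_then_later_pair_fires(self, pair_rois):
        fx = fix_seq(["Face", "Other", "Target", "Face", "Target"])
        fired, t = eval_alternation_trigger(ALT_TRIGGER, fx, pair_rois, 0.0)
        assert fired and t == fx[4].offset  # not the Target at index 2

    def test_face_refixation_does_not_reset(self, pair_rois):
        fx = fix_seq(["Face", "Face", "Target"])
        fired, t = eval_alternation_trigger(ALT_TRIGGER, fx, pair_rois, 0.0)
        assert fired and t == fx[2].offset

    def test_target_first_does_not_fire_by_default(self, pair_rois):
        fx = fix_seq(["Target", "Face"])
        fired, _ = eval_alternation_trigger(ALT_TRIGGER, fx, pair_rois, 0.0)
        assert not fired

    def test_either_order_option_accepts_target_first(self, pair_rois):
        spec = TriggerSpec(
            kind=TriggerKind.ALTERNATION, roi_pair=("Face", "Target"), either_order=True
        )
        fx = fix_seq(["Target", "Face"])
        fired, t = eval_alternation_trigger(spec, fx, pair_rois, 0.0)
        assert fired and t == fx[1].offset

    def test_exhaustive_label_sequences_match_automaton_oracle(self, pair_rois):
        """Every label sequence of length <= 4 over {Face, Target, Other,
        off-ROI} agrees with the independent two-state automaton."""
        alphabet = ["Face", "Target", "Other", None]
        for n in range(0, 5):
            for labels in itertools.product(alphabet, repeat=n):
                fx = fix_seq(labels)
                fired, t = eval_alternation_trigger(ALT_TRIGGER, fx, pair_rois, 0.0)
                want = alternation_oracle(labels)
                assert fired == (want is not None), labels
                if want is not None:
                    assert t == fx[want].offset, labels

    def test_pair_completing_after_timeframe_suppressed(self, pair_rois):
        fx = fix_seq(["Face", "Target"], onset=6_700)  # Target ends at 7,150
        fired, _ = eval_alternation_trigger(
            ALT_TRIGGER, fx, pair_rois, 0.0, timeframe_ms=7_000.0
        )
        assert not fired


class TestRunPhase:
    PHASE = PhaseSpec(
        index=1, duration_ms=4_000.0, trigger=FACE_TRIGGER, on_trigger=2, on_timeout=2
    )

    def test_no_gaze_times_out_at_timeframe(self, pair_rois):
        rec = run_phase(self.PHASE, [], pair_rois, [], phase_onset=0.0)
        assert rec.cause is TransitionCause.TIMEOUT
        assert rec.latency_ms == 4_000.0
        assert not rec.scheduled

    def test_override_preempts_everything(self, pair_rois):
        fx = [FixationEvent(100, 2_000, 960, 300)]  # would fire at 300 ms
        rec = run_phase(self.PHASE, fx, pair_rois, [OverrideCommand(1_200)], 0.0)
        # override is later than the gaze fire time, so gaze wins here
        assert rec.cause is TransitionCause.GAZE_FIXATION and rec.t == 300.0
        rec = run_phase(self.PHASE, [], pair_rois, [OverrideCommand(1_200)], 0.0)
        assert rec.cause is TransitionCause.OVERRIDE and rec.latency_ms == 1_200.0

    def test_gaze_at_timeframe_boundary_beats_timeout(self, pair_rois):
        # fires exactly at 4,000 ms: gaze outranks timeout at equal times
        fx = [FixationEvent(3_800, 4_200, 960, 300)]
        rec = run_phase(self.PHASE, fx, pair_rois, [], 0.0)
        assert rec.cause is TransitionCause.GAZE_FIXATION and rec.t == 4_000.0

    def test_override_outranks_gaze_at_equal_time(self, pair_rois):
        fx = [FixationEvent(100, 2_000, 960, 300)]  # fires at 300
        rec = run_phase(self.PHASE, fx, pair_rois, [OverrideCommand(300)], 0.0)
        assert rec.cause is TransitionCause.OVERRIDE

    def test_scheduled_advance_of_noncontingent_phase(self, pair_rois):
        phase = PhaseSpec(index=2, duration_ms=1_500.0, on_timeout=3)
        rec = run_phase(phase, [], pair_rois, [], phase_onset=10_000.0)
        assert rec.cause is TransitionCause.TIMEOUT and rec.scheduled
        assert rec.t == 11_500.0

    def test_unbounded_phase_without_data_raises(self, pair_rois):
        ag = PhaseSpec(
            index=0, duration_ms=None,
            trigger=TriggerSpec(kind=TriggerKind.FIXATION, roi="Face", min_fixation_ms=100.0),
            on_trigger=1, allow_unbounded=True,
        )
        with pytest.raises(UnboundedWaitError):
            run_phase(ag, [], pair_rois, [], 0.0)
        rec = run_phase(ag, [], pair_rois, [OverrideCommand(2_000)], 0.0)
        assert rec.cause is TransitionCause.OVERRIDE

    def test_phasespec_validation(self):
        with pytest.raises(ValueError):
            PhaseSpec(index=1, duration_ms=None)  # unbounded without permission
        with pytest.raises(ValueError):
            TriggerSpec(kind=TriggerKind.FIXATION, roi="Face", min_fixation_ms=0)
        with pytest.raises(ValueError):
            TriggerSpec(kind=TriggerKind.ALTERNATION, roi_pair=("A", "A"))


class TestRunTrial:
    @pytest.mark.parametrize(
        "task,cue,expected",
        [
            (Task.RJA, Cue.HEAD_TURN, 9_500.0),
            (Task.IJA_REQUEST, None, 26_000.0),
            (Task.IJA_COMMENT, None, 14_000.0),
        ],
    )
    def test_unresponsive_stream_reaches_per_task_maximum(self, task, cue, expected):
        trial = make_trial(task, cue, Direction.LEFT, "s")
        recs = run_trial(trial, [], skip_attention_getter=True)
        assert all(r.cause is TransitionCause.TIMEOUT for r in recs)
        assert trial_elapsed_ms(recs) == expected

    def test_one_record_per_executed_phase_with_one_cause(self):
        trial = make_trial(Task.IJA_REQUEST, None, Direction.RIGHT, "s")
        recs = run_trial(trial, [], skip_attention_getter=True)
        assert [r.phase for r in recs] == [1, 2, 3, 4, 5]

    def test_attention_getter_cap_allows_unresponsive_runs(self):
        trial = make_trial(Task.RJA, Cue.GAZE_SHIFT, Direction.LEFT, "s")
        with pytest.raises(UnboundedWaitError):
            run_trial(trial, [])
        recs = run_trial(trial, [], attention_getter_cap_ms=5_000.0)
        assert recs[0].phase == 0 and recs[0].latency_ms == 5_000.0
        assert trial_elapsed_ms(recs) == 9_500.0  # cap excluded with phase 0

    def test_override_consumed_once(self):
        trial = make_trial(Task.RJA, Cue.GAZE_SHIFT, Direction.LEFT, "s")
        recs = run_trial(trial, [], overrides=[OverrideCommand(1_000)], skip_attention_getter=True)
        causes = [r.cause for r in recs]
        assert causes.count(TransitionCause.OVERRIDE) == 1
        assert recs[0].cause is TransitionCause.OVERRIDE

    def test_determinism(self):
        trial = make_trial(Task.IJA_COMMENT, None, Direction.RIGHT, "spider")
        fx = [FixationEvent(200, 600, 960, 300), FixationEvent(700, 1_100, 1_350, 210)]
        a = run_trial(trial, fx, skip_attention_getter=True)
        b = run_trial(trial, fx, skip_attention_getter=True)
        assert a == b
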