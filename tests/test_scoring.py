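"""Construct-level scoring: RJA gaze-following, IJA alternation success."""

import itertools

import pytest

from jointgaze import (
    Cue,
    Direction,
    FixationEvent,
    OverrideCommand,
    RjaOutcome,
    ScoringError,
    Task,
    TransitionCause,
    make_trial,
    run_trial,
    score_ija,
    score_rja,
    summarize_session,
)

from oracles import rja_oracle

# centroids inside the default RJA trial ROI template
RJA_CENTER = {
    "Face": (960, 300),
    "TargetLeft": (380, 850),
    "TargetRight": (1540, 850),
    None: (960, 1050),
}


def rja_setup(direction=Direction.LEFT):
    trial = make_trial(Task.RJA, Cue.GAZE_SHIFT, direction, "cups")
    # unresponsive engine pass fixes the phase clock: cue (phase 3) onset at 5,500
    recs = run_trial(trial, [], skip_attention_getter=True)
    cue_onset = recs[-1].onset
    return trial, recs, cue_onset


def fixes_after_cue(labels, cue_onset, face_spans_cue=True, dur=300.0, gap=40.0):
    out = []
    if face_spans_cue:
        out.append(FixationEvent(cue_onset - 500, cue_onset + 200, *RJA_CENTER["Face"]))
        t = cue_onset + 240
    else:
        t = cue_onset + 240
    for lab in labels:
        out.append(FixationEvent(t, t + dur, *RJA_CENTER[lab]))
        t += dur + gap
    return out


class TestScoreRja:
    def test_correct_look_with_latency(self):
        trial, recs, cue = rja_setup(Direction.LEFT)
        fx = [
            FixationEvent(cue - 500, cue + 200, *RJA_CENTER["Face"]),
            FixationEvent(cue + 800, cue + 1_100, *RJA_CENTER["TargetLeft"]),
        ]
        r = score_rja(trial, recs, fx)
        assert r.rja_outcome is RjaOutcome.CORRECT
        assert r.latency_ms == 800.0
        assert r.valid_for_analysis

    def test_opposite_target_is_incorrect(self):
        trial, recs, cue = rja_setup(Direction.LEFT)
        fx = fixes_after_cue(["TargetRight"], cue)
        assert score_rja(trial, recs, fx).rja_outcome is RjaOutcome.INCORRECT

    def test_never_leaving_face_is_none(self):
        trial, recs, cue = rja_setup()
        fx = [FixationEvent(cue - 500, cue + 3_900, *RJA_CENTER["Face"])]
        r = score_rja(trial, recs, fx)
        assert r.rja_outcome is RjaOutcome.NONE and r.latency_ms is None

    def test_not_on_face_at_cue_onset_is_none(self):
        """The measure is 'from the face': target looks without prior mutual
        gaze do not count."""
        trial, recs, cue = rja_setup()
        fx = fixes_after_cue(["TargetLeft"], cue, face_spans_cue=False)
        assert score_rja(trial, recs, fx).rja_outcome is RjaOutcome.NONE

    def test_look_after_window_end_is_none(self):
        trial, recs, cue = rja_setup()
        fx = [
            FixationEvent(cue - 500, cue + 200, *RJA_CENTER["Face"]),
            FixationEvent(cue + 4_100, cue + 4_500, *RJA_CENTER["TargetLeft"]),
        ]
        assert score_rja(trial, recs, fx).rja_outcome is RjaOutcome.NONE

    def test_exhaustive_label_sequences_match_oracle(self):
        """All post-cue fixation label sequences of length <= 3 agree with the
        first-look-from-face oracle."""
        trial, recs, cue = rja_setup(Direction.LEFT)
        alphabet = ["Face", "TargetLeft", "TargetRight", None]
        for n in range(0, 4):
            for labels in itertools.product(alphabet, repeat=n):
                fx = fixes_after_cue(labels, cue)
                got = score_rja(trial, recs, fx).rja_outcome.value
                want = rja_oracle(labels, cued="TargetLeft", opposite="TargetRight")
                assert got == want, labels

    def test_missing_cue_phase_record_raises(self):
        trial, recs, _ = rja_setup()
        with pytest.raises(ScoringError):
            score_rja(trial, [r for r in recs if r.phase != 3], [])

    def test_overridden_cue_phase_excluded(self):
        trial = make_trial(Task.RJA, Cue.GAZE_SHIFT, Direction.LEFT, "cups")
        recs = run_trial(
            trial, [], overrides=[OverrideCommand(6_000)], skip_attention_getter=True
        )
        assert recs[-1].cause is TransitionCause.OVERRIDE
        r = score_rja(trial, recs, [])
        assert not r.valid_for_analysis


class TestScoreIja:
    def _alternation_fixes(self, trial, recs, phase):
        onset = next(r.onset for r in recs if r.phase == phase)
        face = next(r for r in trial.rois if r.id == "Face").center
        target_id = trial.phases[phase].trigger.roi_pair[1]
        target = next(r for r in trial.rois if r.id == target_id).center
        return [
            FixationEvent(onset + 1_800, onset + 2_090, *face),
            FixationEvent(onset + 2_120, onset + 2_340, *target),
        ]

    def test_request_success_latency_is_alternation_end(self):
        trial = make_trial(Task.IJA_REQUEST, None, Direction.LEFT, "videos_1")
        probe = run_trial(trial, [], skip_attention_getter=True)
        fx = self._alternation_fixes(trial, probe, phase=3)
        recs = run_trial(trial, fx, skip_attention_getter=True)
        r = score_ija(trial, recs)
        assert r.ija_success is True
        assert r.latency_ms == 2_340.0  # pair's terminal offset minus phase onset
        assert r.valid_for_analysis

    def test_comment_construct_phase_is_phase_two(self):
        trial = make_trial(Task.IJA_COMMENT, None, Direction.RIGHT, "spider")
        probe = run_trial(trial, [], skip_attention_getter=True)
        fx = self._alternation_fixes(trial, probe, phase=2)
        recs = run_trial(trial, fx, skip_attention_getter=True)
        r = score_ija(trial, recs)
        assert r.ija_success is True and r.latency_ms == 2_340.0

    def test_timeout_is_failure_without_latency(self):
        trial = make_trial(Task.IJA_REQUEST, None, Direction.LEFT, "videos_1")
        recs = run_trial(trial, [], skip_attention_getter=True)
        r = score_ija(trial, recs)
        assert r.ija_success is False and r.latency_ms is None
        assert r.valid_for_analysis  # timeouts are failures, not exclusions

    def test_override_excludes_trial(self):
        trial = make_trial(Task.IJA_COMMENT, None, Direction.LEFT, "snake")
        # override lands inside the construct phase (phase 2, onset at 4,000)
        recs = run_trial(
            trial, [], overrides=[OverrideCommand(6_000)], skip_attention_getter=True
        )
        r = score_ija(trial, recs)
        assert r.valid_for_analysis is False
        assert r.ija_success is False

    def test_rja_trial_rejected(self):
        trial = make_trial(Task.RJA, Cue.HEAD_TURN, Direction.LEFT, "cups")
        with pytest.raises(ScoringError):
            score_ija(trial, run_trial(trial, [], skip_attention_getter=True))


class TestSummarize:
    def _results(self, n_correct, n_rja=16):
        out = []
        for i in range(n_rja):
            trial, recs, cue = rja_setup(Direction.LEFT)
            if i < n_correct:
                fx = fixes_after_cue(["TargetLeft"], cue)
            else:
                fx = fixes_after_cue([None], cue)
            r = score_rja(trial, recs, fx)
            out.append(r)
        return out

    def test_correct_rate_arithmetic(self):
        s = summarize_session(self._results(12))
        assert s.rja_n_valid == 16 and s.rja_correct_rate == 0.75

    def test_all_overridden_gives_undefined_proportions(self):
        trial = make_trial(Task.IJA_REQUEST, None, Direction.LEFT, "v")
        recs = run_trial(trial, [], overrides=[OverrideCommand(6_000)], skip_attention_getter=True)
        rs = [score_ija(trial, recs) for _ in range(4)]
        s = summarize_session(rs)
        assert s.request_success_rate is None  # undefined, not zero
        assert s.request_n_valid == 0

    def test_cause_histogram_conserves_counts(self):
        trial = make_trial(Task.IJA_COMMENT, None, Direction.LEFT, "spider")
        recs = run_trial(trial, [], skip_attention_getter=True)
        s = summarize_session([score_ija(trial, recs)], recs)
        assert sum(sum(c.values()) for c in s.cause_histogram.values()) == len(recs)

    def test_latency_stats_over_successes_only(self):
        rs = self._results(4)
        s = summarize_session(rs)
        lats = [r.latency_ms for r in rs if r.latency_ms is not None]
        assert s.latency_mean_ms["RJA"] == pytest.approx(sum(lats) / len(lats))
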