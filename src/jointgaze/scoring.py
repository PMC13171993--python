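"""Joint-attention outcome metrics from transition logs and fixation streams.

Only participant-driven (gaze-caused) transitions count toward construct
success; timeouts are failures and overridden construct phases are excluded
from analysis altogether, so researcher interventions can never masquerade
as joint-attention behavior.

RJA is scored from the fixation stream inside the cue window: the first
fixation leaving the actress's face must land on the cued target (correct)
or the opposite target (incorrect); a participant not on the face at cue
onset, or whose first look from the face goes elsewhere, yields no
gaze-following measure ("none"). IJA is scored from the construct phase's
transition cause: success iff the gaze-alternation trigger ended it, with
latency equal to the time from phase onset to the alternation's completion.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .battery import Cue, Direction, Task, TrialSpec
from .engine import TransitionCause, TransitionRecord
from .fixation import FixationEvent, fixation_roi_label

__all__ = [
    "RjaOutcome",
    "TrialResult",
    "SessionSummary",
    "ScoringError",
    "score_rja",
    "score_ija",
    "score_trial",
    "summarize_session",
]

#: construct phase index per IJA task
CONSTRUCT_PHASE = {Task.IJA_REQUEST: 3, Task.IJA_COMMENT: 2}
RJA_CUE_PHASE = 3


class ScoringError(ValueError):
    """Transition log is missing the record needed to score a trial."""


class RjaOutcome(str, enum.Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    NONE = "none"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class TrialResult:
    """Outcome metrics for one scored trial."""

    trial_id: str
    task: Task
    cue: Optional[Cue]
    direction: Optional[Direction]
    phase1_cause: Optional[TransitionCause]
    rja_outcome: RjaOutcome
    ija_success: Optional[bool]  # None = not applicable (RJA trials)
    latency_ms: Optional[float]
    valid_for_analysis: bool


def _record(transitions: Sequence[TransitionRecord], phase: int, trial_id: str) -> TransitionRecord:
    for r in transitions:
        if r.phase == phase:
            return r
    raise ScoringError(f"trial {trial_id}: no transition record for phase {phase}")


def _phase1_cause(transitions: Sequence[TransitionRecord]) -> Optional[TransitionCause]:
    return next((r.cause for r in transitions if r.phase == 1), None)


def score_rja(
    trial: TrialSpec,
    transitions: Sequence[TransitionRecord],
    fixations: Sequence[FixationEvent],
) -> TrialResult:
    """Score gaze-following in the referential-cue window of an RJA trial.

    Requires the participant to be fixating the Face ROI at cue onset; then
    the first subsequent non-Face fixation starting inside the cue window
    decides the outcome. Latency is that fixation's onset minus cue onset.
    """
    if trial.task is not Task.RJA:
        raise ScoringError(f"trial {trial.trial_id} is {trial.task.value}, not RJA")
    rec = _record(transitions, RJA_CUE_PHASE, trial.trial_id)
    cue_onset = rec.onset
    window_end = rec.t  # cue phase end (normally onset + 4 s; earlier if overridden)
    valid = rec.cause is not TransitionCause.OVERRIDE

    cued = "TargetLeft" if trial.direction is Direction.LEFT else "TargetRight"
    opposite = "TargetRight" if trial.direction is Direction.LEFT else "TargetLeft"

    labeled = [(f, fixation_roi_label(f, trial.rois)) for f in fixations]
    on_face = any(
        lbl == "Face" and f.onset <= cue_onset < f.offset for f, lbl in labeled
    )
    outcome = RjaOutcome.NONE
    latency: Optional[float] = None
    if on_face:
        for f, lbl in labeled:
            if f.onset < cue_onset or f.onset >= window_end:
                continue
            if lbl == "Face":
                continue  # re-fixation on the face keeps the measure armed
            if lbl == cued:
                outcome, latency = RjaOutcome.CORRECT, f.onset - cue_onset
            elif lbl == opposite:
                outcome, latency = RjaOutcome.INCORRECT, f.onset - cue_onset
            break  # first look away from the face decides
    return TrialResult(
        trial_id=trial.trial_id,
        task=trial.task,
        cue=trial.cue,
        direction=trial.direction,
        phase1_cause=_phase1_cause(transitions),
        rja_outcome=outcome,
        ija_success=None,
        latency_ms=latency,
        valid_for_analysis=valid,
    )


def score_ija(trial: TrialSpec, transitions: Sequence[TransitionRecord]) -> TrialResult:
    """Score an IJA trial from its construct phase's transition cause."""
    if trial.task not in CONSTRUCT_PHASE:
        raise ScoringError(f"trial {trial.trial_id} is {trial.task.value}, not IJA")
    phase = CONSTRUCT_PHASE[trial.task]
    rec = _record(transitions, phase, trial.trial_id)
    success = rec.cause is TransitionCause.GAZE_ALTERNATION
    return TrialResult(
        trial_id=trial.trial_id,
        task=trial.task,
        cue=None,
        direction=trial.direction,
        phase1_cause=_phase1_cause(transitions),
        rja_outcome=RjaOutcome.NOT_APPLICABLE,
        ija_success=success,
        latency_ms=rec.latency_ms if success else None,
        valid_for_analysis=rec.cause is not TransitionCause.OVERRIDE,
    )


def score_trial(
    trial: TrialSpec,
    transitions: Sequence[TransitionRecord],
    fixations: Sequence[FixationEvent] = (),
) -> Optional[TrialResult]:
    """Dispatch to the task's scorer; greeting/training are not scored."""
    if trial.task is Task.RJA:
        return score_rja(trial, transitions, fixations)
    if trial.task in CONSTRUCT_PHASE:
        return score_ija(trial, transitions)
    return None


@dataclass(frozen=True)
class SessionSummary:
    """Per-construct aggregation over one session's scored trials.

    Proportions are computed over analysis-valid trials only and are ``None``
    (undefined) when a construct has no valid trials; latency statistics are
    over successful trials only.
    """

    n_scored: int
    rja_n_valid: int
    rja_counts: dict
    rja_correct_rate: Optional[float]
    request_n_valid: int
    request_n_success: int
    request_success_rate: Optional[float]
    comment_n_valid: int
    comment_n_success: int
    comment_success_rate: Optional[float]
    latency_mean_ms: dict
    latency_median_ms: dict
    cause_histogram: dict = field(default_factory=dict)


def summarize_session(
    results: Sequence[TrialResult],
    transitions: Sequence[TransitionRecord] = (),
) -> SessionSummary:
    """Aggregate trial results into construct-level rates and latencies."""
    rja = [r for r in results if r.task is Task.RJA and r.valid_for_analysis]
    req = [r for r in results if r.task is Task.IJA_REQUEST and r.valid_for_analysis]
    com = [r for r in results if r.task is Task.IJA_COMMENT and r.valid_for_analysis]

    rja_counts = {
        o.value: sum(1 for r in rja if r.rja_outcome is o)
        for o in (RjaOutcome.CORRECT, RjaOutcome.INCORRECT, RjaOutcome.NONE)
    }
    n_req_succ = sum(1 for r in req if r.ija_success)
    n_com_succ = sum(1 for r in com if r.ija_success)

    def rate(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    def lat_stats(rs: list[TrialResult]):
        lats = [r.latency_ms for r in rs if r.latency_ms is not None]
        if not lats:
            return None, None
        return statistics.fmean(lats), statistics.median(lats)

    mean_lat, med_lat = {}, {}
    for name, rs in (("RJA", rja), ("IJA_request", req), ("IJA_comment", com)):
        mean_lat[name], med_lat[name] = lat_stats(rs)

    hist: dict[int, dict[str, int]] = {}
    for rec in transitions:
        hist.setdefault(rec.phase, {}).setdefault(rec.cause.value, 0)
        hist[rec.phase][rec.cause.value] += 1

    return SessionSummary(
        n_scored=len(results),
        rja_n_valid=len(rja),
        rja_counts=rja_counts,
        rja_correct_rate=rate(rja_counts["correct"], len(rja)),
        request_n_valid=len(req),
        request_n_success=n_req_succ,
        request_success_rate=rate(n_req_succ, len(req)),
        comment_n_valid=len(com),
        comment_n_success=n_com_succ,
        comment_success_rate=rate(n_com_succ, len(com)),
        latency_mean_ms=mean_lat,
        latency_median_ms=med_lat,
        cause_histogram=hist,
    )
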