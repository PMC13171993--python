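"""Whole-session orchestration: engine over every trial, then scoring.

Trials play back to back: each trial's attention-getter begins the moment
the previous trial's terminal phase ends, exactly as the battery is
deployed. Overrides are global session events; once one has ended a phase
it cannot end another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .battery import BatterySpec
from .engine import OverrideCommand, TransitionRecord, run_trial
from .fixation import FixationEvent
from .scoring import SessionSummary, TrialResult, score_trial, summarize_session

__all__ = ["SessionRun", "run_session"]


@dataclass
class SessionRun:
    """Engine + scorer output for one session."""

    transitions: dict  # trial_id -> list[TransitionRecord]
    results: list[TrialResult]
    summary: SessionSummary
    t_end: float

    @property
    def all_transitions(self) -> list[tuple[str, TransitionRecord]]:
        return [(tid, r) for tid, recs in self.transitions.items() for r in recs]


def run_session(
    battery: BatterySpec,
    fixations: Sequence[FixationEvent],
    overrides: Sequence[OverrideCommand] = (),
    t0: float = 0.0,
    attention_getter_cap_ms: Optional[float] = None,
    include_greeting_training: bool = True,
) -> SessionRun:
    """Run the contingency engine over the whole battery and score it."""
    remaining = sorted(overrides, key=lambda o: o.t)
    per_trial: dict[str, list[TransitionRecord]] = {}
    results: list[TrialResult] = []
    scored_transitions: list[TransitionRecord] = []
    t = t0
    for trial in battery.trials:
        if not include_greeting_training and not trial.scored:
            continue
        recs = run_trial(
            trial, fixations, remaining, t0=t,
            attention_getter_cap_ms=attention_getter_cap_ms,
        )
        per_trial[trial.trial_id] = recs
        t = recs[-1].t
        remaining = [o for o in remaining if o.t > t]
        res = score_trial(trial, recs, fixations)
        if res is not None:
            results.append(res)
            scored_transitions.extend(recs)
    return SessionRun(
        transitions=per_trial,
        results=results,
        summary=summarize_session(results, scored_transitions),
        t_end=t,
    )
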