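"""Event-driven phase state machine for gaze-contingent stimuli.

A trial is a chain of phases. Contingent phases wait for a gaze trigger —
either a single sufficiently long fixation on a target region, or an
uninterrupted face-to-target gaze alternation — within a timeframe, after
which they time out; non-contingent phases simply play for a fixed duration.
A researcher override can force any phase to advance at any moment.

Every executed phase produces exactly one :class:`TransitionRecord` carrying
the cause of its transition (gaze fixation, gaze alternation, timeout, or
override), so that analysis can keep participant-driven transitions apart
from system- or researcher-driven ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .fixation import FixationEvent, fixation_roi_label
from .geometry import Roi

__all__ = [
    "TriggerKind",
    "TransitionCause",
    "TriggerSpec",
    "PhaseSpec",
    "TransitionRecord",
    "OverrideCommand",
    "UnboundedWaitError",
    "eval_fixation_trigger",
    "eval_alternation_trigger",
    "run_phase",
    "run_trial",
    "trial_elapsed_ms",
]


class TriggerKind(str, enum.Enum):
    FIXATION = "fixation"
    ALTERNATION = "alternation"


class TransitionCause(str, enum.Enum):
    GAZE_FIXATION = "gaze_fixation"
    GAZE_ALTERNATION = "gaze_alternation"
    TIMEOUT = "timeout"
    OVERRIDE = "override"

    @property
    def is_gaze(self) -> bool:
        return self in (TransitionCause.GAZE_FIXATION, TransitionCause.GAZE_ALTERNATION)


class UnboundedWaitError(RuntimeError):
    """A phase with no timeframe received no trigger and no override."""


@dataclass(frozen=True)
class TriggerSpec:
    """What gaze behavior ends a contingent phase.

    ``fixation`` kind: a single fixation of at least ``min_fixation_ms`` on
    ROI ``roi``. ``alternation`` kind: a pair of consecutive fixations
    ``roi_pair = (face_id, target_id)`` with no intervening fixation on any
    other region; ``either_order`` additionally accepts target-then-face.
    """

    kind: TriggerKind
    roi: Optional[str] = None
    roi_pair: Optional[tuple[str, str]] = None
    min_fixation_ms: Optional[float] = None
    either_order: bool = False

    def __post_init__(self) -> None:
        if self.kind is TriggerKind.FIXATION:
            if not self.roi or self.min_fixation_ms is None or self.min_fixation_ms <= 0:
                raise ValueError("fixation trigger requires roi and min_fixation_ms > 0")
        elif self.kind is TriggerKind.ALTERNATION:
            if not self.roi_pair or self.roi_pair[0] == self.roi_pair[1]:
                raise ValueError("alternation trigger requires a pair of distinct ROI ids")


@dataclass(frozen=True)
class PhaseSpec:
    """One phase of a trial's interaction map.

    ``duration_ms`` is the playback duration of a non-contingent phase, or the
    trigger timeframe of a contingent one; ``None`` means unlimited wait,
    which is only legal when ``allow_unbounded`` is set (the attention-getter,
    which has a trigger but no timeframe). ``on_trigger`` / ``on_timeout``
    name the next phase index (None = terminal).
    """

    index: int
    duration_ms: Optional[float]
    trigger: Optional[TriggerSpec] = None
    on_trigger: Optional[int] = None
    on_timeout: Optional[int] = None
    allow_unbounded: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.duration_ms is not None and self.duration_ms <= 0:
            raise ValueError(f"phase {self.index}: duration_ms must be positive")
        if self.duration_ms is None and not self.allow_unbounded:
            raise ValueError(
                f"phase {self.index}: unlimited wait requires allow_unbounded"
            )
        if self.trigger is None and self.duration_ms is None:
            raise ValueError(f"phase {self.index}: neither trigger nor finite duration")

    @property
    def contingent(self) -> bool:
        return self.trigger is not None


@dataclass(frozen=True)
class TransitionRecord:
    """The single transition that ended one executed phase."""

    phase: int
    cause: TransitionCause
    t: float
    latency_ms: float
    scheduled: bool = False
    note: str = ""

    @property
    def onset(self) -> float:
        return self.t - self.latency_ms


@dataclass(frozen=True)
class OverrideCommand:
    """Researcher-issued manual advance at time ``t`` (ms)."""

    t: float
    note: str = ""


def _labeled(fixations: Sequence[FixationEvent], rois: Sequence[Roi]):
    return [(f, fixation_roi_label(f, rois)) for f in fixations]


def eval_fixation_trigger(
    spec: TriggerSpec,
    fixations: Sequence[FixationEvent],
    rois: Sequence[Roi],
    phase_onset: float,
    timeframe_ms: Optional[float] = None,
) -> tuple[bool, Optional[float]]:
    """Earliest time a single fixation on the trigger ROI accumulates its threshold.

    A fixation straddling the phase onset contributes only its within-phase
    portion, so gaze arriving before the phase cannot fire it instantly. The
    trigger fires at ``max(fixation onset, phase onset) + min_fixation_ms``;
    fixations that are too short, or on any other region, never fire.
    """
    assert spec.kind is TriggerKind.FIXATION
    phase_end = None if timeframe_ms is None else phase_onset + timeframe_ms
    for fix, label in _labeled(fixations, rois):
        if label != spec.roi:
            continue
        start = max(fix.onset, phase_onset)
        if fix.offset - start < spec.min_fixation_ms:
            continue
        fire = start + spec.min_fixation_ms
        if phase_end is not None and fire > phase_end:
            continue
        return True, fire
    return False, None


def eval_alternation_trigger(
    spec: TriggerSpec,
    fixations: Sequence[FixationEvent],
    rois: Sequence[Roi],
    phase_onset: float,
    timeframe_ms: Optional[float] = None,
) -> tuple[bool, Optional[float]]:
    """Earliest completion of an uninterrupted face-to-target fixation pair.

    Two-state automaton over the phase's fixation labels: a face fixation
    arms the sequence; an immediately following target fixation fires the
    trigger at that fixation's offset; a re-fixation on the face keeps the
    sequence armed; any fixation on another region (or on no region) resets
    it without ending the phase — the stimulus keeps playing and the
    participant may start over.
    """
    assert spec.kind is TriggerKind.ALTERNATION
    face_id, target_id = spec.roi_pair
    phase_end = None if timeframe_ms is None else phase_onset + timeframe_ms
    armed: Optional[str] = None  # id of the pair ROI last fixated in sequence
    for fix, label in _labeled(fixations, rois):
        if fix.offset <= phase_onset:
            continue
        if phase_end is not None and fix.offset > phase_end:
            break  # pair cannot complete inside the timeframe
        if label == face_id:
            if armed == target_id and spec.either_order:
                return True, fix.offset
            armed = face_id
        elif label == target_id:
            if armed == face_id:
                return True, fix.offset
            armed = target_id if spec.either_order else None
        else:
            armed = None  # deviation resets the sequence
    return False, None


_CAUSE_PRIORITY = {
    TransitionCause.OVERRIDE: 0,
    TransitionCause.GAZE_FIXATION: 1,
    TransitionCause.GAZE_ALTERNATION: 1,
    TransitionCause.TIMEOUT: 2,
}


def run_phase(
    phase: PhaseSpec,
    fixations: Sequence[FixationEvent],
    rois: Sequence[Roi],
    overrides: Sequence[OverrideCommand],
    phase_onset: float,
) -> TransitionRecord:
    """Resolve the single transition ending this phase.

    Candidates are the earliest override at or after the phase onset, the
    gaze trigger's fire time, and the timeout at ``onset + duration_ms``.
    The earliest wins; at identical timestamps the precedence is
    override > gaze > timeout, preserving researcher control and favoring
    participant-driven data at boundaries. A phase with no timeframe that
    receives neither trigger nor override cannot end and raises
    :class:`UnboundedWaitError`.
    """
    candidates: list[tuple[float, int, TransitionCause, bool, str]] = []

    ov = next((o for o in sorted(overrides, key=lambda o: o.t) if o.t >= phase_onset), None)
    end = None if phase.duration_ms is None else phase_onset + phase.duration_ms
    if ov is not None and (end is None or ov.t <= end):
        candidates.append((ov.t, 0, TransitionCause.OVERRIDE, False, ov.note))

    if phase.trigger is not None:
        if phase.trigger.kind is TriggerKind.FIXATION:
            fired, fire_t = eval_fixation_trigger(
                phase.trigger, fixations, rois, phase_onset, phase.duration_ms
            )
            cause = TransitionCause.GAZE_FIXATION
        else:
            fired, fire_t = eval_alternation_trigger(
                phase.trigger, fixations, rois, phase_onset, phase.duration_ms
            )
            cause = TransitionCause.GAZE_ALTERNATION
        if fired:
            candidates.append((fire_t, 1, cause, False, ""))

    if end is not None:
        # non-contingent phases end on schedule; the record keeps the timeout
        # cause but flags it as a scheduled advance
        candidates.append((end, 2, TransitionCause.TIMEOUT, not phase.contingent, ""))

    if not candidates:
        raise UnboundedWaitError(
            f"phase {phase.index} has no timeframe and received no trigger or override"
        )
    t, _, cause, scheduled, note = min(candidates, key=lambda c: (c[0], c[1]))
    return TransitionRecord(
        phase=phase.index,
        cause=cause,
        t=t,
        latency_ms=t - phase_onset,
        scheduled=scheduled,
        note=note,
    )


def run_trial(
    trial,
    fixations: Sequence[FixationEvent],
    overrides: Sequence[OverrideCommand] = (),
    t0: float = 0.0,
    skip_attention_getter: bool = False,
    attention_getter_cap_ms: Optional[float] = None,
) -> list[TransitionRecord]:
    """Execute a trial's phase chain against a fixation stream.

    Walks from the attention-getter (or from phase 1 when
    ``skip_attention_getter`` is set, e.g. for desk runs without a display
    anchor) following ``on_trigger`` / ``on_timeout`` edges until a terminal
    phase; returns one :class:`TransitionRecord` per executed phase.
    Overrides are consumed in time order; each can end at most one phase.
    ``attention_getter_cap_ms`` imposes an optional researcher-set ceiling on
    the otherwise unbounded attention-getter wait.
    """
    from dataclasses import replace

    by_index = {p.index: p for p in trial.phases}
    if attention_getter_cap_ms is not None and 0 in by_index and by_index[0].duration_ms is None:
        by_index[0] = replace(by_index[0], duration_ms=attention_getter_cap_ms)
    start = 1 if skip_attention_getter else trial.phases[0].index
    remaining = sorted(overrides, key=lambda o: o.t)

    records: list[TransitionRecord] = []
    onset = t0
    idx: Optional[int] = start
    while idx is not None:
        phase = by_index[idx]
        rec = run_phase(phase, fixations, trial.rois, remaining, onset)
        records.append(rec)
        if rec.cause is TransitionCause.OVERRIDE:
            remaining = [o for o in remaining if o.t > rec.t]
        if rec.cause is TransitionCause.TIMEOUT:
            idx = phase.on_timeout
        else:
            idx = phase.on_trigger
        onset = rec.t
    return records


def trial_elapsed_ms(
    records: Sequence[TransitionRecord], exclude_attention_getter: bool = True
) -> float:
    """Total elapsed time of an executed trial, optionally excluding phase 0."""
    if not records:
        return 0.0
    kept = [r for r in records if not (exclude_attention_getter and r.phase == 0)]
    return sum(r.latency_ms for r in kept)
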