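"""Declarative construction of trials and the full counterbalanced battery.

The battery probes two joint-attention constructs in children: responding to
joint attention (RJA — following an actress's gaze-shift or head-turn cue to
one of two tabletop objects) and initiating joint attention (IJA — directing
her attention by alternating gaze between her face and a tablet, to request
a video, or a suddenly appearing moving object, to comment on it).

32 scored stimuli: 16 RJA (2 cues x 2 directions x 4 object pairs), 8
IJA-Request (4 video pairs x 2 directions), and 8 IJA-Comment/Reference
(4 moving objects x 2 directions), organized into four blocks of eight
(4 RJA + 2 Request + 2 Comment each), directions balanced within every task,
preceded by a greeting (10 s) and a training trial (max 52 s).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import PhaseSpec, TriggerKind, TriggerSpec
from .geometry import Roi, RoiRole, ScreenGeometry, validate_rois

__all__ = [
    "Task",
    "Cue",
    "Direction",
    "TrialSpec",
    "BatterySpec",
    "BatteryValidationError",
    "make_trial",
    "build_battery",
    "battery_max_duration",
    "trial_max_duration",
    "validate_battery",
    "OBJECT_PAIRS",
    "VIDEO_PAIRS",
    "COMMENT_OBJECTS",
]

# --- behavioral thresholds and phase durations (ms) -------------------------
ATTENTION_GETTER_FIXATION_MS = 100.0  # single fixation to start a stimulus
FACE_FIXATION_MS = 200.0              # single fixation on the Face ROI, phase 1
PHASE1_TIMEFRAME_MS = 4_000.0         # wait for initial attention
DIRECT_GAZE_MS = 1_500.0              # actress looks up / offers ("Yes?")
RJA_CUE_MS = 4_000.0                  # referential cue window
ALTERNATION_TIMEFRAME_MS = 7_000.0    # wait for the IJA gaze alternation
REQUEST_RESPONSE_MS = 3_500.0         # "Sure, I can play it for you!" + gesture
REQUEST_VIDEO_MS = 10_000.0           # requested video plays
COMMENT_RESPONSE_MS = 3_000.0         # "Oh!" + head turn to the object
GREETING_MS = 10_000.0
TRAINING_DEMO_MS = 26_000.0           # actress demonstrates both tablets
TRAINING_CAP_MS = 52_000.0

OBJECT_PAIRS = ("cups", "sunglasses", "hats", "balls")
VIDEO_PAIRS = ("videos_1", "videos_2", "videos_3", "videos_4")
COMMENT_OBJECTS = ("spider", "parrot", "swinging_ball", "snake")

ATTENTION_GETTER_SIZE_PX = 200.0
ATTENTION_GETTER_INSET_FRAC = 0.15  # corner inset, mitigates screen-edge effects


class Task(str, enum.Enum):
    GREETING = "greeting"
    TRAINING = "training"
    RJA = "RJA"
    IJA_REQUEST = "IJA_request"
    IJA_COMMENT = "IJA_comment"


class Cue(str, enum.Enum):
    GAZE_SHIFT = "gaze_shift"
    HEAD_TURN = "head_turn"


class Direction(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class BatteryValidationError(ValueError):
    """A trial or battery violates a structural invariant."""


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus: its phase chain, interaction ROIs, and design cell."""

    trial_id: str
    task: Task
    cue: Optional[Cue]
    direction: Optional[Direction]
    stimulus_set: Optional[str]
    phases: tuple[PhaseSpec, ...]
    rois: tuple[Roi, ...]
    block: Optional[int] = None  # 0-based block index; None for greeting/training

    @property
    def scored(self) -> bool:
        return self.task in (Task.RJA, Task.IJA_REQUEST, Task.IJA_COMMENT)


@dataclass(frozen=True)
class BatterySpec:
    """Full ordered battery: greeting, training, then four blocks of eight."""

    trials: tuple[TrialSpec, ...]
    seed: int

    @property
    def scored_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.scored)

    @property
    def blocks(self) -> list[list[TrialSpec]]:
        nblocks = 1 + max((t.block for t in self.scored_trials), default=-1)
        out: list[list[TrialSpec]] = [[] for _ in range(nblocks)]
        for t in self.scored_trials:
            out[t.block].append(t)
        return out


# --- ROI template (1920x1080 recording geometry) ----------------------------

def _scaled(rect: tuple[float, float, float, float], screen: ScreenGeometry):
    sx, sy = screen.width / 1920.0, screen.height / 1080.0
    x0, y0, x1, y1 = rect
    return (x0 * sx, y0 * sy, x1 * sx, y1 * sy)


def default_rois(
    task: Task, direction: Optional[Direction], screen: ScreenGeometry
) -> tuple[Roi, ...]:
    """ROI template per task; the actual deployment would trace video frames."""
    rois: list[Roi] = []
    if direction is not None:
        frac = ATTENTION_GETTER_INSET_FRAC
        cx = screen.width * (frac if direction is Direction.LEFT else 1 - frac)
        cy = screen.height * frac
        h = ATTENTION_GETTER_SIZE_PX / 2.0
        rois.append(
            Roi("AttentionGetter", RoiRole.ATTENTION_GETTER, (cx - h, cy - h, cx + h, cy + h))
        )
    rois.append(Roi("Face", RoiRole.FACE, _scaled((810, 150, 1110, 450), screen)))
    if task is Task.RJA:
        rois.append(Roi("TargetLeft", RoiRole.TARGET_LEFT, _scaled((200, 700, 560, 1000), screen)))
        rois.append(Roi("TargetRight", RoiRole.TARGET_RIGHT, _scaled((1360, 700, 1720, 1000), screen)))
    elif task in (Task.IJA_REQUEST, Task.TRAINING):
        rois.append(Roi("TabletLeft", RoiRole.TABLET_LEFT, _scaled((150, 500, 650, 850), screen)))
        rois.append(Roi("TabletRight", RoiRole.TABLET_RIGHT, _scaled((1270, 500, 1770, 850), screen)))
    elif task is Task.IJA_COMMENT:
        if direction is Direction.LEFT:
            rois.append(Roi("ObjectLeft", RoiRole.OBJECT_LEFT, _scaled((420, 60, 720, 360), screen)))
        else:
            rois.append(Roi("ObjectRight", RoiRole.OBJECT_RIGHT, _scaled((1200, 60, 1500, 360), screen)))
    return tuple(validate_rois(rois, screen))


# --- phase-chain builders ---------------------------------------------------

def _attention_getter_phase() -> PhaseSpec:
    return PhaseSpec(
        index=0,
        duration_ms=None,
        trigger=TriggerSpec(
            kind=TriggerKind.FIXATION,
            roi="AttentionGetter",
            min_fixation_ms=ATTENTION_GETTER_FIXATION_MS,
        ),
        on_trigger=1,
        on_timeout=1,  # reachable only when a researcher-set cap is imposed
        allow_unbounded=True,
        label="attention_getter",
    )


def _face_phase(index: int, nxt: int) -> PhaseSpec:
    return PhaseSpec(
        index=index,
        duration_ms=PHASE1_TIMEFRAME_MS,
        trigger=TriggerSpec(
            kind=TriggerKind.FIXATION, roi="Face", min_fixation_ms=FACE_FIXATION_MS
        ),
        on_trigger=nxt,
        on_timeout=nxt,
        label="initial_attention",
    )


def _alternation_phase(index: int, nxt: Optional[int], target_roi: str) -> PhaseSpec:
    return PhaseSpec(
        index=index,
        duration_ms=ALTERNATION_TIMEFRAME_MS,
        trigger=TriggerSpec(
            kind=TriggerKind.ALTERNATION, roi_pair=("Face", target_roi)
        ),
        on_trigger=nxt,
        on_timeout=nxt,
        label="gaze_alternation",
    )


def _fixed(index: int, duration: float, nxt: Optional[int], label: str) -> PhaseSpec:
    return PhaseSpec(index=index, duration_ms=duration, on_timeout=nxt, label=label)


def _side_roi(prefix: str, direction: Direction) -> str:
    return prefix + ("Left" if direction is Direction.LEFT else "Right")


def make_trial(
    task: Task,
    cue: Optional[Cue] = None,
    direction: Optional[Direction] = None,
    stimulus_set: Optional[str] = None,
    screen: Optional[ScreenGeometry] = None,
    trial_id: Optional[str] = None,
    block: Optional[int] = None,
) -> TrialSpec:
    """Build one trial's phase chain and ROI set for its design cell.

    Raises :class:`BatteryValidationError` for invalid combinations (a cue is
    only meaningful for RJA; scored tasks need a direction).
    """
    task = Task(task)
    if cue is not None and task is not Task.RJA:
        raise BatteryValidationError(f"cue is only valid for RJA trials, not {task.value}")
    if task is Task.RJA and (cue is None or direction is None):
        raise BatteryValidationError("RJA trials require both a cue and a direction")
    if task in (Task.IJA_REQUEST, Task.IJA_COMMENT) and direction is None:
        raise BatteryValidationError(f"{task.value} trials require a direction")
    screen = screen or ScreenGeometry()

    if task is Task.GREETING:
        phases = (_fixed(1, GREETING_MS, None, "greeting"),)
        rois = (default_rois(task, None, screen))
    elif task is Task.TRAINING:
        direction = direction or Direction.LEFT
        phases = (
            _attention_getter_phase(),
            _fixed(1, TRAINING_DEMO_MS, 2, "tablet_demo"),
            _face_phase(2, 3),
            _fixed(3, DIRECT_GAZE_MS, 4, "offer"),
            _alternation_phase(4, 5, _side_roi("Tablet", direction)),
            _fixed(5, REQUEST_RESPONSE_MS, 6, "response"),
            _fixed(6, REQUEST_VIDEO_MS, None, "video"),
        )
        rois = default_rois(task, direction, screen)
    elif task is Task.RJA:
        phases = (
            _attention_getter_phase(),
            _face_phase(1, 2),
            _fixed(2, DIRECT_GAZE_MS, 3, "direct_gaze"),
            _fixed(3, RJA_CUE_MS, None, "referential_cue"),
        )
        rois = default_rois(task, direction, screen)
    elif task is Task.IJA_REQUEST:
        phases = (
            _attention_getter_phase(),
            _face_phase(1, 2),
            _fixed(2, DIRECT_GAZE_MS, 3, "offer"),
            _alternation_phase(3, 4, _side_roi("Tablet", direction)),
            _fixed(4, REQUEST_RESPONSE_MS, 5, "response"),
            _fixed(5, REQUEST_VIDEO_MS, None, "video"),
        )
        rois = default_rois(task, direction, screen)
    else:  # IJA_COMMENT
        phases = (
            _attention_getter_phase(),
            _face_phase(1, 2),
            _alternation_phase(2, 3, _side_roi("Object", direction)),
            _fixed(3, COMMENT_RESPONSE_MS, None, "response"),
        )
        rois = default_rois(task, direction, screen)

    if trial_id is None:
        bits = [task.value]
        if cue:
            bits.append(cue.value)
        if direction:
            bits.append(direction.value)
        if stimulus_set:
            bits.append(stimulus_set)
        trial_id = "-".join(bits)
    return TrialSpec(
        trial_id=trial_id,
        task=task,
        cue=cue,
        direction=direction,
        stimulus_set=stimulus_set,
        phases=phases,
        rois=rois,
        block=block,
    )


def trial_max_duration(trial: TrialSpec, include_attention_getter: bool = False) -> float:
    """Maximum trial duration in ms: sum of finite phase timeframes/durations.

    The attention-getter has no timeframe and is excluded (it contributes no
    bounded time); the flag exists for symmetry and is a no-op for phase 0.
    """
    total = 0.0
    for p in trial.phases:
        if p.index == 0 and not include_attention_getter:
            continue
        if p.duration_ms is not None:
            total += p.duration_ms
    return total


def _interleave(
    trials: list[TrialSpec], rng: np.random.Generator, prev_tasks: tuple = ()
) -> list[TrialSpec]:
    """Seeded shuffle forbidding three consecutive same-task trials, also
    across the boundary with the preceding block (``prev_tasks`` = its tail)."""
    order = list(trials)
    for _ in range(1000):
        rng.shuffle(order)
        tasks = list(prev_tasks[-2:]) + [t.task for t in order]
        ok = all(
            not (tasks[i] == tasks[i + 1] == tasks[i + 2])
            for i in range(len(tasks) - 2)
        )
        if ok:
            return order
    raise RuntimeError("could not find an interleaved order")  # pragma: no cover


def build_battery(seed: int = 0, screen: Optional[ScreenGeometry] = None) -> BatterySpec:
    """Construct the full 32-trial battery for a seed.

    The seed permutes which stimulus set lands in which block and the
    interleaved within-block order; the trial multiset (the counterbalancing
    design) is identical for every seed. Greeting and training precede block 1.
    """
    screen = screen or ScreenGeometry()
    rng = np.random.default_rng(seed)

    combos = [(c, d) for c in Cue for d in Direction]
    rng.shuffle(combos)
    obj_pairs = list(OBJECT_PAIRS)
    rng.shuffle(obj_pairs)
    video_pairs = list(VIDEO_PAIRS)
    rng.shuffle(video_pairs)
    comment_objects = list(COMMENT_OBJECTS)
    rng.shuffle(comment_objects)

    scored: list[TrialSpec] = []
    counter = itertools.count(1)
    for b in range(4):
        block: list[TrialSpec] = []
        # RJA: one trial per cue x direction cell; object pairs rotate across
        # blocks in a Latin square so each pair appears once per block and
        # once per cell overall
        for i, (c, d) in enumerate(combos):
            block.append(
                make_trial(Task.RJA, c, d, obj_pairs[(i + b) % 4], screen, block=b)
            )
        # IJA: each stimulus set appears twice (once per direction) in
        # adjacent blocks; every block gets one left and one right trial
        block.append(
            make_trial(Task.IJA_REQUEST, None, Direction.LEFT, video_pairs[b], screen, block=b)
        )
        block.append(
            make_trial(
                Task.IJA_REQUEST, None, Direction.RIGHT, video_pairs[(b + 1) % 4], screen, block=b
            )
        )
        block.append(
            make_trial(Task.IJA_COMMENT, None, Direction.LEFT, comment_objects[b], screen, block=b)
        )
        block.append(
            make_trial(
                Task.IJA_COMMENT, None, Direction.RIGHT, comment_objects[(b + 1) % 4],
                screen, block=b,
            )
        )
        for t in _interleave(block, rng, tuple(t.task for t in scored[-2:])):
            n = next(counter)
            scored.append(
                TrialSpec(
                    trial_id=f"T{n:02d}-{t.trial_id}",
                    task=t.task, cue=t.cue, direction=t.direction,
                    stimulus_set=t.stimulus_set, phases=t.phases, rois=t.rois,
                    block=t.block,
                )
            )

    greeting = make_trial(Task.GREETING, screen=screen, trial_id="greeting")
    training = make_trial(Task.TRAINING, screen=screen, trial_id="training")
    return BatterySpec(trials=(greeting, training, *scored), seed=seed)


def battery_max_duration(
    battery: BatterySpec,
    include_greeting_training: bool = False,
    include_attention_getter: bool = False,
) -> float:
    """Maximum battery duration in ms (scored trials; flags widen the scope)."""
    trials = [t for t in battery.trials if t.scored or include_greeting_training]
    return sum(trial_max_duration(t, include_attention_getter) for t in trials)


def validate_battery(battery: BatterySpec) -> dict:
    """Check every composition invariant; return the composition summary.

    Raises :class:`BatteryValidationError` naming the first violated invariant.
    """
    scored = battery.scored_trials

    def fail(msg: str):
        raise BatteryValidationError(msg)

    ids = [t.trial_id for t in battery.trials]
    if len(set(ids)) != len(ids):
        fail("duplicate trial ids")
    counts = {task: sum(t.task is task for t in scored) for task in Task}
    if counts[Task.RJA] != 16 or counts[Task.IJA_REQUEST] != 8 or counts[Task.IJA_COMMENT] != 8:
        fail(f"scored composition must be 16/8/8 RJA/Request/Comment, got {counts}")
    blocks = battery.blocks
    if len(blocks) != 4:
        fail(f"expected 4 blocks, got {len(blocks)}")
    for b, blk in enumerate(blocks):
        hist = {task: sum(t.task is task for t in blk) for task in Task}
        if (hist[Task.RJA], hist[Task.IJA_REQUEST], hist[Task.IJA_COMMENT]) != (4, 2, 2):
            fail(f"block {b + 1} composition must be 4/2/2, got {hist}")
    for task in (Task.RJA, Task.IJA_REQUEST, Task.IJA_COMMENT):
        lefts = sum(1 for t in scored if t.task is task and t.direction is Direction.LEFT)
        rights = sum(1 for t in scored if t.task is task and t.direction is Direction.RIGHT)
        if lefts != rights:
            fail(f"{task.value}: direction imbalance {lefts}L/{rights}R")
    for cue in Cue:
        for d in Direction:
            cell = sum(1 for t in scored if t.task is Task.RJA and t.cue is cue and t.direction is d)
            if cell != 4:
                fail(f"RJA cell {cue.value}x{d.value} must have 4 trials, got {cell}")
    for pair, expect, task in (
        (OBJECT_PAIRS, 4, Task.RJA),
        (VIDEO_PAIRS, 2, Task.IJA_REQUEST),
        (COMMENT_OBJECTS, 2, Task.IJA_COMMENT),
    ):
        for s in pair:
            n = sum(1 for t in scored if t.task is task and t.stimulus_set == s)
            if n != expect:
                fail(f"{task.value} stimulus set {s!r} must appear {expect}x, got {n}")
    for t in scored:
        durations = tuple(p.duration_ms for p in t.phases if p.index > 0)
        expected = {
            Task.RJA: (4_000.0, 1_500.0, 4_000.0),
            Task.IJA_REQUEST: (4_000.0, 1_500.0, 7_000.0, 3_500.0, 10_000.0),
            Task.IJA_COMMENT: (4_000.0, 7_000.0, 3_000.0),
        }[t.task]
        if durations != expected:
            fail(f"trial {t.trial_id}: phase durations {durations} != {expected}")
    return {
        "n_scored": len(scored),
        "by_task": {k.value: v for k, v in counts.items() if v},
        "blocks": [[t.trial_id for t in blk] for blk in blocks],
        "max_duration_ms": battery_max_duration(battery),
    }
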