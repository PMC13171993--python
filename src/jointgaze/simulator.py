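"""Synthetic gaze-stream generation from a parameterized participant model.

The simulator co-simulates a participant against the battery's contingency
structure: the simulated viewer reacts to phase changes, fixating the
attention-getter, the actress's face, and the cued or requested targets with
per-construct compliance probabilities and lognormal response latencies.
Non-compliance is modeled as wandering fixations over neutral screen
locations, so timeouts arise from behavior rather than missing data; track
loss is a separate dropout knob applied at the raw-sample level.

Output comes in two forms sharing one ground truth: an intended
fixation-event stream (consumed directly by the engine's fixation-table
input mode) and a rasterized raw sample stream at the model's sampling rate
with landing-error jitter, per-sample tremor, and dropout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .battery import BatterySpec, Task, TrialSpec
from .engine import TransitionCause, TriggerKind
from .fixation import FixationEvent, GazeSample
from .geometry import Roi, ScreenGeometry

__all__ = [
    "ParticipantModel",
    "TrialGroundTruth",
    "SimulatedSession",
    "simulate_session",
    "scripted_stream",
]

SACCADE_MS = 30.0  # nominal saccade transit between scripted fixations


@dataclass(frozen=True)
class ParticipantModel:
    """Behavioral parameters of the simulated participant.

    Compliance probabilities are per construct phase: ``p_initiate`` for the
    initial 200 ms face fixation, ``p_rja`` for correct gaze-following at the
    cue, ``p_request`` / ``p_comment`` for producing the gaze alternation.
    Response latencies are lognormal with the given mean and SD (ms),
    truncated to fit the phase timeframe. ``jitter_px`` is the SD of the
    per-fixation landing error; ``tremor_px`` the SD of per-sample positional
    noise; ``dropout_rate`` the per-sample probability of invalid data.
    """

    p_initiate: float = 0.95
    p_rja: float = 0.8
    p_request: float = 0.8
    p_comment: float = 0.8
    latency_mean_ms: float = 800.0
    latency_sd_ms: float = 400.0
    jitter_px: float = 10.0
    tremor_px: float = 1.5
    dropout_rate: float = 0.02
    sampling_hz: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_initiate", "p_rja", "p_request", "p_comment"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.jitter_px < 0 or self.tremor_px < 0:
            raise ValueError("spatial noise parameters must be non-negative")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.latency_mean_ms <= 0 or self.latency_sd_ms < 0:
            raise ValueError("latency parameters must be positive")


@dataclass
class TrialGroundTruth:
    """The simulated participant's intended behavior for one trial."""

    trial_id: str
    task: Task
    direction: Optional[str]
    t_start: float
    t_end: float
    complied: dict = field(default_factory=dict)          # phase -> bool
    intended_latency_ms: dict = field(default_factory=dict)  # phase -> ms
    intended_cause: dict = field(default_factory=dict)    # phase -> TransitionCause
    rja_intended: Optional[str] = None                    # correct|incorrect|none


@dataclass
class SimulatedSession:
    """A simulated session: intended fixations, optional raw stream, truth."""

    fixations: list[FixationEvent]
    samples: Optional[list[GazeSample]]
    ground_truth: list[TrialGroundTruth]
    t_end: float


class _Events:
    """Time-ordered (onset, dur, x, y) fixation intents; merges contiguous
    same-position events so a held gaze is one fixation."""

    def __init__(self) -> None:
        self.items: list[list[float]] = []

    def add(self, onset: float, dur: float, x: float, y: float) -> None:
        if dur <= 0:
            return
        if self.items:
            last = self.items[-1]
            if last[0] + last[1] > onset + 1e-9:
                raise ValueError("overlapping gaze events")
            if abs(last[2] - x) < 1e-9 and abs(last[3] - y) < 1e-9 and onset - (last[0] + last[1]) < 1.0:
                last[1] = onset + dur - last[0]
                return
        self.items.append([onset, dur, x, y])

    def to_fixations(self) -> list[FixationEvent]:
        return [FixationEvent(o, o + d, x, y) for o, d, x, y in self.items]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


class _Participant:
    def __init__(self, model: ParticipantModel, screen: ScreenGeometry, rng: np.random.Generator):
        self.model = model
        self.screen = screen
        self.rng = rng
        self._mu, self._sigma = _lognormal_params(model.latency_mean_ms, model.latency_sd_ms)
        self._last_wander: Optional[tuple[float, float]] = None

    def latency(self, lo: float, hi: float) -> float:
        """Lognormal response latency truncated to [lo, hi]."""
        for _ in range(100):
            d = float(self.rng.lognormal(self._mu, self._sigma))
            if lo <= d <= hi:
                return d
        return float(np.clip(self.rng.uniform(lo, hi), lo, hi))

    def bern(self, p: float) -> bool:
        return bool(self.rng.random() < p)

    def land(self, roi: Roi) -> tuple[float, float]:
        """Fixation landing point: ROI center plus jitter, kept inside the ROI."""
        cx, cy = roi.center
        x = cx + self.rng.normal(0.0, self.model.jitter_px)
        y = cy + self.rng.normal(0.0, self.model.jitter_px)
        x0, y0, x1, y1 = roi.rect
        return float(np.clip(x, x0 + 10, x1 - 10)), float(np.clip(y, y0 + 10, y1 - 10))

    def wander_point(self, rois: Sequence[Roi]) -> tuple[float, float]:
        """A neutral location: off every ROI (with margin), away from the last."""
        margin = 80.0
        for _ in range(200):
            x = self.rng.uniform(margin, self.screen.width - margin)
            y = self.rng.uniform(margin, self.screen.height - margin)
            if any(
                (r.rect[0] - margin <= x < r.rect[2] + margin)
                and (r.rect[1] - margin <= y < r.rect[3] + margin)
                for r in rois
            ):
                continue
            if self._last_wander is not None:
                lx, ly = self._last_wander
                if abs(x - lx) + abs(y - ly) < 150.0:
                    continue
            self._last_wander = (x, y)
            return float(x), float(y)
        return 100.0, float(self.screen.height - 100)  # pragma: no cover

    def wander(self, events: _Events, t0: float, t1: float, rois: Sequence[Roi]) -> None:
        """Fill [t0, t1) with off-ROI fixations of ~300 ms."""
        t = t0
        while t1 - t >= 80.0:
            dur = min(float(self.rng.uniform(220, 380)), t1 - t - SACCADE_MS)
            if dur < 80.0:
                break
            x, y = self.wander_point(rois)
            events.add(t, dur, x, y)
            t += dur + SACCADE_MS


def _roi(trial: TrialSpec, roi_id: str) -> Roi:
    for r in trial.rois:
        if r.id == roi_id:
            return r
    raise KeyError(f"trial {trial.trial_id} has no ROI {roi_id!r}")


def _simulate_trial(
    trial: TrialSpec, p: _Participant, t0: float, events: _Events
) -> TrialGroundTruth:
    """Walk the trial's phase chain, emitting the participant's gaze intents."""
    m = p.model
    gt = TrialGroundTruth(
        trial_id=trial.trial_id,
        task=trial.task,
        direction=trial.direction.value if trial.direction else None,
        t_start=t0,
        t_end=t0,
    )
    by_index = {ph.index: ph for ph in trial.phases}
    idx: Optional[int] = trial.phases[0].index
    t = t0
    cursor = t0  # time up to which gaze events have been emitted
    engaged = False  # did the initial face fixation succeed?

    while idx is not None:
        phase = by_index[idx]
        onset = t
        cause = TransitionCause.TIMEOUT
        if phase.trigger is not None and phase.trigger.kind is TriggerKind.FIXATION:
            roi = _roi(trial, phase.trigger.roi)
            need = phase.trigger.min_fixation_ms
            hold = need + 100.0
            if phase.index == 0:
                comply, cap = True, 2_500.0
            else:
                comply = p.bern(m.p_initiate)
                cap = (phase.duration_ms or 4_000.0) - hold - 20.0
            if comply:
                lat = p.latency(50.0, max(60.0, cap))
                fix_on = max(onset + lat, cursor)
                x, y = p.land(roi)
                p.wander(events, cursor, fix_on, trial.rois)
                events.add(fix_on, hold, x, y)
                cursor = fix_on + hold
                t = fix_on + need
                cause = TransitionCause.GAZE_FIXATION
                gt.intended_latency_ms[phase.index] = t - onset
                if phase.index != 0:
                    engaged = True
            else:
                t = onset + phase.duration_ms
                p.wander(events, cursor, t, trial.rois)
                cursor = t
            gt.complied[phase.index] = comply
        elif phase.trigger is not None:  # alternation
            face = _roi(trial, phase.trigger.roi_pair[0])
            target = _roi(trial, phase.trigger.roi_pair[1])
            pp = m.p_comment if trial.task is Task.IJA_COMMENT else m.p_request
            comply = p.bern(pp)
            tf = phase.duration_ms
            if comply:
                # pair: face 250 ms, 30 ms saccade, target 250 ms; the trigger
                # fires at the target fixation's offset
                lat = p.latency(620.0, tf - 100.0)
                start = max(onset + lat - 530.0, cursor)
                fx, fy = p.land(face)
                tx, ty = p.land(target)
                p.wander(events, cursor, start, trial.rois)
                events.add(start, 250.0, fx, fy)
                events.add(start + 280.0, 250.0, tx, ty)
                cursor = start + 530.0
                t = cursor
                cause = TransitionCause.GAZE_ALTERNATION
                gt.intended_latency_ms[phase.index] = t - onset
            else:
                t = onset + tf
                p.wander(events, cursor, t, trial.rois)
                cursor = t
            gt.complied[phase.index] = comply
        else:
            # non-contingent playback; behavior depends on what is on screen
            t = onset + phase.duration_ms
            if trial.task is Task.RJA and phase.index == 3:
                _rja_cue_behavior(trial, p, events, onset, t, engaged, gt)
            elif phase.label == "video":
                tab = _roi(trial, "TabletLeft" if trial.direction.value == "left" else "TabletRight")
                x, y = p.land(tab)
                events.add(max(onset, cursor), t - max(onset, cursor), x, y)
            elif engaged or phase.label in ("greeting", "tablet_demo", "direct_gaze", "offer", "response"):
                face = next((r for r in trial.rois if r.id == "Face"), None)
                if face is not None:
                    x, y = p.land(face)
                    events.add(max(onset, cursor), t - max(onset, cursor), x, y)
            else:
                p.wander(events, cursor, t, trial.rois)
            cursor = max(cursor, t)
        gt.intended_cause[phase.index] = cause
        idx = phase.on_trigger if cause is not TransitionCause.TIMEOUT else phase.on_timeout
    gt.t_end = t
    return gt


def _rja_cue_behavior(
    trial: TrialSpec,
    p: _Participant,
    events: _Events,
    cue_onset: float,
    end: float,
    engaged: bool,
    gt: TrialGroundTruth,
) -> None:
    """Gaze-following (or not) during the referential-cue window."""
    m = p.model
    if not engaged:
        p.wander(events, cue_onset, end, trial.rois)
        gt.rja_intended = "none"
        return
    face = _roi(trial, "Face")
    fx, fy = p.land(face)
    cued = "TargetLeft" if trial.direction.value == "left" else "TargetRight"
    other = "TargetRight" if trial.direction.value == "left" else "TargetLeft"
    if p.bern(m.p_rja):
        dest, intended = cued, "correct"
    elif p.bern(0.5):
        dest, intended = other, "incorrect"
    else:
        dest, intended = None, "none"
    if dest is None:
        events.add(cue_onset, end - cue_onset, fx, fy)  # stays on the face
    else:
        lat = p.latency(120.0, max(150.0, end - cue_onset - 450.0))
        events.add(cue_onset, lat, fx, fy)
        x, y = p.land(_roi(trial, dest))
        events.add(cue_onset + lat + SACCADE_MS, end - (cue_onset + lat + SACCADE_MS), x, y)
        gt.intended_latency_ms[3] = lat + SACCADE_MS
    gt.rja_intended = intended


def _rasterize(
    items: Sequence[Sequence[float]],
    sampling_hz: float,
    t_end: float,
    rng: Optional[np.random.Generator] = None,
    tremor_px: float = 0.0,
    dropout_rate: float = 0.0,
) -> list[GazeSample]:
    """Sample the piecewise-stationary gaze path on a uniform clock.

    Position is held during events and moves linearly across the gap between
    consecutive events (the saccade). Samples before the first event or at or
    after the last event's end are emitted as invalid, preserving the clock.
    """
    period = 1000.0 / sampling_hz
    ts = np.arange(0.0, t_end, period)
    if not items or len(ts) == 0:
        return [GazeSample(float(t), 0.0, 0.0, False) for t in ts]
    knots_t, knots_x, knots_y = [], [], []
    eps = 1e-6
    for onset, dur, x, y in items:
        knots_t.extend([onset, onset + dur - eps])
        knots_x.extend([x, x])
        knots_y.extend([y, y])
    xs = np.interp(ts, knots_t, knots_x)
    ys = np.interp(ts, knots_t, knots_y)
    valid = (ts >= items[0][0]) & (ts < items[-1][0] + items[-1][1])
    if rng is not None and dropout_rate > 0:
        valid &= rng.random(len(ts)) >= dropout_rate
    if rng is not None and tremor_px > 0:
        xs = xs + rng.normal(0.0, tremor_px, len(ts))
        ys = ys + rng.normal(0.0, tremor_px, len(ts))
    return [
        GazeSample(float(t), float(x), float(y), bool(v))
        for t, x, y, v in zip(ts, xs, ys, valid)
    ]


def simulate_session(
    battery: BatterySpec,
    model: Optional[ParticipantModel] = None,
    rasterize: bool = True,
    include_greeting_training: bool = True,
    screen: Optional[ScreenGeometry] = None,
) -> SimulatedSession:
    """Simulate one participant playing the whole battery.

    Returns the intended fixation stream, the (optional) rasterized raw
    sample stream, and per-trial ground truth. Identical (battery, model)
    inputs produce identical output: all randomness flows from ``model.seed``.
    """
    model = model or ParticipantModel()
    screen = screen or ScreenGeometry()
    rng = np.random.default_rng(model.seed)
    p = _Participant(model, screen, rng)
    events = _Events()
    truths: list[TrialGroundTruth] = []
    t = 0.0
    for trial in battery.trials:
        if not include_greeting_training and not trial.scored:
            continue
        gt = _simulate_trial(trial, p, t, events)
        truths.append(gt)
        t = gt.t_end
    samples = None
    if rasterize:
        samples = _rasterize(
            events.items, model.sampling_hz, t + 200.0, rng,
            model.tremor_px, model.dropout_rate,
        )
    return SimulatedSession(
        fixations=events.to_fixations(), samples=samples, ground_truth=truths, t_end=t
    )


def scripted_stream(
    events: Sequence[tuple[str, float, float]],
    rois: Sequence[Roi],
    sampling_hz: float = 300.0,
) -> list[GazeSample]:
    """Deterministic zero-noise stream fixating ROI centers.

    ``events`` are ``(roi_id, onset_ms, duration_ms)`` tuples, time-sorted
    and non-overlapping; leave ~30 ms between events for the saccade. The
    returned stream is sampled on a uniform clock from 0 to the last event's
    end.
    """
    by_id = {r.id: r for r in rois}
    items: list[list[float]] = []
    last_end = -math.inf
    for roi_id, onset, dur in events:
        if dur <= 0:
            raise ValueError(f"event on {roi_id!r} has non-positive duration")
        if onset < last_end:
            raise ValueError(f"event on {roi_id!r} at {onset} overlaps the previous event")
        cx, cy = by_id[roi_id].center
        items.append([onset, dur, cx, cy])
        last_end = onset + dur
    if not items:
        return []
    return _rasterize(items, sampling_hz, t_end=last_end)
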