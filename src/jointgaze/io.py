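"""Text-first readers/writers and the session pipeline.

Every artifact is a diff-able plain-text file: gaze samples and fixation
events as CSV, transition logs as JSON lines, battery and participant-model
configuration as YAML, results as CSV, summaries and run manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .battery import (
    BatterySpec,
    Cue,
    Direction,
    Task,
    TrialSpec,
    build_battery,
    make_trial,
    validate_battery,
)
from .engine import OverrideCommand, TransitionCause, TransitionRecord
from .fixation import FixationDetectorParams, FixationEvent, GazeSample, SequencingError, detect_fixations
from .geometry import ScreenGeometry
from .scoring import TrialResult
from .session import SessionRun, run_session
from .simulator import ParticipantModel

__all__ = [
    "GazeStreamParseError",
    "read_gaze_stream",
    "write_gaze_stream",
    "read_fixations",
    "write_fixations",
    "read_overrides",
    "write_overrides",
    "write_transitions",
    "read_transitions",
    "results_to_frame",
    "write_results",
    "summary_to_dict",
    "write_summary",
    "battery_to_config",
    "battery_from_config",
    "save_battery_config",
    "load_battery_config",
    "model_to_config",
    "model_from_config",
    "SessionBundle",
    "run_pipeline",
]

PathLike = Union[str, Path]


class GazeStreamParseError(ValueError):
    """A delimited gaze/fixation/override file failed schema validation."""


# --- gaze samples ------------------------------------------------------------

GAZE_COLUMNS = ["t_ms", "x_px", "y_px", "valid"]


def read_gaze_stream(path: PathLike) -> list[GazeSample]:
    """Read a ``t_ms,x_px,y_px,valid`` CSV into time-sorted gaze samples.

    Unknown columns are ignored with a warning; malformed rows and
    non-monotonic timestamps are rejected with the offending line number
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise GazeStreamParseError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in GAZE_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)

    t = pd.to_numeric(df["t_ms"], errors="coerce")
    x = pd.to_numeric(df["x_px"], errors="coerce")
    y = pd.to_numeric(df["y_px"], errors="coerce")
    v = df["valid"].map(_parse_bool)
    for name, col in (("t_ms", t), ("valid", v)):
        bad = col.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise GazeStreamParseError(f"{path}: malformed {name} at line {line}")
    nonmono = t.diff() <= 0
    if nonmono.any():
        line = int(nonmono.idxmax()) + 2
        raise SequencingError(f"{path}: non-increasing t_ms at line {line}")
    badpos = (x.isna() | y.isna()) & v.astype(bool)
    if badpos.any():
        line = int(badpos.idxmax()) + 2
        raise GazeStreamParseError(f"{path}: malformed position on valid row at line {line}")
    return [
        GazeSample(float(ti), float(xi) if xi == xi else 0.0, float(yi) if yi == yi else 0.0, bool(vi))
        for ti, xi, yi, vi in zip(t, x, y, v)
    ]


def _parse_bool(val) -> Optional[bool]:
    if isinstance(val, bool):
        return val
    if isinstance(val, (int, float)) and val in (0, 1):
        return bool(val)
    if isinstance(val, str):
        s = val.strip().lower()
        if s in ("1", "true", "t", "yes"):
            return True
        if s in ("0", "false", "f", "no"):
            return False
    return None


def write_gaze_stream(samples: Sequence[GazeSample], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "t_ms": [s.t for s in samples],
            "x_px": [s.x for s in samples],
            "y_px": [s.y for s in samples],
            "valid": [int(s.valid) for s in samples],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


# --- fixation events ---------------------------------------------------------

FIXATION_COLUMNS = ["onset_ms", "offset_ms", "cx_px", "cy_px"]


def read_fixations(path: PathLike) -> list[FixationEvent]:
    """Read a pre-detected fixation table (vendor export or our own)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise GazeStreamParseError(f"{path}: missing required columns {missing}")
    fixes = [
        FixationEvent(float(r.onset_ms), float(r.offset_ms), float(r.cx_px), float(r.cy_px))
        for r in df.itertuples()
    ]
    for a, b in zip(fixes, fixes[1:]):
        if b.onset < a.offset:
            raise SequencingError(f"{path}: overlapping fixations at onset {b.onset}")
    return fixes


def write_fixations(fixations: Sequence[FixationEvent], path: PathLike) -> None:
    pd.DataFrame(
        {
            "onset_ms": [f.onset for f in fixations],
            "offset_ms": [f.offset for f in fixations],
            "cx_px": [f.cx for f in fixations],
            "cy_px": [f.cy for f in fixations],
        }
    ).to_csv(path, index=False, float_format="%.17g")


# --- overrides ---------------------------------------------------------------

def read_overrides(path: PathLike) -> list[OverrideCommand]:
    """Read researcher overrides from a ``t_ms,note`` CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "t_ms" not in df.columns:
        raise GazeStreamParseError(f"{path}: missing required column 't_ms'")
    notes = df["note"] if "note" in df.columns else [""] * len(df)
    return [
        OverrideCommand(float(t), "" if n != n else str(n))
        for t, n in zip(pd.to_numeric(df["t_ms"]), notes)
    ]


def write_overrides(overrides: Sequence[OverrideCommand], path: PathLike) -> None:
    pd.DataFrame({"t_ms": [o.t for o in overrides], "note": [o.note for o in overrides]}).to_csv(
        path, index=False
    )


# --- transition log (JSON lines) ----------------------------------------------

def write_transitions(per_trial: dict, path: PathLike) -> None:
    """Write one JSON object per transition: trial, phase, cause, timing."""
    with open(path, "w") as fh:
        for trial_id, recs in per_trial.items():
            for r in recs:
                fh.write(
                    json.dumps(
                        {
                            "trial_id": trial_id,
                            "phase": r.phase,
                            "cause": r.cause.value,
                            "t_ms": r.t,
                            "latency_ms": r.latency_ms,
                            "scheduled": r.scheduled,
                        }
                    )
                    + "\n"
                )


def read_transitions(path: PathLike) -> dict:
    per_trial: dict[str, list[TransitionRecord]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            per_trial.setdefault(d["trial_id"], []).append(
                TransitionRecord(
                    phase=int(d["phase"]),
                    cause=TransitionCause(d["cause"]),
                    t=float(d["t_ms"]),
                    latency_ms=float(d["latency_ms"]),
                    scheduled=bool(d.get("scheduled", False)),
                )
            )
    return per_trial


# --- results and summary -------------------------------------------------------

def results_to_frame(results: Sequence[TrialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in results],
            "task": [r.task.value for r in results],
            "cue": [r.cue.value if r.cue else "" for r in results],
            "direction": [r.direction.value if r.direction else "" for r in results],
            "phase1_cause": [r.phase1_cause.value if r.phase1_cause else "" for r in results],
            "rja_outcome": [r.rja_outcome.value for r in results],
            "ija_success": ["" if r.ija_success is None else int(r.ija_success) for r in results],
            "latency_ms": [r.latency_ms for r in results],
            "valid_for_analysis": [int(r.valid_for_analysis) for r in results],
        }
    )


def write_results(results: Sequence[TrialResult], path: PathLike) -> None:
    results_to_frame(results).to_csv(path, index=False)


def summary_to_dict(summary) -> dict:
    return dataclasses.asdict(summary)


def write_summary(summary, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(summary_to_dict(summary), fh, indent=2, default=str)


# --- configuration -------------------------------------------------------------

def battery_to_config(battery: BatterySpec, screen: Optional[ScreenGeometry] = None) -> dict:
    screen = screen or ScreenGeometry()
    return {
        "seed": battery.seed,
        "screen": {"width": screen.width, "height": screen.height},
        "trials": [
            {
                "trial_id": t.trial_id,
                "task": t.task.value,
                "cue": t.cue.value if t.cue else None,
                "direction": t.direction.value if t.direction else None,
                "stimulus_set": t.stimulus_set,
                "block": t.block,
            }
            for t in battery.trials
        ],
    }


def battery_from_config(cfg: dict, validate: bool = True) -> BatterySpec:
    """Rebuild a battery from its declarative config (trial design cells)."""
    scr = cfg.get("screen", {})
    screen = ScreenGeometry(scr.get("width", 1920), scr.get("height", 1080))
    trials = []
    for tc in cfg["trials"]:
        trials.append(
            make_trial(
                Task(tc["task"]),
                Cue(tc["cue"]) if tc.get("cue") else None,
                Direction(tc["direction"]) if tc.get("direction") else None,
                tc.get("stimulus_set"),
                screen,
                trial_id=tc["trial_id"],
                block=tc.get("block"),
            )
        )
    battery = BatterySpec(trials=tuple(trials), seed=int(cfg.get("seed", 0)))
    if validate:
        validate_battery(battery)
    return battery


def save_battery_config(battery: BatterySpec, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(battery_to_config(battery), fh, sort_keys=False)


def load_battery_config(path: PathLike, validate: bool = True) -> BatterySpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return battery_from_config(cfg, validate=validate)


def model_to_config(model: ParticipantModel) -> dict:
    return dataclasses.asdict(model)


def model_from_config(cfg: dict) -> ParticipantModel:
    known = {f.name for f in dataclasses.fields(ParticipantModel)}
    unknown = set(cfg) - known
    if unknown:
        raise GazeStreamParseError(f"unknown participant-model fields {sorted(unknown)}")
    return ParticipantModel(**cfg)


def load_model_config(path: PathLike) -> ParticipantModel:
    with open(path) as fh:
        return model_from_config(yaml.safe_load(fh) or {})


# --- pipeline ------------------------------------------------------------------

@dataclass
class SessionBundle:
    """Everything needed to (re)run one session end to end."""

    battery_config: PathLike
    gaze_stream: Optional[PathLike] = None
    fixation_events: Optional[PathLike] = None  # pre-detected table, skips detection
    overrides: Optional[PathLike] = None
    out_dir: PathLike = "."
    seed: int = 0
    attention_getter_cap_ms: Optional[float] = 10_000.0
    detector: FixationDetectorParams = dataclasses.field(default_factory=FixationDetectorParams)


def run_pipeline(bundle: SessionBundle) -> SessionRun:
    """validate -> (detect) -> engine -> score; write all artifacts.

    Deterministic given fixed inputs: writes transitions.jsonl, results.csv,
    summary.json and a manifest.json recording inputs and parameters.
    """
    out = Path(bundle.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    battery = load_battery_config(bundle.battery_config)

    if bundle.fixation_events is not None:
        fixations = read_fixations(bundle.fixation_events)
    elif bundle.gaze_stream is not None:
        samples = read_gaze_stream(bundle.gaze_stream)
        fixations = detect_fixations(samples, bundle.detector)
    else:
        raise GazeStreamParseError("bundle provides neither gaze stream nor fixation events")
    overrides = read_overrides(bundle.overrides) if bundle.overrides else []

    run = run_session(
        battery, fixations, overrides,
        attention_getter_cap_ms=bundle.attention_getter_cap_ms,
    )
    write_transitions(run.transitions, out / "transitions.jsonl")
    write_results(run.results, out / "results.csv")
    write_summary(run.summary, out / "summary.json")
    manifest = {
        "battery_config": str(bundle.battery_config),
        "gaze_stream": str(bundle.gaze_stream) if bundle.gaze_stream else None,
        "fixation_events": str(bundle.fixation_events) if bundle.fixation_events else None,
        "overrides": str(bundle.overrides) if bundle.overrides else None,
        "seed": bundle.seed,
        "attention_getter_cap_ms": bundle.attention_getter_cap_ms,
        "detector": dataclasses.asdict(bundle.detector),
        "n_trials": len(battery.trials),
        "t_end_ms": run.t_end,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return run
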