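"""Gaze samples and dispersion-threshold (I-DT) fixation detection.

The perceptual front end of the engine: raw gaze samples are parsed into
fixation events, and every downstream trigger operates on fixations, never
on raw samples. Dispersion is measured as ``(max x - min x) + (max y - min y)``
over the samples in a candidate window.

Time convention: a fixation's ``offset`` is the time of its last sample plus
one sampling period, so a fixation made of *n* samples at rate *f* Hz has
duration ``n / f * 1000`` ms. This keeps scripted event durations exact and
makes duration thresholds behave like dwell time rather than first-to-last
sample span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .geometry import Roi, RoiConfigurationError

__all__ = [
    "GazeSample",
    "FixationEvent",
    "FixationDetectorParams",
    "SequencingError",
    "detect_fixations",
    "fixation_roi_label",
]


class SequencingError(ValueError):
    """Raised when a sample stream is not strictly increasing in time."""


@dataclass(frozen=True)
class GazeSample:
    """One raw gaze sample: time (ms from session start), screen position, validity.

    ``valid=False`` marks blinks or tracking loss; x/y are ignored then.
    """

    t: float
    x: float
    y: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"valid sample at t={self.t} has non-finite position")


@dataclass(frozen=True)
class FixationEvent:
    """A detected fixation: [onset, offset) ms with its spatial centroid."""

    onset: float
    offset: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(f"fixation offset {self.offset} <= onset {self.onset}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class FixationDetectorParams:
    """I-DT parameters.

    max_dispersion_px
        Spatial window: (max x - min x) + (max y - min y) over the fixation's
        samples may not exceed this. Default 60 px is roughly 1.5 degrees of
        visual angle at a typical 60 cm viewing distance on a 1920x1080 display.
    min_duration_ms
        Shortest reportable fixation. Must stay at or below 100 ms, the
        smallest trigger threshold in the battery, or short trigger-qualifying
        fixations would be invisible to the engine.
    max_gap_ms
        Longest inter-sample interval (spanning invalid samples) bridged
        inside a fixation; a longer gap terminates the fixation.
    """

    max_dispersion_px: float = 60.0
    min_duration_ms: float = 60.0
    max_gap_ms: float = 75.0

    def __post_init__(self) -> None:
        if self.max_dispersion_px <= 0 or self.min_duration_ms <= 0 or self.max_gap_ms <= 0:
            raise ValueError("detector parameters must be strictly positive")
        if self.min_duration_ms > 100.0:
            raise ValueError(
                "min_duration_ms must not exceed 100 ms, the smallest trigger threshold"
            )


def _check_sorted(stream: Sequence[GazeSample]) -> None:
    for a, b in zip(stream, stream[1:]):
        if not b.t > a.t:
            raise SequencingError(
                f"gaze stream not strictly increasing at t={a.t} -> t={b.t}"
            )


def _sampling_period(stream: Sequence[GazeSample]) -> float:
    """Median inter-sample interval of the full stream (valid and invalid)."""
    if len(stream) < 2:
        return 0.0
    diffs = sorted(b.t - a.t for a, b in zip(stream, stream[1:]))
    mid = len(diffs) // 2
    if len(diffs) % 2:
        return diffs[mid]
    return 0.5 * (diffs[mid - 1] + diffs[mid])


def detect_fixations(
    stream: Sequence[GazeSample], params: Optional[FixationDetectorParams] = None
) -> list[FixationEvent]:
    """Parse a time-sorted gaze stream into fixation events via I-DT.

    Greedy left-to-right maximal windows: a window is grown while its
    dispersion stays within ``max_dispersion_px`` and no inter-sample gap
    exceeds ``max_gap_ms``; if the maximal window lasts at least
    ``min_duration_ms`` it is emitted as a fixation and scanning resumes
    after it, otherwise the window start advances by one sample.

    An empty stream yields no fixations; an unsorted stream raises
    :class:`SequencingError`.
    """
    if params is None:
        params = FixationDetectorParams()
    stream = list(stream)
    _check_sorted(stream)
    period = _sampling_period(stream)

    valid = [s for s in stream if s.valid]
    if not valid:
        return []

    fixations: list[FixationEvent] = []
    n = len(valid)
    i = 0
    while i < n:
        # grow [i..j] while dispersion and gap constraints hold
        min_x = max_x = valid[i].x
        min_y = max_y = valid[i].y
        j = i
        while j + 1 < n:
            nxt = valid[j + 1]
            if nxt.t - valid[j].t > params.max_gap_ms:
                break
            nmin_x = min(min_x, nxt.x)
            nmax_x = max(max_x, nxt.x)
            nmin_y = min(min_y, nxt.y)
            nmax_y = max(max_y, nxt.y)
            if (nmax_x - nmin_x) + (nmax_y - nmin_y) > params.max_dispersion_px:
                break
            min_x, max_x, min_y, max_y = nmin_x, nmax_x, nmin_y, nmax_y
            j += 1
        onset = valid[i].t
        offset = valid[j].t + period
        if offset - onset >= params.min_duration_ms and offset > onset:
            xs = [valid[k].x for k in range(i, j + 1)]
            ys = [valid[k].y for k in range(i, j + 1)]
            fixations.append(
                FixationEvent(
                    onset=onset,
                    offset=offset,
                    cx=sum(xs) / len(xs),
                    cy=sum(ys) / len(ys),
                )
            )
            i = j + 1
        else:
            i += 1
    return fixations


def fixation_roi_label(fix: FixationEvent, rois: Iterable[Roi]) -> Optional[str]:
    """Id of the ROI containing the fixation centroid, or None.

    ROIs must not overlap at the centroid; if two do, the geometry is
    misconfigured and a :class:`RoiConfigurationError` is raised.
    """
    hits = [roi.id for roi in rois if roi.contains(fix.cx, fix.cy)]
    if len(hits) > 1:
        raise RoiConfigurationError(
            f"fixation centroid ({fix.cx}, {fix.cy}) inside overlapping ROIs {hits}"
        )
    return hits[0] if hits else None
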