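"""Screen regions of interest (ROIs) and point/centroid membership.

Coordinate convention: origin at the top-left of the screen, x increases
rightward, y increases downward, units are pixels. Rectangles are half-open
on their high edges, so abutting ROIs tile the screen without ambiguity:
a point on a shared boundary belongs to exactly one rectangle.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = ["RoiRole", "Roi", "point_in_roi", "ScreenGeometry"]


class RoiRole(str, enum.Enum):
    """Functional role a region plays in a trial's interaction map."""

    ATTENTION_GETTER = "AttentionGetter"
    FACE = "Face"
    TARGET_LEFT = "TargetLeft"
    TARGET_RIGHT = "TargetRight"
    TABLET_LEFT = "TabletLeft"
    TABLET_RIGHT = "TabletRight"
    OBJECT_LEFT = "ObjectLeft"
    OBJECT_RIGHT = "ObjectRight"
    OTHER = "Other"


@dataclass(frozen=True)
class ScreenGeometry:
    """Display dimensions in pixels (default: 1920x1080 recording geometry)."""

    width: int = 1920
    height: int = 1080

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("screen dimensions must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)


@dataclass(frozen=True)
class Roi:
    """A named rectangular screen region with a functional role.

    ``rect`` is ``(x0, y0, x1, y1)`` with the low edges inclusive and the
    high edges exclusive: a point (x, y) is inside iff
    ``x0 <= x < x1 and y0 <= y < y1``.
    """

    id: str
    role: RoiRole
    rect: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"ROI {self.id!r}: degenerate rect {self.rect}")
        if not all(math.isfinite(v) for v in self.rect):
            raise ValueError(f"ROI {self.id!r}: non-finite rect {self.rect}")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.rect
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.rect
        return (x0 <= x < x1) and (y0 <= y < y1)


def point_in_roi(x: float, y: float, roi: Roi) -> bool:
    """True iff (x, y) lies inside the ROI's half-open rectangle."""
    return roi.contains(x, y)


class RoiConfigurationError(ValueError):
    """Raised when ROI geometry is inconsistent (e.g. overlapping regions)."""


def validate_rois(rois: Iterable[Roi], screen: Optional[ScreenGeometry] = None) -> list[Roi]:
    """Check that ROI ids are unique and rects lie on-screen; return as list."""
    rois = list(rois)
    seen: set[str] = set()
    for roi in rois:
        if roi.id in seen:
            raise RoiConfigurationError(f"duplicate ROI id {roi.id!r}")
        seen.add(roi.id)
        if screen is not None:
            x0, y0, x1, y1 = roi.rect
            if x0 < 0 or y0 < 0 or x1 > screen.width or y1 > screen.height:
                raise RoiConfigurationError(
                    f"ROI {roi.id!r} rect {roi.rect} exceeds screen "
                    f"{screen.width}x{screen.height}"
                )
    return rois
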