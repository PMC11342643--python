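"""Coordinate system and visual-angle conversions for the conceptual Amsler grid.

The grid is a 10 x 10 cm lattice of lines spaced 5 mm apart, viewed at a
working distance of 30 cm, so each square subtends very nearly 1 degree of
visual angle.  The centre of the fixation point is the origin of all stimulus
coordinates: x grows rightward and y grows upward on the display, both in
centimetres.  Angles are computed per component as ``atan(offset / distance)``,
which keeps the per-square 1-degree convention additive across the lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

from .errors import ConfigError, DomainError

__all__ = [
    "Point",
    "GridSpec",
    "TreatmentArea",
    "ScreenVerdict",
    "cm_to_deg",
    "deg_to_cm",
    "validate_screen",
]

_DIV_TOL = 1e-9


@dataclass(frozen=True)
class Point:
    """Signed offset from the fixation centre, in centimetres.

    ``x_cm`` is positive rightward, ``y_cm`` positive upward.
    """

    x_cm: float
    y_cm: float

    def __add__(self, other: "Point") -> "Point":
        return Point(self.x_cm + other.x_cm, self.y_cm + other.y_cm)

    def __sub__(self, other: "Point") -> "Point":
        return Point(self.x_cm - other.x_cm, self.y_cm - other.y_cm)

    def norm(self) -> float:
        return math.hypot(self.x_cm, self.y_cm)

    def to_dict(self) -> dict:
        return {"x_cm": self.x_cm, "y_cm": self.y_cm}

    @classmethod
    def from_dict(cls, d: dict) -> "Point":
        return cls(float(d["x_cm"]), float(d["y_cm"]))


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the conceptual self-assessment grid.

    Defaults describe the standard Amsler chart: 10 x 10 cm, 0.5 cm line
    spacing, viewed at 30 cm.  ``diagonal_lines`` and ``thick_center`` mark
    the revised chart variant that eases locating the centre; they do not
    change any computation (rendering is out of scope).
    """

    width_cm: float = 10.0
    height_cm: float = 10.0
    spacing_cm: float = 0.5
    working_distance_cm: float = 30.0
    diagonal_lines: bool = False
    thick_center: bool = False

    def __post_init__(self):
        for name in ("width_cm", "height_cm", "spacing_cm", "working_distance_cm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("width_cm", "height_cm"):
            extent = getattr(self, name)
            ratio = extent / self.spacing_cm
            if abs(ratio - round(ratio)) > _DIV_TOL:
                raise ConfigError(
                    f"spacing_cm={self.spacing_cm} does not divide {name}={extent} exactly"
                )

    @property
    def n_cols(self) -> int:
        return round(self.width_cm / self.spacing_cm)

    @property
    def n_rows(self) -> int:
        return round(self.height_cm / self.spacing_cm)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, row: int, col: int) -> Point:
        """Centre of cell ``(row, col)``; rows count downward from the top-left."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise DomainError(f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        x = -self.width_cm / 2.0 + (col + 0.5) * self.spacing_cm
        y = self.height_cm / 2.0 - (row + 0.5) * self.spacing_cm
        return Point(x, y)

    def cell_of(self, point: Point) -> tuple[int, int]:
        """Cell index containing ``point``; boundary points snap inward."""
        if not self.contains(point):
            raise DomainError(f"point {point} outside grid")
        col = int((point.x_cm + self.width_cm / 2.0) / self.spacing_cm)
        row = int((self.height_cm / 2.0 - point.y_cm) / self.spacing_cm)
        col = min(max(col, 0), self.n_cols - 1)
        row = min(max(row, 0), self.n_rows - 1)
        return row, col

    def contains(self, point: Point, tol: float = 1e-9) -> bool:
        return (
            abs(point.x_cm) <= self.width_cm / 2.0 + tol
            and abs(point.y_cm) <= self.height_cm / 2.0 + tol
        )

    def cells(self) -> Iterator[tuple[int, int]]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield r, c

    def to_dict(self) -> dict:
        return {
            "width_cm": self.width_cm,
            "height_cm": self.height_cm,
            "spacing_cm": self.spacing_cm,
            "working_distance_cm": self.working_distance_cm,
            "diagonal_lines": self.diagonal_lines,
            "thick_center": self.thick_center,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass(frozen=True)
class TreatmentArea:
    """Practitioner-specified peripheral retinal zone where stimuli are projected.

    ``center`` is the offset of the trained zone from the fixation point,
    ``extent_cm`` its radius.  Only practitioner-role operations may change a
    patient's treatment area (enforced by the record store, not here).
    """

    center: Point
    extent_cm: float = 1.0
    entered_by: str = "practitioner"

    def __post_init__(self):
        if self.extent_cm <= 0:
            raise ConfigError(f"extent_cm must be positive, got {self.extent_cm}")

    def to_dict(self) -> dict:
        return {
            "center": self.center.to_dict(),
            "extent_cm": self.extent_cm,
            "entered_by": self.entered_by,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentArea":
        return cls(Point.from_dict(d["center"]), float(d["extent_cm"]), d.get("entered_by", "practitioner"))


def cm_to_deg(offset, distance_cm: float):
    """Visual angle in degrees subtended by ``offset`` at ``distance_cm``.

    ``offset`` may be a scalar length in cm or a :class:`Point`; the Point
    form converts each component independently and returns an ``(x, y)``
    tuple of degrees.
    """
    if distance_cm <= 0:
        raise DomainError(f"distance_cm must be positive, got {distance_cm}")
    if isinstance(offset, Point):
        return (
            math.degrees(math.atan(offset.x_cm / distance_cm)),
            math.degrees(math.atan(offset.y_cm / distance_cm)),
        )
    return math.degrees(math.atan(offset / distance_cm))


def deg_to_cm(angle_deg: float, distance_cm: float) -> float:
    """Length in cm subtending ``angle_deg`` at ``distance_cm`` (inverse of cm_to_deg)."""
    if distance_cm <= 0:
        raise DomainError(f"distance_cm must be positive, got {distance_cm}")
    if abs(angle_deg) >= 90.0:
        raise DomainError(f"|angle_deg| must be < 90, got {angle_deg}")
    return math.tan(math.radians(angle_deg)) * distance_cm


@dataclass(frozen=True)
class ScreenVerdict:
    """Outcome of a device-eligibility check."""

    eligible: bool
    reasons: tuple = ()
    absolute_positioning: bool = False

    def to_dict(self) -> dict:
        return {
            "eligible": self.eligible,
            "reasons": list(self.reasons),
            "absolute_positioning": self.absolute_positioning,
        }


def validate_screen(
    screen_width_cm: float,
    screen_height_cm: float,
    mode: str,
    grid: GridSpec | None = None,
) -> ScreenVerdict:
    """Check whether a device screen can host the grid test or the exercises.

    The grid test needs the full chart on screen, so the screen must be at
    least as large as the grid.  Exercises run on any screen, but stimulus
    positions and sizes are kept in absolute centimetres: a screen narrower
    than the grid gets an ``absolute_positioning`` flag instead of rescaling,
    so the projection on the trained retinal area is preserved as long as the
    working distance is kept.
    """
    if screen_width_cm <= 0 or screen_height_cm <= 0:
        raise DomainError("screen dimensions must be positive")
    if mode not in ("test", "exercise"):
        raise ConfigError(f"mode must be 'test' or 'exercise', got {mode!r}")
    grid = grid or GridSpec()
    if mode == "test":
        reasons = []
        if screen_width_cm < grid.width_cm or screen_height_cm < grid.height_cm:
            reasons.append("grid does not fit")
        return ScreenVerdict(eligible=not reasons, reasons=tuple(reasons))
    flag = screen_width_cm < grid.width_cm or screen_height_cm < grid.height_cm
    reasons = ("stimulus positions kept in absolute cm",) if flag else ()
    return ScreenVerdict(eligible=True, reasons=reasons, absolute_positioning=flag)
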