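"""Synthetic AMD patient: a seeded psychophysical responder.

The simulated patient has a localized scotoma (an axis-aligned cell block or
a disk in grid coordinates) with low detection probability inside and high
outside, optionally blended across the edge by a linear probability ramp.
Exercise responses follow a logistic psychometric function of the margin
between the patient's true ability and the exercise difficulty; reaction
times are truncated-normal; session attendance is a Bernoulli compliance
gate.  Every response stream is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .amsler import StimulusEvent
from .config import DEFAULTS, merge_config
from .errors import ConfigError, DomainError
from .exercises import StimulusStream, StreamEvent, Tap
from .geometry import GridSpec, Point

__all__ = [
    "SimulatedPatient",
    "make_patient",
    "detection_probability",
    "respond_amsler",
    "amsler_responder",
    "respond_exercise",
    "ExerciseResponder",
]

Cell = tuple[int, int]


@dataclass
class SimulatedPatient:
    """Fully specified deterministic responder (given its seed)."""

    scotoma_cells: Optional[frozenset[Cell]] = None
    scotoma_disk: Optional[tuple[Point, float]] = None  # (center, radius_cm)
    p_detect_inside: float = 0.05
    p_detect_outside: float = 0.98
    edge_softness_cm: float = 0.0
    ability: float = 0.6  # scalar true ability; per-skill dicts collapse to their mean
    logistic_slope: float = 8.0
    false_alarm_prob: float = 0.02
    rt_mean_s: float = 0.9
    rt_sd_s: float = 0.3
    rt_floor_s: float = 0.2
    compliance_prob: float = 1.0
    seed: int = 0
    rng: np.random.Generator = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if not (0.0 <= self.p_detect_inside < self.p_detect_outside <= 1.0):
            raise ConfigError(
                f"need 0 <= p_detect_inside < p_detect_outside <= 1, got "
                f"{self.p_detect_inside} and {self.p_detect_outside}"
            )
        if not 0.0 <= self.compliance_prob <= 1.0:
            raise ConfigError("compliance_prob must be in [0, 1]")
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    def reseed(self, seed: int) -> None:
        self.seed = seed
        self.rng = np.random.default_rng(seed)

    def _rt(self, max_s: float) -> float:
        rt = float(self.rng.normal(self.rt_mean_s, self.rt_sd_s))
        return float(np.clip(rt, self.rt_floor_s, max_s))

    def attends(self, rng: Optional[np.random.Generator] = None) -> bool:
        r = rng if rng is not None else self.rng
        return bool(r.random() < self.compliance_prob)


def make_patient(config: Optional[dict] = None, seed: int = 0) -> SimulatedPatient:
    """Build a patient from the ``simulator`` config section."""
    cfg = merge_config(DEFAULTS, config or {})["simulator"]
    scot = cfg.get("scotoma") or {}
    cells: Optional[frozenset[Cell]] = None
    disk: Optional[tuple[Point, float]] = None
    kind = scot.get("kind", "block")
    if kind == "block":
        r0, c0 = int(scot.get("row0", 5)), int(scot.get("col0", 11))
        nr, nc = int(scot.get("n_rows", 3)), int(scot.get("n_cols", 3))
        cells = frozenset((r0 + i, c0 + j) for i in range(nr) for j in range(nc))
    elif kind == "disk":
        disk = (Point(float(scot["x_cm"]), float(scot["y_cm"])), float(scot["radius_cm"]))
    elif kind == "none":
        pass
    else:
        raise ConfigError(f"unknown scotoma kind {kind!r}")
    ability = cfg.get("ability", 0.6)
    if isinstance(ability, dict):
        ability = float(np.mean(list(ability.values())))
    return SimulatedPatient(
        scotoma_cells=cells,
        scotoma_disk=disk,
        p_detect_inside=float(cfg.get("p_detect_inside", 0.05)),
        p_detect_outside=float(cfg.get("p_detect_outside", 0.98)),
        edge_softness_cm=float(cfg.get("edge_softness_cm", 0.0)),
        ability=float(ability),
        logistic_slope=float(cfg.get("logistic_slope", 8.0)),
        false_alarm_prob=float(cfg.get("false_alarm_prob", 0.02)),
        rt_mean_s=float(cfg.get("rt_mean_s", 0.9)),
        rt_sd_s=float(cfg.get("rt_sd_s", 0.3)),
        rt_floor_s=float(cfg.get("rt_floor_s", 0.2)),
        compliance_prob=float(cfg.get("compliance_prob", 1.0)),
        seed=seed,
    )


def _rect_signed_distance(p: Point, r: int, c: int, grid: GridSpec) -> float:
    """Signed distance from ``p`` to the cell rectangle (negative inside)."""
    cx, cy = grid.cell_center(r, c).x_cm, grid.cell_center(r, c).y_cm
    hw = grid.spacing_cm / 2.0
    dx = abs(p.x_cm - cx) - hw
    dy = abs(p.y_cm - cy) - hw
    if dx > 0 or dy > 0:
        return float(np.hypot(max(dx, 0.0), max(dy, 0.0)))
    return float(max(dx, dy))  # negative: depth inside the rectangle


def _scotoma_signed_distance(patient: SimulatedPatient, point: Point, grid: GridSpec) -> Optional[float]:
    """Signed distance to the scotoma boundary (negative inside), or None if no scotoma."""
    if patient.scotoma_disk is not None:
        center, radius = patient.scotoma_disk
        return (point - center).norm() - radius
    if patient.scotoma_cells:
        return min(_rect_signed_distance(point, r, c, grid) for r, c in patient.scotoma_cells)
    return None


def detection_probability(patient: SimulatedPatient, point: Point, grid: Optional[GridSpec] = None) -> float:
    """Detection probability at ``point``: p_inside within the scotoma,
    p_outside elsewhere, linearly interpolated over the edge-softness window."""
    grid = grid or GridSpec()
    d = _scotoma_signed_distance(patient, point, grid)
    if d is None:
        return patient.p_detect_outside
    s = patient.edge_softness_cm
    if s <= 0:
        return patient.p_detect_inside if d <= 0 else patient.p_detect_outside
    t = float(np.clip((d + s / 2.0) / s, 0.0, 1.0))
    return patient.p_detect_inside + t * (patient.p_detect_outside - patient.p_detect_inside)


def respond_amsler(
    patient: SimulatedPatient,
    stimulus: StimulusEvent,
    grid: Optional[GridSpec] = None,
) -> tuple[bool, Optional[float]]:
    """Bernoulli detection of one grid stimulus; reaction time truncated to the window."""
    grid = grid or GridSpec()
    if not grid.contains(stimulus.position):
        raise DomainError(f"stimulus at {stimulus.position} outside the grid")
    p = detection_probability(patient, stimulus.position, grid)
    seen = bool(patient.rng.random() < p)
    if not seen:
        return False, None
    return True, patient._rt(stimulus.window_s)


def amsler_responder(patient: SimulatedPatient, grid: Optional[GridSpec] = None):
    """Callback suitable for :func:`prltrain.amsler.run_test`."""
    g = grid or GridSpec()

    def responder(stimulus: StimulusEvent) -> tuple[bool, Optional[float]]:
        return respond_amsler(patient, stimulus, g)

    return responder


def _hit_probability(patient: SimulatedPatient, difficulty: float) -> float:
    x = patient.logistic_slope * (patient.ability - difficulty)
    return float(1.0 / (1.0 + np.exp(-x)))


def respond_exercise(
    patient: SimulatedPatient,
    event: StreamEvent,
    spec_difficulty: float,
    rng: Optional[np.random.Generator] = None,
) -> bool:
    """Whether the patient taps during this event's window.

    Targets are hit with logistic probability of (ability - difficulty);
    non-targets draw a small false-alarm probability.
    """
    r = rng if rng is not None else patient.rng
    p = _hit_probability(patient, spec_difficulty) if event.is_target else patient.false_alarm_prob
    return bool(r.random() < p)


class ExerciseResponder:
    """Adapter running a simulated patient inside the selection loop.

    Callable as ``responder(stream, difficulty, rng) -> [Tap, ...]`` and
    exposing ``attends(rng)`` for the compliance gate.
    """

    def __init__(self, patient: SimulatedPatient):
        self.patient = patient

    def attends(self, rng: np.random.Generator) -> bool:
        return self.patient.attends(rng)

    def __call__(
        self,
        stream: StimulusStream,
        difficulty: float,
        rng: np.random.Generator,
    ) -> list[Tap]:
        taps: list[Tap] = []
        for event in stream.events:
            if respond_exercise(self.patient, event, difficulty, rng):
                rt = float(np.clip(rng.normal(self.patient.rt_mean_s, self.patient.rt_sd_s),
                                   self.patient.rt_floor_s, event.duration_s * 0.95))
                taps.append(Tap(time_s=event.onset_s + rt, event_index=event.index))
        return taps
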