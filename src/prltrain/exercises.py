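"""Exercise catalogues, seeded stimulus streams, and session scoring.

Two catalogue versions exist.  The *initial* catalogue holds the fifteen
exercises the visual rehabilitator first proposed: a demonstration, figure
recognition with a single fixation point (solid figures, hollow figures,
bold letters, plain letters, in increasing complexity), the same four with
alternating fixation, real-object recognition, two face exercises, a scene
search, and two lines-of-letters reading tasks.  The *revised* catalogue
applies the usability changes agreed with the patients: the demonstration is
no longer counted as an exercise, figure/object exercises accept a touch
anywhere on the screen and present stimuli every 5 s instead of 10 s,
alternating-fixation exercises become sequential (switch prompted after a
missed target) with voice guidance, the requested real object must appear at
least twice at a reduced size, the two face exercises merge into one, the
scene search keeps a fixed fixation dot and is compulsorily voice-guided,
and the two reading tasks are dropped as too difficult.

All stimuli are projected on the treatment area: every event's position is
the treatment-area centre expressed as an offset from the active fixation
point, in absolute centimetres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULTS
from .errors import ConfigError, DomainError, PlacementError
from .geometry import GridSpec, Point, TreatmentArea

__all__ = [
    "TaskKind",
    "ResponseMode",
    "FixationMode",
    "ExerciseParams",
    "ExerciseSpec",
    "StreamEvent",
    "StimulusStream",
    "Tap",
    "ExerciseResult",
    "SanitizedTiming",
    "catalogue",
    "exercises_only",
    "build_stimulus_stream",
    "score_session",
    "sanitize_timing",
    "PRACTITIONER_ADJUSTABLE_PARAMS",
]


class TaskKind(str, Enum):
    DEMO = "demo"
    FIGURE_SINGLE_FIXATION = "figure_single_fixation"
    FIGURE_ALTERNATING_FIXATION = "figure_alternating_fixation"
    REAL_OBJECTS = "real_objects"
    FACES = "faces"
    SCENE_SEARCH = "scene_search"
    LETTER_LINES = "letter_lines"


class ResponseMode(str, Enum):
    TOUCH_TARGET = "touch_target"
    TOUCH_ANYWHERE = "touch_anywhere"


class FixationMode(str, Enum):
    SINGLE = "single"
    ALTERNATING = "alternating"
    NONE = "none"


#: The only exercise parameters the practitioner may adjust per patient.
PRACTITIONER_ADJUSTABLE_PARAMS = frozenset(
    {"inter_stimulus_s", "n_stimuli", "stimulus_size_cm", "duration_s"}
)

# Image families are abstract identifiers; rendering assets are out of scope.
FIGURES_SOLID = ("figure:circle_solid", "figure:square_solid", "figure:triangle_solid", "figure:star_solid")
FIGURES_HOLLOW = ("figure:circle_hollow", "figure:square_hollow", "figure:triangle_hollow", "figure:star_hollow")
LETTERS_BOLD = ("letter_bold:E", "letter_bold:H", "letter_bold:N", "letter_bold:R")
LETTERS_PLAIN = ("letter:e", "letter:h", "letter:n", "letter:r")
OBJECTS_DRINKS = ("object:coffee_cup", "object:water_glass", "object:juice_bottle", "object:soda_can")
FACES_FAMILY = ("face:woman", "face:man", "face:girl", "face:boy")
SCENE_OBJECTS = ("scene:lamp", "scene:chair", "scene:clock", "scene:vase")
LETTER_ROWS = ("letters:row_large", "letters:row_medium", "letters:row_small")


@dataclass(frozen=True)
class ExerciseParams:
    """Tunable presentation parameters of one exercise."""

    inter_stimulus_s: float = 10.0
    n_stimuli: int = 10
    stimulus_size_cm: float = 2.0
    duration_s: Optional[float] = None  # derived as n_stimuli * inter_stimulus_s when None
    fixation_mode: FixationMode = FixationMode.SINGLE
    response_mode: ResponseMode = ResponseMode.TOUCH_TARGET
    voice_guided: bool = False
    forced_voice: bool = False
    fixation_moves: bool = False
    sequential_alternation: bool = False
    min_target_occurrences: int = 1

    def __post_init__(self):
        if self.inter_stimulus_s <= 0:
            raise ConfigError("inter_stimulus_s must be positive")
        if self.n_stimuli < 1:
            raise ConfigError("n_stimuli must be >= 1")
        if self.stimulus_size_cm <= 0:
            raise ConfigError("stimulus_size_cm must be positive")
        if self.min_target_occurrences < 0:
            raise ConfigError("min_target_occurrences must be >= 0")

    @property
    def session_duration_s(self) -> float:
        return self.duration_s if self.duration_s is not None else self.n_stimuli * self.inter_stimulus_s

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fixation_mode"] = self.fixation_mode.value
        d["response_mode"] = self.response_mode.value
        return d


@dataclass(frozen=True)
class ExerciseSpec:
    """Parameterised definition of one rehabilitation exercise."""

    id: int
    version: str  # "initial" | "revised"
    task_kind: TaskKind
    name: str
    target: str
    image_family: tuple[str, ...]
    skill_requirements: dict
    params: ExerciseParams
    complexity_rank: int = 0
    is_demo: bool = False

    def __post_init__(self):
        if self.params.forced_voice and not self.params.voice_guided:
            raise ConfigError("forced_voice requires voice_guided")
        if self.target not in self.image_family and self.task_kind is not TaskKind.DEMO:
            raise ConfigError(f"target {self.target!r} not in image family")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "version": self.version,
            "task_kind": self.task_kind.value,
            "name": self.name,
            "target": self.target,
            "image_family": list(self.image_family),
            "skill_requirements": dict(self.skill_requirements),
            "params": self.params.to_dict(),
            "complexity_rank": self.complexity_rank,
            "is_demo": self.is_demo,
        }


def _figure_series(version: str) -> list[tuple[str, tuple[str, ...], int, dict]]:
    """(label, family, complexity, skills) for the four figure difficulties.

    Complexity increases with the figure type: solid figures are easiest,
    then hollow figures, bold letters, and plain letters.
    """
    return [
        ("solid figures", FIGURES_SOLID, 0, {"fixation_stability": 0.5, "eccentric_detection": 0.5, "shape_discrimination": 0.3}),
        ("hollow figures", FIGURES_HOLLOW, 1, {"fixation_stability": 0.5, "eccentric_detection": 0.6, "shape_discrimination": 0.5}),
        ("bold letters", LETTERS_BOLD, 2, {"fixation_stability": 0.6, "eccentric_detection": 0.6, "letter_recognition": 0.5}),
        ("plain letters", LETTERS_PLAIN, 3, {"fixation_stability": 0.6, "eccentric_detection": 0.7, "letter_recognition": 0.7}),
    ]


def _initial_catalogue() -> list[ExerciseSpec]:
    specs: list[ExerciseSpec] = []
    specs.append(
        ExerciseSpec(
            id=1, version="initial", task_kind=TaskKind.DEMO, name="demonstration",
            target="figure:circle_solid", image_family=FIGURES_SOLID,
            skill_requirements={},
            params=ExerciseParams(n_stimuli=3, response_mode=ResponseMode.TOUCH_ANYWHERE),
        )
    )
    for offset, (label, family, rank, skills) in enumerate(_figure_series("initial")):
        specs.append(
            ExerciseSpec(
                id=2 + offset, version="initial", task_kind=TaskKind.FIGURE_SINGLE_FIXATION,
                name=f"single fixation, {label}", target=family[0], image_family=family,
                skill_requirements=skills,
                params=ExerciseParams(stimulus_size_cm=2.0 if rank < 2 else 1.5),
                complexity_rank=rank,
            )
        )
    for offset, (label, family, rank, skills) in enumerate(_figure_series("initial")):
        specs.append(
            ExerciseSpec(
                id=6 + offset, version="initial", task_kind=TaskKind.FIGURE_ALTERNATING_FIXATION,
                name=f"alternating fixation, {label}", target=family[0], image_family=family,
                skill_requirements={**skills, "fixation_switching": 0.6},
                params=ExerciseParams(
                    stimulus_size_cm=2.0 if rank < 2 else 1.5,
                    fixation_mode=FixationMode.ALTERNATING,
                ),
                complexity_rank=rank,
            )
        )
    specs.append(
        ExerciseSpec(
            id=10, version="initial", task_kind=TaskKind.REAL_OBJECTS, name="real objects (drinks)",
            target=OBJECTS_DRINKS[0], image_family=OBJECTS_DRINKS,
            skill_requirements={"fixation_stability": 0.5, "eccentric_detection": 0.6, "object_recognition": 0.5},
            params=ExerciseParams(stimulus_size_cm=3.0),
        )
    )
    for i, face in enumerate(("face:woman", "face:man")):
        specs.append(
            ExerciseSpec(
                id=11 + i, version="initial", task_kind=TaskKind.FACES,
                name=f"face parts ({face.split(':')[1]})", target=face, image_family=FACES_FAMILY,
                skill_requirements={"fixation_stability": 0.6, "face_recognition": 0.6, "eccentric_detection": 0.6},
                params=ExerciseParams(stimulus_size_cm=3.0, fixation_moves=True),
            )
        )
    specs.append(
        ExerciseSpec(
            id=13, version="initial", task_kind=TaskKind.SCENE_SEARCH, name="scene search (room)",
            target=SCENE_OBJECTS[0], image_family=SCENE_OBJECTS,
            skill_requirements={"visual_search": 0.7, "object_recognition": 0.6, "eccentric_detection": 0.6},
            params=ExerciseParams(stimulus_size_cm=4.0, fixation_moves=True),
        )
    )
    for i, rank in enumerate((2, 3)):
        specs.append(
            ExerciseSpec(
                id=14 + i, version="initial", task_kind=TaskKind.LETTER_LINES,
                name=f"letter lines {'large' if i == 0 else 'small'}",
                target=LETTER_ROWS[0], image_family=LETTER_ROWS,
                skill_requirements={"reading": 0.8, "letter_recognition": 0.7, "visual_search": 0.6},
                params=ExerciseParams(stimulus_size_cm=1.0, fixation_mode=FixationMode.NONE),
                complexity_rank=rank,
            )
        )
    return specs


def _revised_catalogue() -> list[ExerciseSpec]:
    specs: list[ExerciseSpec] = []
    specs.append(
        ExerciseSpec(
            id=1, version="revised", task_kind=TaskKind.DEMO, name="demonstration",
            target="figure:circle_solid", image_family=FIGURES_SOLID,
            skill_requirements={},
            params=ExerciseParams(n_stimuli=3, response_mode=ResponseMode.TOUCH_ANYWHERE),
            is_demo=True,
        )
    )
    for offset, (label, family, rank, skills) in enumerate(_figure_series("revised")):
        specs.append(
            ExerciseSpec(
                id=2 + offset, version="revised", task_kind=TaskKind.FIGURE_SINGLE_FIXATION,
                name=f"single fixation, {label}", target=family[0], image_family=family,
                skill_requirements=skills,
                params=ExerciseParams(
                    inter_stimulus_s=5.0,
                    stimulus_size_cm=2.0 if rank < 2 else 1.5,
                    response_mode=ResponseMode.TOUCH_ANYWHERE,
                ),
                complexity_rank=rank,
            )
        )
    for offset, (label, family, rank, skills) in enumerate(_figure_series("revised")):
        specs.append(
            ExerciseSpec(
                id=6 + offset, version="revised", task_kind=TaskKind.FIGURE_ALTERNATING_FIXATION,
                name=f"sequential alternating fixation, {label}", target=family[0], image_family=family,
                skill_requirements={**skills, "fixation_switching": 0.6},
                params=ExerciseParams(
                    stimulus_size_cm=2.0 if rank < 2 else 1.5,
                    fixation_mode=FixationMode.ALTERNATING,
                    sequential_alternation=True,
                    voice_guided=True,
                    response_mode=ResponseMode.TOUCH_ANYWHERE,
                ),
                complexity_rank=rank,
            )
        )
    specs.append(
        ExerciseSpec(
            id=10, version="revised", task_kind=TaskKind.REAL_OBJECTS, name="real objects (drinks)",
            target=OBJECTS_DRINKS[0], image_family=OBJECTS_DRINKS,
            skill_requirements={"fixation_stability": 0.5, "eccentric_detection": 0.6, "object_recognition": 0.5},
            params=ExerciseParams(
                inter_stimulus_s=5.0,
                stimulus_size_cm=2.0,  # reduced from 3.0 to raise difficulty
                response_mode=ResponseMode.TOUCH_ANYWHERE,
                min_target_occurrences=2,
            ),
        )
    )
    specs.append(
        ExerciseSpec(
            id=11, version="revised", task_kind=TaskKind.FACES, name="faces (merged)",
            target="face:woman", image_family=FACES_FAMILY,
            skill_requirements={"fixation_stability": 0.6, "face_recognition": 0.6, "eccentric_detection": 0.6},
            params=ExerciseParams(
                inter_stimulus_s=5.0,
                stimulus_size_cm=3.0,
                response_mode=ResponseMode.TOUCH_ANYWHERE,
            ),
        )
    )
    specs.append(
        ExerciseSpec(
            id=13, version="revised", task_kind=TaskKind.SCENE_SEARCH, name="scene search (fixed dot)",
            target=SCENE_OBJECTS[0], image_family=SCENE_OBJECTS,
            skill_requirements={"visual_search": 0.7, "object_recognition": 0.6, "eccentric_detection": 0.6},
            params=ExerciseParams(
                stimulus_size_cm=2.0,
                response_mode=ResponseMode.TOUCH_ANYWHERE,
                voice_guided=True,
                forced_voice=True,
            ),
        )
    )
    return specs


def catalogue(version: str) -> list[ExerciseSpec]:
    """Full exercise catalogue for ``version`` in {"initial", "revised"}."""
    if version == "initial":
        return _initial_catalogue()
    if version == "revised":
        return _revised_catalogue()
    raise ConfigError(f"unknown catalogue version {version!r}")


def exercises_only(specs: Sequence[ExerciseSpec]) -> list[ExerciseSpec]:
    """Catalogue entries counted as exercises (demonstration entries excluded)."""
    return [s for s in specs if not s.is_demo]


def spec_by_id(version: str, spec_id: int) -> ExerciseSpec:
    for s in catalogue(version):
        if s.id == spec_id:
            return s
    raise DomainError(f"no exercise {spec_id} in {version} catalogue")


@dataclass(frozen=True)
class StreamEvent:
    """One presentation: an image at the treatment-area offset from its fixation point.

    ``offset`` is relative to the active fixation point; ``fixation`` is the
    fixation point in grid coordinates, or None for alternating streams where
    the active point is resolved at scoring time, and for fixation-free tasks.
    """

    index: int
    image: str
    is_target: bool
    onset_s: float
    duration_s: float
    offset: Point
    fixation: Optional[Point] = None

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def absolute_position(self, fixation: Optional[Point] = None) -> Point:
        fix = fixation if fixation is not None else self.fixation
        if fix is None:
            return self.offset
        return fix + self.offset

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "image": self.image,
            "is_target": self.is_target,
            "onset_s": self.onset_s,
            "duration_s": self.duration_s,
            "offset": self.offset.to_dict(),
            "fixation": self.fixation.to_dict() if self.fixation is not None else None,
        }


@dataclass(frozen=True)
class StimulusStream:
    """Seeded, ordered presentation schedule for one exercise session."""

    spec_id: int
    version: str
    events: tuple[StreamEvent, ...]
    fixation_points: tuple[Point, ...]
    seed: int
    response_mode: ResponseMode
    fixation_mode: FixationMode
    sequential_alternation: bool = False

    @property
    def target_events(self) -> tuple[StreamEvent, ...]:
        return tuple(e for e in self.events if e.is_target)

    def to_dict(self) -> dict:
        return {
            "spec_id": self.spec_id,
            "version": self.version,
            "seed": self.seed,
            "response_mode": self.response_mode.value,
            "fixation_mode": self.fixation_mode.value,
            "sequential_alternation": self.sequential_alternation,
            "fixation_points": [p.to_dict() for p in self.fixation_points],
            "events": [e.to_dict() for e in self.events],
        }


@dataclass(frozen=True)
class Tap:
    """One screen touch: when it happened and, for touch-target exercises,
    whether it landed on the stimulus (hit-testing geometry is out of scope,
    so ``on_target`` is a boolean oracle supplied by the caller)."""

    time_s: float
    event_index: Optional[int] = None
    on_target: Optional[bool] = None


@dataclass(frozen=True)
class ExerciseResult:
    """Hit/miss/attempt score of one session."""

    spec_id: int
    version: str
    hits: int
    misses: int
    false_alarms: int
    attempts: int
    reaction_times_s: tuple[float, ...] = ()
    fixation_switches: tuple[int, ...] = ()  # event indices after which a switch was prompted
    eye_mode: str = "binocular"
    timestamp: float = 0.0

    def __post_init__(self):
        if min(self.hits, self.misses, self.false_alarms, self.attempts) < 0:
            raise DomainError("counts must be non-negative")
        if self.hits + self.misses > self.attempts:
            raise DomainError("hits + misses cannot exceed attempts")

    @property
    def success_rate(self) -> Optional[float]:
        denom = self.hits + self.misses
        return self.hits / denom if denom else None

    def to_dict(self) -> dict:
        return {
            "spec_id": self.spec_id,
            "version": self.version,
            "hits": self.hits,
            "misses": self.misses,
            "false_alarms": self.false_alarms,
            "attempts": self.attempts,
            "reaction_times_s": list(self.reaction_times_s),
            "fixation_switches": list(self.fixation_switches),
            "eye_mode": self.eye_mode,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExerciseResult":
        return cls(
            spec_id=int(d["spec_id"]),
            version=d.get("version", "revised"),
            hits=int(d["hits"]),
            misses=int(d["misses"]),
            false_alarms=int(d.get("false_alarms", 0)),
            attempts=int(d["attempts"]),
            reaction_times_s=tuple(d.get("reaction_times_s", ())),
            fixation_switches=tuple(d.get("fixation_switches", ())),
            eye_mode=d.get("eye_mode", "binocular"),
            timestamp=float(d.get("timestamp", 0.0)),
        )


def _fixation_points(
    spec: ExerciseSpec, area: TreatmentArea, grid: GridSpec, cfg: dict
) -> tuple[Point, ...]:
    if spec.params.fixation_mode is FixationMode.ALTERNATING:
        half = float(cfg.get("fixation_separation_cm", 4.0)) / 2.0
        return (Point(-half, 0.0), Point(half, 0.0))
    if spec.params.fixation_mode is FixationMode.NONE:
        return ()
    return (Point(0.0, 0.0),)


def _check_placement(position: Point, grid: GridSpec, spec: ExerciseSpec):
    if not grid.contains(position):
        raise PlacementError(
            f"stimulus for exercise {spec.id} at ({position.x_cm:.2f}, {position.y_cm:.2f}) cm "
            f"falls outside the {grid.width_cm}x{grid.height_cm} cm grid"
        )


def build_stimulus_stream(
    spec: ExerciseSpec,
    area: TreatmentArea,
    seed: int = 0,
    grid: Optional[GridSpec] = None,
    config: Optional[dict] = None,
) -> StimulusStream:
    """Generate the seeded presentation schedule of one session.

    The designated target is inserted at uniformly chosen slots (at least
    ``min_target_occurrences`` of them); the remaining slots are filled with
    other members of the image family, sampled uniformly without immediate
    repetition.  Every event sits at the treatment-area offset from its
    active fixation point; positions that would leave the conceptual grid
    raise :class:`PlacementError`.
    """
    grid = grid or GridSpec()
    cfg = (config or DEFAULTS).get("exercises", DEFAULTS["exercises"])
    p = spec.params
    rng = np.random.default_rng(seed)

    n = p.n_stimuli
    n_targets = min(n, max(p.min_target_occurrences, round(n * float(cfg.get("target_fraction", 0.5)))))
    n_targets = max(n_targets, 1)
    target_slots = set(rng.choice(n, size=n_targets, replace=False).tolist())

    fillers = [img for img in spec.image_family if img != spec.target]
    images: list[str] = []
    prev: Optional[str] = None
    for i in range(n):
        if i in target_slots:
            img = spec.target
        else:
            pool = [f for f in fillers if f != prev] or fillers
            img = pool[int(rng.integers(len(pool)))]
        images.append(img)
        prev = img

    fixation_points = _fixation_points(spec, area, grid, cfg)
    # validate that the projection stays on the conceptual grid for every
    # fixation point the session can use
    if fixation_points:
        for fp in fixation_points:
            _check_placement(fp + area.center, grid, spec)
    else:
        _check_placement(area.center, grid, spec)

    events = []
    for i, img in enumerate(images):
        if p.fixation_mode is FixationMode.ALTERNATING:
            fixation = None  # resolved by the alternation state machine at scoring time
        elif p.fixation_mode is FixationMode.NONE:
            fixation = None
        elif p.fixation_moves:
            # fixation point wanders; sample it so the projected stimulus stays on-grid
            xlo = -grid.width_cm / 2 - min(0.0, area.center.x_cm)
            xhi = grid.width_cm / 2 - max(0.0, area.center.x_cm)
            ylo = -grid.height_cm / 2 - min(0.0, area.center.y_cm)
            yhi = grid.height_cm / 2 - max(0.0, area.center.y_cm)
            fixation = Point(float(rng.uniform(xlo, xhi)), float(rng.uniform(ylo, yhi)))
            _check_placement(fixation + area.center, grid, spec)
        else:
            fixation = fixation_points[0]
        events.append(
            StreamEvent(
                index=i,
                image=img,
                is_target=(i in target_slots),
                onset_s=i * p.inter_stimulus_s,
                duration_s=p.inter_stimulus_s,
                offset=area.center,
                fixation=fixation,
            )
        )
    return StimulusStream(
        spec_id=spec.id,
        version=spec.version,
        events=tuple(events),
        fixation_points=fixation_points,
        seed=seed,
        response_mode=p.response_mode,
        fixation_mode=p.fixation_mode,
        sequential_alternation=p.sequential_alternation,
    )


def score_session(
    stream: StimulusStream,
    responses: Sequence[Tap],
    eye_mode: str = "binocular",
    timestamp: float = 0.0,
) -> ExerciseResult:
    """Score a session from its tap stream.

    Touch-anywhere rule: a tap inside a target event's window is a hit, a tap
    inside a non-target window is a miss (false alarm), and an untapped
    target is a miss.  Attempts count every tap plus every target
    presentation.  Taps between events are ignored.  For touch-target
    exercises a tap additionally needs ``on_target`` not False.

    For sequential alternating-fixation exercises the alternation state
    machine runs here: after every missed target the patient is prompted to
    switch to the other fixation point.
    """
    for tap in responses:
        if tap.event_index is not None and not (0 <= tap.event_index < len(stream.events)):
            raise DomainError(f"response references unknown event {tap.event_index}")

    taps = sorted(responses, key=lambda t: t.time_s)

    def tap_for(event: StreamEvent) -> Optional[Tap]:
        for tap in taps:
            if tap.event_index is not None:
                if tap.event_index == event.index:
                    return tap
            elif event.onset_s <= tap.time_s < event.end_s:
                return tap
        return None

    hits = 0
    missed_targets = 0
    false_alarms = 0
    reaction_times: list[float] = []
    switches: list[int] = []
    fix_idx = 0

    for event in stream.events:
        tap = tap_for(event)
        effective = tap is not None and (
            stream.response_mode is ResponseMode.TOUCH_ANYWHERE or tap.on_target is not False
        )
        if event.is_target:
            if effective:
                hits += 1
                reaction_times.append(max(0.0, tap.time_s - event.onset_s))
            else:
                missed_targets += 1
                if stream.sequential_alternation and len(stream.fixation_points) > 1:
                    switches.append(event.index)
                    fix_idx = 1 - fix_idx
        else:
            if tap is not None:
                false_alarms += 1

    n_targets = sum(1 for e in stream.events if e.is_target)
    return ExerciseResult(
        spec_id=stream.spec_id,
        version=stream.version,
        hits=hits,
        misses=missed_targets + false_alarms,
        false_alarms=false_alarms,
        attempts=len(taps) + n_targets,
        reaction_times_s=tuple(reaction_times),
        fixation_switches=tuple(switches),
        eye_mode=eye_mode,
        timestamp=timestamp,
    )


@dataclass(frozen=True)
class SanitizedTiming:
    value_s: float
    used_default: bool
    warning: Optional[str] = None


def sanitize_timing(raw_input, default_s: float) -> SanitizedTiming:
    """Error-correct a user-entered timing value.

    An empty or absent entry silently falls back to the exercise default; a
    non-numeric or non-positive entry also falls back but carries a warning
    record.
    """
    if raw_input is None or (isinstance(raw_input, str) and raw_input.strip() == ""):
        return SanitizedTiming(default_s, used_default=True)
    try:
        value = float(raw_input)
    except (TypeError, ValueError):
        return SanitizedTiming(
            default_s, used_default=True,
            warning=f"non-numeric timing {raw_input!r}; default {default_s} s restored",
        )
    if not np.isfinite(value) or value <= 0:
        return SanitizedTiming(
            default_s, used_default=True,
            warning=f"non-positive timing {value}; default {default_s} s restored",
        )
    return SanitizedTiming(value, used_default=False)
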