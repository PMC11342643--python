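"""Content-based exercise recommendation and closed-loop difficulty control.

Each exercise is modelled by the skills it requires; the patient by a
per-skill ability score in [0, 1] updated after every session with an
exponentially weighted moving average of session success rates.  A scalar
difficulty index in [0, 1] summarises an exercise's task complexity,
stimulus size, and inter-stimulus interval.  The recommender closes the loop
around that index: it proposes the enabled exercise whose difficulty is
closest to the patient's aggregate ability plus a small margin (from above,
keeping the task slightly above the current level), and the chosen
exercise's parameters self-adjust one step easier whenever misses exceed
hits — so failure never escalates — and one step harder when the success
rate leaves the target band from above.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .config import DEFAULTS
from .errors import ConfigError, DomainError
from .exercises import (
    ExerciseParams,
    ExerciseResult,
    ExerciseSpec,
    StimulusStream,
    Tap,
    TaskKind,
    build_stimulus_stream,
    score_session,
)
from .geometry import GridSpec, Point, TreatmentArea

__all__ = [
    "AbilityModel",
    "Recommendation",
    "ComplianceRecord",
    "SessionRecord",
    "difficulty_index",
    "update_ability",
    "adjust_difficulty",
    "recommend_next",
    "run_selection_loop",
    "check_compliance",
    "rolling_success",
]

# Task-kind contribution to the difficulty ranking; figure complexity
# (solid < hollow < bold letters < plain letters) adds 0-3 on top.
_TASK_RANK = {
    TaskKind.DEMO: 0,
    TaskKind.FIGURE_SINGLE_FIXATION: 1,
    TaskKind.REAL_OBJECTS: 2,
    TaskKind.FACES: 3,
    TaskKind.FIGURE_ALTERNATING_FIXATION: 4,
    TaskKind.SCENE_SEARCH: 5,
    TaskKind.LETTER_LINES: 6,
}
_MAX_RANK = 9  # letter lines (6) at plain-letter complexity (3)


@dataclass(frozen=True)
class AbilityModel:
    """Per-skill patient ability in [0, 1] plus reaction-time tendencies."""

    abilities: dict = field(default_factory=dict)
    rt_mean_s: dict = field(default_factory=dict)
    rt_count: dict = field(default_factory=dict)
    prior: float = 0.5
    last_update: Optional[float] = None

    @classmethod
    def initial(cls, prior: float = 0.5, age: Optional[float] = None,
                visual_difficulties: Sequence[str] = ()) -> "AbilityModel":
        """Initial model; age and recorded visual difficulties only offset the prior."""
        p = prior
        if age is not None and age >= 75:
            p -= 0.05
        p -= 0.03 * len(tuple(visual_difficulties))
        return cls(prior=float(np.clip(p, 0.1, 0.9)))

    def ability(self, skill: str) -> float:
        return self.abilities.get(skill, self.prior)

    def aggregate_for(self, spec: ExerciseSpec) -> float:
        """Requirement-weighted mean of per-skill abilities for one exercise."""
        reqs = spec.skill_requirements
        if not reqs:
            return self.prior
        weights = np.array(list(reqs.values()), dtype=float)
        scores = np.array([self.ability(s) for s in reqs], dtype=float)
        return float(np.average(scores, weights=weights))

    def is_slow(self, skill: str, threshold_s: float = 1.5) -> bool:
        """Slow/fast tendency flag for a skill's mean reaction time."""
        return self.rt_mean_s.get(skill, 0.0) > threshold_s

    def to_dict(self) -> dict:
        return {
            "abilities": dict(self.abilities),
            "rt_mean_s": dict(self.rt_mean_s),
            "rt_count": dict(self.rt_count),
            "prior": self.prior,
            "last_update": self.last_update,
        }


@dataclass(frozen=True)
class Recommendation:
    spec: ExerciseSpec
    difficulty: float
    rationale: str  # "easier" | "harder" | "hold"

    def to_dict(self) -> dict:
        return {
            "spec_id": self.spec.id,
            "difficulty": self.difficulty,
            "rationale": self.rationale,
        }


@dataclass(frozen=True)
class ComplianceRecord:
    prescribed: int
    completed: int

    @property
    def alert(self) -> bool:
        return self.completed < self.prescribed

    def to_dict(self) -> dict:
        return {"prescribed": self.prescribed, "completed": self.completed, "alert": self.alert}


@dataclass(frozen=True)
class SessionRecord:
    """One entry of the selection-loop trace."""

    index: int
    skipped: bool = False
    recommendation: Optional[Recommendation] = None
    result: Optional[ExerciseResult] = None
    difficulty: Optional[float] = None
    model: Optional[AbilityModel] = None
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "skipped": self.skipped,
            "recommendation": self.recommendation.to_dict() if self.recommendation else None,
            "result": self.result.to_dict() if self.result else None,
            "difficulty": self.difficulty,
            "model": self.model.to_dict() if self.model else None,
            "error": self.error,
        }


def difficulty_index(spec: ExerciseSpec) -> float:
    """Scalar difficulty in [0, 1].

    Strictly increasing in the task/figure complexity rank and strictly
    decreasing in stimulus size and inter-stimulus interval (small, briefly
    spaced stimuli are harder to detect eccentrically).  The saturating
    1/(1+x) transforms keep the index bounded for any positive parameters.
    """
    rank = (_TASK_RANK[spec.task_kind] + spec.complexity_rank) / _MAX_RANK
    size_term = 1.0 / (1.0 + spec.params.stimulus_size_cm)
    interval_term = 1.0 / (1.0 + spec.params.inter_stimulus_s)
    return 0.5 * rank + 0.3 * size_term + 0.2 * interval_term


def update_ability(
    model: AbilityModel,
    result: ExerciseResult,
    spec: ExerciseSpec,
    config: Optional[dict] = None,
) -> AbilityModel:
    """Move every skill the exercise touches toward the session success rate.

    EWMA update ``a' = (1 - alpha) * a + alpha * s`` with the configured
    learning rate; reaction-time tendencies are updated as running means.
    A session with no scoreable targets leaves the model unchanged.
    """
    if result.spec_id != spec.id or result.version != spec.version:
        raise DomainError(
            f"result for exercise {result.spec_id} ({result.version}) does not match "
            f"spec {spec.id} ({spec.version})"
        )
    cfg = (config or DEFAULTS).get("recommender", DEFAULTS["recommender"])
    alpha = float(cfg.get("alpha", 0.3))
    s = result.success_rate
    if s is None:
        return model
    abilities = dict(model.abilities)
    rt_mean = dict(model.rt_mean_s)
    rt_count = dict(model.rt_count)
    session_rt = float(np.mean(result.reaction_times_s)) if result.reaction_times_s else None
    for skill in spec.skill_requirements:
        a = abilities.get(skill, model.prior)
        abilities[skill] = float(np.clip((1.0 - alpha) * a + alpha * s, 0.0, 1.0))
        if session_rt is not None:
            n = rt_count.get(skill, 0)
            rt_mean[skill] = (rt_mean.get(skill, 0.0) * n + session_rt) / (n + 1)
            rt_count[skill] = n + 1
    return AbilityModel(
        abilities=abilities,
        rt_mean_s=rt_mean,
        rt_count=rt_count,
        prior=model.prior,
        last_update=result.timestamp,
    )


def adjust_difficulty(
    spec: ExerciseSpec,
    result: ExerciseResult,
    config: Optional[dict] = None,
) -> ExerciseSpec:
    """Self-adjust one exercise after a session.

    More misses than hits: one step easier (larger stimuli, longer interval),
    so a frustrating session always lowers the difficulty index.  Success
    rate above the target band: one step harder.  Ties and in-band results
    leave the parameters unchanged.
    """
    if result.spec_id != spec.id:
        raise DomainError(f"result for exercise {result.spec_id} does not match spec {spec.id}")
    cfg = (config or DEFAULTS).get("recommender", DEFAULTS["recommender"])
    factor = float(cfg.get("step_factor", 1.5))
    band_high = float(cfg.get("band", [0.6, 0.8])[1])
    s = result.success_rate
    if result.misses > result.hits:
        new_params = dataclasses.replace(
            spec.params,
            stimulus_size_cm=spec.params.stimulus_size_cm * factor,
            inter_stimulus_s=spec.params.inter_stimulus_s * factor,
        )
        return dataclasses.replace(spec, params=new_params)
    if s is not None and s > band_high:
        new_params = dataclasses.replace(
            spec.params,
            stimulus_size_cm=spec.params.stimulus_size_cm / factor,
            inter_stimulus_s=spec.params.inter_stimulus_s / factor,
        )
        return dataclasses.replace(spec, params=new_params)
    return spec


def _last_played(history: Sequence[SessionRecord]) -> Optional[SessionRecord]:
    for rec in reversed(history):
        if not rec.skipped and rec.result is not None:
            return rec
    return None


def recommend_next(
    model: AbilityModel,
    enabled_specs: Sequence[ExerciseSpec],
    history: Sequence[SessionRecord] = (),
    config: Optional[dict] = None,
) -> Recommendation:
    """Pick the enabled exercise keeping difficulty slightly above ability.

    For each enabled exercise the target level is the requirement-weighted
    ability plus the margin delta; the chosen spec is the one whose
    difficulty index is closest to its target from above (or, if none lies
    above, the closest from below).  Ties break on the lower exercise id.
    Safety rule: after a session with more misses than hits the candidate
    set is restricted to difficulties at or below that session's, so failure
    can never escalate difficulty.
    """
    if not enabled_specs:
        raise ConfigError("the enabled exercise set is empty; the practitioner must enable exercises")
    cfg = (config or DEFAULTS).get("recommender", DEFAULTS["recommender"])
    delta = float(cfg.get("delta", 0.1))

    candidates = list(enabled_specs)
    last = _last_played(history)
    if last is not None and last.result.misses > last.result.hits:
        capped = [s for s in candidates if difficulty_index(s) <= last.difficulty + 1e-12]
        if capped:
            candidates = capped
        else:
            candidates = [min(candidates, key=lambda s: (difficulty_index(s), s.id))]

    def sort_key(s: ExerciseSpec):
        d = difficulty_index(s)
        gap = d - (model.aggregate_for(s) + delta)
        # prefer the smallest non-negative gap, then the least negative one
        return (0, gap, s.id) if gap >= 0 else (1, -gap, s.id)

    chosen = min(candidates, key=sort_key)
    d = difficulty_index(chosen)
    if last is None or last.difficulty is None:
        rationale = "hold"
    elif d < last.difficulty - 1e-12:
        rationale = "easier"
    elif d > last.difficulty + 1e-12:
        rationale = "harder"
    else:
        rationale = "hold"
    return Recommendation(spec=chosen, difficulty=d, rationale=rationale)


def run_selection_loop(
    model: AbilityModel,
    enabled_specs: Sequence[ExerciseSpec],
    responder: Callable[[StimulusStream, float, np.random.Generator], Sequence[Tap]],
    n_sessions: int,
    seed: int = 0,
    area: Optional[TreatmentArea] = None,
    grid: Optional[GridSpec] = None,
    config: Optional[dict] = None,
) -> list[SessionRecord]:
    """Automatic selection loop: recommend, execute, store, update.

    ``responder`` maps (stream, difficulty, rng) to a tap sequence; if it
    exposes an ``attends(rng)`` method, sessions it declines are recorded as
    skipped (compliance).  All randomness derives from ``seed``, so the full
    trace is reproducible.  A responder failure truncates the history with
    an error record.
    """
    if n_sessions < 1:
        raise ConfigError("n_sessions must be >= 1")
    area = area or TreatmentArea(center=Point(2.5, 0.0))
    grid = grid or GridSpec()
    cfg = config or DEFAULTS
    rng = np.random.default_rng(seed)
    enabled = {s.id: s for s in enabled_specs}
    history: list[SessionRecord] = []

    for i in range(n_sessions):
        attends = responder.attends(rng) if hasattr(responder, "attends") else True
        if not attends:
            history.append(SessionRecord(index=i, skipped=True))
            continue
        rec = recommend_next(model, list(enabled.values()), history, cfg)
        stream_seed = int(rng.integers(0, 2**31 - 1))
        stream = build_stimulus_stream(rec.spec, area, stream_seed, grid=grid, config=cfg)
        try:
            responses = responder(stream, rec.difficulty, rng)
        except Exception as exc:  # noqa: BLE001 - any responder failure truncates the loop
            history.append(SessionRecord(index=i, error=str(exc)))
            break
        result = score_session(stream, responses, timestamp=float(i))
        model = update_ability(model, result, rec.spec, cfg)
        enabled[rec.spec.id] = adjust_difficulty(rec.spec, result, cfg)
        history.append(
            SessionRecord(
                index=i,
                recommendation=rec,
                result=result,
                difficulty=rec.difficulty,
                model=model,
            )
        )
    return history


def check_compliance(
    history: Sequence[SessionRecord],
    prescribed: int,
    window: Optional[int] = None,
) -> ComplianceRecord:
    """Alert iff fewer sessions were completed than prescribed in the window."""
    if prescribed < 0:
        raise ConfigError("prescribed session count must be >= 0")
    recent = list(history)[-window:] if window else list(history)
    completed = sum(1 for r in recent if not r.skipped and r.result is not None)
    return ComplianceRecord(prescribed=prescribed, completed=completed)


def rolling_success(history: Sequence[SessionRecord], window: Optional[int] = None) -> list[float]:
    """Rolling mean session success rate over completed sessions."""
    w = window or int(DEFAULTS["recommender"]["rolling_window"])
    rates = [
        r.result.success_rate
        for r in history
        if not r.skipped and r.result is not None and r.result.success_rate is not None
    ]
    return [float(np.mean(rates[max(0, i + 1 - w): i + 1])) for i in range(len(rates))]
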