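"""Amsler-grid self-assessment: plan, run, score, and map scotomas.

A full test presents 50 red-dot stimuli (3 s display, 3 s left to respond)
at 50 distinct cells of the 20x20 one-degree lattice, chosen by stratified
random sampling so the whole field is covered reproducibly.  A follow-up
test halves the stimulus count (rounded up) and restricts placement to the
environment of the previously mapped scotoma — cells within a configurable
Chebyshev distance of any missed cell — shortening the test from five
minutes to two or three.

Scotoma maps are strictly per-cell: a cell is ``missed`` or ``seen``
according to the most recent stimulus presented there and ``untested``
otherwise, so the map is always traceable to actual responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .config import DEFAULTS
from .errors import AbortedTestError, ConfigError, DomainError
from .geometry import GridSpec, Point

__all__ = [
    "StimulusEvent",
    "TestPlan",
    "StimulusOutcome",
    "TestResult",
    "ScotomaMap",
    "build_test_plan",
    "test_duration",
    "run_test",
    "estimate_scotoma",
    "delete_result",
    "jaccard",
]

Cell = tuple[int, int]


@dataclass(frozen=True)
class StimulusEvent:
    """One red-dot presentation: where, for how long, and the response window."""

    position: Point
    display_s: float = 3.0
    response_window_s: float = 3.0
    index: int = 0

    def __post_init__(self):
        if self.display_s <= 0:
            raise ConfigError(f"display_s must be positive, got {self.display_s}")
        if self.response_window_s < 0:
            raise ConfigError(f"response_window_s must be >= 0, got {self.response_window_s}")

    @property
    def window_s(self) -> float:
        return self.display_s + self.response_window_s

    def to_dict(self) -> dict:
        return {
            "position": self.position.to_dict(),
            "display_s": self.display_s,
            "response_window_s": self.response_window_s,
            "index": self.index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusEvent":
        return cls(
            Point.from_dict(d["position"]),
            float(d["display_s"]),
            float(d["response_window_s"]),
            int(d["index"]),
        )


@dataclass(frozen=True)
class TestPlan:
    """Ordered stimulus schedule for one test."""

    grid: GridSpec
    mode: str
    stimuli: tuple[StimulusEvent, ...]
    seed: int
    restriction_region: Optional[frozenset[Cell]] = None

    def cells(self) -> list[Cell]:
        return [self.grid.cell_of(ev.position) for ev in self.stimuli]

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "mode": self.mode,
            "seed": self.seed,
            "stimuli": [ev.to_dict() for ev in self.stimuli],
            "restriction_region": (
                sorted(list(c) for c in self.restriction_region)
                if self.restriction_region is not None
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TestPlan":
        region = d.get("restriction_region")
        return cls(
            grid=GridSpec.from_dict(d["grid"]),
            mode=d["mode"],
            stimuli=tuple(StimulusEvent.from_dict(e) for e in d["stimuli"]),
            seed=int(d["seed"]),
            restriction_region=(
                frozenset((int(r), int(c)) for r, c in region) if region is not None else None
            ),
        )


@dataclass(frozen=True)
class StimulusOutcome:
    seen: bool
    reaction_time_s: Optional[float] = None

    def to_dict(self) -> dict:
        return {"seen": self.seen, "rt_s": self.reaction_time_s}


@dataclass(frozen=True)
class TestResult:
    """Per-stimulus seen/missed outcomes aligned 1:1 with the plan."""

    plan: TestPlan
    outcomes: tuple[StimulusOutcome, ...]
    eye: str = "OU"
    timestamp: float = 0.0
    patient_id: Optional[str] = None
    result_id: Optional[str] = None

    def __post_init__(self):
        if len(self.outcomes) != len(self.plan.stimuli):
            raise DomainError(
                f"{len(self.outcomes)} outcomes do not align with "
                f"{len(self.plan.stimuli)} planned stimuli"
            )
        for ev, out in zip(self.plan.stimuli, self.outcomes):
            if out.seen and out.reaction_time_s is not None and out.reaction_time_s > ev.window_s:
                raise DomainError("seen outcome with reaction time beyond the response window")

    @property
    def n_seen(self) -> int:
        return sum(1 for o in self.outcomes if o.seen)

    @property
    def n_missed(self) -> int:
        return len(self.outcomes) - self.n_seen

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "eye": self.eye,
            "timestamp": self.timestamp,
            "result_id": self.result_id,
            "seed": self.plan.seed,
            "mode": self.plan.mode,
            "grid": self.plan.grid.to_dict(),
            "stimuli": [
                {
                    "x_cm": ev.position.x_cm,
                    "y_cm": ev.position.y_cm,
                    "display_s": ev.display_s,
                    "response_window_s": ev.response_window_s,
                    "seen": out.seen,
                    "rt_s": out.reaction_time_s,
                }
                for ev, out in zip(self.plan.stimuli, self.outcomes)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TestResult":
        grid = GridSpec.from_dict(d["grid"])
        stimuli = tuple(
            StimulusEvent(
                Point(float(s["x_cm"]), float(s["y_cm"])),
                float(s.get("display_s", 3.0)),
                float(s.get("response_window_s", 3.0)),
                i,
            )
            for i, s in enumerate(d["stimuli"])
        )
        plan = TestPlan(grid=grid, mode=d.get("mode", "full"), stimuli=stimuli, seed=int(d.get("seed", 0)))
        outcomes = tuple(
            StimulusOutcome(bool(s["seen"]), s.get("rt_s")) for s in d["stimuli"]
        )
        return cls(
            plan=plan,
            outcomes=outcomes,
            eye=d.get("eye", "OU"),
            timestamp=float(d.get("timestamp", 0.0)),
            patient_id=d.get("patient_id"),
            result_id=d.get("result_id"),
        )


@dataclass(frozen=True)
class ScotomaMap:
    """Per-cell detection status derived from one or more test results."""

    grid: GridSpec
    status: dict  # Cell -> "missed" | "seen"
    sources: tuple = ()

    def status_of(self, cell: Cell) -> str:
        return self.status.get(cell, "untested")

    @property
    def missed_cells(self) -> frozenset[Cell]:
        return frozenset(c for c, s in self.status.items() if s == "missed")

    @property
    def seen_cells(self) -> frozenset[Cell]:
        return frozenset(c for c, s in self.status.items() if s == "seen")

    @property
    def n_missed(self) -> int:
        return len(self.missed_cells)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "missed": sorted(list(c) for c in self.missed_cells),
            "seen": sorted(list(c) for c in self.seen_cells),
            "sources": list(self.sources),
        }


def _stratified_cells(grid: GridSpec, n: int, rng: np.random.Generator) -> list[Cell]:
    """Sample ``n`` distinct cells, roughly evenly across a b x b partition of the grid."""
    total = grid.n_cells
    if n > total:
        raise ConfigError(f"cannot place {n} distinct stimuli on {total} cells")
    b = max(1, math.isqrt(max(1, n // 2)))
    row_groups = np.array_split(np.arange(grid.n_rows), min(b, grid.n_rows))
    col_groups = np.array_split(np.arange(grid.n_cols), min(b, grid.n_cols))
    strata: list[list[Cell]] = [
        [(int(r), int(c)) for r in rg for c in cg] for rg in row_groups for cg in col_groups
    ]
    base, rem = divmod(n, len(strata))
    extra = (
        set(rng.choice(len(strata), size=rem, replace=False).tolist()) if rem else set()
    )
    chosen: list[Cell] = []
    leftover: list[Cell] = []
    for i, stratum in enumerate(strata):
        k = base + (1 if i in extra else 0)
        if k >= len(stratum):
            chosen.extend(stratum)
        else:
            idx = sorted(rng.choice(len(stratum), size=k, replace=False).tolist())
            picked = set(idx)
            chosen.extend(stratum[j] for j in idx)
            leftover.extend(s for j, s in enumerate(stratum) if j not in picked)
    deficit = n - len(chosen)
    if deficit > 0:
        idx = sorted(rng.choice(len(leftover), size=deficit, replace=False).tolist())
        chosen.extend(leftover[j] for j in idx)
    order = rng.permutation(len(chosen))
    return [chosen[i] for i in order]


def _environment(missed: Iterable[Cell], grid: GridSpec, radius: int) -> set[Cell]:
    """Cells within Chebyshev distance ``radius`` of any missed cell."""
    env: set[Cell] = set()
    for r, c in missed:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                    env.add((rr, cc))
    return env


def build_test_plan(
    grid: GridSpec,
    mode: str = "full",
    seed: int = 0,
    prior_scotoma: Optional[ScotomaMap] = None,
    config: Optional[dict] = None,
) -> TestPlan:
    """Build a seeded stimulus schedule.

    ``full`` mode samples the configured stimulus count (default 50) as
    distinct cells stratified over the whole grid.  ``followup`` mode halves
    the count (rounded up) and samples only from the environment of the
    prior scotoma, expanding the neighbourhood radius if that region is too
    small to hold the requested number of distinct stimuli.
    """
    cfg = (config or DEFAULTS).get("amsler", DEFAULTS["amsler"])
    n_full = int(cfg.get("n_stimuli_full", 50))
    display_s = float(cfg.get("display_s", 3.0))
    response_window_s = float(cfg.get("response_window_s", 3.0))
    rng = np.random.default_rng(seed)

    restriction: Optional[frozenset[Cell]] = None
    if mode == "full":
        cells = _stratified_cells(grid, n_full, rng)
    elif mode == "followup":
        if prior_scotoma is None or not prior_scotoma.missed_cells:
            raise ConfigError("followup mode requires a prior scotoma with at least one missed cell")
        n = math.ceil(n_full * float(cfg.get("followup_fraction", 0.5)))
        radius = int(cfg.get("environment_chebyshev", 2))
        region = _environment(prior_scotoma.missed_cells, grid, radius)
        while len(region) < n and len(region) < grid.n_cells:
            radius += 1
            region = _environment(prior_scotoma.missed_cells, grid, radius)
        restriction = frozenset(region)
        ordered = sorted(region)
        idx = rng.choice(len(ordered), size=min(n, len(ordered)), replace=False)
        cells = [ordered[i] for i in idx]
    else:
        raise ConfigError(f"unknown test mode {mode!r}")

    stimuli = tuple(
        StimulusEvent(grid.cell_center(r, c), display_s, response_window_s, i)
        for i, (r, c) in enumerate(cells)
    )
    return TestPlan(grid=grid, mode=mode, stimuli=stimuli, seed=seed, restriction_region=restriction)


def test_duration(plan: TestPlan) -> float:
    """Total scheduled test time in seconds (display plus response window per stimulus)."""
    return float(sum(ev.window_s for ev in plan.stimuli))


def run_test(
    plan: TestPlan,
    responder: Callable[[StimulusEvent], tuple[bool, Optional[float]]],
    eye: str = "OU",
    patient_id: Optional[str] = None,
    timestamp: float = 0.0,
) -> TestResult:
    """Present every stimulus to ``responder`` and collect outcomes in plan order.

    A response whose reaction time exceeds the display-plus-response window is
    recorded as missed.  If the responder raises, the test aborts and the
    partial result so far is attached to the :class:`AbortedTestError`.
    """
    outcomes: list[StimulusOutcome] = []
    for ev in plan.stimuli:
        try:
            seen, rt = responder(ev)
        except Exception as exc:
            partial = TestResult(
                plan=replace(plan, stimuli=plan.stimuli[: len(outcomes)]),
                outcomes=tuple(outcomes),
                eye=eye,
                timestamp=timestamp,
                patient_id=patient_id,
            )
            raise AbortedTestError(
                f"responder failed at stimulus {ev.index}: {exc}", partial_result=partial
            ) from exc
        if seen and rt is not None and rt > ev.window_s:
            seen = False
        outcomes.append(StimulusOutcome(bool(seen), rt if seen else None))
    return TestResult(
        plan=plan, outcomes=tuple(outcomes), eye=eye, timestamp=timestamp, patient_id=patient_id
    )


def estimate_scotoma(
    results: Sequence[TestResult] | TestResult,
    grid: Optional[GridSpec] = None,
) -> ScotomaMap:
    """Pool one or more test results into a per-cell scotoma map.

    When a cell was stimulated more than once, the most recent outcome wins
    (results are ordered by timestamp, ties keeping input order), so repeated
    testing tracks changes and progression of the visual loss.
    """
    if isinstance(results, TestResult):
        results = [results]
    if not results:
        raise DomainError("estimate_scotoma needs at least one result")
    grid = grid or results[0].plan.grid
    for res in results:
        if res.plan.grid != grid:
            raise DomainError("results use mixed grid specifications")
    status: dict[Cell, str] = {}
    for res in sorted(results, key=lambda r: r.timestamp):
        for ev, out in zip(res.plan.stimuli, res.outcomes):
            status[grid.cell_of(ev.position)] = "seen" if out.seen else "missed"
    sources = tuple(r.result_id for r in results if r.result_id is not None)
    return ScotomaMap(grid=grid, status=status, sources=sources)


def delete_result(store, result_id: str, actor_role) -> dict:
    """Delete a stored test result; only the practitioner role may do so.

    Thin role-gated front door over any record store exposing
    ``delete_result(result_id, actor_role)``.
    """
    return store.delete_result(result_id, actor_role)


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index between two cell sets (1.0 when both are empty)."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)
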