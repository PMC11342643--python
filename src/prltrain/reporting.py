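"""Progress and evolution reports derived purely from stored records.

A report aggregates, per exercise, the chronological hit/miss series, the
evolution of the scotoma (missed-cell count after each pooled test), and a
compliance summary.  Nothing outside the record store enters the report, so
re-running it over the same store always reproduces the same numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .amsler import TestResult, estimate_scotoma
from .exercises import ExerciseResult
from .records import PatientStore

__all__ = ["ProgressReport", "build_report"]


@dataclass(frozen=True)
class ProgressReport:
    patient_id: str
    exercise_series: dict  # spec_id -> list of {timestamp, hits, misses, attempts}
    scotoma_series: list   # chronological {timestamp, n_missed}
    compliance: dict       # {completed_sessions, completed_tests}

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "exercise_series": {str(k): v for k, v in self.exercise_series.items()},
            "scotoma_series": list(self.scotoma_series),
            "compliance": dict(self.compliance),
        }


def build_report(store: PatientStore, patient_id: str) -> ProgressReport:
    """Chronological per-exercise series plus scotoma evolution for one patient.

    The scotoma series pools all tests up to each timestamp (recency rule),
    so its entries track how the mapped loss grows or shrinks over time.
    An empty store yields a valid, empty report.
    """
    store.get_patient(patient_id)  # not-found check
    exercise_series: dict[int, list] = {}
    test_results: list[TestResult] = []

    for record in store.results_for(patient_id):
        payload = record.payload
        if isinstance(payload, ExerciseResult):
            exercise_series.setdefault(payload.spec_id, []).append(
                {
                    "timestamp": payload.timestamp,
                    "hits": payload.hits,
                    "misses": payload.misses,
                    "attempts": payload.attempts,
                }
            )
        elif isinstance(payload, TestResult):
            test_results.append(payload)

    for series in exercise_series.values():
        series.sort(key=lambda row: row["timestamp"])
    test_results.sort(key=lambda r: r.timestamp)

    scotoma_series = []
    for i in range(len(test_results)):
        pooled = estimate_scotoma(test_results[: i + 1])
        scotoma_series.append(
            {"timestamp": test_results[i].timestamp, "n_missed": pooled.n_missed}
        )

    compliance = {
        "completed_sessions": sum(len(v) for v in exercise_series.values()),
        "completed_tests": len(test_results),
    }
    return ProgressReport(
        patient_id=patient_id,
        exercise_series=exercise_series,
        scotoma_series=scotoma_series,
        compliance=compliance,
    )
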