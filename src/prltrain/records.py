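"""Role-gated patient/practitioner accounts and result storage.

The store models the application's account structure: each practitioner
manages many patients, each patient belongs to exactly one practitioner and
is created with a unique numeric registration code.  Treatment-area
coordinates, the enabled exercise set, and per-exercise parameter overrides
are mutable only through practitioner-role operations, and every
treatment-area change is appended to an audit history.  Results created
locally carry a ``sync_pending`` flag until exported ("uploaded"); export is
atomic — a failed write clears no flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .amsler import TestResult
from .errors import ConfigError, NotFoundError, PermissionDeniedError
from .exercises import PRACTITIONER_ADJUSTABLE_PARAMS, ExerciseResult
from .geometry import TreatmentArea

__all__ = [
    "Role",
    "PractitionerAccount",
    "PatientProfile",
    "PatientAccount",
    "StoredRecord",
    "PatientStore",
]


class Role(str, Enum):
    PRACTITIONER = "practitioner"
    PATIENT = "patient"


def _require_practitioner(actor_role: Role | str, operation: str) -> None:
    role = Role(actor_role)
    if role is not Role.PRACTITIONER:
        raise PermissionDeniedError(f"only the practitioner can {operation}")


@dataclass
class PractitionerAccount:
    id: str
    credentials_hash: str = "<unset>"
    patient_ids: list = field(default_factory=list)


@dataclass
class PatientProfile:
    age: Optional[float] = None
    visual_difficulties: list = field(default_factory=list)
    treatment_area: Optional[TreatmentArea] = None
    eye_mode: str = "binocular"
    enabled_exercise_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "age": self.age,
            "visual_difficulties": list(self.visual_difficulties),
            "treatment_area": self.treatment_area.to_dict() if self.treatment_area else None,
            "eye_mode": self.eye_mode,
            "enabled_exercise_ids": list(self.enabled_exercise_ids),
        }


@dataclass
class PatientAccount:
    id: str
    registration_code: str
    practitioner_id: str
    profile: PatientProfile
    area_audit: list = field(default_factory=list)  # chronological TreatmentArea history
    param_overrides: dict = field(default_factory=dict)  # exercise id -> {param: value}

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "registration_code": self.registration_code,
            "practitioner_id": self.practitioner_id,
            "profile": self.profile.to_dict(),
            "area_audit": [a.to_dict() for a in self.area_audit],
            "param_overrides": {str(k): dict(v) for k, v in self.param_overrides.items()},
        }


@dataclass
class StoredRecord:
    record_id: str
    patient_id: str
    payload: TestResult | ExerciseResult
    sync_pending: bool = True

    @property
    def kind(self) -> str:
        return "test" if isinstance(self.payload, TestResult) else "exercise"

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "patient_id": self.patient_id,
            "kind": self.kind,
            "sync_pending": self.sync_pending,
            "payload": self.payload.to_dict(),
        }


class PatientStore:
    """In-memory account and record store with optional JSON persistence.

    ``root`` (if given) receives a directory tree of JSON documents:
    ``patients/<id>/profile.json``, ``patients/<id>/tests/<record>.json`` and
    ``patients/<id>/exercises/records.jsonl``.
    """

    def __init__(self, root: Optional[Path | str] = None, seed: int = 0):
        self.root = Path(root) if root is not None else None
        self._rng = np.random.default_rng(seed)
        self.practitioners: dict[str, PractitionerAccount] = {}
        self.patients: dict[str, PatientAccount] = {}
        self.records: dict[str, StoredRecord] = {}
        self._counter = 0

    # -- accounts ---------------------------------------------------------

    def add_practitioner(self, practitioner_id: str) -> PractitionerAccount:
        account = PractitionerAccount(id=practitioner_id)
        self.practitioners[practitioner_id] = account
        return account

    def _new_code(self) -> str:
        for _ in range(10_000):
            code = f"{self._rng.integers(0, 1_000_000):06d}"
            if all(p.registration_code != code for p in self.patients.values()):
                return code
        raise ConfigError("could not generate a unique registration code")

    def create_patient(self, practitioner_id: str, profile: PatientProfile) -> PatientAccount:
        """Create a patient linked to exactly one practitioner, with a unique
        6-digit registration code.  The profile must carry a treatment area."""
        if practitioner_id not in self.practitioners:
            raise NotFoundError(f"unknown practitioner {practitioner_id!r}")
        if profile.treatment_area is None:
            raise ConfigError("patient profile must include a treatment area")
        self._counter += 1
        patient_id = f"p{self._counter:04d}"
        account = PatientAccount(
            id=patient_id,
            registration_code=self._new_code(),
            practitioner_id=practitioner_id,
            profile=profile,
            area_audit=[profile.treatment_area],
        )
        self.patients[patient_id] = account
        self.practitioners[practitioner_id].patient_ids.append(patient_id)
        self._persist_patient(account)
        return account

    def get_patient(self, patient_id: str) -> PatientAccount:
        if patient_id not in self.patients:
            raise NotFoundError(f"unknown patient {patient_id!r}")
        return self.patients[patient_id]

    # -- practitioner-only mutations -------------------------------------

    def set_treatment_area(
        self, patient_id: str, area: TreatmentArea, actor_role: Role | str
    ) -> PatientAccount:
        """Update the treatment area (practitioner only); every change — even a
        no-op — is appended to the audit history of the area's evolution."""
        _require_practitioner(actor_role, "modify the treatment area")
        account = self.get_patient(patient_id)
        account.profile.treatment_area = area
        account.area_audit.append(area)
        self._persist_patient(account)
        return account

    def set_enabled_exercises(
        self, patient_id: str, exercise_ids: Sequence[int], actor_role: Role | str
    ) -> PatientAccount:
        _require_practitioner(actor_role, "change the enabled exercise set")
        account = self.get_patient(patient_id)
        account.profile.enabled_exercise_ids = list(exercise_ids)
        self._persist_patient(account)
        return account

    def set_exercise_params(
        self, patient_id: str, exercise_id: int, params: dict, actor_role: Role | str
    ) -> PatientAccount:
        """Override presentation parameters for one exercise (practitioner only);
        only the practitioner-adjustable parameters are accepted."""
        _require_practitioner(actor_role, "adjust exercise parameters")
        unknown = set(params) - PRACTITIONER_ADJUSTABLE_PARAMS
        if unknown:
            raise ConfigError(f"parameters not practitioner-adjustable: {sorted(unknown)}")
        account = self.get_patient(patient_id)
        account.param_overrides.setdefault(exercise_id, {}).update(params)
        self._persist_patient(account)
        return account

    # -- results ----------------------------------------------------------

    def add_result(self, patient_id: str, payload: TestResult | ExerciseResult) -> StoredRecord:
        self.get_patient(patient_id)
        self._counter += 1
        record = StoredRecord(record_id=f"r{self._counter:05d}", patient_id=patient_id, payload=payload)
        self.records[record.record_id] = record
        self._persist_record(record)
        return record

    def results_for(self, patient_id: str, kind: Optional[str] = None) -> list[StoredRecord]:
        self.get_patient(patient_id)
        out = [r for r in self.records.values() if r.patient_id == patient_id]
        if kind is not None:
            out = [r for r in out if r.kind == kind]
        return sorted(out, key=lambda r: r.record_id)

    def delete_result(self, result_id: str, actor_role: Role | str) -> dict:
        """Delete a failed result; only the practitioner role may."""
        _require_practitioner(actor_role, "delete results")
        if result_id not in self.records:
            raise NotFoundError(f"unknown result {result_id!r}")
        record = self.records.pop(result_id)
        return {"deleted": result_id, "patient_id": record.patient_id}

    # -- export / sync -----------------------------------------------------

    @property
    def pending_records(self) -> list[StoredRecord]:
        return sorted(
            (r for r in self.records.values() if r.sync_pending), key=lambda r: r.record_id
        )

    def export_records(self, destination: Path | str) -> dict:
        """Serialize all sync-pending records to ``destination`` and clear
        their flags.  Atomic: if the write fails, no flag is cleared."""
        pending = self.pending_records
        manifest = {
            "n_records": len(pending),
            "record_ids": [r.record_id for r in pending],
        }
        destination = Path(destination)
        payload = json.dumps(
            {"manifest": manifest, "records": [r.to_dict() for r in pending]},
            indent=2, sort_keys=True,
        )
        destination.parent.mkdir(parents=True, exist_ok=True)
        destination.write_text(payload)  # raises before any flag is touched
        for r in pending:
            r.sync_pending = False
        return manifest

    # -- persistence -------------------------------------------------------

    def _persist_patient(self, account: PatientAccount) -> None:
        if self.root is None:
            return
        pdir = self.root / "patients" / account.id
        pdir.mkdir(parents=True, exist_ok=True)
        (pdir / "profile.json").write_text(json.dumps(account.to_dict(), indent=2, sort_keys=True))

    def _persist_record(self, record: StoredRecord) -> None:
        if self.root is None:
            return
        pdir = self.root / "patients" / record.patient_id
        if record.kind == "test":
            tdir = pdir / "tests"
            tdir.mkdir(parents=True, exist_ok=True)
            (tdir / f"{record.record_id}.json").write_text(
                json.dumps(record.to_dict(), indent=2, sort_keys=True)
            )
        else:
            pdir.mkdir(parents=True, exist_ok=True)
            with (pdir / "exercises.jsonl").open("a") as fh:
                fh.write(json.dumps(record.to_dict(), sort_keys=True) + "\n")
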