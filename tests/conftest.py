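import pytest

from prltrain import (
    GridSpec,
    PatientProfile,
    PatientStore,
    Point,
    TreatmentArea,
    make_patient,
)


@pytest.fixture
def grid():
    return GridSpec()


@pytest.fixture
def area():
    return TreatmentArea(center=Point(2.5, 0.0), extent_cm=1.0)


@pytest.fixture
def deterministic_patient():
    """Hard-edged 3x3 scotoma, perfect detection outside, none inside."""
    return make_patient(
        {"simulator": {"p_detect_inside": 0.0, "p_detect_outside": 1.0}}, seed=7
    )


@pytest.fixture
def true_block():
    """Cells of the default simulated scotoma (rows 5-7, cols 11-13)."""
    return frozenset((r, c) for r in range(5, 8) for c in range(11, 14))


@pytest.fixture
def store(tmp_path):
    s = PatientStore(tmp_path / "store", seed=0)
    s.add_practitioner("dr-a")
    return s


@pytest.fixture
def patient_account(store, area):
    return store.create_patient("dr-a", PatientProfile(age=68, treatment_area=area))
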