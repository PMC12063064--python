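from __future__ import annotations

import pytest

from wavelpr.cohort_io import (
    Event,
    PatientRecord,
    PrimaryLocation,
    Sex,
    Timing,
)


def make_patient(
    patient_id: str,
    timing: str = "synchronous",
    months_to_mets: float = 0.0,
    followup_from_mets: float = 10.0,
    event: str = "died",
    sex: str = "female",
    location: str = "head",
) -> PatientRecord:
    """Compact PatientRecord builder for tests."""
    return PatientRecord(
        patient_id=patient_id,
        sex=Sex(sex),
        primary_location=PrimaryLocation(location),
        timing=Timing(timing),
        months_primary_to_mets=months_to_mets,
        followup_from_primary_months=months_to_mets + followup_from_mets,
        followup_from_mets_months=followup_from_mets,
        event=Event(event),
    )


@pytest.fixture
def toy_cohort_files(tmp_path):
    """A tiny two-patient cohort written as canonical CSVs."""
    mets = tmp_path / "metastases.csv"
    pats = tmp_path / "patients.csv"
    mets.write_text(
        "patient_id,organ,diameter_mm\n"
        "P1,lung,6.5\n"
        "P1,lung,7.5\n"
        "P1,lung,12.0\n"
        "P2,liver,16.0\n"
        "P2,liver,17.0\n"
        "P2,liver,30.0\n"
    )
    pats.write_text(
        "patient_id,sex,primary_location,timing,months_primary_to_mets,"
        "followup_from_primary_months,event\n"
        "P1,female,head,synchronous,0,8,died\n"
        "P2,male,tail,metachronous,7.5,15.5,censored\n"
    )
    return mets, pats
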