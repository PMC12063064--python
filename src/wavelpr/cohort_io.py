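"""Tabular schemas and I/O for metastatic-cohort data.

Two delimited text tables describe a cohort:

* the **metastases table** — one row per measured metastasis
  (``patient_id``, ``organ``, ``diameter_mm``), and
* the **patients table** — one row per patient
  (``patient_id``, ``sex``, ``primary_location``, ``timing``,
  ``months_primary_to_mets``, ``followup_from_primary_months``, ``event``).

Diameters are largest axial diameters in millimetres, stored at 0.1 mm
precision.  All time intervals are in months; calendar dates are never
ingested — the data preparer (or the simulator) supplies precomputed
intervals.  ``followup_from_mets_months`` is derived as
``followup_from_primary_months - months_primary_to_mets`` and must be
non-negative.

Reading is validating: rows that violate an invariant are rejected with a
reason, never silently dropped, and ``accepted + rejected == input`` always
holds.  A column-mapping dict adapts externally named layouts to the
canonical schema without code change.
"""

from __future__ import annotations

import json
import math
from collections import OrderedDict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class Organ(str, Enum):
    LUNG = "lung"
    LIVER = "liver"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class PrimaryLocation(str, Enum):
    HEAD = "head"
    BODY = "body"
    TAIL = "tail"


class Timing(str, Enum):
    SYNCHRONOUS = "synchronous"
    METACHRONOUS = "metachronous"


class Event(str, Enum):
    DIED = "died"
    CENSORED = "censored"


METASTASIS_COLUMNS = ("patient_id", "organ", "diameter_mm")
PATIENT_COLUMNS = (
    "patient_id",
    "sex",
    "primary_location",
    "timing",
    "months_primary_to_mets",
    "followup_from_primary_months",
    "event",
)

#: diameters are stored at this decimal precision (0.1 mm)
DIAMETER_DECIMALS = 1
#: tolerance for the additivity check on month intervals (half a month unit,
#: since source intervals may have been rounded to whole months)
MONTH_TOLERANCE = 0.5


class SchemaError(ValueError):
    """A required column is missing or a file is structurally unreadable."""


@dataclass(frozen=True)
class MetastasisRecord:
    """One measured metastasis: largest diameter of one lesion in one organ."""

    patient_id: str
    organ: Organ
    diameter_mm: float


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics, metastasis timing and follow-up."""

    patient_id: str
    sex: Sex
    primary_location: PrimaryLocation
    timing: Timing
    months_primary_to_mets: float
    followup_from_primary_months: float
    followup_from_mets_months: float
    event: Event


@dataclass(frozen=True)
class MetastasisSet:
    """All measured diameters for one (patient, organ) pair.

    Multiset semantics: duplicate diameters are allowed and meaningful —
    identical diameters are the strongest wave signal.
    """

    patient_id: str
    organ: Organ
    diameters: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.diameters) < 1:
            raise ValueError("MetastasisSet requires at least one diameter")
        if any(d <= 0 or not math.isfinite(d) for d in self.diameters):
            raise ValueError("diameters must be positive and finite")


@dataclass(frozen=True)
class RejectedRow:
    """A row that failed validation; ``line`` is the 1-based data-row number."""

    table: str
    line: int
    reason: str


def _read_table(
    path: str | Path,
    required: Sequence[str],
    delimiter: str,
    column_map: Mapping[str, str] | None,
) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={v.strip().lower(): k for k, v in column_map.items()})
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}' in {path}")
    return df


def _parse_enum(token: str, enum: type[Enum], what: str) -> Enum:
    try:
        return enum(str(token).strip().lower())
    except ValueError:
        allowed = "/".join(e.value for e in enum)
        raise ValueError(f"unknown {what} '{token}' (expected {allowed})")


def _parse_number(token: object, what: str) -> float:
    try:
        value = float(token)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric {what} '{token}'")
    if not math.isfinite(value):
        raise ValueError(f"non-finite {what} '{token}'")
    return value


def parse_patient_row(row: Mapping[str, object]) -> PatientRecord:
    """Validate one patients-table row; raises ``ValueError`` with a reason."""
    pid = str(row["patient_id"]).strip()
    if not pid or pid.lower() == "nan":
        raise ValueError("empty patient_id")
    sex = _parse_enum(str(row["sex"]), Sex, "sex")
    loc = _parse_enum(str(row["primary_location"]), PrimaryLocation, "primary_location")
    timing = _parse_enum(str(row["timing"]), Timing, "timing")
    m2m = _parse_number(row["months_primary_to_mets"], "months_primary_to_mets")
    fup = _parse_number(row["followup_from_primary_months"], "followup_from_primary_months")
    event = _parse_enum(str(row["event"]), Event, "event")
    if m2m < 0:
        raise ValueError("negative months_primary_to_mets")
    if fup < 0:
        raise ValueError("negative followup_from_primary_months")
    if timing is Timing.SYNCHRONOUS and m2m > MONTH_TOLERANCE:
        raise ValueError("synchronous patient with nonzero months_primary_to_mets")
    if timing is Timing.SYNCHRONOUS:
        m2m = 0.0
    from_mets = round(fup - m2m, 6)  # scrub float noise from the subtraction
    if from_mets < -MONTH_TOLERANCE:
        raise ValueError("followup_from_primary_months shorter than months_primary_to_mets")
    return PatientRecord(
        patient_id=pid,
        sex=sex,  # type: ignore[arg-type]
        primary_location=loc,  # type: ignore[arg-type]
        timing=timing,  # type: ignore[arg-type]
        months_primary_to_mets=m2m,
        followup_from_primary_months=fup,
        followup_from_mets_months=max(from_mets, 0.0),
        event=event,  # type: ignore[arg-type]
    )


def parse_metastasis_row(row: Mapping[str, object]) -> MetastasisRecord:
    """Validate one metastases-table row; raises ``ValueError`` with a reason."""
    pid = str(row["patient_id"]).strip()
    if not pid or pid.lower() == "nan":
        raise ValueError("empty patient_id")
    organ = _parse_enum(str(row["organ"]), Organ, "organ")
    diameter = _parse_number(row["diameter_mm"], "diameter")
    if diameter <= 0:
        raise ValueError("non-positive diameter")
    return MetastasisRecord(
        patient_id=pid,
        organ=organ,  # type: ignore[arg-type]
        diameter_mm=round(diameter, DIAMETER_DECIMALS),
    )


def read_cohort(
    metastases_table: str | Path,
    patients_table: str | Path,
    *,
    delimiter: str = ",",
    metastasis_column_map: Mapping[str, str] | None = None,
    patient_column_map: Mapping[str, str] | None = None,
) -> tuple[list[MetastasisRecord], list[PatientRecord], list[RejectedRow]]:
    """Read and validate the two cohort tables.

    Returns accepted metastasis records (file order), accepted patient
    records (file order) and the list of rejected rows with reasons.
    Metastases whose ``patient_id`` has no accepted patient row are rejected
    as orphans.  A missing required column raises :class:`SchemaError`.
    """
    pat_df = _read_table(patients_table, PATIENT_COLUMNS, delimiter, patient_column_map)
    met_df = _read_table(metastases_table, METASTASIS_COLUMNS, delimiter, metastasis_column_map)

    rejects: list[RejectedRow] = []
    patients: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(pat_df.to_dict("records"), start=1):
        try:
            rec = parse_patient_row(row)
            if rec.patient_id in seen:
                raise ValueError(f"duplicate patient_id '{rec.patient_id}'")
            seen.add(rec.patient_id)
            patients.append(rec)
        except ValueError as exc:
            rejects.append(RejectedRow("patients", i, str(exc)))

    metastases: list[MetastasisRecord] = []
    for i, row in enumerate(met_df.to_dict("records"), start=1):
        try:
            rec = parse_metastasis_row(row)
            if rec.patient_id not in seen:
                raise ValueError(f"orphan metastasis: patient_id '{rec.patient_id}' not in patients table")
            metastases.append(rec)
        except ValueError as exc:
            rejects.append(RejectedRow("metastases", i, str(exc)))

    return metastases, patients, rejects


def group_by_patient_organ(records: Iterable[MetastasisRecord]) -> list[MetastasisSet]:
    """Group validated metastasis records into per-(patient, organ) sets.

    Output is sorted by ``patient_id`` then organ name; the sum of set sizes
    equals the number of input records.
    """
    groups: "OrderedDict[tuple[str, Organ], list[float]]" = OrderedDict()
    for rec in records:
        groups.setdefault((rec.patient_id, rec.organ), []).append(rec.diameter_mm)
    return [
        MetastasisSet(pid, organ, tuple(diams))
        for (pid, organ), diams in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
    ]


def metastases_frame(records: Iterable[MetastasisRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patient_id, r.organ.value, f"{r.diameter_mm:.1f}") for r in records],
        columns=list(METASTASIS_COLUMNS),
    )


def patients_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.patient_id,
                r.sex.value,
                r.primary_location.value,
                r.timing.value,
                f"{r.months_primary_to_mets:.1f}",
                f"{r.followup_from_primary_months:.1f}",
                r.event.value,
            )
            for r in records
        ],
        columns=list(PATIENT_COLUMNS),
    )


def write_cohort(
    metastases: Iterable[MetastasisRecord],
    patients: Iterable[PatientRecord],
    metastases_path: str | Path,
    patients_path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    """Write the two canonical tables; a later :func:`read_cohort` round-trips."""
    metastases_frame(metastases).to_csv(metastases_path, sep=delimiter, index=False)
    patients_frame(patients).to_csv(patients_path, sep=delimiter, index=False)


def write_validation_report(rejects: Iterable[RejectedRow], path: str | Path) -> None:
    """Write rejected rows as JSON lines (one object per row)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rej in rejects:
            fh.write(json.dumps({"table": rej.table, "line": rej.line, "reason": rej.reason}) + "\n")
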