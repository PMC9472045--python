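"""Reading and writing chart bundles.

A bundle is a directory of CSV tables (UTF-8, header row) plus a plain-text
``manifest.txt`` of ``key: value`` lines naming the member tables and the
covered date range.  The column schema is documented in
``docs/bundle_schema.md`` and mirrored by the ``*_COLUMNS`` constants below.

Unparseable rows are collected into a reject report rather than silently
dropped; structural problems (missing patients table, duplicate note ids)
abort the load.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import (
    ClinicalNote,
    CodeSystem,
    DiagnosisRecord,
    Education,
    EncounterEvent,
    EncounterStatus,
    EthnicGroup,
    ImagingModality,
    ImagingOrder,
    LabResult,
    MaritalStatus,
    MedicationRecord,
    Patient,
    PatientChart,
    RefillRequest,
    Sex,
)

MANIFEST_NAME = "manifest.txt"

PATIENT_COLUMNS = [
    "patient_id", "birth_date", "sex", "ethnic_group", "marital_status",
    "education", "pcp_id", "care_coordination_note",
]
NOTE_COLUMNS = [
    "note_id", "patient_id", "date", "reason_for_visit", "text",
    "encounter_type", "provider_department", "provider_specialty",
    "provider_qualifications",
]
ENCOUNTER_COLUMNS = ["encounter_id", "patient_id", "date", "status", "kind"]
MEDICATION_COLUMNS = ["patient_id", "name", "date", "current"]
DIAGNOSIS_COLUMNS = ["patient_id", "code", "system", "description", "date"]
LAB_COLUMNS = ["patient_id", "test_name", "value", "units", "date"]
IMAGING_COLUMNS = ["patient_id", "modality", "body_site", "date"]
REFILL_COLUMNS = ["patient_id", "date", "medication_name"]

TABLE_FILES = {
    "patients": PATIENT_COLUMNS,
    "notes": NOTE_COLUMNS,
    "encounters": ENCOUNTER_COLUMNS,
    "medications": MEDICATION_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "labs": LAB_COLUMNS,
    "imaging": IMAGING_COLUMNS,
    "refills": REFILL_COLUMNS,
}

REQUIRED_TABLES = ("patients",)


class BundleError(Exception):
    """Fatal structural problem in a chart bundle."""


@dataclass(frozen=True)
class RejectedRow:
    table: str
    row_index: int
    reason: str


@dataclass
class RejectReport:
    rows: list[RejectedRow] = field(default_factory=list)

    def add(self, table: str, row_index: int, reason: str) -> None:
        self.rows.append(RejectedRow(table, row_index, reason))

    def __len__(self) -> int:
        return len(self.rows)

    def __bool__(self) -> bool:
        return bool(self.rows)


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value.strip())


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value or None


def _enum(cls, value: str, *, missing_ok: bool = True):
    value = value.strip()
    if not value and missing_ok:
        return cls("missing")
    try:
        return cls(value)
    except ValueError:
        # accept the enum name as well as its value, case-insensitively
        try:
            return cls[value.upper().replace("-", "_").replace(" ", "_")]
        except KeyError:
            raise ValueError(f"unrecognized {cls.__name__} value {value!r}") from None


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise BundleError(f"table {path.name} missing columns {missing}")
    return df


def read_manifest(bundle_dir: Path) -> dict[str, str]:
    path = bundle_dir / MANIFEST_NAME
    if not path.exists():
        raise BundleError(f"bundle manifest not found: {path}")
    manifest: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        manifest[key.strip()] = value.strip()
    return manifest


def load_chart_bundle(
    path: str | Path,
) -> tuple[list[PatientChart], RejectReport]:
    """Load a bundle directory into one :class:`PatientChart` per patient.

    Returns ``(charts, rejects)``.  Rows that fail to parse (bad dates,
    unknown enum values, references to unknown patients) land in the reject
    report with a reason; missing required tables or duplicate note ids are
    fatal (:class:`BundleError`).
    """
    bundle_dir = Path(path)
    if not bundle_dir.is_dir():
        raise BundleError(f"bundle directory not found: {bundle_dir}")
    manifest = read_manifest(bundle_dir)
    period_start = _parse_date(manifest["period_start"]) if "period_start" in manifest else None
    period_end = _parse_date(manifest["period_end"]) if "period_end" in manifest else None

    rejects = RejectReport()
    tables: dict[str, pd.DataFrame] = {}
    for name, columns in TABLE_FILES.items():
        file_path = bundle_dir / f"{name}.csv"
        if not file_path.exists():
            if name in REQUIRED_TABLES:
                raise BundleError(f"required table {name}.csv missing from {bundle_dir}")
            tables[name] = pd.DataFrame(columns=columns)
            continue
        tables[name] = _read_table(file_path, columns)

    charts: dict[str, PatientChart] = {}
    for i, row in tables["patients"].iterrows():
        try:
            patient = Patient(
                patient_id=row["patient_id"].strip(),
                birth_date=_parse_date(row["birth_date"]),
                sex=_enum(Sex, row["sex"]),
                ethnic_group=_enum(EthnicGroup, row["ethnic_group"]),
                marital_status=_enum(MaritalStatus, row["marital_status"]),
                education=_enum(Education, row["education"]),
                pcp_id=_opt(row["pcp_id"]),
                care_coordination_note=_opt(row["care_coordination_note"]),
            )
        except ValueError as exc:
            rejects.add("patients", int(i), str(exc))
            continue
        if patient.patient_id in charts:
            raise BundleError(f"duplicate patient_id {patient.patient_id!r}")
        charts[patient.patient_id] = PatientChart(
            patient=patient, period_start=period_start, period_end=period_end
        )

    def _route(table: str, i: int, row, builder) -> None:
        pid = row["patient_id"].strip()
        if pid not in charts:
            rejects.add(table, i, f"unknown patient_id {pid!r}")
            return
        try:
            builder(charts[pid], row)
        except ValueError as exc:
            rejects.add(table, i, str(exc))

    seen_note_ids: set[str] = set()

    def _note(chart: PatientChart, row) -> None:
        note_id = row["note_id"].strip()
        if note_id in seen_note_ids:
            raise BundleError(f"duplicate note_id {note_id!r}")
        note = ClinicalNote(
            note_id=note_id,
            patient_id=chart.patient.patient_id,
            date=_parse_date(row["date"]),
            text=row["text"],
            reason_for_visit=_opt(row["reason_for_visit"]),
            encounter_type=row["encounter_type"].strip() or "office visit",
            provider_department=_opt(row["provider_department"]),
            provider_specialty=_opt(row["provider_specialty"]),
            provider_qualifications=_opt(row["provider_qualifications"]),
        )
        seen_note_ids.add(note_id)
        chart.notes.append(note)

    def _encounter(chart: PatientChart, row) -> None:
        chart.encounters.append(
            EncounterEvent(
                encounter_id=row["encounter_id"].strip(),
                patient_id=chart.patient.patient_id,
                date=_parse_date(row["date"]),
                status=_enum(EncounterStatus, row["status"], missing_ok=False),
                kind=_opt(row["kind"]),
            )
        )

    def _medication(chart: PatientChart, row) -> None:
        raw_date = row["date"].strip()
        chart.medications.append(
            MedicationRecord(
                patient_id=chart.patient.patient_id,
                name=row["name"],
                date=_parse_date(raw_date) if raw_date else None,
                current=row["current"].strip().lower() in ("true", "1", "yes"),
            )
        )

    def _diagnosis(chart: PatientChart, row) -> None:
        raw_date = row["date"].strip()
        chart.diagnoses.append(
            DiagnosisRecord(
                patient_id=chart.patient.patient_id,
                code=row["code"].strip(),
                system=_enum(CodeSystem, row["system"].upper(), missing_ok=False),
                description=_opt(row["description"]),
                date=_parse_date(raw_date) if raw_date else None,
            )
        )

    def _lab(chart: PatientChart, row) -> None:
        raw_value = row["value"].strip()
        try:
            value: float | str = float(raw_value)
        except ValueError:
            value = raw_value
        chart.labs.append(
            LabResult(
                patient_id=chart.patient.patient_id,
                test_name=row["test_name"].strip(),
                value=value,
                units=_opt(row["units"]),
                date=_parse_date(row["date"]),
            )
        )

    def _imaging(chart: PatientChart, row) -> None:
        chart.imaging.append(
            ImagingOrder(
                patient_id=chart.patient.patient_id,
                modality=_enum(ImagingModality, row["modality"], missing_ok=False),
                body_site=_opt(row["body_site"]),
                date=_parse_date(row["date"]),
            )
        )

    def _refill(chart: PatientChart, row) -> None:
        chart.refills.append(
            RefillRequest(
                patient_id=chart.patient.patient_id,
                date=_parse_date(row["date"]),
                medication_name=_opt(row["medication_name"]),
            )
        )

    builders = {
        "notes": _note,
        "encounters": _encounter,
        "medications": _medication,
        "diagnoses": _diagnosis,
        "labs": _lab,
        "imaging": _imaging,
        "refills": _refill,
    }
    for table, builder in builders.items():
        for i, row in tables[table].iterrows():
            _route(table, int(i), row, builder)

    out = []
    for pid in sorted(charts):
        chart = charts[pid]
        chart.notes.sort(key=lambda n: (n.date, n.note_id))
        chart.validate()
        out.append(chart)
    return out, rejects


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, dt.date):
        return value.isoformat()
    if hasattr(value, "value"):  # Enum
        return str(value.value)
    return str(value)


def write_chart_bundle(
    charts: list[PatientChart],
    path: str | Path,
    *,
    period_start: Optional[dt.date] = None,
    period_end: Optional[dt.date] = None,
) -> Path:
    """Write charts as a bundle directory; the inverse of :func:`load_chart_bundle`."""
    bundle_dir = Path(path)
    bundle_dir.mkdir(parents=True, exist_ok=True)

    starts = [c.period_start for c in charts if c.period_start]
    ends = [c.period_end for c in charts if c.period_end]
    period_start = period_start or (min(starts) if starts else None)
    period_end = period_end or (max(ends) if ends else None)

    rows: dict[str, list[list[str]]] = {name: [] for name in TABLE_FILES}
    for chart in charts:
        p = chart.patient
        rows["patients"].append([
            p.patient_id, _fmt(p.birth_date), _fmt(p.sex), _fmt(p.ethnic_group),
            _fmt(p.marital_status), _fmt(p.education), _fmt(p.pcp_id),
            _fmt(p.care_coordination_note),
        ])
        for n in chart.notes:
            rows["notes"].append([
                n.note_id, n.patient_id, _fmt(n.date), _fmt(n.reason_for_visit),
                n.text, n.encounter_type, _fmt(n.provider_department),
                _fmt(n.provider_specialty), _fmt(n.provider_qualifications),
            ])
        for e in chart.encounters:
            rows["encounters"].append(
                [e.encounter_id, e.patient_id, _fmt(e.date), _fmt(e.status), _fmt(e.kind)]
            )
        for m in chart.medications:
            rows["medications"].append(
                [m.patient_id, m.name, _fmt(m.date), _fmt(m.current)]
            )
        for d in chart.diagnoses:
            rows["diagnoses"].append(
                [d.patient_id, d.code, _fmt(d.system), _fmt(d.description), _fmt(d.date)]
            )
        for l in chart.labs:
            rows["labs"].append(
                [l.patient_id, l.test_name, _fmt(l.value), _fmt(l.units), _fmt(l.date)]
            )
        for im in chart.imaging:
            rows["imaging"].append(
                [im.patient_id, _fmt(im.modality), _fmt(im.body_site), _fmt(im.date)]
            )
        for r in chart.refills:
            rows["refills"].append(
                [r.patient_id, _fmt(r.date), _fmt(r.medication_name)]
            )

    for name, columns in TABLE_FILES.items():
        df = pd.DataFrame(rows[name], columns=columns)
        df.to_csv(bundle_dir / f"{name}.csv", index=False, lineterminator="\n")

    manifest_lines = [f"tables: {', '.join(sorted(TABLE_FILES))}"]
    if period_start:
        manifest_lines.append(f"period_start: {period_start.isoformat()}")
    if period_end:
        manifest_lines.append(f"period_end: {period_end.isoformat()}")
    manifest_lines.append(f"n_patients: {len(charts)}")
    (bundle_dir / MANIFEST_NAME).write_text(
        "\n".join(manifest_lines) + "\n", encoding="utf-8"
    )
    return bundle_dir
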