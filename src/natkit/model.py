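"""Domain types for EHR chart bundles.

A *chart bundle* is the file-based stand-in for an EHR warehouse extraction:
one table per record kind (patients, notes, encounters, medications,
diagnoses, labs, imaging orders, refill requests) plus a manifest naming the
covered study period.  The in-memory aggregate is :class:`PatientChart`, one
per patient, holding every record type restricted to the study period.

Clinical notes are additionally segmented into *note sequences* -- bounded
character windows that receive their own keyword highlights and
classification.  Offsets are 0-based half-open over NFC-normalized text so
that highlight placement is unambiguous.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from datetime import date as Date
from enum import Enum
from typing import Iterable, Optional, Union


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    OTHER = "other"
    MISSING = "missing"


class EthnicGroup(str, Enum):
    BLACK = "black"
    HISPANIC = "hispanic"
    ASIAN = "asian"
    INDIGENOUS = "indigenous"
    WHITE = "white"
    OTHER = "other"
    MISSING = "missing"


class MaritalStatus(str, Enum):
    MARRIED = "married"
    NOT_MARRIED = "not_married"
    MISSING = "missing"


class Education(str, Enum):
    COLLEGE_OR_MORE = "college_or_more"
    LESS_THAN_COLLEGE = "less_than_college"
    MISSING = "missing"


class EncounterStatus(str, Enum):
    COMPLETED = "completed"
    NO_SHOW = "no_show"
    CANCELLED = "cancelled"


class CodeSystem(str, Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


class ImagingModality(str, Enum):
    MRI = "MRI"
    CT = "CT"
    OTHER = "other"


#: Minority ethnic groups reported individually in cohort summaries.
MINORITY_GROUPS = (
    EthnicGroup.BLACK,
    EthnicGroup.HISPANIC,
    EthnicGroup.ASIAN,
    EthnicGroup.INDIGENOUS,
)


@dataclass(frozen=True)
class Patient:
    """Demographics and care-context for one patient."""

    patient_id: str
    birth_date: Date
    sex: Sex = Sex.MISSING
    ethnic_group: EthnicGroup = EthnicGroup.MISSING
    marital_status: MaritalStatus = MaritalStatus.MISSING
    education: Education = Education.MISSING
    pcp_id: Optional[str] = None
    care_coordination_note: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")

    def age_years(self, on: Date) -> int:
        """Completed years of age on the given date."""
        years = on.year - self.birth_date.year
        if (on.month, on.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return years


@dataclass(frozen=True)
class ClinicalNote:
    """One clinician note. ``text`` may be empty but never ``None``."""

    note_id: str
    patient_id: str
    date: Date
    text: str
    reason_for_visit: Optional[str] = None
    encounter_type: str = "office visit"
    provider_department: Optional[str] = None
    provider_specialty: Optional[str] = None
    provider_qualifications: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.note_id:
            raise ValueError("note_id must be nonempty")
        if self.text is None:  # pragma: no cover - guarded by type
            raise ValueError("note text may be empty but not absent")
        # NFC normalization keeps highlight offsets unambiguous.
        object.__setattr__(self, "text", unicodedata.normalize("NFC", self.text))


@dataclass(frozen=True)
class EncounterEvent:
    encounter_id: str
    patient_id: str
    date: Date
    status: EncounterStatus
    kind: Optional[str] = None


@dataclass(frozen=True)
class MedicationRecord:
    patient_id: str
    name: str
    date: Optional[Date] = None
    current: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("medication name must be nonempty")


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    code: str
    system: CodeSystem
    description: Optional[str] = None
    date: Optional[Date] = None

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("diagnosis code must be nonempty")


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    test_name: str
    value: Union[float, str]
    date: Date
    units: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.test_name:
            raise ValueError("lab test_name must be nonempty")


@dataclass(frozen=True)
class ImagingOrder:
    patient_id: str
    modality: ImagingModality
    date: Date
    body_site: Optional[str] = None


@dataclass(frozen=True)
class RefillRequest:
    patient_id: str
    date: Date
    medication_name: Optional[str] = None


@dataclass
class PatientChart:
    """One patient's full record within a study period.

    Invariants (enforced by :meth:`validate`): every child record carries the
    patient's id; every dated record falls inside ``[period_start,
    period_end]``; notes are sorted ascending by date then note id.
    """

    patient: Patient
    notes: list[ClinicalNote] = field(default_factory=list)
    encounters: list[EncounterEvent] = field(default_factory=list)
    medications: list[MedicationRecord] = field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    imaging: list[ImagingOrder] = field(default_factory=list)
    refills: list[RefillRequest] = field(default_factory=list)
    period_start: Optional[Date] = None
    period_end: Optional[Date] = None

    def __post_init__(self) -> None:
        self.notes = sorted(self.notes, key=lambda n: (n.date, n.note_id))

    def validate(self) -> None:
        pid = self.patient.patient_id
        for group in (
            self.notes,
            self.encounters,
            self.medications,
            self.diagnoses,
            self.labs,
            self.imaging,
            self.refills,
        ):
            for rec in group:
                if rec.patient_id != pid:
                    raise ValueError(
                        f"record patient_id {rec.patient_id!r} != chart patient {pid!r}"
                    )
                rec_date = getattr(rec, "date", None)
                if rec_date is not None:
                    if rec_date <= self.patient.birth_date:
                        raise ValueError(
                            f"record dated {rec_date} not after birth date "
                            f"{self.patient.birth_date} for patient {pid!r}"
                        )
                    if self.period_start is not None and rec_date < self.period_start:
                        raise ValueError(f"record dated {rec_date} before period start")
                    if self.period_end is not None and rec_date > self.period_end:
                        raise ValueError(f"record dated {rec_date} after period end")
        note_ids = [n.note_id for n in self.notes]
        if len(note_ids) != len(set(note_ids)):
            raise ValueError(f"duplicate note_id in chart for patient {pid!r}")
        if list(self.notes) != sorted(self.notes, key=lambda n: (n.date, n.note_id)):
            raise ValueError("notes not sorted by (date, note_id)")


@dataclass(frozen=True)
class NoteSequence:
    """A character window of one note, the unit of highlighting/classification."""

    note_id: str
    seq_index: int
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid sequence span [{self.start}, {self.end})")
        if len(self.text) != self.end - self.start:
            raise ValueError("sequence text length does not match its span")


def filter_period(chart: PatientChart, start: Date, end: Date) -> PatientChart:
    """Restrict a chart to records dated within ``[start, end]`` (inclusive).

    Undated records (e.g. current medications) are always retained.  Returns
    a new chart with ``period_start``/``period_end`` set; the input chart is
    untouched.
    """
    if start > end:
        raise ValueError(f"invalid period window: start {start} > end {end}")

    def keep(rec) -> bool:
        d = getattr(rec, "date", None)
        return d is None or start <= d <= end

    return PatientChart(
        patient=chart.patient,
        notes=[n for n in chart.notes if keep(n)],
        encounters=[e for e in chart.encounters if keep(e)],
        medications=[m for m in chart.medications if keep(m)],
        diagnoses=[d for d in chart.diagnoses if keep(d)],
        labs=[l for l in chart.labs if keep(l)],
        imaging=[i for i in chart.imaging if keep(i)],
        refills=[r for r in chart.refills if keep(r)],
        period_start=start,
        period_end=end,
    )


_SENTENCE_BREAK = re.compile(r"(?<=[.!?])\s+")
_WHITESPACE = re.compile(r"\s")


def segment_note(note: ClinicalNote, max_len: int = 512) -> list[NoteSequence]:
    """Split a note into sequences of at most ``max_len`` characters.

    Break points are chosen preferentially at sentence boundaries (after
    ``.!?`` followed by whitespace), then at any whitespace, then -- only if a
    single unbroken run exceeds ``max_len`` -- at an arbitrary character.
    The concatenation of the returned sequence texts reproduces the note text
    exactly, so offsets into sequences map back into the note.
    """
    if max_len < 32:
        raise ValueError("max_len must be >= 32")
    text = note.text
    if not text:
        return []

    sentence_breaks = {m.end() for m in _SENTENCE_BREAK.finditer(text)}
    sequences: list[NoteSequence] = []
    pos = 0
    while pos < len(text):
        if len(text) - pos <= max_len:
            cut = len(text)
        else:
            window_hi = pos + max_len
            candidates = [b for b in sentence_breaks if pos < b <= window_hi]
            if candidates:
                cut = max(candidates)
            else:
                ws = [m.end() for m in _WHITESPACE.finditer(text, pos, window_hi)]
                cut = max(ws) if ws else window_hi
        sequences.append(
            NoteSequence(
                note_id=note.note_id,
                seq_index=len(sequences),
                start=pos,
                end=cut,
                text=text[pos:cut],
            )
        )
        pos = cut
    return sequences


def segment_chart(chart: PatientChart, max_len: int = 512) -> list[NoteSequence]:
    """Segment every note of a chart, in note order."""
    out: list[NoteSequence] = []
    for note in chart.notes:
        out.extend(segment_note(note, max_len=max_len))
    return out


def chart_replace(chart: PatientChart, **kwargs) -> PatientChart:
    """``dataclasses.replace`` convenience for charts."""
    return replace(chart, **kwargs)
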