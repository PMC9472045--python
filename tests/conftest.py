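import datetime as dt

import pytest

from natkit.lexicon import compile_lexicon, default_lexicon
from natkit.model import (
    ClinicalNote,
    CodeSystem,
    DiagnosisRecord,
    EncounterEvent,
    EncounterStatus,
    LabResult,
    MedicationRecord,
    Patient,
    PatientChart,
    RefillRequest,
)


def make_patient(pid="p1", **kwargs) -> Patient:
    defaults = dict(patient_id=pid, birth_date=dt.date(1940, 6, 15))
    defaults.update(kwargs)
    return Patient(**defaults)


def make_note(note_id, pid="p1", date=dt.date(2017, 3, 1), text="Routine visit.", **kw):
    return ClinicalNote(note_id=note_id, patient_id=pid, date=date, text=text, **kw)


def make_chart(pid="p1", notes=(), encounters=(), medications=(), diagnoses=(),
               labs=(), refills=(), **kwargs) -> PatientChart:
    defaults = dict(
        period_start=dt.date(2017, 1, 1), period_end=dt.date(2018, 12, 31)
    )
    defaults.update(kwargs)
    return PatientChart(
        patient=make_patient(pid),
        notes=list(notes),
        encounters=list(encounters),
        medications=list(medications),
        diagnoses=list(diagnoses),
        labs=list(labs),
        refills=list(refills),
        **defaults,
    )


@pytest.fixture(scope="session")
def default_matcher():
    return compile_lexicon(default_lexicon())


@pytest.fixture
def simple_chart():
    return make_chart(
        notes=[
            make_note("n1", date=dt.date(2017, 2, 1),
                      text="Patient reports memory loss. Follow up soon."),
            make_note("n2", date=dt.date(2017, 5, 1),
                      text="Blood pressure controlled. No new complaints."),
        ],
        encounters=[
            EncounterEvent("e1", "p1", dt.date(2017, 2, 1), EncounterStatus.COMPLETED),
            EncounterEvent("e2", "p1", dt.date(2017, 3, 1), EncounterStatus.NO_SHOW),
            EncounterEvent("e3", "p1", dt.date(2017, 4, 1), EncounterStatus.CANCELLED),
        ],
        medications=[MedicationRecord("p1", "Donepezil 10 mg tablet", current=True)],
        diagnoses=[DiagnosisRecord("p1", "G30.9", CodeSystem.ICD10,
                                   date=dt.date(2017, 2, 1))],
        labs=[LabResult("p1", "TSH", 2.1, dt.date(2017, 2, 15), units="mIU/L")],
        refills=[RefillRequest("p1", dt.date(2017, 6, 1), "Donepezil")],
    )
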