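"""Structured-data feature engineering for cognitive-status chart review.

Four signal families are extracted from the structured side of a chart:
acetylcholinesterase-inhibitor / NMDA-antagonist prescriptions (the four
dementia drugs: galantamine, donepezil, rivastigmine, memantine), dementia
ICD code families (ICD-9 290.X / 294.X / 331.X / 780.93 exact; ICD-10
G30.X / G31.X), reversible-cause laboratory tests (vitamin B12, folate,
TSH), and utilization counts (no-shows, cancellations, refill requests
relative to all scheduled encounters).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .lexicon import MatchSummary
from .model import (
    DiagnosisRecord,
    EncounterEvent,
    EncounterStatus,
    CodeSystem,
    LabResult,
    MedicationRecord,
    PatientChart,
    RefillRequest,
)

#: Generic-name stems of the four dementia medications.
DEMENTIA_MED_STEMS = ("galantamine", "donepezil", "rivastigmine", "memantine")

#: ICD-9 prefix families for dementia (over dot-stripped, upper-cased codes).
ICD9_PREFIXES = ("290", "294", "331")
#: ICD-9 exact code (listed without a family wildcard): altered mental status.
ICD9_EXACT = ("78093",)
#: ICD-10 prefix families for dementia.
ICD10_PREFIXES = ("G30", "G31")

#: Default laboratory panel for reversible causes of cognitive change.
DEFAULT_LAB_PANEL = (
    "vitamin b12", "b12", "cobalamin",
    "folate", "folic acid",
    "tsh", "thyroid-stimulating hormone", "thyroid stimulating hormone",
)


def normalize_icd(code: str) -> str:
    """Canonical form used for family matching: dots removed, upper-cased."""
    return code.replace(".", "").replace(" ", "").upper()


def flag_dementia_medications(
    meds: Sequence[MedicationRecord],
) -> tuple[bool, list[str]]:
    """Flag charts containing any of the four dementia drugs.

    Stem matching is case-insensitive substring, so brand/strength variants
    like ``"Donepezil 10 mg tablet"`` are caught.
    """
    hits = [
        m.name
        for m in meds
        if any(stem in m.name.lower() for stem in DEMENTIA_MED_STEMS)
    ]
    return bool(hits), hits


def flag_dementia_icd(
    diagnoses: Sequence[DiagnosisRecord],
) -> tuple[bool, list[str]]:
    """Flag charts containing a dementia-family ICD code.

    ICD-9: prefixes 290/294/331 or exactly 780.93; ICD-10: prefixes G30/G31.
    Codes are normalized (dots stripped, upper-cased) before matching; hits
    report the original code text.
    """
    hits = []
    for d in diagnoses:
        norm = normalize_icd(d.code)
        if d.system is CodeSystem.ICD9:
            if norm.startswith(ICD9_PREFIXES) or norm in ICD9_EXACT:
                hits.append(d.code)
        else:
            if norm.startswith(ICD10_PREFIXES):
                hits.append(d.code)
    return bool(hits), hits


def select_relevant_labs(
    labs: Sequence[LabResult],
    panel: Sequence[str] = DEFAULT_LAB_PANEL,
) -> list[LabResult]:
    """Labs whose test name matches a panel entry, case-insensitively.

    A lab matches if its name equals a panel entry or contains one as a
    whole phrase; input order is preserved.
    """
    if not panel:
        raise ValueError("lab panel must be nonempty")
    lowered = [p.lower() for p in panel]
    return [l for l in labs if any(p in l.test_name.lower() for p in lowered)]


@dataclass(frozen=True)
class UtilizationCounts:
    n_encounters: int
    n_completed: int
    n_no_shows: int
    n_cancellations: int
    n_refill_requests: int
    #: fractions are None when there are no encounters (undefined, not zero)
    frac_no_shows: Optional[float]
    frac_cancellations: Optional[float]
    frac_refills: Optional[float]


def utilization_counts(
    encounters: Sequence[EncounterEvent],
    refills: Sequence[RefillRequest],
) -> UtilizationCounts:
    """No-show/cancellation/refill counts relative to all scheduled encounters."""
    n = len(encounters)
    n_no = sum(1 for e in encounters if e.status is EncounterStatus.NO_SHOW)
    n_cx = sum(1 for e in encounters if e.status is EncounterStatus.CANCELLED)
    n_ok = n - n_no - n_cx
    n_refills = len(refills)
    return UtilizationCounts(
        n_encounters=n,
        n_completed=n_ok,
        n_no_shows=n_no,
        n_cancellations=n_cx,
        n_refill_requests=n_refills,
        frac_no_shows=(n_no / n) if n else None,
        frac_cancellations=(n_cx / n) if n else None,
        frac_refills=(n_refills / n) if n else None,
    )


@dataclass(frozen=True)
class PatientFeatures:
    """Engineered structured + text-match features for one patient."""

    patient_id: str
    n_notes: int
    n_encounters: int
    n_no_shows: int
    n_cancellations: int
    n_refill_requests: int
    frac_no_shows: Optional[float]
    frac_cancellations: Optional[float]
    frac_refills: Optional[float]
    dementia_med_flag: bool
    dementia_med_hits: tuple[str, ...]
    dementia_icd_flag: bool
    dementia_icd_hits: tuple[str, ...]
    relevant_labs: tuple[LabResult, ...]
    cognition_seq_count: int
    adl_seq_count: int

    def __post_init__(self) -> None:
        if self.dementia_med_flag != bool(self.dementia_med_hits):
            raise ValueError("dementia_med_flag inconsistent with hits")
        if self.dementia_icd_flag != bool(self.dementia_icd_hits):
            raise ValueError("dementia_icd_flag inconsistent with hits")


def build_patient_features(
    chart: PatientChart,
    match_summary: Optional[MatchSummary] = None,
    lab_panel: Sequence[str] = DEFAULT_LAB_PANEL,
) -> PatientFeatures:
    """Aggregate all engineered features for one chart.

    ``match_summary`` (from :func:`natkit.lexicon.count_matches`) must belong
    to the same patient; pass ``None`` for a chart with no text matches.
    """
    pid = chart.patient.patient_id
    if match_summary is not None and match_summary.patient_id != pid:
        raise ValueError(
            f"match summary for patient {match_summary.patient_id!r} "
            f"does not belong to chart of {pid!r}"
        )
    med_flag, med_hits = flag_dementia_medications(chart.medications)
    icd_flag, icd_hits = flag_dementia_icd(chart.diagnoses)
    util = utilization_counts(chart.encounters, chart.refills)
    return PatientFeatures(
        patient_id=pid,
        n_notes=len(chart.notes),
        n_encounters=util.n_encounters,
        n_no_shows=util.n_no_shows,
        n_cancellations=util.n_cancellations,
        n_refill_requests=util.n_refill_requests,
        frac_no_shows=util.frac_no_shows,
        frac_cancellations=util.frac_cancellations,
        frac_refills=util.frac_refills,
        dementia_med_flag=med_flag,
        dementia_med_hits=tuple(med_hits),
        dementia_icd_flag=icd_flag,
        dementia_icd_hits=tuple(icd_hits),
        relevant_labs=tuple(select_relevant_labs(chart.labs, lab_panel)),
        cognition_seq_count=(
            match_summary.n_sequences_with_cognition if match_summary else 0
        ),
        adl_seq_count=(match_summary.n_sequences_with_adl if match_summary else 0),
    )


FEATURE_COLUMNS = [
    "patient_id", "n_notes", "n_encounters", "n_no_shows", "n_cancellations",
    "n_refill_requests", "frac_no_shows", "frac_cancellations", "frac_refills",
    "dementia_med_flag", "dementia_med_hits", "dementia_icd_flag",
    "dementia_icd_hits", "n_relevant_labs", "cognition_seq_count",
    "adl_seq_count",
]


def write_features_table(
    features: Sequence[PatientFeatures], path: str | Path
) -> None:
    """One CSV row per patient, columns in :data:`FEATURE_COLUMNS` order."""

    def fmt_frac(x: Optional[float]) -> str:
        return "" if x is None else repr(x)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(FEATURE_COLUMNS)
        for f in features:
            writer.writerow([
                f.patient_id, f.n_notes, f.n_encounters, f.n_no_shows,
                f.n_cancellations, f.n_refill_requests,
                fmt_frac(f.frac_no_shows), fmt_frac(f.frac_cancellations),
                fmt_frac(f.frac_refills),
                f.dementia_med_flag, "|".join(f.dementia_med_hits),
                f.dementia_icd_flag, "|".join(f.dementia_icd_hits),
                len(f.relevant_labs), f.cognition_seq_count, f.adl_seq_count,
            ])
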