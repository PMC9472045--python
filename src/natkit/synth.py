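"""Seeded synthetic-EHR cohort generator with planted cognitive status.

Real chart data are protected health information, so the package ships a
generator that emulates the statistical structure the pipeline assumes: a
cohort with a configured prevalence of cognitive impairment (CI), a
configured fraction of sparse-record "undetermined" patients, per-note
emission probabilities of impaired/intact cognition language, structured
dementia evidence (ICD families, the four dementia drugs) at configured
rates among CI patients, and utilization streams (encounters with no-shows
and cancellations, refill requests, labs, imaging).

Two cohort templates mirror commonly reported cohort shapes: an elderly
Medicare-style cohort (ages ~ Normal(78.8, 7.4), high dementia-signal
prevalence) and a younger mixed cohort (ages ~ Normal(52.6, 15), ~20%
sparse/undetermined).

Note text is template-based: clinical-sounding sentences with slot-filled
keywords, deterministic given the seed.  Ground-truth labels are emitted in
a separate table, never inside the bundle itself.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

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

# ---------------------------------------------------------------------------
# Sentence templates
# ---------------------------------------------------------------------------

NEUTRAL_SENTENCES = [
    "Patient presents for routine follow-up of chronic conditions.",
    "Blood pressure well controlled on current regimen.",
    "Reviewed immunization history; influenza vaccine administered.",
    "Discussed diet and exercise; patient agreeable to plan.",
    "Lungs clear to auscultation bilaterally; heart regular rate and rhythm.",
    "Medication list reconciled; no changes made today.",
    "Labs reviewed with patient; results within expected limits.",
    "Follow up in three months or sooner if symptoms worsen.",
    "Patient reports no new complaints since the last visit.",
    "Plan: continue current medications and monitor.",
]

IMPAIRED_SENTENCES = [
    "Family reports progressive memory loss over the past year.",
    "Patient appears forgetful and repeats questions during the visit.",
    "Concern for cognitive decline raised by the patient's daughter.",
    "Episodes of confusion noted by home health aide.",
    "Assessment consistent with mild cognitive impairment.",
    "Patient is disoriented to time and place at today's visit.",
]

INTACT_SENTENCES = [
    "Language, attention, and memory function are intact with good fund of knowledge.",
    "Cognition is normal for age; no cognitive concerns reported.",
    "Alert and oriented x3; no memory complaints.",
]

DEMENTIA_ICD9 = [
    ("290.0", "Senile dementia, uncomplicated"),
    ("294.10", "Dementia in conditions classified elsewhere"),
    ("331.0", "Alzheimer's disease"),
    ("780.93", "Memory loss"),
]
DEMENTIA_ICD10 = [
    ("G30.9", "Alzheimer's disease, unspecified"),
    ("G31.84", "Mild cognitive impairment"),
    ("G30.1", "Alzheimer's disease with late onset"),
]
OTHER_ICD10 = [
    ("E11.9", "Type 2 diabetes mellitus without complications"),
    ("I10", "Essential (primary) hypertension"),
    ("E78.5", "Hyperlipidemia, unspecified"),
    ("J44.9", "Chronic obstructive pulmonary disease"),
    ("M17.9", "Osteoarthritis of knee"),
]
DEMENTIA_MEDS = [
    "Donepezil 10 MG tablet",
    "Memantine 10 MG tablet",
    "Rivastigmine 4.6 MG/24HR patch",
    "Galantamine 8 MG capsule",
]
OTHER_MEDS = [
    "Metformin 500 MG tablet",
    "Lisinopril 20 MG tablet",
    "Atorvastatin 40 MG tablet",
    "Amlodipine 5 MG tablet",
    "Omeprazole 20 MG capsule",
]
LAB_TESTS = [
    ("Vitamin B12", 180.0, 900.0, "pg/mL"),
    ("Folate", 3.0, 20.0, "ng/mL"),
    ("TSH", 0.4, 4.5, "mIU/L"),
    ("Hemoglobin A1c", 5.0, 9.0, "%"),
    ("Creatinine", 0.6, 1.6, "mg/dL"),
]


@dataclass(frozen=True)
class NotesDistribution:
    """Family + parameters for the per-patient note count."""

    family: str = "poisson"  # "poisson" | "uniform"
    mean: float = 8.0
    low: int = 3
    high: int = 15
    minimum: int = 3  # floor for determined (CN/CI) patients

    def sample(self, rng: np.random.Generator) -> int:
        if self.family == "poisson":
            return max(self.minimum, int(rng.poisson(self.mean)))
        if self.family == "uniform":
            return max(self.minimum, int(rng.integers(self.low, self.high + 1)))
        raise ValueError(f"unknown notes distribution family {self.family!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; every probability is per-patient or per-note."""

    n_patients: int = 500
    prevalence_ci: float = 0.3
    frac_undetermined: float = 0.2
    notes_per_patient: NotesDistribution = field(default_factory=NotesDistribution)
    # per-note keyword emission probabilities
    p_impaired_keyword_given_ci: float = 0.6
    p_impaired_keyword_given_cn: float = 0.0
    p_intact_keyword_given_cn: float = 0.5
    p_intact_keyword_given_ci: float = 0.0
    p_adl_impaired_given_ci: float = 0.3
    p_adl_intact_given_cn: float = 0.3
    # structured evidence rates (per patient)
    p_dementia_icd_given_ci: float = 0.5
    p_dementia_med_given_ci: float = 0.4
    p_dementia_icd_given_cn: float = 0.0
    p_dementia_med_given_cn: float = 0.0
    #: fraction of CN patients with a transient early impaired mention
    #: followed by a later intact note (the confounder the latest-evidence
    #: adjudication rule exists for)
    frac_transient_cn: float = 0.1
    # utilization
    encounter_rate: float = 30.0
    no_show_rate: float = 0.05
    cancellation_rate: float = 0.10
    refill_rate: float = 2.0
    # demographics (elderly Medicare-style cohort by default)
    age_mean: float = 78.8
    age_sd: float = 7.4
    frac_female: float = 0.6
    period_start: dt.date = dt.date(2017, 1, 1)
    period_end: dt.date = dt.date(2018, 12, 31)
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "prevalence_ci": self.prevalence_ci,
            "frac_undetermined": self.frac_undetermined,
            "p_impaired_keyword_given_ci": self.p_impaired_keyword_given_ci,
            "p_impaired_keyword_given_cn": self.p_impaired_keyword_given_cn,
            "p_intact_keyword_given_cn": self.p_intact_keyword_given_cn,
            "p_intact_keyword_given_ci": self.p_intact_keyword_given_ci,
            "p_adl_impaired_given_ci": self.p_adl_impaired_given_ci,
            "p_adl_intact_given_cn": self.p_adl_intact_given_cn,
            "p_dementia_icd_given_ci": self.p_dementia_icd_given_ci,
            "p_dementia_med_given_ci": self.p_dementia_med_given_ci,
            "p_dementia_icd_given_cn": self.p_dementia_icd_given_cn,
            "p_dementia_med_given_cn": self.p_dementia_med_given_cn,
            "frac_transient_cn": self.frac_transient_cn,
            "no_show_rate": self.no_show_rate,
            "cancellation_rate": self.cancellation_rate,
            "frac_female": self.frac_female,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.prevalence_ci + self.frac_undetermined > 1.0:
            raise ValueError("prevalence_ci + frac_undetermined must be <= 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.no_show_rate + self.cancellation_rate > 1.0:
            raise ValueError("no_show_rate + cancellation_rate must be <= 1")
        if self.period_start > self.period_end:
            raise ValueError("period_start after period_end")

    @classmethod
    def aco_like(cls, n_patients: int = 100, seed: int = 0) -> "CohortConfig":
        """Elderly Medicare-style cohort: high dementia-signal prevalence."""
        return cls(
            n_patients=n_patients,
            prevalence_ci=0.5,
            frac_undetermined=0.05,
            age_mean=78.8,
            age_sd=7.4,
            frac_female=0.63,
            encounter_rate=160.0,
            seed=seed,
        )

    @classmethod
    def covid_like(cls, n_patients: int = 527, seed: int = 0) -> "CohortConfig":
        """Younger mixed cohort with ~20% sparse-record undetermined patients."""
        return cls(
            n_patients=n_patients,
            prevalence_ci=0.1,
            frac_undetermined=0.21,
            age_mean=52.6,
            age_sd=15.0,
            frac_female=0.43,
            encounter_rate=100.0,
            period_start=dt.date(2018, 3, 1),
            period_end=dt.date(2020, 12, 31),
            seed=seed,
        )


def _random_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _pick(rng: np.random.Generator, items: Sequence) -> object:
    return items[int(rng.integers(0, len(items)))]


def _note_text(
    rng: np.random.Generator,
    kind: Optional[str],
    adl_kind: Optional[str],
) -> str:
    """Assemble a note from neutral filler plus optional keyword sentences."""
    n_filler = int(rng.integers(2, 5))
    sents = [str(_pick(rng, NEUTRAL_SENTENCES)) for _ in range(n_filler)]
    if kind == "impaired":
        sents.insert(int(rng.integers(0, len(sents) + 1)), str(_pick(rng, IMPAIRED_SENTENCES)))
    elif kind == "intact":
        sents.insert(int(rng.integers(0, len(sents) + 1)), str(_pick(rng, INTACT_SENTENCES)))
    if adl_kind == "impaired":
        sents.append("Needs assistance with dressing and bathing per family.")
    elif adl_kind == "intact":
        sents.append("Independent in all activities of daily living.")
    return " ".join(sents)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientChart], dict[str, str]]:
    """Generate a cohort of charts plus a planted ground-truth label table.

    Deterministic given ``config.seed``.  Undetermined patients get sparse
    charts (0-2 notes, no dementia evidence, neutral text only); CI patients
    emit impaired-cognition sentences, dementia ICD codes, and dementia
    medications at the configured rates; CN patients emit intact-cognition
    sentences, with a configured fraction carrying a transient early
    impaired mention superseded by a later intact note.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    charts: list[PatientChart] = []
    truth: dict[str, str] = {}
    width = max(4, len(str(max(config.n_patients, 1))))

    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        u = rng.random()
        if u < config.prevalence_ci:
            label = "CI"
        elif u < config.prevalence_ci + config.frac_undetermined:
            label = "undetermined"
        else:
            label = "CN"
        truth[pid] = label
        charts.append(_generate_chart(pid, label, config, rng))
    return charts, truth


def _generate_chart(
    pid: str, label: str, cfg: CohortConfig, rng: np.random.Generator
) -> PatientChart:
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 20.0, 100.0))
    birth_date = cfg.period_end - dt.timedelta(days=int(age * 365.25))
    patient = Patient(
        patient_id=pid,
        birth_date=birth_date,
        sex=Sex.FEMALE if rng.random() < cfg.frac_female else Sex.MALE,
        ethnic_group=EthnicGroup(
            str(_pick(rng, ["white", "white", "white", "black", "hispanic", "asian"]))
        ),
        marital_status=MaritalStatus(
            str(_pick(rng, ["married", "not_married"]))
        ),
        education=Education(
            str(_pick(rng, ["college_or_more", "less_than_college"]))
        ),
        pcp_id=f"DR{int(rng.integers(100, 999))}" if rng.random() < 0.8 else None,
    )

    sparse = label == "undetermined"
    if sparse:
        n_notes = int(rng.integers(0, 3))  # below the sparsity threshold
    else:
        n_notes = cfg.notes_per_patient.sample(rng)

    note_dates = sorted(
        _random_date(rng, cfg.period_start, cfg.period_end) for _ in range(n_notes)
    )

    transient = (
        label == "CN" and n_notes >= 2 and rng.random() < cfg.frac_transient_cn
    )
    if transient and note_dates[-1] <= note_dates[0]:
        # the recovery note must strictly postdate the transient deficit
        if note_dates[-1] < cfg.period_end:
            note_dates[-1] = note_dates[-1] + dt.timedelta(days=1)
        else:
            note_dates[0] = note_dates[0] - dt.timedelta(days=1)

    notes: list[ClinicalNote] = []
    for j, nd in enumerate(note_dates):
        kind: Optional[str] = None
        adl_kind: Optional[str] = None
        if sparse:
            pass  # neutral text only
        elif label == "CI":
            if rng.random() < cfg.p_impaired_keyword_given_ci:
                kind = "impaired"
            elif rng.random() < cfg.p_intact_keyword_given_ci:
                kind = "intact"
            if rng.random() < cfg.p_adl_impaired_given_ci:
                adl_kind = "impaired"
        else:  # CN
            if transient and j == 0:
                kind = "impaired"  # transient early deficit
            elif transient and j == n_notes - 1:
                kind = "intact"  # guaranteed later recovery note
            elif rng.random() < cfg.p_intact_keyword_given_cn:
                kind = "intact"
            elif rng.random() < cfg.p_impaired_keyword_given_cn:
                kind = "impaired"
            if rng.random() < cfg.p_adl_intact_given_cn:
                adl_kind = "intact"
        notes.append(
            ClinicalNote(
                note_id=f"{pid}-N{j:03d}",
                patient_id=pid,
                date=nd,
                text=_note_text(rng, kind, adl_kind),
                reason_for_visit=str(_pick(rng, ["follow-up", "annual exam", "new concern"])),
                encounter_type="office visit",
                provider_department=str(_pick(rng, ["Internal Medicine", "Geriatrics", "Neurology"])),
            )
        )

    n_enc = 0 if sparse else max(1, int(rng.poisson(cfg.encounter_rate)))
    if sparse:
        n_enc = int(rng.integers(1, 4))
    encounters = []
    for j in range(n_enc):
        r = rng.random()
        if r < cfg.no_show_rate:
            status = EncounterStatus.NO_SHOW
        elif r < cfg.no_show_rate + cfg.cancellation_rate:
            status = EncounterStatus.CANCELLED
        else:
            status = EncounterStatus.COMPLETED
        encounters.append(
            EncounterEvent(
                encounter_id=f"{pid}-E{j:04d}",
                patient_id=pid,
                date=_random_date(rng, cfg.period_start, cfg.period_end),
                status=status,
                kind=str(_pick(rng, ["office visit", "telehealth", "lab draw"])),
            )
        )

    medications: list[MedicationRecord] = []
    diagnoses: list[DiagnosisRecord] = []
    if not sparse:
        for _ in range(int(rng.integers(1, 4))):
            medications.append(
                MedicationRecord(
                    patient_id=pid,
                    name=str(_pick(rng, OTHER_MEDS)),
                    date=_random_date(rng, cfg.period_start, cfg.period_end),
                )
            )
        for _ in range(int(rng.integers(1, 4))):
            code, desc = _pick(rng, OTHER_ICD10)
            diagnoses.append(
                DiagnosisRecord(
                    patient_id=pid,
                    code=code,
                    system=CodeSystem.ICD10,
                    description=desc,
                    date=_random_date(rng, cfg.period_start, cfg.period_end),
                )
            )
        p_icd = cfg.p_dementia_icd_given_ci if label == "CI" else cfg.p_dementia_icd_given_cn
        p_med = cfg.p_dementia_med_given_ci if label == "CI" else cfg.p_dementia_med_given_cn
        if rng.random() < p_icd:
            if rng.random() < 0.5:
                code, desc = _pick(rng, DEMENTIA_ICD9)
                system = CodeSystem.ICD9
            else:
                code, desc = _pick(rng, DEMENTIA_ICD10)
                system = CodeSystem.ICD10
            diagnoses.append(
                DiagnosisRecord(
                    patient_id=pid, code=code, system=system, description=desc,
                    date=_random_date(rng, cfg.period_start, cfg.period_end),
                )
            )
        if rng.random() < p_med:
            medications.append(
                MedicationRecord(
                    patient_id=pid,
                    name=str(_pick(rng, DEMENTIA_MEDS)),
                    date=None,  # current medication, undated
                    current=True,
                )
            )

    labs: list[LabResult] = []
    imaging: list[ImagingOrder] = []
    if not sparse:
        for _ in range(int(rng.integers(0, 4))):
            test, lo, hi, units = _pick(rng, LAB_TESTS)
            labs.append(
                LabResult(
                    patient_id=pid,
                    test_name=test,
                    value=round(float(rng.uniform(lo, hi)), 1),
                    units=units,
                    date=_random_date(rng, cfg.period_start, cfg.period_end),
                )
            )
        if label == "CI" and rng.random() < 0.3:
            imaging.append(
                ImagingOrder(
                    patient_id=pid,
                    modality=ImagingModality(str(_pick(rng, ["MRI", "CT"]))),
                    body_site="brain",
                    date=_random_date(rng, cfg.period_start, cfg.period_end),
                )
            )

    refills = [
        RefillRequest(
            patient_id=pid,
            date=_random_date(rng, cfg.period_start, cfg.period_end),
            medication_name=str(_pick(rng, OTHER_MEDS)),
        )
        for _ in range(int(rng.poisson(cfg.refill_rate)) if not sparse else 0)
    ]

    return PatientChart(
        patient=patient,
        notes=notes,
        encounters=encounters,
        medications=medications,
        diagnoses=diagnoses,
        labs=labs,
        imaging=imaging,
        refills=refills,
        period_start=cfg.period_start,
        period_end=cfg.period_end,
    )


def write_ground_truth(truth: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "true_label"])
        for pid in sorted(truth):
            writer.writerow([pid, truth[pid]])


def load_ground_truth(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[row["patient_id"]] = row["true_label"]
    return out


# ---------------------------------------------------------------------------
# Timing-study generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimingStudyConfig:
    """Paired tool-vs-manual timing fixture.

    Manual chart-review time is log-normal (median ``manual_median_min``
    minutes, log-scale sigma ``manual_sigma``); tool-assisted time is the
    manual time divided by ``speedup`` with additional multiplicative
    log-normal noise (sigma ``tool_sigma``).  ``speedup = 1`` is the null
    generator: differences centered at zero.
    """

    n_pairs: int = 32
    speedup: float = 2.2
    manual_median_min: float = 2.3
    manual_sigma: float = 0.5
    tool_sigma: float = 0.25
    seed: int = 0


def generate_timing_study(
    config: TimingStudyConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(tool_times, manual_times)`` in minutes, deterministic by seed."""
    if config.n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if config.speedup <= 0:
        raise ValueError("speedup must be positive")
    rng = np.random.default_rng(config.seed)
    manual = config.manual_median_min * np.exp(
        rng.normal(0.0, config.manual_sigma, size=config.n_pairs)
    )
    tool = (manual / config.speedup) * np.exp(
        rng.normal(0.0, config.tool_sigma, size=config.n_pairs)
    )
    return tool, manual
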