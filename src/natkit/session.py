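"""Annotation sessions: assignment, label suggestion, recording, dashboards.

The adjudication vocabulary is three labels: cognitively normal (CN),
cognitively impaired (CI), and undetermined (chart too sparse to decide).
``suggest_label`` formalizes the clinical adjudication guideline as a
decision-support heuristic: structured dementia evidence (ICD codes or
dementia drugs) or impaired-cognition language implies CI; when impaired and
intact language conflict, the latest-dated evidence wins; explicit intact
language implies CN; a chart with neither signal is undetermined if sparse,
else CN on implicit evidence.  Suggestions carry their triggered-rule
rationale and are never auto-saved -- a human makes the final call.

Session storage is an append-only JSONL file; the latest record per
(patient, annotator) pair is authoritative.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .features import PatientFeatures
from .lexicon import Category, HighlightSpan, Polarity
from .model import PatientChart
from .triage import NoteRanking

LABELS = ("CN", "CI", "undetermined")
CONFIDENCE_GRADES = ("low", "medium", "moderate", "high")

#: Fewer notes than this (with no cognition evidence) => undetermined.
DEFAULT_SPARSITY_THRESHOLD = 3


@dataclass(frozen=True)
class Assignment:
    patient_id: str
    annotator_ids: tuple[str, ...]
    mode: str  # "individual" | "shared"

    def __post_init__(self) -> None:
        if self.mode not in ("individual", "shared"):
            raise ValueError(f"unknown assignment mode {self.mode!r}")
        if not self.annotator_ids:
            raise ValueError("assignment requires at least one annotator")
        if self.mode == "shared" and len(self.annotator_ids) < 2:
            raise ValueError("shared mode requires >= 2 annotators")


def assign_patients(
    patient_ids: Sequence[str],
    annotators: Sequence[str],
    mode: str = "individual",
    seed: int = 0,
) -> list[Assignment]:
    """Randomly assign patients to annotators.

    ``individual``: a seeded shuffle dealt round-robin, so partition sizes
    differ by at most one and the result is reproducible.  ``shared``: every
    annotator reviews every patient (for interrater-agreement studies).
    """
    if not annotators:
        raise ValueError("at least one annotator required")
    if mode not in ("individual", "shared"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    patient_ids = list(patient_ids)
    if mode == "shared":
        return [
            Assignment(pid, tuple(annotators), "shared") for pid in patient_ids
        ]
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(patient_ids)))
    out = []
    for slot, idx in enumerate(order):
        annotator = annotators[slot % len(annotators)]
        out.append(Assignment(patient_ids[idx], (annotator,), "individual"))
    out.sort(key=lambda a: a.patient_id)
    return out


@dataclass(frozen=True)
class LabelSuggestion:
    label: str
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != "undetermined" and not self.rationale:
            raise ValueError("CN/CI suggestions must carry a rationale")


def suggest_label(
    features: PatientFeatures,
    spans: Sequence[HighlightSpan],
    chart: PatientChart,
    sparsity_threshold: int = DEFAULT_SPARSITY_THRESHOLD,
) -> LabelSuggestion:
    """Rule-based label suggestion for one patient.

    Rules, in order:

    1. structured dementia evidence (ICD family or dementia drug) -> CI
    2. impaired-cognition language only -> CI
    3. conflicting impaired and intact language -> polarity of the
       latest-dated span (same-date tie -> impaired, i.e. suspicion wins)
    4. intact-cognition language only -> CN
    5. no cognition evidence, sparse chart (< ``sparsity_threshold`` notes)
       -> undetermined
    6. otherwise -> CN on implicit evidence
    """
    pid = chart.patient.patient_id
    if features.patient_id != pid:
        raise ValueError("features and chart belong to different patients")

    rationale: list[str] = []
    if features.dementia_icd_flag:
        rationale.append(
            "dementia_icd_codes: " + ", ".join(features.dementia_icd_hits)
        )
    if features.dementia_med_flag:
        rationale.append(
            "dementia_medications: " + ", ".join(features.dementia_med_hits)
        )
    if rationale:
        return LabelSuggestion(label="CI", rationale=tuple(rationale))

    dates_by_note = {n.note_id: n.date for n in chart.notes}
    impaired = []
    intact = []
    for s in spans:
        if s.category is not Category.COGNITION:
            continue
        if s.note_id not in dates_by_note:
            raise ValueError(f"span references note {s.note_id!r} not in chart")
        if s.polarity is Polarity.IMPAIRED:
            impaired.append(s)
        else:
            intact.append(s)

    def latest(group: list[HighlightSpan]) -> dt.date:
        return max(dates_by_note[s.note_id] for s in group)

    if impaired and not intact:
        return LabelSuggestion(
            label="CI",
            rationale=(
                f"impaired_cognition_language: {len(impaired)} span(s), "
                f"latest {latest(impaired).isoformat()} "
                f"(notes {_note_list(impaired)})",
            ),
        )
    if impaired and intact:
        latest_imp, latest_int = latest(impaired), latest(intact)
        if latest_int > latest_imp:
            return LabelSuggestion(
                label="CN",
                rationale=(
                    f"latest_evidence_intact: intact {latest_int.isoformat()} "
                    f"postdates impaired {latest_imp.isoformat()}",
                ),
            )
        return LabelSuggestion(
            label="CI",
            rationale=(
                f"latest_evidence_impaired: impaired {latest_imp.isoformat()} "
                f"vs intact {latest_int.isoformat()}",
            ),
        )
    if intact:
        return LabelSuggestion(
            label="CN",
            rationale=(
                f"intact_cognition_language: {len(intact)} span(s) "
                f"(notes {_note_list(intact)})",
            ),
        )
    if features.n_notes < sparsity_threshold:
        return LabelSuggestion(label="undetermined", rationale=())
    return LabelSuggestion(
        label="CN",
        rationale=(
            f"implicit_evidence: {features.n_notes} notes with no cognitive concern",
        ),
    )


def _note_list(spans: Sequence[HighlightSpan], limit: int = 5) -> str:
    ids = sorted({s.note_id for s in spans})
    shown = ", ".join(ids[:limit])
    return shown + (", ..." if len(ids) > limit else "")


@dataclass(frozen=True)
class AnnotationRecord:
    patient_id: str
    annotator_id: str
    label: str
    started_at: dt.datetime
    saved_at: dt.datetime
    duration_min: float
    confidence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.confidence is not None and self.confidence not in CONFIDENCE_GRADES:
            raise ValueError(f"unknown confidence grade {self.confidence!r}")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        elapsed = (self.saved_at - self.started_at).total_seconds() / 60.0
        # manual duration entry is allowed; recorded timestamps must agree
        # with the stated duration to within a minute of rounding slack
        if self.saved_at < self.started_at:
            raise ValueError("saved_at precedes started_at")
        if abs(elapsed - self.duration_min) > 1.0:
            raise ValueError(
                f"duration_min {self.duration_min} inconsistent with timestamps "
                f"({elapsed:.2f} min elapsed)"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "annotator_id": self.annotator_id,
                "label": self.label,
                "confidence": self.confidence,
                "started_at": self.started_at.isoformat(),
                "saved_at": self.saved_at.isoformat(),
                "duration_min": self.duration_min,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "AnnotationRecord":
        obj = json.loads(line)
        return cls(
            patient_id=obj["patient_id"],
            annotator_id=obj["annotator_id"],
            label=obj["label"],
            confidence=obj.get("confidence"),
            started_at=dt.datetime.fromisoformat(obj["started_at"]),
            saved_at=dt.datetime.fromisoformat(obj["saved_at"]),
            duration_min=float(obj["duration_min"]),
        )


def make_record(
    patient_id: str,
    annotator_id: str,
    label: str,
    duration_min: float,
    started_at: Optional[dt.datetime] = None,
    confidence: Optional[str] = None,
) -> AnnotationRecord:
    """Build a record from a manually entered duration."""
    start = started_at or dt.datetime(2000, 1, 1, 9, 0, 0)
    return AnnotationRecord(
        patient_id=patient_id,
        annotator_id=annotator_id,
        label=label,
        confidence=confidence,
        started_at=start,
        saved_at=start + dt.timedelta(minutes=duration_min),
        duration_min=duration_min,
    )


class SessionStore:
    """Append-only annotation log, optionally persisted as JSONL.

    Records are never mutated or deleted; re-annotation appends a new record
    and the latest per (patient, annotator) pair is authoritative.
    """

    def __init__(
        self,
        assignments: Sequence[Assignment],
        path: Optional[str | Path] = None,
    ) -> None:
        self.assignments = list(assignments)
        self._assigned: set[tuple[str, str]] = {
            (a.patient_id, ann) for a in assignments for ann in a.annotator_ids
        }
        self.path = Path(path) if path is not None else None
        self.records: list[AnnotationRecord] = []
        if self.path is not None and self.path.exists():
            for line in self.path.read_text(encoding="utf-8").splitlines():
                if line.strip():
                    self.records.append(AnnotationRecord.from_json(line))

    def record(self, rec: AnnotationRecord) -> None:
        if (rec.patient_id, rec.annotator_id) not in self._assigned:
            raise ValueError(
                f"annotator {rec.annotator_id!r} is not assigned patient "
                f"{rec.patient_id!r}"
            )
        self.records.append(rec)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(rec.to_json() + "\n")

    def latest(self) -> dict[tuple[str, str], AnnotationRecord]:
        """Authoritative record per (patient_id, annotator_id)."""
        out: dict[tuple[str, str], AnnotationRecord] = {}
        for rec in self.records:  # later records supersede earlier ones
            out[(rec.patient_id, rec.annotator_id)] = rec
        return out

    def current_label(self, patient_id: str) -> Optional[str]:
        """The most recently saved label for a patient, by any annotator."""
        label = None
        for rec in self.records:
            if rec.patient_id == patient_id:
                label = rec.label
        return label

    def __len__(self) -> int:
        return len(self.records)


def record_annotation(store: SessionStore, rec: AnnotationRecord) -> SessionStore:
    """Functional wrapper over :meth:`SessionStore.record`."""
    store.record(rec)
    return store


@dataclass(frozen=True)
class DashboardRow:
    patient_id: str
    age_years: Optional[int]
    sex: str
    n_notes: int
    cognition_seq_count: int
    adl_seq_count: int
    notes_per_class: tuple[tuple[str, int], ...]
    label: str  # "unlabeled" until annotated


def dashboard_summary(
    assignments: Sequence[Assignment],
    charts: dict[str, PatientChart],
    features: dict[str, PatientFeatures],
    rankings: dict[str, NoteRanking],
    store: Optional[SessionStore] = None,
) -> list[DashboardRow]:
    """One row per assigned patient, sorted by patient id."""
    rows = []
    for assignment in sorted(assignments, key=lambda a: a.patient_id):
        pid = assignment.patient_id
        chart = charts[pid]
        feats = features[pid]
        ranking = rankings.get(pid)
        per_class: dict[str, int] = {"CI": 0, "no_CI": 0, "neither": 0}
        if ranking is not None:
            for note in ranking.notes:
                per_class[note.predicted] += 1
        label = store.current_label(pid) if store is not None else None
        age = (
            chart.patient.age_years(chart.period_end)
            if chart.period_end is not None
            else None
        )
        rows.append(
            DashboardRow(
                patient_id=pid,
                age_years=age,
                sex=chart.patient.sex.value,
                n_notes=feats.n_notes,
                cognition_seq_count=feats.cognition_seq_count,
                adl_seq_count=feats.adl_seq_count,
                notes_per_class=tuple(sorted(per_class.items())),
                label=label if label is not None else "unlabeled",
            )
        )
    return rows
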