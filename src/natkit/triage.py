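"""Sequence classification and CI-first note ranking.

A *classifier* is anything that maps a text to a probability triple over
{CI, no_CI, neither}.  The trained neural model used in production systems
is pluggable behind this contract; the package ships a self-contained
lexicon-count baseline (softmax over weighted impaired/intact cognition
match counts) so the full pipeline runs without any model artifact.

Notes are ranked for reviewer attention: notes whose sequences indicate
cognitive impairment first, then notes with explicit no-impairment language,
then uninformative notes; within a class by descending CI probability, then
by recency (the latest-evidence convention), then note id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from typing import Callable, Optional, Protocol, Sequence

from .lexicon import Category, CompiledLexicon, Polarity
from .model import NoteSequence

#: Predicted class labels, in tie-breaking priority order.
CLASS_ORDER = ("CI", "no_CI", "neither")

_PROB_TOL = 1e-9


class SequenceClassifier(Protocol):
    """Contract for pluggable classifiers: text in, probability triple out."""

    def classify(self, text: str) -> tuple[float, float, float]:
        """Return ``(p_ci, p_no_ci, p_neither)`` summing to 1."""
        ...


@dataclass(frozen=True)
class SequenceClassification:
    note_id: str
    seq_index: int
    p_ci: float
    p_no_ci: float
    p_neither: float
    predicted: str
    flagged_incorrect: bool = False

    def __post_init__(self) -> None:
        probs = (self.p_ci, self.p_no_ci, self.p_neither)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError(f"probabilities outside [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities do not sum to 1: {probs}")
        if self.predicted != _argmax_class(probs):
            raise ValueError(
                f"predicted {self.predicted!r} is not the argmax of {probs}"
            )

    @property
    def probs(self) -> tuple[float, float, float]:
        return (self.p_ci, self.p_no_ci, self.p_neither)


def _argmax_class(probs: Sequence[float]) -> str:
    best = max(probs)
    for cls, p in zip(CLASS_ORDER, probs):
        if p == best:  # first in priority order wins ties: CI > no_CI > neither
            return cls
    raise AssertionError("unreachable")


def classify_sequences(
    sequences: Sequence[NoteSequence], model: SequenceClassifier
) -> list[SequenceClassification]:
    """Apply a classifier to each sequence, validating its output.

    A model returning a non-normalized or out-of-range triple raises
    ``ValueError`` naming the offending sequence.
    """
    out: list[SequenceClassification] = []
    for seq in sequences:
        probs = tuple(float(p) for p in model.classify(seq.text))
        if len(probs) != 3 or abs(sum(probs) - 1.0) > _PROB_TOL or any(
            not (0.0 <= p <= 1.0) for p in probs
        ):
            raise ValueError(
                f"classifier returned invalid probability triple {probs} "
                f"for sequence {seq.note_id}#{seq.seq_index}"
            )
        out.append(
            SequenceClassification(
                note_id=seq.note_id,
                seq_index=seq.seq_index,
                p_ci=probs[0],
                p_no_ci=probs[1],
                p_neither=probs[2],
                predicted=_argmax_class(probs),
            )
        )
    return out


def _softmax3(a: float, b: float, c: float) -> tuple[float, float, float]:
    m = max(a, b, c)
    ea, eb, ec = math.exp(a - m), math.exp(b - m), math.exp(c - m)
    z = ea + eb + ec
    return ea / z, eb / z, ec / z


@dataclass(frozen=True)
class BaselineLexiconClassifier:
    """Softmax over weighted cognition match counts.

    For a text with ``c_imp`` cognition/impaired matches and ``c_int``
    cognition/intact matches, scores are ``(w_impaired * c_imp,
    w_intact * c_int, bias_neither)`` and probabilities their softmax.  With
    no matches the neither class dominates; evidence of either polarity
    pushes mass to the corresponding class.
    """

    matcher: CompiledLexicon
    w_impaired: float = 2.0
    w_intact: float = 2.0
    bias_neither: float = 1.0

    def __post_init__(self) -> None:
        for w in (self.w_impaired, self.w_intact, self.bias_neither):
            if not math.isfinite(w):
                raise ValueError("classifier weights must be finite")

    def classify(self, text: str) -> tuple[float, float, float]:
        c_imp = 0
        c_int = 0
        for entry, start, end in self.matcher.finditer(text):
            if entry.category is Category.COGNITION:
                if entry.polarity is Polarity.IMPAIRED:
                    c_imp += 1
                else:
                    c_int += 1
        return _softmax3(
            self.w_impaired * c_imp, self.w_intact * c_int, self.bias_neither
        )


def baseline_lexicon_classifier(
    lexicon: CompiledLexicon,
    w_impaired: float = 2.0,
    w_intact: float = 2.0,
    bias_neither: float = 1.0,
) -> BaselineLexiconClassifier:
    """Construct the self-contained lexicon-count baseline classifier."""
    return BaselineLexiconClassifier(
        matcher=lexicon,
        w_impaired=w_impaired,
        w_intact=w_intact,
        bias_neither=bias_neither,
    )


@dataclass(frozen=True)
class NoteResult:
    """Note-level aggregation of its sequence classifications."""

    note_id: str
    date: Date
    predicted: str
    score: float  # max p_ci over the note's sequences


def note_level_class(
    classifications: Sequence[SequenceClassification],
) -> tuple[str, float]:
    """Aggregate one note's sequence classifications.

    The note class is CI if any sequence predicted CI, else no_CI if any
    predicted no_CI, else neither; the note score is the maximum CI
    probability over its sequences.
    """
    if not classifications:
        raise ValueError("note_level_class requires at least one classification")
    note_ids = {c.note_id for c in classifications}
    if len(note_ids) > 1:
        raise ValueError(f"classifications span multiple notes: {sorted(note_ids)}")
    predicted_set = {c.predicted for c in classifications}
    for cls in CLASS_ORDER:
        if cls in predicted_set:
            note_class = cls
            break
    score = max(c.p_ci for c in classifications)
    return note_class, score


@dataclass(frozen=True)
class RankedNote:
    note_id: str
    rank: int  # 1-based display position
    predicted: str
    score: float
    date: Date


@dataclass(frozen=True)
class NoteRanking:
    notes: tuple[RankedNote, ...]

    @property
    def note_ids(self) -> list[str]:
        return [n.note_id for n in self.notes]


def rank_notes(results: Sequence[NoteResult]) -> NoteRanking:
    """Order notes CI-first for reviewer display.

    Sort key: class priority (CI, no_CI, neither), then descending score,
    then most recent date, then note id -- so the ordering is a
    deterministic permutation of the input.
    """
    ids = [r.note_id for r in results]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate note_id(s) in ranking input: {dupes}")
    ordered = sorted(
        results,
        key=lambda r: (
            CLASS_ORDER.index(r.predicted),
            -r.score,
            -r.date.toordinal(),
            r.note_id,
        ),
    )
    return NoteRanking(
        notes=tuple(
            RankedNote(
                note_id=r.note_id,
                rank=i + 1,
                predicted=r.predicted,
                score=r.score,
                date=r.date,
            )
            for i, r in enumerate(ordered)
        )
    )


def classify_and_rank(
    sequences: Sequence[NoteSequence],
    note_dates: dict[str, Date],
    model: SequenceClassifier,
) -> tuple[list[SequenceClassification], NoteRanking]:
    """Convenience: classify all sequences of a chart and rank its notes."""
    classifications = classify_sequences(sequences, model)
    by_note: dict[str, list[SequenceClassification]] = {}
    for c in classifications:
        by_note.setdefault(c.note_id, []).append(c)
    results = []
    for note_id, group in by_note.items():
        cls, score = note_level_class(group)
        results.append(
            NoteResult(note_id=note_id, date=note_dates[note_id], predicted=cls, score=score)
        )
    return classifications, rank_notes(results)
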