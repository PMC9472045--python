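"""Keyword/regex lexicons and note-text highlighting.

Two lexicon categories are used for chart review of cognitive status:
``cognition`` (language about memory and cognitive function) and ``adl``
(activities of daily living).  Each entry additionally carries a *polarity*
-- whether the pattern signals impairment or intact function.  Matching is
case-insensitive, leftmost, non-overlapping per entry, and deterministic.

The default lexicon shipped here is a documented reconstruction assembled
from the phrases the clinical literature on chart review of cognitive status
typically keys on; any user lexicon CSV (columns ``entry_id, pattern,
category, polarity``) can be used instead.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .model import NoteSequence, PatientChart


class Category(str, Enum):
    COGNITION = "cognition"
    ADL = "adl"


class Polarity(str, Enum):
    IMPAIRED = "impaired"
    INTACT = "intact"


@dataclass(frozen=True)
class LexiconEntry:
    entry_id: str
    pattern: str
    category: Category
    polarity: Polarity


@dataclass(frozen=True)
class HighlightSpan:
    """A matched character interval within one note sequence."""

    note_id: str
    seq_index: int
    start: int
    end: int
    entry_id: str
    category: Category
    polarity: Polarity

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid highlight span [{self.start}, {self.end})")


class LexiconError(ValueError):
    """A lexicon entry failed to compile; names the offending entry."""


@dataclass
class CompiledLexicon:
    """Reusable matcher over a set of lexicon entries."""

    entries: list[LexiconEntry]
    _compiled: list[tuple[LexiconEntry, re.Pattern]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise LexiconError("lexicon must contain at least one entry")
        ids = [e.entry_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LexiconError(f"duplicate entry_id(s): {dupes}")
        self._compiled = []
        for entry in self.entries:
            try:
                pat = re.compile(entry.pattern, re.IGNORECASE)
            except re.error as exc:
                raise LexiconError(
                    f"entry {entry.entry_id!r}: invalid pattern {entry.pattern!r}: {exc}"
                ) from exc
            self._compiled.append((entry, pat))

    def finditer(self, text: str) -> Iterable[tuple[LexiconEntry, int, int]]:
        """All per-entry leftmost non-overlapping matches, unordered."""
        for entry, pat in self._compiled:
            for m in pat.finditer(text):
                if m.end() > m.start():  # ignore zero-width matches
                    yield entry, m.start(), m.end()


def compile_lexicon(entries: Sequence[LexiconEntry]) -> CompiledLexicon:
    """Compile entries into a reusable case-insensitive matcher."""
    return CompiledLexicon(entries=list(entries))


def find_spans(sequence: NoteSequence, matcher: CompiledLexicon) -> list[HighlightSpan]:
    """All highlight spans in one sequence.

    Spans are sorted by start offset, ties broken longer-span-first then by
    entry id, so output is deterministic and independent of lexicon order.
    """
    spans = [
        HighlightSpan(
            note_id=sequence.note_id,
            seq_index=sequence.seq_index,
            start=start,
            end=end,
            entry_id=entry.entry_id,
            category=entry.category,
            polarity=entry.polarity,
        )
        for entry, start, end in matcher.finditer(sequence.text)
    ]
    spans.sort(key=lambda s: (s.start, -(s.end - s.start), s.entry_id))
    return spans


@dataclass(frozen=True)
class MatchSummary:
    """Per-patient tally of highlight activity."""

    patient_id: str
    n_sequences_with_cognition: int
    n_sequences_with_adl: int
    span_counts: tuple[tuple[tuple[str, str], int], ...]  # ((category, polarity) -> count)

    def count(self, category: Category, polarity: Polarity) -> int:
        return dict(self.span_counts).get((category.value, polarity.value), 0)

    @property
    def total_spans(self) -> int:
        return sum(c for _, c in self.span_counts)


def count_matches(chart: PatientChart, spans: Sequence[HighlightSpan]) -> MatchSummary:
    """Tally spans per (category, polarity) and sequences with any match."""
    note_ids = {n.note_id for n in chart.notes}
    cog_seqs: set[tuple[str, int]] = set()
    adl_seqs: set[tuple[str, int]] = set()
    cells: dict[tuple[str, str], int] = {}
    for span in spans:
        if span.note_id not in note_ids:
            raise ValueError(
                f"span references note {span.note_id!r} not in chart of patient "
                f"{chart.patient.patient_id!r}"
            )
        key = (span.category.value, span.polarity.value)
        cells[key] = cells.get(key, 0) + 1
        seq_key = (span.note_id, span.seq_index)
        if span.category is Category.COGNITION:
            cog_seqs.add(seq_key)
        else:
            adl_seqs.add(seq_key)
    return MatchSummary(
        patient_id=chart.patient.patient_id,
        n_sequences_with_cognition=len(cog_seqs),
        n_sequences_with_adl=len(adl_seqs),
        span_counts=tuple(sorted(cells.items())),
    )


def _merge_same_category(spans: Sequence[HighlightSpan]) -> dict[str, list[tuple[int, int, str]]]:
    """Union overlapping spans within each category.

    Returns {category: [(start, end, polarity)]} with disjoint, sorted
    intervals.  A merged interval keeps the polarity of its earliest span.
    """
    by_cat: dict[str, list[HighlightSpan]] = {}
    for s in spans:
        by_cat.setdefault(s.category.value, []).append(s)
    merged: dict[str, list[tuple[int, int, str]]] = {}
    for cat, group in by_cat.items():
        group.sort(key=lambda s: (s.start, -(s.end - s.start)))
        out: list[tuple[int, int, str]] = []
        for s in group:
            if out and s.start < out[-1][1]:
                prev = out[-1]
                out[-1] = (prev[0], max(prev[1], s.end), prev[2])
            else:
                out.append((s.start, s.end, s.polarity.value))
        merged[cat] = out
    return merged


#: Rendering order: cognition tags wrap adl tags where they overlap.
_CATEGORY_ORDER = (Category.COGNITION.value, Category.ADL.value)


def partition_text(
    text: str, spans: Sequence[HighlightSpan]
) -> list[tuple[str, list[tuple[str, str]]]]:
    """Cut ``text`` into segments with a constant set of active highlights.

    Each element is ``(segment_text, [(category, polarity), ...])`` with the
    active categories listed cognition-first.  Concatenating the segment
    texts reproduces ``text`` exactly.  Same-category overlaps are merged
    beforehand; cross-category overlaps simply yield segments active in both.
    """
    for s in spans:
        if s.end > len(text):
            raise ValueError(
                f"span [{s.start}, {s.end}) out of bounds for text of length {len(text)}"
            )
    merged = _merge_same_category(spans)
    cuts = {0, len(text)}
    for intervals in merged.values():
        for start, end, _ in intervals:
            cuts.add(start)
            cuts.add(end)
    points = sorted(cuts)

    def active_at(pos: int) -> list[tuple[str, str]]:
        out = []
        for cat in _CATEGORY_ORDER:
            for start, end, pol in merged.get(cat, []):
                if start <= pos < end:
                    out.append((cat, pol))
                    break
        return out

    segments = []
    for lo, hi in zip(points, points[1:]):
        if lo < hi:
            segments.append((text[lo:hi], active_at(lo)))
    return segments


def render_highlights(text: str, spans: Sequence[HighlightSpan]) -> str:
    """Wrap highlighted regions of ``text`` in ``<mark>`` tags.

    Tags carry ``data-category``/``data-polarity`` attributes; overlapping
    same-category spans are merged first and cross-category overlaps nest
    with cognition outermost.  :func:`strip_highlights` of the result
    reproduces ``text`` exactly (the text itself is not escaped or altered).
    """
    out: list[str] = []
    open_stack: list[tuple[str, str]] = []
    for segment, active in partition_text(text, spans):
        # close tags no longer active (innermost first)
        while open_stack and (
            len(open_stack) > len(active)
            or open_stack != active[: len(open_stack)]
        ):
            open_stack.pop()
            out.append("</mark>")
        for cat, pol in active[len(open_stack):]:
            out.append(f'<mark data-category="{cat}" data-polarity="{pol}">')
            open_stack.append((cat, pol))
        out.append(segment)
    while open_stack:
        open_stack.pop()
        out.append("</mark>")
    return "".join(out)


_TAG_RE = re.compile(r"</?mark(?:\s[^>]*)?>")


def strip_highlights(marked_up: str) -> str:
    """Remove highlight tags, recovering the original text."""
    return _TAG_RE.sub("", marked_up)


# --------------------------------------------------------------------------
# Default lexicon (a reconstruction, shipped as a usable fixture)
# --------------------------------------------------------------------------

_DEFAULT_ROWS: list[tuple[str, str, str, str]] = [
    # cognition / impaired
    ("cog_imp_memory_loss", r"memory\s+loss", "cognition", "impaired"),
    ("cog_imp_decline", r"cognitive\s+decline", "cognition", "impaired"),
    ("cog_imp_dementia", r"dementia", "cognition", "impaired"),
    ("cog_imp_alzheimer", r"alzheimer'?s?(\s+disease)?", "cognition", "impaired"),
    ("cog_imp_confusion", r"confus(?:ion|ed)", "cognition", "impaired"),
    ("cog_imp_forgetful", r"forgetful(?:ness)?", "cognition", "impaired"),
    ("cog_imp_mci", r"\bMCI\b|mild\s+cognitive\s+impairment", "cognition", "impaired"),
    ("cog_imp_memory_concern", r"(?:concern|worr\w+)[^.]{0,40}\bmemory\b", "cognition", "impaired"),
    ("cog_imp_disoriented", r"disorient(?:ed|ation)", "cognition", "impaired"),
    # cognition / intact
    ("cog_int_memory_intact", r"memory(?:\s+\w+){0,3}\s+(?:is\s+|are\s+)?intact", "cognition", "intact"),
    ("cog_int_cognition_normal", r"cogniti(?:on|ve\s+function)(?:\s+\w+){0,3}\s+(?:is\s+|are\s+)?(?:normal|intact)", "cognition", "intact"),
    ("cog_int_fund_knowledge", r"good\s+fund\s+of\s+knowledge", "cognition", "intact"),
    ("cog_int_no_deficit", r"no\s+(?:cognitive|memory)\s+(?:deficits?|concerns?|complaints?)", "cognition", "intact"),
    ("cog_int_oriented", r"alert\s+and\s+oriented(?:\s*x\s*3)?", "cognition", "intact"),
    # adl / impaired
    ("adl_imp_assist", r"(?:needs?|requires?)\s+(?:assistance|help)\s+with\s+(?:dressing|bathing|finances|medications|driving|ADLs?|IADLs?)", "adl", "impaired"),
    ("adl_imp_unable", r"unable\s+to\s+(?:manage|handle)\s+(?:finances|medications|own\s+affairs)", "adl", "impaired"),
    ("adl_imp_stopped_driving", r"stopped\s+driving", "adl", "impaired"),
    ("adl_imp_dependent", r"\bdependent\s+(?:in|for)\s+(?:all\s+)?(?:ADLs?|IADLs?|activities\s+of\s+daily\s+living)", "adl", "impaired"),
    # adl / intact
    ("adl_int_independent", r"independent\s+(?:in|with)\s+(?:all\s+)?(?:ADLs?|IADLs?|activities\s+of\s+daily\s+living)", "adl", "intact"),
    ("adl_int_manages", r"manag(?:es|ing)\s+(?:own|her|his|their)\s+(?:finances|medications|care|affairs)", "adl", "intact"),
    ("adl_int_drives", r"(?:still\s+)?driv(?:es|ing)\s+(?:independently|without\s+difficulty)", "adl", "intact"),
    ("adl_int_works", r"continues\s+to\s+work", "adl", "intact"),
]


def default_lexicon() -> list[LexiconEntry]:
    """The built-in cognition/ADL lexicon (a documented reconstruction)."""
    return [
        LexiconEntry(entry_id=eid, pattern=pat, category=Category(cat), polarity=Polarity(pol))
        for eid, pat, cat, pol in _DEFAULT_ROWS
    ]


def load_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Read a lexicon CSV with columns entry_id, pattern, category, polarity."""
    entries: list[LexiconEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"entry_id", "pattern", "category", "polarity"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise LexiconError(f"lexicon file must have columns {sorted(required)}")
        for row in reader:
            entries.append(
                LexiconEntry(
                    entry_id=row["entry_id"].strip(),
                    pattern=row["pattern"],
                    category=Category(row["category"].strip().lower()),
                    polarity=Polarity(row["polarity"].strip().lower()),
                )
            )
    return entries


def write_lexicon(entries: Sequence[LexiconEntry], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["entry_id", "pattern", "category", "polarity"])
        for e in entries:
            writer.writerow([e.entry_id, e.pattern, e.category.value, e.polarity.value])
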