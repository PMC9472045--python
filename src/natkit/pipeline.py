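"""End-to-end processing: chart -> highlights -> classifications -> features.

This is the library face of the whole workflow: filter the chart to the
study period, segment notes, find lexicon highlights, classify sequences,
rank notes CI-first, build engineered features, and produce a rule-based
label suggestion.  Everything downstream (reports, the CLI, evaluation)
consumes :class:`ProcessedChart`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

from .features import PatientFeatures, build_patient_features
from .lexicon import (
    CompiledLexicon,
    HighlightSpan,
    MatchSummary,
    count_matches,
    find_spans,
)
from .model import NoteSequence, PatientChart, filter_period, segment_chart
from .session import DEFAULT_SPARSITY_THRESHOLD, LabelSuggestion, suggest_label
from .triage import (
    NoteRanking,
    SequenceClassification,
    SequenceClassifier,
    classify_and_rank,
)


@dataclass(frozen=True)
class ProcessedChart:
    chart: PatientChart
    sequences: tuple[NoteSequence, ...]
    spans: tuple[HighlightSpan, ...]
    match_summary: MatchSummary
    classifications: tuple[SequenceClassification, ...]
    ranking: NoteRanking
    features: PatientFeatures
    suggestion: LabelSuggestion


def process_chart(
    chart: PatientChart,
    matcher: CompiledLexicon,
    classifier: SequenceClassifier,
    period: Optional[tuple[dt.date, dt.date]] = None,
    max_seq_len: int = 512,
    sparsity_threshold: int = DEFAULT_SPARSITY_THRESHOLD,
) -> ProcessedChart:
    """Run the full per-patient pipeline; pure given its inputs."""
    if period is not None:
        chart = filter_period(chart, period[0], period[1])
    sequences = segment_chart(chart, max_len=max_seq_len)
    spans: list[HighlightSpan] = []
    for seq in sequences:
        spans.extend(find_spans(seq, matcher))
    summary = count_matches(chart, spans)
    note_dates = {n.note_id: n.date for n in chart.notes}
    classifications, ranking = classify_and_rank(sequences, note_dates, classifier)
    features = build_patient_features(chart, summary)
    suggestion = suggest_label(
        features, spans, chart, sparsity_threshold=sparsity_threshold
    )
    return ProcessedChart(
        chart=chart,
        sequences=tuple(sequences),
        spans=tuple(spans),
        match_summary=summary,
        classifications=tuple(classifications),
        ranking=ranking,
        features=features,
        suggestion=suggestion,
    )


def process_cohort(
    charts: Sequence[PatientChart],
    matcher: CompiledLexicon,
    classifier: SequenceClassifier,
    **kwargs,
) -> list[ProcessedChart]:
    return [process_chart(c, matcher, classifier, **kwargs) for c in charts]
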