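"""Static HTML reports: cohort dashboard and per-patient annotation views.

The dashboard lists assigned patients with note counts, keyword-match
counts, per-class note counts, and current label (color-coded).  A patient
page shows demographics, engineered features, diagnosis codes, medications,
labs and imaging, and the notes in ranked order with keyword highlights.
Pages are self-contained (inline CSS, no network assets).  Note text is
HTML-escaped segment-by-segment so that stripping markup and unescaping
recovers the original text exactly.
"""

from __future__ import annotations

import html
import re
from pathlib import Path
from typing import Optional, Sequence

from .lexicon import HighlightSpan, partition_text
from .pipeline import ProcessedChart
from .session import DashboardRow, SessionStore

_CSS = """
body { font-family: sans-serif; margin: 1.5em; color: #222; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #bbb; padding: 4px 8px; text-align: left; }
th { background: #f0f0f0; }
mark[data-category="cognition"] { background: #ffd54f; }
mark[data-category="adl"] { background: #90caf9; }
.label-CI { background: #ffcdd2; }
.label-CN { background: #c8e6c9; }
.label-undetermined { background: #e0e0e0; }
.label-unlabeled { background: #ffffff; }
.note { border: 1px solid #ccc; padding: 0.6em; margin: 0.6em 0; }
.note .meta { color: #666; font-size: 0.85em; margin-bottom: 0.4em; }
.empty { color: #888; font-style: italic; }
"""


def render_note_html(text: str, spans: Sequence[HighlightSpan]) -> str:
    """Escape-aware highlight rendering for HTML pages.

    Segments between highlight boundaries are HTML-escaped individually, so
    ``html.unescape(strip_note_markup(result)) == text``.
    """
    out = []
    for segment, active in partition_text(text, spans):
        opened = 0
        for cat, pol in active:
            out.append(f'<mark data-category="{cat}" data-polarity="{pol}">')
            opened += 1
        out.append(html.escape(segment, quote=False))
        out.extend("</mark>" for _ in range(opened))
    return "".join(out)


_MARKUP_RE = re.compile(r"</?mark(?:\s[^>]*)?>")


def strip_note_markup(rendered: str) -> str:
    """Inverse of :func:`render_note_html`: drop tags and unescape."""
    return html.unescape(_MARKUP_RE.sub("", rendered))


def _page(title: str, body: str) -> str:
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{html.escape(title)}</title><style>{_CSS}</style></head>\n"
        f"<body>\n<h1>{html.escape(title)}</h1>\n{body}\n</body></html>\n"
    )


def render_dashboard(rows: Sequence[DashboardRow]) -> str:
    """Cohort dashboard page (one row per assigned patient)."""
    cells = []
    for r in rows:
        per_class = dict(r.notes_per_class)
        cells.append(
            f'<tr class="label-{html.escape(r.label)}">'
            f'<td><a href="patient_{html.escape(r.patient_id)}.html">'
            f"{html.escape(r.patient_id)}</a></td>"
            f"<td>{r.age_years if r.age_years is not None else ''}</td>"
            f"<td>{html.escape(r.sex)}</td>"
            f"<td>{r.n_notes}</td>"
            f"<td>{r.cognition_seq_count}</td>"
            f"<td>{r.adl_seq_count}</td>"
            f"<td>{per_class.get('CI', 0)}</td>"
            f"<td>{per_class.get('no_CI', 0)}</td>"
            f"<td>{per_class.get('neither', 0)}</td>"
            f"<td>{html.escape(r.label)}</td></tr>"
        )
    table = (
        "<table><thead><tr><th>Patient</th><th>Age</th><th>Sex</th>"
        "<th>Notes</th><th>Cognition seqs</th><th>ADL seqs</th>"
        "<th>CI notes</th><th>no-CI notes</th><th>neither notes</th>"
        "<th>Label</th></tr></thead><tbody>"
        + "".join(cells)
        + "</tbody></table>"
    )
    return _page("Chart review dashboard", table)


def _kv_table(pairs: Sequence[tuple[str, str]]) -> str:
    rows = "".join(
        f"<tr><th>{html.escape(k)}</th><td>{html.escape(v)}</td></tr>"
        for k, v in pairs
    )
    return f"<table>{rows}</table>"


def render_patient_page(
    processed: ProcessedChart,
    label: Optional[str] = None,
) -> str:
    """Annotation view for one patient."""
    chart = processed.chart
    p = chart.patient
    f = processed.features

    def fmt_frac(x: Optional[float]) -> str:
        return "n/a" if x is None else f"{x:.3f}"

    age = (
        str(p.age_years(chart.period_end)) if chart.period_end is not None else "?"
    )
    demo = _kv_table([
        ("Patient ID", p.patient_id),
        ("Age (years)", age),
        ("Sex", p.sex.value),
        ("Ethnic group", p.ethnic_group.value),
        ("Marital status", p.marital_status.value),
        ("Education", p.education.value),
        ("PCP", p.pcp_id or "none on file"),
        ("Current label", label or "unlabeled"),
        ("Suggested label", f"{processed.suggestion.label} "
                            f"({'; '.join(processed.suggestion.rationale) or 'sparse chart'})"),
    ])
    feats = _kv_table([
        ("Notes", str(f.n_notes)),
        ("Encounters", str(f.n_encounters)),
        ("No-shows", f"{f.n_no_shows} (frac {fmt_frac(f.frac_no_shows)})"),
        ("Cancellations", f"{f.n_cancellations} (frac {fmt_frac(f.frac_cancellations)})"),
        ("Refill requests", f"{f.n_refill_requests} (frac {fmt_frac(f.frac_refills)})"),
        ("Dementia medications", ", ".join(f.dementia_med_hits) or "none"),
        ("Dementia ICD codes", ", ".join(f.dementia_icd_hits) or "none"),
        ("Cognition-matching sequences", str(f.cognition_seq_count)),
        ("ADL-matching sequences", str(f.adl_seq_count)),
    ])

    dx = "".join(
        f"<li>{html.escape(d.code)} ({d.system.value}) "
        f"{html.escape(d.description or '')}</li>"
        for d in chart.diagnoses
    ) or '<li class="empty">no diagnoses in period</li>'
    meds = "".join(
        f"<li>{html.escape(m.name)}{' (current)' if m.current else ''}</li>"
        for m in chart.medications
    ) or '<li class="empty">no medications in period</li>'
    labs = "".join(
        f"<li>{html.escape(l.test_name)}: {html.escape(str(l.value))} "
        f"{html.escape(l.units or '')} ({l.date.isoformat()})</li>"
        for l in f.relevant_labs
    ) or '<li class="empty">no relevant labs in period</li>'
    imaging = "".join(
        f"<li>{i.modality.value} {html.escape(i.body_site or '')} "
        f"({i.date.isoformat()})</li>"
        for i in chart.imaging
    ) or '<li class="empty">no imaging in period</li>'

    spans_by_seq: dict[tuple[str, int], list[HighlightSpan]] = {}
    for s in processed.spans:
        spans_by_seq.setdefault((s.note_id, s.seq_index), []).append(s)
    seq_by_key = {(s.note_id, s.seq_index): s for s in processed.sequences}
    cls_by_key = {
        (c.note_id, c.seq_index): c for c in processed.classifications
    }
    notes_by_id = {n.note_id: n for n in chart.notes}

    note_blocks = []
    for ranked in processed.ranking.notes:
        note = notes_by_id[ranked.note_id]
        seq_parts = []
        for key in sorted(k for k in seq_by_key if k[0] == ranked.note_id):
            seq = seq_by_key[key]
            cls = cls_by_key[key]
            seq_parts.append(
                f"<p>{render_note_html(seq.text, spans_by_seq.get(key, []))}"
                f' <span class="meta">[{cls.predicted}, '
                f"p(CI)={cls.p_ci:.2f}]</span></p>"
            )
        note_blocks.append(
            f'<div class="note"><div class="meta">#{ranked.rank} '
            f"{html.escape(note.note_id)} &middot; {note.date.isoformat()} "
            f"&middot; predicted {ranked.predicted} "
            f"(score {ranked.score:.2f})</div>"
            + "".join(seq_parts)
            + "</div>"
        )
    notes_html = "".join(note_blocks) or (
        '<p class="empty">no notes in period</p>'
    )

    body = (
        "<h2>Patient information</h2>" + demo
        + "<h2>Engineered features</h2>" + feats
        + "<h2>Diagnoses</h2><ul>" + dx + "</ul>"
        + "<h2>Medications</h2><ul>" + meds + "</ul>"
        + "<h2>Relevant labs</h2><ul>" + labs + "</ul>"
        + "<h2>Imaging</h2><ul>" + imaging + "</ul>"
        + "<h2>Notes (ranked)</h2>" + notes_html
    )
    return _page(f"Patient {p.patient_id}", body)


def write_report(
    processed_charts: Sequence[ProcessedChart],
    rows: Sequence[DashboardRow],
    out_dir: str | Path,
) -> Path:
    """Write the dashboard plus one page per patient into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "dashboard.html").write_text(render_dashboard(rows), encoding="utf-8")
    labels = {r.patient_id: r.label for r in rows}
    for pc in processed_charts:
        pid = pc.chart.patient.patient_id
        label = labels.get(pid)
        (out / f"patient_{pid}.html").write_text(
            render_patient_page(pc, None if label == "unlabeled" else label),
            encoding="utf-8",
        )
    return out
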