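# natkit

A toolkit for **semiautomated chart review of cognitive status** in
electronic health records (EHR). Research cohorts for dementia studies need
each patient phenotyped as cognitively normal (CN), cognitively impaired
(CI), or undetermined — a judgment buried in free-text notes, diagnosis
codes, medications, and utilization patterns. Fully manual chart review is
slow and inconsistent; fully automated classifiers are not trusted for
final adjudication. `natkit` implements the middle path for the scientists
and clinical annotators who build such cohorts: it extracts and engineers
the relevant signals, highlights and ranks the decisive text, suggests a
rule-based label with its rationale, records human adjudications, and
computes the statistics used to evaluate the workflow.

## What it computes

- **Chart model + ingestion** — flat-file "chart bundles" (CSV tables +
  manifest; see `docs/bundle_schema.md`), study-period filtering, and
  sentence-aware segmentation of notes into classifiable sequences.
- **Keyword highlighting** — cognition and ADL regex lexicons with
  impaired/intact polarity; deterministic span finding and `<mark>`
  rendering that never alters the underlying text.
- **Engineered features** — dementia drugs (galantamine, donepezil,
  rivastigmine, memantine), dementia ICD families (ICD-9 290.X/294.X/331.X
  and 780.93; ICD-10 G30.X/G31.X), reversible-cause labs (B12, folate,
  TSH), and no-show/cancellation/refill fractions.
- **Note triage** — pluggable text → (p_CI, p_no_CI, p_neither)
  classifiers, a self-contained softmax-over-match-counts baseline, and
  CI-first note ranking.
- **Label suggestion** — the adjudication guideline as ordered rules,
  including the latest-evidence resolution of conflicting impaired/intact
  language and the sparse-chart undetermined rule.
- **Evaluation statistics** — Cohen's κ = (p_o − p_e)/(1 − p_e) with
  five-class→CN/CI collapsing and undetermined filtering; the paired
  Wilcoxon signed-rank test, exact (full null distribution of W) up to 25
  retained pairs; learning-effect splits; Table-1-style cohort summaries.
- **Synthetic EHR** — a seeded generator with planted ground truth so the
  entire pipeline is testable without protected health data.

## Worked example

```python
from natkit import (CohortConfig, generate_cohort, compile_lexicon,
                    default_lexicon, baseline_lexicon_classifier, process_chart)

charts, truth = generate_cohort(CohortConfig(n_patients=30, seed=11))
matcher = compile_lexicon(default_lexicon())
clf = baseline_lexicon_classifier(matcher)

pc = process_chart(charts[0], matcher, clf)
print(truth[pc.chart.patient.patient_id], pc.suggestion.label)
for note in pc.ranking.notes[:3]:
    print(note.rank, note.note_id, note.predicted, round(note.score, 2))
```

prints

```
CI CI
1 P0000-N006 CI 0.67
2 P0000-N005 CI 0.67
3 P0000-N004 CI 0.67
```

the planted truth and suggested label agree (here via a dementia
medication on the chart), and the three notes the reviewer sees first are
exactly the ones whose sequences contain impaired-cognition language, each
with probability 0.67 = softmax(2, 0, 1)₁ from one impaired keyword match.
The scripts in `examples/` walk through each capability (simulation,
highlighting, triage + suggestion, agreement + timing statistics) and print
annotated output.

A thin CLI wraps the same library:

```bash
natkit simulate --out run/sim --n-patients 100 --seed 7
natkit process  --bundle run/sim/bundle --out run/proc
natkit report   --bundle run/sim/bundle --out run/report   # static HTML
natkit annotate --session run/session.jsonl --patient P0001 \
                --annotator dr_a --label CI --duration-min 2.5
natkit evaluate --labels-a run/labels_a.csv --labels-b run/labels_b.csv \
                --out run/eval
```

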