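# Methods

`natkit` implements a semiautomated chart-review workflow for phenotyping
cognitive status — cognitively normal (CN), cognitively impaired (CI), or
undetermined — from electronic health record (EHR) extracts, together with
the statistics used to evaluate such a workflow and a synthetic-EHR
generator that makes the whole pipeline testable without protected health
data. This note records the models, rules, parameters, and design choices,
and what the synthetic experiments do and do not demonstrate.

## The chart model and note sequences

A patient chart aggregates demographics, clinical notes, encounter events
(completed / no-show / cancelled), medication and diagnosis records, lab
results, imaging orders, and refill requests, restricted to a study period
`[period_start, period_end]` (inclusive on both ends). Undated medication
records are treated as current medications and survive period filtering —
current therapy is relevant whenever the chart is reviewed.

Notes are segmented into *sequences*: character windows of at most
`max_len` characters (default 512) cut preferentially at sentence
boundaries, then at whitespace, then — only inside an unbroken run longer
than `max_len` — at an arbitrary character. Offsets are 0-based, half-open,
over NFC-normalized text, and the concatenation of a note's sequences
reproduces its text exactly, so sequence-level highlights and
classifications map back to the note unambiguously. The 512-character
default approximates the context window of sentence-level clinical text
classifiers while staying tokenizer-agnostic.

## Keyword lexicons and highlighting

Two lexicon categories drive highlighting: *cognition* (memory/cognitive
function language) and *adl* (activities of daily living). Each entry is a
case-insensitive regular expression with a *polarity* — whether the matched
language signals impairment ("memory loss", dementia, confusion) or intact
function ("memory … intact", "good fund of knowledge", independence in
ADLs). Matching is leftmost and non-overlapping per entry, and results are
sorted (start ascending, longer span first) so they are deterministic and
independent of lexicon file order.

The shipped default lexicon is a documented reconstruction assembled from
the phrases chart reviewers key on; it is a usable fixture, not a validated
clinical instrument, and any user lexicon CSV can replace it.

Rendering wraps highlight regions in `<mark>` tags carrying category and
polarity attributes. Same-category overlaps are merged before tagging;
cross-category overlaps nest with cognition outermost (splitting tags at
boundaries so output is well-formed). Stripping tags recovers the input
text byte-for-byte; the HTML report applies entity escaping per segment, so
strip-plus-unescape is exact there as well.

## Structured features

From the structured side of the chart the package engineers:

- **Dementia medications** — case-insensitive substring match on the four
  generic stems galantamine, donepezil, rivastigmine, memantine, so brand
  and strength variants are caught.
- **Dementia ICD families** — after normalization (dots stripped,
  upper-cased): ICD-9 prefixes 290/294/331 and the exact code 780.93
  (matched exactly, not as a 780.9X family, because it denotes the specific
  memory-loss code); ICD-10 prefixes G30/G31. Family matching is restricted
  to the record's stated code system.
- **Reversible-cause labs** — a configurable panel defaulting to vitamin
  B12, folate, and TSH name variants.
- **Utilization** — counts of no-shows, cancellations, and refill requests
  relative to all scheduled encounters (completed + no-show + cancelled).
  With zero encounters the fractions are flagged undefined (`None`), never
  reported as 0.

Flags are monotone (more records can only turn them on) and all counts are
order-invariant.

## Sequence classification and note triage

A classifier is anything mapping text to a probability triple
`(p_CI, p_no_CI, p_neither)`; the trained neural sequence model such a
system would use in production is pluggable behind this contract. The
package ships a self-contained baseline: with `c_imp` cognition/impaired
and `c_int` cognition/intact matches in a sequence,

    scores = (w_imp * c_imp, w_int * c_int, b0),    p = softmax(scores)

with defaults `w_imp = w_int = 2`, `b0 = 1`. With no matches the *neither*
class dominates; each additional match multiplies the corresponding odds by
`e^2 ≈ 7.4`, which makes a single keyword decisive without saturating.
Ties in the argmax break CI > no_CI > neither, i.e. toward the class a
reviewer must not miss.

Note-level aggregation: a note is CI if any of its sequences is CI, else
no_CI if any is no_CI, else neither; its score is the maximum `p_CI` over
sequences. Ranking sorts by class (CI first), then descending score, then
recency (newest first, matching the latest-evidence convention of the
adjudication guideline), then note id. The ranking is a deterministic
permutation of its input.

## Label suggestion rules

`suggest_label` formalizes the adjudication guideline as an ordered rule
list and always reports the triggered rule with supporting records:

1. any dementia ICD family or dementia medication → **CI**;
2. impaired-cognition language with no intact language → **CI**;
3. both impaired and intact language → the polarity of the latest-dated
   span decides (CN if the intact evidence is newer); a same-date tie goes
   to impaired, since documented suspicion outweighs a same-day reassurance;
4. intact language only → **CN**;
5. no cognition evidence and fewer than `sparsity_threshold` notes
   (default 3, configurable — the guideline gives no numeric criterion) →
   **undetermined**;
6. otherwise → **CN** on implicit evidence (a multi-note chart with no
   documented cognitive concern).

The rule order differs from a naive "any impaired language → CI" reading:
conflict resolution (rule 3) must see both polarities, otherwise the
latest-evidence principle — the reason a transiently impaired, later
recovered patient is CN — could never fire. The suggestion is
decision support only: it is returned with its rationale and never
auto-saved; a human records the final label.

Annotation sessions are append-only JSONL; re-annotation appends and the
latest record per (patient, annotator) pair is authoritative. Assignment is
either *individual* (seeded shuffle dealt round-robin, partition sizes
within one) or *shared* (everyone reviews everyone, for interrater
studies). Stated durations must agree with the record's timestamps to
within a minute of rounding slack; manually entered durations are accepted
for parity with timed paper studies.

## Evaluation statistics

**Cohen's kappa.** Unweighted (the labels are nominal):
`kappa = (po − pe)/(1 − pe)` with `po` the contingency diagonal and
`pe = Σ_k (row_k/n)(col_k/n)`. When both raters use a single category,
`pe = 1` and kappa is undefined; the result carries an explicit flag rather
than a sentinel number. Preprocessing helpers mirror the comparisons such
studies need: collapsing a five-level cognition adjudication (normal,
borderline-MCI, MCI, borderline-dementia, dementia) to CN/CI by mapping
everything non-normal to CI, and removing pairs the tool-side rater marked
undetermined (reported as an exclusion count). No confidence interval is
attached; multi-rater generalizations are out of scope.

**Paired Wilcoxon signed-rank.** Differences `d_i = a_i − b_i`; zeros are
dropped (Wilcoxon's convention, the commonest for "paired samples Wilcoxon
test"), absolute differences are ranked with midranks for ties, and `W` is
the sum of positive-difference ranks. For ≤ 25 retained pairs the two-sided
p-value is exact: midranks are multiples of ½, so doubling them makes the
null distribution of `2W` an integer polynomial convolution whose counts
are identical to full `2^n` sign enumeration (the test suite verifies this
against literal enumeration for all n ≤ 12). Above 25 a normal
approximation with tie and continuity corrections is used; 25 keeps exact
enumeration cheap while the approximation is standard at that size. Mean
and SD of differences are reported both including and excluding zero pairs,
since conventions differ. Ratio summaries (median, min, max of `a_i/b_i`)
require strictly positive times and are otherwise withheld.

**Learning effect.** Chronologically ordered durations are split at the
midpoint (odd counts put the extra observation in the first half) and the
halves compared with a two-sided rank-sum test, with per-half medians
reported.

**Demographic summaries.** Categorical cells report `count (percent)` with
percents computed over the full cohort — missing values are reported
separately and never subtracted from the denominator — and rounded half-up
to one decimal. Numeric variables report mean (SD) or median (min–max).
The dementia-signal row counts patients with *either* a dementia ICD code
or a dementia medication: the disjunction is what the review tool surfaces,
and requiring both would make the high prevalence typical of elderly
Medicare cohorts unattainable.

## The synthetic-EHR generator

The generator emulates the statistical structure the pipeline assumes — it
is a study-conditions fixture, not a language model. Per patient it draws a
planted label (CI with probability `prevalence_ci`, undetermined with
`frac_undetermined`, else CN), then a chart:

- default cohort: 500 patients, 30% CI, 20% undetermined (the share of
  sparse-record patients reported for large mixed cohorts), note count
  Poisson(8) floored at 3 for determined patients;
- *undetermined* patients get 0–2 neutral-text notes and no dementia
  evidence — exactly the sparse charts the sparsity rule exists for;
- *CI* patients emit an impaired-cognition sentence per note with
  probability 0.6, a dementia ICD code with probability 0.5, and a dementia
  medication with probability 0.4 — rates chosen so that structured and
  text evidence are each informative but neither is guaranteed;
- *CN* patients emit intact-cognition sentences (0.5 per note); a 10%
  fraction carries a transient early impaired mention followed by a
  strictly later intact note — the confounder the latest-evidence rule
  resolves. Spurious impaired language in CN charts is modeled through this
  transient mechanism rather than an i.i.d. per-note leak (default leak
  rates 0), because real spurious mentions cluster in episodes rather than
  scattering independently;
- utilization: encounters Poisson(30) with 5% no-shows and 10%
  cancellations, refills Poisson(2), labs drawn from a five-test menu,
  occasional brain imaging for CI patients;
- two templates shift demographics: an elderly Medicare-style cohort
  (age ~ Normal(78.8, 7.4), high dementia-signal prevalence) and a younger
  mixed cohort (age ~ Normal(52.6, 15), ~21% undetermined).

A single integer seed drives one root generator from which everything is
drawn sequentially, so identical configurations produce byte-identical
bundles. Ground-truth labels are written to a separate table and never
appear inside the bundle.

The paired timing-study generator draws manual review times log-normal
(median 2.3 min, sigma 0.5), and tool-assisted times as manual divided by a
multiplicative speed-up (default 2.2, the size of effect such studies
report) with log-normal noise (sigma 0.25); 32 pairs by default. A speed-up
of 1.0 is the null generator.

**What passing synthetic tests shows — and does not.** The recovery tests
(rule-suggestion accuracy ≥ 0.90 against planted truth, ≥ 95% of CI
patients with a CI note in the top 3 ranks, emission rates inside exact
binomial 99% intervals of their configured values) validate the *plumbing*:
rules fire as specified, ranking surfaces planted evidence, the generator
hits its configured rates. They say nothing about performance on real
clinical text, where keyword lists miss paraphrases, negations, and
context, and where the published headline numbers (interrater kappa ≈ 0.89,
tool-vs-chart kappa ≈ 0.67) come from human experts reading real charts.
Those numbers require real EHR data and annotators and are out of reach of
a synthetic fixture by design.

## Numerical and degenerate-input conventions

- Probability triples must sum to 1 within 1e-9; violations are errors
  naming the offending sequence, not silent renormalizations.
- Kappa with `pe = 1`, fractions with zero encounters, and the signed-rank
  p with all-zero differences all return explicit undefined flags.
- Percent rounding is decimal half-up (not banker's), to one decimal.
- Sorting tie-breaks are always completed with a lexicographic id so every
  ordering is total and reproducible.
- Empty inputs: an empty note segments to no sequences; an empty patient
  list assigns to no one; an empty cohort summary and kappa on zero pairs
  are errors.

## Problem sizes

The shipped test and acceptance runs use cohorts of up to 500 synthetic
patients, 1,000-replicate null simulations at 30 pairs, full sign
enumeration up to n = 12, and 1,000-case randomized oracle comparisons —
sizes at which every oracle is computable exactly and the whole suite runs
in well under a minute on one core.

## Known limitations

- Pattern-based matching only: no negation scoping, no learned NER; a real
  deployment would plug a trained classifier into the triage contract.
- The default lexicon is a reconstruction and deliberately small.
- Note deduplication policy is strict: duplicate note ids abort ingestion
  rather than guessing at addendum semantics.
- Flat-file sessions: no concurrency, authentication, or database; the
  static HTML report replaces an interactive web application.
- The synthetic generator's text is template-based; its notes exercise the
  matcher but not the linguistic variability of clinical prose.
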