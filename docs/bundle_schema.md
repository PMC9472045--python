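# Chart-bundle schema

A chart bundle is a directory of UTF-8 CSV tables (RFC 4180, header row)
plus a plain-text manifest. The `patients` table and `manifest.txt` are
required; every other table is optional and defaults to empty. Dates are
ISO 8601 (`YYYY-MM-DD`). Blank cells mean "missing"/absent.

## manifest.txt

`key: value` lines; `#` starts a comment. Recognized keys:

| key            | meaning                                   |
|----------------|-------------------------------------------|
| `tables`       | comma-separated list of member tables      |
| `period_start` | first covered date (inclusive)             |
| `period_end`   | last covered date (inclusive)              |
| `n_patients`   | informational row count                    |

## Tables

### patients.csv
`patient_id, birth_date, sex, ethnic_group, marital_status, education, pcp_id, care_coordination_note`

- `sex`: `male | female | other` (blank → missing)
- `ethnic_group`: `black | hispanic | asian | indigenous | white | other` (blank → missing)
- `marital_status`: `married | not_married` (blank → missing)
- `education`: `college_or_more | less_than_college` (blank → missing)

### notes.csv
`note_id, patient_id, date, reason_for_visit, text, encounter_type, provider_department, provider_specialty, provider_qualifications`

`note_id` must be unique across the whole bundle (duplicates abort the
load); `text` may be empty but the column is mandatory.

### encounters.csv
`encounter_id, patient_id, date, status, kind` with
`status ∈ {completed, no_show, cancelled}`.

### medications.csv
`patient_id, name, date, current` — `date` may be blank for current
medications (`current ∈ {true, false}`); undated records are never removed
by period filtering.

### diagnoses.csv
`patient_id, code, system, description, date` with `system ∈ {ICD9, ICD10}`.
Codes keep their printed form; matching normalizes (dots stripped,
upper-cased).

### labs.csv
`patient_id, test_name, value, units, date` — `value` is numeric when it
parses as a float, otherwise kept as text.

### imaging.csv
`patient_id, modality, body_site, date` with `modality ∈ {MRI, CT, other}`.

### refills.csv
`patient_id, date, medication_name`.

## Error handling

Rows that fail to parse (bad date, unknown enum value, unknown
`patient_id`) are collected in a reject report with table, row index, and
reason — never silently dropped. A missing `patients.csv`, a missing
manifest, or a duplicate `note_id`/`patient_id` aborts the load.

## Lexicon file

Separate from the bundle: a CSV with columns
`entry_id, pattern, category, polarity` where `category ∈ {cognition, adl}`
and `polarity ∈ {impaired, intact}`; `pattern` is a case-insensitive
regular expression.
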