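"""Generate a synthetic chart cohort and summarize its demographics.

The generator plants a ground-truth cognitive status per patient (CN, CI,
or undetermined) and emits realistic chart structure: notes with keyword
sentences, encounters with no-shows/cancellations, medications, ICD codes,
labs, and refill requests.
"""

from natkit import CohortConfig, demographic_summary, generate_cohort

config = CohortConfig(n_patients=200, prevalence_ci=0.3, seed=7)
charts, truth = generate_cohort(config)

counts = {label: sum(1 for v in truth.values() if v == label)
          for label in ("CN", "CI", "undetermined")}
print(f"generated {len(charts)} patients: {counts}")

summary = demographic_summary(charts)
print(f"age mean (SD): {summary.age_mean:.1f} ({summary.age_sd:.1f}) years")
print(f"female: {summary.sex['female'].count} ({summary.sex['female'].pct}%)")
print(f"encounters median (min-max): {summary.encounters_median:.0f} "
      f"({summary.encounters_min}-{summary.encounters_max})")
print(f"dementia ICD/medication signal: {summary.dementia_signal.count} "
      f"({summary.dementia_signal.pct}%)")
# The dementia-signal percent tracks prevalence_ci times the configured
# ICD/medication emission rates; ages follow the configured normal law.
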