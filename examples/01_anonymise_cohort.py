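"""Anonymise a simulated cohort and inspect what changed.

Simulates a 500-person stratified cohort (four skewed biomarkers, four
sex-by-smoking strata), replaces every record's continuous values by the
centroid of itself and its 2 nearest neighbours within its stratum (k = 3),
and shows that the released table keeps each variable's standard deviation
exactly while every individual value moved.
"""

import pandas as pd

from detanon import AnonymisationConfig, anonymise, birth_cohort_config, simulate_cohort

cohort = simulate_cohort(birth_cohort_config(n=500, seed=7))
result = anonymise(cohort, AnonymisationConfig(k=3))
anon = result.anonymised

print("strata (sex, smoker) -> size:")
for key, rows in result.partition.groups.items():
    print(f"  {key}: {len(rows)}")

print("\nfirst three records, original vs anonymised glucose/weight:")
view = pd.DataFrame({
    "glucose_or": cohort.data["glucose"].head(3).round(3),
    "glucose_an": anon.data["glucose"].head(3).round(3),
    "weight_or": cohort.data["weight"].head(3).round(2),
    "weight_an": anon.data["weight"].head(3).round(2),
})
print(view.to_string())

print("\nper-variable sd, original vs anonymised (preserved exactly):")
summary = pd.DataFrame({
    "sd_original": cohort.continuous.std(ddof=1),
    "sd_anonymised": anon.continuous.std(ddof=1),
    "mean_original": cohort.continuous.mean(),
    "mean_anonymised": anon.continuous.mean(),
}).round(4)
print(summary.to_string())
print("\nEvery value is perturbed, but the scale (sd) of each variable is "
      "restored exactly and the mean almost exactly, so downstream analyses "
      "see data with the original spread.")
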