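"""Quantify how much analytic value anonymisation cost.

Three views of utility loss on one anonymised cohort: the global
propensity-score metric U (0 = indistinguishable from the original, 1/4 =
fully distinguishable), the per-variable delta (the share of each
anonymised variable's variability introduced by anonymisation), and the
coefficients of a regression an analyst might actually run, fitted to both
tables and compared in units of the original standard errors.
"""

from detanon import (
    AnonymisationConfig,
    anonymise,
    birth_cohort_config,
    simulate_cohort,
    utility_report,
)

cohort = simulate_cohort(birth_cohort_config(n=500, seed=7))
anon = anonymise(cohort, AnonymisationConfig(k=3)).anonymised

report = utility_report(
    cohort, anon,
    outcome="glucose",
    covariates=["hdl", "height", "weight", "sex", "smoker"],
    family="linear",
)

print(f"global utility loss U = {report.propensity.U:.6f}  (0 best, 0.25 worst)")
print("\nper-variable delta (fraction of variability due to anonymisation):")
for name, value in report.deltas.items():
    print(f"  {name:8s} {value:.4f}")

print("\nglucose ~ hdl + height + weight + sex + smoker, both tables:")
print(report.comparison.to_frame().round(4).to_string())
print("\nA std_difference well below 1 means the anonymised estimate moved "
      "by less than one original standard error; ci_overlap confirms the "
      "95% confidence intervals still intersect.")
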