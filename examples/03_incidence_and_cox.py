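"""STDR incidence rates by ethnicity and the mutually adjusted Cox model.

Rates are events per 100 person-years with exact Poisson intervals; the Cox
fit adjusts age group, sex, ethnicity, diabetes type, duration and
deprivation simultaneously.
"""

from screenlag import (
    SimulationConfig,
    build_cohort,
    cox_fit,
    generate_registry,
    incidence_rate,
    person_years,
    proportionality_check,
    rates_by,
)

episodes, profiles = generate_registry(SimulationConfig(n_persons=50_000, seed=3))
cohort, _ = build_cohort(episodes, profiles)

total = person_years(cohort)
overall = incidence_rate(int(total["events"][0]), float(total["person_years"][0]))
print(f"overall STDR rate: {overall.point:.2f} "
      f"(95% CI {overall.ci_low:.2f} to {overall.ci_high:.2f}) per 100 person-years")

print("\nby ethnicity (per 100 person-years):")
eth = rates_by(cohort, by="ethnicity")
print(eth[["ethnicity", "events", "person_years", "rate", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))

fit = cox_fit(cohort)
eth_rows = fit.table[fit.table["term"] == "ethnicity"]
print("\nmutually adjusted hazard ratios (ethnicity, reference white):")
print(eth_rows[["level", "hr", "ci_low", "ci_high", "p"]].round(3).to_string(index=False))

ph = proportionality_check(fit)
print(f"\nproportional-hazards check: max |corr with time| = "
      f"{ph['corr_with_time'].abs().max():.3f} (small values support proportionality)")
# Black and South Asian groups show substantially higher adjusted hazards than
# white — the inequality that drives unequal harm from longer recall intervals.
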