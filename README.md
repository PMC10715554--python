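# screenlag

Screening-interval policy analysis for diabetic eye screening registries.

People living with diabetes in England are offered annual retinal photography;
policy bodies have recommended a two-year recall for people at low risk (no
retinopathy on two consecutive annual screens). Whether that is safe depends
on how fast sight-threatening diabetic retinopathy (STDR — any R2, R3 or M1
grade in either eye) arises in the low-risk group, and that speed differs
sharply between sociodemographic groups. `screenlag` is a library for
quantifying, from screening-episode records, (1) STDR and proliferative
retinopathy (PDR, R3) incidence by stratum and (2) how many events a biennial
schedule would have detected at least one year later than annual screening.

It is written for epidemiologists and screening-programme analysts. Because
real programme registries cannot leave NHS networks, the package ships a
synthetic-registry generator that reproduces the statistical structure of a
large urban multi-ethnic programme, so every stage is runnable and testable
end to end.

## The model

For person *i* with covariates *x* (age band, sex, ethnicity, diabetes type,
duration, deprivation quintile), latent progression follows two independent
exponential clocks from programme entry:

- time to STDR onset: `T_stdr ~ Exp(λ0 · exp(x'β))` — a proportional-hazards
  structure with baseline hazard λ0 calibrated so the marginal cohort rate is
  0.51 per 100 person-years;
- time to non-referable retinopathy (R1M0): `T_r1 ~ Exp(λ_r1)`.

Disease is observed only at attended visits (log-normal gaps, median 1.0,
IQR 0.9–1.1 years). Cohort entry (baseline) is the second of two consecutive
R0M0 screens 0.5–1.5 years apart; follow-up is right-censored at the first
R1 or ungradable episode and ends with the event at the first STDR
presentation. Incidence is events per person-time with exact Poisson
(Garwood) intervals; the adjusted analysis is a Cox partial-likelihood fit
with Efron tie handling. For the policy question, visits are binned into
14-month cycles from baseline; under biennial screening only even cycles are
attended, so events surfacing in an odd cycle are *delayed* by at least a
year, reported per 100,000 eligible persons with Clopper–Pearson intervals.

## Worked example

```python
from screenlag import (SimulationConfig, generate_registry, build_cohort,
                       person_years, incidence_rate, cox_fit,
                       simulate_biennial, stratify_policy)

episodes, profiles = generate_registry(SimulationConfig(n_persons=50_000, seed=3))
cohort, cascade = build_cohort(episodes, profiles)

total = person_years(cohort)
rate = incidence_rate(int(total["events"][0]), float(total["person_years"][0]))
print(f"overall STDR rate {rate.point:.2f} ({rate.ci_low:.2f}-{rate.ci_high:.2f}) /100 py")

hr = cox_fit(cohort).table
print(hr[(hr.term == "ethnicity") & (hr.level == "black")][["hr", "ci_low", "ci_high"]]
      .to_string(index=False))

res = simulate_biennial(cohort, episodes)
print(f"delayed STDR {res.delayed_stdr}/{res.total_stdr}")
```

prints (seed 3):

```
overall STDR rate 0.48 (0.44-0.52) /100 py
      hr   ci_low  ci_high
2.056637 1.641778 2.576327
delayed STDR 309/606
```

Read: in this replicate the low-risk cohort develops sight-threatening
retinopathy at 0.48 events per 100 person-years; black ethnicity carries
roughly twice the adjusted hazard of white; and about half of all events fall
in screening cycles a biennial schedule would skip, i.e. would be diagnosed
at least one year later. The `examples/` directory has one narrative script
per capability (generator, cascade, incidence/Cox, policy delay, full
pipeline), and the `screenlag` CLI exposes the same stages
(`screenlag run --config pipeline.yaml --out-dir out`).

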