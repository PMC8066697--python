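# renalcea

Cost-effectiveness and budget-impact modelling of dietary interventions —
the DASH diet and potassium supplementation — in renal transplant
recipients (RTR).

## The problem

Once a kidney transplant fails, a patient returns to dialysis, which costs
roughly eight times the annual upkeep of a functioning graft and carries a
much lower quality of life. Observational evidence links better adherence
to the DASH diet and higher potassium intake to lower risks of both death
with a functioning graft (DWFG) and graft failure. `renalcea` asks the
health-economic question: if intensified dietician counselling moves
patients from the least-adherent tertile (group 1) into the middle and top
tertiles (groups 2 and 3), what happens to lifetime costs and
quality-adjusted life years (QALYs), and what would a national roll-out
cost a payer?

## The model

A five-state Markov cohort model with annual cycles over a lifetime
horizon:

    FG1 → GF1 → FG2 → GF2 → Death

FG/GF are functioning-graft and graft-failure (dialysis) states; the
second pair covers the single allowed re-transplantation, which can also
fail immediately (primary non-function, GF1 → GF2). Transition
probabilities per adherence group come from Weibull fits
S(t) = exp(−(t/λ)^k) to right-censored time-to-event data for the two
competing endpoints; annual probabilities are p_t = 1 − S(t+1)/S(t), and
extrapolated death probabilities converge with background mortality once
the curves cross. Costs (2017 euros, discounted at 4%) and utilities
(discounted at 1.5%) accrue with a half-cycle correction; productivity
losses follow the friction-cost method. Scenario results mix the three
group traces by adherence weights,

    Total = w1·Total(group 1) + w2·Total(group 2) + w3·Total(group 3),

and compare each intervention mix against 100% group 1 as an incremental
cost-effectiveness ratio (ICER = ΔCost/ΔQALY) or a dominance label.
One-way (tornado) and probabilistic (Monte-Carlo with a
cost-effectiveness acceptability curve) sensitivity analyses and a
five-year budget-impact calculation complete the pipeline.

The original patient-level registry data are not public, so the package
ships a clearly-labelled synthetic cohort generator with group-ordered
hazards; see `docs/methods.md` for what it does and does not emulate.

## Worked example

```python
from renalcea import default_config
from renalcea.pipeline import build_diet_model
from renalcea.synthetic import default_calibration, simulate_event_times

cfg = default_config()                       # published parameter tables
datasets = simulate_event_times(default_calibration("dash"), n=4000, seed=7)
model = build_diet_model("dash", cfg, datasets)
print(model.scenario_table().head(4).to_string(index=False))
```

```
 group1  group2  group3 incremental_cost incremental_qalys     icer
    0.0    0.50    0.50      -13,404,526             5,227 Dominant
    0.1    0.45    0.45      -12,012,609             4,704 Dominant
    0.2    0.40    0.40      -10,620,693             4,181 Dominant
    0.3    0.35    0.35       -9,228,776             3,659 Dominant
```

Each row is an adherence scenario for a 1000-patient cohort: with full
uptake (0% remaining in group 1) the intervention saves €13.4 million and
gains 5,227 QALYs on this synthetic calibration — it *dominates* standard
care — and the gain shrinks linearly as more patients stay in group 1.
The same pipeline runs from the shell:

```sh
renalcea --seed 7 run-all --diet dash        # cohort → fits → CEA → DSA → PSA → BIA
renalcea run-bia                             # {"initial_cost": 5818520, "annual_cost": 465234, "total_cost": 8144693}
```

The budget impact uses the per-patient intervention cost of
8 × (€60 + 7 km × €0.19 + €3) = €514.64 with 11,306 prevalent and 904
incident transplant recipients per year over five years.

## Layout

- `src/renalcea/survival.py` — datasets, Kaplan–Meier, censored Weibull
  MLE, annual probabilities, background-mortality convergence, Cholesky
  factors, life tables.
- `src/renalcea/markov.py` — the five-state engine: transition schedules
  and cohort traces.
- `src/renalcea/economics.py` — cost/QALY accrual, adherence mixing,
  ICER/dominance.
- `src/renalcea/uncertainty.py` — one-way (tornado) and probabilistic
  (CE-plane, CEAC) sensitivity analyses.
- `src/renalcea/budget.py` — budget impact.
- `src/renalcea/synthetic.py` — synthetic competing-risks cohorts.
- `src/renalcea/config.py`, `src/renalcea/pipeline.py`,
  `src/renalcea/cli.py` — configuration, stage chaining, command line.
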