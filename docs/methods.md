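# Methods

## Model structure

`renalcea` implements a cohort (expected-value) Markov model for renal
transplant recipients with five states — FG1, GF1, FG2, GF2, Death — and
annual cycles. All patients enter in FG1 (they are transplanted already,
so no transplantation cost is charged at entry). One re-transplantation is
allowed (third grafts are rare enough to ignore); a re-transplant can fail
immediately through primary non-function, routing GF1 → GF2 within the
cycle of the attempt, and the transplantation event cost is still charged
because the operation took place. Death is absorbing. There is no
pre-emptive re-transplantation pathway and no cardiovascular or other
comorbidity events.

Per cycle t (cohort age = start age + t) the transition matrix is built
from four ingredients:

* the group's annual graft-failure probability (FG → GF) and DWFG
  probability (FG → Death), both derived from Weibull survival fits;
* age-banded death probabilities on dialysis (GF → Death);
* an annual re-transplantation probability of 0.150 up to age 65,
  declining linearly to zero at age 80 (GF1 → FG2/GF2);
* the primary non-function probability 0.007 splitting the re-transplant
  flow.

Rows whose off-diagonal probabilities exceed 1 raise a configuration error
naming the cycle and state; nothing is silently renormalised, because a
row that overflows means the calibration is wrong, not the arithmetic.

## Survival inputs

Each diet has three adherence groups; for each group the two endpoints —
death with a functioning graft and graft failure — are analysed as
separate right-censored time-to-event problems, each censoring the other
(no joint cause-specific model). Kaplan–Meier estimation and Weibull
maximum likelihood run through `lifelines`; the package adds a censored
Weibull log-likelihood of its own, used to cross-check the fit, to compute
AIC = 4 − 2ℓ and BIC = 2 ln n − 2ℓ, and to obtain the covariance of
(log k, log λ) as the inverse of a numerically differentiated observed
information matrix (central differences; eigenvalues floored at 1e−12
when rounding makes the matrix indefinite). The Weibull family is fixed —
no alternative parametric families are offered.

Annual probabilities are computed on the cumulative-hazard scale,
p_t = 1 − exp(H(t) − H(t+1)), which never underflows, and satisfy the
telescoping identity Π(1−p_t) = S(T) to machine precision.

**Background convergence.** Extrapolated DWFG probabilities are replaced
by general-population mortality from the first cycle at which the
extrapolation falls below the background annual death probability for the
cohort's age, and are kept at the maximum of the two thereafter. This
applies only to the death endpoint: background mortality is a death
process, so the graft-failure extrapolation runs to the end of the
horizon. A real national life table can be supplied as CSV
(`age,q_annual`); the shipped default is a synthetic Gompertz–Makeham
table, h(a) = 5·10⁻⁴ + 1.677·10⁻⁵·e^{0.1a}, calibrated to the order of
magnitude of Dutch adult mortality (q ≈ 0.004 at 53, ≈ 0.05 at 80).

## Economics

State accruals use the half-cycle correction in trapezoidal form — the
mean of successive occupancy rows — and every cycle-t accrual is
discounted at t + 0.5 (events happen mid-year). Whether discounting uses
t or t + 0.5 is a genuinely open convention; it is configurable
(`mid_cycle_discount`), with t + 0.5 the default. Costs discount at 4%,
effects at 1.5%.

Cost categories: transplant upkeep €10,820/yr (FG states), dialysis
upkeep €87,855/yr (GF states), diet costs (FG states of groups 2–3 only —
the dietary changes stop on dialysis; DASH €182.50/€365 per year,
potassium €84.74/€169.47), graft-failure event €2,397, transplantation
event €59,949, death event €1,165 (charged on every entry into Death,
from dialysis as well as from FG), and productivity. Utilities: 0.81 for
FG; the GF state blends haemodialysis (0.56, 86% of patients) and
peritoneal dialysis (0.58, 14%) to 0.5628; Death is 0.

**Productivity (friction-cost method).** A move FG → GF costs
Δworking-share(age band) × 85 friction days × 8 h × the sex-blended wage
(0.563 × €37.90 + 0.437 × €31.60 = €35.15/h); the reverse move GF1 → FG2
books the same magnitude as a saving, so a round trip at one age nets
zero. Re-transplantation additionally costs the hospital stay,
working-share(FG) × 10.58 days × 8 h × wage. Ages below 45 reuse the
45–54 working shares.

**Intervention cost.** Eight dietician visits at €60 plus 7 km of travel
at €0.19/km and €3 parking per visit: €514.64 per patient. Travel is
charged one way per visit — the only convention consistent with the
published national roll-out arithmetic (€5,818,520 / 11,306 = €514.64).
The cost is charged once, undiscounted, to every cohort member in every
intervention scenario (all members sat in group 1 before the
intervention), so it is a constant offset across adherence rows.

**Mixing and comparison.** Scenario totals are adherence-weighted sums of
the three group traces; the non-adherent remainder (1 − p) splits equally
between groups 2 and 3. Incremental results against the 100%-group-1
comparator are therefore affine in p — incremental QALYs at p equal
(1 − p) times the 0%-adherence value. ICERs are reported truncated toward
zero to whole euros, matching the published rounding (168,552/580 → 290;
341,846/290 → 1178); negative-cost/positive-QALY results are labelled
Dominant, the reverse Dominated, and a zero QALY difference is flagged
undefined rather than divided.

## Cohort settings

Start age 53 (cohort mean), cohort size 1000, horizon 57 cycles (to age
110). A lifetime horizon must leave essentially nobody alive: the
pipeline warns if more than 0.5% of the cohort outlives the horizon.
Age 100 was considered but leaves ~1% of the synthetic cohort alive under
the shipped calibration, so the default extends to 110.

## Sensitivity analyses

**One-way (tornado).** Every parameter is varied to the lower and upper
limit of its 95% CI — the printed range when the source tables give one,
otherwise base ± 1.96 × (25% of base), clipped to domain bounds — with
everything else at base, and the full pipeline re-runs at each limit.
Transition probabilities enter as multiplicative factors (base 1.0) on
each group's extrapolated DWFG/graft-failure vectors, clipped to [0, 1],
with convergence re-applied. Bars are ordered by the width of the
incremental net monetary benefit (NMB = WTP·ΔQALY − ΔCost, WTP
€20,000/QALY) rather than by ICER width, because the base case is
dominant and ICERs are undefined or discontinuous around dominance; the
ICER at each limit is still reported. Failures at a limit flag the entry
instead of dropping it.

**Probabilistic.** Each iteration jointly draws: utilities and working
shares from beta distributions and costs from gamma distributions, both
moment-matched to (base, SE) with SE backed out of the printed CI or
assumed at 25% of base; hospital days, dietician visits and scalar
probabilities from normals truncated (by resampling) to their domains;
and the six (log shape, log scale) Weibull pairs as base + L·z with L the
Cholesky factor of each fit's covariance — so survival uncertainty enters
through correlated parameter draws, not through independent perturbation
of each annual probability. Default 10,000 iterations (configurable; the
test suite uses 200). Results feed a CE-plane pair list and a CEAC over a
WTP grid of €0–80,000 in €500 steps; the CEAC value at λ is the fraction
of draws with λ·ΔQALY − ΔCost > 0.

## Budget impact

Payer perspective, no discounting, no uptake ramp or downstream savings:
initial = prevalent (11,306) × €514.64, annual = incident (904) ×
€514.64, total = initial + 5 × annual. Whole-euro reporting uses
nearest-euro rounding for the initial and total amounts and truncation
for the recurring annual amount; the three published figures are not
mutually consistent under any single rounding rule, and this convention
reproduces all three.

## Synthetic cohort generator

The registry data behind the original fits are not available, so the
generator creates patient-level datasets with the structure the analysis
assumes: per patient, independent latent Weibull times for the two
endpoints; the earlier is observed for its endpoint and censors the
other; administrative censoring at 12 years of follow-up plus a 15%
fraction censored uniformly at random. Default cohort size 632 patients
per group (the size of the source cohort; tests use larger cohorts where
estimation precision matters).

The shipped calibration (synthetic stand-ins, not study estimates) shares
the Weibull shape within an endpoint — 1.2 for DWFG, 1.1 for graft
failure — so that the scale ordering implies hazard ordering at every
time, with group 1 riskiest: DASH scales (7.5, 18, 22) years for DWFG and
(9, 23, 29) for graft failure; potassium (7.5, 19, 24) and (9, 22, 27).
Group 1's short, dialysis-heavy prognosis makes the base case dominant
and makes the group-1 event probabilities the strongest levers in the
tornado; the potassium groups gain relatively more on patient survival
(QALYs) and the DASH groups more on graft survival (cost savings).

What the generator does *not* emulate: covariates (age, sex, BMI,
diabetes), dependence between the two endpoint processes, time-varying
adherence, and calendar effects. Passing tests therefore demonstrate that
the pipeline is internally correct and behaves as the analysis assumes —
not that the shipped numbers describe any real cohort.

## Numerical conventions and degenerate inputs

* Annual probabilities computed on the hazard scale; vectors validated to
  [0, 1]; survival-ratio underflow raises instead of propagating NaN.
* Trace conservation holds to 1e−9 persons on a 1000-person cohort; row
  sums of transition matrices to 1e−12.
* Datasets without a single event are accepted by Kaplan–Meier (flagged
  `all_censored`, S ≡ 1) but refused by the Weibull fitter.
* Beta moment-matching rejects SEs too large for the unit interval,
  naming the parameter; zero SE reproduces the base value exactly.
* Second-graft (FG2) event probabilities reuse the group's vectors
  indexed by model time, not time since re-transplant — a memoryless
  reading forced by the absence of separate second-graft fits; the
  alternative indexing is noted as a known unknown.
* One global seed drives every stochastic stage; fixed seed ⇒
  bit-identical cohorts, PSA pair clouds, and CSV outputs.

## Known limitations

Cohort expected values only (no microsimulation, no individual
heterogeneity); a single re-transplantation; diet effects switch on
instantly and persist for life; adherence groups differ only in their
transition probabilities; the synthetic life table and calibration are
stand-ins, so absolute cost/QALY magnitudes on synthetic data carry no
clinical meaning.
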