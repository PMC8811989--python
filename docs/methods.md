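# Methods

## Model structure

`strokeburden` is an incidence-based, patient-level state-transition model.
Health states are the seven modified Rankin Scale (mRS) levels; mRS 6 (dead)
is absorbing and states never improve. Patients enter 12 months after an
index stroke in an mRS state drawn from the published 12-month distribution
(which includes an 8.66% probability of having died in the first year) and
advance through annual cycles.

Within a cycle the event hierarchy is:

1. **Recurrent stroke** (never in cycle 1 — the first year's events are
   already embedded in the entry distribution and short-term inputs) with
   probability `min(1, r · RR^k)`, `r = 0.0201/yr`, `RR = 1.39`, `k` = number
   of post-index recurrences. A recurrence is fatal with probability 0.0866
   below attained age 65 and 0.2683 at 65+; survivors move to a state drawn
   uniformly from {current, …, 5}.
2. **Background death** otherwise, at the life-table annual probability for
   the attained integer age.
3. **No event** otherwise.

A patient cannot both recur and die of background causes in the same cycle;
at the rates involved the interaction is second order. Cycle length is one
year because every published rate, cost and utility is annual. There is no
half-cycle correction: rewards are whole-cycle, which matches the published
per-case totals on back-calculation.

### Age clock

Entry age is the index age plus one year (entry is 12 months post stroke);
attained age in cycle *t* is `entry age + t − 1` and all age thresholds (the
65-year case-fatality switch and the indirect-cost cutoff) use attained age,
so patients who cross 65 mid-simulation switch regimes in the corresponding
cycle.

## Accounting

Every cycle accrues a cost triple (medical, non-medical, indirect; 2018 AUD
per year) and a utility for the occupied state:

- **Cycle 1** always accrues the short-term (first-year, trial-measured)
  triple of the entry state — including mRS 6, whose published first-year
  costs describe a fatal index stroke — and the short-term utility if the
  cycle is completed alive.
- **Cycles ≥ 2** accrue the long-term triple and long-term utility. The
  cycle of a survived recurrence accrues the short-term triple of the
  post-recurrence state instead (acute re-hospitalisation loading); a fatal
  recurrence accrues the short-term mRS 6 triple once; background-death
  cycles accrue nothing. Each of these is a configuration toggle
  (`AccountingOptions`).
- **Indirect costs** (productivity losses, human-capital approach) are
  zeroed from cycle 2 onwards once attained age reaches 65. Cycle-1 indirect
  costs are never cut off because they were measured directly on the cohort.
- **Discounting**: costs at 5%/yr with cycle 1 as the undiscounted reference
  year, `(1+r)^−(t−1)`. QALYs are undiscounted in the base case — the
  published per-case QALY totals are consistent only with undiscounted
  accumulation — with a configurable rate for alternative analyses.

Life years are undiscounted completed alive cycles, so a patient dying
during cycle *t* contributes *t − 1* years. QALYs ≤ LYs holds by
construction since utilities are ≤ 1.

## Background mortality

A single combined-sex Gompertz–Makeham hazard `μ(x) = a + b·e^{cx}` is
least-squares calibrated (scipy, log-parameterized) so that the implied
remaining life expectancies match the five published general-population
values at the representative (bracket-midpoint) index ages; the fitted table
reproduces them within 0.18 years, well inside the 0.5-year contract. Annual
death probabilities integrate the hazard exactly over each year of age;
everyone dies by age 110, bounding lifetime runs. A CSV life table
(`age,qx`) can replace the fitted one. Combined-sex is used because the
published life-expectancy targets are combined-sex; sex is carried on each
patient but does not enter the base-case hazard.

## Synthetic cohort

The generator reproduces the published cohort structure exactly where it is
printed: per-bracket counts (499 / 657 / 1,649 / 3,842 / 6,908 summing to
13,555), male fraction 0.6007 (Bernoulli), and the 12-month mRS distribution
— by largest-remainder quota by default (removing multinomial noise from
base-case runs; a multinomial mode is used inside the PSA). What is *not*
printed is filled with minimal assumptions: ages uniform within each index
bracket (the `<25` bracket spans 18–24, an adult-only population), stroke
type (82/12/6% ischaemic/ICH/undetermined) carried as metadata only. The
generator does not emulate comorbidity, sex-specific severity or any
covariate correlation — passing tests therefore demonstrate internal
consistency with the published marginals, not fidelity to individual-level
registry data.

## Sensitivity analyses

**One-way (tornado).** Every published input cell is varied over its
published range, plus three structural parameters: recurrence rate and cost
discount rate over null-to-double ranges, and the entry-age distribution
shifted ±5 years. Legs use common random numbers (identical cohort and
simulation seeds), so the swing isolates the parameter. Outcome: per-case
total cost at the 30-year horizon. The three structural parameters produce
the largest swings (discount rate, recurrence rate, entry age, in that
order), matching the published qualitative ranking.

**Probabilistic (PSA).** No distributional families were published, so draws
are uniform over the published ranges (utilities clipped to [0, 1]; the
entry distribution drawn per-state over its ±10% range and renormalized).
Several published ranges exclude their own point estimate (e.g. short-term
mRS 6 non-medical 19,738 with range 0–2,627); they are used verbatim, which
is why the PSA mean sits below the base case here while the published PSA
means sit above it — the original distribution settings are unrecoverable,
so published PSA means are treated as qualitative context only. Default
5,000 draws × 1,000 patients per draw.

## Loss of life years and QALYs

A lifetime simulation provides each entry group's mean remaining life years
(decedent entrants count zero). The general-population comparator is the
calibrated life table's expectancy at the group's mean entry age. QALYs
multiply life years by an age-bracket utility (separate published columns
for the general and stroke populations); the base case holds the entry-age
bracket's utility constant, the sensitivity mode walks year by year through
the brackets as the cohort ages (pro-rating the final fractional year), and
ages beyond the last bracket (80–85) reuse its utilities. Because both
utility columns are non-increasing in age, aging-mode QALYs never exceed
constant-mode QALYs and sensitivity losses exceed base losses, as in the
published pattern. Note one deliberate convention mismatch: simulated life
years are completed whole years while the life-table expectancy carries a
half-year correction, so a perfectly null comparison would still show a
~0.5-year "loss"; in the real comparison this is small against the
11–12-year gap driven by first-year deaths and recurrence mortality.

## Numerical choices

- Vectorized simulation: one uniform variate per patient × cycle × decision,
  pre-drawn from a single seeded PCG64 generator, so each patient consumes a
  dedicated slice of randomness and results are independent of evaluation
  order; the scalar per-cycle path (`advance_cycle`, `accumulate`) is kept
  as a readable reference implementation and the two are tested for exact
  agreement.
- Largest-remainder quota allocation breaks remainder ties toward the lower
  index (stable argsort).
- Calibration runs Levenberg–Marquardt on log-parameters with tight
  (1e-14) tolerances; residuals above 0.5 years raise a calibration error.
- Percentile intervals use linear-interpolation empirical percentiles.
- Parameter validation rejects invariant violations (probabilities outside
  [0, 1], distributions not summing to 1, negative costs) but keeps
  published ranges that exclude their point estimate, recording a warning.

## Fidelity and limitations

With the packaged inputs and five-seed averaging the model reproduces the
published per-case burden closely: 5-year cost −4.8%, 5-year QALYs −0.8%,
30-year cost +9.4%, 30-year QALYs −6.0%; per-case medical and non-medical
components match within ~0.5% at both horizons, and the 5-year patient-level
cost percentile interval (37.8k–496.3k) reproduces the published interval
almost exactly. The residual discrepancies are concentrated in the 30-year
indirect component and in slightly lower simulated survival (lifetime
remaining life years for the 55–64 group come out ≈6% below the published
value); both are sensitive to conventions the original report does not
specify — how recurrent events are costed, how the age clock is initialized,
and how productivity losses were truncated — and the chosen conventions are
the ones documented above. Other known limitations: no within-first-year
modelling (the entry distribution summarizes it), no stroke-type-specific
costs, no sex-specific background mortality in the base case, no mortality
improvement trends, and the human-capital indirect costing (no frictional
method, presenteeism or transfer payments).

## Problem sizes

Default analyses simulate the full 13,555-patient cohort (a 30-year run
takes well under a second). The test suite uses the full cohort for
base-case checks, 5 × 10⁵ patients for rate-recovery checks, 10⁵ for
survival-oracle checks, and reduced per-draw cohorts (300–2,000 patients)
inside PSA and tornado structure tests; the full default pipeline including
a 5,000-draw PSA completes in well under five minutes on one CPU.
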