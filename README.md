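# strokeburden

A patient-level (Markov microsimulation) cost-of-illness model of stroke in
working-age adults (18–64 years), built for health economists and policy
analysts who need incidence-based burden estimates from a societal
perspective.

The model simulates one year of incident working-age strokes in Australia
(13,555 cases, 23.58% of 57,487 incident strokes) entering 12 months after
the index event in one of the seven modified Rankin Scale (mRS) health
states, mRS 0 (no symptoms) to mRS 6 (dead). Each annual cycle a survivor
can

- suffer a recurrent stroke with probability `min(1, 0.0201 · 1.39^k)` where
  `k` counts prior recurrences, which is fatal with the age-dependent case
  fatality (8.66% under 65, 26.83% at 65+), otherwise moving the patient to a
  state drawn uniformly from {current, …, 5} — states never improve;
- die of background causes at the annual probability `q(x)` of a
  Gompertz–Makeham life table calibrated to published general-population
  remaining life expectancies; or
- remain in the same state.

Each cycle accrues state-specific annual costs (medical, non-medical,
indirect; 2018 AUD) and a utility. The first model year uses the short-term
(trial-measured) cost and utility set, later years the long-term set; costs
are discounted at 5% per year, QALYs are undiscounted in the base case;
indirect (productivity) costs stop at attained age 65. Outputs are 5- and
30-year population totals and per-case means, one-way (tornado) and
probabilistic sensitivity analyses, and a lifetime comparison of remaining
life years and QALYs against the age-matched general population.

## Worked example

```bash
strokeburden simulate --horizon 5 --seed 1 --out outputs/
```

writes `burden-summary-5y.{csv,json}` plus per-patient outcomes and a run
manifest. With the packaged default parameters this prints (seed 1):

| quantity | value |
| --- | --- |
| cohort size | 13,555 |
| total 5-year cost | AUD 1.92 billion (USD 1.50 billion) |
| total 5-year QALYs | 41,241 |
| per-case cost | AUD 141,577 |
| per-case cost percentile interval (2.5–97.5%) | AUD 37,774 – 496,310 |
| per-case QALYs | 3.04 |
| per-case medical / non-medical / indirect | AUD 52,399 / 18,193 / 70,985 |

The per-case mean is the population total divided by the 13,555 cases; the
interval is the 2.5th–97.5th percentile of the patient-level cost
distribution, which is strongly right-skewed because severely disabled
survivors accrue far larger annual costs than mRS 0–1 survivors, while the
8.66% of entrants who die within the first year accrue only first-year
costs. The same command with `--horizon 30` gives the long-term burden, and

```bash
strokeburden all --seed 1 --out outputs/
```

runs both horizons, the tornado and probabilistic sensitivity analyses and
the QALY-loss table in one pass (a few minutes on one CPU; the full
pipeline is deterministic given the seed).

Library use mirrors the CLI:

```python
import strokeburden as sb

params = sb.load_parameters()                       # packaged inputs
table = sb.build_life_table(sb.calibrate(dict(params.le_targets)))
cohort = sb.sample_cohort(params.cohort, params.initial_distribution, seed=1)
sim = sb.simulate(cohort, params, table, horizon=5, seed=2)
summary = sb.summarize(sb.accumulate_all(sim, params), horizon=5)
print(summary.per_case_cost_mean, summary.per_case_qaly_mean)
```

## Layout

| module | role |
| --- | --- |
| `parameters` | load/validate every model input; packaged JSON fixture |
| `lifetable` | Gompertz–Makeham background mortality, calibrated to published life expectancies |
| `cohort` | synthetic entry cohort (ages, sex, initial mRS states) |
| `engine` | the annual-cycle microsimulation |
| `accounting` | discounted costs and QALYs per trajectory |
| `burden` | population totals, per-case means, percentile intervals |
| `sensitivity` | tornado and probabilistic sensitivity analyses |
| `qaly_loss` | lifetime LY/QALY loss versus the general population |
| `cli` | `strokeburden` command-line interface |

See `docs/methods.md` for the model assumptions, parameter provenance and
known limitations.
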