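"""One-way (tornado) and probabilistic sensitivity analysis.

Parameters are addressed by dotted names:

* ``initial_mrs.K``              entry probability of mRS K (others renormalized)
* ``utility.short.K`` / ``utility.long.K``
* ``cost.short.K.medical|nonmedical|indirect`` / ``cost.long.K....``
* ``recurrence.annual_rate``, ``recurrence.risk_ratio``
* ``discount.cost_rate``
* ``entry_age_shift``            shift of every index-age bracket, in years

The default range set varies each published Table-style input over its
published sensitivity range, the recurrence rate and discount rate over
null-to-double ranges, and the entry ages by +/-5 years.  One-way legs use
common random numbers (identical cohort and simulation seeds) so the swing
isolates the varied parameter.  PSA draws costs and utilities uniformly over
their published ranges (no distributional families were published) and the
entry distribution per-state uniformly over its +/-10% range, renormalized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import accounting, cohort as cohort_mod, engine
from .errors import ConfigurationError, ValidationError
from .lifetable import LifeTable
from .parameters import (
    DEAD,
    CostTriple,
    InitialStateDistribution,
    ModelParameters,
    UtilityTable,
)


@dataclass(frozen=True)
class ParameterRange:
    name: str
    low: float
    high: float
    base: float

    def validate(self) -> None:
        if self.low > self.high:
            raise ValidationError(f"range {self.name}: low {self.low} > high {self.high}")


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    outcome_at_low: float
    outcome_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


@dataclass(frozen=True)
class PsaResult:
    n_draws: int
    per_case_cost: tuple[float, float, float]   # mean, p2.5, p97.5
    per_case_qalys: tuple[float, float, float]
    draws: pd.DataFrame                         # columns draw, per_case_cost, per_case_qalys

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "per_case_cost": {"mean": self.per_case_cost[0],
                              "pct2p5": self.per_case_cost[1],
                              "pct97p5": self.per_case_cost[2]},
            "per_case_qalys": {"mean": self.per_case_qalys[0],
                               "pct2p5": self.per_case_qalys[1],
                               "pct97p5": self.per_case_qalys[2]},
        }


def _set_initial_prob(params: ModelParameters, state: int, value: float) -> ModelParameters:
    probs = np.asarray(params.initial_distribution.prob_by_mrs, dtype=float)
    others = np.delete(np.arange(len(probs)), state)
    rest = probs[others].sum()
    new = probs.copy()
    new[state] = value
    new[others] = probs[others] * (1.0 - value) / rest  # proportional renormalization
    dist = dataclasses.replace(params.initial_distribution, prob_by_mrs=tuple(new))
    return dataclasses.replace(params, initial_distribution=dist)


def _set_cost(params: ModelParameters, period: str, state: int,
              component: str, value: float) -> ModelParameters:
    attr = "short_term" if period == "short" else "long_term"
    triples = list(getattr(params.costs, attr))
    triples[state] = triples[state]._replace(**{component: value})
    costs = dataclasses.replace(params.costs, **{attr: tuple(triples)})
    return dataclasses.replace(params, costs=costs)


def _set_utility(params: ModelParameters, period: str, state: int,
                 value: float) -> ModelParameters:
    attr = "short_term" if period == "short" else "long_term"
    vals = list(getattr(params.utilities, attr))
    vals[state] = min(1.0, max(0.0, value))
    utilities = dataclasses.replace(params.utilities, **{attr: tuple(vals)})
    return dataclasses.replace(params, utilities=utilities)


def apply_parameter(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one named parameter set to ``value``.

    ``entry_age_shift`` is handled by the caller (it changes the cohort, not
    the parameter set) and passes through unchanged here.
    """
    parts = name.split(".")
    try:
        if parts[0] == "initial_mrs":
            return _set_initial_prob(params, int(parts[1]), value)
        if parts[0] == "utility":
            return _set_utility(params, parts[1], int(parts[2]), value)
        if parts[0] == "cost":
            return _set_cost(params, parts[1], int(parts[2]), parts[3], value)
        if name == "recurrence.annual_rate":
            rec = dataclasses.replace(params.recurrence, annual_rate=value)
            return dataclasses.replace(params, recurrence=rec)
        if name == "recurrence.risk_ratio":
            rec = dataclasses.replace(params.recurrence, risk_ratio_per_prior_event=value)
            return dataclasses.replace(params, recurrence=rec)
        if name == "discount.cost_rate":
            disc = dataclasses.replace(params.discount, cost_rate=value)
            return dataclasses.replace(params, discount=disc)
        if name == "entry_age_shift":
            return params
    except (IndexError, ValueError) as exc:
        raise ConfigurationError(f"malformed parameter name '{name}': {exc}") from exc
    raise ConfigurationError(f"unknown parameter name '{name}'")


def default_ranges(params: ModelParameters) -> list[ParameterRange]:
    """Every published range plus the structural one-way parameters."""
    ranges: list[ParameterRange] = []
    d = params.initial_distribution
    for k in range(DEAD + 1):
        ranges.append(ParameterRange(f"initial_mrs.{k}", d.low[k], d.high[k], d.prob_by_mrs[k]))
    u = params.utilities
    for k in range(DEAD):
        ranges.append(ParameterRange(f"utility.short.{k}", *u.short_range[k], u.short_term[k]))
        ranges.append(ParameterRange(f"utility.long.{k}", *u.long_range[k], u.long_term[k]))
    for period, triples, rngs in (("short", params.costs.short_term, params.costs.short_range),
                                  ("long", params.costs.long_term, params.costs.long_range)):
        n_states = DEAD + 1 if period == "short" else DEAD
        for k in range(n_states):
            for comp in CostTriple._fields:
                lo = getattr(rngs[k][0], comp)
                hi = getattr(rngs[k][1], comp)
                base = getattr(triples[k], comp)
                if lo == hi == base == 0:
                    continue  # unpublished/absent input (e.g. mRS 0 long-term indirect)
                ranges.append(ParameterRange(f"cost.{period}.{k}.{comp}", lo, hi, base))
    rate = params.recurrence.annual_rate
    ranges.append(ParameterRange("recurrence.annual_rate", 0.0, 2 * rate, rate))
    cr = params.discount.cost_rate
    ranges.append(ParameterRange("discount.cost_rate", 0.0, 2 * cr, cr))
    ranges.append(ParameterRange("entry_age_shift", -5.0, 5.0, 0.0))
    return ranges


def _run_leg(params: ModelParameters, table: LifeTable, horizon: int,
             seed: int, n_patients: int | None, age_shift: float = 0.0) -> float:
    spec = params.cohort
    if n_patients is not None and n_patients != spec.n_patients:
        spec = cohort_mod.scaled_spec(spec, n_patients)
    coh = cohort_mod.sample_cohort(spec, params.initial_distribution, seed=seed,
                                   age_shift=age_shift)
    sim = engine.simulate(coh, params, table, horizon=horizon, seed=seed + 1)
    outcomes = accounting.accumulate_all(sim, params)
    return float(outcomes["total"].mean())


def one_way(
    params: ModelParameters,
    ranges: list[ParameterRange],
    table: LifeTable,
    horizon: int = 30,
    seed: int = 0,
    n_patients: int | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: per-case total cost at each range end, common random numbers.

    Entries come back sorted by descending swing.
    """
    entries = []
    for r in ranges:
        r.validate()
        legs = {}
        for end, value in (("low", r.low), ("high", r.high)):
            if r.name == "entry_age_shift":
                legs[end] = _run_leg(params, table, horizon, seed, n_patients,
                                     age_shift=value)
            else:
                varied = apply_parameter(params, r.name, value)
                legs[end] = _run_leg(varied, table, horizon, seed, n_patients)
        entries.append(TornadoEntry(r.name, legs["low"], legs["high"]))
    return sorted(entries, key=lambda e: -e.swing)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": e.name,
        "outcome_at_low": e.outcome_at_low,
        "outcome_at_high": e.outcome_at_high,
        "swing": e.swing,
    } for e in entries])


def sample_psa(params: ModelParameters, rng: np.random.Generator) -> ModelParameters:
    """One PSA parameter draw: uniform over every published range.

    Utilities are clipped to [0, 1]; the entry distribution is drawn per-state
    over its +/-10% range and renormalized to sum to 1.  Structure (recurrence,
    discounting, cohort) is unchanged.
    """
    d = params.initial_distribution
    probs = rng.uniform(d.low, d.high)
    probs = probs / probs.sum()
    dist = InitialStateDistribution(prob_by_mrs=tuple(probs), low=d.low, high=d.high)

    u = params.utilities
    short_u = tuple(np.clip(rng.uniform(lo, hi), 0, 1) for lo, hi in u.short_range)
    long_u = tuple(np.clip(rng.uniform(lo, hi), 0, 1) for lo, hi in u.long_range)
    utilities = UtilityTable(short_term=short_u, long_term=long_u,
                             short_range=u.short_range, long_range=u.long_range)

    def draw_triples(ranges, n_states):
        out = []
        for k in range(n_states):
            lo, hi = ranges[k]
            out.append(CostTriple(*(rng.uniform(getattr(lo, c), getattr(hi, c))
                                    for c in CostTriple._fields)))
        return tuple(out)

    costs = dataclasses.replace(
        params.costs,
        short_term=draw_triples(params.costs.short_range, DEAD + 1),
        long_term=draw_triples(params.costs.long_range, DEAD) + (CostTriple(0.0, 0.0, 0.0),),
    )
    return dataclasses.replace(params, initial_distribution=dist,
                               utilities=utilities, costs=costs)


def run_psa(
    params: ModelParameters,
    table: LifeTable,
    n_draws: int = 5000,
    n_patients_per_draw: int = 1000,
    horizon: int = 5,
    seed: int = 0,
) -> PsaResult:
    """Probabilistic sensitivity analysis: re-simulate under sampled parameters.

    Each draw samples a parameter set, builds a fresh (scaled) cohort under the
    drawn entry distribution, simulates the horizon and records the per-case
    mean cost and QALYs.  Means and percentile intervals are taken over draws.
    """
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
    param_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    sim_seeds = np.random.SeedSequence([seed, 2]).generate_state(2 * n_draws) % (2 ** 31)
    spec = params.cohort
    if n_patients_per_draw != spec.n_patients:
        spec = cohort_mod.scaled_spec(spec, n_patients_per_draw)
    cost_draws = np.empty(n_draws)
    qaly_draws = np.empty(n_draws)
    for i in range(n_draws):
        drawn = sample_psa(params, param_rng)
        coh = cohort_mod.sample_cohort(spec, drawn.initial_distribution,
                                       seed=int(sim_seeds[2 * i]), mrs_mode="multinomial")
        sim = engine.simulate(coh, drawn, table, horizon=horizon,
                              seed=int(sim_seeds[2 * i + 1]))
        outcomes = accounting.accumulate_all(sim, drawn)
        cost_draws[i] = outcomes["total"].mean()
        qaly_draws[i] = outcomes["qalys"].mean()
    c_lo, c_hi = np.percentile(cost_draws, [2.5, 97.5])
    q_lo, q_hi = np.percentile(qaly_draws, [2.5, 97.5])
    return PsaResult(
        n_draws=n_draws,
        per_case_cost=(float(cost_draws.mean()), float(c_lo), float(c_hi)),
        per_case_qalys=(float(qaly_draws.mean()), float(q_lo), float(q_hi)),
        draws=pd.DataFrame({"draw": np.arange(n_draws),
                            "per_case_cost": cost_draws,
                            "per_case_qalys": qaly_draws}),
    )
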