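"""Turn trajectories into discounted costs and QALYs.

Accrual rules (base case; every structural choice is a toggle on
:class:`~strokeburden.parameters.AccountingOptions`):

* Cycle 1 always accrues the short-term (first-year) cost triple of the entry
  state — including mRS 6, whose published first-year costs cover a fatal
  index stroke — and the short-term utility if the patient completes the
  cycle alive.
* Later cycles accrue the long-term triple and long-term utility of the
  occupied state.  The cycle of a survived recurrence accrues the short-term
  triple of the post-recurrence state instead (acute re-hospitalisation
  loading); a fatal recurrence accrues the short-term mRS 6 triple once.
  Background-death cycles accrue nothing.
* Indirect (productivity) costs are zeroed from cycle 2 onwards once attained
  age reaches the working-age cutoff (65); cycle-1 indirect costs are never
  cut off because they were measured directly.
* Costs discount at ``(1 + r)^-(cycle - 1)`` — the first cycle is the
  reference year.  QALYs use their own rate (0 in the base case).

Life years are undiscounted completed alive cycles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import (
    EVENT_NONE,
    EVENT_NOT_IN_MODEL,
    EVENT_RECURRENCE_DEATH,
    EVENT_RECURRENCE_SURVIVED,
    SimulationResult,
    Trajectory,
)
from .errors import DomainError
from .parameters import DEAD, CostTable, CostTriple, ModelParameters, UtilityTable


def discount_factor(rate: float, cycle: int) -> float:
    """Present-value factor for a cycle; the reference cycle (1) is undiscounted."""
    if cycle < 1:
        raise DomainError(f"cycle must be >= 1, got {cycle}")
    if rate < 0:
        raise DomainError(f"rate must be >= 0, got {rate}")
    return (1.0 + rate) ** -(cycle - 1)


def annuity_factor(rate: float, n_cycles: int) -> float:
    """Sum of discount factors for cycles 2..(n_cycles + 1): the long-term stream."""
    return sum(discount_factor(rate, k) for k in range(2, n_cycles + 2))


def cycle_cost(
    mrs: int,
    cycle: int,
    attained_age: float,
    recurred_this_cycle: bool,
    costs: CostTable,
    cutoff: float = 65.0,
    *,
    recurrence_costing: bool = True,
    indirect_cutoff: bool = True,
) -> CostTriple:
    """Undiscounted cost triple accrued by an occupied state in one cycle.

    ``mrs`` is the state occupied at the end of the cycle (the post-recurrence
    state in a recurrence cycle; 6 in a fatal-recurrence cycle).  mRS 6 beyond
    its entry/death cycle costs nothing — callers pass those cycles only via
    the death-cycle rules.
    """
    if cycle == 1:
        triple = costs.short_term[mrs]
        return triple
    if mrs == DEAD and not recurred_this_cycle:
        return CostTriple(0.0, 0.0, 0.0)
    if recurred_this_cycle and recurrence_costing:
        triple = costs.short_term[mrs]
    else:
        triple = costs.long_term[mrs]
    if indirect_cutoff and attained_age >= cutoff:
        triple = CostTriple(triple.medical, triple.nonmedical, 0.0)
    return triple


def cycle_qaly(mrs: int, cycle: int, utilities: UtilityTable, qaly_rate: float = 0.0) -> float:
    """Discounted utility accrued by completing one cycle alive in ``mrs``."""
    if mrs == DEAD:
        return 0.0
    u = utilities.short_term[mrs] if cycle == 1 else utilities.long_term[mrs]
    return u * discount_factor(qaly_rate, cycle)


def accumulate(trajectory: Trajectory, params: ModelParameters) -> dict:
    """Discounted per-patient outcome, cycle by cycle (scalar reference path).

    Returns a dict with keys medical, nonmedical, indirect, total, qalys, lys.
    The vectorized :func:`accumulate_all` must agree with this exactly.
    """
    opts = params.accounting
    cutoff = params.cohort.indirect_cost_age_cutoff
    med = non = ind = qalys = 0.0
    horizon = len(trajectory.states)
    for cycle in range(1, horizon + 1):
        event = int(trajectory.events[cycle - 1])
        age = trajectory.age_at_entry + (cycle - 1)
        df = discount_factor(params.discount.cost_rate, cycle)
        if cycle == 1:
            triple = params.costs.short_term[trajectory.initial_mrs]
        elif event == EVENT_RECURRENCE_DEATH:
            if opts.death_cycle_costing:
                triple = cycle_cost(DEAD, cycle, age, True, params.costs, cutoff,
                                    recurrence_costing=True,
                                    indirect_cutoff=opts.indirect_cutoff)
            else:
                triple = CostTriple(0.0, 0.0, 0.0)
        elif event in (EVENT_NONE, EVENT_RECURRENCE_SURVIVED):
            triple = cycle_cost(
                int(trajectory.states[cycle - 1]), cycle, age,
                event == EVENT_RECURRENCE_SURVIVED, params.costs, cutoff,
                recurrence_costing=opts.recurrence_costing,
                indirect_cutoff=opts.indirect_cutoff)
        else:  # background death or out of model: nothing accrues
            triple = CostTriple(0.0, 0.0, 0.0)
        med += df * triple.medical
        non += df * triple.nonmedical
        ind += df * triple.indirect
        if event in (EVENT_NONE, EVENT_RECURRENCE_SURVIVED):
            state = trajectory.initial_mrs if cycle == 1 else int(trajectory.states[cycle - 1])
            qalys += cycle_qaly(state, cycle, params.utilities, params.discount.qaly_rate)
    return {
        "medical": med, "nonmedical": non, "indirect": ind,
        "total": med + non + ind,
        "qalys": qalys, "lys": float(trajectory.alive_cycles),
    }


def accumulate_all(result: SimulationResult, params: ModelParameters) -> pd.DataFrame:
    """Vectorized accounting over a whole :class:`SimulationResult`.

    Returns one row per patient with columns
    ``medical, nonmedical, indirect, total, qalys, lys``.
    """
    opts = params.accounting
    cutoff = params.cohort.indirect_cost_age_cutoff
    u_short, u_long = params.utility_arrays()
    u_short = np.asarray(u_short)
    u_long = np.asarray(u_long)
    short, long_ = params.cost_arrays()
    short = np.asarray(short, dtype=float)   # (7, 3)
    long_ = np.asarray(long_, dtype=float)

    n, t_max = result.states.shape
    cost = np.zeros((n, 3))
    qalys = np.zeros(n)

    # cycle 1: short-term triple of the entry state for everyone
    cost += short[result.initial_mrs]
    survived1 = (result.events[:, 0] == EVENT_NONE) | (
        result.events[:, 0] == EVENT_RECURRENCE_SURVIVED)
    qalys += np.where(survived1, u_short[result.initial_mrs], 0.0)

    for t in range(2, t_max + 1):
        col = t - 1
        ev = result.events[:, col]
        st = result.states[:, col]
        if not (ev != EVENT_NOT_IN_MODEL).any():
            break
        dfc = discount_factor(params.discount.cost_rate, t)
        dfq = discount_factor(params.discount.qaly_rate, t)
        age = result.age_at_entry + (t - 1)
        over = age >= cutoff if opts.indirect_cutoff else np.zeros(n, dtype=bool)

        quiet = ev == EVENT_NONE
        recs = ev == EVENT_RECURRENCE_SURVIVED
        recd = ev == EVENT_RECURRENCE_DEATH

        triple = np.zeros((n, 3))
        triple[quiet] = long_[st[quiet]]
        if opts.recurrence_costing:
            triple[recs] = short[st[recs]]
        else:
            triple[recs] = long_[st[recs]]
        if opts.death_cycle_costing:
            triple[recd] = short[DEAD]
        triple[over, 2] = 0.0
        cost += dfc * triple

        alive_now = quiet | recs
        qalys += dfq * np.where(alive_now, u_long[st], 0.0)

    df = pd.DataFrame({
        "medical": cost[:, 0],
        "nonmedical": cost[:, 1],
        "indirect": cost[:, 2],
        "qalys": qalys,
        "lys": result.alive_cycles.astype(float),
    })
    df.insert(3, "total", df["medical"] + df["nonmedical"] + df["indirect"])
    return df
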