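"""The discrete-time microsimulation engine.

Each patient advances through annual cycles.  Within a cycle, the event
hierarchy is:

1. From cycle 2 onwards, a recurrent stroke occurs with probability
   ``min(1, rate * RR**n_prior)`` where ``n_prior`` counts recurrences since
   the index stroke.  A recurrence is fatal with the age-dependent case
   fatality (attained age >= 65 switches to the higher rate); survivors move
   to a state drawn uniformly from {current, ..., 5} — states never improve.
2. Patients without a recurrence face background mortality at the life-table
   annual probability for their attained integer age.
3. Otherwise nothing happens and the state carries over.

Cycle 1 carries no recurrence risk: the first year after the 12-month entry
point is already summarized by the entry distribution and short-term inputs.
Ages accrue one year per cycle from the entry age.  mRS 6 is absorbing;
patients who enter dead (the published 8.66%) contribute zero alive cycles.

The vectorized :func:`simulate` pre-draws one uniform variate per patient,
cycle and decision from a single seeded generator, so each patient consumes a
dedicated slice of randomness and results do not depend on evaluation order.
The scalar :func:`advance_cycle` exposes the same per-cycle logic for
inspection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import DomainError, ValidationError
from .lifetable import LifeTable
from .parameters import DEAD, ModelParameters, RecurrenceModel

# per-cycle event codes
EVENT_NONE = 0
EVENT_RECURRENCE_SURVIVED = 1
EVENT_RECURRENCE_DEATH = 2
EVENT_BACKGROUND_DEATH = 3
EVENT_NOT_IN_MODEL = 4  # dead at entry, or cycles after death

EVENT_LABELS = {
    EVENT_NONE: "none",
    EVENT_RECURRENCE_SURVIVED: "recurrence_survived",
    EVENT_RECURRENCE_DEATH: "recurrence_death",
    EVENT_BACKGROUND_DEATH: "background_death",
    EVENT_NOT_IN_MODEL: "not_in_model",
}

CASE_FATALITY_AGE_THRESHOLD = 65.0


@dataclass(frozen=True)
class CycleEvent:
    """Outcome of one cycle for one patient."""

    kind: str
    new_mrs: int


@dataclass(frozen=True)
class Trajectory:
    """One patient's simulated path: end-of-cycle states and events."""

    patient_id: int
    age_at_entry: float
    initial_mrs: int
    states: np.ndarray  # end-of-cycle mRS per cycle 1..T (6 once dead)
    events: np.ndarray  # event codes per cycle
    alive_cycles: int
    recurrence_count: int


@dataclass(frozen=True)
class SimulationResult:
    """Vectorized trajectories for a whole cohort."""

    states: np.ndarray       # (n, T) end-of-cycle mRS
    events: np.ndarray       # (n, T) event codes
    initial_mrs: np.ndarray  # (n,)
    age_at_entry: np.ndarray  # (n,)
    alive_cycles: np.ndarray  # (n,)
    recurrence_count: np.ndarray  # (n,)
    horizon: int | None      # None = lifetime
    seed: int

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.states.shape[1]

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory(
            patient_id=i,
            age_at_entry=float(self.age_at_entry[i]),
            initial_mrs=int(self.initial_mrs[i]),
            states=self.states[i],
            events=self.events[i],
            alive_cycles=int(self.alive_cycles[i]),
            recurrence_count=int(self.recurrence_count[i]),
        )

    def trajectories(self) -> Iterator[Trajectory]:
        return (self.trajectory(i) for i in range(self.n))

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: patient_id, cycle, mrs, event, age."""
        n, t = self.states.shape
        cycles = np.tile(np.arange(1, t + 1), n)
        pid = np.repeat(np.arange(n), t)
        return pd.DataFrame({
            "patient_id": pid,
            "cycle": cycles,
            "mrs": self.states.ravel(),
            "event": pd.Series(self.events.ravel()).map(EVENT_LABELS),
            "age": np.repeat(self.age_at_entry, t) + cycles - 1,
        })


def recurrence_probability(rec: RecurrenceModel, n_prior: int) -> float:
    """Annual recurrence probability after ``n_prior`` post-index recurrences."""
    if n_prior < 0:
        raise DomainError(f"n_prior must be >= 0, got {n_prior}")
    return min(1.0, rec.annual_rate * rec.risk_ratio_per_prior_event ** n_prior)


def case_fatality(rec: RecurrenceModel, age: float) -> float:
    """Probability that a recurrent stroke at the given attained age is fatal."""
    if age < 0:
        raise DomainError(f"age must be >= 0, got {age}")
    if age >= CASE_FATALITY_AGE_THRESHOLD:
        return rec.case_fatality_65plus
    return rec.case_fatality_under65


def post_recurrence_state(current: int, rng: np.random.Generator) -> int:
    """State after a survived recurrence: uniform over {current, ..., 5}."""
    if not 0 <= current < DEAD:
        raise DomainError(f"dead or invalid state {current} cannot have a recurrence")
    return int(rng.integers(current, DEAD))


def advance_cycle(
    state: tuple[int, float, int],
    params: ModelParameters,
    table: LifeTable,
    cycle: int,
    rng: np.random.Generator,
) -> CycleEvent:
    """Advance one alive patient by one cycle; returns the cycle's event.

    ``state`` is (mrs, attained age at the start of the cycle, prior
    recurrences).  Recurrence is checked first (never in cycle 1), then
    background mortality; a patient cannot experience both in one cycle.
    """
    mrs, age, n_prior = state
    if mrs == DEAD:
        raise DomainError("dead patients have no cycle events")
    if cycle < 1:
        raise DomainError(f"cycle must be >= 1, got {cycle}")
    rec = params.recurrence
    first_cycle_blocked = cycle == 1 and rec.no_recurrence_in_first_cycle
    if not first_cycle_blocked and rng.random() < recurrence_probability(rec, n_prior):
        if rng.random() < case_fatality(rec, age):
            return CycleEvent(kind="recurrence_death", new_mrs=DEAD)
        return CycleEvent(kind="recurrence_survived", new_mrs=post_recurrence_state(mrs, rng))
    if rng.random() < table.death_probability(min(age, table.max_age)):
        return CycleEvent(kind="background_death", new_mrs=DEAD)
    return CycleEvent(kind="none", new_mrs=mrs)


def simulate(
    cohort: Cohort,
    params: ModelParameters,
    table: LifeTable,
    horizon: int | None,
    seed: int,
) -> SimulationResult:
    """Run the microsimulation for every patient in the cohort.

    ``horizon`` is the number of annual cycles, or ``None`` for lifetime
    (until death or the life-table terminal age).  Deterministic given
    ``seed``.
    """
    n = cohort.n
    ages0 = np.asarray(cohort.age_at_entry, dtype=float)
    if horizon is None:
        if n:
            t_max = int(np.ceil(table.max_age - ages0.min())) + 1
        else:
            t_max = 1
    else:
        if horizon < 1:
            raise ValidationError(f"horizon must be >= 1, got {horizon}")
        t_max = int(horizon)

    rng = np.random.default_rng(seed)
    draws = rng.random((n, t_max, 3))

    rec = params.recurrence
    qx = table.qx
    max_age = table.max_age

    states = np.full((n, t_max), DEAD, dtype=np.int8)
    events = np.full((n, t_max), EVENT_NOT_IN_MODEL, dtype=np.int8)
    cur = np.asarray(cohort.initial_mrs, dtype=np.int8).copy()
    n_prior = np.zeros(n, dtype=np.int64)
    rec_count = np.zeros(n, dtype=np.int64)
    alive = cur != DEAD

    for t in range(1, t_max + 1):
        if not alive.any():
            break
        col = t - 1
        age = ages0 + (t - 1)
        u_rec, u_death, u_state = draws[:, col, 0], draws[:, col, 1], draws[:, col, 2]

        if t == 1 and rec.no_recurrence_in_first_cycle:
            recur = np.zeros(n, dtype=bool)
        else:
            p_rec = np.minimum(
                1.0, rec.annual_rate * rec.risk_ratio_per_prior_event ** n_prior)
            recur = alive & (u_rec < p_rec)

        cf = np.where(age >= CASE_FATALITY_AGE_THRESHOLD,
                      rec.case_fatality_65plus, rec.case_fatality_under65)
        rec_death = recur & (u_death < cf)
        rec_surv = recur & ~rec_death

        iage = np.clip(np.floor(age).astype(int), 0, max_age)
        bg_death = alive & ~recur & (u_death < qx[iage])

        quiet = alive & ~recur & ~bg_death
        events[quiet, col] = EVENT_NONE
        events[rec_surv, col] = EVENT_RECURRENCE_SURVIVED
        events[rec_death, col] = EVENT_RECURRENCE_DEATH
        events[bg_death, col] = EVENT_BACKGROUND_DEATH

        # survived recurrences redistribute uniformly over {current, ..., 5}
        worse = cur + np.floor(u_state * (DEAD - cur)).astype(np.int8)
        cur = np.where(rec_surv, worse, cur).astype(np.int8)
        cur[rec_death | bg_death] = DEAD
        states[:, col] = cur

        n_prior[rec_surv] += 1
        rec_count[recur] += 1
        alive = alive & ~rec_death & ~bg_death

    alive_cycles = ((events == EVENT_NONE) | (events == EVENT_RECURRENCE_SURVIVED)).sum(axis=1)
    return SimulationResult(
        states=states,
        events=events,
        initial_mrs=np.asarray(cohort.initial_mrs, dtype=np.int8),
        age_at_entry=ages0,
        alive_cycles=alive_cycles.astype(np.int64),
        recurrence_count=rec_count,
        horizon=horizon,
        seed=seed,
    )
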