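"""Lifetime loss of life years and QALYs versus the age-matched general population.

For each entry age group the stroke cohort's mean remaining life years come
from the lifetime microsimulation (decedent entrants count as zero), while
the general-population comparator is the calibrated life table's remaining
life expectancy at the group's mean entry age.  QALYs are life years times an
age-bracket utility — in the base case the utility of the bracket containing
the entry age, held constant; the aging sensitivity walks year by year
through the brackets as the cohort ages, pro-rating the final fractional
year.  The difference between the general and stroke QALYs, using each
population's own utility column, is the reported loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .cohort import Cohort
from .errors import DomainError, StateError, ValidationError
from .lifetable import LifeTable
from .parameters import ModelParameters


@dataclass(frozen=True)
class AgeUtilityTable:
    """Age-bracket utilities for the general and stroke populations.

    Ages beyond the last bracket reuse the last bracket's utilities.
    """

    bounds: tuple[tuple[float, float], ...]  # [low, high) per bracket
    general: tuple[float, ...]
    stroke: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def validate(self) -> None:
        if not len(self.bounds) == len(self.general) == len(self.stroke):
            raise ValidationError("age-utility brackets and columns differ in length")
        for col_name, col in (("general", self.general), ("stroke", self.stroke)):
            for i, u in enumerate(col):
                if not 0.0 <= u <= 1.0:
                    raise ValidationError(f"age utility {col_name}[{i}] = {u} not in [0, 1]")
        for i, (g, s) in enumerate(zip(self.general, self.stroke)):
            if s > g:
                raise ValidationError(
                    f"stroke utility {s} exceeds general utility {g} in bracket {i}")

    def bracket_of(self, age: float) -> int:
        if age < 0:
            raise DomainError(f"age must be >= 0, got {age}")
        for i, (lo, hi) in enumerate(self.bounds):
            if lo <= age < hi:
                return i
        return len(self.bounds) - 1

    def utility(self, age: float, population: str) -> float:
        col = self.general if population == "general" else self.stroke
        return col[self.bracket_of(age)]

    @classmethod
    def from_parameters(cls, params: ModelParameters) -> "AgeUtilityTable":
        table = cls(
            bounds=params.age_utility_bounds,
            general=params.age_utility_general,
            stroke=params.age_utility_stroke,
            labels=params.age_utility_labels,
        )
        table.validate()
        return table


@dataclass(frozen=True)
class QalyLossRow:
    age_group: str
    n: int
    mean_entry_age: float
    general_lys: float
    stroke_lys: float
    loss_lys: float
    loss_qalys_base: float
    loss_qalys_sensitivity: float


@dataclass(frozen=True)
class QalyLossTable:
    rows: tuple[QalyLossRow, ...]
    weighted_loss_lys: float
    weighted_loss_qalys_base: float
    weighted_loss_qalys_sensitivity: float

    def to_frame(self) -> pd.DataFrame:
        records = [{
            "age_group": r.age_group, "n": r.n,
            "general_lys": r.general_lys, "stroke_lys": r.stroke_lys,
            "loss_lys": r.loss_lys,
            "loss_qalys_base": r.loss_qalys_base,
            "loss_qalys_sensitivity": r.loss_qalys_sensitivity,
        } for r in self.rows]
        records.append({
            "age_group": "weighted", "n": sum(r.n for r in self.rows),
            "general_lys": np.nan, "stroke_lys": np.nan,
            "loss_lys": self.weighted_loss_lys,
            "loss_qalys_base": self.weighted_loss_qalys_base,
            "loss_qalys_sensitivity": self.weighted_loss_qalys_sensitivity,
        })
        return pd.DataFrame(records)

    def to_dict(self) -> dict:
        return {
            "rows": [vars(r) for r in self.rows],
            "weighted_loss_lys": self.weighted_loss_lys,
            "weighted_loss_qalys_base": self.weighted_loss_qalys_base,
            "weighted_loss_qalys_sensitivity": self.weighted_loss_qalys_sensitivity,
        }


def weighted_average(values, weights) -> float:
    """Count-weighted mean: sum(w*v) / sum(w)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise DomainError("values and weights must have equal length")
    if (weights < 0).any() or weights.sum() == 0:
        raise DomainError("weights must be non-negative with a positive total")
    return float((values * weights).sum() / weights.sum())


def expected_qalys(
    remaining_lys: float,
    entry_age: float,
    utilities: AgeUtilityTable,
    population: str,
    mode: str = "constant",
) -> float:
    """QALYs over the remaining lifespan.

    ``constant`` multiplies the whole span by the utility of the entry-age
    bracket; ``aging`` accrues each year of life at the utility of the
    attained-age bracket, with the final fractional year pro-rated.
    """
    if remaining_lys < 0:
        raise DomainError(f"remaining_lys must be >= 0, got {remaining_lys}")
    if mode == "constant":
        return remaining_lys * utilities.utility(entry_age, population)
    if mode != "aging":
        raise DomainError(f"unknown mode '{mode}'")
    whole = int(np.floor(remaining_lys))
    total = sum(utilities.utility(entry_age + k, population) for k in range(whole))
    frac = remaining_lys - whole
    if frac > 0:
        total += frac * utilities.utility(entry_age + whole, population)
    return float(total)


def build_loss_table(
    cohort: Cohort,
    params: ModelParameters,
    table: LifeTable,
    utilities: AgeUtilityTable | None = None,
    sim: engine.SimulationResult | None = None,
    seed: int = 0,
) -> QalyLossTable:
    """Per-age-group LY and QALY losses of the stroke cohort, plus weighted rows.

    Runs (or reuses) a lifetime simulation; ``seed`` is used only when ``sim``
    is not supplied.
    """
    if utilities is None:
        utilities = AgeUtilityTable.from_parameters(params)
    if sim is None:
        sim = engine.simulate(cohort, params, table, horizon=None, seed=seed)
    if sim.horizon is not None:
        raise StateError("loss analysis needs a lifetime simulation (horizon=None)")
    if sim.n != cohort.n:
        raise StateError("simulation and cohort sizes differ")

    rows = []
    for gi, label in enumerate(cohort.spec.age_group_labels):
        mask = cohort.group_index == gi
        n = int(mask.sum())
        if n == 0:
            continue
        mean_age = float(cohort.age_at_entry[mask].mean())
        stroke_lys = float(sim.alive_cycles[mask].mean())
        general_lys = table.life_expectancy(mean_age)
        gen_base = expected_qalys(general_lys, mean_age, utilities, "general", "constant")
        str_base = expected_qalys(stroke_lys, mean_age, utilities, "stroke", "constant")
        gen_aging = expected_qalys(general_lys, mean_age, utilities, "general", "aging")
        str_aging = expected_qalys(stroke_lys, mean_age, utilities, "stroke", "aging")
        rows.append(QalyLossRow(
            age_group=label,
            n=n,
            mean_entry_age=mean_age,
            general_lys=general_lys,
            stroke_lys=stroke_lys,
            loss_lys=general_lys - stroke_lys,
            loss_qalys_base=gen_base - str_base,
            loss_qalys_sensitivity=gen_aging - str_aging,
        ))
    weights = [r.n for r in rows]
    return QalyLossTable(
        rows=tuple(rows),
        weighted_loss_lys=weighted_average([r.loss_lys for r in rows], weights),
        weighted_loss_qalys_base=weighted_average([r.loss_qalys_base for r in rows], weights),
        weighted_loss_qalys_sensitivity=weighted_average(
            [r.loss_qalys_sensitivity for r in rows], weights),
    )
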