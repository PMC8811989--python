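"""Background mortality: a synthetic combined-sex life table.

The microsimulation needs an annual probability of death from causes other
than recurrent stroke at every attained age.  Rather than shipping a national
life table, a Gompertz-Makeham hazard

    mu(x) = a + b * exp(c * x)

is calibrated so that the remaining life expectancies it implies match the
published general-population values at the representative age of each entry
age bracket.  The Makeham term ``a`` is an age-independent background hazard;
the Gompertz pair ``(b, c)`` captures the exponential rise of adult mortality
with age.  Annual death probabilities follow from exact integration of the
hazard over each year of age,

    q(x) = 1 - exp(-[a + (b/c) (e^{c(x+1)} - e^{cx})]),

and remaining life expectancy uses the standard discrete recursion with a
half-year correction, e(x) = sum_k S(x -> x+k) + 0.5.  Everyone dies at
``max_age`` (q = 1), which bounds lifetime simulations.

A user-supplied table can replace the fitted one via :func:`life_table_from_csv`
(columns ``age,qx``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import CalibrationError, DomainError, ValidationError

DEFAULT_MAX_AGE = 110


@dataclass(frozen=True)
class MortalityParams:
    """Gompertz-Makeham hazard parameters (per year)."""

    makeham_a: float
    gompertz_b: float
    gompertz_c: float
    max_age: int = DEFAULT_MAX_AGE

    def validate(self) -> None:
        if self.makeham_a < 0 or self.gompertz_b < 0:
            raise ValidationError("hazard parameters must be >= 0")
        if self.gompertz_c <= 0:
            raise ValidationError(f"gompertz_c must be > 0, got {self.gompertz_c}")
        if self.max_age <= 0:
            raise ValidationError("max_age must be positive")


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities and remaining life expectancies by integer age."""

    qx: np.ndarray  # shape (max_age + 1,), qx[max_age] == 1
    ex: np.ndarray  # shape (max_age + 1,)

    @property
    def max_age(self) -> int:
        return len(self.qx) - 1

    def death_probability(self, age: float) -> float:
        """q at floor(age); 1.0 at the terminal age."""
        if age < 0 or age > self.max_age:
            raise DomainError(f"age {age} outside [0, {self.max_age}]")
        return float(self.qx[int(np.floor(age))])

    def life_expectancy(self, age: float) -> float:
        """Remaining life expectancy, linearly interpolated at fractional ages."""
        if age < 0 or age > self.max_age:
            raise DomainError(f"age {age} outside [0, {self.max_age}]")
        return float(np.interp(age, np.arange(len(self.ex)), self.ex))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": np.arange(len(self.qx)), "qx": self.qx, "ex": self.ex})


def _annual_qx(params: MortalityParams) -> np.ndarray:
    ages = np.arange(params.max_age + 1, dtype=float)
    a, b, c = params.makeham_a, params.gompertz_b, params.gompertz_c
    cumhaz = a + (b / c) * (np.exp(c * (ages + 1.0)) - np.exp(c * ages))
    qx = 1.0 - np.exp(-cumhaz)
    qx = np.clip(qx, 0.0, 1.0)
    qx[params.max_age] = 1.0
    return qx


def _ex_from_qx(qx: np.ndarray) -> np.ndarray:
    """Discrete life-table recursion: e(x) = p(x) * (1 + e(x+1)), plus half a year."""
    n = len(qx)
    ex = np.zeros(n)
    ex[n - 1] = 0.5  # the terminal age is lived for half a year on average
    tail = 0.0  # expected whole years lived beyond age x
    for x in range(n - 2, -1, -1):
        tail = (1.0 - qx[x]) * (1.0 + tail)
        ex[x] = tail + 0.5
    return ex


def build_life_table(params: MortalityParams) -> LifeTable:
    """Materialize qx and ex for integer ages 0..max_age."""
    params.validate()
    qx = _annual_qx(params)
    return LifeTable(qx=qx, ex=_ex_from_qx(qx))


def life_table_from_csv(path) -> LifeTable:
    """Load an override table with columns ``age,qx`` (integer ages from 0)."""
    df = pd.read_csv(path)
    for col in ("age", "qx"):
        if col not in df.columns:
            raise ValidationError(f"life-table CSV is missing column '{col}'")
    df = df.sort_values("age")
    ages = df["age"].to_numpy()
    if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)) or ages[0] != 0:
        raise ValidationError("life-table CSV must cover consecutive integer ages from 0")
    qx = df["qx"].to_numpy(dtype=float)
    if ((qx < 0) | (qx > 1)).any():
        raise ValidationError("qx values must lie in [0, 1]")
    qx = qx.copy()
    qx[-1] = 1.0
    return LifeTable(qx=qx, ex=_ex_from_qx(qx))


def _check_targets(targets: dict[float, float], max_age: int) -> list[tuple[float, float]]:
    pairs = sorted((float(a), float(e)) for a, e in dict(targets).items())
    if len(pairs) < 3:
        raise DomainError("calibration needs at least 3 (age, life-expectancy) pairs")
    for age, le in pairs:
        if not 0 <= age < max_age:
            raise DomainError(f"target age {age} outside [0, {max_age})")
        if le <= 0:
            raise DomainError(f"life expectancy at age {age} must be positive, got {le}")
    les = [le for _, le in pairs]
    if any(b >= a for a, b in zip(les, les[1:])):
        raise DomainError("target life expectancies must be strictly decreasing in age")
    return pairs


def calibrate(
    targets: dict[float, float],
    max_age: int = DEFAULT_MAX_AGE,
    tolerance_years: float = 0.5,
) -> MortalityParams:
    """Fit Gompertz-Makeham parameters to remaining-life-expectancy targets.

    Least-squares over log-parameters (keeping all three positive) minimizing
    the life-expectancy residual at each target age.  Raises
    :class:`CalibrationError` if any fitted residual exceeds
    ``tolerance_years``.
    """
    pairs = _check_targets(targets, max_age)
    ages = np.array([a for a, _ in pairs])
    les = np.array([e for _, e in pairs])

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, c = np.exp(theta)
        table = build_life_table(MortalityParams(a, b, c, max_age))
        model = np.interp(ages, np.arange(max_age + 1), table.ex)
        return model - les

    x0 = np.log([5e-4, 3e-5, 0.095])
    fit = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    a, b, c = np.exp(fit.x)
    params = MortalityParams(float(a), float(b), float(c), max_age)
    resid = residuals(fit.x)
    worst = float(np.max(np.abs(resid)))
    if worst > tolerance_years:
        detail = ", ".join(f"age {a:g}: {r:+.3f}y" for a, r in zip(ages, resid))
        raise CalibrationError(
            f"calibration residual {worst:.3f}y exceeds {tolerance_years}y ({detail})"
        )
    return params


def death_probability(table: LifeTable, age: float) -> float:
    """Annual background death probability at floor(age)."""
    return table.death_probability(age)
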