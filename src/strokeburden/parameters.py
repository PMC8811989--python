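"""Model parameters: every published model input, loaded and validated.

The packaged default fixture (``data/parameters.json``) transcribes the
complete input set of the costing model: the modified Rankin Scale (mRS)
distribution at 12 months post stroke, short- and long-term utilities and
annual costs per mRS state (with sensitivity ranges), the recurrence and
case-fatality parameters, discounting settings, the entry-cohort structure,
age-dependent utilities for the stroke and general populations, and the
general-population life-expectancy targets used to calibrate the background
life table.  All monetary amounts are 2018 Australian dollars per year.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .errors import ConfigurationError, DomainError, ValidationError

N_STATES = 7  # mRS 0..5 plus 6 = dead
DEAD = 6


class CostTriple(NamedTuple):
    """Annual cost by societal category, 2018 AUD."""

    medical: float
    nonmedical: float
    indirect: float

    @property
    def total(self) -> float:
        return self.medical + self.nonmedical + self.indirect


@dataclass(frozen=True)
class InitialStateDistribution:
    """Probability of each mRS state (0-6) at model entry, 12 months post stroke."""

    prob_by_mrs: tuple[float, ...]
    low: tuple[float, ...] = ()
    high: tuple[float, ...] = ()

    def validate(self) -> None:
        if len(self.prob_by_mrs) != N_STATES:
            raise ValidationError(
                f"initial_distribution.prob_by_mrs needs {N_STATES} entries, "
                f"got {len(self.prob_by_mrs)}"
            )
        for i, p in enumerate(self.prob_by_mrs):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"initial_distribution.prob_by_mrs[{i}] = {p} not in [0, 1]")
        total = sum(self.prob_by_mrs)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"initial_distribution probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class UtilityTable:
    """Utility per alive mRS state (0-5); the dead state scores 0."""

    short_term: tuple[float, ...]
    long_term: tuple[float, ...]
    short_range: tuple[tuple[float, float], ...] = ()
    long_range: tuple[tuple[float, float], ...] = ()

    def validate(self) -> None:
        for name, vals in (("short_term", self.short_term), ("long_term", self.long_term)):
            if len(vals) != DEAD:
                raise ValidationError(f"utilities.{name} needs {DEAD} entries (mRS 0-5)")
            for i, u in enumerate(vals):
                if not 0.0 <= u <= 1.0:
                    raise ValidationError(f"utilities.{name}[{i}] = {u} not in [0, 1]")
        for name, rng in (("short_range", self.short_range), ("long_range", self.long_range)):
            for i, (lo, hi) in enumerate(rng):
                if lo > hi:
                    raise ValidationError(f"utilities.{name}[{i}] has low {lo} > high {hi}")


@dataclass(frozen=True)
class CostTable:
    """Annual cost triples per mRS state for the first model year and thereafter.

    ``short_term`` covers mRS 0-6 (the mRS 6 entry costs are the published
    first-year costs of a fatal stroke); ``long_term`` costs for mRS 6 are zero.
    Ranges are the published sensitivity ranges and are kept verbatim even
    where a point estimate falls outside its own range.
    """

    short_term: tuple[CostTriple, ...]
    long_term: tuple[CostTriple, ...]
    short_range: tuple[tuple[CostTriple, CostTriple], ...] = ()
    long_range: tuple[tuple[CostTriple, CostTriple], ...] = ()

    def validate(self) -> list[str]:
        warnings: list[str] = []
        for name, triples in (("short_term", self.short_term), ("long_term", self.long_term)):
            if len(triples) != N_STATES:
                raise ValidationError(f"costs.{name} needs {N_STATES} state entries")
            for i, t in enumerate(triples):
                for comp, v in zip(t._fields, t):
                    if v < 0:
                        raise ValidationError(f"costs.{name}[{i}].{comp} = {v} is negative")
        if any(v != 0 for v in self.long_term[DEAD]):
            raise ValidationError("long-term costs for mRS 6 must all be zero")
        for name, triples, ranges in (
            ("short_term", self.short_term, self.short_range),
            ("long_term", self.long_term, self.long_range),
        ):
            for i, (lo, hi) in enumerate(ranges):
                for comp in CostTriple._fields:
                    lo_v, hi_v = getattr(lo, comp), getattr(hi, comp)
                    if lo_v > hi_v:
                        raise ValidationError(
                            f"costs.{name}[{i}].{comp} range low {lo_v} > high {hi_v}"
                        )
                    point = getattr(triples[i], comp)
                    if not lo_v <= point <= hi_v:
                        warnings.append(
                            f"costs.{name} mRS {i} {comp}: point {point} outside "
                            f"published range [{lo_v}, {hi_v}]"
                        )
        return warnings


@dataclass(frozen=True)
class RecurrenceModel:
    annual_rate: float = 0.0201
    risk_ratio_per_prior_event: float = 1.39
    case_fatality_under65: float = 0.0866
    case_fatality_65plus: float = 0.2683
    no_recurrence_in_first_cycle: bool = True

    def validate(self) -> None:
        for name in ("annual_rate", "case_fatality_under65", "case_fatality_65plus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"recurrence.{name} = {v} not in [0, 1]")
        if self.risk_ratio_per_prior_event < 1.0:
            raise ValidationError(
                f"recurrence.risk_ratio_per_prior_event = "
                f"{self.risk_ratio_per_prior_event} must be >= 1"
            )


@dataclass(frozen=True)
class DiscountSettings:
    cost_rate: float = 0.05
    qaly_rate: float = 0.0
    reference_cycle: int = 1

    def validate(self) -> None:
        if self.cost_rate < 0 or self.qaly_rate < 0:
            raise ValidationError("discount rates must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Structure of the simulated entry cohort (working-age strokes, one year)."""

    n_patients: int = 13555
    total_strokes: int = 57487
    younger_share: float = 0.2358
    male_fraction: float = 0.6007
    age_group_labels: tuple[str, ...] = ("<25", "25-34", "35-44", "45-54", "55-64")
    age_group_counts: tuple[int, ...] = (499, 657, 1649, 3842, 6908)
    age_group_bounds: tuple[tuple[float, float], ...] = (
        (18, 25), (25, 35), (35, 45), (45, 55), (55, 65))
    stroke_type_mix: tuple[tuple[str, float], ...] = (
        ("ischaemic", 0.82), ("ich", 0.12), ("undetermined", 0.06))
    indirect_cost_age_cutoff: float = 65.0

    def validate(self) -> None:
        if sum(self.age_group_counts) != self.n_patients:
            raise ValidationError(
                f"cohort.age_group_counts sum to {sum(self.age_group_counts)}, "
                f"expected n_patients = {self.n_patients}"
            )
        if not len(self.age_group_labels) == len(self.age_group_counts) == len(self.age_group_bounds):
            raise ValidationError("cohort age-group labels/counts/bounds lengths differ")
        for name in ("younger_share", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"cohort.{name} = {v} not in [0, 1]")
        mix_total = sum(p for _, p in self.stroke_type_mix)
        if abs(mix_total - 1.0) > 1e-9:
            raise ValidationError(f"cohort.stroke_type_mix sums to {mix_total}, not 1")


@dataclass(frozen=True)
class AccountingOptions:
    """Structural accounting toggles (all default to the base-case analysis).

    recurrence_costing:  the cycle of a recurrence accrues the short-term
        (first-year) cost triple of the post-recurrence state.
    death_cycle_costing: a fatal recurrence accrues the short-term mRS 6
        triple once in the death cycle; background deaths accrue nothing.
    indirect_cutoff:     long-term indirect (productivity) costs stop once
        attained age reaches the working-age cutoff.
    """

    recurrence_costing: bool = True
    death_cycle_costing: bool = True
    indirect_cutoff: bool = True


@dataclass(frozen=True)
class ModelParameters:
    """Complete validated input set for the microsimulation."""

    initial_distribution: InitialStateDistribution
    utilities: UtilityTable
    costs: CostTable
    recurrence: RecurrenceModel
    discount: DiscountSettings
    cohort: CohortSpec
    horizon_years: int | None = 5  # None means lifetime
    accounting: AccountingOptions = field(default_factory=AccountingOptions)
    # auxiliary published inputs carried alongside the core set
    age_utility_bounds: tuple[tuple[float, float], ...] = ()
    age_utility_labels: tuple[str, ...] = ()
    age_utility_general: tuple[float, ...] = ()
    age_utility_stroke: tuple[float, ...] = ()
    max_age: int = 110
    le_targets: tuple[tuple[float, float], ...] = ()
    usd_per_aud: float = 0.784
    published: dict = field(default_factory=dict, compare=False)
    validation_warnings: tuple[str, ...] = field(default=(), compare=False)

    def validate(self) -> "ModelParameters":
        """Run every component invariant; returns self with warnings recorded."""
        self.initial_distribution.validate()
        self.utilities.validate()
        warnings = self.costs.validate()
        self.recurrence.validate()
        self.discount.validate()
        self.cohort.validate()
        if self.horizon_years is not None and self.horizon_years < 1:
            raise ValidationError(f"horizon_years = {self.horizon_years} must be >= 1 or None")
        object.__setattr__(self, "validation_warnings", tuple(warnings))
        return self

    # -- dense array views used by the simulation kernels ------------------

    def utility_arrays(self):
        """(u_short, u_long) as length-7 lists with the dead state at 0."""
        u_short = list(self.utilities.short_term) + [0.0]
        u_long = list(self.utilities.long_term) + [0.0]
        return u_short, u_long

    def cost_arrays(self):
        """(short, long) as 7x3 nested lists ordered medical/nonmedical/indirect."""
        short = [list(t) for t in self.costs.short_term]
        long = [list(t) for t in self.costs.long_term]
        return short, long


def _require(mapping: dict, key: str, context: str):
    try:
        return mapping[key]
    except KeyError:
        raise ConfigurationError(f"missing required key '{context}.{key}'") from None


def _parse(raw: dict) -> ModelParameters:
    dist_raw = _require(raw, "initial_distribution", "")
    dist = InitialStateDistribution(
        prob_by_mrs=tuple(_require(dist_raw, "prob_by_mrs", "initial_distribution")),
        low=tuple(dist_raw.get("low", ())),
        high=tuple(dist_raw.get("high", ())),
    )
    util_raw = _require(raw, "utilities", "")
    utilities = UtilityTable(
        short_term=tuple(_require(util_raw, "short_term", "utilities")),
        long_term=tuple(_require(util_raw, "long_term", "utilities")),
        short_range=tuple(zip(util_raw.get("short_low", ()), util_raw.get("short_high", ()))),
        long_range=tuple(zip(util_raw.get("long_low", ()), util_raw.get("long_high", ()))),
    )

    def triples(block: dict, key: str) -> tuple[CostTriple, ...]:
        sub = _require(block, key, "costs")
        med = _require(sub, "medical", f"costs.{key}")
        non = _require(sub, "nonmedical", f"costs.{key}")
        ind = _require(sub, "indirect", f"costs.{key}")
        return tuple(CostTriple(*v) for v in zip(med, non, ind))

    costs_raw = _require(raw, "costs", "")
    costs = CostTable(
        short_term=triples(costs_raw, "short_term"),
        long_term=triples(costs_raw, "long_term"),
        short_range=tuple(zip(triples(costs_raw, "short_low"), triples(costs_raw, "short_high")))
        if "short_low" in costs_raw else (),
        long_range=tuple(zip(triples(costs_raw, "long_low"), triples(costs_raw, "long_high")))
        if "long_low" in costs_raw else (),
    )
    rec_raw = _require(raw, "recurrence", "")
    recurrence = RecurrenceModel(
        annual_rate=_require(rec_raw, "annual_rate", "recurrence"),
        risk_ratio_per_prior_event=_require(rec_raw, "risk_ratio_per_prior_event", "recurrence"),
        case_fatality_under65=_require(rec_raw, "case_fatality_under65", "recurrence"),
        case_fatality_65plus=_require(rec_raw, "case_fatality_65plus", "recurrence"),
        no_recurrence_in_first_cycle=rec_raw.get("no_recurrence_in_first_cycle", True),
    )
    disc_raw = _require(raw, "discount", "")
    discount = DiscountSettings(
        cost_rate=_require(disc_raw, "cost_rate", "discount"),
        qaly_rate=disc_raw.get("qaly_rate", 0.0),
        reference_cycle=disc_raw.get("reference_cycle", 1),
    )
    coh_raw = _require(raw, "cohort", "")
    cohort = CohortSpec(
        n_patients=_require(coh_raw, "n_patients", "cohort"),
        total_strokes=_require(coh_raw, "total_strokes", "cohort"),
        younger_share=_require(coh_raw, "younger_share", "cohort"),
        male_fraction=_require(coh_raw, "male_fraction", "cohort"),
        age_group_labels=tuple(_require(coh_raw, "age_group_labels", "cohort")),
        age_group_counts=tuple(_require(coh_raw, "age_group_counts", "cohort")),
        age_group_bounds=tuple(tuple(b) for b in _require(coh_raw, "age_group_bounds", "cohort")),
        stroke_type_mix=tuple(sorted(coh_raw.get(
            "stroke_type_mix", {"ischaemic": 0.82, "ich": 0.12, "undetermined": 0.06}).items())),
        indirect_cost_age_cutoff=coh_raw.get("indirect_cost_age_cutoff", 65.0),
    )
    age_util = raw.get("age_utilities", {})
    lt = raw.get("lifetable", {})
    return ModelParameters(
        initial_distribution=dist,
        utilities=utilities,
        costs=costs,
        recurrence=recurrence,
        discount=discount,
        cohort=cohort,
        horizon_years=raw.get("horizon_years", 5),
        age_utility_bounds=tuple(tuple(b) for b in age_util.get("bracket_bounds", ())),
        age_utility_labels=tuple(age_util.get("bracket_labels", ())),
        age_utility_general=tuple(age_util.get("general", ())),
        age_utility_stroke=tuple(age_util.get("stroke", ())),
        max_age=lt.get("max_age", 110),
        le_targets=tuple(sorted((float(a), float(e)) for a, e in lt.get("le_targets", {}).items())),
        usd_per_aud=raw.get("currency", {}).get("usd_per_aud", 0.784),
        published=raw.get("published", {}),
    ).validate()


def load_parameters(path: str | Path | None = None) -> ModelParameters:
    """Load and validate model parameters.

    With no ``path``, the packaged default fixture is used.  Raises
    :class:`ConfigurationError` for missing/unparseable input and
    :class:`ValidationError` when an invariant is violated; ranges whose
    published point estimate lies outside the range are kept verbatim and
    recorded in ``validation_warnings``.
    """
    if path is None:
        text = resources.files("strokeburden.data").joinpath("parameters.json").read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"parameter file not found: {p}")
        text = p.read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"parameter file is not valid JSON: {exc}") from exc
    return _parse(raw)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set back to JSON such that a reload is value-identical."""
    raw = {
        "initial_distribution": {
            "prob_by_mrs": list(params.initial_distribution.prob_by_mrs),
            "low": list(params.initial_distribution.low),
            "high": list(params.initial_distribution.high),
        },
        "utilities": {
            "short_term": list(params.utilities.short_term),
            "short_low": [r[0] for r in params.utilities.short_range],
            "short_high": [r[1] for r in params.utilities.short_range],
            "long_term": list(params.utilities.long_term),
            "long_low": [r[0] for r in params.utilities.long_range],
            "long_high": [r[1] for r in params.utilities.long_range],
        },
        "costs": {
            key: {
                comp: [getattr(t, comp) for t in triples]
                for comp in CostTriple._fields
            }
            for key, triples in (
                ("short_term", params.costs.short_term),
                ("short_low", [r[0] for r in params.costs.short_range]),
                ("short_high", [r[1] for r in params.costs.short_range]),
                ("long_term", params.costs.long_term),
                ("long_low", [r[0] for r in params.costs.long_range]),
                ("long_high", [r[1] for r in params.costs.long_range]),
            )
        },
        "recurrence": dataclasses.asdict(params.recurrence),
        "discount": dataclasses.asdict(params.discount),
        "cohort": {
            "n_patients": params.cohort.n_patients,
            "total_strokes": params.cohort.total_strokes,
            "younger_share": params.cohort.younger_share,
            "male_fraction": params.cohort.male_fraction,
            "age_group_labels": list(params.cohort.age_group_labels),
            "age_group_counts": list(params.cohort.age_group_counts),
            "age_group_bounds": [list(b) for b in params.cohort.age_group_bounds],
            "stroke_type_mix": dict(params.cohort.stroke_type_mix),
            "indirect_cost_age_cutoff": params.cohort.indirect_cost_age_cutoff,
        },
        "age_utilities": {
            "bracket_bounds": [list(b) for b in params.age_utility_bounds],
            "bracket_labels": list(params.age_utility_labels),
            "general": list(params.age_utility_general),
            "stroke": list(params.age_utility_stroke),
        },
        "lifetable": {
            "max_age": params.max_age,
            "le_targets": {repr(a).rstrip("0").rstrip(".") if a != int(a) else str(int(a)): e
                           for a, e in params.le_targets},
        },
        "currency": {"usd_per_aud": params.usd_per_aud},
        "horizon_years": params.horizon_years,
        "published": params.published,
    }
    Path(path).write_text(json.dumps(raw, indent=2))


def compute_modelled_population(total_strokes: int, younger_share: float) -> int:
    """Number of working-age cases out of all incident strokes, nearest integer."""
    if total_strokes <= 0:
        raise DomainError(f"total_strokes must be positive, got {total_strokes}")
    if not 0.0 < younger_share <= 1.0:
        raise DomainError(f"younger_share must be in (0, 1], got {younger_share}")
    return round(total_strokes * younger_share)


def params_to_frame(params: ModelParameters) -> pd.DataFrame:
    """Flatten the loaded parameter set for CSV audit export."""
    rows: list[dict] = []

    def add(section, key, mrs, value, low=None, high=None):
        rows.append({"section": section, "key": key, "mrs": mrs,
                     "value": value, "low": low, "high": high})

    d = params.initial_distribution
    for i, p in enumerate(d.prob_by_mrs):
        lo = d.low[i] if d.low else None
        hi = d.high[i] if d.high else None
        add("initial_distribution", "probability", i, p, lo, hi)
    u = params.utilities
    for i in range(DEAD):
        add("utilities", "short_term", i, u.short_term[i], *u.short_range[i])
        add("utilities", "long_term", i, u.long_term[i], *u.long_range[i])
    for period, triples, ranges in (
        ("short_term", params.costs.short_term, params.costs.short_range),
        ("long_term", params.costs.long_term, params.costs.long_range),
    ):
        for i, t in enumerate(triples):
            for comp in CostTriple._fields:
                lo = getattr(ranges[i][0], comp) if ranges else None
                hi = getattr(ranges[i][1], comp) if ranges else None
                add("costs", f"{period}.{comp}", i, getattr(t, comp), lo, hi)
    for name in ("annual_rate", "risk_ratio_per_prior_event",
                 "case_fatality_under65", "case_fatality_65plus"):
        add("recurrence", name, None, getattr(params.recurrence, name))
    add("discount", "cost_rate", None, params.discount.cost_rate)
    add("discount", "qaly_rate", None, params.discount.qaly_rate)
    add("cohort", "n_patients", None, params.cohort.n_patients)
    add("cohort", "male_fraction", None, params.cohort.male_fraction)
    for label, count in zip(params.cohort.age_group_labels, params.cohort.age_group_counts):
        add("cohort", f"age_group[{label}]", None, count)
    add("currency", "usd_per_aud", None, params.usd_per_aud)
    return pd.DataFrame(rows)
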