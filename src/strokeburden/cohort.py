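"""Synthetic entry cohort: the simulated working-age stroke population.

Patients enter the model 12 months after their index stroke, in an mRS state
drawn from the published 12-month distribution.  The generator reproduces the
published structure exactly where it is printed: per-age-bracket counts are
hit exactly, sex is Bernoulli with the published male fraction, and the
initial-state mix is allocated by largest-remainder quota by default (exact up
to rounding) with a multinomial mode for probabilistic analyses.  Ages at the
index stroke are uniform within each bracket; model entry is one year later.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ValidationError
from .parameters import DEAD, CohortSpec, InitialStateDistribution

ENTRY_LAG_YEARS = 1.0  # model entry is 12 months after the index stroke

SEX_LABELS = ("female", "male")


@dataclass(frozen=True)
class Patient:
    """One simulated individual at model entry."""

    id: int
    age_at_entry: float
    sex: str
    initial_mrs: int
    n_prior_recurrences: int = 0
    stroke_type: str = "ischaemic"
    age_group: str = ""


@dataclass(frozen=True)
class Cohort:
    """Array-backed collection of patients plus the spec and seed that built it."""

    ids: np.ndarray
    age_at_entry: np.ndarray
    sex: np.ndarray            # 1 = male, 0 = female
    initial_mrs: np.ndarray
    stroke_type: np.ndarray    # index into spec.stroke_type_mix labels
    group_index: np.ndarray    # index into spec.age_group_labels
    spec: CohortSpec
    seed: int

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    def patient(self, i: int) -> Patient:
        labels = [name for name, _ in self.spec.stroke_type_mix]
        return Patient(
            id=int(self.ids[i]),
            age_at_entry=float(self.age_at_entry[i]),
            sex=SEX_LABELS[int(self.sex[i])],
            initial_mrs=int(self.initial_mrs[i]),
            stroke_type=labels[int(self.stroke_type[i])],
            age_group=self.spec.age_group_labels[int(self.group_index[i])],
        )

    def __iter__(self) -> Iterator[Patient]:
        return (self.patient(i) for i in range(self.n))

    def to_frame(self) -> pd.DataFrame:
        labels = np.array([name for name, _ in self.spec.stroke_type_mix])
        return pd.DataFrame({
            "id": self.ids,
            "age_at_entry": self.age_at_entry,
            "sex": np.array(SEX_LABELS)[self.sex],
            "initial_mrs": self.initial_mrs,
            "stroke_type": labels[self.stroke_type],
            "age_group": np.array(self.spec.age_group_labels)[self.group_index],
        })


def allocate_quota(probs, n: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` units across probabilities.

    Counts sum to ``n`` and each count differs from ``n * p`` by less than 1;
    remainder ties are broken in favour of the lower index.
    """
    probs = np.asarray(probs, dtype=float)
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    if probs.ndim != 1 or len(probs) == 0:
        raise ValidationError("probs must be a non-empty 1-d vector")
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probs must be non-negative and sum to 1, got sum {probs.sum()}")
    exact = probs * n
    counts = np.floor(exact).astype(int)
    shortfall = int(round(n - counts.sum()))
    if shortfall:
        order = np.argsort(-(exact - counts), kind="stable")  # stable: ties to lower index
        counts[order[:shortfall]] += 1
    return counts


def sample_cohort(
    spec: CohortSpec,
    dist: InitialStateDistribution,
    seed: int,
    mrs_mode: str = "quota",
    age_shift: float = 0.0,
) -> Cohort:
    """Draw the entry cohort.

    ``mrs_mode`` selects how initial states are assigned: ``"quota"``
    (largest-remainder counts, shuffled across patients — the deterministic
    default that removes multinomial noise from base-case runs) or
    ``"multinomial"``.  ``age_shift`` moves every index-age bracket by the
    given number of years (used by the one-way sensitivity analysis).
    """
    spec.validate()
    dist.validate()
    if mrs_mode not in ("quota", "multinomial"):
        raise ValidationError(f"unknown mrs_mode '{mrs_mode}'")
    rng = np.random.default_rng(seed)
    n = spec.n_patients

    ages = np.empty(n)
    group = np.empty(n, dtype=np.int8)
    pos = 0
    for gi, (count, (lo, hi)) in enumerate(zip(spec.age_group_counts, spec.age_group_bounds)):
        ages[pos:pos + count] = rng.uniform(lo + age_shift, hi + age_shift, size=count)
        group[pos:pos + count] = gi
        pos += count
    ages += ENTRY_LAG_YEARS

    sex = (rng.random(n) < spec.male_fraction).astype(np.int8)

    probs = np.asarray(dist.prob_by_mrs)
    if mrs_mode == "quota":
        counts = allocate_quota(probs, n)
        mrs = np.repeat(np.arange(DEAD + 1, dtype=np.int8), counts)
        rng.shuffle(mrs)
    else:
        mrs = rng.choice(DEAD + 1, size=n, p=probs / probs.sum()).astype(np.int8)

    type_probs = np.array([p for _, p in spec.stroke_type_mix])
    stroke_type = rng.choice(len(type_probs), size=n, p=type_probs).astype(np.int8)

    return Cohort(
        ids=np.arange(n),
        age_at_entry=ages,
        sex=sex,
        initial_mrs=mrs,
        stroke_type=stroke_type,
        group_index=group,
        spec=spec,
        seed=seed,
    )


def scaled_spec(spec: CohortSpec, n_patients: int) -> CohortSpec:
    """A spec with the same age structure re-apportioned to ``n_patients``."""
    shares = np.asarray(spec.age_group_counts, dtype=float)
    counts = allocate_quota(shares / shares.sum(), n_patients)
    return CohortSpec(
        n_patients=n_patients,
        total_strokes=spec.total_strokes,
        younger_share=spec.younger_share,
        male_fraction=spec.male_fraction,
        age_group_labels=spec.age_group_labels,
        age_group_counts=tuple(int(c) for c in counts),
        age_group_bounds=spec.age_group_bounds,
        stroke_type_mix=spec.stroke_type_mix,
        indirect_cost_age_cutoff=spec.indirect_cost_age_cutoff,
    )
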