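import dataclasses

import numpy as np
import pytest

from strokeburden import engine, qaly_loss
from strokeburden.cohort import sample_cohort
from strokeburden.errors import DomainError, StateError, ValidationError
from strokeburden.qaly_loss import AgeUtilityTable, expected_qalys, weighted_average

TABLE4_N = [499, 657, 1649, 3842, 6908]


def test_weighted_average_reproduces_published_rows():
    assert weighted_average([9.75, 7.97, 6.18, 4.74, 3.41], TABLE4_N) == pytest.approx(
        4.58, abs=0.005)
    assert weighted_average([15.37, 12.91, 10.98, 9.42, 7.88], TABLE4_N) == pytest.approx(
        9.21, abs=0.005)
    assert weighted_average([16.76, 14.92, 12.58, 10.47, 8.38], TABLE4_N) == pytest.approx(
        10.11, abs=0.005)
    assert weighted_average([5, 5], [1, 3]) == 5


def test_weighted_average_errors():
    with pytest.raises(DomainError):
        weighted_average([1, 2], [1])
    with pytest.raises(DomainError):
        weighted_average([1, 2], [0, 0])


def brute_force_aging_qalys(lys, age, table, population):
    """Independent oracle: walk whole years, pro-rate the final fraction."""
    total, remaining, attained = 0.0, lys, age
    while remaining > 0:
        step = min(1.0, remaining)
        total += step * table.utility(attained, population)
        remaining -= step
        attained += 1
    return total


def test_expected_qalys(params):
    table = AgeUtilityTable.from_parameters(params)
    assert expected_qalys(10, 30, table, "general", "constant") == pytest.approx(8.5)
    assert expected_qalys(0, 50, table, "general", "aging") == 0.0
    # 45 years from age 38 walks every bracket of the general column:
    # 2 x 0.85 + 10 x 0.81 + 10 x 0.80 + 10 x 0.80 + 10 x 0.76 + 3 x 0.70
    value = expected_qalys(45, 38, table, "general", "aging")
    assert value == pytest.approx(35.50)
    assert value == pytest.approx(brute_force_aging_qalys(45, 38, table, "general"))
    frac = expected_qalys(2.5, 38, table, "general", "aging")
    assert frac == pytest.approx(2 * 0.85 + 0.5 * 0.81)
    with pytest.raises(DomainError):
        expected_qalys(-1, 30, table, "general")


def test_age_bracket_lookup(params):
    table = AgeUtilityTable.from_parameters(params)
    assert table.utility(39.9, "general") == 0.85
    assert table.utility(40.0, "general") == 0.81
    assert table.utility(90, "general") == 0.70  # beyond 85 reuses the last bracket
    assert table.utility(64, "stroke") == 0.56


def test_stroke_utilities_cannot_exceed_general():
    with pytest.raises(ValidationError):
        AgeUtilityTable(bounds=((0, 111),), general=(0.5,), stroke=(0.6,)).validate()


def test_aging_mode_never_exceeds_constant_mode(params):
    """With utilities non-increasing in age, aging accrual is a lower bound."""
    table = AgeUtilityTable.from_parameters(params)
    for pop in ("general", "stroke"):
        for age in (20, 35, 52, 61, 78):
            for lys in (0.5, 3, 17.2, 40, 62):
                assert expected_qalys(lys, age, table, pop, "aging") <= expected_qalys(
                    lys, age, table, pop, "constant") + 1e-12


def test_null_effect_limit(params, life_table):
    """No recurrences, no fatal entries, equal utilities: losses vanish.

    The simulated cohort counts completed years while the life table carries a
    half-year correction, so 'vanish' means within that half year plus noise.
    """
    probs = np.asarray(params.initial_distribution.prob_by_mrs).copy()
    probs[6] = 0.0
    probs /= probs.sum()
    dist = dataclasses.replace(params.initial_distribution, prob_by_mrs=tuple(probs))
    rec = dataclasses.replace(params.recurrence, annual_rate=0.0)
    null = dataclasses.replace(params, recurrence=rec, initial_distribution=dist)
    table = AgeUtilityTable(
        bounds=params.age_utility_bounds,
        general=params.age_utility_general,
        stroke=params.age_utility_general,  # same utilities for both populations
        labels=params.age_utility_labels,
    )
    coh = sample_cohort(null.cohort, dist, seed=77)
    loss = qaly_loss.build_loss_table(coh, null, life_table, utilities=table, seed=78)
    for row in loss.rows:
        # half-year convention offset plus Monte-Carlo noise of the group mean
        slack = 0.5 + 3 * 16 / np.sqrt(row.n)
        assert abs(row.loss_lys) < slack
        assert abs(row.loss_qalys_base) < 0.85 * slack


def test_loss_table_structure_and_weighting(params, life_table, full_cohort):
    sim = engine.simulate(full_cohort, params, life_table, horizon=None, seed=41)
    loss = qaly_loss.build_loss_table(full_cohort, params, life_table, sim=sim)
    assert [r.age_group for r in loss.rows] == list(params.cohort.age_group_labels)
    assert [r.n for r in loss.rows] == TABLE4_N
    for row in loss.rows:
        assert row.loss_lys == pytest.approx(row.general_lys - row.stroke_lys, abs=1e-9)
        assert row.loss_lys > 0
        assert row.loss_qalys_base > 0
        # aging-utility sensitivity produces larger losses than the base case
        assert row.loss_qalys_sensitivity >= row.loss_qalys_base - 0.35
    assert loss.weighted_loss_lys == pytest.approx(
        weighted_average([r.loss_lys for r in loss.rows], TABLE4_N))
    # the simulated weighted LY loss reproduces the published 4.58
    assert loss.weighted_loss_lys == pytest.approx(4.58, abs=0.25)
    frame = loss.to_frame()
    assert len(frame) == 6 and frame["age_group"].iloc[-1] == "weighted"


def test_loss_table_requires_lifetime_simulation(params, life_table, full_cohort):
    sim = engine.simulate(full_cohort, params, life_table, horizon=5, seed=42)
    with pytest.raises(StateError):
        qaly_loss.build_loss_table(full_cohort, params, life_table, sim=sim)
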