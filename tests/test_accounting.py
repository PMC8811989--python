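import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokeburden import accounting, engine
from strokeburden.errors import DomainError
from strokeburden.parameters import DEAD, AccountingOptions

from conftest import uniform_cohort


def test_discount_factor():
    assert accounting.discount_factor(0.05, 1) == 1.0
    assert accounting.discount_factor(0.05, 2) == pytest.approx(1 / 1.05)
    for k in (1, 7, 30):
        assert accounting.discount_factor(0.0, k) == 1.0
    with pytest.raises(DomainError):
        accounting.discount_factor(0.05, 0)


@settings(max_examples=50, derandomize=True)
@given(st.floats(0.0, 0.2), st.integers(1, 60))
def test_discount_factor_bounded_and_decreasing(rate, cycle):
    f = accounting.discount_factor(rate, cycle)
    assert 0 < f <= 1.0
    assert f >= accounting.discount_factor(rate, cycle + 1)


def test_cycle_cost_published_values(params):
    costs = params.costs
    assert accounting.cycle_cost(2, 1, 50, False, costs) == (40408, 5236, 47534)
    assert accounting.cycle_cost(2, 3, 50, False, costs) == (1774, 730, 19855)
    assert accounting.cycle_cost(2, 3, 70, False, costs) == (1774, 730, 0)
    # recurrence cycle accrues the short-term triple of the new state
    assert accounting.cycle_cost(4, 3, 50, True, costs) == (85578, 58569, 43301)
    assert accounting.cycle_cost(4, 3, 50, True, costs,
                                 recurrence_costing=False) == (13715, 5648, 43301)
    # dead state after cycle 1 accrues nothing without a recurrence death
    assert accounting.cycle_cost(DEAD, 3, 50, False, costs) == (0, 0, 0)
    assert accounting.cycle_cost(DEAD, 3, 50, True, costs) == (43644, 19738, 39612)


def test_cycle_qaly_published_values(params):
    assert accounting.cycle_qaly(0, 1, params.utilities) == 0.85
    assert accounting.cycle_qaly(3, 5, params.utilities, 0.0) == 0.51
    assert accounting.cycle_qaly(DEAD, 1, params.utilities) == 0.0
    assert accounting.cycle_qaly(DEAD, 10, params.utilities) == 0.0


def quiet_sim(params, table, mrs, horizon, n=1, age=40.0):
    rec = dataclasses.replace(params.recurrence, annual_rate=0.0)
    quiet = dataclasses.replace(params, recurrence=rec)
    coh = uniform_cohort(n, age, mrs, params.cohort)
    return engine.simulate(coh, quiet, table, horizon=horizon, seed=0), quiet


def test_accumulate_event_free_closed_form(params, zero_hazard_table):
    """A patient held in mRS 1 for 5 years: short-term year plus a 4-year annuity."""
    sim, quiet = quiet_sim(params, zero_hazard_table, mrs=1, horizon=5)
    outcome = accounting.accumulate(sim.trajectory(0), quiet)
    annuity = sum(1.05 ** -(t - 1) for t in range(2, 6))
    assert annuity == pytest.approx(3.545951, abs=1e-6)
    assert outcome["medical"] == pytest.approx(21901 + annuity * 1400)
    assert outcome["nonmedical"] == pytest.approx(2112 + annuity * 576)
    assert outcome["indirect"] == pytest.approx(27400 + annuity * 2998)
    assert outcome["qalys"] == pytest.approx(0.78 + 4 * 0.80)
    assert outcome["lys"] == 5.0


def test_accumulate_dead_entrant(params, life_table):
    coh = uniform_cohort(1, 50.0, DEAD, params.cohort)
    sim = engine.simulate(coh, params, life_table, horizon=5, seed=0)
    outcome = accounting.accumulate(sim.trajectory(0), params)
    assert (outcome["medical"], outcome["nonmedical"], outcome["indirect"]) == (
        43644, 19738, 39612)
    assert outcome["qalys"] == 0.0
    assert outcome["lys"] == 0.0


@pytest.mark.parametrize("horizon", [5, 30])
def test_vectorized_accounting_matches_scalar(params, life_table, full_cohort, horizon):
    """The fast array path and the per-trajectory reference path agree exactly."""
    rng = np.random.default_rng(0)
    idx = rng.choice(full_cohort.n, size=300, replace=False)
    sim = engine.simulate(full_cohort, params, life_table, horizon=horizon, seed=21)
    table = accounting.accumulate_all(sim, params)
    for i in idx:
        scalar = accounting.accumulate(sim.trajectory(i), params)
        for key, value in scalar.items():
            assert table[key].iloc[i] == pytest.approx(value, abs=1e-9), (i, key)


def test_discounting_never_increases_costs(params, life_table, full_cohort):
    sim = engine.simulate(full_cohort, params, life_table, horizon=30, seed=22)
    discounted = accounting.accumulate_all(sim, params)
    disc0 = dataclasses.replace(params.discount, cost_rate=0.0)
    undiscounted = accounting.accumulate_all(
        sim, dataclasses.replace(params, discount=disc0))
    assert np.all(discounted["total"].to_numpy() <= undiscounted["total"].to_numpy() + 1e-9)


def test_outcome_invariants(params, life_table, full_cohort):
    sim = engine.simulate(full_cohort, params, life_table, horizon=30, seed=23)
    out = accounting.accumulate_all(sim, params)
    for col in ("medical", "nonmedical", "indirect", "total", "qalys", "lys"):
        assert np.all(np.isfinite(out[col]))
        assert np.all(out[col] >= 0)
    assert np.all(out["qalys"] <= out["lys"] + 1e-12)
    assert np.all(out["qalys"] <= 30)


def test_indirect_cutoff_toggle(params, zero_hazard_table):
    sim, quiet = quiet_sim(params, zero_hazard_table, mrs=2, horizon=5, age=63.0)
    with_cutoff = accounting.accumulate_all(sim, quiet)["indirect"].iloc[0]
    free = dataclasses.replace(
        quiet, accounting=AccountingOptions(indirect_cutoff=False))
    without = accounting.accumulate_all(sim, free)["indirect"].iloc[0]
    # attained ages 65-67 in cycles 3-5 accrue indirect costs only without the cutoff
    lost = 19855 * sum(1.05 ** -(t - 1) for t in (3, 4, 5))
    assert without - with_cutoff == pytest.approx(lost)
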