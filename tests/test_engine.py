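import dataclasses

import numpy as np
import pytest

from strokeburden import engine
from strokeburden.errors import DomainError
from strokeburden.parameters import DEAD

from conftest import uniform_cohort


def no_event_params(params):
    rec = dataclasses.replace(params.recurrence, annual_rate=0.0)
    return dataclasses.replace(params, recurrence=rec)


def test_recurrence_probability(params):
    rec = params.recurrence
    assert engine.recurrence_probability(rec, 0) == 0.0201
    assert engine.recurrence_probability(rec, 2) == pytest.approx(0.0201 * 1.39**2)
    assert engine.recurrence_probability(rec, 50) == 1.0
    with pytest.raises(DomainError):
        engine.recurrence_probability(rec, -1)


def test_case_fatality_age_threshold(params):
    rec = params.recurrence
    assert engine.case_fatality(rec, 64.9) == 0.0866
    assert engine.case_fatality(rec, 65.0) == 0.2683
    assert engine.case_fatality(rec, 30) == 0.0866


def test_post_recurrence_state_is_uniform_over_same_or_worse():
    rng = np.random.default_rng(0)
    assert all(engine.post_recurrence_state(5, rng) == 5 for _ in range(100))
    for current, options in ((3, [3, 4, 5]), (0, [0, 1, 2, 3, 4, 5])):
        draws = np.array([engine.post_recurrence_state(current, rng) for _ in range(100_000)])
        assert set(np.unique(draws)) == set(options)
        p = 1 / len(options)
        se = np.sqrt(p * (1 - p) / len(draws))
        for state in options:
            assert abs((draws == state).mean() - p) < 3 * se
    with pytest.raises(DomainError):
        engine.post_recurrence_state(DEAD, rng)


def test_advance_cycle_first_cycle_has_no_recurrence(params, life_table):
    rng = np.random.default_rng(1)
    kinds = {engine.advance_cycle((1, 55.0, 0), params, life_table, 1, rng).kind
             for _ in range(5000)}
    assert kinds <= {"none", "background_death"}
    with pytest.raises(DomainError):
        engine.advance_cycle((DEAD, 55.0, 0), params, life_table, 2, rng)


def test_advance_cycle_event_free_limit(params, zero_hazard_table):
    quiet = no_event_params(params)
    rng = np.random.default_rng(2)
    for cycle in (1, 2, 10):
        event = engine.advance_cycle((2, 40.0, 0), quiet, zero_hazard_table, cycle, rng)
        assert event.kind == "none" and event.new_mrs == 2


def test_simulate_all_dead_cohort(params, life_table):
    coh = uniform_cohort(50, 60.0, DEAD, params.cohort)
    sim = engine.simulate(coh, params, life_table, horizon=5, seed=0)
    assert np.all(sim.alive_cycles == 0)
    assert np.all(sim.recurrence_count == 0)
    assert np.all(sim.states == DEAD)


def test_simulate_absorbing_free_limit(params, zero_hazard_table):
    coh = uniform_cohort(200, 40.0, 2, params.cohort)
    sim = engine.simulate(coh, no_event_params(params), zero_hazard_table,
                          horizon=5, seed=0)
    assert np.all(sim.alive_cycles == 5)
    assert np.all(sim.states == 2)


def test_trajectories_monotone_and_death_absorbing(params, life_table, full_cohort):
    sim = engine.simulate(full_cohort, params, life_table, horizon=30, seed=3)
    first = np.repeat(full_cohort.initial_mrs[:, None], 1, axis=1)
    path = np.concatenate([first, sim.states], axis=1)
    assert np.all(np.diff(path.astype(int), axis=1) >= 0)
    dead = sim.states == DEAD
    # once dead, always dead
    assert np.all(dead[:, :-1] <= dead[:, 1:])
    # death events imply the dead state from that cycle on
    death_cycle = np.isin(sim.events, (engine.EVENT_RECURRENCE_DEATH,
                                       engine.EVENT_BACKGROUND_DEATH))
    assert np.all(sim.states[death_cycle] == DEAD)


def test_same_seed_bit_identical(params, life_table, full_cohort):
    a = engine.simulate(full_cohort, params, life_table, horizon=10, seed=42)
    b = engine.simulate(full_cohort, params, life_table, horizon=10, seed=42)
    assert np.array_equal(a.states, b.states)
    assert np.array_equal(a.events, b.events)
    assert np.array_equal(a.alive_cycles, b.alive_cycles)


def test_recurrence_rate_recovery(params, zero_hazard_table):
    """Cycle-2 recurrence frequency recovers 2.01%/yr; one prior event scales it by 1.39."""
    n = 500_000
    coh = uniform_cohort(n, 40.0, 0, params.cohort)
    sim = engine.simulate(coh, params, zero_hazard_table, horizon=3, seed=7)
    rec2 = np.isin(sim.events[:, 1], (engine.EVENT_RECURRENCE_SURVIVED,
                                      engine.EVENT_RECURRENCE_DEATH))
    p0 = params.recurrence.annual_rate
    se0 = np.sqrt(p0 * (1 - p0) / n)
    assert abs(rec2.mean() - p0) < 3 * se0

    survivors = sim.events[:, 1] == engine.EVENT_RECURRENCE_SURVIVED
    rec3 = np.isin(sim.events[survivors, 2], (engine.EVENT_RECURRENCE_SURVIVED,
                                              engine.EVENT_RECURRENCE_DEATH))
    p1 = p0 * params.recurrence.risk_ratio_per_prior_event
    se1 = np.sqrt(p1 * (1 - p1) / survivors.sum())
    assert abs(rec3.mean() - p1) < 3 * se1


def test_lifetime_mode_everyone_dies(params, life_table):
    coh = uniform_cohort(2000, 60.0, 1, params.cohort)
    sim = engine.simulate(coh, params, life_table, horizon=None, seed=9)
    last = sim.states[:, -1]
    assert np.all(last == DEAD)
    assert sim.horizon is None


def test_trajectory_view_and_long_export(params, life_table):
    coh = uniform_cohort(5, 50.0, 1, params.cohort)
    sim = engine.simulate(coh, params, life_table, horizon=4, seed=11)
    traj = sim.trajectory(0)
    assert traj.initial_mrs == 1
    assert len(traj.states) == 4
    df = sim.to_frame()
    assert len(df) == 5 * 4
    assert set(df["event"]).issubset(set(engine.EVENT_LABELS.values()))
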