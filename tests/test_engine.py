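"""Engine: weight chain, cycle mechanics, tunnel states, CRN, chain oracle."""
import numpy as np
import pytest

from sodasim import (HealthState, ModelConfig, STATUS_QUO, calibrate,
                     calories_to_weight_rate, generate_cohort, simulate,
                     soda_tax_arm, sugar_to_calories, weight_step)
from sodasim.engine import ArmSpec, CompiledTransitions, advance_cycle
from sodasim.population import Cohort

NO_GAIN = (0.0, 0.0)


def _fixed_cohort(states, weight=70.0, height=1.70):
    n = len(states)
    codes = np.array([int(s) for s in states], dtype=np.int8)
    return Cohort(np.full(n, weight), np.full(n, height), codes,
                  alive=codes != int(HealthState.DEATH))


# ---------------------------------------------------------------------------
# weight-effect chain
# ---------------------------------------------------------------------------

def test_weight_step_additive_and_floor():
    assert weight_step(80.0, 0.0, 0.68) == pytest.approx(80.68)
    assert weight_step(80.0, -0.56, 0.68) == pytest.approx(80.12)
    assert weight_step(30.1, -1.93, 0.45) == 30.0  # floored


def test_sugar_to_calories():
    assert sugar_to_calories(3.08) == pytest.approx(12.32)
    assert sugar_to_calories(0.0) == 0.0
    assert sugar_to_calories(-10.27) == pytest.approx(-41.08)


def test_calories_to_weight_rate():
    assert calories_to_weight_rate(12.32) == pytest.approx(0.583, abs=5e-4)
    assert calories_to_weight_rate(0.0) == 0.0
    # unit inversion: the deficit equivalent to exactly 1 kg/y
    kcal = 3500.0 / 365 * 2.20462
    assert calories_to_weight_rate(kcal) == pytest.approx(1.0, rel=1e-12)


def test_status_quo_arm_must_have_no_effect():
    with pytest.raises(ValueError):
        ArmSpec("status_quo", -0.5)


# ---------------------------------------------------------------------------
# cycle mechanics
# ---------------------------------------------------------------------------

def test_frozen_dynamics_leave_cohort_unchanged():
    # weights chosen so each state matches its BMI category (heights 1.70 m)
    cohort = Cohort(np.array([60.0, 80.0, 95.0]), np.full(3, 1.70),
                    np.array([int(HealthState.NORMAL), int(HealthState.OVERWEIGHT),
                              int(HealthState.OBESITY)], dtype=np.int8))
    compiled = CompiledTransitions({})
    rng = np.random.default_rng(0)
    before = cohort.state.copy()
    weights = cohort.weight.copy()
    for _ in range(5):
        advance_cycle(cohort, STATUS_QUO, compiled, rng, gain_range=NO_GAIN)
    assert np.array_equal(cohort.state, before)
    assert np.array_equal(cohort.weight, weights)


def test_tunnel_promotion_stroke_to_poststroke():
    cohort = _fixed_cohort([HealthState.STROKE])
    cohort.tenure[:] = 1  # entered last cycle
    compiled = CompiledTransitions({})  # no transitions -> always "remain"
    advance_cycle(cohort, STATUS_QUO, compiled, np.random.default_rng(1),
                  gain_range=NO_GAIN)
    assert cohort.state[0] == HealthState.POSTSTROKE


def test_death_is_absorbing_and_accrues_nothing():
    cohort = _fixed_cohort([HealthState.DEATH])
    compiled = CompiledTransitions({(HealthState.NORMAL, HealthState.DEATH): 0.5})
    w0 = cohort.weight.copy()
    for _ in range(3):
        advance_cycle(cohort, STATUS_QUO, compiled, np.random.default_rng(2))
    assert cohort.state[0] == HealthState.DEATH
    assert not cohort.alive[0]
    assert np.array_equal(cohort.weight, w0)


def test_certain_transition_fires():
    cohort = _fixed_cohort([HealthState.ESRD] * 100)
    compiled = CompiledTransitions({(HealthState.ESRD, HealthState.DEATH): 1.0})
    advance_cycle(cohort, STATUS_QUO, compiled, np.random.default_rng(3),
                  gain_range=NO_GAIN)
    assert np.all(cohort.state == HealthState.DEATH)
    assert not cohort.alive.any()


def test_row_sum_above_one_rejected():
    with pytest.raises(ValueError):
        CompiledTransitions({(HealthState.MI, HealthState.STROKE): 0.7,
                             (HealthState.MI, HealthState.DEATH): 0.5})


# ---------------------------------------------------------------------------
# full-horizon invariants
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_cohort(pop_spec):
    return generate_cohort(pop_spec.with_n(4_000), seed=21)


def test_person_conservation_and_monotone_deaths(small_cohort, pset, config):
    cfg = config.replace(n_individuals=small_cohort.n)
    trace, final = simulate(small_cohort, STATUS_QUO, pset.transitions.central(),
                            cfg, seed=5)
    assert np.all(trace.state_counts.sum(axis=1) == small_cohort.n)
    deaths = trace.state_counts[:, HealthState.DEATH]
    assert np.all(np.diff(deaths) >= 0)
    assert final.alive.sum() + deaths[-1] == small_cohort.n
    assert np.all(trace.events.to_numpy() >= 0)


def test_null_intervention_crn_equivalence(small_cohort, pset, config):
    """With zero weight effect and shared seeds the two arms are identical."""
    cfg = config.replace(n_individuals=small_cohort.n)
    probs = pset.transitions.central()
    t_sq, f_sq = simulate(small_cohort, STATUS_QUO, probs, cfg, seed=17)
    t_null, f_null = simulate(small_cohort, soda_tax_arm(0.0), probs, cfg, seed=17)
    assert np.array_equal(t_sq.state_counts, t_null.state_counts)
    assert t_sq.events.equals(t_null.events)
    assert np.array_equal(f_sq.state, f_null.state)
    assert np.array_equal(f_sq.weight, f_null.weight)


def test_simulation_deterministic_under_seed(small_cohort, pset, config):
    cfg = config.replace(n_individuals=small_cohort.n)
    probs = pset.transitions.central()
    t1, _ = simulate(small_cohort, soda_tax_arm(), probs, cfg, seed=23)
    t2, _ = simulate(small_cohort, soda_tax_arm(), probs, cfg, seed=23)
    assert np.array_equal(t1.state_counts, t2.state_counts)


def test_stronger_tax_effect_does_not_increase_obesity(small_cohort, pset, config):
    """Under CRN, a more negative weight effect cannot add obesity person-cycles."""
    cfg = config.replace(n_individuals=small_cohort.n)
    probs = pset.transitions.central()
    totals = []
    for effect in (0.0, -0.56, -1.5):
        trace, _ = simulate(small_cohort, ArmSpec("soda_tax", effect), probs,
                            cfg, seed=31)
        totals.append(trace.total_events("person_cycles_obese"))
    assert totals[0] >= totals[1] >= totals[2]


def test_zero_horizon_empty_trace(small_cohort, pset, config):
    cfg = config.replace(n_individuals=small_cohort.n, horizon_years=0)
    trace, final = simulate(small_cohort, STATUS_QUO, pset.transitions.central(), cfg)
    assert trace.state_counts.shape == (0, 10)
    assert np.array_equal(final.state, small_cohort.state)


def test_three_state_chain_matches_matrix_power_oracle():
    """Microsimulated occupancy of a normal->diabetes->death chain equals the
    closed-form cohort (matrix-power) solution within 3 binomial SEs."""
    n, horizon = 100_000, 20
    p_nd, p_dd = 0.02, 0.05
    probs = {(HealthState.NORMAL, HealthState.DIABETES): p_nd,
             (HealthState.DIABETES, HealthState.DEATH): p_dd}
    cohort = _fixed_cohort([HealthState.NORMAL] * n, weight=60.0)
    cfg = ModelConfig(n_individuals=n, horizon_years=horizon,
                      natural_gain_range=NO_GAIN)
    trace, _ = simulate(cohort, STATUS_QUO, probs, cfg, seed=13)

    P = np.zeros((3, 3))  # states: normal, diabetes, death
    P[0] = [1 - p_nd, p_nd, 0.0]
    P[1] = [0.0, 1 - p_dd, p_dd]
    P[2] = [0.0, 0.0, 1.0]
    occ = np.array([1.0, 0.0, 0.0])
    for t in range(horizon):
        occ = occ @ P
        for j, s in enumerate((HealthState.NORMAL, HealthState.DIABETES,
                               HealthState.DEATH)):
            expected = n * occ[j]
            se = np.sqrt(n * occ[j] * (1 - occ[j]))
            assert abs(trace.state_counts[t, s] - expected) <= 3 * se + 1e-9, \
                f"cycle {t}, state {s.name}"
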