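"""Parameter ingestion, interval conventions, measure conversions, PSA fits."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sodasim import (HealthState, ParameterValue, TransitionTable,
                     fit_distribution, load_parameters,
                     multi_year_risk_to_annual, pm25_bounds,
                     ratio_to_probability)
from sodasim.parameters import (MissingParameterError, ValidationError,
                                renormalize_rows)


# ---------------------------------------------------------------------------
# pm25 interval convention
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mean, low, high", [
    (8_627_229, 6_470_421.75, 10_784_036.25),   # admin cost row
    (0.0, 0.0, 0.0),
    (0.0090, 0.00675, 0.01125),                 # printed rounded as 0.0067-0.0112
])
def test_pm25_bounds_values(mean, low, high):
    assert pm25_bounds(mean) == pytest.approx((low, high))


@given(m=st.floats(0.001, 1e9), c=st.floats(0.01, 100))
@settings(derandomize=True, max_examples=50)
def test_pm25_bounds_linear(m, c):
    lo, hi = pm25_bounds(m)
    clo, chi = pm25_bounds(c * m)
    assert clo == pytest.approx(c * lo, rel=1e-12)
    assert chi == pytest.approx(c * hi, rel=1e-12)


# ---------------------------------------------------------------------------
# multi-year risk -> annual probability
# ---------------------------------------------------------------------------

def test_risk_identity_and_zero():
    assert multi_year_risk_to_annual(0.0, 7) == 0.0
    assert multi_year_risk_to_annual(0.2, 1) == pytest.approx(0.2)


def test_risk_ten_year_closed_form_and_simulation():
    p1 = multi_year_risk_to_annual(0.2, 10)
    assert p1 == pytest.approx(1 - 0.8 ** 0.1, abs=1e-15)
    # oracle: 10 independent annual Bernoulli(p1) rounds reproduce the 10-y risk
    rng = np.random.default_rng(7)
    n = 200_000
    hit = (rng.random((10, n)) < p1).any(axis=0)
    se = math.sqrt(0.2 * 0.8 / n)
    assert abs(hit.mean() - 0.2) < 3 * se


def test_certain_risk_rejected():
    with pytest.raises(ValidationError):
        multi_year_risk_to_annual(1.0, 10)


# ---------------------------------------------------------------------------
# ratio -> probability
# ---------------------------------------------------------------------------

def test_null_ratio_is_identity():
    for kind in ("rr", "hr", "irr", "or"):
        assert ratio_to_probability(0.1, 1.0, kind) == pytest.approx(0.1)


def test_odds_ratio_against_two_by_two_table():
    """Inverting the OR definition on an explicit 2x2 table."""
    p0, OR = 0.1, 2.0
    p1 = ratio_to_probability(p0, OR, "or")
    assert p1 == pytest.approx(0.2 / 1.1, abs=1e-12)
    # the resulting odds ratio of the 2x2 table equals OR
    odds0, odds1 = p0 / (1 - p0), p1 / (1 - p1)
    assert odds1 / odds0 == pytest.approx(OR, abs=1e-12)


def test_hazard_ratio_against_survival_oracle():
    """S1(t) = S0(t)^HR at t = 1 year."""
    p0, HR = 0.1, 2.0
    p1 = ratio_to_probability(p0, HR, "hr")
    assert p1 == pytest.approx(1 - (1 - p0) ** HR, abs=1e-12)
    assert p1 == pytest.approx(0.19, abs=1e-12)


def test_risk_ratio_caps_at_one():
    assert ratio_to_probability(0.6, 3.0, "rr") == 1.0


@given(p=st.floats(0.001, 0.5), r1=st.floats(0.1, 5), r2=st.floats(0.1, 5))
@settings(derandomize=True, max_examples=100)
def test_ratio_conversion_monotone_in_ratio(p, r1, r2):
    lo, hi = sorted((r1, r2))
    for kind in ("rr", "hr", "irr", "or"):
        assert ratio_to_probability(p, lo, kind) <= ratio_to_probability(p, hi, kind) + 1e-15


@given(p=st.floats(1e-6, 0.01), r=st.floats(0.5, 2.0))
@settings(derandomize=True, max_examples=100)
def test_rare_disease_limit_agreement(p, r):
    """For rare outcomes the rr/hr/or conversions agree within 5% relative."""
    vals = [ratio_to_probability(p, r, k) for k in ("rr", "hr", "or")]
    assert max(vals) <= min(vals) * 1.05


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------

def _pv(name, mean, low, high, kind="ci95", family="gamma"):
    return ParameterValue(name, mean, low, high, kind, family)


def test_gamma_fit_matches_mean_and_sd():
    pv = _pv("cost:diabetes", 21_218, 15_913, 26_522, family="gamma")
    dist = fit_distribution(pv)
    shape, scale = dist.params
    assert shape * scale == pytest.approx(21_218, abs=1e-9)
    sd = (26_522 - 15_913) / 3.92
    assert math.sqrt(shape) * scale == pytest.approx(sd, rel=1e-12)


def test_beta_fit_matches_mean():
    pv = _pv("utility:diabetes", 0.785, 0.681, 0.889, family="beta")
    dist = fit_distribution(pv)
    a, b = dist.params
    assert a / (a + b) == pytest.approx(0.785, abs=1e-9)


def test_lognormal_fit_matches_both_moments():
    pv = _pv("rr", 1.4, 1.1, 1.9, family="lognormal")
    mu, sigma = fit_distribution(pv).params
    mean = math.exp(mu + sigma**2 / 2)
    sd = mean * math.sqrt(math.expm1(sigma**2))
    assert mean == pytest.approx(1.4, abs=1e-9)
    assert sd == pytest.approx((1.9 - 1.1) / 3.92, rel=1e-9)


def test_degenerate_interval_is_point_mass():
    pv = _pv("overweight->death", 0.0087, 0.0087, 0.0087, family="beta")
    dist = fit_distribution(pv)
    assert dist.family == "fixed"
    assert dist.sample(np.random.default_rng(0)) == 0.0087


def test_beta_mean_one_collapses_to_fixed():
    pv = _pv("utility:normal", 1.0, 0.75, 1.0, kind="pm25", family="beta")
    assert fit_distribution(pv).family == "fixed"


def test_nonpositive_mean_gamma_warns_and_fixes():
    pv = _pv("weird", 0.0, -1.0, 1.0, family="gamma")
    with pytest.warns(UserWarning):
        dist = fit_distribution(pv)
    assert dist.family == "fixed"


@pytest.mark.parametrize("pv", [
    _pv("cost:diabetes", 21_218, 15_913, 26_522, family="gamma"),
    _pv("utility:diabetes", 0.785, 0.681, 0.889, family="beta"),
    _pv("rr", 1.4, 1.1, 1.9, family="lognormal"),
    _pv("weight_change", -0.56, -1.93, 0.77, family="normal"),
])
def test_monte_carlo_recovers_mean(pv):
    """10^5 draws recover the analytic mean within 3 Monte-Carlo SEs."""
    dist = fit_distribution(pv)
    draws = dist.sample(np.random.default_rng(11), 100_000)
    se = draws.std(ddof=1) / math.sqrt(draws.size)
    assert abs(draws.mean() - pv.mean) < 3 * se


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------

def test_default_config_shape(pset):
    assert len(pset.transitions.entries) == 30
    assert len(pset.costs) == 9
    assert len(pset.utilities) == 8


def test_default_rows_sum_below_one(pset):
    for origin in {o for o, _ in pset.transitions.entries}:
        assert pset.transitions.row_sum(origin) < 1.0


def test_out_of_range_probability_rejected():
    raw = {"transitions": {"normal": {"diabetes": {"mean": 1.5}}}}
    with pytest.raises(ValidationError):
        load_parameters(raw)


def test_missing_transition_named():
    import yaml
    from sodasim.parameters import _default_config_path
    raw = yaml.safe_load(_default_config_path().read_text())
    del raw["transitions"]["obesity"]["diabetes"]
    with pytest.raises(MissingParameterError, match="obesity->diabetes"):
        load_parameters(raw)


def test_row_renormalization_conserves_mass():
    probs = {(HealthState.STROKE, HealthState.MI): 0.8,
             (HealthState.STROKE, HealthState.DEATH): 0.6,
             (HealthState.NORMAL, HealthState.DEATH): 0.01}
    out = renormalize_rows(probs)
    stroke_sum = (out[(HealthState.STROKE, HealthState.MI)]
                  + out[(HealthState.STROKE, HealthState.DEATH)])
    assert stroke_sum == pytest.approx(1.0)
    # untouched row and preserved proportions
    assert out[(HealthState.NORMAL, HealthState.DEATH)] == 0.01
    ratio = out[(HealthState.STROKE, HealthState.MI)] / out[(HealthState.STROKE, HealthState.DEATH)]
    assert ratio == pytest.approx(0.8 / 0.6)


def test_transition_table_csv_round_trip(pset, tmp_path):
    path = tmp_path / "transitions.csv"
    pset.transitions.to_csv(path)
    back = TransitionTable.from_csv(path)
    assert back.central() == pytest.approx(pset.transitions.central())
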