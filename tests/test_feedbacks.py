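import numpy as np
import pytest

from fiscalfood.clinical import ILLNESSES
from fiscalfood.demography import N_AGES
from fiscalfood.feedbacks import (
    FeedbackError,
    HealthEconParams,
    health_costs,
    labour_supply,
    time_losses,
)

HH = ["hh.a", "hh.b"]


def make_params(public_share=0.8):
    return HealthEconParams(
        caregiver_work={"mi_nonfatal": 0.10, "stroke_nonfatal": 0.15},
        caregiver_leisure={"mi_nonfatal": 0.15, "stroke_nonfatal": 0.25},
        illness_duration={"mi_nonfatal": 28.0 / 365.0, "stroke_nonfatal": 1.0},
        yld_weight={"mi_nonfatal": 0.12, "stroke_nonfatal": 0.27},
        participation={"male": 0.8, "female": 0.65},
        skill_share=np.array([[0.7, 0.3], [0.6, 0.4]]),
        huc0={
            "mi_nonfatal": np.array([100.0, 0.0, 0.0, 0.0]),
            "stroke_nonfatal": np.array([200.0, 80.0, 40.0, 20.0]),
            "mi_fatal": np.zeros(4),
            "stroke_fatal": np.zeros(4),
        },
        public_share=public_share,
    )


def levels_with(mi=0.0, stroke=0.0, h=0, g=0, a=10):
    lev = np.zeros((2, 2, N_AGES, len(ILLNESSES)))
    lev[h, g, a, ILLNESSES.index("mi_nonfatal")] = mi
    lev[h, g, a, ILLNESSES.index("stroke_nonfatal")] = stroke
    return lev


def test_zero_cases_zero_losses():
    tl = time_losses(np.zeros((2, 2, N_AGES, 4)), HH, make_params())
    assert np.all(tl.caregiver_work == 0)
    assert np.all(tl.yld == 0)
    assert np.all(tl.patient_work == 0)


def test_losses_linear_in_cases():
    p = make_params()
    one = time_losses(levels_with(mi=10.0, stroke=5.0), HH, p)
    two = time_losses(levels_with(mi=20.0, stroke=10.0), HH, p)
    np.testing.assert_allclose(two.caregiver_work, 2 * one.caregiver_work, rtol=1e-12)
    np.testing.assert_allclose(two.patient_work, 2 * one.patient_work, rtol=1e-12)


def test_single_illness_hand_example():
    """100 male MI cases: rate x duration x cases, YLD-weighted patient time."""
    p = make_params()
    tl = time_losses(levels_with(mi=100.0, g=0), HH, p)
    dur = 28.0 / 365.0
    assert tl.caregiver_work[0, 0] == pytest.approx(0.10 * dur * 100.0, rel=1e-12)
    assert tl.caregiver_leisure[0, 0] == pytest.approx(0.15 * dur * 100.0, rel=1e-12)
    assert tl.yld[0, 0, 0] == pytest.approx(0.12 * dur * 100.0, rel=1e-12)
    # patient worktime = participation-weighted YLD (male cases only)
    assert tl.patient_work[0, 0] == pytest.approx(0.8 * 0.12 * dur * 100.0, rel=1e-12)
    assert tl.caregiver_work[1, 0] == 0.0


def test_labour_supply_baseline():
    p = make_params()
    pop = np.zeros((2, 2, N_AGES))
    pop[:, 0, 5] = 100.0  # males in one working-age group
    pop[:, 1, 5] = 100.0
    ls = labour_supply(pop, p)
    base = 0.8 * 100 + 0.65 * 100
    np.testing.assert_allclose(ls[0], [0.7 * base, 0.3 * base], rtol=1e-12)
    np.testing.assert_allclose(ls[1], [0.6 * base, 0.4 * base], rtol=1e-12)


def test_labour_supply_marginal_accounting():
    p = make_params()
    pop = np.zeros((2, 2, N_AGES))
    pop[:, :, 5] = 100.0
    base = labour_supply(pop, p)
    delta = np.zeros((2, 2))
    delta[0, 0] = 1.0
    shifted = labour_supply(pop, p, caregiver_delta=delta)
    np.testing.assert_allclose(base[0] - shifted[0], p.skill_share[0] * 1.0, rtol=1e-12)
    np.testing.assert_allclose(shifted[1], base[1], rtol=1e-12)


def test_labour_supply_ignores_non_working_ages():
    p = make_params()
    pop = np.zeros((2, 2, N_AGES))
    pop[:, :, 0] = 500.0   # children
    pop[:, :, 14] = 500.0  # 70+
    assert np.all(labour_supply(pop, p) == 0)


def test_health_costs_mi_zero_lag_only():
    p = make_params()
    hist = {y: np.zeros((2, 2)) for y in range(2013, 2018)}
    hist[2016] = np.array([[1.0, 0.0], [0.0, 0.0]])  # one MI case in hh 0
    hc_now = health_costs(hist, 2016, p, deflator=1.0)
    assert hc_now.total[0, 0] == pytest.approx(100.0)
    hc_later = health_costs(hist, 2017, p, deflator=1.0)
    assert np.all(hc_later.total == 0.0)  # MI carries no lagged costs


def test_health_costs_stroke_lag_profile():
    p = make_params()
    hist = {y: np.zeros((2, 2)) for y in range(2012, 2020)}
    hist[2016] = np.array([[0.0, 1.0], [0.0, 0.0]])  # one stroke case
    costs = [health_costs(hist, y, p, deflator=1.0).total[0, 1] for y in range(2016, 2020)]
    assert costs == pytest.approx([200.0, 80.0, 40.0, 20.0])


def test_health_costs_deflator_scaling():
    p = make_params()
    hist = {y: np.zeros((2, 2)) for y in range(2013, 2017)}
    hist[2016] = np.array([[1.0, 1.0], [0.0, 0.0]])
    nominal = health_costs(hist, 2016, p, deflator=2.0)
    base = health_costs(hist, 2016, p, deflator=1.0)
    np.testing.assert_allclose(nominal.total, 2 * base.total, rtol=1e-12)
    # real costs (nominal deflated) unchanged
    np.testing.assert_allclose(nominal.total / 2.0, base.total, rtol=1e-12)


def test_health_costs_public_private_split():
    p = make_params(public_share=0.8)
    hist = {y: np.zeros((2, 2)) for y in range(2013, 2017)}
    hist[2016] = np.array([[1.0, 0.0], [0.0, 0.0]])
    hc = health_costs(hist, 2016, p, deflator=1.0)
    assert hc.public[0, 0] == pytest.approx(80.0)
    assert hc.private[0, 0] == pytest.approx(20.0)


def test_missing_history_rejected():
    p = make_params()
    with pytest.raises(FeedbackError, match="missing"):
        health_costs({2016: np.zeros((2, 2))}, 2016, p, deflator=1.0)


def test_lagged_mi_costs_rejected_in_params():
    with pytest.raises(FeedbackError):
        HealthEconParams(
            caregiver_work={"mi_nonfatal": 0.1, "stroke_nonfatal": 0.1},
            caregiver_leisure={"mi_nonfatal": 0.1, "stroke_nonfatal": 0.1},
            illness_duration={"mi_nonfatal": 0.08, "stroke_nonfatal": 1.0},
            yld_weight={"mi_nonfatal": 0.1, "stroke_nonfatal": 0.2},
            participation={"male": 0.8, "female": 0.6},
            skill_share=np.array([[0.5, 0.5]]),
            huc0={"mi_nonfatal": np.array([1.0, 1.0, 0.0, 0.0])},
        )
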