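import numpy as np
import pytest

from fiscalfood.demography import (
    FERTILE,
    N_AGES,
    DemographicState,
    DemographyError,
    VitalRates,
    apply_excess_feedback,
    calibrate_transitions,
    excess_mortality,
    project_year,
    vital_events,
)

HH = ["hh.a", "hh.b"]


def zero_rates(n_h=2):
    shape = (n_h, 2, N_AGES)
    return VitalRates(
        sexratio=np.array([0.5, 0.5]),
        asfr=np.zeros(N_AGES),
        mortality=np.zeros(shape),
        migration=np.zeros(shape),
        ptrans=np.zeros(shape),
    )


def test_stasis():
    pop = np.random.default_rng(0).uniform(10, 100, (2, 2, N_AGES))
    state = DemographicState(HH, pop)
    new = project_year(state, zero_rates())
    np.testing.assert_array_equal(new.pop, pop)
    assert new.year == state.year + 1


def test_conveyor_conserves_totals():
    rates = zero_rates()
    rates.ptrans = np.ones((2, 2, N_AGES))
    pop = np.random.default_rng(1).uniform(10, 100, (2, 2, N_AGES))
    state = DemographicState(HH, pop)
    new = project_year(state, rates)
    assert new.total == pytest.approx(state.total, rel=1e-12)
    # every cohort advanced one group; terminal group accumulates
    np.testing.assert_allclose(new.pop[:, :, 1:-1], pop[:, :, :-2], rtol=1e-12)
    np.testing.assert_allclose(new.pop[:, :, -1], pop[:, :, -2] + pop[:, :, -1], rtol=1e-12)
    np.testing.assert_array_equal(new.pop[:, :, 0], 0.0)


def test_three_age_group_hand_example():
    """Two-year hand-computed projection for one household, one gender."""
    rates = zero_rates(n_h=1)
    mu, mig, p, asfr = 0.02, 0.01, 0.25, 0.08
    # populate groups 3..5 (ages 15-29); group 4 is fertile
    rates.mortality[0, :, 3:6] = mu
    rates.migration[0, :, 3:6] = mig
    rates.ptrans[0, :, 3:6] = p
    rates.asfr[4] = asfr
    pop = np.zeros((1, 2, N_AGES))
    pop[0, 1, 3], pop[0, 1, 4], pop[0, 1, 5] = 100.0, 80.0, 60.0
    state = DemographicState(["hh.a"], pop)

    def step(p3, p4, p5):
        s = (1 - mig) * (1 - mu)
        births = 0.5 * asfr * p4  # female share of births
        n3 = (1 - p) * s * p3
        n4 = p * s * p3 + (1 - p) * s * p4
        n5 = p * s * p4 + (1 - p) * s * p5
        n6 = p * s * p5
        n0 = births
        return n0, n3, n4, n5, n6

    f0, f3, f4, f5, f6 = step(100.0, 80.0, 60.0)
    one = project_year(state, rates)
    assert one.pop[0, 1, 0] == pytest.approx(f0, rel=1e-12)
    assert one.pop[0, 1, 3] == pytest.approx(f3, rel=1e-12)
    assert one.pop[0, 1, 4] == pytest.approx(f4, rel=1e-12)
    assert one.pop[0, 1, 5] == pytest.approx(f5, rel=1e-12)
    assert one.pop[0, 1, 6] == pytest.approx(f6, rel=1e-12)

    g0, g3, g4, g5, g6 = step(f3, f4, f5)
    two = project_year(one, rates)
    assert two.pop[0, 1, 3] == pytest.approx(g3, rel=1e-12)
    assert two.pop[0, 1, 4] == pytest.approx(g4, rel=1e-12)
    assert two.pop[0, 1, 5] == pytest.approx(g5, rel=1e-12)
    # group 6 had f6 sitting in it (no rates there), plus inflow from group 5
    assert two.pop[0, 1, 6] == pytest.approx(g6 + f6, rel=1e-12)


def test_population_accounting_identity(bundle):
    """POP(t) = POP(t-1) - deaths - emigration + births, to 1e-9 relative."""
    state = bundle.demog.initial
    rates = bundle.demog.rates_path[0]
    new = project_year(state, rates)
    deaths, migr = vital_events(state, rates)
    births_by_mother = (rates.asfr[FERTILE] * state.pop[:, 1, FERTILE]).sum(axis=1)
    births = births_by_mother.sum()
    expected = state.total - deaths.sum() - migr.sum() + births
    assert new.total == pytest.approx(expected, rel=1e-9)


def test_transition_recovery_from_planted_path(bundle):
    """Targets generated by a forward run recover the planted probabilities."""
    recovered = calibrate_transitions(
        bundle.demog.initial, bundle.demog.targets[:5], bundle.demog.rates_path[:5]
    )
    for p in recovered:  # terminal-group probability is never used for exit
        np.testing.assert_allclose(
            p[:, :, :-1], bundle.demog.planted_ptrans[:, :, :-1], atol=1e-8
        )


def test_transition_recovery_matches_targets(bundle):
    recovered = calibrate_transitions(
        bundle.demog.initial, bundle.demog.targets[:3], bundle.demog.rates_path[:3]
    )
    state = bundle.demog.initial.copy()
    for t, p in enumerate(recovered):
        r = bundle.demog.rates_path[t]
        state = project_year(state, VitalRates(r.sexratio, r.asfr, r.mortality, r.migration, p))
        np.testing.assert_allclose(state.pop, bundle.demog.targets[t], rtol=1e-6)


def test_stationary_targets_zero_rates_give_zero_ptrans():
    pop = np.random.default_rng(2).uniform(10, 100, (2, 2, N_AGES))
    state = DemographicState(HH, pop)
    out = calibrate_transitions(state, [pop.copy(), pop.copy()], [zero_rates(), zero_rates()])
    for p in out:
        np.testing.assert_allclose(p[:, :, :-1], 0.0, atol=1e-10)


def test_infeasible_target_raises():
    pop = np.full((2, 2, N_AGES), 100.0)
    state = DemographicState(HH, pop)
    target = pop.copy()
    target[:, :, 5] = 300.0  # unreachable without negative stay probability
    with pytest.raises(DemographyError):
        calibrate_transitions(state, [target], [zero_rates()])


def test_excess_feedback_null_delta():
    mu = np.random.default_rng(3).uniform(0, 0.05, (2, 2, N_AGES))
    ex = np.random.default_rng(4).uniform(0, 0.001, (2, 2, N_AGES, 2))
    np.testing.assert_array_equal(apply_excess_feedback(mu, ex, ex), mu)


def test_excess_feedback_additivity():
    mu = np.full((1, 2, N_AGES), 0.01)
    ex_c = np.zeros((1, 2, N_AGES, 2))
    ex_p = ex_c.copy()
    ex_p[0, 0, 5, 0] += 0.001
    out = apply_excess_feedback(mu, ex_p, ex_c)
    assert out[0, 0, 5] == pytest.approx(0.011, abs=1e-15)
    assert out[0, 1, 5] == pytest.approx(0.01, abs=1e-15)


def test_excess_feedback_clamps_and_warns(caplog):
    mu = np.full((1, 2, N_AGES), 0.9995)
    ex_p = np.full((1, 2, N_AGES, 2), 0.01)
    ex_c = np.zeros_like(ex_p)
    with caplog.at_level("WARNING", logger="fiscalfood.demography"):
        out = apply_excess_feedback(mu, ex_p, ex_c)
    assert np.all(out <= 1.0)
    assert "clamped" in caplog.text


def test_excess_mortality_definition():
    freq = np.zeros(10)
    freq[2], freq[7] = 0.3, 0.7
    fatal = np.zeros((10, 2, N_AGES, 2))
    fatal[2, 0, 10, 0] = 0.004
    fatal[7, 0, 10, 0] = 0.008
    out = excess_mortality(freq, fatal)
    assert out[0, 10, 0] == pytest.approx(0.3 * 0.004 + 0.7 * 0.008, abs=1e-15)


def test_twin_run_person_years_oracle(bundle):
    """Excess-feedback projection equals an independent run with hand-modified mortality."""
    base = bundle.demog.rates_path[0]
    ex_c = np.zeros((*base.mortality.shape, 2))
    ex_p = ex_c.copy()
    ex_p[:, :, 8:, 0] = 0.0005
    mu_policy = apply_excess_feedback(base.mortality, ex_p, ex_c)
    via_feedback = project_year(
        bundle.demog.initial,
        VitalRates(base.sexratio, base.asfr, mu_policy, base.migration, base.ptrans),
    )
    mu_hand = base.mortality.copy()
    mu_hand[:, :, 8:] += 0.0005
    by_hand = project_year(
        bundle.demog.initial,
        VitalRates(base.sexratio, base.asfr, mu_hand, base.migration, base.ptrans),
    )
    np.testing.assert_allclose(via_feedback.pop, by_hand.pop, rtol=1e-12)
    assert via_feedback.total < bundle.demog.targets[0].sum()
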