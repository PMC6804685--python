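import math

import numpy as np
import pandas as pd
import pytest

from fiscalfood.clinical import (
    AGE_GROUPS,
    GENDERS,
    ILLNESSES,
    LOCATIONS,
    POLY_DEGREE,
    REFERENCE_BIOMARKER,
    ClinicalError,
    ClinicalLookup,
    evaluate_poly,
    generate_lookup,
    household_location,
    levels,
    rates,
)
from fiscalfood.nutrition import BiomarkerDistribution, shift_distribution


def flat_risk_params(rate=0.01, log_rr=0.0):
    rows = [
        {"gender": g, "age": a, "location": l, "illness": i,
         "baseline_rate": rate, "log_rr": log_rr}
        for g in GENDERS for a in AGE_GROUPS for l in LOCATIONS for i in ILLNESSES
    ]
    return pd.DataFrame(rows)


def test_zero_relative_risk_gives_flat_polynomial():
    lookup = generate_lookup(0, flat_risk_params(rate=0.013, log_rr=0.0))
    assert np.all(lookup.coef[..., 0] == 0.013)
    assert np.all(lookup.coef[..., 1:] == 0.0)


def test_generator_matches_logistic_oracle(bundle):
    """Polynomials reproduce the logistic hazard to 1e-6 on a dense grid."""
    lookup = bundle.lookup
    grid = np.linspace(2.0, 7.0, 1001)
    rp = bundle.risk_params.set_index(["gender", "age", "location", "illness"])
    for g_i, g in enumerate(GENDERS):
        for a_i, a in enumerate(AGE_GROUPS[8:12], start=8):
            for l_i, l in enumerate(LOCATIONS):
                for i_i, ill in enumerate(ILLNESSES):
                    b = rp.loc[(g, a, l, ill), "baseline_rate"]
                    lrr = rp.loc[(g, a, l, ill), "log_rr"]
                    if b == 0 or lrr == 0:
                        oracle = np.full_like(grid, b)
                    else:
                        z = math.log(b / (1 - b))
                        oracle = 1.0 / (1.0 + np.exp(-(z + lrr * (grid - REFERENCE_BIOMARKER))))
                    pred = evaluate_poly(lookup.coef[g_i, a_i, l_i, i_i], grid)
                    assert np.max(np.abs(pred - oracle)) <= 1e-6


def test_rates_monotone_in_biomarker(bundle):
    low = evaluate_poly(bundle.lookup.coef, np.array([2.0]))
    high = evaluate_poly(bundle.lookup.coef, np.array([7.0]))
    assert np.all(high >= low - 1e-12)


def test_horner_matches_naive_power_sum():
    rng = np.random.default_rng(3)
    coef = rng.normal(size=(2, 3, POLY_DEGREE + 1)) * 1e-3
    x = rng.uniform(2.0, 7.0, size=5)
    naive = sum(coef[..., r, None] * x[None, None, :] ** r for r in range(POLY_DEGREE + 1))
    got = evaluate_poly(coef, x)
    np.testing.assert_allclose(got, naive, rtol=1e-12)


def constant_lookup(value=0.02):
    shape = (len(GENDERS), len(AGE_GROUPS), len(LOCATIONS), len(ILLNESSES), POLY_DEGREE + 1)
    coef = np.zeros(shape)
    coef[..., 0] = value
    return ClinicalLookup(coef)


def uniform_dist():
    return BiomarkerDistribution(mean=4.4, freq=np.full(10, 0.1))


def test_constant_polynomial_rate_independent_of_biomarker():
    lookup = constant_lookup(0.02)
    r1 = rates(lookup, uniform_dist(), "hh.bangkok")
    r2 = rates(lookup, shift_distribution(uniform_dist(), 1.5), "hh.bangkok")
    np.testing.assert_array_equal(r1, r2)
    assert np.all(r1 == 0.02)


def test_shifted_distribution_weakly_increases_rates(bundle):
    d0 = uniform_dist()
    d1 = shift_distribution(d0, 0.5)
    r0 = rates(bundle.lookup, d0, "hh.north_rural")
    r1 = rates(bundle.lookup, d1, "hh.north_rural")
    assert np.all(r1 >= r0 - 1e-12)


def test_household_location_resolution():
    assert household_location("hh.north_rural") == "rural"
    assert household_location("hh.north_urban") == "urban"
    assert household_location("hh.bangkok") == "urban"


def test_levels_zero_population():
    out = levels(rates(constant_lookup(), uniform_dist(), "hh.bangkok"),
                 uniform_dist(), np.zeros((2, 15)))
    assert np.all(out.levels == 0)


def test_levels_uniform_rate_degenerate_mixture():
    pop = np.full((2, 15), 100.0)
    out = levels(rates(constant_lookup(0.02), uniform_dist(), "hh.bangkok"),
                 uniform_dist(), pop)
    np.testing.assert_allclose(out.levels, 0.02 * 100.0, rtol=1e-12)


def test_levels_two_stratum_hand_mixture():
    shape = (len(GENDERS), len(AGE_GROUPS), len(LOCATIONS), len(ILLNESSES), POLY_DEGREE + 1)
    coef = np.zeros(shape)
    freq = np.zeros(10)
    freq[0], freq[1] = 0.4, 0.6
    dist = BiomarkerDistribution(mean=2.5, freq=freq)
    # linear polynomial: rate = 0.001 * chol at midpoints 2.25 and 2.75
    coef[..., 1] = 0.001
    lookup = ClinicalLookup(coef)
    pop = np.full((2, 15), 50.0)
    out = levels(rates(lookup, dist, "hh.bangkok"), dist, pop)
    expected = (0.4 * 0.001 * 2.25 + 0.6 * 0.001 * 2.75) * 50.0
    np.testing.assert_allclose(out.levels, expected, rtol=1e-12)


def test_levels_linear_in_population_and_frequencies():
    lookup = constant_lookup(0.01)
    d = uniform_dist()
    pop = np.random.default_rng(0).uniform(10, 100, (2, 15))
    base = levels(rates(lookup, d, "hh.bangkok"), d, pop).levels
    double = levels(rates(lookup, d, "hh.bangkok"), d, 2 * pop).levels
    np.testing.assert_allclose(double, 2 * base, rtol=1e-12)


def test_stochastic_dominance_orders_levels(bundle):
    """First-order stochastically dominated biomarker distribution gives lower levels."""
    freq = np.full(10, 0.1)
    low = BiomarkerDistribution(mean=4.0, freq=freq)
    high = shift_distribution(low, 0.8)  # same freq, higher representative values
    pop = np.full((2, 15), 100.0)
    lev_low = levels(rates(bundle.lookup, low, "hh.bangkok"), low, pop).levels
    lev_high = levels(rates(bundle.lookup, high, "hh.bangkok"), high, pop).levels
    assert np.all(lev_high >= lev_low - 1e-12)


def test_generator_rejects_bad_baseline():
    bad = flat_risk_params()
    bad.loc[0, "baseline_rate"] = 1.5
    with pytest.raises(ClinicalError):
        generate_lookup(0, bad)
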