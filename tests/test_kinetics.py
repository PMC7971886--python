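"""Rate-law library: printed-constant examples, saturation identities and
the structural invariants every mechanism must satisfy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acrykin import kinetics
from acrykin.kinetics import (
    MECHANISMS,
    ConcentrationDomainError,
    IncompleteBindingError,
    capacity,
    evaluate,
    saturation_factor,
)

# representative parameter/concentration bindings per mechanism
CASES = {
    "michaelis_menten_1s": ({"Vmax": 1.0, "Km": 2.9}, {"A": 1.3}),
    "mm_2s_multiplicative": ({"Vmax": 2.0, "Km_a": 0.495, "Km_b": 0.037}, {"A": 0.7, "B": 0.11}),
    "mm_3s_multiplicative": (
        {"Kcat": 36.0, "E_total": 100.0, "Km_a": 0.015, "Km_b": 0.01, "Km_c": 0.05},
        {"A": 0.4, "B": 0.2, "C": 1.1},
    ),
    "mm_2s_random_bibi_denominator": (
        {"Vmax": 1.5, "Km_a": 0.0084, "Km_b": 0.0049, "Kd_a": 0.086},
        {"A": 0.3, "B": 2.0},
    ),
    "mm_competitive_product_inhibition_2s": (
        {"Kcat": 16.73, "E_total": 100.0, "Km_a": 0.39, "Km_b": 1.3, "Ki_p": 0.12},
        {"A": 0.5, "B": 1.0, "P": 0.3},
    ),
    "ordered_bibi_product_inhibition": (
        {"Vmax": 0.284, "Km_a": 0.018, "Km_b": 0.06, "Ki_p": 0.07},
        {"A": 0.3, "B": 2.1, "P": 0.05},
    ),
    "rapid_equilibrium_random_bibi_reversible": (
        {"Vmax": 1.0, "Km_a": 0.175, "Km_b": 0.0037, "Km_p": 0.12, "Km_q": 0.165, "Keq": 900.0},
        {"A": 0.4, "B": 0.12, "P": 0.6, "Q": 0.2},
    ),
    "ping_pong_bibi_reversible": (
        {"Vmax": 2.55, "Km_a": 19.07, "Km_b": 0.19, "Km_p": 0.437, "Km_q": 2.94, "Keq": 3.2},
        {"A": 0.8, "B": 0.4, "P": 0.3, "Q": 0.5},
    ),
    "ping_pong_bibi_substrate_inhibition": (
        {"Kcat": 47.4, "E_total": 100.0, "Km_a": 5.8, "Km_b": 1.07, "Ki_b": 10.2},
        {"A": 3.0, "B": 2.0},
    ),
    "hill_2s": ({"Vmax": 1.0, "Km_a": 47.83, "Km_b": 1.385, "n": 0.98}, {"A": 20.0, "B": 1.0}),
    "specific_activation": (
        {"Kcat": 0.0621, "E_total": 100.0, "Km_a": 6.15, "Ka": 0.008},
        {"A": 2.0, "Activator": 1.0},
    ),
    "mass_action": ({"k": 0.7}, {"A": 2.0, "B": 3.0}),
}

IRREVERSIBLE_SATURATING = [
    m for m, law in MECHANISMS.items() if not law.reversible and m != "mass_action"
]


def test_half_saturation_identity():
    # single-substrate MM at A = Km gives exactly half of Vmax
    assert evaluate("michaelis_menten_1s", {"Vmax": 1.0, "Km": 2.9}, {"A": 2.9}) == pytest.approx(0.5)


def test_reversible_law_vanishes_at_equilibrium():
    p = CASES["rapid_equilibrium_random_bibi_reversible"][0]
    conc = {"A": 0.5, "B": 0.4, "P": 9.0, "Q": 0.5 * 0.4 * 900.0 / 9.0}
    assert evaluate("rapid_equilibrium_random_bibi_reversible", p, conc) == pytest.approx(0.0, abs=1e-14)
    p2 = CASES["ping_pong_bibi_reversible"][0]
    conc2 = {"A": 1.0, "B": 2.0, "P": 4.0, "Q": 1.0 * 2.0 * 3.2 / 4.0}
    assert evaluate("ping_pong_bibi_reversible", p2, conc2) == pytest.approx(0.0, abs=1e-14)


def test_mass_action_definition():
    assert evaluate("mass_action", {"k": 1.0}, {"A": 2.0, "B": 3.0}) == pytest.approx(6.0)
    # a feed reaction binds no substrate and runs at constant rate k
    assert evaluate("mass_action", {"k": 0.25}, {}) == pytest.approx(0.25)


def test_ping_pong_substrate_inhibition_matches_symbolic_substitution():
    # independent oracle: direct sympy substitution into the canonical
    # closed form of the substrate-inhibited ping-pong mechanism
    import sympy

    A, B, Kma, Kmb, Kib, E, kcat = sympy.symbols("A B Kma Kmb Kib E kcat", positive=True)
    expr = E * kcat * A * B / (Kmb * A + Kma * B * (1 + B / Kib) + A * B)
    expected = float(
        expr.subs({A: 5.8, B: 1.07, Kma: 5.8, Kmb: 1.07, Kib: 10.2, E: 100.0, kcat: 47.4})
    )
    got = evaluate(
        "ping_pong_bibi_substrate_inhibition",
        {"Kcat": 47.4, "E_total": 100.0, "Km_a": 5.8, "Km_b": 1.07, "Ki_b": 10.2},
        {"A": 5.8, "B": 1.07},
    )
    assert got == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("mechanism", sorted(CASES))
def test_rate_is_capacity_times_saturation(mechanism):
    params, conc = CASES[mechanism]
    rate = evaluate(mechanism, params, conc)
    assert rate == pytest.approx(capacity(params) * saturation_factor(mechanism, params, conc))
    assert math.isfinite(rate)


@pytest.mark.parametrize("mechanism", sorted(CASES))
def test_homogeneous_degree_one_in_capacity(mechanism):
    params, conc = CASES[mechanism]
    doubled = dict(params)
    for slot in ("Vmax", "Kcat", "k"):
        if slot in doubled:
            doubled[slot] *= 2.0
            break
    assert evaluate(mechanism, doubled, conc) == pytest.approx(
        2.0 * evaluate(mechanism, params, conc), rel=1e-12
    )


@pytest.mark.parametrize("mechanism", IRREVERSIBLE_SATURATING)
def test_saturation_factor_bounded_and_limits(mechanism):
    params, conc = CASES[mechanism]
    f = saturation_factor(mechanism, params, conc)
    assert 0.0 <= f <= 1.0
    if mechanism != "ping_pong_bibi_substrate_inhibition":
        # all substrates saturating -> F -> 1 (the substrate-inhibited law is
        # the documented exception: its joint limit is 1/(1 + Km_a/Ki_b))
        high = {role: 1e9 for role in conc}
        for role in ("P",):
            if role in high:
                high[role] = 0.0  # products off for the inhibited laws
        assert saturation_factor(mechanism, params, high) == pytest.approx(1.0, abs=1e-6)
    # zero substrate -> zero rate
    zero = dict(conc)
    zero["A"] = 0.0
    assert evaluate(mechanism, params, zero) == pytest.approx(0.0, abs=1e-15)


@pytest.mark.parametrize("mechanism", IRREVERSIBLE_SATURATING)
def test_monotone_in_first_substrate(mechanism):
    params, conc = CASES[mechanism]
    grid = np.linspace(0.0, 20.0, 60)
    rates = [evaluate(mechanism, params, {**conc, "A": a}) for a in grid]
    assert all(r2 >= r1 - 1e-12 for r1, r2 in zip(rates, rates[1:]))


def test_substrate_inhibition_has_interior_optimum_in_b():
    params, _ = CASES["ping_pong_bibi_substrate_inhibition"]
    grid = np.linspace(1e-3, 200.0, 400)
    rates = [evaluate("ping_pong_bibi_substrate_inhibition", params, {"A": 3.0, "B": b}) for b in grid]
    peak = int(np.argmax(rates))
    assert 0 < peak < len(grid) - 1
    assert rates[peak] > rates[-1]  # decreasing branch beyond the optimum


@given(
    a=st.floats(0.01, 50.0),
    b=st.floats(0.01, 50.0),
    kma=st.floats(0.05, 20.0),
    kmb=st.floats(0.05, 20.0),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_hill_reduces_to_multiplicative_mm_at_n_one(a, b, kma, kmb):
    hill = evaluate("hill_2s", {"Vmax": 1.0, "Km_a": kma, "Km_b": kmb, "n": 1.0}, {"A": a, "B": b})
    mm = evaluate("mm_2s_multiplicative", {"Vmax": 1.0, "Km_a": kma, "Km_b": kmb}, {"A": a, "B": b})
    assert hill == pytest.approx(mm, rel=1e-12)


def test_reversible_sign_tracks_equilibrium_side():
    p = CASES["rapid_equilibrium_random_bibi_reversible"][0]
    forward = evaluate("rapid_equilibrium_random_bibi_reversible", p, {"A": 1, "B": 1, "P": 0.1, "Q": 0.1})
    backward = evaluate(
        "rapid_equilibrium_random_bibi_reversible", p, {"A": 1e-4, "B": 1e-4, "P": 50.0, "Q": 50.0}
    )
    assert forward > 0 > backward


def test_missing_parameter_and_role_errors_name_the_slot():
    with pytest.raises(IncompleteBindingError, match="Km"):
        evaluate("michaelis_menten_1s", {"Vmax": 1.0}, {"A": 1.0})
    with pytest.raises(IncompleteBindingError, match="role 'A'"):
        evaluate("michaelis_menten_1s", {"Vmax": 1.0, "Km": 1.0}, {})
    with pytest.raises(IncompleteBindingError):
        capacity({"Km": 1.0})


def test_negative_concentration_is_a_domain_error():
    with pytest.raises(ConcentrationDomainError):
        evaluate("michaelis_menten_1s", {"Vmax": 1.0, "Km": 1.0}, {"A": -0.1})


def test_invalid_parameters_rejected():
    with pytest.raises(kinetics.RateLawError):
        evaluate("michaelis_menten_1s", {"Vmax": 1.0, "Km": -2.0}, {"A": 1.0})
    with pytest.raises(kinetics.RateLawError):
        evaluate("hill_2s", {"Vmax": 1.0, "Km_a": 1.0, "Km_b": 1.0, "n": 0.0}, {"A": 1.0, "B": 1.0})


@pytest.mark.parametrize("mechanism", sorted(CASES))
def test_denominators_strictly_positive_at_zero_concentrations(mechanism):
    # the canonical forms need no epsilon guards: rate at the origin is 0,
    # never a division error
    params, conc = CASES[mechanism]
    zero = {role: 0.0 for role in conc}
    rate = evaluate(mechanism, params, zero)
    assert rate == pytest.approx(0.0, abs=1e-15) or mechanism == "mass_action"
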