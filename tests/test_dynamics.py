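"""Simulation, steady states and control analysis against analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import lambertw

from acrykin.chassis import make_continuous
from acrykin.dynamics import (
    NoSteadyStateError,
    UnstableSteadyStateError,
    elasticities,
    find_steady_state,
    flux_control_coefficients,
    link_matrix,
    simulate,
)
from acrykin.network import KineticModel, Reaction, Species, assemble_odes, carbon_total


def test_mm_drain_matches_lambert_w_solution():
    """Integrated single Michaelis-Menten drain has the implicit closed form
    Km ln(A0/A) + (A0 - A) = Vmax t, i.e. A(t) = Km W((A0/Km) e^{(A0 - Vmax t)/Km})."""
    Vmax, Km, A0 = 0.05, 0.8, 5.0
    m = KineticModel()
    m.species = [Species("A", initial_concentration=A0)]
    m.add_reaction(
        Reaction("drain", {"A": -1}, "michaelis_menten_1s", {"A": "A"}, {"Vmax": Vmax, "Km": Km})
    )
    traj = simulate(m, duration=120.0, reltol=1e-10, abstol=1e-12, n_points=41)
    analytic = Km * np.real(
        lambertw((A0 / Km) * np.exp((A0 - Vmax * traj.time) / Km))
    )
    assert np.max(np.abs(traj.conc["A"].to_numpy() - analytic)) < 1e-6


def test_simulation_with_lsoda_agrees_with_bdf(glu_mcoa_aa):
    bdf = simulate(glu_mcoa_aa, duration=1800.0, n_points=5)
    lsoda = simulate(glu_mcoa_aa, duration=1800.0, n_points=5, method="LSODA",
                     reltol=1e-8, abstol=1e-10)
    final_b, final_l = bdf.conc.iloc[-1], lsoda.conc.iloc[-1]
    assert float((final_b - final_l).abs().max()) < 1e-4


def test_simulation_invariant_under_tolerance_halving(glu_mcoa_aa):
    t1 = simulate(glu_mcoa_aa, duration=3600.0, reltol=1e-8, abstol=1e-10, n_points=5)
    t2 = simulate(glu_mcoa_aa, duration=3600.0, reltol=5e-9, abstol=5e-11, n_points=5)
    a, b = t1.conc.iloc[-1], t2.conc.iloc[-1]
    scale = np.maximum(np.abs(a.to_numpy()), 1.0)
    assert float(np.max(np.abs(a.to_numpy() - b.to_numpy()) / scale)) < 1e-6


def test_batch_variant_conserves_carbon(glu_gly_aa):
    """The batch variant is closed for carbon (CO2, bicarbonate and the
    biomass proxy are all counted), so total carbon drifts < 1e-6 relative."""
    traj = simulate(glu_gly_aa, duration=10800.0, n_points=25)
    model = glu_gly_aa
    totals = []
    for _, row in traj.conc.iterrows():
        conc = {s.id: s.initial_concentration for s in model.species}
        conc.update({k: max(v, 0.0) for k, v in row.items()})
        totals.append(carbon_total(model, conc))
    totals = np.array(totals)
    assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-6


def test_linear_chain_steady_state_matches_closed_form():
    # feed (k0) -> A -(k1)-> B -(k2)-> out: A* = k0/k1, B* = k0/k2
    k0, k1, k2 = 0.3, 0.05, 0.2
    m = KineticModel()
    m.species = [Species("A", initial_concentration=0.1), Species("B", initial_concentration=0.1)]
    m.add_reaction(Reaction("feed", {"A": 1}, "mass_action", {}, {"k": k0}))
    m.add_reaction(Reaction("r1", {"A": -1, "B": 1}, "mass_action", {"A": "A"}, {"k": k1}))
    m.add_reaction(Reaction("r2", {"B": -1}, "mass_action", {"A": "B"}, {"k": k2}))
    ss = find_steady_state(m)
    assert ss.conc["A"] == pytest.approx(k0 / k1, rel=1e-8)
    assert ss.conc["B"] == pytest.approx(k0 / k2, rel=1e-8)
    assert ss.stable and ss.residual < 1e-10


def test_batch_model_reports_no_steady_state():
    # pure decay A -> B never balances the non-zero flux until A is exhausted;
    # the carbon-exhausted end state (flux ~ 0) is the admissible answer
    m = KineticModel()
    m.species = [Species("A", initial_concentration=1.0), Species("B")]
    m.add_reaction(Reaction("r", {"A": -1, "B": 1}, "mass_action", {"A": "A"}, {"k": 1e-3}))
    ss = find_steady_state(m)
    assert ss.conc["A"] == pytest.approx(0.0, abs=1e-6)


def test_mini_chassis_steady_state_residual(chassis_steady_state):
    cont, ss = chassis_steady_state
    assert ss.residual < 1e-10
    assert ss.stable


def test_link_matrix_recovers_conserved_moieties(chassis_steady_state):
    cont, ss = chassis_steady_state
    N, sids, rids = cont.stoichiometric_matrix()
    indep, L = link_matrix(N)
    assert N == pytest.approx(L @ N[indep, :], abs=1e-9)
    n_conserved = len(sids) - len(indep)
    # NAD/NADH, NADP/NADPH, adenylates, CoA pool at minimum
    assert n_conserved >= 4


def test_elasticity_of_isolated_mm_step():
    # scaled elasticity of an MM drain: eps = Km/(Km+S) exactly
    Km, S0 = 0.8, 1.7
    m = KineticModel()
    m.species = [Species("S", initial_concentration=S0), Species("P")]
    m.add_reaction(Reaction("feed", {"S": 1}, "mass_action", {}, {"k": 0.05}))
    m.add_reaction(
        Reaction("v", {"S": -1, "P": 1}, "michaelis_menten_1s", {"A": "S"}, {"Vmax": 0.1, "Km": Km})
    )
    m.add_reaction(Reaction("out", {"P": -1}, "mass_action", {"A": "P"}, {"k": 1.0}))
    ss = find_steady_state(m)
    eps = elasticities(m, ss)
    assert eps.loc["v", "S"] == pytest.approx(Km / (Km + ss.conc["S"]), rel=1e-4)


def _two_enzyme_chain():
    """X0 =(E1, product-inhibited)=> S =(E2, MM)=> P, X0 and P clamped."""
    m = KineticModel()
    m.species = [
        Species("X0", initial_concentration=2.0, is_fixed=True),
        Species("W", initial_concentration=1.0, is_fixed=True),
        Species("S", initial_concentration=0.5),
        Species("P", initial_concentration=0.0, is_fixed=True),
    ]
    m.add_reaction(
        Reaction(
            "E1", {"X0": -1, "S": 1}, "mm_competitive_product_inhibition_2s",
            {"A": "X0", "B": "W", "P": "S"},
            {"Vmax": 0.1, "Km_a": 1.0, "Km_b": 0.5, "Ki_p": 0.4},
        )
    )
    m.add_reaction(
        Reaction("E2", {"S": -1, "P": 1}, "michaelis_menten_1s", {"A": "S"},
                 {"Vmax": 0.2, "Km": 1.5})
    )
    return m


def test_two_enzyme_chain_fccs_match_textbook_form():
    """C1 = eps2/(eps2 - eps1), C2 = -eps1/(eps2 - eps1), with the scaled
    elasticities evaluated analytically at the steady state."""
    m = _two_enzyme_chain()
    ss = find_steady_state(m)
    S = ss.conc["S"]
    Km_a, Ki, Km2 = 1.0, 0.4, 1.5
    X0 = 2.0
    # analytic scaled elasticities w.r.t. S
    den = Km_a * (1 + S / Ki) + X0
    eps1 = -(Km_a * S / Ki) / den
    eps2 = Km2 / (Km2 + S)
    c1 = eps2 / (eps2 - eps1)
    c2 = -eps1 / (eps2 - eps1)
    fcc = flux_control_coefficients(m, ss, "E2")
    for method in ("structural", "fd"):
        coeffs = fcc.coefficients(method)
        assert coeffs["E1"] == pytest.approx(c1, rel=2e-3)
        assert coeffs["E2"] == pytest.approx(c2, rel=2e-3)
    assert fcc.summation("structural") == pytest.approx(1.0, abs=1e-9)


def test_single_reaction_pathway_has_unit_control():
    m = KineticModel()
    m.species = [
        Species("X", initial_concentration=1.0, is_fixed=True),
        Species("S", initial_concentration=0.5),
        Species("Y", initial_concentration=0.0, is_fixed=True),
    ]
    m.add_reaction(
        Reaction("in_", {"X": -1, "S": 1}, "michaelis_menten_1s", {"A": "X"},
                 {"Vmax": 0.1, "Km": 1.0})
    )
    m.add_reaction(Reaction("out", {"S": -1, "Y": 1}, "mass_action", {"A": "S"}, {"k": 0.3}))
    ss = find_steady_state(m)
    fcc = flux_control_coefficients(m, ss, "out")
    assert fcc.summation("structural") == pytest.approx(1.0, abs=1e-9)
    # the clamped-substrate feed has all the control; the linear drain none
    assert fcc.coefficients()["in_"] == pytest.approx(1.0, abs=1e-6)


def test_mca_summation_theorem_on_chassis(chassis_steady_state):
    from acrykin.chassis import REFERENCE_FCC_TARGET

    cont, ss = chassis_steady_state
    fcc = flux_control_coefficients(cont, ss, REFERENCE_FCC_TARGET)
    assert abs(fcc.summation("structural") - 1.0) < 1e-3
    assert abs(fcc.summation("fd") - 1.0) < 1e-3


def test_structural_and_fd_fccs_agree_on_chassis(chassis_steady_state):
    from acrykin.chassis import REFERENCE_FCC_TARGET

    cont, ss = chassis_steady_state
    fcc = flux_control_coefficients(cont, ss, REFERENCE_FCC_TARGET)
    big = fcc.table[fcc.table.fcc_structural.abs() > 0.01].dropna()
    rel = ((big.fcc_structural - big.fcc_fd).abs() / big.fcc_structural.abs()).max()
    assert rel < 0.01


def test_unstable_steady_state_is_refused():
    fcc_input = pd.DataFrame({"reaction": ["r"], "fcc_structural": [1.0], "fcc_fd": [1.0]})
    from acrykin.dynamics import SteadyState

    fake = SteadyState(conc={"A": 1.0}, fluxes={"r": 0.1}, residual=0.0,
                       stable=False, max_eig_real=0.5, free_ids=["A"])
    m = KineticModel()
    m.species = [Species("A", initial_concentration=1.0)]
    m.add_reaction(Reaction("r", {"A": -1}, "mass_action", {"A": "A"}, {"k": 0.1}))
    with pytest.raises(UnstableSteadyStateError):
        flux_control_coefficients(m, fake, "r")
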