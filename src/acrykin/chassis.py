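"""Synthetic central-carbon chassis and its stoichiometric twin.

A deliberately small (~15 reaction) kinetic model of glucose/glycerol
catabolism — lumped glycolysis, a two-step TCA loop, anaplerosis, oxidative
phosphorylation, transhydrogenation and adenylate recycling — exposing
every species the pathway extension attaches to.  Kinetics are kept to
irreversible Michaelis-Menten and mass action so that closed-loop test
oracles stay tractable; cofactor pairs (NAD/NADH, NADP/NADPH, adenylates,
the CoA thioester pool) are conserved moieties, which exercises the
link-matrix reduction in control analysis.  CO2 and bicarbonate are free
carbon-bearing species and the synth drains deposit carbon into a biomass
proxy, so a batch variant is carbon-closed end to end.

The stoichiometric twin is derived directly from the kinetic reactions, so
the kinetic steady-state flux lies inside its feasible cone by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import KineticModel, Reaction, Species

__all__ = ["ChassisSpec", "make_chassis", "make_continuous", "reference_results"]


@dataclass(frozen=True)
class ChassisSpec:
    carbon_source: str = "glucose"  # glucose | glycerol | both
    seed: int | None = None  # parameter jitter; None = canonical chassis
    jitter_sigma: float = 0.1  # lognormal sigma applied to chassis capacities
    glucose_uptake_vmax: float = 0.015  # mM/s
    glycerol_uptake_vmax: float = 0.012  # mM/s

    def __post_init__(self):
        if self.carbon_source not in ("glucose", "glycerol", "both"):
            raise ValueError(f"unknown carbon source {self.carbon_source!r}")


def _species() -> list[Species]:
    mk = Species
    return [
        mk("GLCx", "extracellular glucose", "extracellular", 55.5, False, 6),
        mk("GLYx", "extracellular glycerol", "extracellular", 0.0, False, 3),
        mk("G6P", "hexose phosphate pool", "cytosol", 0.5, False, 6),
        mk("DAP", "dihydroxyacetone phosphate", "cytosol", 0.5, False, 3),
        mk("PEP", "phosphoenolpyruvate", "cytosol", 0.5, False, 3),
        mk("PYR", "pyruvate", "cytosol", 0.5, False, 3),
        mk("ACCOA", "acetyl-CoA", "cytosol", 0.3, False, 2),
        mk("OAA", "oxaloacetate", "cytosol", 0.1, False, 4),
        mk("AKG", "2-oxoglutarate", "cytosol", 0.3, False, 5),
        mk("CO2", "dissolved CO2", "cytosol", 0.1, False, 1),
        mk("HCO3", "bicarbonate", "cytosol", 5.0, False, 1),
        mk("COA", "coenzyme A", "cytosol", 0.5, False, 0),
        mk("NAD", "NAD+", "cytosol", 1.5, False, 0),
        mk("NADH", "NADH", "cytosol", 0.1, False, 0),
        mk("NADP", "NADP+", "cytosol", 0.05, False, 0),
        mk("NADPH", "NADPH", "cytosol", 0.15, False, 0),
        mk("ATP", "ATP", "cytosol", 2.5, False, 0),
        mk("ADP", "ADP", "cytosol", 0.6, False, 0),
        mk("AMP", "AMP", "cytosol", 0.3, False, 0),
        mk("PI", "inorganic phosphate (buffered)", "cytosol", 10.0, True, 0),
        mk("NH4", "ammonium (buffered)", "cytosol", 10.0, True, 0),
        mk("BIOM", "biomass carbon proxy", "cytosol", 0.0, False, 1),
    ]


def _mm2(rid, stoich, a, ka, b, kb, vmax):
    return Reaction(rid, stoich, "mm_2s_multiplicative",
                    {"A": a, "B": b}, {"Km_a": ka, "Km_b": kb, "Vmax": vmax})


def _mm1(rid, stoich, a, km, vmax):
    return Reaction(rid, stoich, "michaelis_menten_1s", {"A": a}, {"Km": km, "Vmax": vmax})


def _mm3(rid, stoich, a, ka, b, kb, c, kc, vmax):
    return Reaction(rid, stoich, "mm_3s_multiplicative", {"A": a, "B": b, "C": c},
                    {"Km_a": ka, "Km_b": kb, "Km_c": kc, "Vmax": vmax})


def _ma(rid, stoich, roles, k):
    return Reaction(rid, stoich, "mass_action", roles, {"k": k})


def _reactions(spec: ChassisSpec) -> list[Reaction]:
    rxns = []
    if spec.carbon_source in ("glucose", "both"):
        rxns.append(
            _mm2("PTS", {"GLCx": -1, "PEP": -1, "G6P": 1, "PYR": 1},
                 "GLCx", 0.05, "PEP", 0.3, spec.glucose_uptake_vmax)
        )
    if spec.carbon_source in ("glycerol", "both"):
        rxns.append(
            _mm1("GLYT", {"GLYx": -1, "GLY": 1}, "GLYx", 1.0, spec.glycerol_uptake_vmax)
        )
    rxns += [
        _mm2("PFK", {"G6P": -1, "ATP": -1, "DAP": 2, "ADP": 1},
             "G6P", 0.1, "ATP", 0.2, 0.05),
        _mm3("GAPDH", {"DAP": -1, "NAD": -1, "ADP": -1, "PEP": 1, "NADH": 1, "ATP": 1},
             "DAP", 0.2, "NAD", 0.3, "ADP", 0.05, 0.1),
        # PYK capacity kept below the PTS's so a positive PEP level survives
        # (the PTS needs PEP; a faster PYK deadlocks glucose uptake)
        _mm2("PYK", {"PEP": -1, "ADP": -1, "PYR": 1, "ATP": 1},
             "PEP", 0.6, "ADP", 0.3, 0.012),
        _mm3("PDH", {"PYR": -1, "NAD": -1, "COA": -1, "ACCOA": 1, "NADH": 1, "CO2": 1},
             "PYR", 0.5, "NAD", 0.3, "COA", 0.05, 0.05),
        # pyruvate overflow (acetate-excretion proxy): soaks surplus pyruvate
        # when PDH is CoA-throttled, so a continuous steady state exists
        _mm1("POX", {"PYR": -1, "BIOM": 3}, "PYR", 2.0, 0.02),
        _mm3("CS", {"ACCOA": -1, "OAA": -1, "NAD": -1, "AKG": 1, "COA": 1, "NADH": 1, "CO2": 1},
             "ACCOA", 0.1, "OAA", 0.1, "NAD", 0.1, 0.05),
        _mm3("AKGDH", {"AKG": -1, "NAD": -1, "ADP": -1, "OAA": 1, "NADH": 1, "ATP": 1, "CO2": 1},
             "AKG", 0.3, "NAD", 0.3, "ADP", 0.05, 0.05),
        _mm2("PPC", {"PEP": -1, "HCO3": -1, "OAA": 1, "PI": 1},
             "PEP", 0.4, "HCO3", 1.0, 0.01),
        # lumped anabolic drains: keep OAA and acetyl-CoA balanced under
        # continuous feed (aspartate-family and lipid biosynthesis proxies)
        _mm2("ANA_OAA", {"OAA": -1, "ATP": -1, "BIOM": 4, "ADP": 1},
             "OAA", 0.5, "ATP", 0.05, 0.01),
        _mm2("ANA_ACCOA", {"ACCOA": -1, "ATP": -1, "BIOM": 2, "ADP": 1, "COA": 1},
             "ACCOA", 0.3, "ATP", 0.05, 0.005),
        _mm2("OXPHOS", {"NADH": -1, "ADP": -2, "NAD": 1, "ATP": 2},
             "NADH", 0.1, "ADP", 0.3, 0.4),
        _mm1("ATPASE", {"ATP": -1, "ADP": 1, "PI": 1}, "ATP", 0.5, 0.1),
        _ma("ADK", {"AMP": -1, "ATP": -1, "ADP": 2}, {"A": "AMP", "B": "ATP"}, 0.1),
        _ma("THD_f", {"NADH": -1, "NADP": -1, "NAD": 1, "NADPH": 1},
            {"A": "NADH", "B": "NADP"}, 5.0),
        _ma("THD_r", {"NADPH": -1, "NAD": -1, "NADP": 1, "NADH": 1},
            {"A": "NADPH", "B": "NAD"}, 0.05),
        _ma("CDH_f", {"CO2": -1, "HCO3": 1}, {"A": "CO2"}, 0.01),
        _ma("CDH_r", {"HCO3": -1, "CO2": 1}, {"A": "HCO3"}, 0.02),
    ]
    return rxns


#: chassis reactions whose capacity is jittered (uptake excluded so the
#: carbon budget of a jittered instance stays comparable)
_JITTERABLE = ("PFK", "GAPDH", "PYK", "PDH", "CS", "AKGDH", "PPC", "OXPHOS", "ATPASE", "ANA_OAA", "ANA_ACCOA")


def make_chassis(spec: ChassisSpec = ChassisSpec()):
    """Build (KineticModel, StoichModel twin) for the requested carbon source."""
    from .estimation import StoichModel  # local import to avoid a cycle

    model = KineticModel(species=_species(), reactions=[])
    if spec.carbon_source in ("glycerol", "both"):
        model.add_species(Species("GLY", "glycerol", "cytosol", 1e-3, False, 3))
        model.get_species("GLYx").initial_concentration = 217.2
        if spec.carbon_source == "glycerol":
            model.get_species("GLCx").initial_concentration = 0.0
    for rxn in _reactions(spec):
        model.add_reaction(rxn)
    if spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        for rxn in model.reactions:
            if rxn.id in _JITTERABLE:
                factor = float(np.exp(rng.normal(0.0, spec.jitter_sigma)))
                slot = "Vmax" if "Vmax" in rxn.params else "k"
                rxn.params[slot] = rxn.params[slot] * factor
    model.annotations["chassis"] = f"synthetic-{spec.carbon_source}"
    if spec.seed is not None:
        model.annotations["jitter_seed"] = str(spec.seed)
    twin = StoichModel.from_kinetic(model)
    return model, twin


def make_continuous(
    model: KineticModel,
    *,
    feed_rate: float | None = None,
    drain_k: float = 0.01,
) -> KineticModel:
    """Continuous (feed + drain) variant used to find a valid steady state.

    A constant-rate feed replaces the batch bolus of the carbon source, the
    route intermediates glycerol / malonyl-CoA / beta-alanine and the end
    product get first-order drains, and accumulating sinks (extracellular
    product, CO2, biomass proxy) are clamped so the remaining network can
    equilibrate.  Feed default: 30% of the uptake capacity.
    """
    cont = model.copy()
    if model.has_reaction("PTS"):
        carbon, uptake_vmax = "GLCx", model.get_reaction("PTS").params["Vmax"]
    elif model.has_reaction("GLYT"):
        carbon, uptake_vmax = "GLYx", model.get_reaction("GLYT").params["Vmax"]
    else:
        raise ValueError("model has no carbon uptake reaction")
    rate = feed_rate if feed_rate is not None else 0.3 * uptake_vmax
    cont.add_reaction(
        Reaction(f"feed_{carbon}", {carbon: 1}, "mass_action", {}, {"k": rate})
    )
    cont.get_species(carbon).initial_concentration = max(
        0.5, 0.02 * cont.get_species(carbon).initial_concentration
    )
    # dissolved CO2 is vented so decarboxylation does not pile up carbon
    if cont.has_species("CO2"):
        cont.add_reaction(
            Reaction("vent_CO2", {"CO2": -1}, "mass_action", {"A": "CO2"}, {"k": 0.01})
        )
    for met in ("GLY", "MCOA", "BA", "AA"):
        if cont.has_species(met):
            stoich = {met: -1}
            if met == "MCOA":
                stoich["COA"] = 1  # the drained thioester returns its CoA moiety
            cont.add_reaction(
                Reaction(f"drain_{met}", stoich, "mass_action", {"A": met}, {"k": drain_k})
            )
    for sink in ("HPx", "AAx", "CO2", "BIOM", "HP"):
        if cont.has_species(sink) and not any(
            coeff < 0
            for rxn in cont.reactions
            for sid, coeff in rxn.stoichiometry.items()
            if sid == sink
        ):
            cont.get_species(sink).is_fixed = True
    cont.annotations["mode"] = "continuous"
    return cont


#: flux whose control distribution is frozen in the reference fixture
REFERENCE_FCC_TARGET = "ANA_OAA"


def reference_results(spec: ChassisSpec = ChassisSpec()):
    """Steady state and control coefficients of the default continuous chassis.

    Recomputed from scratch (steady state by integration + Newton polish,
    FCCs by the brute-force finite-difference route); the shipped fixture
    under ``data/reference`` must match to the stated tolerances — a
    regression guard on the generator itself.
    """
    from . import dynamics

    model, _ = make_chassis(spec)
    cont = make_continuous(model)
    ss = dynamics.find_steady_state(cont)
    fcc = dynamics.flux_control_coefficients(cont, ss, REFERENCE_FCC_TARGET)
    return cont, ss, fcc


def load_reference_fixture():
    """The frozen (conc, flux, fcc) tables for the default glucose chassis."""
    from importlib import resources

    import pandas as pd

    base = resources.files("acrykin.data").joinpath("reference")
    with base.joinpath("chassis_glucose_conc.csv").open() as fh:
        conc = pd.read_csv(fh, index_col=0)["mM"]
    with base.joinpath("chassis_glucose_flux.csv").open() as fh:
        flux = pd.read_csv(fh, index_col=0)["mM_per_s"]
    with base.joinpath("chassis_glucose_fcc.csv").open() as fh:
        fcc = pd.read_csv(fh)
    return conc, flux, fcc


def regenerate_reference_fixtures(outdir) -> None:
    """Recompute and overwrite the shipped reference fixture CSVs."""
    from pathlib import Path

    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _, ss, fcc = reference_results()
    pd.Series(ss.conc, name="mM").to_csv(out / "chassis_glucose_conc.csv")
    pd.Series(ss.fluxes, name="mM_per_s").to_csv(out / "chassis_glucose_flux.csv")
    fcc.table.to_csv(out / "chassis_glucose_fcc.csv", index=False)
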