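"""The pathway extension: native reactions, heterologous routes, variants.

Nine native reactions (G3pD, G3pP, GlyK, GlyD, DhaPT, AccC, GluD, AspAT,
AspC) extend the central-carbon chassis with glycerol, malonyl-CoA and
beta-alanine production.  Three heterologous routes then convert those
intermediates to 3-hydroxypropionate (3-HP), and a shared phase-2 trio
(hpcoaS, hpcoaDH, AcoaTioE) converts 3-HP to acrylic acid (AA).  Crossing
{glucose, glycerol} x {glycerol, malonyl_coa, beta_alanine} x {3-HP, AA}
gives the twelve variant models.

Kinetic constants are shipped as versioned CSV fixtures (one row per
parameter) and loaded at import; heterologous capacities are Kcat x E_total
with E_total = 100 mM by default (deliberately in surplus so the route
itself is never the artificial bottleneck), overridable for sensitivity
runs.  Native capacities use Vmax values that the FVA-based estimator can
recompute; package defaults are documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .network import AssemblyError, KineticModel, Reaction, Species

__all__ = [
    "PATHWAYS",
    "VariantSpec",
    "all_variants",
    "native_extension_reactions",
    "heterologous_reactions",
    "phase2_reactions",
    "synth_reactions",
    "synth_constants",
    "build_variant",
    "parameter_table",
    "NATIVE_VMAX_DEFAULTS",
    "DEFAULT_DHAPT_K",
    "DEFAULT_E_TOTAL",
    "SYNTH_TARGETS",
    "ATTACHMENT_SPECIES",
]

log = logging.getLogger(__name__)

PATHWAYS = ("glycerol", "malonyl_coa", "beta_alanine")
END_PRODUCTS = ("3-HP", "AA")
CARBON_SOURCES = ("glucose", "glycerol")

#: chassis species every variant attaches to
ATTACHMENT_SPECIES = (
    "DAP", "PEP", "PYR", "ACCOA", "OAA", "AKG", "COA",
    "NAD", "NADH", "NADP", "NADPH", "ATP", "ADP", "AMP",
    "PI", "NH4", "HCO3", "CO2",
)

#: metabolites given a first-order synth drain (unmodelled consumption),
#: routed into a one-carbon biomass proxy so carbon stays closed.
SYNTH_TARGETS = ("DAP", "ACCOA", "MCOA", "LGLU", "ASP", "BA")

DEFAULT_E_TOTAL = 100.0  # mM, enzyme in surplus for all heterologous laws
DEFAULT_DHAPT_K = 0.05  # mM^-1 s^-1; explicit configuration, no printed source
DEFAULT_SYNTH_K = 0.002  # s^-1 fallback before synth_constants is run
DEFAULT_EXPORT_K = 0.1  # s^-1 first-order export of 3-HP / AA (stand-in)
DEFAULT_B12 = 1.0  # mM, saturating vs Ka = 0.008 mM

#: native Vmax in mM/s.  G3pD, AccC and AspAT are the pre-overexpression
#: values implied by the reported mutant edits (1.392/45, 0.568/2,
#: 127.4869/50); AspC is the Kcat*E estimate (57); the rest are package
#: defaults recomputable by the FVA-based estimator.
NATIVE_VMAX_DEFAULTS = {
    "G3pD": 0.0309,
    "G3pP": 0.05,
    "GlyK": 0.02,
    "GlyD": 10.0,
    "AccC": 0.284,
    "GluD": 0.02,
    "AspAT": 2.549738,
    "AspC": 57.0,
}

# species introduced by the extension / heterologous routes
_NEW_SPECIES = {
    # id: (name, carbon, compartment, fixed, default initial mM)
    "G3P": ("glycerol 3-phosphate", 3, "cytosol", False, 1e-3),
    "GLY": ("glycerol", 3, "cytosol", False, 1e-3),
    "DHA": ("dihydroxyacetone", 3, "cytosol", False, 1e-3),
    "MCOA": ("malonyl-CoA", 3, "cytosol", False, 1e-3),
    "LGLU": ("L-glutamate", 5, "cytosol", False, 1e-3),
    "ASP": ("L-aspartate", 4, "cytosol", False, 1e-3),
    "BA": ("beta-alanine", 3, "cytosol", False, 1e-3),
    "MSA": ("malonic semialdehyde", 3, "cytosol", False, 1e-3),
    "HPA": ("3-hydroxypropionaldehyde", 3, "cytosol", False, 1e-3),
    "HP": ("3-hydroxypropionate", 3, "cytosol", False, 1e-3),
    "HPCOA": ("3-hydroxypropionyl-CoA", 3, "cytosol", False, 1e-3),
    "AACOA": ("acrylyl-CoA", 3, "cytosol", False, 1e-3),
    "AA": ("acrylic acid", 3, "cytosol", False, 1e-3),
    "B12": ("vitamin B12 coenzyme", 0, "cytosol", True, DEFAULT_B12),
    "HPx": ("extracellular 3-HP", 3, "extracellular", False, 0.0),
    "AAx": ("extracellular acrylic acid", 3, "extracellular", False, 0.0),
    "BIOM": ("biomass carbon proxy", 1, "cytosol", False, 0.0),
}

_STOICH = {
    "G3pD": {"DAP": -1, "NADPH": -1, "G3P": 1, "NADP": 1},
    "G3pP": {"G3P": -1, "GLY": 1, "PI": 1},
    "GlyK": {"GLY": -1, "ATP": -1, "G3P": 1, "ADP": 1},
    "GlyD": {"GLY": -1, "NAD": -1, "DHA": 1, "NADH": 1},
    "DhaPT": {"DHA": -1, "PEP": -1, "DAP": 1, "PYR": 1},
    "AccC": {"ACCOA": -1, "ATP": -1, "HCO3": -1, "MCOA": 1, "ADP": 1, "PI": 1},
    "GluD": {"AKG": -1, "NADPH": -1, "NH4": -1, "LGLU": 1, "NADP": 1},
    "AspAT": {"OAA": -1, "LGLU": -1, "ASP": 1, "AKG": 1},
    "AspC": {"ASP": -1, "BA": 1, "CO2": 1},
    "GlyDH": {"GLY": -1, "HPA": 1},
    "hpaD": {"HPA": -1, "NAD": -1, "HP": 1, "NADH": 1},
    "McoaR": {"MCOA": -1, "NADPH": -1, "MSA": 1, "COA": 1, "NADP": 1},
    "MsaR": {"MSA": -1, "NADPH": -1, "HP": 1, "NADP": 1},
    "BaTA": {"BA": -1, "AKG": -1, "MSA": 1, "LGLU": 1},
    "hpcoaS": {"HP": -1, "COA": -1, "ATP": -1, "HPCOA": 1, "PI": 2, "AMP": 1},
    "hpcoaDH": {"HPCOA": -1, "AACOA": 1},
    "AcoaTioE": {"AACOA": -1, "AA": 1, "COA": 1},
}

_ROLES = {
    "G3pD": {"A": "DAP", "B": "NADPH", "P": "G3P", "Q": "NADP"},
    "G3pP": {"A": "G3P"},
    "GlyK": {"A": "GLY", "B": "ATP"},
    "GlyD": {"A": "GLY", "B": "NAD"},
    "DhaPT": {"A": "DHA", "B": "PEP"},
    # B bound to bicarbonate (the carboxylation co-substrate), so the rate
    # shuts off as HCO3 runs out; the ATP hydrolysis is treated as non-limiting
    "AccC": {"A": "ACCOA", "B": "HCO3", "P": "MCOA"},
    "GluD": {"A": "AKG", "B": "NADPH"},
    "AspAT": {"A": "OAA", "B": "LGLU", "P": "ASP", "Q": "AKG"},
    "AspC": {"A": "ASP"},
    "GlyDH": {"A": "GLY", "Activator": "B12"},
    "hpaD": {"A": "HPA", "B": "NAD", "P": "HP"},
    "McoaR": {"A": "MCOA", "B": "NADPH"},
    "MsaR": {"A": "MSA", "B": "NADPH"},
    "BaTA": {"A": "BA", "B": "AKG"},
    "hpcoaS": {"A": "HP", "B": "COA", "C": "ATP"},
    "hpcoaDH": {"A": "HPCOA"},
    "AcoaTioE": {"A": "AACOA"},
}

_REVERSIBLE = {"G3pD", "AspAT"}

_PHASE1 = {
    "glycerol": ("GlyDH", "hpaD"),
    "malonyl_coa": ("McoaR", "MsaR"),
    "beta_alanine": ("BaTA", "MsaR"),
}
_PHASE2 = ("hpcoaS", "hpcoaDH", "AcoaTioE")

_NATIVE_ORDER = ("G3pD", "G3pP", "GlyK", "GlyD", "DhaPT", "AccC", "GluD", "AspAT", "AspC")


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("acrykin.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


_NATIVE_PARAMS = _load_table("parameters_native.csv")
_HETEROLOGOUS_PARAMS = _load_table("parameters_heterologous.csv")


def parameter_table() -> pd.DataFrame:
    """The transcribed kinetic-constant fixture (native + heterologous)."""
    return pd.concat([_NATIVE_PARAMS, _HETEROLOGOUS_PARAMS], ignore_index=True)


def _params_for(rid: str) -> dict[str, float]:
    table = parameter_table()
    rows = table[table.reaction == rid]
    return {row.slot: float(row.value) for row in rows.itertuples()}


def _mechanism_for(rid: str) -> str:
    table = parameter_table()
    rows = table[table.reaction == rid]
    if rows.empty:
        raise KeyError(rid)
    return rows.mechanism.iloc[0]


@dataclass(frozen=True)
class VariantSpec:
    """One of the twelve {carbon source} x {pathway} x {end product} models."""

    carbon_source: str
    pathway: str
    end_product: str

    def __post_init__(self):
        if self.carbon_source not in CARBON_SOURCES:
            raise ValueError(f"unknown carbon source {self.carbon_source!r}")
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.end_product not in END_PRODUCTS:
            raise ValueError(f"unknown end product {self.end_product!r}")

    @property
    def name(self) -> str:
        src = {"glucose": "Glu", "glycerol": "Gly"}[self.carbon_source]
        pth = {"glycerol": "Gly", "malonyl_coa": "Mcoa", "beta_alanine": "Ba"}[self.pathway]
        suffix = "" if self.end_product == "AA" else "-3HP"
        return f"{src}-{pth}{suffix}"


def all_variants() -> list[VariantSpec]:
    return [
        VariantSpec(c, p, e)
        for c in CARBON_SOURCES
        for p in PATHWAYS
        for e in END_PRODUCTS
    ]


def _native_reaction(rid: str, vmax: Mapping[str, float], dhapt_k: float) -> Reaction:
    if rid == "DhaPT":
        return Reaction(
            id=rid, stoichiometry=dict(_STOICH[rid]), mechanism="mass_action",
            roles=dict(_ROLES[rid]), params={"k": dhapt_k},
        )
    params = _params_for(rid)
    params["Vmax"] = float(vmax.get(rid, NATIVE_VMAX_DEFAULTS[rid]))
    return Reaction(
        id=rid, stoichiometry=dict(_STOICH[rid]), mechanism=_mechanism_for(rid),
        roles=dict(_ROLES[rid]), params=params, reversible=rid in _REVERSIBLE,
    )


def native_extension_reactions(
    vmax: Mapping[str, float] | None = None, dhapt_k: float = DEFAULT_DHAPT_K
) -> list[Reaction]:
    """The nine reactions extending the chassis (Vmax overridable per id)."""
    vmax = vmax or {}
    return [_native_reaction(rid, vmax, dhapt_k) for rid in _NATIVE_ORDER]


def _heterologous_reaction(rid: str, e_total: float) -> Reaction:
    params = _params_for(rid)
    params["E_total"] = float(e_total)
    return Reaction(
        id=rid, stoichiometry=dict(_STOICH[rid]), mechanism=_mechanism_for(rid),
        roles=dict(_ROLES[rid]), params=params,
    )


def phase2_reactions(e_total: float = DEFAULT_E_TOTAL) -> list[Reaction]:
    """Shared 3-HP -> AA trio (identical across the three routes)."""
    return [_heterologous_reaction(rid, e_total) for rid in _PHASE2]


def heterologous_reactions(
    pathway: str, end_product: str = "AA", e_total: float = DEFAULT_E_TOTAL
) -> list[Reaction]:
    """Phase-1 reactions of the named route, plus phase 2 when making AA."""
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    rxns = [_heterologous_reaction(rid, e_total) for rid in _PHASE1[pathway]]
    if end_product == "AA":
        rxns += phase2_reactions(e_total)
    return rxns


_SYNTH_CARBON = {"DAP": 3, "ACCOA": 2, "MCOA": 3, "LGLU": 5, "ASP": 4, "BA": 3}


def synth_reactions(ks: Mapping[str, float] | None = None, carbon: Mapping[str, int] | None = None) -> list[Reaction]:
    """First-order drains of the six synth metabolites into the biomass proxy."""
    ks = ks or {}
    carbon = carbon or _SYNTH_CARBON
    out = []
    for met in SYNTH_TARGETS:
        k = float(ks.get(met, DEFAULT_SYNTH_K))
        if k < 0:
            raise ValueError(f"synth k for {met} must be >= 0")
        c = carbon.get(met, 1) or 1
        stoich = {met: -1, "BIOM": c}
        if met in ("ACCOA", "MCOA"):
            stoich["COA"] = 1  # thioester drains must return the CoA moiety
        out.append(
            Reaction(
                id=f"synth_{met}", stoichiometry=stoich,
                mechanism="mass_action", roles={"A": met}, params={"k": k},
            )
        )
    return out


def synth_constants(
    stoich_model, flux_distribution: Mapping[str, float], ss_conc: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Synth mass-action constants from a stoichiometric flux distribution.

    For each synth metabolite M, k_M = (sum of fluxes consuming M) / [M]_ss,
    with [M]_ss = 1 mM for newly added metabolites, so the synth rate at the
    reference state equals the summed consumption flux.
    """
    ss_conc = ss_conc or {}
    ks = {}
    for met in SYNTH_TARGETS:
        if met not in stoich_model.species:
            raise KeyError(f"metabolite {met!r} absent from stoichiometric model")
        i = stoich_model.species.index(met)
        total = 0.0
        for j, rid in enumerate(stoich_model.reactions):
            if rid.startswith("synth_"):
                continue  # the synth reaction itself is not a consumer here
            coeff = stoich_model.S[i, j]
            flux = flux_distribution.get(rid, 0.0)
            consumed = -coeff * flux
            if consumed > 1e-12:
                total += consumed
        ks[met] = total / float(ss_conc.get(met, 1.0))
    return ks


def _initial_carbon(spec: VariantSpec) -> tuple[str, float]:
    if spec.carbon_source == "glucose":
        return "GLCx", 55.5  # 10 g/L
    return "GLYx", 217.2  # 20 g/L


def build_variant(
    chassis: KineticModel,
    spec: VariantSpec,
    *,
    native_vmax: Mapping[str, float] | None = None,
    synth_k: Mapping[str, float] | None = None,
    dhapt_k: float = DEFAULT_DHAPT_K,
    e_total: float = DEFAULT_E_TOTAL,
    export_k: float = DEFAULT_EXPORT_K,
    initial_carbon_mM: float | None = None,
) -> KineticModel:
    """Assemble chassis + native extension + synth drains + heterologous route.

    Glucose-source variants omit GlyD and DhaPT (with glucose feeding the
    network they would deflect newly made glycerol straight back into
    central metabolism instead of supplying the route); glycerol-source
    variants carry all nine native reactions.
    """
    missing = [sid for sid in ATTACHMENT_SPECIES if not chassis.has_species(sid)]
    uptake = "GLCx" if spec.carbon_source == "glucose" else "GLYx"
    if not chassis.has_species(uptake):
        missing.append(uptake)
    if missing:
        raise AssemblyError(f"chassis lacks attachment species: {missing}")

    model = chassis.copy()
    for sid, (name, carbon, comp, fixed, init) in _NEW_SPECIES.items():
        model.add_species(
            Species(id=sid, name=name, carbon=carbon, compartment=comp,
                    is_fixed=fixed, initial_concentration=init),
            exist_ok=True,
        )

    native = native_extension_reactions(native_vmax, dhapt_k)
    if spec.carbon_source == "glucose":
        native = [r for r in native if r.id not in ("GlyD", "DhaPT")]
    else:
        log.info("DhaPT mass-action k = %g mM^-1 s^-1 (explicit configuration)", dhapt_k)
    for rxn in native:
        model.add_reaction(rxn)
    for rxn in synth_reactions(synth_k):
        model.add_reaction(rxn)
    for rxn in heterologous_reactions(spec.pathway, spec.end_product, e_total):
        if not model.has_reaction(rxn.id):
            model.add_reaction(rxn)

    # first-order export of the end product (synthetic stand-in for the
    # unspecified transport step; the deposited models are the arbiter)
    if spec.end_product == "AA":
        model.add_reaction(
            Reaction(id="export_AA", stoichiometry={"AA": -1, "AAx": 1},
                     mechanism="mass_action", roles={"A": "AA"}, params={"k": export_k})
        )
    else:
        model.add_reaction(
            Reaction(id="export_HP", stoichiometry={"HP": -1, "HPx": 1},
                     mechanism="mass_action", roles={"A": "HP"}, params={"k": export_k})
        )

    carbon_species, default_mM = _initial_carbon(spec)
    model.get_species(carbon_species).initial_concentration = (
        default_mM if initial_carbon_mM is None else float(initial_carbon_mM)
    )
    other = "GLYx" if carbon_species == "GLCx" else "GLCx"
    if model.has_species(other):
        model.get_species(other).initial_concentration = 0.0

    model.annotations.update(
        {
            "variant": spec.name,
            "carbon_source": spec.carbon_source,
            "pathway": spec.pathway,
            "end_product": spec.end_product,
        }
    )
    return model
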