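"""Reaction-network data model, ODE assembly and model I/O.

The in-memory containers are deliberately small: :class:`Species`,
:class:`Reaction` and :class:`KineticModel` hold exactly what the ODE
assembler, the SBML writer and the stoichiometric-twin builder need.
Concentrations are in mM, rates in mM/s, time in seconds; hours and g/L
appear only in reporting helpers (:func:`convert_concentration`).

SBML round-tripping uses libsbml.  Models written by this package carry a
small annotation per reaction naming the mechanism and the role->species
binding, so a read restores the exact structured form; kinetic laws written
by other tools are kept as opaque "foreign" laws whose MathML is evaluated
numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from . import kinetics
from .kinetics import MECHANISMS, RateLawError

__all__ = [
    "Species",
    "Reaction",
    "KineticModel",
    "AssemblyError",
    "SBMLReadError",
    "assemble_odes",
    "reaction_fluxes",
    "read_sbml",
    "write_sbml",
    "write_sbml_string",
    "convert_concentration",
    "MOLAR_MASS",
    "carbon_total",
]

ACRYKIN_NS = "https://acrykin.invalid/ratelaw"


class AssemblyError(ValueError):
    pass


class SBMLReadError(ValueError):
    pass


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    initial_concentration: float = 0.0
    is_fixed: bool = False
    carbon: int = 0  # carbon atoms counted by the conservation audit (0 for cofactors)

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ValueError(f"{self.id}: initial concentration must be >= 0")


@dataclass
class Reaction:
    """A reaction: stoichiometry plus a bound rate law.

    ``roles`` maps mechanism roles (A, B, P, ...) to species ids; ``params``
    holds the kinetic constants including the capacity slot (Vmax, or
    Kcat+E_total, or k).  ``foreign_rate``, when set, overrides the
    mechanism: it is called with a {species_id: concentration} mapping.
    """

    id: str
    stoichiometry: dict[str, float]
    mechanism: str = "mass_action"
    roles: dict[str, str] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    foreign_rate: Callable[[Mapping[str, float]], float] | None = None
    foreign_math: str | None = None  # L3 infix of a foreign kinetic law

    def __post_init__(self):
        if not any(v != 0 for v in self.stoichiometry.values()):
            raise ValueError(f"{self.id}: stoichiometry has no non-zero coefficient")

    def copy(self) -> "Reaction":
        return replace(
            self, stoichiometry=dict(self.stoichiometry), roles=dict(self.roles),
            params=dict(self.params),
        )


@dataclass
class KineticModel:
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: dict[str, float] = field(
        default_factory=lambda: {"cytosol": 1.0, "extracellular": 1.0}
    )
    annotations: dict[str, str] = field(default_factory=dict)

    # -- bookkeeping -------------------------------------------------------
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def has_species(self, sid: str) -> bool:
        return any(s.id == sid for s in self.species)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def add_species(self, sp: Species, *, exist_ok: bool = False) -> None:
        if self.has_species(sp.id):
            if exist_ok:
                return
            raise ValueError(f"duplicate species id {sp.id}")
        self.species.append(sp)

    def add_reaction(self, rxn: Reaction) -> None:
        if self.has_reaction(rxn.id):
            raise ValueError(f"duplicate reaction id {rxn.id}")
        missing = [sid for sid in rxn.stoichiometry if not self.has_species(sid)]
        missing += [sid for sid in rxn.roles.values() if not self.has_species(sid)]
        if missing:
            raise AssemblyError(f"{rxn.id}: unknown species {sorted(set(missing))}")
        self.reactions.append(rxn)

    def copy(self) -> "KineticModel":
        return KineticModel(
            species=[replace(s) for s in self.species],
            reactions=[r.copy() for r in self.reactions],
            compartments=dict(self.compartments),
            annotations=dict(self.annotations),
        )

    def initial_state(self) -> dict[str, float]:
        return {s.id: s.initial_concentration for s in self.species}

    def stoichiometric_matrix(self, free_only: bool = True) -> tuple[np.ndarray, list[str], list[str]]:
        """(N, species ids, reaction ids); rows restricted to non-fixed species."""
        sids = [s.id for s in self.species if (not free_only or not s.is_fixed)]
        idx = {sid: i for i, sid in enumerate(sids)}
        rids = [r.id for r in self.reactions]
        N = np.zeros((len(sids), len(rids)))
        for j, r in enumerate(self.reactions):
            for sid, coeff in r.stoichiometry.items():
                if sid in idx:
                    N[idx[sid], j] = coeff
        return N, sids, rids


# --------------------------------------------------------------------------
# ODE assembly
# --------------------------------------------------------------------------

def _rate_closure(rxn: Reaction, species_index: Mapping[str, int]):
    """Compile one reaction into rate(conc_vector) -> mM/s."""
    if rxn.foreign_rate is not None:
        all_ids = list(species_index)
        fr = rxn.foreign_rate

        def foreign(c, _ids=all_ids, _idx=species_index, _fr=fr):
            return _fr({sid: c[_idx[sid]] for sid in _ids})

        return foreign

    law = MECHANISMS.get(rxn.mechanism)
    if law is None:
        raise AssemblyError(f"{rxn.id}: unknown mechanism {rxn.mechanism!r}")
    kinetics.validate_params(rxn.mechanism, rxn.params)
    needed = law.roles if rxn.mechanism != "mass_action" else tuple(rxn.roles)
    for role in needed:
        if role not in rxn.roles:
            raise AssemblyError(f"{rxn.id}: unbound rate-law role {role!r}")
        if rxn.roles[role] not in species_index:
            raise AssemblyError(f"{rxn.id}: role {role!r} bound to unknown species")
    pairs = [(role, species_index[sid]) for role, sid in rxn.roles.items()]
    cap = kinetics.capacity(rxn.params)
    sat = law.saturation
    params = dict(rxn.params)

    def rate(c, _pairs=pairs, _cap=cap, _sat=sat, _p=params):
        return _cap * _sat(_p, {role: c[i] for role, i in _pairs})

    return rate


def assemble_odes(
    model: KineticModel, activities: Mapping[str, float] | None = None
):
    """Build the mass-balance right-hand side d[S]/dt = sum_r nu_{S,r} v_r.

    Returns ``(rhs, flux_fn, free_ids)`` where ``rhs(t, y)`` takes the free
    (non-fixed) concentration vector, ``flux_fn(y)`` returns the per-reaction
    rate vector in model reaction order, and ``free_ids`` names the state.
    ``activities`` optionally scales whole reactions (enzyme-activity
    multipliers used by control analysis and strain design).
    """
    sindex = {s.id: i for i, s in enumerate(model.species)}
    full0 = np.array([s.initial_concentration for s in model.species], dtype=float)
    free_ids = [s.id for s in model.species if not s.is_fixed]
    free_idx = np.array([sindex[sid] for sid in free_ids], dtype=int)

    rates = []
    acts = np.ones(len(model.reactions))
    for j, rxn in enumerate(model.reactions):
        rates.append(_rate_closure(rxn, sindex))
        if activities and rxn.id in activities:
            acts[j] = float(activities[rxn.id])

    # stoichiometry over free species only (fixed species have zero derivative)
    stoich = []
    free_pos = {sid: k for k, sid in enumerate(free_ids)}
    for rxn in model.reactions:
        stoich.append(
            [(free_pos[sid], coeff) for sid, coeff in rxn.stoichiometry.items() if sid in free_pos]
        )

    nfree = len(free_ids)

    def flux_fn(y: np.ndarray) -> np.ndarray:
        full = full0.copy()
        full[free_idx] = np.maximum(y, 0.0)  # clamp transient negatives from the integrator
        return np.array([a * r(full) for a, r in zip(acts, rates)])

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        v = flux_fn(y)
        dy = np.zeros(nfree)
        for vj, pairs in zip(v, stoich):
            for k, coeff in pairs:
                dy[k] += coeff * vj
        return dy

    return rhs, flux_fn, free_ids


def reaction_fluxes(model: KineticModel, conc: Mapping[str, float]) -> dict[str, float]:
    """Per-reaction rates at a given full concentration map (brute-force path)."""
    out = {}
    for rxn in model.reactions:
        if rxn.foreign_rate is not None:
            out[rxn.id] = rxn.foreign_rate(conc)
        else:
            bound = {role: conc[sid] for role, sid in rxn.roles.items()}
            out[rxn.id] = kinetics.evaluate(rxn.mechanism, rxn.params, bound)
    return out


# --------------------------------------------------------------------------
# Unit conversions
# --------------------------------------------------------------------------

MOLAR_MASS = {  # g/mol
    "glucose": 180.16,
    "glycerol": 92.09,
    "3-HP": 90.08,
    "AA": 72.06,
}


def convert_concentration(value: float, direction: str, compound: str) -> float:
    """Convert between g/L and mM for the four headline compounds.

    ``direction`` is ``"g_per_L_to_mM"`` or ``"mM_to_g_per_L"``.
    """
    if value < 0:
        raise ValueError("concentration must be >= 0")
    try:
        mass = MOLAR_MASS[compound]
    except KeyError:
        raise ValueError(f"unknown compound {compound!r}") from None
    if direction == "g_per_L_to_mM":
        return value / mass * 1000.0
    if direction == "mM_to_g_per_L":
        return value * mass / 1000.0
    raise ValueError(f"unknown direction {direction!r}")


def carbon_total(model: KineticModel, conc: Mapping[str, float]) -> float:
    """Total carbon (mM of C) over non-fixed carbon-bearing species."""
    return sum(
        s.carbon * conc[s.id] for s in model.species if s.carbon and not s.is_fixed
    )


# --------------------------------------------------------------------------
# SBML I/O
# --------------------------------------------------------------------------

def _infix_for(rxn: Reaction) -> str:
    """L3 infix formula of the reaction's kinetic law, over species ids."""
    if rxn.foreign_math is not None:
        return rxn.foreign_math
    r = rxn.roles
    p = set(rxn.params)
    cap = "Vmax" if "Vmax" in p else ("E_total * Kcat" if "Kcat" in p else "k")
    m = rxn.mechanism
    if m == "michaelis_menten_1s":
        return f"{cap} * {r['A']} / (Km + {r['A']})"
    if m == "mm_2s_multiplicative":
        return (
            f"{cap} * {r['A']} / (Km_a + {r['A']}) * {r['B']} / (Km_b + {r['B']})"
        )
    if m == "mm_3s_multiplicative":
        return (
            f"{cap} * {r['A']} / (Km_a + {r['A']}) * {r['B']} / (Km_b + {r['B']})"
            f" * {r['C']} / (Km_c + {r['C']})"
        )
    if m == "mm_2s_random_bibi_denominator":
        kda = "Kd_a" if "Kd_a" in p else "Km_a"
        return (
            f"{cap} * {r['A']} * {r['B']} / ({kda} * Km_b + Km_b * {r['A']}"
            f" + Km_a * {r['B']} + {r['A']} * {r['B']})"
        )
    if m in ("mm_competitive_product_inhibition_2s", "ordered_bibi_product_inhibition"):
        return (
            f"{cap} * {r['A']} / (Km_a * (1 + {r['P']} / Ki_p) + {r['A']})"
            f" * {r['B']} / (Km_b + {r['B']})"
        )
    if m == "rapid_equilibrium_random_bibi_reversible":
        return (
            f"{cap} * ({r['A']} * {r['B']} - {r['P']} * {r['Q']} / Keq) / (Km_a * Km_b)"
            f" / ((1 + {r['A']} / Km_a) * (1 + {r['B']} / Km_b)"
            f" + (1 + {r['P']} / Km_p) * (1 + {r['Q']} / Km_q) - 1)"
        )
    if m == "ping_pong_bibi_reversible":
        return (
            f"{cap} * ({r['A']} * {r['B']} - {r['P']} * {r['Q']} / Keq) / (Km_a * Km_b)"
            f" / ((1 + {r['A']} / Km_a + {r['Q']} / Km_q)"
            f" * (1 + {r['B']} / Km_b + {r['P']} / Km_p))"
        )
    if m == "ping_pong_bibi_substrate_inhibition":
        return (
            f"{cap} * {r['A']} * {r['B']} / (Km_b * {r['A']}"
            f" + Km_a * {r['B']} * (1 + {r['B']} / Ki_b) + {r['A']} * {r['B']})"
        )
    if m == "hill_2s":
        return (
            f"{cap} * {r['A']}^n / (Km_a^n + {r['A']}^n)"
            f" * {r['B']}^n / (Km_b^n + {r['B']}^n)"
        )
    if m == "specific_activation":
        return (
            f"{cap} * {r['A']} * {r['Activator']}"
            f" / (Km_a * Ka + (Km_a + {r['A']}) * {r['Activator']})"
        )
    if m == "mass_action":
        terms = [cap] + [r[role] for role in ("A", "B", "C") if role in r]
        return " * ".join(terms)
    raise AssemblyError(f"{rxn.id}: no SBML formula template for {m!r}")


def write_sbml_string(model: KineticModel) -> str:
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    sm = doc.createModel()
    sm.setId(model.annotations.get("model_id", "acrykin_model"))
    sm.setTimeUnits("second")
    for cid, vol in sorted(model.compartments.items()):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
        comp.setSize(vol)
        comp.setSpatialDimensions(3)
    for sp in model.species:
        s = sm.createSpecies()
        s.setId(sp.id)
        if sp.name:
            s.setName(sp.name)
        s.setCompartment(sp.compartment)
        s.setInitialConcentration(sp.initial_concentration)
        s.setBoundaryCondition(sp.is_fixed)
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
        if sp.carbon:
            s.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'><p>carbon={sp.carbon}</p></body>")
    if model.annotations:
        items = "".join(
            f'<item key="{k}" value="{v}"/>' for k, v in sorted(model.annotations.items())
        )
        sm.setAnnotation(f'<meta xmlns="{ACRYKIN_NS}">{items}</meta>')
    for rxn in model.reactions:
        r = sm.createReaction()
        r.setId(rxn.id)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for sid, coeff in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        for sid in sorted(set(rxn.roles.values()) - set(rxn.stoichiometry)):
            mod = r.createModifier()
            mod.setSpecies(sid)
        kl = r.createKineticLaw()
        ast = libsbml.parseL3Formula(_infix_for(rxn))
        if ast is None:
            raise AssemblyError(f"{rxn.id}: could not build kinetic-law MathML")
        kl.setMath(ast)
        for slot, value in sorted(rxn.params.items()):
            lp = kl.createLocalParameter()
            lp.setId(slot)
            lp.setValue(float(value))
        if rxn.foreign_rate is None:
            roles = ";".join(f"{role}={sid}" for role, sid in sorted(rxn.roles.items()))
            r.setAnnotation(
                f'<ratelaw xmlns="{ACRYKIN_NS}" mechanism="{rxn.mechanism}" roles="{roles}"/>'
            )
    return libsbml.writeSBMLToString(doc)


def write_sbml(model: KineticModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_sbml_string(model))


def _eval_ast(node, env: Mapping[str, float]) -> float:
    """Numeric evaluation of a libsbml ASTNode over an id->value environment."""
    import libsbml

    t = node.getType()
    if t == libsbml.AST_INTEGER:
        return float(node.getInteger())
    if t in (libsbml.AST_REAL, libsbml.AST_REAL_E):
        return node.getReal()
    if t == libsbml.AST_RATIONAL:
        return node.getNumerator() / node.getDenominator()
    if t == libsbml.AST_NAME:
        name = node.getName()
        if name in env:
            return env[name]
        raise SBMLReadError(f"unknown symbol {name!r} in kinetic law")
    if t == libsbml.AST_CONSTANT_PI:
        return math.pi
    if t == libsbml.AST_CONSTANT_E:
        return math.e
    kids = [_eval_ast(node.getChild(i), env) for i in range(node.getNumChildren())]
    if t == libsbml.AST_PLUS:
        return sum(kids) if kids else 0.0
    if t == libsbml.AST_MINUS:
        return -kids[0] if len(kids) == 1 else kids[0] - kids[1]
    if t == libsbml.AST_TIMES:
        return math.prod(kids)
    if t == libsbml.AST_DIVIDE:
        return kids[0] / kids[1]
    if t in (libsbml.AST_POWER, libsbml.AST_FUNCTION_POWER):
        return kids[0] ** kids[1]
    if t == libsbml.AST_FUNCTION_EXP:
        return math.exp(kids[0])
    if t == libsbml.AST_FUNCTION_LN:
        return math.log(kids[0])
    if t == libsbml.AST_FUNCTION_ROOT:
        return kids[1] ** (1.0 / kids[0])
    raise SBMLReadError(f"unsupported MathML node type {node.getType()}")


def _parse_our_annotation(r) -> tuple[str, dict[str, str]] | None:
    ann = r.getAnnotation()
    if ann is None:
        return None
    for i in range(ann.getNumChildren()):
        child = ann.getChild(i)
        if child.getURI() == ACRYKIN_NS and child.getName() == "ratelaw":
            mech = child.getAttrValue("mechanism")
            roles_raw = child.getAttrValue("roles")
            roles = {}
            if roles_raw:
                for pair in roles_raw.split(";"):
                    role, sid = pair.split("=")
                    roles[role] = sid
            return mech, roles
    return None


def read_sbml(path) -> KineticModel:
    """Read an SBML Level 2/3 model with kinetic laws.

    Reactions annotated by this package are restored to their structured
    mechanisms; anything else becomes an opaque foreign law that still
    evaluates numerically (global + local parameters substituted).
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None:
        raise SBMLReadError(f"could not parse SBML from {path}")
    sm = doc.getModel()
    model = KineticModel(compartments={}, species=[], reactions=[])
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        model.compartments[comp.getId()] = comp.getSize() if comp.isSetSize() else 1.0
    if not model.compartments:
        model.compartments = {"cytosol": 1.0}
    ann = sm.getAnnotation()
    if ann is not None:
        for i in range(ann.getNumChildren()):
            child = ann.getChild(i)
            if child.getURI() == ACRYKIN_NS and child.getName() == "meta":
                for j in range(child.getNumChildren()):
                    item = child.getChild(j)
                    model.annotations[item.getAttrValue("key")] = item.getAttrValue("value")
    global_params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }
    compartment_sizes = {cid: size for cid, size in model.compartments.items()}
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        carbon = 0
        if s.isSetNotes():
            notes = s.getNotesString()
            marker = "carbon="
            if marker in notes:
                carbon = int(notes.split(marker)[1].split("<")[0])
        conc = s.getInitialConcentration() if s.isSetInitialConcentration() else 0.0
        if math.isnan(conc) and s.isSetInitialAmount():
            vol = compartment_sizes.get(s.getCompartment(), 1.0)
            conc = s.getInitialAmount() / vol
        model.species.append(
            Species(
                id=s.getId(),
                name=s.getName() or "",
                compartment=s.getCompartment() or "cytosol",
                initial_concentration=0.0 if math.isnan(conc) else conc,
                is_fixed=bool(s.getBoundaryCondition()),
                carbon=carbon,
            )
        )
    missing_kl = [
        sm.getReaction(i).getId()
        for i in range(sm.getNumReactions())
        if sm.getReaction(i).getKineticLaw() is None
    ]
    if missing_kl:
        raise SBMLReadError(f"reactions without kinetic laws: {missing_kl}")
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        kl = r.getKineticLaw()
        local = {}
        for j in range(kl.getNumLocalParameters()):
            lp = kl.getLocalParameter(j)
            local[lp.getId()] = lp.getValue()
        for j in range(kl.getNumParameters()):  # SBML L2 style
            lp = kl.getParameter(j)
            local.setdefault(lp.getId(), lp.getValue())
        ours = _parse_our_annotation(r)
        if ours is not None:
            mech, roles = ours
            model.reactions.append(
                Reaction(
                    id=r.getId(), stoichiometry=stoich, mechanism=mech, roles=roles,
                    params=local, reversible=bool(r.getReversible()),
                )
            )
        else:
            # deep-copied so the AST outlives the libsbml document
            math_ast = kl.getMath().deepCopy()
            consts = dict(global_params)
            consts.update(compartment_sizes)
            consts.update(local)
            infix = libsbml.formulaToL3String(math_ast)

            def foreign(conc, _ast=math_ast, _consts=consts):
                env = dict(_consts)
                env.update(conc)
                return _eval_ast(_ast, env)

            model.reactions.append(
                Reaction(
                    id=r.getId(), stoichiometry=stoich, mechanism="foreign",
                    roles={}, params=local, reversible=bool(r.getReversible()),
                    foreign_rate=foreign, foreign_math=infix,
                )
            )
    return model
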