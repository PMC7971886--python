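"""Vmax estimation: FVA-constrained Method 1 and turnover-based Method 2.

Method 1 (for reactions of the native metabolism): the kinetic model is run
to a steady state, the reactions shared with a stoichiometric model are
pinned to that flux distribution (+-0.01 mM/s by default), a flux
variability analysis maximises the flux v through the reaction of
interest, and Vmax = v / F where F is the rate law's saturation factor at
the steady-state concentrations (newly added metabolites assumed at 1 mM).

Method 2 (for heterologous reactions): Vmax = Kcat * [E]_total with the
enzyme deliberately in surplus (100 mM) so that the heterologous step is
never an artificial bottleneck.

LPs are solved with scipy's HiGHS interface; genome-scale models in SBML
(FBC bounds honoured) are read through cobrapy.  The flux-unit bridge
between kinetic mM/s and stoichiometric model units is an explicit,
configurable scale factor (default 1.0 — kinetic fluxes taken as model
units directly) and is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from . import kinetics
from .network import KineticModel

__all__ = [
    "StoichModel",
    "VmaxEstimate",
    "InfeasibleError",
    "UnboundedError",
    "vmax_method2",
    "constrained_fva_max",
    "pinned_fba",
    "vmax_method1",
    "saturation_at_state",
]

log = logging.getLogger(__name__)

DEFAULT_PIN_TOL = 0.01  # mM/s, width of the flux pins around the kinetic values
_BIG = 1.0e4  # default magnitude bound on unconstrained reactions


class InfeasibleError(RuntimeError):
    pass


class UnboundedError(RuntimeError):
    pass


@dataclass
class StoichModel:
    """Stoichiometric matrix with bounds, for FBA/FVA."""

    species: list[str]
    reactions: list[str]
    S: np.ndarray  # species x reactions
    lb: np.ndarray
    ub: np.ndarray
    objective: str | None = None
    #: kinetic-reaction-id -> stoichiometric-reaction-id (explicit, no fuzzy matching)
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.lb > self.ub):
            raise ValueError("lower bound exceeds upper bound")
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("kinetic->stoichiometric mapping must be injective")

    def index(self, rid: str) -> int:
        return self.reactions.index(rid)

    @classmethod
    def from_kinetic(cls, model: KineticModel, extra_bound: float = _BIG) -> "StoichModel":
        """Twin built from the kinetic reactions over the free species.

        Sinks that only accumulate (no consumer) are dropped from the
        balance rows so the twin admits the kinetic steady-state flux.
        """
        N, sids, rids = model.stoichiometric_matrix()
        consumed = (N < 0).any(axis=1)
        produced = (N > 0).any(axis=1)
        keep = [i for i in range(len(sids)) if consumed[i] or not produced[i]]
        lb = np.array(
            [-extra_bound if r.reversible else 0.0 for r in model.reactions]
        )
        ub = np.full(len(rids), extra_bound)
        return cls(
            species=[sids[i] for i in keep],
            reactions=list(rids),
            S=N[keep, :],
            lb=lb,
            ub=ub,
            mapping={rid: rid for rid in rids},
        )

    @classmethod
    def read_sbml_fbc(cls, path, mapping: Mapping[str, str] | None = None) -> "StoichModel":
        """Genome-scale SBML (FBC bounds honoured), via cobrapy."""
        import cobra.io

        cb = cobra.io.read_sbml_model(str(path))
        species = [m.id for m in cb.metabolites]
        reactions = [r.id for r in cb.reactions]
        midx = {m: i for i, m in enumerate(species)}
        S = np.zeros((len(species), len(reactions)))
        for j, r in enumerate(cb.reactions):
            for met, coeff in r.metabolites.items():
                S[midx[met.id], j] = coeff
        lb = np.array([r.lower_bound for r in cb.reactions])
        ub = np.array([r.upper_bound for r in cb.reactions])
        objective = None
        for r in cb.reactions:
            if r.objective_coefficient:
                objective = r.id
                break
        return cls(species, reactions, S, lb, ub, objective, dict(mapping or {}))


@dataclass
class VmaxEstimate:
    reaction: str
    method: int
    v: float  # flux used, mM/s
    F: float  # saturation factor at the reference state
    Vmax: float  # mM/s
    notes: str = ""


def vmax_method2(kcat: float, e_total: float = 100.0) -> float:
    """Vmax = Kcat * [E]_total (enzyme in surplus, default 100 mM)."""
    if kcat < 0 or e_total < 0:
        raise ValueError("kcat and e_total must be >= 0")
    return float(kcat) * float(e_total)


def _solve_lp(c, stoich: StoichModel, lb, ub):
    res = linprog(
        c,
        A_eq=stoich.S,
        b_eq=np.zeros(stoich.S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res


def _pinned_bounds(stoich: StoichModel, kinetic_fluxes, tol, scale):
    lb, ub = stoich.lb.astype(float).copy(), stoich.ub.astype(float).copy()
    pinned = []
    for kid, v in kinetic_fluxes.items():
        sid = stoich.mapping.get(kid)
        if sid is None:
            continue
        if not np.isfinite(v):
            raise ValueError(f"non-finite kinetic flux for {kid}")
        j = stoich.index(sid)
        lb[j] = max(lb[j], scale * v - tol)
        ub[j] = min(ub[j], scale * v + tol)
        pinned.append(sid)
        if lb[j] > ub[j]:
            raise InfeasibleError(
                f"pin on {sid} ({scale * v:+.4g} +- {tol}) contradicts its bounds"
            )
    return lb, ub, pinned


def constrained_fva_max(
    stoich: StoichModel,
    kinetic_fluxes: Mapping[str, float],
    target: str,
    tol: float = DEFAULT_PIN_TOL,
    flux_scale: float = 1.0,
) -> float:
    """Maximum feasible flux of ``target`` with shared reactions pinned.

    ``kinetic_fluxes`` is keyed by kinetic reaction id and routed through
    the model's mapping table; ``flux_scale`` bridges kinetic mM/s to
    stoichiometric-model units (default 1.0, logged).
    """
    log.info("FVA flux-unit scale factor: %g (kinetic mM/s -> model units)", flux_scale)
    lb, ub, pinned = _pinned_bounds(stoich, kinetic_fluxes, tol, flux_scale)
    j = stoich.index(target)
    c = np.zeros(len(stoich.reactions))
    c[j] = -1.0  # maximise
    res = _solve_lp(c, stoich, lb, ub)
    if res.status == 2:
        raise InfeasibleError(
            f"FVA infeasible; pinned set (+-{tol}): {sorted(pinned)}"
        )
    if res.status == 3:
        raise UnboundedError(f"target {target} is unbounded above")
    if not res.success:
        raise RuntimeError(f"LP failed: {res.message}")
    return float(-res.fun)


def pinned_fba(
    stoich: StoichModel,
    kinetic_fluxes: Mapping[str, float],
    objective: str | None = None,
    tol: float = DEFAULT_PIN_TOL,
    flux_scale: float = 1.0,
) -> dict[str, float]:
    """Full flux distribution maximising ``objective`` under the pins."""
    lb, ub, pinned = _pinned_bounds(stoich, kinetic_fluxes, tol, flux_scale)
    c = np.zeros(len(stoich.reactions))
    obj = objective or stoich.objective
    if obj is not None:
        c[stoich.index(obj)] = -1.0
    res = _solve_lp(c, stoich, lb, ub)
    if res.status == 2:
        raise InfeasibleError(f"FBA infeasible; pinned set: {sorted(pinned)}")
    if not res.success:
        raise RuntimeError(f"LP failed: {res.message}")
    return {rid: float(v) for rid, v in zip(stoich.reactions, res.x)}


def saturation_at_state(
    model: KineticModel,
    target: str,
    conc: Mapping[str, float],
    new_species_conc: float = 1.0,
) -> float:
    """Saturation factor F of the target's law at a reference state.

    Species absent from ``conc`` (newly added metabolites without a chassis
    steady state) are taken at ``new_species_conc`` (1 mM).
    """
    rxn = model.get_reaction(target)
    bound = {
        role: float(conc.get(sid, new_species_conc)) for role, sid in rxn.roles.items()
    }
    return kinetics.saturation_factor(rxn.mechanism, rxn.params, bound)


def vmax_method1(
    kinetic_model: KineticModel,
    stoich: StoichModel,
    target: str,
    steady_conc: Mapping[str, float] | None = None,
    kinetic_fluxes: Mapping[str, float] | None = None,
    tol: float = DEFAULT_PIN_TOL,
    flux_scale: float = 1.0,
    new_species_conc: float = 1.0,
) -> VmaxEstimate:
    """Method 1: Vmax = v_FVA / F(steady state).

    When ``steady_conc``/``kinetic_fluxes`` are not supplied, the kinetic
    model's steady state is found first (continuous-mode model expected).
    The target itself must not be pinned, so its flux is free to reach the
    stoichiometric maximum.
    """
    if steady_conc is None or kinetic_fluxes is None:
        from .dynamics import find_steady_state

        ss = find_steady_state(kinetic_model)
        steady_conc = ss.conc
        kinetic_fluxes = ss.fluxes
    pins = {
        kid: v for kid, v in kinetic_fluxes.items() if stoich.mapping.get(kid) != target
    }
    v = constrained_fva_max(stoich, pins, target, tol=tol, flux_scale=flux_scale)
    F = saturation_at_state(kinetic_model, target, steady_conc, new_species_conc)
    if abs(F) < 1e-12:
        raise ZeroDivisionError(
            f"undefined Vmax for {target}: saturation factor is 0 at the reference state"
        )
    vmax = v / F
    est = VmaxEstimate(
        reaction=target, method=1, v=v, F=F, Vmax=vmax,
        notes=f"pins +-{tol} mM/s, flux scale {flux_scale}, new species at {new_species_conc} mM",
    )
    assert abs(est.Vmax * est.F - est.v) <= 1e-9 * max(1.0, abs(est.v))
    return est
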