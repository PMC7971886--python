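"""FCC-guided iterative strain design.

Each iteration: find a steady state of the continuous (feed + drain)
variant, compute flux control coefficients for the acrylic-acid-forming
flux, pick the reaction with the largest |FCC| (positive coefficient ->
over-expression, negative -> under-expression / knock-down), then search
that reaction's capacity within a 50-fold band to maximise the end-time AA
titer of the batch model (10 g/L glucose, no end-product drains).  The
loop stops when the feed limits production, the limiting reaction is
already optimised, or the continuous model no longer reaches a stable
steady state.

The inner search is deterministic: Brent's bounded minimiser over log10 of
the capacity multiplier (relative tolerance 1e-3), with both band edges
checked explicitly so bound-active optima are returned exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import kinetics
from .chassis import make_continuous
from .dynamics import (
    FCCTable,
    IntegrationError,
    NoSteadyStateError,
    UnstableSteadyStateError,
    find_steady_state,
    flux_control_coefficients,
    simulate,
)
from .network import KineticModel

__all__ = ["MutantSpec", "select_target", "optimise_vmax", "design_loop"]

log = logging.getLogger(__name__)

#: pseudo-reactions never proposed as engineering targets
_NON_ENZYMATIC_PREFIXES = ("synth_", "export_", "feed_", "drain_")


class DesignError(RuntimeError):
    pass


@dataclass
class MutantSpec:
    iteration: int
    reaction: str
    original_vmax: float
    new_vmax: float
    fold_change: float
    objective_gL: float  # AA titer at the horizon
    stop_reason: str | None = None  # feed_limited | already_optimised | no_steady_state | max_iterations

    def bound_ok(self, bound_fold: float = 50.0) -> bool:
        return (
            self.original_vmax / bound_fold - 1e-12
            <= self.new_vmax
            <= self.original_vmax * bound_fold + 1e-12
        )


def _capacity_slot(model: KineticModel, rid: str) -> str:
    params = model.get_reaction(rid).params
    if "Vmax" in params:
        return "Vmax"
    if "Kcat" in params:
        return "Kcat"
    if "k" in params:
        return "k"
    raise DesignError(f"{rid}: no capacity parameter to edit")


def select_target(fcc: FCCTable, method: str = "structural", candidates=None) -> tuple[str, str]:
    """Reaction with the largest |FCC| and the proposed direction.

    Returns ``(reaction_id, direction)`` with direction ``"over"`` for a
    positive coefficient and ``"under"`` for a negative one.  Pseudo
    reactions (synth drains, exports, feeds) are never proposed.
    """
    coeffs = fcc.coefficients(method).dropna()
    if candidates is not None:
        coeffs = coeffs[coeffs.index.isin(candidates)]
    coeffs = coeffs[
        [not rid.startswith(_NON_ENZYMATIC_PREFIXES) and rid != fcc.target for rid in coeffs.index]
    ]
    if coeffs.empty:
        raise DesignError("empty flux-control table: no candidate reactions")
    rid = coeffs.abs().idxmax()
    return rid, ("over" if coeffs[rid] > 0 else "under")


def optimise_vmax(
    model: KineticModel,
    reaction: str,
    horizon: float = 10800.0,
    bound_fold: float = 50.0,
    objective_species: str = "AAx",
    reltol: float = 1e-7,
    log10_xatol: float = 2e-4,
) -> MutantSpec:
    """Bounded 1-D search of a reaction's capacity maximising the AA titer.

    Returns the optimum within [original/bound_fold, original*bound_fold];
    band edges are evaluated explicitly so a monotone objective yields the
    exact bound.  Candidates whose simulation fails are rejected (logged)
    and scored as zero titer.
    """
    slot = _capacity_slot(model, reaction)
    original = kinetics.capacity(model.get_reaction(reaction).params)

    def titer(fold: float) -> float:
        trial = model.copy()
        trial.get_reaction(reaction).params[slot] *= fold
        try:
            traj = simulate(trial, duration=horizon, reltol=reltol, abstol=1e-9, n_points=13)
            return traj.final_titer_gL(objective_species)
        except IntegrationError as err:
            log.warning("candidate %s x%.4g rejected: %s", reaction, fold, err)
            return 0.0

    if bound_fold == 1.0:
        return MutantSpec(0, reaction, original, original, 1.0, titer(1.0))

    lo, hi = -np.log10(bound_fold), np.log10(bound_fold)
    res = minimize_scalar(
        lambda x: -titer(10.0**x), bounds=(lo, hi), method="bounded",
        options={"xatol": log10_xatol},
    )
    cands = {10.0**lo: None, 10.0**hi: None, 10.0**float(res.x): None}
    best_fold, best_val = None, -np.inf
    for fold in cands:
        val = titer(fold)
        if val > best_val + 1e-12:
            best_fold, best_val = fold, val
    new = original * best_fold
    return MutantSpec(0, reaction, original, new, best_fold, best_val)


def _carbon_exhausted(model: KineticModel, horizon: float, reltol=1e-7) -> bool:
    carbon = "GLCx" if model.get_species("GLCx").initial_concentration > 0 else "GLYx"
    traj = simulate(model, duration=horizon, reltol=reltol, abstol=1e-9, n_points=13)
    init = model.get_species(carbon).initial_concentration
    return traj.final(carbon) < 1e-3 * init


def design_loop(
    model: KineticModel,
    max_iter: int = 5,
    horizon: float = 10800.0,
    bound_fold: float = 50.0,
    target_flux: str = "AcoaTioE",
    objective_species: str = "AAx",
    fcc_method: str = "structural",
    feed_rate: float | None = None,
    drain_k: float = 0.01,
) -> list[MutantSpec]:
    """Alternate control analysis (continuous) and capacity search (batch).

    Stop reasons recorded on the last mutant: ``no_steady_state`` (the
    continuous mutant fails the next MCA), ``already_optimised`` (the top
    |FCC| reaction was already edited), ``feed_limited`` (carbon source is
    exhausted before the horizon and relaxing the bound buys < 1e-4
    relative titer), or ``max_iterations``.
    """
    current = model.copy()
    edited: list[str] = []
    mutants: list[MutantSpec] = []

    for it in range(1, max_iter + 1):
        cont = make_continuous(current, feed_rate=feed_rate, drain_k=drain_k)
        try:
            ss = find_steady_state(cont)
            fcc = flux_control_coefficients(
                cont, ss, target_flux, compute_fd=(fcc_method == "fd")
            )
        except (NoSteadyStateError, UnstableSteadyStateError) as err:
            log.info("iteration %d: %s", it, err)
            if mutants:
                mutants[-1].stop_reason = "no_steady_state"
            else:
                mutants.append(
                    MutantSpec(it, "", np.nan, np.nan, np.nan, np.nan, "no_steady_state")
                )
            return mutants

        rid, direction = select_target(fcc, method=fcc_method)
        if rid in edited:
            mutants[-1].stop_reason = "already_optimised"
            return mutants

        spec = optimise_vmax(
            current, rid, horizon=horizon, bound_fold=bound_fold,
            objective_species=objective_species,
        )
        spec.iteration = it
        if mutants and spec.objective_gL < mutants[-1].objective_gL - 1e-9:
            # objective may never decrease across accepted iterations
            mutants[-1].stop_reason = "already_optimised"
            return mutants
        slot = _capacity_slot(current, rid)
        current.get_reaction(rid).params[slot] *= spec.fold_change
        edited.append(rid)
        mutants.append(spec)
        log.info(
            "iteration %d: %s %s-expressed x%.3g -> %.4g g/L",
            it, rid, direction, spec.fold_change, spec.objective_gL,
        )

        if _carbon_exhausted(current, horizon):
            # relaxing the capacity a further 1% must buy essentially nothing
            probe = current.copy()
            probe.get_reaction(rid).params[slot] *= 1.01
            try:
                probe_titer = simulate(
                    probe, duration=horizon, reltol=1e-7, abstol=1e-9, n_points=13
                ).final_titer_gL(objective_species)
            except IntegrationError:
                probe_titer = spec.objective_gL
            gain = (probe_titer - spec.objective_gL) / max(spec.objective_gL, 1e-12)
            log.info("carbon exhausted before horizon; bound-relaxation gain %.3e", gain)
            if gain < 1e-4:
                spec.stop_reason = "feed_limited"
                return mutants

    mutants[-1].stop_reason = "max_iterations"
    return mutants
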