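"""Time-course simulation, steady-state finding and metabolic control analysis.

Batch time courses integrate the assembled mass balances with a stiff
solver (BDF by default; LSODA selectable).  Steady states are located by
integrating towards equilibrium and polishing with a Newton-type root solve
on the conservation-reduced system (the link-matrix reduction removes the
singular directions contributed by conserved moieties such as NAD(H) or the
adenylate pool).  Flux control coefficients for a target flux are computed
two interchangeable ways: structurally, from the elasticity matrix and the
reduced Jacobian, and by central finite differences on 1% enzyme-activity
modulations with a re-solved steady state; the summation theorem
(sum_i C^J_i = 1) is the built-in cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy
from scipy.integrate import solve_ivp

from .network import KineticModel, assemble_odes, convert_concentration

__all__ = [
    "Trajectory",
    "SteadyState",
    "FCCTable",
    "IntegrationError",
    "NoSteadyStateError",
    "UnstableSteadyStateError",
    "simulate",
    "find_steady_state",
    "flux_control_coefficients",
    "elasticities",
    "link_matrix",
]

log = logging.getLogger(__name__)

HEADLINE = {"GLCx": "glucose", "GLYx": "glycerol", "HPx": "3-HP", "AAx": "AA"}


class IntegrationError(RuntimeError):
    def __init__(self, message, last_time=None):
        super().__init__(message)
        self.last_time = last_time


class NoSteadyStateError(RuntimeError):
    """The model offers no (reachable, non-negative) steady state."""


class UnstableSteadyStateError(RuntimeError):
    """Steady state found but dynamically unstable; control analysis refused."""


@dataclass
class Trajectory:
    time: np.ndarray  # seconds
    conc: pd.DataFrame  # mM, one column per free species
    flux: pd.DataFrame  # mM/s, one column per reaction
    annotations: dict = field(default_factory=dict)

    def final(self, species: str) -> float:
        return max(float(self.conc[species].iloc[-1]), 0.0)

    def final_titer_gL(self, species: str, compound: str | None = None) -> float:
        compound = compound or HEADLINE[species]
        return convert_concentration(self.final(species), "mM_to_g_per_L", compound)

    def to_csv(self, path) -> None:
        out = self.conc.clip(lower=0.0).copy()
        out.insert(0, "time_s", self.time)
        out.to_csv(path, index=False)

    def headline_report(self) -> pd.DataFrame:
        """Time in hours and g/L for the headline extracellular species."""
        rows = {"time_h": self.time / 3600.0}
        for sid, compound in HEADLINE.items():
            if sid in self.conc:
                rows[f"{sid}_gL"] = [
                    convert_concentration(max(v, 0.0), "mM_to_g_per_L", compound)
                    for v in self.conc[sid]
                ]
        return pd.DataFrame(rows)


@dataclass
class SteadyState:
    conc: dict[str, float]  # full concentration map, fixed species included
    fluxes: dict[str, float]
    residual: float  # ||rhs||_inf in mM/s
    stable: bool
    max_eig_real: float
    free_ids: list[str] = field(default_factory=list)

    def flux(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FCCTable:
    target: str
    table: pd.DataFrame  # columns: reaction, fcc_structural, fcc_fd

    def coefficients(self, method: str = "structural") -> pd.Series:
        col = {"structural": "fcc_structural", "fd": "fcc_fd"}[method]
        return self.table.set_index("reaction")[col]

    def summation(self, method: str = "structural") -> float:
        return float(self.coefficients(method).sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def simulate(
    model: KineticModel,
    duration: float = 10800.0,
    reltol: float = 1e-8,
    abstol: float = 1e-10,
    n_points: int = 241,
    activities=None,
    method: str = "BDF",
) -> Trajectory:
    """Stiff batch time course of ``duration`` seconds.

    The default integrator is BDF; ``method="LSODA"`` selects the classic
    stiff/non-stiff switching solver (same trajectories to well below the
    reporting precision, at a large step-count premium on this system).
    """
    rhs, flux_fn, free_ids = assemble_odes(model, activities)
    y0 = np.array([model.get_species(sid).initial_concentration for sid in free_ids])
    t_eval = np.linspace(0.0, duration, n_points)
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(
                rhs, (0.0, duration), y0, method=method, t_eval=t_eval,
                rtol=reltol, atol=abstol,
            )
    except (ValueError, FloatingPointError) as err:
        # a diverging trajectory can poison the implicit solver's LU factor
        raise IntegrationError(f"integration failed: {err}") from err
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message}",
            last_time=float(sol.t[-1]) if sol.t.size else 0.0,
        )
    conc = pd.DataFrame(sol.y.T, columns=free_ids)
    flux = pd.DataFrame(
        np.array([flux_fn(y) for y in sol.y.T]), columns=[r.id for r in model.reactions]
    )
    ann = dict(model.annotations)
    ann["duration_s"] = str(duration)
    return Trajectory(time=sol.t, conc=conc, flux=flux, annotations=ann)


# --------------------------------------------------------------------------
# conservation analysis / steady state
# --------------------------------------------------------------------------

def link_matrix(N: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Independent-species rows and link matrix L with N = L @ N[indep].

    Exact rational row reduction (stoichiometries are small integers), so
    conserved-moiety structure is detected without numerical thresholds.
    """
    M = sympy.Matrix(N).T  # columns of M = rows of N
    _, pivots = M.rref()
    indep = list(pivots)
    N_I = N[indep, :]
    # exact solve of L @ N_I = N  (rows of N_I span the row space)
    L_T, _ = np.linalg.lstsq(N_I.T, N.T, rcond=None)[:2]
    L = L_T.T
    # embedded identity rows for the independent species
    for k, i in enumerate(indep):
        L[i, :] = 0.0
        L[i, k] = 1.0
    return indep, L


def _integrate_towards_ss(rhs, y0, tol, max_time=2.0e6):
    y = np.array(y0, dtype=float)
    t_chunk, total = 2000.0, 0.0
    best = y
    while total < max_time:
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                sol = solve_ivp(rhs, (0.0, t_chunk), y, method="BDF", rtol=1e-9, atol=1e-11)
        except (ValueError, FloatingPointError):
            break
        if not sol.success:
            break
        y = sol.y[:, -1]
        best = y
        total += t_chunk
        if np.max(np.abs(rhs(0.0, y))) < tol:
            break
        t_chunk = min(t_chunk * 2.0, 2.5e5)
    return best


def find_steady_state(
    model: KineticModel,
    guess=None,
    activities=None,
    tol: float = 1e-10,
    require_stable: bool = False,
) -> SteadyState:
    """Locate a non-negative steady state of the (continuous) model.

    Integration towards equilibrium, then Newton polish in log space on the
    conservation-reduced coordinates.  Raises :class:`NoSteadyStateError`
    when the residual cannot be brought under ``max(tol, 1e-8)`` or the
    root leaves the positive orthant.
    """
    from scipy.optimize import root

    rhs, flux_fn, free_ids = assemble_odes(model, activities)
    N, sids, rids = model.stoichiometric_matrix()
    assert sids == free_ids
    indep, L = link_matrix(N)
    dep = [i for i in range(len(free_ids)) if i not in indep]

    if guess is None:
        y0 = np.array([model.get_species(s).initial_concentration for s in free_ids])
        y0 = _integrate_towards_ss(rhs, np.maximum(y0, 1e-9), tol)
    else:
        y0 = np.array([max(guess[s], 1e-12) for s in free_ids])

    accept = max(tol, 1e-8)

    def polish(y_start):
        # dependent species are affine in the independent ones along a trajectory
        offset = y_start - L @ y_start[indep]

        def g(z):
            with np.errstate(over="ignore", invalid="ignore"):
                y = offset + L @ np.exp(np.clip(z, -60.0, 60.0))
                v = N[indep, :] @ flux_fn(y)
            return np.where(np.isfinite(v), v, 1e6)

        z0 = np.log(np.maximum(y_start[indep], 1e-12))
        sol = root(g, z0, method="hybr", options={"xtol": 1e-13})
        y = offset + L @ np.exp(np.clip(sol.x, -60.0, 60.0))
        if np.all(np.isfinite(y)) and np.all(y > -1e-9):
            return y, float(np.max(np.abs(rhs(0.0, y))))
        return y_start, np.inf

    def admissible(y_cand):
        # clamp integrator-level negatives; anything grossly negative is invalid
        if np.any(y_cand < -1e-6) or not np.all(np.isfinite(y_cand)):
            return None
        return np.maximum(y_cand, 0.0)

    candidates = [polish(y0)]
    if candidates[0][1] > accept:
        # re-approach by integration (essential when a warm-start guess sits in
        # a different basin after a parameter perturbation), then re-polish
        y1 = _integrate_towards_ss(rhs, np.maximum(y0, 1e-12), tol, max_time=5.0e5)
        candidates.append((y1, float(np.max(np.abs(rhs(0.0, y1))))))
        candidates.append(polish(y1))
    y, resid = None, np.inf
    for y_cand, r_cand in candidates:
        yc = admissible(y_cand)
        if yc is not None and r_cand < resid:
            y, resid = yc, r_cand
    if y is None or resid > accept:
        raise NoSteadyStateError(
            f"no steady state: residual {resid:.3e} mM/s after Newton polish"
        )
    y = np.maximum(y, 0.0)

    E = _dv_ds(flux_fn, y)
    J_red = N[indep, :] @ E @ L
    eigs = np.linalg.eigvals(J_red)
    max_re = float(np.max(eigs.real)) if eigs.size else -np.inf
    stable = max_re < 1e-9
    if require_stable and not stable:
        raise UnstableSteadyStateError(f"max Re(eig) = {max_re:.3e} > 0")

    conc = {s.id: s.initial_concentration for s in model.species}
    conc.update({sid: float(v) for sid, v in zip(free_ids, y)})
    v = flux_fn(y)
    return SteadyState(
        conc=conc,
        fluxes={rid: float(val) for rid, val in zip(rids, v)},
        residual=resid,
        stable=stable,
        max_eig_real=max_re,
        free_ids=list(free_ids),
    )


def _dv_ds(flux_fn, y, rel=1e-6, floor=1e-9):
    """Unscaled elasticity matrix dv/ds by central differences."""
    v0 = flux_fn(y)
    E = np.zeros((v0.size, y.size))
    for i in range(y.size):
        h = max(abs(y[i]) * rel, floor)
        yp, ym = y.copy(), y.copy()
        yp[i] += h
        ym[i] = max(ym[i] - h, 0.0)
        E[:, i] = (flux_fn(yp) - flux_fn(ym)) / (yp[i] - ym[i])
    return E


def elasticities(model: KineticModel, steady: SteadyState, activities=None) -> pd.DataFrame:
    """Scaled elasticities eps_{v,S} = (S/v) dv/dS at the steady state."""
    _, flux_fn, free_ids = assemble_odes(model, activities)
    y = np.array([steady.conc[s] for s in free_ids])
    E = _dv_ds(flux_fn, y)
    v = flux_fn(y)
    rids = [r.id for r in model.reactions]
    scaled = np.zeros_like(E)
    for j in range(len(rids)):
        for i in range(len(free_ids)):
            if abs(v[j]) > 1e-15:
                scaled[j, i] = E[j, i] * y[i] / v[j]
    return pd.DataFrame(scaled, index=rids, columns=free_ids)


def flux_control_coefficients(
    model: KineticModel,
    steady: SteadyState,
    target: str,
    activities=None,
    fd_delta: float = 0.01,
    compute_fd: bool = True,
) -> FCCTable:
    """Flux control coefficients of every reaction over the target flux.

    Refuses unstable steady states (a subsequent mutant-design step would
    be meaningless); both the structural and the finite-difference route
    are reported so they can cross-check each other.
    """
    if not steady.stable:
        raise UnstableSteadyStateError(
            "steady state is unstable; flux control coefficients not available"
        )
    base_act = {r.id: 1.0 for r in model.reactions}
    if activities:
        base_act.update(activities)
    rids = [r.id for r in model.reactions]
    J = steady.fluxes[target]
    if abs(J) < 1e-15:
        raise ValueError(f"target flux {target!r} is zero at the steady state")

    # structural: C^J = I + E C^S with C^S = -L (N_I E L)^-1 N_I
    _, flux_fn, free_ids = assemble_odes(model, base_act)
    N, sids, _ = model.stoichiometric_matrix()
    indep, L = link_matrix(N)
    y = np.array([steady.conc[s] for s in free_ids])
    E = _dv_ds(flux_fn, y)
    v = flux_fn(y)
    M = N[indep, :] @ E @ L
    CS = -L @ np.linalg.solve(M, N[indep, :])
    CJ = np.eye(len(rids)) + E @ CS
    t_idx = rids.index(target)
    structural = np.array(
        [CJ[t_idx, i] * v[i] / v[t_idx] for i in range(len(rids))]
    )

    # finite differences: 1% activity modulation, re-solved steady state
    fd = np.full(len(rids), np.nan)
    for i, rid in enumerate(rids) if compute_fd else ():
        try:
            acts_p = dict(base_act)
            acts_p[rid] = base_act[rid] * (1.0 + fd_delta)
            ss_p = find_steady_state(model, guess=steady.conc, activities=acts_p)
            acts_m = dict(base_act)
            acts_m[rid] = base_act[rid] * (1.0 - fd_delta)
            ss_m = find_steady_state(model, guess=steady.conc, activities=acts_m)
            jp, jm = ss_p.fluxes[target], ss_m.fluxes[target]
            if jp > 0 and jm > 0:
                fd[i] = (np.log(jp) - np.log(jm)) / (
                    np.log1p(fd_delta) - np.log1p(-fd_delta)
                )
            else:
                fd[i] = ((jp - jm) / J) / (2.0 * fd_delta)
        except NoSteadyStateError:
            log.warning("finite-difference FCC: no steady state when perturbing %s", rid)
    table = pd.DataFrame(
        {"reaction": rids, "fcc_structural": structural, "fcc_fd": fd}
    )
    return FCCTable(target=target, table=table)
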