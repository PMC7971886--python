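"""Closed-form enzyme rate laws for the central-carbon-metabolism extension.

Every mechanism used by the native-extension and heterologous reactions
(glycerol, malonyl-CoA and beta-alanine routes towards 3-hydroxypropionate
and acrylic acid) is available as a named closed form.  A rate law is
evaluated from two plain mappings:

* ``params`` — kinetic constants by slot name (``Km_a``, ``Ki_b``, ``Keq``,
  ``n``, and exactly one capacity specification: either ``Vmax`` [mM/s],
  or ``Kcat`` [1/s] together with ``E_total`` [mM], or ``k`` for mass
  action);
* ``conc`` — concentrations by *role* (``A``, ``B``, ``C``, ``P``, ``Q``,
  ``Activator``), all in mM.

Rates are returned in mM/s.  Irreversible mechanisms are non-negative for
non-negative inputs; reversible mechanisms (those with a ``Keq`` slot)
vanish exactly on the equilibrium manifold ``A*B == P*Q/Keq``.

The saturation factor ``F`` is defined by ``rate == capacity * F``; for the
irreversible saturating mechanisms ``0 <= F <= 1``, which is what the
FVA-based Vmax estimation divides by.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

__all__ = [
    "RateLaw",
    "RateLawError",
    "IncompleteBindingError",
    "ConcentrationDomainError",
    "MECHANISMS",
    "mechanism_roles",
    "capacity",
    "evaluate",
    "saturation_factor",
    "validate_params",
]


class RateLawError(ValueError):
    """Base class for rate-law evaluation problems."""


class IncompleteBindingError(RateLawError, KeyError):
    """A role or parameter slot required by the mechanism is missing."""


class ConcentrationDomainError(RateLawError):
    """A concentration outside the physical domain (negative) was supplied."""


@dataclass(frozen=True)
class RateLaw:
    """Descriptor of a kinetic mechanism.

    ``saturation`` maps ``(params, conc-by-role)`` to the dimensionless
    factor F; the rate is ``capacity(params) * F``.
    """

    mechanism_id: str
    roles: tuple[str, ...]
    parameter_slots: tuple[str, ...]
    saturation: Callable[[Mapping[str, float], Mapping[str, float]], float]
    reversible: bool = False
    optional_slots: Mapping[str, str] = field(default_factory=dict)  # slot -> fallback slot
    optional_roles: tuple[str, ...] = ()


def _sat_mm_1s(p, c):
    return c["A"] / (p["Km"] + c["A"])


def _sat_mm_2s(p, c):
    return (c["A"] / (p["Km_a"] + c["A"])) * (c["B"] / (p["Km_b"] + c["B"]))


def _sat_mm_3s(p, c):
    return (
        (c["A"] / (p["Km_a"] + c["A"]))
        * (c["B"] / (p["Km_b"] + c["B"]))
        * (c["C"] / (p["Km_c"] + c["C"]))
    )


def _sat_random_bibi_denominator(p, c):
    # Random bi-bi with a single composite denominator; Kd_a falls back to
    # Km_a when the dissociation constant is not separately reported.
    kda = p.get("Kd_a", p["Km_a"])
    a, b = c["A"], c["B"]
    return a * b / (kda * p["Km_b"] + p["Km_b"] * a + p["Km_a"] * b + a * b)


def _sat_competitive_product_inhibition_2s(p, c):
    a, b, prod = c["A"], c["B"], c["P"]
    return (a / (p["Km_a"] * (1.0 + prod / p["Ki_p"]) + a)) * (b / (p["Km_b"] + b))


def _sat_re_random_bibi_reversible(p, c):
    a, b, prod, q = c["A"], c["B"], c["P"], c["Q"]
    num = (a * b - prod * q / p["Keq"]) / (p["Km_a"] * p["Km_b"])
    den = (
        (1.0 + a / p["Km_a"]) * (1.0 + b / p["Km_b"])
        + (1.0 + prod / p["Km_p"]) * (1.0 + q / p["Km_q"])
        - 1.0
    )
    return num / den


def _sat_ping_pong_bibi_reversible(p, c):
    a, b, prod, q = c["A"], c["B"], c["P"], c["Q"]
    num = (a * b - prod * q / p["Keq"]) / (p["Km_a"] * p["Km_b"])
    den = (1.0 + a / p["Km_a"] + q / p["Km_q"]) * (1.0 + b / p["Km_b"] + prod / p["Km_p"])
    return num / den


def _sat_ping_pong_substrate_inhibition(p, c):
    a, b = c["A"], c["B"]
    if a == 0.0 or b == 0.0:
        return 0.0  # removable singularity: rate -> 0 along every path to the origin
    return a * b / (p["Km_b"] * a + p["Km_a"] * b * (1.0 + b / p["Ki_b"]) + a * b)


def _sat_hill_2s(p, c):
    n = p["n"]
    a, b = c["A"], c["B"]
    return (a**n / (p["Km_a"] ** n + a**n)) * (b**n / (p["Km_b"] ** n + b**n))


def _sat_specific_activation(p, c):
    a, act = c["A"], c["Activator"]
    return a * act / (p["Km_a"] * p["Ka"] + (p["Km_a"] + a) * act)


def _sat_mass_action(p, c):
    # product over every bound substrate role; a feed reaction binds none
    # and runs at constant rate k.
    out = 1.0
    for role in ("A", "B", "C"):
        if role in c:
            out *= c[role]
    return out


MECHANISMS: dict[str, RateLaw] = {
    law.mechanism_id: law
    for law in (
        RateLaw("michaelis_menten_1s", ("A",), ("Km",), _sat_mm_1s),
        RateLaw("mm_2s_multiplicative", ("A", "B"), ("Km_a", "Km_b"), _sat_mm_2s),
        RateLaw(
            "mm_3s_multiplicative", ("A", "B", "C"), ("Km_a", "Km_b", "Km_c"), _sat_mm_3s
        ),
        RateLaw(
            "mm_2s_random_bibi_denominator",
            ("A", "B"),
            ("Km_a", "Km_b"),
            _sat_random_bibi_denominator,
            optional_slots={"Kd_a": "Km_a"},
        ),
        RateLaw(
            "mm_competitive_product_inhibition_2s",
            ("A", "B", "P"),
            ("Km_a", "Km_b", "Ki_p"),
            _sat_competitive_product_inhibition_2s,
        ),
        RateLaw(
            "ordered_bibi_product_inhibition",
            ("A", "B", "P"),
            ("Km_a", "Km_b", "Ki_p"),
            _sat_competitive_product_inhibition_2s,
        ),
        RateLaw(
            "rapid_equilibrium_random_bibi_reversible",
            ("A", "B", "P", "Q"),
            ("Km_a", "Km_b", "Km_p", "Km_q", "Keq"),
            _sat_re_random_bibi_reversible,
            reversible=True,
        ),
        RateLaw(
            "ping_pong_bibi_reversible",
            ("A", "B", "P", "Q"),
            ("Km_a", "Km_b", "Km_p", "Km_q", "Keq"),
            _sat_ping_pong_bibi_reversible,
            reversible=True,
        ),
        RateLaw(
            "ping_pong_bibi_substrate_inhibition",
            ("A", "B"),
            ("Km_a", "Km_b", "Ki_b"),
            _sat_ping_pong_substrate_inhibition,
        ),
        RateLaw("hill_2s", ("A", "B"), ("Km_a", "Km_b", "n"), _sat_hill_2s),
        RateLaw("specific_activation", ("A", "Activator"), ("Km_a", "Ka"), _sat_specific_activation),
        RateLaw(
            "mass_action",
            ("A",),
            (),
            _sat_mass_action,
            optional_roles=("A", "B", "C"),
        ),
    )
}

#: slots whose values must be non-negative when present
_NONNEG_PREFIXES = ("Km", "Kd", "Ki", "Ka", "Keq")
_CAPACITY_SLOTS = ("Vmax", "Kcat", "E_total", "k")


def mechanism_roles(mechanism_id: str) -> tuple[str, ...]:
    """Substrate/product roles the mechanism binds, in canonical order."""
    return _law(mechanism_id).roles


def _law(mechanism_id: str) -> RateLaw:
    try:
        return MECHANISMS[mechanism_id]
    except KeyError:
        raise RateLawError(f"unknown mechanism {mechanism_id!r}") from None


def capacity(params: Mapping[str, float]) -> float:
    """The linear capacity factor of a rate law.

    ``Vmax`` [mM/s] if present, else ``E_total * Kcat``, else the mass-action
    constant ``k``.  Raising the capacity x-fold raises every rate x-fold.
    """
    if "Vmax" in params:
        return float(params["Vmax"])
    if "Kcat" in params and "E_total" in params:
        return float(params["Kcat"]) * float(params["E_total"])
    if "k" in params:
        return float(params["k"])
    raise IncompleteBindingError("Vmax (or Kcat+E_total, or k)")


def validate_params(mechanism_id: str, params: Mapping[str, float]) -> None:
    """Check presence, finiteness and sign of every referenced slot."""
    law = _law(mechanism_id)
    for slot in law.parameter_slots:
        if slot not in params and slot not in law.optional_slots:
            raise IncompleteBindingError(f"{mechanism_id}: missing parameter slot {slot!r}")
    for slot, value in params.items():
        v = float(value)
        if not math.isfinite(v):
            raise RateLawError(f"{mechanism_id}: non-finite value for {slot!r}")
        if slot.startswith(_NONNEG_PREFIXES) or slot in _CAPACITY_SLOTS:
            if v < 0:
                raise RateLawError(f"{mechanism_id}: {slot!r} must be >= 0, got {v}")
        if slot == "n" and v <= 0:
            raise RateLawError(f"{mechanism_id}: Hill coefficient n must be > 0, got {v}")
    capacity(params)  # raises if no capacity specification


def _bound_conc(law: RateLaw, conc: Mapping[str, float]) -> dict[str, float]:
    roles = law.roles if law.mechanism_id != "mass_action" else law.optional_roles
    out: dict[str, float] = {}
    for role in roles:
        if role not in conc:
            if law.mechanism_id == "mass_action":
                continue  # mass action binds any subset of A, B, C
            raise IncompleteBindingError(
                f"{law.mechanism_id}: no concentration bound for role {role!r}"
            )
        v = float(conc[role])
        if v < 0:
            raise ConcentrationDomainError(
                f"{law.mechanism_id}: negative concentration for role {role!r}: {v}"
            )
        out[role] = v
    return out


def saturation_factor(
    mechanism_id: str, params: Mapping[str, float], conc: Mapping[str, float]
) -> float:
    """Dimensionless factor F with ``rate == capacity(params) * F``.

    For irreversible saturating mechanisms 0 <= F <= 1 (F -> 1 as every
    substrate saturates); reversible mechanisms may return negative F.  For
    mass action F is the (dimensionful) concentration product.
    """
    law = _law(mechanism_id)
    validate_params(mechanism_id, params)
    bound = _bound_conc(law, conc)
    f = law.saturation(params, bound)
    if not math.isfinite(f):
        raise RateLawError(f"{mechanism_id}: non-finite saturation factor")
    return f


def evaluate(
    mechanism_id: str, params: Mapping[str, float], conc: Mapping[str, float]
) -> float:
    """Reaction rate in mM/s."""
    return capacity(params) * saturation_factor(mechanism_id, params, conc)
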