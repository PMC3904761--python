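"""Dependency kinds: role signatures and executable residual equations.

Each registered kind is the executable form of one physical-law class from
the dependency taxonomy (t = time; all quantities in canonical units):

====================  =====================================================
boundary_flow         d(amount)/dt = Σ inflow − Σ outflow
boundary_force        d(momentum)/dt = Σ force_high − Σ force_low
summation             whole_amount = Σ part_amounts
spatial               derived_state = a · primary_state^b
resistive             flow = (force_high − force_low) / R        (Ohm analogue)
mass_action           flow = k_f·Π fwd^s − k_r·Π rev^s
diffusion             flow = k_d · (amount_high − amount_low)    (Fick analogue)
michaelis_menten      flow = V_max · amount / (K_m + amount)
transformer           force_2 = m·force_1 ; flow_1 = m·flow_2
transducer            same equations, the two sides in distinct domains
capacitive            force = amount / C                        (Hooke analogue)
inductive             flow = momentum / L
transactor            target = c · source                       (wild card)
====================  =====================================================

Sign convention, used everywhere: positive flow runs from the "high" to the
"low" force player (and from the diffusion/mass-action source side to the
target side).  Inductive storage is factored as flow = momentum/L plus a
separate boundary_force dependency accumulating the momentum, the standard
network-thermodynamics decomposition that makes the storage row realizable
in an ODE formalism.

Only ideal proportional laws plus the Michaelis-Menten hook are registered;
non-proportional conductances (Hodgkin-Huxley gating, shear-dependent
viscosity) are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import (
    BadConstitutiveError,
    BadStateError,
    MissingRoleError,
    NegativeStateError,
)

# Tolerance below which an amount is treated as "gone negative" during
# integration rather than as round-off.
NEGATIVE_AMOUNT_TOL = 1e-9


# ---------------------------------------------------------------------------
# Elementary law evaluations
# ---------------------------------------------------------------------------


def resistive_flow(force_high: float, force_low: float, R: float) -> float:
    """Ohm-analogue flow through an ideal resistive element.

    flow = (force_high − force_low)/R; positive flow runs high -> low.
    Antisymmetric in the two force players.
    """
    if R <= 0:
        raise BadConstitutiveError(f"resistance must be > 0, got {R}")
    return (force_high - force_low) / R


def capacitive_force(amount: float, C: float) -> float:
    """Hooke-analogue force of a capacitive storage element: force = amount/C.

    Monotone increasing in the stored amount (more blood, more pressure).
    """
    if C <= 0:
        raise BadConstitutiveError(f"capacitance must be > 0, got {C}")
    return amount / C


def inductive_flow(momentum: float, L: float) -> float:
    """Flow sustained by inertial storage: flow = momentum/L."""
    if L <= 0:
        raise BadConstitutiveError(f"inductance must be > 0, got {L}")
    return momentum / L


def diffusion_flow(amount_high: float, amount_low: float, k_d: float) -> float:
    """Fick-analogue amount-driven flow: k_d · (amount_high − amount_low)."""
    if k_d <= 0:
        raise BadConstitutiveError(f"diffusion rate constant must be > 0, got {k_d}")
    return k_d * (amount_high - amount_low)


def mass_action_flow(
    fwd_amounts: Sequence[float],
    rev_amounts: Sequence[float],
    k_f: float,
    k_r: float,
    stoich_fwd: Optional[Sequence[float]] = None,
    stoich_rev: Optional[Sequence[float]] = None,
) -> float:
    """Net mass-action reaction flux k_f·Π fwd^s − k_r·Π rev^s.

    Vanishes exactly at detailed balance.  Amounts more negative than the
    round-off tolerance raise :class:`NegativeStateError`.
    """
    if k_f < 0 or k_r < 0:
        raise BadConstitutiveError("rate constants must be >= 0")
    stoich_fwd = stoich_fwd if stoich_fwd is not None else [1.0] * len(fwd_amounts)
    stoich_rev = stoich_rev if stoich_rev is not None else [1.0] * len(rev_amounts)

    def product(amounts: Sequence[float], stoich: Sequence[float]) -> float:
        p = 1.0
        for a, s in zip(amounts, stoich):
            if a < -NEGATIVE_AMOUNT_TOL:
                raise NegativeStateError(f"amount {a} < 0 in mass-action law")
            p *= max(a, 0.0) ** s
        return p

    return k_f * product(fwd_amounts, stoich_fwd) - k_r * product(rev_amounts, stoich_rev)


def michaelis_menten_flow(amount: float, v_max: float, k_m: float) -> float:
    """Saturating enzyme flux V_max·amount/(K_m + amount).

    The single sanctioned non-proportional kind; V_max and K_m are its two
    empirical coefficients.
    """
    if v_max <= 0 or k_m <= 0:
        raise BadConstitutiveError("V_max and K_m must be > 0")
    if amount < -NEGATIVE_AMOUNT_TOL:
        raise NegativeStateError(f"amount {amount} < 0 in Michaelis-Menten law")
    return v_max * amount / (k_m + amount)


def transformer_pair(force_1: float, flow_2: float, m: float) -> Tuple[float, float]:
    """Ideal transformer coupling: returns (force_2, flow_1) = (m·force_1, m·flow_2).

    Power is conserved exactly: force_1·flow_1 == force_2·flow_2.
    """
    if m == 0:
        raise BadConstitutiveError("transformer modulus must be nonzero")
    return m * force_1, m * flow_2


def transactor_value(source: float, c: float) -> float:
    """Proportional wild-card dependency: target = c·source."""
    return c * source


def summation_value(parts: Sequence[float]) -> float:
    """Whole = sum of proper parts (instantaneous state dependency).

    Uses a correctly rounded sum, so the result is exactly invariant under
    permutation of the parts.
    """
    if len(parts) == 0:
        raise MissingRoleError("summation requires at least one part player")
    return math.fsum(parts)


def spatial_value(primary: float, a: float, b: float) -> float:
    """Instantaneous spatial state map: derived = a·primary^b.

    Non-integer exponents require a non-negative primary state.
    """
    if primary < 0 and b != int(b):
        raise BadStateError(
            f"primary state {primary} < 0 with non-integer exponent {b}"
        )
    return a * primary ** b


# ---------------------------------------------------------------------------
# Kind registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoleSpec:
    """Constraints on one role of a dependency kind.

    ``categories`` is a frozenset of admissible category ids (empty = any);
    ``min_count``/``max_count`` bound the number of bindings (max None =
    unbounded); ``side`` groups roles for the transducer two-domain rule.
    """

    categories: frozenset
    min_count: int = 1
    max_count: Optional[int] = 1
    side: int = 0


@dataclass(frozen=True)
class DependencyKind:
    """Signature and causal form of one dependency class."""

    id: str
    opb_label: str
    roles: Dict[str, RoleSpec]
    outputs: Tuple[str, ...]            # causal output roles; () for boundary kinds
    domain_rule: str                    # 'same' | 'cross' | 'any'
    state_role: Optional[str] = None    # boundary kinds: the accumulated state player
    param_names: Tuple[str, ...] = ()

    @property
    def is_boundary(self) -> bool:
        return self.state_role is not None


def _cats(*names: str) -> frozenset:
    return frozenset(names)


_ANY = frozenset()

KINDS: Dict[str, DependencyKind] = {}


def _register(kind: DependencyKind) -> DependencyKind:
    KINDS[kind.id] = kind
    return kind


_register(DependencyKind(
    id="boundary_flow",
    opb_label="Boundary flow dependency",
    roles={
        "amount_player": RoleSpec(_cats("amount")),
        "inflow": RoleSpec(_cats("flow"), 0, None),
        "outflow": RoleSpec(_cats("flow"), 0, None),
    },
    outputs=(),
    domain_rule="same",
    state_role="amount_player",
))

_register(DependencyKind(
    id="boundary_force",
    opb_label="Boundary force dependency",
    roles={
        "momentum_player": RoleSpec(_cats("momentum")),
        "force_player_high": RoleSpec(_cats("force"), 0, None),
        "force_player_low": RoleSpec(_cats("force"), 0, None),
    },
    outputs=(),
    domain_rule="same",
    state_role="momentum_player",
))

_register(DependencyKind(
    id="summation",
    opb_label="Summation dependency",
    roles={
        "whole_player": RoleSpec(_cats("amount")),
        "part_player": RoleSpec(_cats("amount"), 1, None),
    },
    outputs=("whole_player",),
    domain_rule="same",
))

_register(DependencyKind(
    id="spatial",
    opb_label="Spatial dependency",
    roles={
        "source_player": RoleSpec(_cats("amount")),
        "target_player": RoleSpec(_cats("amount")),
    },
    outputs=("target_player",),
    domain_rule="any",
    param_names=("a", "b"),
))

_register(DependencyKind(
    id="resistive",
    opb_label="Resistive flow dependency",
    roles={
        "flow_player": RoleSpec(_cats("flow")),
        "force_player_high": RoleSpec(_cats("force")),
        "force_player_low": RoleSpec(_cats("force")),
        "constitutive": RoleSpec(_cats("constitutive.resistance", "constitutive.conductance")),
    },
    outputs=("flow_player",),
    domain_rule="same",
))

_register(DependencyKind(
    id="mass_action",
    opb_label="Chemical mass-action rate dependency",
    roles={
        "flow_player": RoleSpec(_cats("flow")),
        "source_player": RoleSpec(_cats("amount"), 0, None),
        "target_player": RoleSpec(_cats("amount"), 0, None),
        "constitutive": RoleSpec(_cats("constitutive.rate_constant"), 1, 2),
    },
    outputs=("flow_player",),
    domain_rule="same",
))

_register(DependencyKind(
    id="diffusion",
    opb_label="Diffusion gradient rate dependency",
    roles={
        "flow_player": RoleSpec(_cats("flow")),
        "source_player": RoleSpec(_cats("amount")),
        "target_player": RoleSpec(_cats("amount")),
        "constitutive": RoleSpec(_cats("constitutive.rate_constant")),
    },
    outputs=("flow_player",),
    domain_rule="same",
))

_register(DependencyKind(
    id="michaelis_menten",
    opb_label="Michaelis-Menten rate dependency",
    roles={
        "flow_player": RoleSpec(_cats("flow")),
        "amount_player": RoleSpec(_cats("amount")),
    },
    outputs=("flow_player",),
    domain_rule="same",
    param_names=("v_max", "k_m"),
))

_TRANSFORMER_ROLES = {
    "force_player_1": RoleSpec(_cats("force"), side=1),
    "flow_player_1": RoleSpec(_cats("flow"), side=1),
    "force_player_2": RoleSpec(_cats("force"), side=2),
    "flow_player_2": RoleSpec(_cats("flow"), side=2),
    "constitutive": RoleSpec(_cats("constitutive.modulus")),
}

_register(DependencyKind(
    id="transformer",
    opb_label="Mechanical transformer dependency",
    roles=dict(_TRANSFORMER_ROLES),
    outputs=("force_player_2", "flow_player_1"),
    domain_rule="same",
))

_register(DependencyKind(
    id="transducer",
    opb_label="Chemo-mechanical transducer dependency",
    roles=dict(_TRANSFORMER_ROLES),
    outputs=("force_player_2", "flow_player_1"),
    domain_rule="cross",
))

_register(DependencyKind(
    id="capacitive",
    opb_label="Capacitive storage dependency",
    roles={
        "force_player": RoleSpec(_cats("force")),
        "amount_player": RoleSpec(_cats("amount")),
        "constitutive": RoleSpec(_cats("constitutive.capacitance")),
    },
    outputs=("force_player",),
    domain_rule="same",
))

_register(DependencyKind(
    id="inductive",
    opb_label="Inductive flow dependency",
    roles={
        "flow_player": RoleSpec(_cats("flow")),
        "momentum_player": RoleSpec(_cats("momentum")),
        "constitutive": RoleSpec(_cats("constitutive.inductance")),
    },
    outputs=("flow_player",),
    domain_rule="same",
))

_register(DependencyKind(
    id="transactor",
    opb_label="Transactor dependency",
    roles={
        "source_player": RoleSpec(_ANY),
        "target_player": RoleSpec(_ANY),
        "constitutive": RoleSpec(_cats("constitutive.coefficient")),
    },
    outputs=("target_player",),
    domain_rule="any",
))


def get_kind(kind_id: str) -> DependencyKind:
    try:
        return KINDS[kind_id]
    except KeyError:
        raise KeyError(f"unknown dependency kind {kind_id!r}") from None


# ---------------------------------------------------------------------------
# Generic evaluation used by the compiler
# ---------------------------------------------------------------------------


def effective_resistance(category: str, value: float) -> float:
    """Normalize a resistive constitutive binding to a resistance (R = 1/G)."""
    if category == "constitutive.conductance":
        if value <= 0:
            raise BadConstitutiveError(f"conductance must be > 0, got {value}")
        return 1.0 / value
    return value


def evaluate_output(
    kind: DependencyKind,
    output_role: str,
    role_values: Dict[str, List[float]],
    constitutive: List[Tuple[str, float]],
    params: Dict[str, float],
) -> float:
    """Evaluate one causal output of an algebraic dependency.

    ``role_values`` maps role name -> bound values in binding order;
    ``constitutive`` lists (category, value) of constitutive bindings.
    """
    kid = kind.id
    if kid == "resistive":
        cat, val = constitutive[0]
        return resistive_flow(
            role_values["force_player_high"][0],
            role_values["force_player_low"][0],
            effective_resistance(cat, val),
        )
    if kid == "capacitive":
        return capacitive_force(role_values["amount_player"][0], constitutive[0][1])
    if kid == "inductive":
        return inductive_flow(role_values["momentum_player"][0], constitutive[0][1])
    if kid == "diffusion":
        return diffusion_flow(
            role_values["source_player"][0],
            role_values["target_player"][0],
            constitutive[0][1],
        )
    if kid == "mass_action":
        k_f = constitutive[0][1]
        k_r = constitutive[1][1] if len(constitutive) > 1 else 0.0
        return mass_action_flow(
            role_values.get("source_player", []),
            role_values.get("target_player", []),
            k_f,
            k_r,
            params.get("stoich_fwd"),
            params.get("stoich_rev"),
        )
    if kid == "michaelis_menten":
        return michaelis_menten_flow(
            role_values["amount_player"][0], params["v_max"], params["k_m"]
        )
    if kid == "summation":
        return summation_value(role_values["part_player"])
    if kid == "spatial":
        return spatial_value(
            role_values["source_player"][0],
            params.get("a", 1.0),
            params.get("b", 1.0),
        )
    if kid == "transactor":
        return transactor_value(role_values["source_player"][0], constitutive[0][1])
    if kid in ("transformer", "transducer"):
        m = constitutive[0][1]
        if output_role == "force_player_2":
            return transformer_pair(role_values["force_player_1"][0], 0.0, m)[0]
        if output_role == "flow_player_1":
            return transformer_pair(0.0, role_values["flow_player_2"][0], m)[1]
    raise KeyError(f"no evaluator for kind {kid!r} output {output_role!r}")


def output_inputs(kind: DependencyKind, output_role: str) -> Tuple[str, ...]:
    """Role names whose bound values feed the given causal output."""
    if kind.id in ("transformer", "transducer"):
        return ("force_player_1",) if output_role == "force_player_2" else ("flow_player_2",)
    return tuple(
        r for r in kind.roles
        if r not in ("constitutive", output_role)
    )


def boundary_derivative(kind: DependencyKind, role_values: Dict[str, List[float]]) -> float:
    """Net accumulation rate of a boundary dependency's state player."""
    if kind.id == "boundary_flow":
        return sum(role_values.get("inflow", [])) - sum(role_values.get("outflow", []))
    if kind.id == "boundary_force":
        return sum(role_values.get("force_player_high", [])) - sum(
            role_values.get("force_player_low", [])
        )
    raise KeyError(f"{kind.id} is not a boundary kind")
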