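"""Compile a validated model network into an explicit ODE system.

The compiler (1) identifies the state variables — every amount/momentum that
a boundary dependency accumulates; (2) assigns causality — which player each
algebraic dependency computes (capacitors output force, inductors and
resistor-like elements output flow, transformers output (force_2, flow_1),
summation/spatial/transactor output their derived player) — and verifies that
every remaining property is computed exactly once; (3) topologically orders
the algebraic steps; and (4) packages a right-hand-side function that
evaluates sources at t, runs the schedule, and accumulates net flows/forces
into state derivatives.

Algebraic loops (e.g. a resistive cycle with no storage node breaking it) are
rejected with E_ALGEBRAIC_LOOP rather than solved implicitly: under storage
causality every well-posed lumped network schedules explicitly, and honest
failure beats fragile fixed-point iteration.  Transformer causality is fixed
(inputs force_1 and flow_2); a network needing the reverse orientation must
swap its sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from . import laws
from .errors import (
    AlgebraicLoopError,
    NoInitialValueError,
    OverdeterminedError,
    UnderdeterminedError,
)
from .network import ModelNetwork, SourceSpec, has_errors, validate_network
from .taxonomy import category_group

DERIVATIVE = "derivative"


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------


def evaluate_waveform(src: SourceSpec, t: float) -> float:
    """Value of a prescribed source at time t (canonical units)."""
    p = src.params
    if src.waveform == "constant":
        return float(p.get("level", 0.0))
    if src.waveform == "step":
        return float(p.get("level", 0.0)) if t >= p.get("time", 0.0) else float(p.get("base", 0.0))
    if src.waveform == "sine":
        period = float(p.get("period", 1.0))
        return float(p.get("offset", 0.0)) + float(p.get("amplitude", 1.0)) * math.sin(
            2.0 * math.pi * t / period + float(p.get("phase", 0.0))
        )
    raise ValueError(f"unknown waveform {src.waveform!r}")


def is_constant_source(src: SourceSpec) -> bool:
    if src.waveform == "constant":
        return True
    if src.waveform == "step":
        return float(src.params.get("time", 0.0)) <= 0.0
    return False


# ---------------------------------------------------------------------------
# Causality
# ---------------------------------------------------------------------------


def identify_states(net: ModelNetwork) -> List[str]:
    """State vector: boundary-accumulated amounts/momenta, ordered by id.

    Raises E_NO_INITIAL for a state without an initial value.
    """
    states = set()
    for dep in net.dependencies.values():
        kind = laws.KINDS[dep.kind]
        if kind.is_boundary:
            states.update(dep.bound(kind.state_role))
    ordered = sorted(states)
    for pid in ordered:
        if net.properties[pid].value is None:
            raise NoInitialValueError("state lacks an initial value", subject=pid)
    return ordered


def assign_causality(net: ModelNetwork) -> Dict[str, Tuple[str, ...]]:
    """Orient every dependency; verify single-assignment of each property.

    Returns dependency id -> output roles ('derivative' for boundary kinds).
    Raises E_OVERDETERMINED if a property is computed twice (or is also a
    state or a source) and E_UNDERDETERMINED if a non-state, non-source,
    non-parameter property is never computed.
    """
    states = set()
    for dep in net.dependencies.values():
        kind = laws.KINDS[dep.kind]
        if kind.is_boundary:
            states.update(dep.bound(kind.state_role))

    causality: Dict[str, Tuple[str, ...]] = {}
    provider: Dict[str, str] = {}
    state_boundary: Dict[str, str] = {}

    for dep_id in sorted(net.dependencies):
        dep = net.dependencies[dep_id]
        kind = laws.KINDS[dep.kind]
        if kind.is_boundary:
            causality[dep_id] = (DERIVATIVE,)
            for pid in dep.bound(kind.state_role):
                if pid in state_boundary:
                    raise OverdeterminedError(
                        "state accumulated by two boundary dependencies", subject=pid)
                state_boundary[pid] = dep_id
            continue
        causality[dep_id] = kind.outputs
        for role in kind.outputs:
            for pid in dep.bound(role):
                if pid in provider:
                    raise OverdeterminedError(
                        f"property computed by both {provider[pid]} and {dep_id}",
                        subject=pid)
                if pid in states:
                    raise OverdeterminedError(
                        "state property also computed algebraically", subject=pid)
                if pid in net.sources:
                    raise OverdeterminedError(
                        "source property also computed algebraically", subject=pid)
                provider[pid] = dep_id

    for pid in sorted(net.properties):
        prop = net.properties[pid]
        if category_group(prop.prop_class.category) == "constitutive":
            continue
        if prop.fixed and prop.value is not None:
            continue
        if pid in states or pid in net.sources or pid in provider:
            continue
        raise UnderdeterminedError("property is never computed", subject=pid)

    return causality


def build_schedule(net: ModelNetwork,
                   causality: Dict[str, Tuple[str, ...]]) -> List[Tuple[str, str]]:
    """Topologically order the algebraic (dependency, output property) steps.

    Deterministic (ties broken by dependency id); a cycle raises
    E_ALGEBRAIC_LOOP listing the dependency ids on the cycle.
    """
    steps: List[Tuple[str, str, Tuple[str, ...]]] = []  # (dep, out_pid, input pids)
    produced: Dict[str, Tuple[str, str]] = {}
    for dep_id in sorted(causality):
        dep = net.dependencies[dep_id]
        kind = laws.KINDS[dep.kind]
        if kind.is_boundary:
            continue
        for role in causality[dep_id]:
            inputs: List[str] = []
            for in_role in laws.output_inputs(kind, role):
                inputs.extend(dep.bound(in_role))
            for pid in dep.bound(role):
                steps.append((dep_id, pid, tuple(inputs)))
                produced[pid] = (dep_id, pid)

    g = nx.DiGraph()
    for dep_id, pid, inputs in steps:
        g.add_node((dep_id, pid))
        for in_pid in inputs:
            if in_pid in produced:
                g.add_edge(produced[in_pid], (dep_id, pid))

    try:
        order = list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle_deps = sorted({n[0] for comp in nx.strongly_connected_components(g)
                             if len(comp) > 1 for n in comp})
        raise AlgebraicLoopError(cycle=cycle_deps) from None
    return [(d, p) for d, p in order]


# ---------------------------------------------------------------------------
# ODE system
# ---------------------------------------------------------------------------


@dataclass
class ODESystem:
    """Executable form of a compiled network.

    ``rhs(t, y)`` returns (state derivatives, values of every property).
    """

    network: ModelNetwork
    states: List[str]
    schedule: List[Tuple[str, str]]
    causality: Dict[str, Tuple[str, ...]]
    parameters: Dict[str, float]

    @property
    def state_index(self) -> Dict[str, int]:
        return {pid: i for i, pid in enumerate(self.states)}

    def initial_state(self) -> np.ndarray:
        return np.array([self.network.properties[p].value for p in self.states],
                        dtype=float)

    def rhs(self, t: float, y: Sequence[float]) -> Tuple[np.ndarray, Dict[str, float]]:
        net = self.network
        values: Dict[str, float] = dict(self.parameters)
        for pid, src in net.sources.items():
            values[pid] = evaluate_waveform(src, t)
        for pid, yi in zip(self.states, y):
            values[pid] = float(yi)

        for dep_id, out_pid in self.schedule:
            dep = net.dependencies[dep_id]
            kind = laws.KINDS[dep.kind]
            out_role = next(r for r in kind.outputs if out_pid in dep.bound(r))
            role_values = {
                role: [values[p] for p in dep.bound(role)]
                for role in laws.output_inputs(kind, out_role)
            }
            constitutive = [
                (net.properties[p].prop_class.category, values[p])
                for p in dep.bound("constitutive")
            ]
            values[out_pid] = laws.evaluate_output(
                kind, out_role, role_values, constitutive, dep.params)

        dydt = np.zeros(len(self.states))
        idx = self.state_index
        for dep_id, roles in self.causality.items():
            if roles != (DERIVATIVE,):
                continue
            dep = net.dependencies[dep_id]
            kind = laws.KINDS[dep.kind]
            role_values = {
                role: [values[p] for p in dep.bound(role)]
                for role in kind.roles
            }
            rate = laws.boundary_derivative(kind, role_values)
            for pid in dep.bound(kind.state_role):
                dydt[idx[pid]] += rate
        return dydt, values

    def constant_sources_only(self) -> bool:
        return all(is_constant_source(s) for s in self.network.sources.values())

    def equation_text(self) -> str:
        """Human-readable equation listing: one line per state and step."""
        lines = [f"# {self.network.name or 'model'}"]
        for pid in self.states:
            deps = [d for d, roles in self.causality.items()
                    if roles == (DERIVATIVE,)
                    and pid in self.network.dependencies[d].bound(
                        laws.KINDS[self.network.dependencies[d].kind].state_role)]
            terms = []
            for d in deps:
                dep = self.network.dependencies[d]
                kind = laws.KINDS[dep.kind]
                if kind.id == "boundary_flow":
                    terms += [f"+ {p}" for p in dep.bound("inflow")]
                    terms += [f"- {p}" for p in dep.bound("outflow")]
                else:
                    terms += [f"+ {p}" for p in dep.bound("force_player_high")]
                    terms += [f"- {p}" for p in dep.bound("force_player_low")]
            lines.append(f"d({pid})/dt = {' '.join(terms) if terms else '0'}")
        for dep_id, out_pid in self.schedule:
            dep = self.network.dependencies[dep_id]
            lines.append(f"{out_pid} = {dep.kind}({dep_id})")
        for pid, src in sorted(self.network.sources.items()):
            lines.append(f"{pid} = source[{src.waveform}]")
        return "\n".join(lines) + "\n"


def compile(net: ModelNetwork) -> ODESystem:
    """Validate, orient, schedule and package a network as an ODESystem."""
    findings = validate_network(net)
    if has_errors(findings):
        first = next(f for f in findings if f.level == "error")
        raise ValueError(f"network does not validate: {first}")
    states = identify_states(net)
    causality = assign_causality(net)
    schedule = build_schedule(net, causality)
    parameters = {
        pid: float(prop.value)
        for pid, prop in net.properties.items()
        if (category_group(prop.prop_class.category) == "constitutive" or prop.fixed)
        and prop.value is not None
    }
    return ODESystem(net, states, schedule, causality, parameters)
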