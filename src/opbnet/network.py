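"""Model networks: entities, processes, property instances, dependency instances.

A :class:`ModelNetwork` is the typed graph at the heart of the formalism:
physical entities (and optional processes) bear property instances; dependency
instances bind property instances to named roles of a dependency kind; source
specs prescribe driving forces/flows as boundary conditions.

``assemble_network`` builds the container and resolves references;
``validate_network`` checks physics validity (role signatures, domain rules,
constitutive positivity, initial values) and returns findings as data;
``influence_edges`` unrolls the causally oriented network into a signed
influence graph for qualitative perturbation reasoning.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import laws, taxonomy
from .errors import DuplicateIdError, NotCompiledError, UnresolvedRefError
from .taxonomy import PropertyClass, category_group

# ---------------------------------------------------------------------------
# Node types
# ---------------------------------------------------------------------------


@dataclass
class EntityNode:
    """A physical entity (portion of blood, cell, circuit element, ...)."""

    id: str
    label: str = ""
    domain: Optional[str] = None
    part_of: Optional[str] = None


@dataclass
class ProcessNode:
    """A physical process; bookkeeping for hasParticipant annotations."""

    id: str
    label: str = ""
    participants: List[str] = field(default_factory=list)


@dataclass
class PropertyInstance:
    """One physical property borne by an entity or process.

    ``value`` holds a constitutive parameter, a state initial condition, or a
    fixed boundary constant (``fixed=True``); it is None for quantities the
    compiled system computes.
    """

    id: str
    prop_class: PropertyClass
    bearer: str
    value: Optional[float] = None
    label: str = ""
    fixed: bool = False


@dataclass
class PlayerBinding:
    """One role binding: a property instance playing a named role."""

    role: str
    property: str


@dataclass
class DependencyInstance:
    """One occurrence of a dependency kind with its role bindings and params."""

    id: str
    kind: str
    bindings: List[PlayerBinding] = field(default_factory=list)
    params: Dict[str, object] = field(default_factory=dict)

    def bound(self, role: str) -> List[str]:
        """Property ids bound to a role, in binding order."""
        return [b.property for b in self.bindings if b.role == role]


@dataclass
class SourceSpec:
    """A prescribed (driven) force or flow property with its waveform."""

    property: str
    waveform: str = "constant"          # constant | step | sine
    params: Dict[str, float] = field(default_factory=dict)


@dataclass
class ModelNetwork:
    """The full typed model graph."""

    name: str = ""
    description: str = ""
    entities: Dict[str, EntityNode] = field(default_factory=dict)
    processes: Dict[str, ProcessNode] = field(default_factory=dict)
    properties: Dict[str, PropertyInstance] = field(default_factory=dict)
    dependencies: Dict[str, DependencyInstance] = field(default_factory=dict)
    sources: Dict[str, SourceSpec] = field(default_factory=dict)

    # -- construction helpers ------------------------------------------------

    def add_entity(self, id: str, label: str = "", domain: Optional[str] = None,
                   part_of: Optional[str] = None) -> EntityNode:
        self._check_new(id, self.entities, "entity")
        node = EntityNode(id, label or id, domain, part_of)
        self.entities[id] = node
        return node

    def add_process(self, id: str, label: str = "",
                    participants: Sequence[str] = ()) -> ProcessNode:
        self._check_new(id, self.processes, "process")
        node = ProcessNode(id, label or id, list(participants))
        self.processes[id] = node
        return node

    def add_property(self, id: str, prop_class: PropertyClass, bearer: str,
                     value: Optional[float] = None, label: str = "",
                     fixed: bool = False) -> PropertyInstance:
        self._check_new(id, self.properties, "property")
        inst = PropertyInstance(id, prop_class, bearer, value, label or id, fixed)
        self.properties[id] = inst
        return inst

    def add_dependency(self, id: str, kind: str,
                       bindings: Sequence[Tuple[str, str]],
                       params: Optional[Mapping[str, object]] = None) -> DependencyInstance:
        self._check_new(id, self.dependencies, "dependency")
        dep = DependencyInstance(
            id, kind, [PlayerBinding(r, p) for r, p in bindings], dict(params or {})
        )
        self.dependencies[id] = dep
        return dep

    def add_source(self, property: str, waveform: str = "constant",
                   **params: float) -> SourceSpec:
        if property in self.sources:
            raise DuplicateIdError("source already prescribed", subject=property)
        src = SourceSpec(property, waveform, dict(params))
        self.sources[property] = src
        return src

    def _check_new(self, id: str, coll: Mapping[str, object], what: str) -> None:
        if id in coll:
            raise DuplicateIdError(f"duplicate {what} id", subject=id)

    # -- queries -------------------------------------------------------------

    def property_domain(self, prop_id: str) -> Optional[str]:
        return self.properties[prop_id].prop_class.domain

    def copy(self) -> "ModelNetwork":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_network(spec: Mapping) -> ModelNetwork:
    """Build a ModelNetwork from a parsed model description (plain mappings).

    Resolves all cross-references; raises E_UNRESOLVED_REF / E_DUPLICATE_ID on
    broken ones.  Physics validity is not enforced here — that is
    :func:`validate_network`'s job.
    """
    meta = spec.get("metadata", {}) or {}
    net = ModelNetwork(name=meta.get("name", ""), description=meta.get("description", ""))

    for ent in spec.get("entities", []) or []:
        net.add_entity(ent["id"], ent.get("label", ""), ent.get("domain"),
                       ent.get("part_of"))
    for proc in spec.get("processes", []) or []:
        net.add_process(proc["id"], proc.get("label", ""), proc.get("participants", []))
    for prop in spec.get("properties", []) or []:
        pc = taxonomy.class_by_id(prop["class"])
        net.add_property(prop["id"], pc, prop["bearer"], prop.get("value"),
                         prop.get("label", ""), bool(prop.get("fixed", False)))
    for dep in spec.get("dependencies", []) or []:
        bindings = [(b["role"], b["property"]) for b in dep.get("bindings", [])]
        net.add_dependency(dep["id"], dep["kind"], bindings, dep.get("params", {}))
    for src in spec.get("sources", []) or []:
        params = {k: v for k, v in src.items() if k not in ("property", "waveform")}
        net.add_source(src["property"], src.get("waveform", "constant"), **params)

    _resolve_refs(net)
    return net


def _resolve_refs(net: ModelNetwork) -> None:
    for ent in net.entities.values():
        if ent.part_of is not None and ent.part_of not in net.entities:
            raise UnresolvedRefError("entity part_of target missing", subject=ent.part_of)
    for proc in net.processes.values():
        for pid in proc.participants:
            if pid not in net.entities:
                raise UnresolvedRefError("process participant missing", subject=pid)
    for prop in net.properties.values():
        if prop.bearer not in net.entities and prop.bearer not in net.processes:
            raise UnresolvedRefError("property bearer missing", subject=prop.bearer)
    for dep in net.dependencies.values():
        for b in dep.bindings:
            if b.property not in net.properties:
                raise UnresolvedRefError("bound property missing", subject=b.property)
    for src in net.sources.values():
        if src.property not in net.properties:
            raise UnresolvedRefError("source property missing", subject=src.property)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    level: str      # 'error' | 'warning'
    code: str
    message: str
    subject: str

    def __str__(self) -> str:  # CLI line format
        return f"{self.level}\t{self.code}\t{self.subject}\t{self.message}"


def validate_network(net: ModelNetwork) -> List[Finding]:
    """Check an assembled network against the dependency-kind signatures.

    Returns a deterministic, subject-ordered list of findings.  An empty
    error list means: every dependency matches its kind's role signature
    (categories, multiplicities, domain rules), constitutive values are set
    and positive where required, every boundary-targeted state has an initial
    value, and sources drive only force/flow properties.  Idempotent and
    side-effect free.
    """
    findings: List[Finding] = []

    def err(code: str, msg: str, subject: str) -> None:
        findings.append(Finding("error", code, msg, subject))

    def warn(code: str, msg: str, subject: str) -> None:
        findings.append(Finding("warning", code, msg, subject))

    _check_part_of_forest(net, err)

    for proc in net.processes.values():
        if not proc.participants:
            err("E_MISSING_ROLE", "process has no participants", proc.id)

    for dep in sorted(net.dependencies.values(), key=lambda d: d.id):
        if dep.kind not in laws.KINDS:
            err("E_SCHEMA", f"unknown dependency kind {dep.kind!r}", dep.id)
            continue
        kind = laws.KINDS[dep.kind]
        _check_signature(net, dep, kind, err, warn)

    for prop in sorted(net.properties.values(), key=lambda p: p.id):
        if category_group(prop.prop_class.category) == "constitutive":
            _check_constitutive_value(net, prop, err)

    # boundary-targeted states need initial values
    for dep in sorted(net.dependencies.values(), key=lambda d: d.id):
        kind = laws.KINDS.get(dep.kind)
        if kind is None or not kind.is_boundary:
            continue
        for pid in dep.bound(kind.state_role):
            prop = net.properties.get(pid)
            if prop is not None and prop.value is None:
                err("E_NO_INITIAL", "boundary-targeted state lacks an initial value", pid)

    for pid, src in sorted(net.sources.items()):
        prop = net.properties.get(pid)
        if prop is not None and prop.prop_class.category not in ("force", "flow"):
            err("E_WRONG_CATEGORY",
                "source must drive a force or flow property", pid)
        if src.waveform not in ("constant", "step", "sine"):
            err("E_SCHEMA", f"unknown waveform {src.waveform!r}", pid)

    findings.sort(key=lambda f: (f.subject, f.code, f.message))
    return findings


def _check_part_of_forest(net: ModelNetwork, err) -> None:
    for ent in sorted(net.entities.values(), key=lambda e: e.id):
        seen = {ent.id}
        cur = ent.part_of
        while cur is not None:
            if cur in seen:
                err("E_PART_OF_CYCLE", "part_of references form a cycle", ent.id)
                break
            seen.add(cur)
            cur = net.entities[cur].part_of if cur in net.entities else None


def _check_signature(net: ModelNetwork, dep: DependencyInstance,
                     kind: laws.DependencyKind, err, warn) -> None:
    by_role: Dict[str, List[str]] = {}
    for b in dep.bindings:
        if b.role not in kind.roles:
            err("E_UNKNOWN_ROLE", f"role {b.role!r} not in {kind.id} signature", dep.id)
            continue
        by_role.setdefault(b.role, []).append(b.property)

    for role, spec in kind.roles.items():
        n = len(by_role.get(role, []))
        if n < spec.min_count:
            err("E_MISSING_ROLE", f"{kind.id} requires role {role}", dep.id)
        if spec.max_count is not None and n > spec.max_count:
            err("E_EXTRA_ROLE", f"{kind.id} allows at most {spec.max_count} {role}", dep.id)
        for pid in by_role.get(role, []):
            prop = net.properties[pid]
            cat = prop.prop_class.category
            if spec.categories and cat not in spec.categories:
                err("E_WRONG_CATEGORY",
                    f"{role} of {kind.id} must have category in "
                    f"{sorted(spec.categories)}, got {cat}", dep.id)

    if kind.id == "boundary_flow":
        if not by_role.get("inflow") and not by_role.get("outflow"):
            err("E_MISSING_ROLE", "boundary_flow needs at least one in/outflow", dep.id)
    if kind.id == "boundary_force":
        if not by_role.get("force_player_high") and not by_role.get("force_player_low"):
            err("E_MISSING_ROLE", "boundary_force needs at least one force player", dep.id)
    if kind.id == "summation":
        whole = by_role.get("whole_player", [])
        parts = by_role.get("part_player", [])
        if whole and parts:
            wcls = net.properties[whole[0]].prop_class
            for pid in parts:
                if net.properties[pid].prop_class != wcls:
                    err("E_WRONG_CATEGORY",
                        "summation whole and parts must share a property class", dep.id)
                    break

    _check_domain_rule(net, dep, kind, by_role, err, warn)
    _check_params(dep, kind, by_role, err)


def _check_domain_rule(net: ModelNetwork, dep: DependencyInstance,
                       kind: laws.DependencyKind, by_role, err, warn) -> None:
    def domains_of(roles: Sequence[str]) -> List[Optional[str]]:
        out = []
        for r in roles:
            for pid in by_role.get(r, []):
                d = net.property_domain(pid)
                if d is not None:
                    out.append(d)
        return out

    dynamic_roles = [r for r in kind.roles if r != "constitutive"]
    if kind.domain_rule == "same":
        doms = set(domains_of(dynamic_roles))
        if len(doms) > 1:
            err("E_DOMAIN_MISMATCH",
                f"{kind.id} players span domains {sorted(doms)}", dep.id)
    elif kind.domain_rule == "cross":
        side1 = set(domains_of([r for r, s in kind.roles.items() if s.side == 1]))
        side2 = set(domains_of([r for r, s in kind.roles.items() if s.side == 2]))
        if len(side1) > 1 or len(side2) > 1:
            err("E_DOMAIN_MISMATCH", "transducer side players span domains", dep.id)
        elif side1 and side2 and side1 == side2:
            err("E_DOMAIN_MISMATCH",
                "transducer must span two distinct domains", dep.id)
    elif kind.id == "transactor":
        doms = set(domains_of(dynamic_roles))
        if len(doms) > 1:
            warn("E_DOMAIN_MISMATCH",
                 f"transactor players span domains {sorted(doms)}", dep.id)


def _check_params(dep: DependencyInstance, kind: laws.DependencyKind,
                  by_role, err) -> None:
    if kind.id == "mass_action":
        for key in ("stoich_fwd", "stoich_rev"):
            stoich = dep.params.get(key)
            if stoich is not None and any(s <= 0 for s in stoich):
                err("E_BAD_CONSTITUTIVE", f"{key} entries must be > 0", dep.id)
    if kind.id == "michaelis_menten":
        for key in ("v_max", "k_m"):
            val = dep.params.get(key)
            if val is None or val <= 0:
                err("E_BAD_CONSTITUTIVE", f"michaelis_menten needs {key} > 0", dep.id)


_SIGN_FREE_CONSTITUTIVE = ("constitutive.coefficient",)


def _check_constitutive_value(net: ModelNetwork, prop: PropertyInstance, err) -> None:
    cat = prop.prop_class.category
    if prop.value is None:
        err("E_BAD_CONSTITUTIVE", "constitutive property has no value", prop.id)
        return
    if cat in _SIGN_FREE_CONSTITUTIVE:
        return
    if cat == "constitutive.modulus":
        if prop.value == 0:
            err("E_BAD_CONSTITUTIVE", "transformer modulus must be nonzero", prop.id)
        return
    if prop.value <= 0:
        err("E_BAD_CONSTITUTIVE",
            f"{cat} must be strictly positive, got {prop.value}", prop.id)


def has_errors(findings: Sequence[Finding]) -> bool:
    return any(f.level == "error" for f in findings)


# ---------------------------------------------------------------------------
# Influence edges (feeds qualitative reasoning)
# ---------------------------------------------------------------------------


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def influence_edges(net: ModelNetwork) -> List[Tuple[str, str, int]]:
    """Unroll each dependency into signed directed influence edges.

    Edges follow the compiler's causal orientation: e.g. a resistive element
    contributes (force_high -> flow, +) and (force_low -> flow, −); a
    capacitive element contributes (amount -> force, +); a boundary flow
    contributes (flow -> amount) with + for inflows and − for outflows.
    Zero-influence edges (a transactor with c = 0) are omitted.  Constitutive
    parameters are not nodes: their local influence sign depends on the
    operating point, which sign algebra cannot rank.
    """
    from . import compiler  # deferred: compiler imports this module's types

    try:
        compiler.assign_causality(net)
    except Exception as exc:  # causal orientation unavailable
        raise NotCompiledError(f"causal orientation unavailable: {exc}") from exc

    edges: List[Tuple[str, str, int]] = []
    for dep in net.dependencies.values():
        kind = laws.KINDS[dep.kind]
        edges.extend(_dependency_edges(net, dep, kind))
    return sorted(set(edges))


def _dependency_edges(net: ModelNetwork, dep: DependencyInstance,
                      kind: laws.DependencyKind) -> List[Tuple[str, str, int]]:
    out: List[Tuple[str, str, int]] = []
    kid = kind.id
    if kid == "boundary_flow":
        target = dep.bound("amount_player")[0]
        out += [(p, target, +1) for p in dep.bound("inflow")]
        out += [(p, target, -1) for p in dep.bound("outflow")]
    elif kid == "boundary_force":
        target = dep.bound("momentum_player")[0]
        out += [(p, target, +1) for p in dep.bound("force_player_high")]
        out += [(p, target, -1) for p in dep.bound("force_player_low")]
    elif kid == "resistive":
        flow = dep.bound("flow_player")[0]
        out.append((dep.bound("force_player_high")[0], flow, +1))
        out.append((dep.bound("force_player_low")[0], flow, -1))
    elif kid == "diffusion":
        flow = dep.bound("flow_player")[0]
        out.append((dep.bound("source_player")[0], flow, +1))
        out.append((dep.bound("target_player")[0], flow, -1))
    elif kid == "mass_action":
        flow = dep.bound("flow_player")[0]
        consts = dep.bound("constitutive")
        k_f = net.properties[consts[0]].value or 0.0
        k_r = net.properties[consts[1]].value if len(consts) > 1 else 0.0
        if k_f:
            out += [(p, flow, +1) for p in dep.bound("source_player")]
        if k_r:
            out += [(p, flow, -1) for p in dep.bound("target_player")]
    elif kid == "michaelis_menten":
        out.append((dep.bound("amount_player")[0], dep.bound("flow_player")[0], +1))
    elif kid == "capacitive":
        out.append((dep.bound("amount_player")[0], dep.bound("force_player")[0], +1))
    elif kid == "inductive":
        out.append((dep.bound("momentum_player")[0], dep.bound("flow_player")[0], +1))
    elif kid == "summation":
        whole = dep.bound("whole_player")[0]
        out += [(p, whole, +1) for p in dep.bound("part_player")]
    elif kid == "spatial":
        a = float(dep.params.get("a", 1.0))
        b = float(dep.params.get("b", 1.0))
        s = _sign(a * b)
        if s:
            out.append((dep.bound("source_player")[0], dep.bound("target_player")[0], s))
    elif kid == "transactor":
        c = net.properties[dep.bound("constitutive")[0]].value or 0.0
        s = _sign(c)
        if s:
            out.append((dep.bound("source_player")[0], dep.bound("target_player")[0], s))
    elif kid in ("transformer", "transducer"):
        m = net.properties[dep.bound("constitutive")[0]].value or 0.0
        s = _sign(m)
        if s:
            out.append((dep.bound("force_player_1")[0], dep.bound("force_player_2")[0], s))
            out.append((dep.bound("flow_player_2")[0], dep.bound("flow_player_1")[0], s))
    return out
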