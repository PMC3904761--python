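"""Qualitative up/down perturbation reasoning over the influence graph.

Sign propagation answers "if this driving property is nudged up, which way
does everything else move?" without a numerical solver.  Signs live in the
four-valued algebra {+, −, 0, ?}: products follow the usual sign rules and
sums of conflicting signs collapse to the conservative conflict value '?'.

The propagation semantics is sign-summation over all *simple* paths from the
perturbed node (enumerated by depth-first search).  On feedback cycles this
ignores the re-entrant loop contribution — a negative feedback loop damps but
cannot reverse the direct effect in a stable system — and marks genuinely
opposing parallel pathways as '?'.  It never resolves loop-gain magnitudes:
sign algebra cannot rank opposing influences, so '?' is the sound answer.

``check_against_numeric`` is the built-in validation harness: it compares
every propagated sign against the numeric steady-state difference produced by
a small relative perturbation of the same property.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from . import compiler, network as network_mod, simulator
from .errors import UnresolvedRefError
from .network import ModelNetwork
from .taxonomy import category_group

SIGNS = ("+", "-", "0", "?")


def sign_mul(a: str, b: str) -> str:
    if a == "0" or b == "0":
        return "0"
    if a == "?" or b == "?":
        return "?"
    return "+" if a == b else "-"


def sign_add(a: str, b: str) -> str:
    if a == "0":
        return b
    if b == "0":
        return a
    if a == "?" or b == "?":
        return "?"
    return a if a == b else "?"


def of_number(x: float, atol: float = 0.0) -> str:
    if x > atol:
        return "+"
    if x < -atol:
        return "-"
    return "0"


@dataclass
class InfluenceGraph:
    """Signed directed influence graph over dynamical property ids."""

    nodes: List[str]
    edges: List[Tuple[str, str, int]]   # (source, target, ±1)

    def successors(self, node: str) -> List[Tuple[str, int]]:
        return [(t, s) for f, t, s in self.edges if f == node]


def build_influence_graph(net: ModelNetwork) -> InfluenceGraph:
    """Influence graph of a network: dynamical properties + causal edges."""
    nodes = sorted(
        pid for pid, prop in net.properties.items()
        if category_group(prop.prop_class.category) != "constitutive"
    )
    return InfluenceGraph(nodes, network_mod.influence_edges(net))


def propagate(graph: InfluenceGraph, perturbed: str, direction: str = "up") -> Dict[str, str]:
    """Propagate an up/down perturbation through the influence graph.

    The perturbed node gets '+' (up) or '-' (down); every other node gets the
    sign-sum over all simple paths from the perturbed node ('?' on conflict,
    '0' if unreached).  Deterministic and independent of iteration order (the
    simple-path sum is order-free).
    """
    if perturbed not in graph.nodes:
        raise UnresolvedRefError("unknown property id", subject=perturbed)
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    start_sign = "+" if direction == "up" else "-"

    succ: Dict[str, List[Tuple[str, int]]] = {}
    for f, t, s in graph.edges:
        succ.setdefault(f, []).append((t, s))
    for lst in succ.values():
        lst.sort()

    result: Dict[str, str] = {n: "0" for n in graph.nodes}
    result[perturbed] = start_sign

    # DFS over simple paths; each path's sign product is folded into the
    # endpoint's running sign-sum.
    stack: List[Tuple[str, str, frozenset]] = [(perturbed, start_sign, frozenset({perturbed}))]
    while stack:
        node, s, on_path = stack.pop()
        for nxt, edge_sign in succ.get(node, []):
            if nxt in on_path or nxt == perturbed:
                continue
            s_next = sign_mul(s, "+" if edge_sign > 0 else "-")
            result[nxt] = sign_add(result[nxt], s_next)
            stack.append((nxt, s_next, on_path | {nxt}))
    return result


# ---------------------------------------------------------------------------
# Numeric validation harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementRow:
    property: str
    qualitative: str
    numeric: str
    status: str      # agree | conservative | overestimate | missed | contradict


@dataclass
class AgreementReport:
    perturbed: str
    rel_step: float
    rows: List[AgreementRow]

    @property
    def contradictions(self) -> List[AgreementRow]:
        return [r for r in self.rows if r.status == "contradict"]

    @property
    def strict_agreement_rate(self) -> float:
        if not self.rows:
            return 1.0
        return sum(r.status == "agree" for r in self.rows) / len(self.rows)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("property\tqualitative\tnumeric\tstatus\n")
            for r in self.rows:
                fh.write(f"{r.property}\t{r.qualitative}\t{r.numeric}\t{r.status}\n")


def _classify(qual: str, num: str) -> str:
    if qual == num:
        return "agree"
    if qual == "?":
        return "conservative"
    if num == "0":
        return "overestimate"   # transient influence that cancels at steady state
    if qual == "0":
        return "missed"
    return "contradict"


def check_against_numeric(net: ModelNetwork, perturbed: str,
                          rel_step: float = 0.01,
                          t_max: float = 200.0,
                          tol: float = 1e-12) -> AgreementReport:
    """Compare sign propagation with a numeric steady-state perturbation.

    The perturbed source level (or constitutive/fixed parameter value) is
    scaled by (1 + rel_step); each dynamical property's steady-state change is
    classified as +/−/0 with tolerance 1e-9·scale and compared with the
    propagated sign.  '?' counts as conservative agreement with any numeric
    sign; a strict +/− contradiction marks unsoundness.
    """
    base_sys = compiler.compile(net)
    base = simulator.steady_state(base_sys, t_max=t_max, tol=tol)

    pert_net = net.copy()
    if perturbed in pert_net.sources:
        src = pert_net.sources[perturbed]
        src.params["level"] = src.params.get("level", 0.0) * (1.0 + rel_step)
    elif perturbed in pert_net.properties and pert_net.properties[perturbed].value is not None:
        pert_net.properties[perturbed].value *= (1.0 + rel_step)
    else:
        raise UnresolvedRefError(
            "perturbation target must be a source or a valued parameter",
            subject=perturbed)
    pert_sys = compiler.compile(pert_net)
    pert = simulator.steady_state(pert_sys, t_max=t_max, tol=tol)

    graph = build_influence_graph(net)
    # direction follows the realized change of the perturbed quantity itself
    if perturbed in graph.nodes:
        delta0 = pert[perturbed] - base[perturbed]
        direction = "down" if delta0 < 0 else "up"
        qual = propagate(graph, perturbed, direction)
    else:
        qual = {n: "?" for n in graph.nodes}   # parameter node: no edges kept

    rows = []
    for pid in graph.nodes:
        atol = 1e-9 * max(1.0, abs(base[pid]))
        num = of_number(pert[pid] - base[pid], atol)
        q = qual.get(pid, "0")
        rows.append(AgreementRow(pid, q, num, _classify(q, num)))
    return AgreementReport(perturbed, rel_step, rows)
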