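"""Canonical model fixtures: the repository's stand-in for external data.

Each generator returns a fully parameterized :class:`ModelNetwork` that
validates with zero errors.  Parameters are in canonical units throughout and
make no claim to physiological calibration — the point is exercising the
formalism (cross-domain analogies, storage, coupling, wild cards), not
reproducing real hemodynamics.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from . import taxonomy
from .errors import BadConstitutiveError
from .network import ModelNetwork
from .taxonomy import analog_of, get_property_class

FIXTURE_NAMES = (
    "rc_circuit",
    "windkessel",
    "windkessel_discharge",
    "lc_oscillator",
    "mass_action_pair",
    "chemo_mech_transducer",
    "baroreflex_toy",
    "multiscale_sum",
)


def _require_positive(**params: float) -> None:
    for name, value in params.items():
        if value <= 0:
            raise BadConstitutiveError(f"fixture parameter {name} must be > 0, got {value}")


def make_fixture(name: str, **params) -> ModelNetwork:
    """Build a named fixture; unknown names raise KeyError."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}") from None
    return builder(**params)


def rc_circuit(R: float = 2.0, C: float = 0.5, E0: float = 1.0,
               q0: float = 0.0) -> ModelNetwork:
    """Series RC circuit driven by a constant source force.

    d(charge)/dt = (E0 − charge/C)/R; the canonical single-state relaxation
    model (capacitor force approaches E0 as 1 − e^(−t/RC)).
    """
    _require_positive(R=R, C=C)
    net = ModelNetwork(name="rc_circuit",
                       description="Series RC charging circuit (electrical domain)")
    net.add_entity("source", "Voltage source", "electrical")
    net.add_entity("capacitor", "RC element", "electrical")

    force = get_property_class("electrical", "force")
    flow = get_property_class("electrical", "flow")
    amount = get_property_class("electrical", "amount")

    net.add_property("src_force", force, "source", label="Source potential")
    net.add_property("current", flow, "capacitor", label="Charging current")
    net.add_property("charge", amount, "capacitor", value=q0, label="Capacitor charge")
    net.add_property("cap_force", force, "capacitor", label="Capacitor potential")
    net.add_property("resistance", get_property_class("electrical", "constitutive.resistance"),
                     "capacitor", value=R)
    net.add_property("capacitance", get_property_class("electrical", "constitutive.capacitance"),
                     "capacitor", value=C)

    net.add_dependency("res_dep", "resistive", [
        ("force_player_high", "src_force"),
        ("force_player_low", "cap_force"),
        ("flow_player", "current"),
        ("constitutive", "resistance"),
    ])
    net.add_dependency("cap_dep", "capacitive", [
        ("amount_player", "charge"),
        ("force_player", "cap_force"),
        ("constitutive", "capacitance"),
    ])
    net.add_dependency("bnd_dep", "boundary_flow", [
        ("amount_player", "charge"),
        ("inflow", "current"),
    ])
    net.add_source("src_force", "constant", level=E0)
    return net


def windkessel(R: float = 1.0, C: float = 1.0, Q0: float = 1.0,
               V0: float = 0.0) -> ModelNetwork:
    """Two-element Windkessel: prescribed inflow, compliant vessel, resistive drain.

    The arterial volume obeys dV/dt = Q0 − P/R with P = V/C; its steady state
    is P = Q0·R and V = C·Q0·R.  The drain empties into a zero-pressure
    venous sink.
    """
    _require_positive(R=R, C=C)
    net = ModelNetwork(name="windkessel",
                       description="Two-element Windkessel (fluid domain)")
    net.add_entity("heart", "Inflow pump", "fluid")
    net.add_entity("artery", "Compliant arterial segment", "fluid")
    net.add_entity("vein", "Venous sink", "fluid")

    force = get_property_class("fluid", "force")
    flow = get_property_class("fluid", "flow")
    amount = get_property_class("fluid", "amount")

    net.add_property("inflow", flow, "heart", label="Cardiac inflow")
    net.add_property("volume", amount, "artery", value=V0, label="Arterial volume")
    net.add_property("pressure", force, "artery", label="Arterial pressure")
    net.add_property("outflow", flow, "artery", label="Peripheral outflow")
    net.add_property("venous_pressure", force, "vein", label="Venous pressure")
    net.add_property("resistance", get_property_class("fluid", "constitutive.resistance"),
                     "artery", value=R)
    net.add_property("compliance", get_property_class("fluid", "constitutive.capacitance"),
                     "artery", value=C)

    net.add_dependency("cap_dep", "capacitive", [
        ("amount_player", "volume"),
        ("force_player", "pressure"),
        ("constitutive", "compliance"),
    ])
    net.add_dependency("res_dep", "resistive", [
        ("force_player_high", "pressure"),
        ("force_player_low", "venous_pressure"),
        ("flow_player", "outflow"),
        ("constitutive", "resistance"),
    ])
    net.add_dependency("bnd_dep", "boundary_flow", [
        ("amount_player", "volume"),
        ("inflow", "inflow"),
        ("outflow", "outflow"),
    ])
    net.add_source("inflow", "constant", level=Q0)
    net.add_source("venous_pressure", "constant", level=0.0)
    return net


def transpose_network(net: ModelNetwork, target_domain: str) -> ModelNetwork:
    """Map every state/rate property class of a single-domain network into
    ``target_domain`` via the analogy table, keeping ids, values and topology.

    The executable form of the cross-domain analogy: an Ohm/Hooke network and
    its analogue integrate to identical trajectories.
    """
    out = net.copy()
    for ent in out.entities.values():
        if ent.domain is not None:
            ent.domain = target_domain
    for prop in out.properties.values():
        pc = prop.prop_class
        if pc.domain is None:
            continue
        if taxonomy.category_group(pc.category) == "constitutive":
            prop.prop_class = get_property_class(target_domain, pc.category)
        else:
            prop.prop_class = analog_of(pc, target_domain)
    return out


def windkessel_discharge(R: float = 2.0, C: float = 0.5, P0: float = 0.0,
                         V0: float = 1.0) -> ModelNetwork:
    """Fluid analogue of the RC circuit: a compliant vessel discharging
    through a resistance toward a constant source pressure P0.

    Constructed as the domain transpose of :func:`rc_circuit`, so it is
    structurally isomorphic to it under the analogy map (same ids, analogous
    property classes).
    """
    net = transpose_network(rc_circuit(R=R, C=C, E0=P0, q0=V0), "fluid")
    net.name = "windkessel_discharge"
    net.description = "Compliant vessel discharging through a resistance (fluid domain)"
    return net


def lc_oscillator(L: float = 1.0, C: float = 1.0, q0: float = 1.0) -> ModelNetwork:
    """Lossless LC loop: capacitive + inductive storage, two boundary laws.

    dq/dt = −I with I = p/L, dp/dt = V with V = q/C: a conservative
    oscillator with period 2π·sqrt(LC) and invariant energy
    q²/(2C) + p²/(2L).
    """
    _require_positive(L=L, C=C)
    net = ModelNetwork(name="lc_oscillator",
                       description="Lossless LC oscillator (electrical domain)")
    net.add_entity("capacitor", "Capacitor", "electrical")
    net.add_entity("inductor", "Inductor", "electrical")

    net.add_property("charge", get_property_class("electrical", "amount"),
                     "capacitor", value=q0, label="Capacitor charge")
    net.add_property("cap_force", get_property_class("electrical", "force"),
                     "capacitor", label="Capacitor potential")
    net.add_property("flux", get_property_class("electrical", "momentum"),
                     "inductor", value=0.0, label="Inductor flux linkage")
    net.add_property("current", get_property_class("electrical", "flow"),
                     "inductor", label="Loop current")
    net.add_property("capacitance", get_property_class("electrical", "constitutive.capacitance"),
                     "capacitor", value=C)
    net.add_property("inductance", get_property_class("electrical", "constitutive.inductance"),
                     "inductor", value=L)

    net.add_dependency("cap_dep", "capacitive", [
        ("amount_player", "charge"),
        ("force_player", "cap_force"),
        ("constitutive", "capacitance"),
    ])
    net.add_dependency("ind_dep", "inductive", [
        ("momentum_player", "flux"),
        ("flow_player", "current"),
        ("constitutive", "inductance"),
    ])
    net.add_dependency("bnd_flow", "boundary_flow", [
        ("amount_player", "charge"),
        ("outflow", "current"),
    ])
    net.add_dependency("bnd_force", "boundary_force", [
        ("momentum_player", "flux"),
        ("force_player_high", "cap_force"),
    ])
    return net


def mass_action_pair(k_f: float = 2.0, k_r: float = 1.0, A0: float = 1.0,
                     B0: float = 2.0) -> ModelNetwork:
    """Reversible A <-> B with one shared flux and two boundary flows.

    Net flux v = k_f·A − k_r·B; total amount A + B is conserved exactly.  The
    defaults sit at detailed balance (k_f·A0 = k_r·B0), so the system starts
    at its equilibrium.
    """
    _require_positive(k_f=k_f, k_r=k_r)
    net = ModelNetwork(name="mass_action_pair",
                       description="Reversible mass-action pair A <-> B (chemical domain)")
    net.add_entity("pool_a", "Species pool A", "chemical")
    net.add_entity("pool_b", "Species pool B", "chemical")

    amount = get_property_class("chemical", "amount")
    net.add_property("amount_a", amount, "pool_a", value=A0, label="Amount of A")
    net.add_property("amount_b", amount, "pool_b", value=B0, label="Amount of B")
    net.add_property("flux", get_property_class("chemical", "flow"),
                     "pool_a", label="Net reaction flux")
    net.add_property("kf", get_property_class("chemical", "constitutive.rate_constant"),
                     "pool_a", value=k_f, label="Forward rate constant")
    net.add_property("kr", get_property_class("chemical", "constitutive.rate_constant"),
                     "pool_b", value=k_r, label="Reverse rate constant")

    net.add_dependency("rxn", "mass_action", [
        ("flow_player", "flux"),
        ("source_player", "amount_a"),
        ("target_player", "amount_b"),
        ("constitutive", "kf"),
        ("constitutive", "kr"),
    ])
    net.add_dependency("bnd_a", "boundary_flow", [
        ("amount_player", "amount_a"),
        ("outflow", "flux"),
    ])
    net.add_dependency("bnd_b", "boundary_flow", [
        ("amount_player", "amount_b"),
        ("inflow", "flux"),
    ])
    return net


def chemo_mech_transducer(m: float = 2.0, mu0: float = 1.0,
                          R_load: float = 1.0) -> ModelNetwork:
    """Chemical potential driving mechanical motion through a transducer.

    A constant chemical potential mu0 (side 1) couples through modulus m to a
    mechanical side (side 2) loaded by a viscous resistance: force_2 = m·mu0,
    velocity = force_2/R_load, molar flux = m·velocity.  Power is conserved
    across the coupling.
    """
    _require_positive(R_load=R_load)
    if m == 0:
        raise BadConstitutiveError("transducer modulus must be nonzero")
    net = ModelNetwork(name="chemo_mech_transducer",
                       description="Chemo-mechanical transduction against a viscous load")
    net.add_entity("fuel", "Chemical fuel pool", "chemical")
    net.add_entity("fiber", "Contractile fiber", "mechanical")
    net.add_entity("anchor", "Mechanical anchor", "mechanical")

    net.add_property("mu", get_property_class("chemical", "force"),
                     "fuel", label="Chemical potential")
    net.add_property("molar_flux", get_property_class("chemical", "flow"),
                     "fuel", label="Fuel consumption flux")
    net.add_property("mech_force", get_property_class("mechanical", "force"),
                     "fiber", label="Contractile force")
    net.add_property("velocity", get_property_class("mechanical", "flow"),
                     "fiber", label="Shortening velocity")
    net.add_property("anchor_force", get_property_class("mechanical", "force"),
                     "anchor", label="Anchor reference force")
    net.add_property("modulus", get_property_class(None, "constitutive.modulus"),
                     "fiber", value=m, label="Transduction modulus")
    net.add_property("drag", get_property_class("mechanical", "constitutive.resistance"),
                     "fiber", value=R_load, label="Viscous load resistance")

    net.add_dependency("xdc", "transducer", [
        ("force_player_1", "mu"),
        ("flow_player_1", "molar_flux"),
        ("force_player_2", "mech_force"),
        ("flow_player_2", "velocity"),
        ("constitutive", "modulus"),
    ])
    net.add_dependency("load", "resistive", [
        ("force_player_high", "mech_force"),
        ("force_player_low", "anchor_force"),
        ("flow_player", "velocity"),
        ("constitutive", "drag"),
    ])
    net.add_source("mu", "constant", level=mu0)
    net.add_source("anchor_force", "constant", level=0.0)
    return net


def baroreflex_toy(c: float = -0.5, P0: float = 1.0) -> ModelNetwork:
    """Transactor wild card: aortic pressure proportionally sets heart rate.

    The neural pathway is not modelled — the dependency is the bare
    proportionality heart_rate = c·pressure with c < 0, so raising aortic
    pressure lowers heart rate.  The rate property is a cross-domain proxy,
    which the validator flags with a (benign) domain-mismatch warning.
    """
    if c >= 0:
        raise BadConstitutiveError("baroreflex gain must be negative")
    net = ModelNetwork(name="baroreflex_toy",
                       description="Baroreceptor reflex as a proportional transactor")
    net.add_entity("aorta", "Aortic segment", "fluid")
    net.add_entity("sa_node", "Sinoatrial pacemaker", "chemical")

    net.add_property("aortic_pressure", get_property_class("fluid", "force"),
                     "aorta", label="Aortic pressure")
    net.add_property("heart_rate", get_property_class("chemical", "flow"),
                     "sa_node", label="Heart rate (proxy rate property)")
    net.add_property("gain", get_property_class(None, "constitutive.coefficient"),
                     "sa_node", value=c, label="Reflex gain")

    net.add_dependency("reflex", "transactor", [
        ("source_player", "aortic_pressure"),
        ("target_player", "heart_rate"),
        ("constitutive", "gain"),
    ])
    net.add_source("aortic_pressure", "constant", level=P0)
    return net


def multiscale_sum(parts: Sequence[float] = (1.0, 2.0, 3.0)) -> ModelNetwork:
    """Whole-organ volume as the sum of its lobes' volumes (part_of forest)."""
    if len(parts) == 0:
        raise BadConstitutiveError("multiscale_sum needs at least one part")
    net = ModelNetwork(name="multiscale_sum",
                       description="Summation over proper parts (fluid volumes)")
    net.add_entity("organ", "Whole organ", "fluid")
    amount = get_property_class("fluid", "amount")
    net.add_property("vol_organ", amount, "organ", label="Organ volume")
    bindings = [("whole_player", "vol_organ")]
    for i, v in enumerate(parts, start=1):
        ent = f"lobe_{i}"
        net.add_entity(ent, f"Lobe {i}", "fluid", part_of="organ")
        pid = f"vol_lobe_{i}"
        net.add_property(pid, amount, ent, value=float(v), fixed=True,
                         label=f"Lobe {i} volume")
        bindings.append(("part_player", pid))
    net.add_dependency("sum_dep", "summation", bindings)
    return net


def shipped_model_path(name: str):
    """Path of the YAML model file shipped for a named fixture."""
    from importlib.resources import files

    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}")
    return files("opbnet") / "models" / f"{name}.yaml"


_BUILDERS = {
    "rc_circuit": rc_circuit,
    "windkessel": windkessel,
    "windkessel_discharge": windkessel_discharge,
    "lc_oscillator": lc_oscillator,
    "mass_action_pair": mass_action_pair,
    "chemo_mech_transducer": chemo_mech_transducer,
    "baroreflex_toy": baroreflex_toy,
    "multiscale_sum": multiscale_sum,
}


def randomized_network(seed: int, n_storage: int = 3,
                       n_resistive: int = 2) -> ModelNetwork:
    """Random single-domain capacitive tree for property-based testing.

    ``n_storage`` capacitive storage nodes are joined by resistive elements:
    a spanning tree first, then extra parallel connectors up to
    max(n_resistive, n_storage − 1) edges, plus one constant source feeding
    node 0 through its own resistance.  Every endpoint of a resistive element
    is a stored force or the source, so the result is always loop-free under
    storage causality, validates cleanly, and compiles.  Deterministic per
    seed.
    """
    if n_storage < 1:
        raise ValueError("n_storage must be >= 1")
    rng = np.random.default_rng(seed)
    net = ModelNetwork(name=f"randomized_{seed}",
                       description="Randomized capacitive tree")
    force = get_property_class("electrical", "force")
    flow = get_property_class("electrical", "flow")
    amount = get_property_class("electrical", "amount")
    cap = get_property_class("electrical", "constitutive.capacitance")
    res = get_property_class("electrical", "constitutive.resistance")

    for i in range(n_storage):
        ent = f"node_{i:02d}"
        net.add_entity(ent, f"Storage node {i}", "electrical")
        net.add_property(f"q_{i:02d}", amount, ent,
                         value=float(rng.uniform(0.5, 1.5)))
        net.add_property(f"v_{i:02d}", force, ent)
        net.add_property(f"c_{i:02d}", cap, ent,
                         value=float(rng.uniform(0.5, 2.0)))
        net.add_dependency(f"cap_{i:02d}", "capacitive", [
            ("amount_player", f"q_{i:02d}"),
            ("force_player", f"v_{i:02d}"),
            ("constitutive", f"c_{i:02d}"),
        ])

    boundary: Dict[int, list] = {i: [] for i in range(n_storage)}

    def add_edge(idx: int, hi: int, lo: int) -> None:
        fid = f"f_{idx:02d}"
        net.add_property(fid, flow, f"node_{hi:02d}")
        net.add_property(f"r_{idx:02d}", res, f"node_{hi:02d}",
                         value=float(rng.uniform(0.5, 2.0)))
        net.add_dependency(f"res_{idx:02d}", "resistive", [
            ("force_player_high", f"v_{hi:02d}"),
            ("force_player_low", f"v_{lo:02d}"),
            ("flow_player", fid),
            ("constitutive", f"r_{idx:02d}"),
        ])
        boundary[hi].append(("outflow", fid))
        boundary[lo].append(("inflow", fid))

    n_edges = max(n_resistive, n_storage - 1)
    idx = 0
    for i in range(1, n_storage):
        parent = int(rng.integers(0, i))
        add_edge(idx, parent, i)
        idx += 1
    while idx < n_edges:
        a, b = rng.choice(n_storage, size=2, replace=False) if n_storage > 1 else (0, 0)
        if n_storage == 1:
            break
        add_edge(idx, int(a), int(b))
        idx += 1

    # one constant source feeding node 0 through its own resistance
    net.add_entity("driver", "Source node", "electrical")
    net.add_property("v_src", force, "driver",
                     label="Driving potential")
    net.add_property("r_src", res, "driver", value=float(rng.uniform(0.5, 2.0)))
    net.add_property("f_src", flow, "driver")
    net.add_dependency("res_src", "resistive", [
        ("force_player_high", "v_src"),
        ("force_player_low", "v_00"),
        ("flow_player", "f_src"),
        ("constitutive", "r_src"),
    ])
    boundary[0].append(("inflow", "f_src"))
    net.add_source("v_src", "constant", level=float(rng.uniform(0.5, 1.5)))

    for i in range(n_storage):
        net.add_dependency(f"bnd_{i:02d}", "boundary_flow",
                           [("amount_player", f"q_{i:02d}")] + boundary[i])
    return net
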