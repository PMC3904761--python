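"""Compiler: state identification, causality, scheduling, rhs correctness."""

import numpy as np
import pytest

from opbnet import compiler, fixtures
from opbnet.errors import (
    AlgebraicLoopError,
    NoInitialValueError,
    OverdeterminedError,
    UnderdeterminedError,
)
from opbnet.network import ModelNetwork
from opbnet.taxonomy import get_property_class


def _loop_net():
    """A resistive cycle with no storage node: the flow feeds back into one
    of the resistive element's own force players through a transactor."""
    net = ModelNetwork(name="loop")
    net.add_entity("e", "node", "electrical")
    net.add_property("va", get_property_class("electrical", "force"), "e")
    net.add_property("vb", get_property_class("electrical", "force"), "e")
    net.add_property("i", get_property_class("electrical", "flow"), "e")
    net.add_property("r", get_property_class("electrical", "constitutive.resistance"),
                     "e", value=1.0)
    net.add_property("c", get_property_class(None, "constitutive.coefficient"),
                     "e", value=1.0)
    net.add_dependency("res", "resistive", [
        ("force_player_high", "va"), ("force_player_low", "vb"),
        ("flow_player", "i"), ("constitutive", "r")])
    net.add_dependency("fb", "transactor", [
        ("source_player", "i"), ("target_player", "vb"), ("constitutive", "c")])
    net.add_source("va", "constant", level=1.0)
    return net


def test_identify_states_rc(rc_network):
    assert compiler.identify_states(rc_network) == ["charge"]


def test_identify_states_lc(lc_network):
    assert compiler.identify_states(lc_network) == ["charge", "flux"]


def test_identify_states_pure_algebraic_network():
    assert compiler.identify_states(fixtures.multiscale_sum()) == []


def test_identify_states_requires_initial_value(rc_network):
    rc_network.properties["charge"].value = None
    with pytest.raises(NoInitialValueError):
        compiler.identify_states(rc_network)


def test_rc_causality(rc_network):
    causality = compiler.assign_causality(rc_network)
    assert causality["cap_dep"] == ("force_player",)
    assert causality["res_dep"] == ("flow_player",)
    assert causality["bnd_dep"] == (compiler.DERIVATIVE,)


def test_two_providers_is_overdetermined(rc_network):
    net = rc_network
    net.add_property("r2", get_property_class("electrical", "constitutive.resistance"),
                     "capacitor", value=1.0)
    net.add_dependency("res_dep2", "resistive", [
        ("force_player_high", "src_force"), ("force_player_low", "cap_force"),
        ("flow_player", "current"), ("constitutive", "r2")])
    with pytest.raises(OverdeterminedError):
        compiler.assign_causality(net)


def test_unprovided_force_is_underdetermined(rc_network):
    rc_network.add_property("orphan", get_property_class("electrical", "force"),
                            "capacitor")
    with pytest.raises(UnderdeterminedError) as exc:
        compiler.assign_causality(rc_network)
    assert "orphan" in str(exc.value)


def test_rc_schedule_orders_capacitor_before_resistor(rc_network):
    causality = compiler.assign_causality(rc_network)
    schedule = compiler.build_schedule(rc_network, causality)
    deps = [d for d, _ in schedule]
    assert deps.index("cap_dep") < deps.index("res_dep")
    # the schedule is a permutation of all algebraic dependencies
    assert sorted(deps) == ["cap_dep", "res_dep"]


def test_resistive_loop_without_storage_raises_algebraic_loop():
    with pytest.raises(AlgebraicLoopError) as exc:
        compiler.compile(_loop_net())
    assert "res" in exc.value.cycle


def test_rc_rhs_example():
    sys = compiler.compile(fixtures.rc_circuit(R=1.0, C=1.0, E0=1.0, q0=0.0))
    dydt, _ = sys.rhs(0.0, [0.0])
    assert dydt[0] == pytest.approx(1.0)


def test_lc_rhs_example(lc_network):
    sys = compiler.compile(lc_network)
    dydt, _ = sys.rhs(0.0, sys.initial_state())
    q0, C = 1.0, 1.0
    i = sys.states.index("charge")
    j = sys.states.index("flux")
    assert dydt[i] == 0.0
    assert dydt[j] == q0 / C


def test_rc_rhs_matches_hand_written_form():
    """Compiled rhs == f(q) = (E(t) − q/C)/R at 100 random points."""
    R, C, E0 = 2.0, 0.5, 1.0
    sys = compiler.compile(fixtures.rc_circuit(R=R, C=C, E0=E0))
    rng = np.random.default_rng(42)
    for _ in range(100):
        q = rng.uniform(-5, 5)
        t = rng.uniform(0, 10)
        dydt, _ = sys.rhs(t, [q])
        assert dydt[0] == pytest.approx((E0 - q / C) / R, rel=1e-14, abs=1e-14)


def test_closed_network_amount_derivatives_sum_to_zero():
    """Boundary flows only move amount between entities: Σ d(amount)/dt == 0."""
    sys = compiler.compile(fixtures.mass_action_pair(k_f=2.0, k_r=1.0, A0=3.0, B0=0.5))
    rng = np.random.default_rng(7)
    for _ in range(50):
        y = rng.uniform(0.0, 5.0, size=2)
        dydt, _ = sys.rhs(0.0, y)
        assert dydt.sum() == 0.0


def test_compilation_is_deterministic(windkessel_network):
    a = compiler.compile(windkessel_network)
    b = compiler.compile(fixtures.windkessel())
    assert a.states == b.states
    assert a.schedule == b.schedule


def test_equation_text_lists_states_and_steps(rc_network):
    sys = compiler.compile(rc_network)
    text = sys.equation_text()
    assert "d(charge)/dt" in text
    assert "cap_force" in text and "current" in text


def test_conductance_normalized_to_resistance():
    net = fixtures.rc_circuit(R=2.0)
    g = get_property_class("electrical", "constitutive.conductance")
    net.properties["resistance"].prop_class = g
    net.properties["resistance"].value = 0.5   # G = 1/R
    sys = compiler.compile(net)
    dydt, _ = sys.rhs(0.0, [0.0])
    assert dydt[0] == pytest.approx(0.5)       # (E0 - 0)/R with R = 1/0.5
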