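"""Network assembly, signature validation and influence-edge extraction."""

import pytest

from opbnet import fixtures, io_cli, network, taxonomy
from opbnet.errors import DuplicateIdError, NotCompiledError, UnresolvedRefError
from opbnet.network import (
    ModelNetwork,
    assemble_network,
    has_errors,
    influence_edges,
    validate_network,
)
from opbnet.taxonomy import get_property_class


def codes(findings, level="error"):
    return {f.code for f in findings if f.level == level}


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def test_assemble_rc_fixture_counts(rc_network):
    doc = io_cli.network_to_document(rc_network)
    net = assemble_network(doc)
    assert len(net.entities) == 2
    assert len(net.properties) == 6
    assert len(net.dependencies) == 3
    assert len(net.sources) == 1


def test_assemble_reports_dangling_reference(rc_network):
    doc = io_cli.network_to_document(rc_network)
    doc["dependencies"][0]["bindings"][0]["property"] = "p99"
    with pytest.raises(UnresolvedRefError) as exc:
        assemble_network(doc)
    assert "p99" in str(exc.value)


def test_assemble_rejects_duplicate_ids(rc_network):
    doc = io_cli.network_to_document(rc_network)
    doc["properties"].append(dict(doc["properties"][0]))
    with pytest.raises(DuplicateIdError):
        assemble_network(doc)


def test_empty_spec_yields_empty_valid_container():
    net = assemble_network({})
    assert isinstance(net, ModelNetwork)
    assert not net.properties and not net.dependencies
    assert validate_network(net) == []


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _bare_net(domain="electrical"):
    net = ModelNetwork(name="t")
    net.add_entity("e", "entity", domain)
    return net


def test_missing_role_detected():
    net = _bare_net()
    net.add_property("i", get_property_class("electrical", "flow"), "e")
    net.add_property("r", get_property_class("electrical", "constitutive.resistance"),
                     "e", value=1.0)
    net.add_dependency("dep", "resistive", [
        ("flow_player", "i"), ("constitutive", "r")])
    assert "E_MISSING_ROLE" in codes(validate_network(net))


def test_domain_mismatch_detected_for_resistive():
    net = _bare_net()
    net.add_entity("f", "pipe", "fluid")
    net.add_property("q", get_property_class("fluid", "flow"), "f")
    net.add_property("va", get_property_class("electrical", "force"), "e")
    net.add_property("vb", get_property_class("electrical", "force"), "e")
    net.add_property("r", get_property_class("fluid", "constitutive.resistance"),
                     "f", value=1.0)
    net.add_dependency("dep", "resistive", [
        ("flow_player", "q"), ("force_player_high", "va"),
        ("force_player_low", "vb"), ("constitutive", "r")])
    assert "E_DOMAIN_MISMATCH" in codes(validate_network(net))


def test_transducer_crossing_domains_is_valid():
    net = fixtures.chemo_mech_transducer()
    assert not has_errors(validate_network(net))


def test_transducer_in_single_domain_rejected():
    net = fixtures.chemo_mech_transducer()
    # drag the chemical side into the mechanical domain
    mech_force = get_property_class("mechanical", "force")
    mech_flow = get_property_class("mechanical", "flow")
    net.properties["mu"].prop_class = mech_force
    net.properties["molar_flux"].prop_class = mech_flow
    assert "E_DOMAIN_MISMATCH" in codes(validate_network(net))


def test_wrong_category_detected():
    net = _bare_net()
    net.add_property("q", get_property_class("electrical", "amount"), "e", value=0.0)
    net.add_property("v", get_property_class("electrical", "force"), "e")
    net.add_property("c", get_property_class("electrical", "constitutive.capacitance"),
                     "e", value=1.0)
    net.add_dependency("dep", "capacitive", [
        ("amount_player", "v"),          # force where an amount belongs
        ("force_player", "q"),
        ("constitutive", "c")])
    assert "E_WRONG_CATEGORY" in codes(validate_network(net))


def test_nonpositive_constitutive_detected(rc_network):
    rc_network.properties["resistance"].value = -1.0
    assert "E_BAD_CONSTITUTIVE" in codes(validate_network(rc_network))


def test_missing_initial_value_detected(rc_network):
    rc_network.properties["charge"].value = None
    assert "E_NO_INITIAL" in codes(validate_network(rc_network))


def test_transactor_domain_mismatch_is_only_a_warning():
    findings = validate_network(fixtures.baroreflex_toy())
    assert not has_errors(findings)
    assert "E_DOMAIN_MISMATCH" in codes(findings, level="warning")


def test_validation_is_idempotent_and_deterministic(rc_network):
    rc_network.properties["resistance"].value = -1.0
    rc_network.properties["charge"].value = None
    first = validate_network(rc_network)
    second = validate_network(rc_network)
    assert first == second
    subjects = [f.subject for f in first]
    assert subjects == sorted(subjects)


# ---------------------------------------------------------------------------
# Influence edges
# ---------------------------------------------------------------------------


def test_rc_influence_edges(rc_network):
    edges = influence_edges(rc_network)
    assert ("charge", "cap_force", 1) in edges
    assert ("src_force", "current", 1) in edges
    assert ("cap_force", "current", -1) in edges
    assert ("current", "charge", 1) in edges


def test_baroreflex_edge_sign_follows_negative_gain():
    edges = influence_edges(fixtures.baroreflex_toy(c=-0.5))
    assert ("aortic_pressure", "heart_rate", -1) in edges


def test_summation_gives_one_positive_edge_per_part():
    edges = influence_edges(fixtures.multiscale_sum([1.0, 2.0, 3.0]))
    plus = [(s, t) for s, t, sign in edges if t == "vol_organ" and sign == 1]
    assert len(plus) == 3


def test_influence_edges_requires_compilable_network():
    net = _bare_net()
    net.add_property("v", get_property_class("electrical", "force"), "e")
    # v has no provider: causality cannot be assigned
    with pytest.raises(NotCompiledError):
        influence_edges(net)
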