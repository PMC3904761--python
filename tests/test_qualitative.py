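"""Sign propagation and its agreement with the numeric steady-state oracle."""

import random

import pytest

from opbnet import fixtures, qualitative
from opbnet.errors import UnresolvedRefError
from opbnet.network import ModelNetwork
from opbnet.qualitative import (
    InfluenceGraph,
    build_influence_graph,
    check_against_numeric,
    propagate,
    sign_add,
    sign_mul,
)
from opbnet.taxonomy import get_property_class

# fixtures with a unique steady state and at least one driving source
STEADY_FIXTURES = (
    "rc_circuit",
    "windkessel",
    "windkessel_discharge",
    "chemo_mech_transducer",
    "baroreflex_toy",
)


def test_sign_algebra_tables():
    assert sign_mul("+", "+") == "+"
    assert sign_mul("+", "-") == "-"
    assert sign_mul("-", "-") == "+"
    assert sign_mul("?", "+") == "?"
    assert sign_mul("0", "?") == "0"
    assert sign_add("+", "+") == "+"
    assert sign_add("+", "-") == "?"
    assert sign_add("+", "0") == "+"
    assert sign_add("?", "-") == "?"
    assert sign_add("0", "0") == "0"


def test_rc_propagation_examples(rc_network):
    graph = build_influence_graph(rc_network)
    signs = propagate(graph, "src_force", "up")
    assert signs["charge"] == "+"
    assert signs["cap_force"] == "+"


def test_unknown_property_rejected(rc_network):
    graph = build_influence_graph(rc_network)
    with pytest.raises(UnresolvedRefError):
        propagate(graph, "nope", "up")


def test_sink_perturbation_leaves_rest_at_zero(rc_network):
    graph = build_influence_graph(rc_network)
    signs = propagate(graph, "charge", "up")  # charge -> cap_force -> current
    assert signs["src_force"] == "0"          # no path back to the source


@pytest.mark.parametrize("name", STEADY_FIXTURES)
def test_up_down_antisymmetry(name):
    graph = build_influence_graph(fixtures.make_fixture(name))
    neg = {"+": "-", "-": "+", "0": "0", "?": "?"}
    for node in graph.nodes:
        up = propagate(graph, node, "up")
        down = propagate(graph, node, "down")
        assert down == {k: neg[v] for k, v in up.items()}


def test_propagation_independent_of_edge_order(windkessel_network):
    graph = build_influence_graph(windkessel_network)
    shuffled = list(graph.edges)
    random.Random(3).shuffle(shuffled)
    g2 = InfluenceGraph(graph.nodes, shuffled)
    for node in graph.nodes:
        assert propagate(graph, node, "up") == propagate(g2, node, "up")


def _opposing_paths_net():
    """One source feeding a sum through a +2 and a −1 transactor path.

    Numerically the sum moves up with the source; qualitatively the two
    opposing paths collapse to '?' — conservative, not wrong.
    """
    net = ModelNetwork(name="opposing")
    net.add_entity("e", "node", "fluid")
    force = get_property_class("fluid", "force")
    amount = get_property_class("fluid", "amount")
    coeff = get_property_class(None, "constitutive.coefficient")
    net.add_property("drive", force, "e")
    net.add_property("x", amount, "e")
    net.add_property("y", amount, "e")
    net.add_property("z", amount, "e")
    net.add_property("c_pos", coeff, "e", value=2.0)
    net.add_property("c_neg", coeff, "e", value=-1.0)
    net.add_dependency("t_pos", "transactor", [
        ("source_player", "drive"), ("target_player", "x"), ("constitutive", "c_pos")])
    net.add_dependency("t_neg", "transactor", [
        ("source_player", "drive"), ("target_player", "y"), ("constitutive", "c_neg")])
    net.add_dependency("sum", "summation", [
        ("whole_player", "z"), ("part_player", "x"), ("part_player", "y")])
    net.add_source("drive", "constant", level=1.0)
    return net


def test_opposing_paths_yield_conservative_conflict():
    net = _opposing_paths_net()
    graph = build_influence_graph(net)
    signs = propagate(graph, "drive", "up")
    assert signs["x"] == "+" and signs["y"] == "-"
    assert signs["z"] == "?"
    report = check_against_numeric(net, "drive")
    z_row = next(r for r in report.rows if r.property == "z")
    assert z_row.numeric == "+"             # 2·P − 1·P rises with P
    assert z_row.status == "conservative"
    assert not report.contradictions


def test_rc_numeric_agreement(rc_network):
    report = check_against_numeric(rc_network, "src_force")
    assert not report.contradictions
    by_prop = {r.property: r for r in report.rows}
    assert by_prop["charge"].status == "agree"
    assert by_prop["cap_force"].status == "agree"


def test_windkessel_inflow_up_raises_pressure_and_volume(windkessel_network):
    report = check_against_numeric(windkessel_network, "inflow")
    by_prop = {r.property: r for r in report.rows}
    for pid in ("pressure", "volume", "outflow"):
        assert by_prop[pid].qualitative == "+"
        assert by_prop[pid].numeric == "+"
        assert by_prop[pid].status == "agree"


def test_baroreflex_heart_rate_opposes_pressure():
    report = check_against_numeric(fixtures.baroreflex_toy(), "aortic_pressure")
    hr = next(r for r in report.rows if r.property == "heart_rate")
    assert hr.qualitative == "-" and hr.numeric == "-" and hr.status == "agree"


@pytest.mark.parametrize("name", STEADY_FIXTURES)
def test_soundness_against_numeric_oracle(name):
    """Propagated signs never strictly contradict the numeric steady state."""
    net = fixtures.make_fixture(name)
    for src in list(net.sources):
        report = check_against_numeric(net, src)
        assert report.contradictions == []


def test_report_writer(tmp_path, rc_network):
    report = check_against_numeric(rc_network, "src_force")
    out = tmp_path / "report.tsv"
    report.write_tsv(out)
    lines = out.read_text().splitlines()
    assert lines[0] == "property\tqualitative\tnumeric\tstatus"
    assert len(lines) == len(report.rows) + 1
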