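"""Domain/property taxonomy: canonical units, dimensional rules, analogies."""

import re

import pytest
import sympy

from opbnet import taxonomy
from opbnet.errors import NoSuchPropertyError
from opbnet.taxonomy import (
    DOMAINS,
    RATE_CATEGORIES,
    STATE_CATEGORIES,
    analog_of,
    canonical_unit,
    category_group,
    dependency_catalog,
    dimension_of,
    get_property_class,
)

BUILTIN_DOMAINS = ("electrical", "fluid", "chemical", "mechanical")

# Independent symbolic oracle: expand unit atoms into SI base symbols with
# sympy and compare simplified expressions.
_SI = {
    "Wb": "(kg*m**2/(s**2*A))",
    "Pa": "(kg/(m*s**2))",
    "mol": "mol",
    "kg": "kg",
    "V": "(kg*m**2/(s**3*A))",
    "C": "(A*s)",
    "N": "(kg*m/s**2)",
    "J": "(kg*m**2/s**2)",
    "A": "A",
    "m": "m",
    "s": "s",
}


def _sympy_unit(expr: str):
    expr = expr.replace("·", "*").replace("^", "**")
    for atom in sorted(_SI, key=len, reverse=True):
        expr = re.sub(rf"(?<![A-Za-z]){atom}(?![A-Za-z])", _SI[atom], expr)
    return sympy.sympify(expr)


@pytest.mark.parametrize("domain,category,expected", [
    ("electrical", "flow", "A"),
    ("electrical", "force", "V"),
    ("fluid", "amount", "m^3"),
    ("chemical", "force", "J/mol"),
    ("mechanical", "momentum", "N·s"),
])
def test_canonical_unit_table(domain, category, expected):
    assert canonical_unit(domain, category) == expected


def test_mechanical_inductance_reduces_to_kilograms():
    unit = canonical_unit("mechanical", "constitutive.inductance")
    assert dimension_of(unit) == dimension_of("kg")
    assert sympy.simplify(_sympy_unit(unit) / _sympy_unit("kg")) == 1


def test_chemical_momentum_is_absent():
    with pytest.raises(NoSuchPropertyError):
        canonical_unit("chemical", "momentum")
    with pytest.raises(NoSuchPropertyError):
        get_property_class("chemical", "constitutive.inductance")


@pytest.mark.parametrize("domain", BUILTIN_DOMAINS)
def test_flow_is_amount_per_time(domain):
    flow = dimension_of(canonical_unit(domain, "flow"))
    amount = dimension_of(canonical_unit(domain, "amount"))
    per_second = tuple(f - a for f, a in zip(flow, amount))
    assert per_second == dimension_of("1/s")


@pytest.mark.parametrize("category,numerator,denominator", [
    ("constitutive.resistance", "force", "flow"),
    ("constitutive.conductance", "flow", "force"),
    ("constitutive.capacitance", "amount", "force"),
    ("constitutive.inductance", "momentum", "flow"),
    ("constitutive.rate_constant", "flow", "amount"),
])
@pytest.mark.parametrize("domain", BUILTIN_DOMAINS)
def test_constitutive_units_obey_defining_relations(domain, category, numerator, denominator):
    """Every constitutive canonical unit is the quotient its law mandates."""
    try:
        cons = canonical_unit(domain, category)
        num = canonical_unit(domain, numerator)
        den = canonical_unit(domain, denominator)
    except NoSuchPropertyError:
        assert domain == "chemical"  # only the inductive column may be absent
        return
    lhs = dimension_of(cons)
    rhs = tuple(a - b for a, b in zip(dimension_of(num), dimension_of(den)))
    assert lhs == rhs
    # independent symbolic reduction
    ratio = _sympy_unit(cons) * _sympy_unit(den) / _sympy_unit(num)
    assert sympy.simplify(ratio) == 1


def test_analogy_examples():
    e_force = get_property_class("electrical", "force")
    assert analog_of(e_force, "fluid").label == "Fluid pressure"
    f_vol = get_property_class("fluid", "amount")
    assert analog_of(f_vol, "chemical").label == "Molar amount"
    with pytest.raises(NoSuchPropertyError):
        analog_of(get_property_class("mechanical", "momentum"), "chemical")


def test_analogy_is_a_bijection_where_defined():
    """analog_of(analog_of(p, d2), d1) == p for categories both domains have."""
    for d1 in BUILTIN_DOMAINS:
        for d2 in BUILTIN_DOMAINS:
            for cat in STATE_CATEGORIES + RATE_CATEGORIES:
                try:
                    p = get_property_class(d1, cat)
                except NoSuchPropertyError:
                    continue
                try:
                    q = analog_of(p, d2)
                except NoSuchPropertyError:
                    assert d2 == "chemical" and cat == "momentum"
                    continue
                assert analog_of(q, d1) == p


def test_dependency_catalog_contents_and_order():
    catalog = dependency_catalog()
    ids = [k.id for k in catalog]
    assert len(ids) >= 12
    for expected in ("boundary_flow", "boundary_force", "summation", "spatial",
                     "resistive", "mass_action", "diffusion", "transformer",
                     "transducer", "capacitive", "inductive", "transactor"):
        assert expected in ids
    assert ids == [k.id for k in dependency_catalog()]  # stable order

    resistive = next(k for k in catalog if k.id == "resistive")
    assert set(resistive.roles) == {"flow_player", "force_player_high",
                                    "force_player_low", "constitutive"}
    force_roles = [r for r in resistive.roles if r.startswith("force_player")]
    assert len(force_roles) == 2
    capacitive = next(k for k in catalog if k.id == "capacitive")
    assert set(capacitive.roles) == {"force_player", "amount_player", "constitutive"}
    assert "capacitance" in next(iter(capacitive.roles["constitutive"].categories))


def test_category_groups():
    assert category_group("amount") == "state"
    assert category_group("momentum") == "state"
    assert category_group("force") == "rate"
    assert category_group("flow") == "rate"
    assert category_group("constitutive.resistance") == "constitutive"
    with pytest.raises(NoSuchPropertyError):
        category_group("entropy")


def test_register_domain_hook_adds_full_unit_row():
    if "rotational" not in DOMAINS:
        taxonomy.register_domain("rotational", "Rotational domain", {
            "force": "N·m", "flow": "1/s", "amount": "1", "momentum": "N·m·s",
        })
    r = canonical_unit("rotational", "constitutive.resistance")
    assert dimension_of(r) == dimension_of("N·m·s")
    assert analog_of(get_property_class("electrical", "force"), "rotational").domain == "rotational"


def test_export_taxonomy_is_complete():
    doc = taxonomy.export_taxonomy()
    assert {d["id"] for d in doc["domains"]} >= set(BUILTIN_DOMAINS)
    ids = {c["id"] for c in doc["property_classes"]}
    assert "electrical.force" in ids and "modulus" in ids
    assert {k["id"] for k in doc["dependency_kinds"]} == {
        k.id for k in dependency_catalog()}
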