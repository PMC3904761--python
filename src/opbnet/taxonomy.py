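"""Property taxonomy, biophysical domains, cross-domain analogies, canonical units.

Lumped-parameter biophysics rests on a small set of system-dynamic analogies:
every biophysical domain (electrical, fluid, chemical, mechanical, ...) has a
generalized *force* (effort: voltage, pressure, chemical potential, mechanical
force), a generalized *flow* (current, volume flow rate, molar flux, velocity),
a generalized *amount* (displacement state: charge, volume, molar amount,
position) and — where inertial storage exists — a generalized *momentum*
(flux linkage, fluid momentum, linear momentum).  Constitutive proportionality
properties (resistance, conductance, capacitance, inductance, rate constant,
transformer modulus, transactor coefficient) parameterize the ideal physical
laws that relate these.

This module registers the four built-in domains, the property categories, one
property class per (domain, category) pair — the chemical domain deliberately
lacks momentum and inductance, as there is no accepted chemical inertial
analogue — and the canonical-unit table.  Canonical units obey the defining
dimensional relations::

    unit(resistance)  = unit(force)  / unit(flow)
    unit(capacitance) = unit(amount) / unit(force)
    unit(inductance)  = unit(momentum) / unit(flow)
    unit(flow)        = unit(amount) / time

A tiny symbolic dimension algebra (`dimension_of`) verifies these reductions;
only canonical units and dimensional checking are supported, never general
unit conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

from .errors import NoSuchPropertyError

# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------

STATE_CATEGORIES = ("amount", "momentum")
RATE_CATEGORIES = ("force", "flow")
CONSTITUTIVE_CATEGORIES = (
    "constitutive.resistance",
    "constitutive.conductance",
    "constitutive.capacitance",
    "constitutive.inductance",
    "constitutive.rate_constant",
    "constitutive.modulus",
    "constitutive.coefficient",
)
ALL_CATEGORIES = STATE_CATEGORIES + RATE_CATEGORIES + CONSTITUTIVE_CATEGORIES


def category_group(category: str) -> str:
    """Return 'state', 'rate' or 'constitutive' for a category id."""
    if category in STATE_CATEGORIES:
        return "state"
    if category in RATE_CATEGORIES:
        return "rate"
    if category in CONSTITUTIVE_CATEGORIES:
        return "constitutive"
    raise NoSuchPropertyError(f"unknown category {category!r}")


# ---------------------------------------------------------------------------
# Dimension algebra (for dimensional checking only)
# ---------------------------------------------------------------------------

# SI base-dimension exponents: (kg, m, s, A, mol)
_ATOM_DIMS: Dict[str, Tuple[int, ...]] = {
    "kg": (1, 0, 0, 0, 0),
    "m": (0, 1, 0, 0, 0),
    "s": (0, 0, 1, 0, 0),
    "A": (0, 0, 0, 1, 0),
    "mol": (0, 0, 0, 0, 1),
    "C": (0, 0, 1, 1, 0),          # coulomb = A*s
    "V": (1, 2, -3, -1, 0),        # volt
    "Wb": (1, 2, -2, -1, 0),       # weber
    "Pa": (1, -1, -2, 0, 0),       # pascal
    "N": (1, 1, -2, 0, 0),         # newton
    "J": (1, 2, -2, 0, 0),         # joule
    "1": (0, 0, 0, 0, 0),          # dimensionless
}

Dimension = Tuple[int, int, int, int, int]

DIMENSIONLESS: Dimension = (0, 0, 0, 0, 0)


def _dim_mul(a: Dimension, b: Dimension, sign: int = 1) -> Dimension:
    return tuple(x + sign * y for x, y in zip(a, b))  # type: ignore[return-value]


def _dim_pow(a: Dimension, n: int) -> Dimension:
    return tuple(x * n for x in a)  # type: ignore[return-value]


def dimension_of(unit: str) -> Dimension:
    """Reduce a canonical unit expression to SI base-dimension exponents.

    Supports atoms (V, A, Pa, mol, ...), '·' or '*' products, '/' quotients,
    integer '^' powers and parentheses, e.g. ``"(N·s)/(m/s)"`` -> kg.
    """
    tokens = _tokenize(unit)
    dim, pos = _parse_expr(tokens, 0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in unit {unit!r}")
    return dim


def _tokenize(unit: str) -> List[str]:
    out: List[str] = []
    i = 0
    s = unit.replace("·", "*").replace(" ", "")
    while i < len(s):
        ch = s[i]
        if ch in "*/^()":
            out.append(ch)
            i += 1
        elif ch.isalnum():
            j = i
            while j < len(s) and (s[j].isalnum() or s[j] == "-"):
                j += 1
            out.append(s[i:j])
            i = j
        else:
            raise ValueError(f"bad character {ch!r} in unit {unit!r}")
    return out


def _parse_expr(tokens: List[str], pos: int) -> Tuple[Dimension, int]:
    dim, pos = _parse_factor(tokens, pos)
    while pos < len(tokens) and tokens[pos] in "*/":
        op = tokens[pos]
        rhs, pos = _parse_factor(tokens, pos + 1)
        dim = _dim_mul(dim, rhs, 1 if op == "*" else -1)
    return dim, pos


def _parse_factor(tokens: List[str], pos: int) -> Tuple[Dimension, int]:
    if pos >= len(tokens):
        raise ValueError("unexpected end of unit expression")
    tok = tokens[pos]
    if tok == "(":
        dim, pos = _parse_expr(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise ValueError("unbalanced parentheses in unit expression")
        pos += 1
    else:
        if tok not in _ATOM_DIMS:
            raise ValueError(f"unknown unit atom {tok!r}")
        dim = _ATOM_DIMS[tok]
        pos += 1
        if pos < len(tokens) and tokens[pos] == "^":
            dim = _dim_pow(dim, int(tokens[pos + 1]))
            pos += 2
    return dim, pos


# ---------------------------------------------------------------------------
# Domains and property classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiophysicalDomain:
    """One biophysical domain (electrical, fluid, chemical, mechanical, ...)."""

    id: str
    label: str


@dataclass(frozen=True)
class PropertyClass:
    """A physical-property class: one (domain, category) cell of the analogy table.

    ``domain`` is None for domain-generic constitutive classes (transformer
    modulus, transactor coefficient).
    """

    id: str
    category: str
    domain: Optional[str]
    label: str
    canonical_unit: str


DOMAINS: Dict[str, BiophysicalDomain] = {}

# (domain id, category id) -> PropertyClass
_PROPERTY_CLASSES: Dict[Tuple[Optional[str], str], PropertyClass] = {}

_DOMAIN_LABELS = {
    "electrical": "Electrical domain",
    "fluid": "Fluid domain",
    "chemical": "Chemical domain",
    "mechanical": "Solid mechanical domain",
}

# Base (state/rate) canonical units per built-in domain; chemical momentum is
# deliberately absent — the taxonomy declares it missing rather than zero.
_BASE_UNITS: Dict[str, Dict[str, str]] = {
    "electrical": {"force": "V", "flow": "A", "amount": "C", "momentum": "Wb"},
    "fluid": {"force": "Pa", "flow": "m^3/s", "amount": "m^3", "momentum": "Pa·s"},
    "chemical": {"force": "J/mol", "flow": "mol/s", "amount": "mol"},
    "mechanical": {"force": "N", "flow": "m/s", "amount": "m", "momentum": "N·s"},
}

_BASE_LABELS: Dict[str, Dict[str, str]] = {
    "electrical": {
        "force": "Electrical potential",
        "flow": "Electrical current",
        "amount": "Electrical charge",
        "momentum": "Flux linkage",
    },
    "fluid": {
        "force": "Fluid pressure",
        "flow": "Fluid flow rate",
        "amount": "Fluid volume",
        "momentum": "Fluid momentum",
    },
    "chemical": {
        "force": "Chemical potential",
        "flow": "Molar flow rate",
        "amount": "Molar amount",
    },
    "mechanical": {
        "force": "Mechanical force",
        "flow": "Translational velocity",
        "amount": "Displacement",
        "momentum": "Linear momentum",
    },
}

_CONSTITUTIVE_LABEL = {
    "constitutive.resistance": "resistance",
    "constitutive.conductance": "conductance",
    "constitutive.capacitance": "capacitance",
    "constitutive.inductance": "inductance",
    "constitutive.rate_constant": "rate constant",
}


def _short_category(category: str) -> str:
    return category.split(".", 1)[-1]


def register_domain(domain_id: str, label: str, units: Mapping[str, str]) -> BiophysicalDomain:
    """Register a biophysical domain with its full canonical-unit row.

    ``units`` maps state/rate category ids to canonical unit strings; momentum
    may be omitted (as in the chemical domain).  Constitutive classes are
    derived from the dimensional rules.  This is the extension hook for
    domains beyond the built-in four (e.g. thermal, rotational).
    """
    if domain_id in DOMAINS:
        raise ValueError(f"domain {domain_id!r} already registered")
    if "force" not in units or "flow" not in units or "amount" not in units:
        raise ValueError("a domain needs at least force, flow and amount units")
    dom = BiophysicalDomain(domain_id, label)
    DOMAINS[domain_id] = dom
    labels = _BASE_LABELS.get(domain_id, {})
    for cat, unit in units.items():
        lab = labels.get(cat, f"{label} {cat}")
        _add_class(domain_id, cat, lab, unit)
    # derived constitutive rows
    u = dict(units)
    derived = {
        "constitutive.resistance": f"({u['force']})/({u['flow']})",
        "constitutive.conductance": f"({u['flow']})/({u['force']})",
        "constitutive.capacitance": f"({u['amount']})/({u['force']})",
        "constitutive.rate_constant": f"({u['flow']})/({u['amount']})",
    }
    if "momentum" in u:
        derived["constitutive.inductance"] = f"({u['momentum']})/({u['flow']})"
    cap = label.split()[0].capitalize()
    for cat, unit in derived.items():
        lab = f"{cap} {_CONSTITUTIVE_LABEL[cat]}"
        _add_class(domain_id, cat, lab, unit)
    return dom


def _add_class(domain_id: Optional[str], category: str, label: str, unit: str) -> PropertyClass:
    cls_id = f"{domain_id}.{_short_category(category)}" if domain_id else _short_category(category)
    pc = PropertyClass(cls_id, category, domain_id, label, unit)
    _PROPERTY_CLASSES[(domain_id, category)] = pc
    return pc


def _bootstrap() -> None:
    for dom_id, units in _BASE_UNITS.items():
        register_domain(dom_id, _DOMAIN_LABELS[dom_id], units)
    # domain-generic constitutive classes
    _add_class(None, "constitutive.modulus", "Transformer modulus", "1")
    _add_class(None, "constitutive.coefficient", "Transactor coefficient", "1")


_bootstrap()


# ---------------------------------------------------------------------------
# Lookup operations
# ---------------------------------------------------------------------------


def get_property_class(domain: Optional[str], category: str) -> PropertyClass:
    """Look up the unique property class for a (domain, category) pair.

    Domain-generic constitutive classes (modulus, coefficient) are found under
    domain None regardless of the domain argument.
    """
    category_group(category)  # validates the category id
    if category in ("constitutive.modulus", "constitutive.coefficient"):
        return _PROPERTY_CLASSES[(None, category)]
    if domain is not None and domain not in DOMAINS:
        raise NoSuchPropertyError(f"unknown domain {domain!r}")
    try:
        return _PROPERTY_CLASSES[(domain, category)]
    except KeyError:
        raise NoSuchPropertyError(f"no property class for ({domain}, {category})") from None


def class_by_id(class_id: str) -> PropertyClass:
    """Resolve a property class from its id string (e.g. 'electrical.force')."""
    for pc in _PROPERTY_CLASSES.values():
        if pc.id == class_id:
            return pc
    raise NoSuchPropertyError(f"unknown property class id {class_id!r}")


def canonical_unit(domain: str, category: str) -> str:
    """Canonical unit string for a (domain, category) pair.

    Raises :class:`NoSuchPropertyError` for absent pairs such as chemical
    momentum.
    """
    return get_property_class(domain, category).canonical_unit


def analog_of(prop: PropertyClass, target_domain: str) -> PropertyClass:
    """Map a state/rate property class to its analogue in another domain.

    The analogy map preserves the category: e.g. electrical potential (force)
    maps to fluid pressure; fluid volume (amount) maps to molar amount.  It is
    a bijection between any two domains restricted to the categories both
    possess; pairs the target lacks (chemical momentum) raise
    :class:`NoSuchPropertyError`.
    """
    if category_group(prop.category) == "constitutive":
        raise NoSuchPropertyError(
            f"analog_of is defined for state/rate categories, not {prop.category}"
        )
    return get_property_class(target_domain, prop.category)


def dependency_catalog():
    """Every registered dependency kind with its role signature, in stable order.

    Delegates to :mod:`opbnet.laws`, which owns the kind registry.
    """
    from . import laws

    return list(laws.KINDS.values())


def export_taxonomy() -> dict:
    """The full taxonomy as one machine-readable document (plain dict).

    Covers domains, categories, property classes with canonical units, the
    dependency-kind role signatures and the analogy table; used for docs and
    as the seed for the RDF exporter's IRI map.
    """
    from . import laws

    classes = sorted(_PROPERTY_CLASSES.values(), key=lambda c: c.id)
    doc = {
        "domains": [{"id": d.id, "label": d.label} for d in sorted(DOMAINS.values(), key=lambda d: d.id)],
        "categories": [
            {"id": c, "group": category_group(c)} for c in ALL_CATEGORIES
        ],
        "property_classes": [
            {
                "id": c.id,
                "category": c.category,
                "domain": c.domain,
                "label": c.label,
                "canonical_unit": c.canonical_unit,
            }
            for c in classes
        ],
        "dependency_kinds": [
            {
                "id": k.id,
                "opb_label": k.opb_label,
                "roles": {
                    r: {
                        "categories": sorted(spec.categories) if spec.categories else "any",
                        "min": spec.min_count,
                        "max": spec.max_count,
                    }
                    for r, spec in k.roles.items()
                },
                "outputs": list(k.outputs),
                "domain_rule": k.domain_rule,
            }
            for k in dependency_catalog()
        ],
        "analogies": [
            {
                "category": cat,
                "classes": {
                    d: _PROPERTY_CLASSES[(d, cat)].id
                    for d in sorted(DOMAINS)
                    if (d, cat) in _PROPERTY_CLASSES
                },
            }
            for cat in STATE_CATEGORIES + RATE_CATEGORIES
        ],
    }
    return doc
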