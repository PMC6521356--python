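"""SBML import/export of the reaction network.

Networks are written as SBML Level 3 Version 1 with MathML kinetic laws;
a compact annotation (namespace ``he4ns``) records the rate-law kind and
its parameter-role mapping plus species roles and feature flags, so a
write→read round trip is the identity on the supported construct subset.
Level 2 (e.g. the COPASI dialect) and Level 3 documents are both accepted
on read.  Documents containing constructs outside the subset — events,
rules, function definitions, constraints — are rejected with a clear
error rather than silently dropped.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .network import (
    Compartment,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
)

__all__ = ["read_sbml", "write_sbml", "UnsupportedSBMLError"]

SBML_L3_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://example.org/her4jakstat/sbml-annotations"

_UNSUPPORTED = {
    "listOfEvents", "event",
    "listOfRules", "assignmentRule", "rateRule", "algebraicRule",
    "listOfFunctionDefinitions", "functionDefinition",
    "listOfConstraints", "constraint",
    "listOfInitialAssignments", "initialAssignment",
}


class UnsupportedSBMLError(ValueError):
    """The document uses SBML constructs outside the supported subset."""


def _local(el) -> str:
    return etree.QName(el).localname


def _mathml_mass_action(root, rxn: Reaction, reverse_params: bool) -> None:
    """<math> for kf*prod(reactants) [- kr*prod(products)]."""
    math = etree.SubElement(root, f"{{{MATHML_NS}}}math")

    def product(parent, k_id, participants):
        apply_ = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
        etree.SubElement(apply_, f"{{{MATHML_NS}}}ci").text = k_id
        for sid, st in participants:
            for _ in range(st):
                etree.SubElement(apply_, f"{{{MATHML_NS}}}ci").text = sid

    if reverse_params:
        apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_, f"{{{MATHML_NS}}}minus")
        product(apply_, rxn.rate_law.params["kf"], rxn.reactants)
        product(apply_, rxn.rate_law.params["kr"], rxn.products)
    elif rxn.rate_law.kind == "hill_activation":
        p = rxn.rate_law.params
        m = rxn.modifiers[0]
        apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_, f"{{{MATHML_NS}}}divide")
        num = etree.SubElement(apply_, f"{{{MATHML_NS}}}apply")
        etree.SubElement(num, f"{{{MATHML_NS}}}times")
        etree.SubElement(num, f"{{{MATHML_NS}}}ci").text = p["V_transc"]
        pw = etree.SubElement(num, f"{{{MATHML_NS}}}apply")
        etree.SubElement(pw, f"{{{MATHML_NS}}}power")
        etree.SubElement(pw, f"{{{MATHML_NS}}}ci").text = m
        etree.SubElement(pw, f"{{{MATHML_NS}}}ci").text = p["n_transc"]
        den = etree.SubElement(apply_, f"{{{MATHML_NS}}}apply")
        etree.SubElement(den, f"{{{MATHML_NS}}}plus")
        pw = etree.SubElement(den, f"{{{MATHML_NS}}}apply")
        etree.SubElement(pw, f"{{{MATHML_NS}}}power")
        etree.SubElement(pw, f"{{{MATHML_NS}}}ci").text = p["K_transc"]
        etree.SubElement(pw, f"{{{MATHML_NS}}}ci").text = p["n_transc"]
        pw = etree.SubElement(den, f"{{{MATHML_NS}}}apply")
        etree.SubElement(pw, f"{{{MATHML_NS}}}power")
        etree.SubElement(pw, f"{{{MATHML_NS}}}ci").text = m
        etree.SubElement(pw, f"{{{MATHML_NS}}}ci").text = p["n_transc"]
    else:
        key = "k_transport" if rxn.rate_law.kind == "first_order_transport" else "kf"
        product(math, rxn.rate_law.params[key], rxn.reactants)


def write_sbml(net: ReactionNetwork, path: str | Path) -> None:
    """Serialize a network as SBML Level 3 Version 1."""
    nsmap = {None: SBML_L3_NS, "he4": ANNOT_NS}
    sbml = etree.Element(f"{{{SBML_L3_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    model = etree.SubElement(sbml, f"{{{SBML_L3_NS}}}model")
    model.set("id", "her4_jak_stat")
    model.set(f"{{{ANNOT_NS}}}heterodimerization_on", str(net.heterodimerization_on).lower())
    model.set(f"{{{ANNOT_NS}}}jak_independent_on", str(net.jak_independent_on).lower())

    locomp = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfCompartments")
    for c in net.compartments:
        el = etree.SubElement(locomp, f"{{{SBML_L3_NS}}}compartment")
        el.set("id", c.id)
        el.set("name", c.name)
        el.set("size", repr(c.volume))
        el.set("constant", "true")

    losp = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfSpecies")
    for s in net.species:
        el = etree.SubElement(losp, f"{{{SBML_L3_NS}}}species")
        el.set("id", s.id)
        el.set("name", s.name)
        el.set("compartment", s.compartment)
        el.set("initialConcentration", repr(s.initial_amount))
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "true" if s.boundary else "false")
        el.set("constant", "false")
        el.set(f"{{{ANNOT_NS}}}role", s.role)

    lopar = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfParameters")
    for pid, val in net.parameters.items():
        el = etree.SubElement(lopar, f"{{{SBML_L3_NS}}}parameter")
        el.set("id", pid)
        el.set("value", repr(val))
        el.set("constant", "true")

    lorxn = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfReactions")
    for r in net.reactions:
        el = etree.SubElement(lorxn, f"{{{SBML_L3_NS}}}reaction")
        el.set("id", r.id)
        el.set("name", r.name)
        reversible = r.rate_law.kind == "mass_action_reversible"
        el.set("reversible", str(reversible).lower())
        el.set("fast", "false")
        el.set(f"{{{ANNOT_NS}}}kind", r.rate_law.kind)
        el.set(f"{{{ANNOT_NS}}}params",
               ";".join(f"{role}={pid}" for role, pid in sorted(r.rate_law.params.items())))
        if r.reactants:
            lo = etree.SubElement(el, f"{{{SBML_L3_NS}}}listOfReactants")
            for sid, st in r.reactants:
                ref = etree.SubElement(lo, f"{{{SBML_L3_NS}}}speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(st))
                ref.set("constant", "true")
        if r.products:
            lo = etree.SubElement(el, f"{{{SBML_L3_NS}}}listOfProducts")
            for sid, st in r.products:
                ref = etree.SubElement(lo, f"{{{SBML_L3_NS}}}speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(st))
                ref.set("constant", "true")
        if r.modifiers:
            lo = etree.SubElement(el, f"{{{SBML_L3_NS}}}listOfModifiers")
            for sid in r.modifiers:
                ref = etree.SubElement(lo, f"{{{SBML_L3_NS}}}modifierSpeciesReference")
                ref.set("species", sid)
        kl = etree.SubElement(el, f"{{{SBML_L3_NS}}}kineticLaw")
        _mathml_mass_action(kl, r, reversible)

    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _infer_rate_law(el, reactants, products, modifiers) -> RateLaw:
    """Reconstruct the rate law from the annotation attributes."""
    kind = el.get(f"{{{ANNOT_NS}}}kind")
    params_attr = el.get(f"{{{ANNOT_NS}}}params")
    if kind is None or params_attr is None:
        raise UnsupportedSBMLError(
            f"reaction {el.get('id')!r}: kinetic law lacks the rate-law "
            "annotation; generic MathML kinetics are not supported"
        )
    params = dict(item.split("=", 1) for item in params_attr.split(";") if item)
    return RateLaw(kind, params)


def read_sbml(path: str | Path) -> ReactionNetwork:
    """Parse an SBML Level 2/3 document into a :class:`ReactionNetwork`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as err:
        raise ValueError(f"malformed XML: {err}") from err
    root = tree.getroot()
    if _local(root) != "sbml":
        raise ValueError("not an SBML document (no <sbml> root)")
    level = root.get("level")
    if level not in ("2", "3"):
        raise UnsupportedSBMLError(f"SBML level {level!r} not supported")
    for el in root.iter():
        if isinstance(el.tag, str) and _local(el) in _UNSUPPORTED:
            raise UnsupportedSBMLError(
                f"unsupported SBML construct <{_local(el)}>"
            )
    model = next((el for el in root if _local(el) == "model"), None)
    if model is None:
        raise ValueError("SBML document has no <model>")

    def children(parent, name):
        if parent is None:
            return []
        return [el for el in parent if isinstance(el.tag, str) and _local(el) == name]

    def section(name):
        return next((el for el in model if _local(el) == name), None)

    compartments = [
        Compartment(
            el.get("id"),
            el.get("name", el.get("id")),
            float(el.get("size", el.get("volume", "1.0"))),
        )
        for el in children(section("listOfCompartments"), "compartment")
    ]
    species = [
        Species(
            el.get("id"),
            el.get("name", el.get("id")),
            el.get("compartment"),
            float(el.get("initialConcentration", el.get("initialAmount", "0.0"))),
            el.get(f"{{{ANNOT_NS}}}role", "protein"),
            el.get("boundaryCondition", "false") == "true",
        )
        for el in children(section("listOfSpecies"), "species")
    ]
    parameters = {
        el.get("id"): float(el.get("value"))
        for el in children(section("listOfParameters"), "parameter")
    }

    reactions = []
    for el in children(section("listOfReactions"), "reaction"):
        def refs(name):
            lo = next((c for c in el if _local(c) == name), None)
            return [
                (c.get("species"), int(float(c.get("stoichiometry", "1"))))
                for c in children(lo, "speciesReference")
            ]
        lo_mod = next((c for c in el if _local(c) == "listOfModifiers"), None)
        modifiers = [c.get("species")
                     for c in children(lo_mod, "modifierSpeciesReference")]
        reactants, products = refs("listOfReactants"), refs("listOfProducts")
        reactions.append(Reaction(
            el.get("id"), el.get("name", el.get("id")),
            reactants, products,
            _infer_rate_law(el, reactants, products, modifiers),
            modifiers=modifiers,
        ))

    return ReactionNetwork(
        compartments, species, reactions, parameters,
        heterodimerization_on=model.get(f"{{{ANNOT_NS}}}heterodimerization_on") == "true",
        jak_independent_on=model.get(f"{{{ANNOT_NS}}}jak_independent_on") == "true",
    )
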