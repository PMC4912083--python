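"""SBML Level 3 export of a ModelSpec (export-only).

The document is written directly as SBML L3V2 core XML: compartments of
size 1 for the membrane/cytosol/nucleus labels, species with initial
concentrations in nM, and reactions whose kinetic laws carry the rate
expression as MathML with local parameters.  Feedback production terms
become reactions with modifier references and no reactants.

A small structural reader (:func:`read_sbml_summary`) parses an exported
document back into counts and kinetic-law structure for round-trip checks.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .errors import SpecificationError
from .network import (
    FIRST_ORDER_DECAY,
    MASS_ACTION,
    MICHAELIS_MENTEN,
    SATURATING_INDUCTION,
    ZERO_ORDER_PRODUCTION,
    COMPARTMENTS,
    ModelSpec,
)

__all__ = ["export_sbml", "read_sbml_summary"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _math(parent):
    return ET.SubElement(parent, f"{{{MATHML_NS}}}math")


def _apply(parent, op):
    node = ET.SubElement(parent, f"{{{MATHML_NS}}}apply")
    ET.SubElement(node, f"{{{MATHML_NS}}}{op}")
    return node


def _ci(parent, name):
    el = ET.SubElement(parent, f"{{{MATHML_NS}}}ci")
    el.text = f" {name} "


def _times_chain(parent, names):
    """name1 * name2 * ...; a single name is emitted bare."""
    if len(names) == 1:
        _ci(parent, names[0])
        return
    node = _apply(parent, "times")
    for n in names:
        _ci(node, n)


def _rate_math(parent, reaction):
    law = reaction.rate_law
    kind = law.kind
    if kind in (MASS_ACTION, FIRST_ORDER_DECAY):
        const = "k" if kind == MASS_ACTION else "beta"
        factors = [const]
        for sp, st in reaction.reactants:
            factors.extend([sp] * st)
        factors.extend(reaction.modifiers)
        _times_chain(parent, factors)
    elif kind == ZERO_ORDER_PRODUCTION:
        _ci(parent, "alpha")
    elif kind == MICHAELIS_MENTEN:
        sub = reaction.reactants[0][0]
        enz = reaction.modifiers[0]
        div = _apply(parent, "divide")
        _times_chain(div, ["kcat", enz, sub])
        plus = _apply(div, "plus")
        _ci(plus, "Km")
        _ci(plus, sub)
    elif kind == SATURATING_INDUCTION:
        mod = reaction.modifiers[0]
        div = _apply(parent, "divide")
        _times_chain(div, ["Vmax", mod])
        plus = _apply(div, "plus")
        _ci(plus, "K")
        _ci(plus, mod)
    else:  # pragma: no cover - guarded by RateLaw validation
        raise SpecificationError(
            f"reaction {reaction.name!r}: rate law {kind!r} has no SBML encoding")


def export_sbml(spec: ModelSpec, path) -> None:
    """Write ``spec`` as an SBML Level 3 Version 2 document."""
    spec.validate()
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model",
                          {"id": "il1_p38_network", "substanceUnits": "item",
                           "timeUnits": "second"})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    used = {s.compartment_label for s in spec.species} or set(COMPARTMENTS)
    for c in COMPARTMENTS:
        if c in used:
            ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                          {"id": c, "size": "1", "constant": "true",
                           "spatialDimensions": "3"})

    sps = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in spec.species:
        ET.SubElement(sps, f"{{{SBML_NS}}}species", {
            "id": s.name,
            "compartment": s.compartment_label,
            "initialConcentration": repr(s.initial_concentration),
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false",
            "constant": "false",
        })

    rxs = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in spec.reactions:
        rx = ET.SubElement(rxs, f"{{{SBML_NS}}}reaction",
                           {"id": r.name, "reversible": "false"})
        if r.reactants:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sp, st in r.reactants:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(st),
                               "constant": "true"})
        if r.products:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sp, st in r.products:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(st),
                               "constant": "true"})
        if r.modifiers:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            for sp in r.modifiers:
                ET.SubElement(lst, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": sp})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        _rate_math(_math(kl), r)
        lp = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        for cname, cval in r.rate_law.constants.items():
            ET.SubElement(lp, f"{{{SBML_NS}}}localParameter",
                          {"id": cname, "value": repr(float(cval))})

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")


def read_sbml_summary(path) -> dict:
    """Parse an exported document back into structural counts.

    Returns species/compartment/reaction counts, per-reaction
    reactant/product/modifier species and local-parameter names, and
    whether each kinetic law carries MathML.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    ns = {"s": SBML_NS, "m": MATHML_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise SpecificationError(f"{path}: no <model> element")
    species = [el.get("id") for el in model.findall(".//s:listOfSpecies/s:species", ns)]
    comps = [el.get("id") for el in model.findall(".//s:listOfCompartments/s:compartment", ns)]
    reactions = {}
    for rx in model.findall(".//s:listOfReactions/s:reaction", ns):
        kl = rx.find("s:kineticLaw", ns)
        reactions[rx.get("id")] = {
            "reactants": [el.get("species") for el in
                          rx.findall("s:listOfReactants/s:speciesReference", ns)],
            "products": [el.get("species") for el in
                         rx.findall("s:listOfProducts/s:speciesReference", ns)],
            "modifiers": [el.get("species") for el in
                          rx.findall("s:listOfModifiers/s:modifierSpeciesReference", ns)],
            "parameters": [el.get("id") for el in
                           kl.findall("s:listOfLocalParameters/s:localParameter", ns)]
            if kl is not None else [],
            "has_math": kl is not None and kl.find("m:math", ns) is not None,
        }
    return {
        "species": species,
        "compartments": comps,
        "reactions": reactions,
        "n_species": len(species),
        "n_reactions": len(reactions),
    }
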