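"""SBML Level 3 Version 2 export/import for mass-action models.

The writer emits a minimal, schema-conformant core document: one compartment,
species for the model states, global parameters for rate constants and
constant inputs, and one reaction per model reaction whose kinetic law is the
mass-action product ``k * modifier`` (or ``k`` for sources).  The importer
reads such documents back; observables have no SBML representation and are
therefore not round-tripped.
"""

from __future__ import annotations

from lxml import etree

from .model import ModelDefinition, Reaction

__all__ = ["export_sbml", "import_sbml", "validate_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_S = "{%s}" % SBML_NS
_M = "{%s}" % MATHML_NS


def export_sbml(model: ModelDefinition, path: str | None = None) -> str:
    """Serialize a model to an SBML L3V2 core document; returns the XML text."""
    root = etree.Element(_S + "sbml", nsmap={None: SBML_NS})
    root.set("level", "3")
    root.set("version", "2")
    m = etree.SubElement(root, _S + "model")
    m.set("id", model.name)

    comps = etree.SubElement(m, _S + "listOfCompartments")
    comp = etree.SubElement(comps, _S + "compartment")
    comp.set("id", "system")
    comp.set("size", "1")
    comp.set("spatialDimensions", "3")
    comp.set("constant", "true")

    species = etree.SubElement(m, _S + "listOfSpecies")
    for sid, x0 in zip(model.state_ids, model.default_initial_state):
        sp = etree.SubElement(species, _S + "species")
        sp.set("id", sid)
        sp.set("compartment", "system")
        sp.set("initialConcentration", repr(float(x0)))
        sp.set("hasOnlySubstanceUnits", "false")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")

    params = etree.SubElement(m, _S + "listOfParameters")
    for pid in model.parameter_ids:
        p = etree.SubElement(params, _S + "parameter")
        p.set("id", pid)
        p.set("value", "1")
        p.set("constant", "true")
    for uid in model.input_ids:
        p = etree.SubElement(params, _S + "parameter")
        p.set("id", uid)
        p.set("value", "1")
        p.set("constant", "true")

    rxns = etree.SubElement(m, _S + "listOfReactions")
    state_set = set(model.state_ids)
    for r in model.reactions:
        rx = etree.SubElement(rxns, _S + "reaction")
        rx.set("id", r.id)
        rx.set("reversible", "false")
        reactants = [(s, -c) for s, c in r.stoichiometry.items() if c < 0]
        products = [(s, c) for s, c in r.stoichiometry.items() if c > 0]
        if reactants:
            lo = etree.SubElement(rx, _S + "listOfReactants")
            for sid, c in reactants:
                ref = etree.SubElement(lo, _S + "speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(c))
                ref.set("constant", "true")
        if products:
            lo = etree.SubElement(rx, _S + "listOfProducts")
            for sid, c in products:
                ref = etree.SubElement(lo, _S + "speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(c))
                ref.set("constant", "true")
        if r.modifier in state_set and r.stoichiometry.get(r.modifier, 0) >= 0:
            lo = etree.SubElement(rx, _S + "listOfModifiers")
            ref = etree.SubElement(lo, _S + "modifierSpeciesReference")
            ref.set("species", r.modifier)
        law = etree.SubElement(rx, _S + "kineticLaw")
        math = etree.SubElement(law, _M + "math", nsmap={None: MATHML_NS})
        if r.modifier is None:
            ci = etree.SubElement(math, _M + "ci")
            ci.text = r.rate_constant
        else:
            ap = etree.SubElement(math, _M + "apply")
            etree.SubElement(ap, _M + "times")
            ci1 = etree.SubElement(ap, _M + "ci")
            ci1.text = r.rate_constant
            ci2 = etree.SubElement(ap, _M + "ci")
            ci2.text = r.modifier

    text = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def import_sbml(text_or_path: str) -> ModelDefinition:
    """Parse an SBML document written by :func:`export_sbml` back to a model.

    States come from non-boundary species, parameters and inputs from global
    parameters (an id referenced as a kinetic-law factor that is not a rate
    constant is classified as an input).  Observables are not represented in
    SBML and the returned model has none.
    """
    if "\n" not in text_or_path and text_or_path.endswith(".xml") or \
            text_or_path.endswith(".sbml"):
        tree = etree.parse(text_or_path)
        root = tree.getroot()
    else:
        root = etree.fromstring(text_or_path.encode())
    m = root.find(_S + "model")
    state_ids = [
        sp.get("id")
        for sp in m.findall(f"{_S}listOfSpecies/{_S}species")
        if sp.get("boundaryCondition") != "true"
    ]
    x0 = [
        float(sp.get("initialConcentration", "0"))
        for sp in m.findall(f"{_S}listOfSpecies/{_S}species")
        if sp.get("boundaryCondition") != "true"
    ]
    all_params = [p.get("id") for p in m.findall(f"{_S}listOfParameters/{_S}parameter")]

    reactions = []
    rate_constants = set()
    for rx in m.findall(f"{_S}listOfReactions/{_S}reaction"):
        stoich: dict[str, int] = {}
        for ref in rx.findall(f"{_S}listOfReactants/{_S}speciesReference"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0) - int(
                float(ref.get("stoichiometry", "1"))
            )
        for ref in rx.findall(f"{_S}listOfProducts/{_S}speciesReference"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0) + int(
                float(ref.get("stoichiometry", "1"))
            )
        cis = [
            ci.text.strip()
            for ci in rx.findall(f"{_S}kineticLaw/{_M}math//{_M}ci")
        ]
        rate = cis[0]
        modifier = cis[1] if len(cis) > 1 else None
        rate_constants.add(rate)
        reactions.append(
            Reaction(
                id=rx.get("id"), rate_constant=rate, modifier=modifier,
                stoichiometry={k: v for k, v in stoich.items() if v != 0},
            )
        )
    parameter_ids = [p for p in all_params if p in rate_constants]
    state_set = set(state_ids)
    input_ids = [
        p for p in all_params
        if p not in rate_constants and any(
            r.modifier == p and p not in state_set for r in reactions
        )
    ]
    return ModelDefinition(
        state_ids=state_ids,
        parameter_ids=parameter_ids,
        input_ids=input_ids,
        reactions=reactions,
        observables=[],
        default_initial_state=x0,
        name=m.get("id", "model"),
    )


def validate_sbml(text: str) -> list[str]:
    """Structural validation of an SBML L3V2 core document.

    Checks namespace and level/version, id uniqueness, that species
    references and kinetic-law symbols resolve to declared components, and
    that required attributes are present.  Returns a list of error strings
    (empty when the document is structurally valid).
    """
    errors: list[str] = []
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    if root.tag != _S + "sbml":
        errors.append(f"root element is {root.tag}, expected SBML L3V2 core <sbml>")
        return errors
    if root.get("level") != "3":
        errors.append("level attribute must be 3")
    if root.get("version") is None:
        errors.append("missing version attribute")
    m = root.find(_S + "model")
    if m is None:
        return errors + ["missing <model> element"]

    ids: list[str] = []
    for tag in ("listOfCompartments/" + _S + "compartment",
                "listOfSpecies/" + _S + "species",
                "listOfParameters/" + _S + "parameter",
                "listOfReactions/" + _S + "reaction"):
        for el in m.findall(_S + tag):
            el_id = el.get("id")
            if not el_id:
                errors.append(f"element {el.tag} without id")
            else:
                ids.append(el_id)
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        errors.append(f"duplicate ids: {dup}")

    species = {sp.get("id") for sp in m.findall(f"{_S}listOfSpecies/{_S}species")}
    comps = {c.get("id") for c in m.findall(f"{_S}listOfCompartments/{_S}compartment")}
    symbols = species | {
        p.get("id") for p in m.findall(f"{_S}listOfParameters/{_S}parameter")
    }
    for sp in m.findall(f"{_S}listOfSpecies/{_S}species"):
        if sp.get("compartment") not in comps:
            errors.append(f"species {sp.get('id')}: unknown compartment")
        for attr in ("hasOnlySubstanceUnits", "boundaryCondition", "constant"):
            if sp.get(attr) is None:
                errors.append(f"species {sp.get('id')}: missing required attribute {attr}")
    for rx in m.findall(f"{_S}listOfReactions/{_S}reaction"):
        rid = rx.get("id")
        if rx.get("reversible") is None:
            errors.append(f"reaction {rid}: missing required attribute reversible")
        for ref in rx.findall(f".//{_S}speciesReference"):
            if ref.get("species") not in species:
                errors.append(f"reaction {rid}: unknown species {ref.get('species')}")
            if ref.get("constant") is None:
                errors.append(f"reaction {rid}: speciesReference missing constant")
        for ci in rx.findall(f"{_S}kineticLaw/{_M}math//{_M}ci"):
            if (ci.text or "").strip() not in symbols:
                errors.append(f"reaction {rid}: kinetic law symbol {ci.text!r} undeclared")
    return errors
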