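"""SBML Level 3 import/export for network models.

Writes the model as SBML L3 core (compartment, species, global parameters,
reactions with MathML kinetic laws) using the standard library XML tools.
Because SBML has no native notion of a typed rate law or a feedback link,
two companions travel with the document:

* a package annotation inside each reaction (namespace
  ``https://nfatnet.invalid/sbml``) recording the structured law — form,
  Hill exponent, parameter roles, modifier kinds, input gating — which the
  reader uses to reconstruct the typed :class:`~nfatnet.network.Reaction`
  losslessly;
* a sidecar YAML file (``<model>.links.yaml``) carrying the feedback-link
  annotation (name, sign, controlled parameters) and conserved moieties.

The reader accepts this package's documents and any L3 document restricted
to the same constructs; unsupported constructs (rules, events, function
definitions, reactions without the annotation) are collected and reported,
never silently dropped.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import yaml

from .network import (
    FeedbackLink,
    FeedbackSign,
    KineticLaw,
    LawForm,
    NetworkModel,
    Reaction,
    Species,
    SpeciesRole,
)
from .parameters import ParameterSet

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://nfatnet.invalid/sbml"


class SBMLError(ValueError):
    pass


@dataclass
class UnsupportedConstruct:
    element: str
    path: str
    detail: str = ""


def _links_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".links.yaml")


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

def _mathml_law(rxn: Reaction, law: KineticLaw) -> ET.Element:
    """MathML <math> tree for the reaction's rate expression."""

    def ci(name: str) -> ET.Element:
        el = ET.Element(f"{{{MATHML_NS}}}ci")
        el.text = f" {name} "
        return el

    def cn(value: float) -> ET.Element:
        el = ET.Element(f"{{{MATHML_NS}}}cn")
        el.text = f" {value:g} "
        return el

    def apply(op: str, *args: ET.Element) -> ET.Element:
        el = ET.Element(f"{{{MATHML_NS}}}apply")
        el.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
        el.extend(args)
        return el

    p = law.params
    if law.form is LawForm.MASS_ACTION:
        factors = [ci(p["k"])]
        for sp, st in rxn.substrates:
            factors += [ci(sp)] * st
        expr = factors[0] if len(factors) == 1 else apply("times", *factors)
    elif law.form is LawForm.MICHAELIS_MENTEN:
        (sub, _), = rxn.substrates
        vmax = apply("times", ci(p["kc"]), ci(rxn.enzyme)) if "kc" in p else ci(p["Vmax"])
        expr = apply("divide", apply("times", vmax, ci(sub)),
                     apply("plus", ci(p["Km"]), ci(sub)))
    else:  # HILL
        s, n = rxn.regulator, law.hill_n
        sn = apply("power", ci(s), cn(n))
        kn = apply("power", ci(p["Km"]), cn(n))
        expr = apply("divide", apply("times", ci(p["Vmax"]), sn), apply("plus", kn, sn))
        if "basal" in p:
            expr = apply("plus", expr, ci(p["basal"]))
    for sp, kname in rxn.activators:
        expr = apply("times", expr,
                     apply("divide", ci(sp), apply("plus", ci(kname), ci(sp))))
    for sp, kname in rxn.enhancers:
        expr = apply("times", expr,
                     apply("plus", cn(1.0), apply("divide", ci(sp), ci(kname))))
    for sp, kname in rxn.inhibitors:
        expr = apply("divide", expr,
                     apply("plus", cn(1.0), apply("times", ci(kname), ci(sp))))
    if rxn.driven_by_input:
        expr = apply("times", ci("MHC_input"), expr)
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(expr)
    return math


def _law_annotation(rxn: Reaction, law: KineticLaw) -> ET.Element:
    annot = ET.Element(f"{{{SBML_NS}}}annotation")
    el = ET.SubElement(annot, f"{{{ANNOT_NS}}}kineticLaw")
    el.set("form", law.form.value)
    el.set("hillN", f"{law.hill_n:g}")
    el.set("drivenByInput", str(rxn.driven_by_input).lower())
    for role, pname in sorted(law.params.items()):
        ET.SubElement(el, f"{{{ANNOT_NS}}}param", {"role": role, "name": pname})
    if rxn.enzyme:
        ET.SubElement(el, f"{{{ANNOT_NS}}}modifier", {"kind": "enzyme", "species": rxn.enzyme})
    if rxn.regulator:
        ET.SubElement(el, f"{{{ANNOT_NS}}}modifier", {"kind": "regulator", "species": rxn.regulator})
    for kind, pairs in (("activator", rxn.activators), ("enhancer", rxn.enhancers),
                        ("inhibitor", rxn.inhibitors)):
        for sp, kname in pairs:
            ET.SubElement(el, f"{{{ANNOT_NS}}}modifier",
                          {"kind": kind, "species": sp, "parameter": kname})
    return annot


def write_sbml(model: NetworkModel, params: ParameterSet, path: str | Path) -> Path:
    """Serialize model + parameter values to an SBML L3 document.

    The feedback-link annotation goes to ``<path>.links.yaml``. Writing the
    same model twice produces byte-identical files.
    """
    path = Path(path)
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("nfatnet", ANNOT_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": model.name.replace("-", "_").replace("[", "_").replace("]", "").replace("+", "_")})
    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true"})
    sps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for sp in model.species:
        ET.SubElement(sps, f"{{{SBML_NS}}}species", {
            "id": sp.name, "compartment": "cell",
            "initialConcentration": f"{sp.initial_value:.17g}",
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
            "constant": "false", "sboTerm": f"SBO:00002{ {'signalling': '47', 'transcript': '50', 'complex': '53', 'input': '47'}[sp.role.value] }",
        })
    pars = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    missing = [n for n in model.parameter_names if n not in params]
    if missing:
        raise SBMLError(f"parameter set incomplete: missing {missing}")
    for name in model.parameter_names:
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter",
                      {"id": name, "value": f"{params[name]:.17g}", "constant": "true"})
    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rxn in model.reactions:
        r = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction",
                          {"id": f"R_{rxn.rid}", "reversible": "false"})
        r.append(_law_annotation(rxn, rxn.law))
        if rxn.substrates:
            lst = ET.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for sp, st in rxn.substrates:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(st), "constant": "true"})
        if rxn.products:
            lst = ET.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for sp, st in rxn.products:
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(st), "constant": "true"})
        mods = sorted(rxn.species_names() - {s for s, _ in rxn.substrates}
                      - {s for s, _ in rxn.products})
        if mods:
            lst = ET.SubElement(r, f"{{{SBML_NS}}}listOfModifiers")
            for sp in mods:
                ET.SubElement(lst, f"{{{SBML_NS}}}modifierSpeciesReference", {"species": sp})
        kl = ET.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_mathml_law(rxn, rxn.law))
    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, xml_declaration=True, encoding="UTF-8")

    sidecar = {
        "model": model.name,
        "inputs": list(model.inputs),
        "feedback_links": [
            {"name": l.name, "sign": l.sign.value,
             "controlled_parameters": sorted(l.controlled_parameters)}
            for l in model.feedback_links
        ],
        "conserved_moieties": {k: list(v) for k, v in model.conserved_moieties.items()},
        "species_roles": {s.name: s.role.value for s in model.species},
    }
    with open(_links_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return path


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

def read_sbml(path: str | Path) -> tuple[NetworkModel, ParameterSet, list[UnsupportedConstruct]]:
    """Parse an SBML document (plus sidecar, if present) into domain types.

    Returns (model, parameters, unsupported) where ``unsupported`` lists
    constructs the importer recognized but cannot represent. Raises
    :class:`SBMLError` for malformed documents.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SBMLError(f"malformed SBML document: {exc}") from exc
    root = tree.getroot()
    if root.tag != f"{{{SBML_NS}}}sbml":
        raise SBMLError(f"not an SBML L3 document (root {root.tag})")
    mdl = root.find(f"{{{SBML_NS}}}model")
    if mdl is None:
        raise SBMLError("document has no <model> element")

    unsupported: list[UnsupportedConstruct] = []
    for bad in ("listOfRules", "listOfEvents", "listOfFunctionDefinitions",
                "listOfConstraints", "listOfInitialAssignments"):
        el = mdl.find(f"{{{SBML_NS}}}{bad}")
        if el is not None:
            unsupported.append(UnsupportedConstruct(bad, f"model/{bad}",
                                                    f"{len(el)} entries ignored"))

    sidecar = {}
    if _links_path(path).exists():
        with open(_links_path(path)) as fh:
            sidecar = yaml.safe_load(fh) or {}
    roles = sidecar.get("species_roles", {})

    species = []
    for el in mdl.iterfind(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        sid = el.get("id")
        if sid is None:
            raise SBMLError("species without id")
        init = float(el.get("initialConcentration", el.get("initialAmount", 0.0)))
        species.append(Species(sid, SpeciesRole(roles.get(sid, "signalling")), init))

    values = {}
    for el in mdl.iterfind(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        values[el.get("id")] = float(el.get("value"))

    reactions = []
    for el in mdl.iterfind(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rid = el.get("id", "")
        rid = rid[2:] if rid.startswith("R_") else rid
        annot = el.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}kineticLaw")
        if annot is None:
            unsupported.append(UnsupportedConstruct(
                "reaction", f"reaction[{rid}]",
                "no structured-law annotation; MathML-only laws are not reconstructed"))
            continue
        law_params = {p.get("role"): p.get("name")
                      for p in annot.iterfind(f"{{{ANNOT_NS}}}param")}
        enzyme = regulator = None
        activators, enhancers, inhibitors = [], [], []
        for m in annot.iterfind(f"{{{ANNOT_NS}}}modifier"):
            kind, sp = m.get("kind"), m.get("species")
            if kind == "enzyme":
                enzyme = sp
            elif kind == "regulator":
                regulator = sp
            elif kind == "activator":
                activators.append((sp, m.get("parameter")))
            elif kind == "enhancer":
                enhancers.append((sp, m.get("parameter")))
            elif kind == "inhibitor":
                inhibitors.append((sp, m.get("parameter")))
            else:
                unsupported.append(UnsupportedConstruct(
                    "modifier", f"reaction[{rid}]/modifier", f"kind {kind!r}"))

        def refs(kind: str) -> tuple[tuple[str, int], ...]:
            return tuple(
                (ref.get("species"), int(float(ref.get("stoichiometry", 1))))
                for ref in el.iterfind(f"{{{SBML_NS}}}{kind}/{{{SBML_NS}}}speciesReference")
            )

        reactions.append(Reaction(
            rid=rid,
            law=KineticLaw(LawForm(annot.get("form")), law_params,
                           hill_n=float(annot.get("hillN", 1.0))),
            substrates=refs("listOfReactants"),
            products=refs("listOfProducts"),
            enzyme=enzyme,
            regulator=regulator,
            activators=tuple(activators),
            enhancers=tuple(enhancers),
            inhibitors=tuple(inhibitors),
            driven_by_input=annot.get("drivenByInput") == "true",
        ))

    links = tuple(
        FeedbackLink(d["name"], FeedbackSign(d["sign"]),
                     frozenset(d["controlled_parameters"]))
        for d in sidecar.get("feedback_links", [])
    )
    model = NetworkModel(
        name=sidecar.get("model", mdl.get("id", path.stem)),
        species=tuple(species),
        reactions=tuple(reactions),
        feedback_links=links,
        inputs=tuple(sidecar.get("inputs", ("MHC",))),
        conserved_moieties={k: tuple(v) for k, v in
                            sidecar.get("conserved_moieties", {}).items()},
    )
    params = ParameterSet(values, provenance="imported")
    return model, params, unsupported
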