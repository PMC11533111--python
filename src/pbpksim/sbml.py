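"""SBML Level 3 Version 2 export/import for flow-limited PBPK models.

The dialect written here encodes the ODE system directly rather than as a
reaction network:

* one compartment per pool — ``blood`` (size = blood volume, litres) and
  one per tissue (size = tissue weight, kg);
* species ``A_<compartment>`` carrying chemical *amounts* in mg, governed
  by rate rules (the net-flow ODEs);
* assignment rules defining the concentrations ``C_<compartment>``;
* a ``Dosing`` parameter toggled by two events — set to ``Dose`` when
  simulation time reaches the exposure start and back to 0 at the exposure
  end — so the infusion is a first-class discrete event, not an
  if-expression buried in the maths;
* an explicit unit definition on every parameter, species and compartment
  (minute, litre, kg, mg and the derived rate/concentration units).

Import is the inverse and is guaranteed only for documents produced by
:func:`to_sbml` or structurally equivalent ones; anything else (e.g. a
reaction network) raises :class:`UnsupportedModelError` naming the first
unrecognised construct. Documents are checked for internal consistency
(identifier uniqueness, unit and reference resolution, rule/event
structure) by :func:`check_consistency`.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

from lxml import etree

from .model import (
    USER_CLOSURE_RTOL,
    BloodPool,
    ExposureScenario,
    ModelMetadata,
    PBPKModel,
    Tissue,
    validate_model,
)

__all__ = [
    "SBMLBundle",
    "to_sbml",
    "from_sbml",
    "check_consistency",
    "write_sbml",
    "read_sbml",
    "UnsupportedModelError",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"
XHTML_NS = "http://www.w3.org/1999/xhtml"
ANNOT_NS = "urn:pbpksim:annotation"

_WRITER_VERSION = "pbpksim-sbml-writer/1"

# SBML base unit kinds we may reference directly
_BASE_UNIT_KINDS = {
    "second", "litre", "kilogram", "gram", "metre", "mole", "dimensionless",
    "item", "hertz", "becquerel", "candela", "kelvin", "ampere",
}


class UnsupportedModelError(ValueError):
    """The document contains a construct outside the supported dialect."""


@dataclass(frozen=True)
class SBMLBundle:
    """A serialized SBML document plus writer provenance."""

    document: str
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# MathML construction helpers

def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _ci(name: str) -> etree._Element:
    el = etree.Element(_m("ci"))
    el.text = f" {name} "
    return el


def _cn(value: float) -> etree._Element:
    el = etree.Element(_m("cn"))
    if float(value) == int(value):
        el.set("type", "integer")
        el.text = f" {int(value)} "
    else:
        el.text = f" {value!r} "
    return el


def _time_symbol() -> etree._Element:
    el = etree.Element(_m("csymbol"))
    el.set("encoding", "text")
    el.set("definitionURL", TIME_URL)
    el.text = " time "
    return el


def _apply(op: str, *args: etree._Element) -> etree._Element:
    el = etree.Element(_m("apply"))
    el.append(etree.Element(_m(op)))
    for a in args:
        el.append(a)
    return el


def _math(expr: etree._Element) -> etree._Element:
    root = etree.Element(_m("math"))
    root.append(expr)
    return root


# ---------------------------------------------------------------------------
# Unit definitions

def _unit(kind: str, exponent: int = 1, scale: int = 0, multiplier: float = 1.0):
    el = etree.Element(f"{{{SBML_NS}}}unit")
    el.set("kind", kind)
    el.set("exponent", str(exponent))
    el.set("scale", str(scale))
    el.set("multiplier", repr(float(multiplier)))
    return el


_UNIT_DEFS: dict[str, list[tuple[str, int, int, float]]] = {
    "minute": [("second", 1, 0, 60.0)],
    "mg": [("gram", 1, -3, 1.0)],
    "kg": [("kilogram", 1, 0, 1.0)],
    "L": [("litre", 1, 0, 1.0)],
    "mg_per_min": [("gram", 1, -3, 1.0), ("second", -1, 0, 60.0)],
    "L_per_min": [("litre", 1, 0, 1.0), ("second", -1, 0, 60.0)],
    "mg_per_L": [("gram", 1, -3, 1.0), ("litre", -1, 0, 1.0)],
    "mg_per_kg": [("gram", 1, -3, 1.0), ("kilogram", -1, 0, 1.0)],
    "L_per_kg": [("litre", 1, 0, 1.0), ("kilogram", -1, 0, 1.0)],
}


# ---------------------------------------------------------------------------
# Export

def _s(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _sub(parent: etree._Element, tag: str, **attrs: str) -> etree._Element:
    el = etree.SubElement(parent, _s(tag))
    for k, v in attrs.items():
        el.set(k, v)
    return el


def _num(x: float) -> str:
    return repr(float(x))


def to_sbml(
    model: PBPKModel,
    scenario: ExposureScenario,
    *,
    pretty: bool = False,
) -> SBMLBundle:
    """Export a validated model plus exposure scenario to SBML L3V2.

    Raises :class:`ValueError` if the model fails physiological validation
    or a compartment is unnamed.
    """
    findings = validate_model(model)
    if findings:
        raise ValueError(
            "cannot export an inconsistent model: "
            + "; ".join(f.message for f in findings)
        )
    if any(not name for name in model.compartment_names):
        raise ValueError("cannot export a model with unnamed compartments")

    nsmap = {None: SBML_NS}
    root = etree.Element(_s("sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    mdl = _sub(root, "model", id=model.name or "pbpk_model")
    if model.metadata.model_name:
        mdl.set("name", model.metadata.model_name)

    _write_notes_and_annotation(mdl, model)

    # units
    lud = _sub(mdl, "listOfUnitDefinitions")
    for uid, parts in _UNIT_DEFS.items():
        ud = _sub(lud, "unitDefinition", id=uid)
        lou = _sub(ud, "listOfUnits")
        for kind, exp, scale, mult in parts:
            lou.append(_unit(kind, exp, scale, mult))
    mdl.set("timeUnits", "minute")
    mdl.set("substanceUnits", "mg")
    mdl.set("extentUnits", "mg")

    # compartments: blood in litres, tissues sized by weight in kg
    loc = _sub(mdl, "listOfCompartments")
    _sub(loc, "compartment", id="blood", size=_num(model.blood.V_blood),
         units="L", constant="true", spatialDimensions="3")
    for t in model.tissues:
        _sub(loc, "compartment", id=t.name, size=_num(t.W),
             units="kg", constant="true", spatialDimensions="3")

    # species: amounts in mg
    los = _sub(mdl, "listOfSpecies")
    for name, a0 in zip(model.compartment_names, model.initial_amounts):
        _sub(los, "species", id=f"A_{name}", compartment=name,
             initialAmount=_num(a0), substanceUnits="mg",
             hasOnlySubstanceUnits="true", boundaryCondition="false",
             constant="false")

    # parameters
    lop = _sub(mdl, "listOfParameters")

    def par(pid, value, units, constant=True):
        _sub(lop, "parameter", id=pid, value=_num(value), units=units,
             constant="true" if constant else "false")

    par("BW", model.BW, "kg")
    par("V_blood", model.blood.V_blood, "L")
    par("W_blood", model.blood.W_blood, "kg")
    par("QC", model.blood.QC, "L_per_min")
    for t in model.tissues:
        par(f"W_{t.name}", t.W, "kg")
        par(f"Q_{t.name}", t.Q, "L_per_min")
        par(f"PC_{t.name}", t.PC, "L_per_kg")
        par(f"ER_{t.name}", t.ER, "dimensionless")
    par("Dose", scenario.Dose, "mg_per_min")
    dosing0 = scenario.Dose if scenario.Time_start_expos <= scenario.Time_start_simul else 0.0
    par("Dosing", dosing0, "mg_per_min", constant=False)
    par("Time_start_simul", scenario.Time_start_simul, "minute")
    par("Time_end_simul", scenario.Time_end_simul, "minute")
    par("Time_start_expos", scenario.Time_start_expos, "minute")
    par("Time_end_expos", scenario.Time_end_expos, "minute")
    par("C_blood", 0.0, "mg_per_L", constant=False)
    for t in model.tissues:
        par(f"C_{t.name}", 0.0, "mg_per_kg", constant=False)

    # rules: assignment (concentrations) then rate (net flows)
    lor = _sub(mdl, "listOfRules")
    ar = _sub(lor, "assignmentRule", variable="C_blood")
    ar.append(_math(_apply("divide", _ci("A_blood"), _ci("V_blood"))))
    for t in model.tissues:
        ar = _sub(lor, "assignmentRule", variable=f"C_{t.name}")
        ar.append(_math(_apply("divide", _ci(f"A_{t.name}"), _ci(f"W_{t.name}"))))

    # blood: sum over tissues of Q*(C_t/PC_t - C_blood), plus Dosing
    terms = [
        _apply("times", _ci(f"Q_{t.name}"),
               _apply("minus",
                      _apply("divide", _ci(f"C_{t.name}"), _ci(f"PC_{t.name}")),
                      _ci("C_blood")))
        for t in model.tissues
    ]
    terms.append(_ci("Dosing"))
    rr = _sub(lor, "rateRule", variable="A_blood")
    rr.append(_math(_apply("plus", *terms)))
    for t in model.tissues:
        uptake = _apply("times", _ci(f"Q_{t.name}"),
                        _apply("minus", _ci("C_blood"),
                               _apply("divide", _ci(f"C_{t.name}"), _ci(f"PC_{t.name}"))))
        extraction = _apply("times", _ci(f"Q_{t.name}"), _ci(f"ER_{t.name}"),
                            _ci("C_blood"))
        rr = _sub(lor, "rateRule", variable=f"A_{t.name}")
        rr.append(_math(_apply("minus", uptake, extraction)))

    # dosing events
    loe = _sub(mdl, "listOfEvents")
    for eid, t_param, target_value in (
        ("exposure_start", "Time_start_expos", _ci("Dose")),
        ("exposure_end", "Time_end_expos", _cn(0.0)),
    ):
        ev = _sub(loe, "event", id=eid, useValuesFromTriggerTime="true")
        trig = _sub(ev, "trigger", initialValue="true", persistent="true")
        trig.append(_math(_apply("geq", _time_symbol(), _ci(t_param))))
        loea = _sub(ev, "listOfEventAssignments")
        ea = _sub(loea, "eventAssignment", variable="Dosing")
        ea.append(_math(target_value))

    doc = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=pretty
    ).decode()
    return SBMLBundle(
        document=doc,
        provenance={
            "writer": _WRITER_VERSION,
            "exported": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "source_model": model.name,
        },
    )


def _write_notes_and_annotation(mdl: etree._Element, model: PBPKModel) -> None:
    md = model.metadata
    notes = _sub(mdl, "notes")
    body = etree.SubElement(notes, f"{{{XHTML_NS}}}body", nsmap={None: XHTML_NS})
    lines = [
        f"Model: {md.model_name or model.name}",
        f"Version: {md.code_version}" if md.code_version else "",
        f"License: {md.license}" if md.license else "",
        f"Article: {md.article_citation}" if md.article_citation else "",
    ]
    for line in filter(None, lines):
        p = etree.SubElement(body, f"{{{XHTML_NS}}}p")
        p.text = line
    ann = _sub(mdl, "annotation")
    meta = etree.SubElement(ann, f"{{{ANNOT_NS}}}metadata", nsmap={"pbpksim": ANNOT_NS})

    def leaf(tag, text):
        el = etree.SubElement(meta, f"{{{ANNOT_NS}}}{tag}")
        el.text = text or ""

    leaf("modelName", md.model_name)
    leaf("codeVersion", md.code_version)
    leaf("articleCitation", md.article_citation)
    leaf("codeCitation", md.code_citation)
    leaf("license", md.license)
    leaf("aiToolsDisclosure", md.ai_tools_disclosure)
    for name, orcid, contact in md.authors:
        a = etree.SubElement(meta, f"{{{ANNOT_NS}}}author")
        a.set("name", name)
        if orcid:
            a.set("orcid", orcid)
        if contact:
            a.set("contact", contact)
    for s in md.sources:
        el = etree.SubElement(meta, f"{{{ANNOT_NS}}}source")
        el.text = s


# ---------------------------------------------------------------------------
# Consistency checking

def _parse(document: str | bytes) -> etree._Element:
    if isinstance(document, str):
        document = document.encode()
    return etree.fromstring(document)


def check_consistency(bundle: SBMLBundle | str | bytes) -> list[str]:
    """Structural consistency check of an SBML L3 document.

    Verifies identifier uniqueness, that every parameter/species/compartment
    carries resolvable units, that rule and event-assignment targets exist
    and are non-constant, that no variable is governed by two rules, and
    that every symbol referenced in maths is declared. Returns a list of
    error strings; an empty list means the document is consistent.
    """
    document = bundle.document if isinstance(bundle, SBMLBundle) else bundle
    errors: list[str] = []
    try:
        root = _parse(document)
    except etree.XMLSyntaxError as exc:
        return [f"XML parse error: {exc}"]
    if etree.QName(root).localname != "sbml":
        return ["root element is not <sbml>"]
    mdl = root.find(_s("model"))
    if mdl is None:
        return ["document has no <model>"]

    unit_ids = {ud.get("id") for ud in mdl.iterfind(f"{_s('listOfUnitDefinitions')}/{_s('unitDefinition')}")}
    comp_ids = [c.get("id") for c in mdl.iterfind(f"{_s('listOfCompartments')}/{_s('compartment')}")]
    species = list(mdl.iterfind(f"{_s('listOfSpecies')}/{_s('species')}"))
    params = list(mdl.iterfind(f"{_s('listOfParameters')}/{_s('parameter')}"))

    all_ids = [i for i in unit_ids if i] + comp_ids \
        + [s.get("id") for s in species] + [p.get("id") for p in params] \
        + [e.get("id") for e in mdl.iterfind(f"{_s('listOfEvents')}/{_s('event')}") if e.get("id")]
    seen: set[str] = set()
    for i in all_ids:
        if i is None:
            errors.append("element missing required id")
        elif i in seen:
            errors.append(f"duplicate identifier {i!r}")
        else:
            seen.add(i)

    def units_ok(u: str | None) -> bool:
        return bool(u) and (u in unit_ids or u in _BASE_UNIT_KINDS)

    for p in params:
        if not units_ok(p.get("units")):
            errors.append(f"parameter {p.get('id')!r} lacks a resolvable unit "
                          f"(units={p.get('units')!r})")
    for c in mdl.iterfind(f"{_s('listOfCompartments')}/{_s('compartment')}"):
        if not units_ok(c.get("units")):
            errors.append(f"compartment {c.get('id')!r} lacks a resolvable unit")
    for sp in species:
        if not units_ok(sp.get("substanceUnits")):
            errors.append(f"species {sp.get('id')!r} lacks resolvable substance units")
        if sp.get("compartment") not in comp_ids:
            errors.append(f"species {sp.get('id')!r} references unknown compartment "
                          f"{sp.get('compartment')!r}")

    constant_of = {p.get("id"): p.get("constant", "true") for p in params}
    constant_of.update({sp.get("id"): sp.get("constant", "false") for sp in species})
    declared = set(seen) | {"time"}

    ruled: set[str] = set()
    for rule in mdl.iterfind(f"{_s('listOfRules')}/*"):
        var = rule.get("variable")
        tag = etree.QName(rule).localname
        if var not in constant_of:
            errors.append(f"{tag} targets unknown variable {var!r}")
            continue
        if constant_of[var] == "true":
            errors.append(f"{tag} targets constant variable {var!r}")
        if var in ruled:
            errors.append(f"variable {var!r} governed by more than one rule")
        ruled.add(var)
        if rule.find(_m("math")) is None:
            errors.append(f"{tag} for {var!r} has no <math>")

    for ev in mdl.iterfind(f"{_s('listOfEvents')}/{_s('event')}"):
        eid = ev.get("id") or "<anonymous>"
        trig = ev.find(_s("trigger"))
        if trig is None or trig.find(_m("math")) is None:
            errors.append(f"event {eid!r} lacks a trigger with <math>")
        for ea in ev.iterfind(f"{_s('listOfEventAssignments')}/{_s('eventAssignment')}"):
            var = ea.get("variable")
            if var not in constant_of:
                errors.append(f"event {eid!r} assigns unknown variable {var!r}")
            elif constant_of[var] == "true":
                errors.append(f"event {eid!r} assigns constant variable {var!r}")
            if ea.find(_m("math")) is None:
                errors.append(f"event assignment in {eid!r} has no <math>")

    for ci in mdl.iter(_m("ci")):
        ref = (ci.text or "").strip()
        if ref and ref not in declared:
            errors.append(f"math references undeclared symbol {ref!r}")

    return errors


# ---------------------------------------------------------------------------
# Import

_EXPECTED_SCENARIO_PARAMS = (
    "Dose", "Time_start_simul", "Time_end_simul", "Time_start_expos", "Time_end_expos",
)


def from_sbml(bundle: SBMLBundle | str | bytes) -> tuple[PBPKModel, ExposureScenario]:
    """Reconstruct a model and scenario from a document written by
    :func:`to_sbml` (or one following the same dialect).

    All numeric fields round-trip exactly (values are serialized with
    ``repr`` and parsed with ``float``) and compartment order is preserved.
    Unsupported constructs — reactions, algebraic rules, function
    definitions — raise :class:`UnsupportedModelError` naming the first
    offending element.
    """
    document = bundle.document if isinstance(bundle, SBMLBundle) else bundle
    root = _parse(document)
    mdl = root.find(_s("model"))
    if mdl is None:
        raise UnsupportedModelError("document has no <model> element")

    for tag in ("listOfReactions", "listOfFunctionDefinitions", "listOfConstraints",
                "listOfInitialAssignments"):
        el = mdl.find(_s(tag))
        if el is not None and len(el):
            child = etree.QName(el[0]).localname
            raise UnsupportedModelError(
                f"unsupported construct <{child}> in <{tag}>: this importer "
                "reads rate-rule/event PBPK documents only"
            )
    for rule in mdl.iterfind(f"{_s('listOfRules')}/*"):
        if etree.QName(rule).localname not in ("assignmentRule", "rateRule"):
            raise UnsupportedModelError(
                f"unsupported rule type <{etree.QName(rule).localname}>"
            )

    comps = list(mdl.iterfind(f"{_s('listOfCompartments')}/{_s('compartment')}"))
    if not comps or comps[0].get("id") != "blood":
        raise UnsupportedModelError(
            "expected the first compartment to be 'blood'"
        )
    tissue_names = [c.get("id") for c in comps[1:]]
    if not tissue_names:
        raise UnsupportedModelError("no tissue compartments found")

    params = {
        p.get("id"): float(p.get("value"))
        for p in mdl.iterfind(f"{_s('listOfParameters')}/{_s('parameter')}")
        if p.get("value") is not None
    }
    missing = [k for k in _EXPECTED_SCENARIO_PARAMS if k not in params]
    if missing:
        raise UnsupportedModelError(f"missing scenario parameter(s): {missing}")
    for name in tissue_names:
        for prefix in ("W_", "Q_", "PC_", "ER_"):
            if f"{prefix}{name}" not in params:
                raise UnsupportedModelError(
                    f"missing tissue parameter {prefix}{name!r}"
                )
    for key in ("BW", "V_blood", "W_blood", "QC"):
        if key not in params:
            raise UnsupportedModelError(f"missing parameter {key!r}")

    amounts: dict[str, float] = {}
    for sp in mdl.iterfind(f"{_s('listOfSpecies')}/{_s('species')}"):
        comp = sp.get("compartment")
        amounts[comp] = float(sp.get("initialAmount", "0"))
    ruled = {r.get("variable") for r in mdl.iterfind(f"{_s('listOfRules')}/{_s('rateRule')}")}
    for name in ["blood"] + tissue_names:
        if name not in amounts:
            raise UnsupportedModelError(f"no species for compartment {name!r}")
        if f"A_{name}" not in ruled:
            raise UnsupportedModelError(f"species A_{name} has no rate rule")

    metadata = _read_metadata(mdl)
    model = PBPKModel(
        BW=params["BW"],
        blood=BloodPool(V_blood=params["V_blood"], W_blood=params["W_blood"], QC=params["QC"]),
        tissues=tuple(
            Tissue(name, W=params[f"W_{name}"], Q=params[f"Q_{name}"],
                   PC=params[f"PC_{name}"], ER=params[f"ER_{name}"])
            for name in tissue_names
        ),
        initial_amounts=tuple(amounts[name] for name in ["blood"] + tissue_names),
        metadata=metadata,
        closure_rtol=USER_CLOSURE_RTOL,
        name=mdl.get("id") or "pbpk_model",
    )
    scenario = ExposureScenario(
        Dose=params["Dose"],
        Time_start_simul=params["Time_start_simul"],
        Time_end_simul=params["Time_end_simul"],
        Time_start_expos=params["Time_start_expos"],
        Time_end_expos=params["Time_end_expos"],
    )
    return model, scenario


def _read_metadata(mdl: etree._Element) -> ModelMetadata:
    meta = mdl.find(f"{_s('annotation')}/{{{ANNOT_NS}}}metadata")
    if meta is None:
        return ModelMetadata(model_name=mdl.get("name") or mdl.get("id") or "")

    def text(tag: str) -> str:
        el = meta.find(f"{{{ANNOT_NS}}}{tag}")
        return (el.text or "") if el is not None else ""

    authors = tuple(
        (a.get("name", ""), a.get("orcid") or None, a.get("contact", ""))
        for a in meta.iterfind(f"{{{ANNOT_NS}}}author")
    )
    sources = tuple((s.text or "") for s in meta.iterfind(f"{{{ANNOT_NS}}}source"))
    return ModelMetadata(
        model_name=text("modelName"),
        code_version=text("codeVersion"),
        article_citation=text("articleCitation"),
        code_citation=text("codeCitation"),
        license=text("license"),
        sources=sources,
        authors=authors,
        ai_tools_disclosure=text("aiToolsDisclosure"),
    )


# ---------------------------------------------------------------------------
# File helpers

def write_sbml(model: PBPKModel, scenario: ExposureScenario, path, *, pretty: bool = True) -> SBMLBundle:
    bundle = to_sbml(model, scenario, pretty=pretty)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(bundle.document)
    return bundle


def read_sbml(path) -> tuple[PBPKModel, ExposureScenario]:
    with open(path, "rb") as fh:
        return from_sbml(fh.read())
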