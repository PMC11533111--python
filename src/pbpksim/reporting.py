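"""Reproducibility reporting: metadata checklist, naming linter, and the
simulation results table.

The checklist scores only objectively machine-checkable items of the
community reporting guidance (MIRIAM/MIASE-style): metadata completeness,
units, sources, initial values, attached quantitative results, solver
record, license. Items requiring human judgement (prose quality of the
model-purpose statement, conceptual diagram clarity) are surfaced as
``not-applicable`` with a note and never scored.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import pandas as pd

from .model import ModelMetadata, PBPKModel
from .simulate import SimulationResult

__all__ = [
    "ChecklistItem",
    "ChecklistReport",
    "checklist_evaluate",
    "NamingFinding",
    "naming_check",
    "write_results_table",
    "results_frame",
    "load_metadata_manifest",
]

PASS, FAIL, NA = "pass", "fail", "not-applicable"


@dataclass(frozen=True)
class ChecklistItem:
    item_id: str
    description: str
    status: str  # pass | fail | not-applicable
    evidence: str = ""


@dataclass(frozen=True)
class ChecklistReport:
    items: tuple[ChecklistItem, ...]

    @property
    def applicable(self) -> tuple[ChecklistItem, ...]:
        return tuple(i for i in self.items if i.status != NA)

    @property
    def score(self) -> float:
        app = self.applicable
        if not app:
            return 0.0
        return sum(1 for i in app if i.status == PASS) / len(app)

    @property
    def failed(self) -> tuple[ChecklistItem, ...]:
        return tuple(i for i in self.items if i.status == FAIL)

    def to_json(self) -> str:
        return json.dumps(
            {
                "score": self.score,
                "items": [vars(i) for i in self.items],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"Reproducibility checklist — score {self.score:.2f} "
                 f"({sum(1 for i in self.applicable if i.status == PASS)}"
                 f"/{len(self.applicable)} applicable items)"]
        for i in self.items:
            lines.append(f"  [{i.status:>14}] {i.item_id}: {i.description}"
                         + (f" — {i.evidence}" if i.evidence else ""))
        return "\n".join(lines)


def checklist_evaluate(
    metadata: ModelMetadata,
    model: PBPKModel | None = None,
    result: SimulationResult | None = None,
) -> ChecklistReport:
    """Evaluate the machine-checkable reporting items.

    ``result`` may be omitted, in which case the quantitative-results and
    solver-record items fail (published models must ship simulation output
    for reproducibility checks).
    """
    items: list[ChecklistItem] = []

    def check(item_id, description, ok, evidence_ok="", evidence_bad=""):
        items.append(ChecklistItem(
            item_id, description, PASS if ok else FAIL,
            evidence_ok if ok else evidence_bad,
        ))

    check("model_name", "model is named", bool(metadata.model_name),
          metadata.model_name, "model_name is empty")
    check("code_version", "code version / dates recorded",
          bool(metadata.code_version), metadata.code_version)
    check("article_citation", "reference description (article) cited",
          bool(metadata.article_citation), metadata.article_citation)
    check("code_citation", "model code citation / persistent identifier",
          bool(metadata.code_citation), metadata.code_citation)
    check("authors", "code authors with contact details",
          bool(metadata.authors) and all(a[0] and a[2] for a in metadata.authors),
          f"{len(metadata.authors)} author(s)",
          "no authors with name and contact recorded")
    check("license", "license declared", bool(metadata.license),
          metadata.license, "no license — reuse terms undefined")
    check("sources", "parameter/model sources cited", bool(metadata.sources),
          f"{len(metadata.sources)} source(s)")
    check("ai_tools", "use of AI tools disclosed (possibly 'none')",
          bool(metadata.ai_tools_disclosure), metadata.ai_tools_disclosure)

    if model is not None:
        # units are fixed by construction in the typed model: kg, L/min,
        # L/kg, unitless; initial amounts carried in mg
        check("units", "all parameters carry units", True,
              "typed model: kg, L, L/min, L/kg, mg throughout")
        check("initial_values", "initial compartment values recorded with units",
              len(model.initial_amounts) == model.n_compartments,
              f"{model.n_compartments} initial amounts (mg)")
    else:
        items.append(ChecklistItem(
            "units", "all parameters carry units", FAIL, "no model supplied"))
        items.append(ChecklistItem(
            "initial_values", "initial compartment values recorded", FAIL,
            "no model supplied"))

    has_result = result is not None and result.times.size > 0
    check("simulation_results", "quantitative simulation results attached",
          has_result,
          f"{result.times.size} output points" if has_result else "",
          "no simulation results attached")
    solver_ok = has_result and all(
        k in result.solver_diagnostics for k in ("method", "rtol", "atol"))
    check("solver_record", "solver and tolerances recorded", solver_ok,
          str(result.solver_diagnostics) if solver_ok else "",
          "solver/tolerance record missing")

    # human-judgement items: reported, never scored
    for item_id, description in (
        ("model_purpose", "model purpose and applicability domain described"),
        ("conceptual_diagram", "conceptual model diagram provided and consistent"),
        ("assumptions", "model assumptions stated"),
    ):
        items.append(ChecklistItem(
            item_id, description, NA,
            "requires human judgement; not machine-checkable"))

    return ChecklistReport(items=tuple(items))


# ---------------------------------------------------------------------------
# Naming linter

@dataclass(frozen=True)
class NamingFinding:
    name: str
    message: str
    suggestion: str | None = None


_PREFIXES = ("PC", "ER", "A", "C", "Q", "W", "V")  # longest first
_WHOLE_NAMES = {"BW", "QC", "Dose", "Dosing", "time"}
_PREFIX_MEANING = {
    "A": "amount", "C": "concentration", "Q": "blood flow", "W": "weight",
    "V": "volume", "PC": "partition coefficient", "ER": "extraction ratio",
}
_CONFORMING = re.compile(
    r"^(?:%s)_[a-z][a-z0-9]*(?:_[a-z0-9]+)*$" % "|".join(_PREFIXES)
)
_TIME_RE = re.compile(r"^Time_[a-z][a-z0-9_]*$")


def naming_check(names) -> list[NamingFinding]:
    """Lint component identifiers against the prefix conventions
    ``A_/C_/Q_/W_/V_/PC_/ER_`` + full lowercase tissue name (plus the whole
    names BW, QC, Dose and ``Time_...``). Non-conforming names get a
    suggested rename where one is derivable."""
    findings: list[NamingFinding] = []
    for name in names:
        if name in _WHOLE_NAMES or _CONFORMING.match(name) or _TIME_RE.match(name):
            continue
        suggestion = _suggest(name)
        msg = f"{name!r} does not follow the prefix_tissue convention"
        findings.append(NamingFinding(name, msg, suggestion))
    return findings


def _suggest(name: str) -> str | None:
    for prefix in _PREFIXES:
        # missing underscore after a known prefix, e.g. Qliver -> Q_liver
        m = re.match(rf"^{prefix}([A-Za-z].*)$", name)
        if m and not name.startswith(prefix + "_"):
            rest = m.group(1).lstrip("_")
            candidate = f"{prefix}_{rest.lower()}"
            if _CONFORMING.match(candidate):
                return candidate
        # right prefix, malformed remainder, e.g. C_Blood -> C_blood
        if name.startswith(prefix + "_"):
            candidate = prefix + "_" + name[len(prefix) + 1:].lower()
            if _CONFORMING.match(candidate):
                return candidate
    return None


# ---------------------------------------------------------------------------
# Results table

_COLUMN_UNITS = {"blood": ("mg", "mg_per_L"), "tissue": ("mg", "mg_per_kg")}


def results_frame(result: SimulationResult) -> pd.DataFrame:
    """Simulation result as a tidy wide table (one row per output time)."""
    if result.times.size == 0:
        raise ValueError("cannot tabulate an empty simulation result")
    data = {"time_min": result.times}
    for j, name in enumerate(result.compartments):
        data[f"A_{name}_mg"] = result.amounts[:, j]
    for j, name in enumerate(result.compartments):
        unit = "mg_per_L" if j == 0 else "mg_per_kg"
        data[f"C_{name}_{unit}"] = result.concentrations[:, j]
    data["cumulative_dosed_mg"] = result.cumulative_dosed
    data["cumulative_eliminated_mg"] = result.cumulative_eliminated
    return pd.DataFrame(data)


def write_results_table(result: SimulationResult, destination, *, spreadsheet=None) -> pd.DataFrame:
    """Write the results table as CSV and optionally as a spreadsheet.
    Returns the frame written.

    Values are serialized with the shortest round-trip representation;
    reading with ``pd.read_csv(..., float_precision="round_trip")``
    reproduces them bit-exactly."""
    frame = results_frame(result)
    frame.to_csv(destination, index=False)
    if spreadsheet is not None:
        frame.to_excel(spreadsheet, index=False)
    return frame


# ---------------------------------------------------------------------------
# Manifest I/O

def load_metadata_manifest(path) -> ModelMetadata:
    """Read a metadata manifest (JSON or YAML) into :class:`ModelMetadata`.

    Author entries may be mappings with ``name``/``orcid``/``contact`` keys
    or 3-sequences.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)  # YAML is a JSON superset
    if not isinstance(raw, dict):
        raise ValueError(f"manifest {path} must contain a mapping")
    authors = []
    for a in raw.get("authors", []):
        if isinstance(a, dict):
            authors.append((a.get("name", ""), a.get("orcid"), a.get("contact", "")))
        else:
            name, orcid, contact = (list(a) + [None, ""])[:3]
            authors.append((name, orcid, contact))
    return ModelMetadata(
        model_name=raw.get("model_name", ""),
        code_version=str(raw.get("code_version", "")),
        article_citation=raw.get("article_citation", ""),
        code_citation=raw.get("code_citation", ""),
        authors=tuple(authors),
        license=raw.get("license", ""),
        sources=tuple(raw.get("sources", ())),
        ai_tools_disclosure=raw.get("ai_tools_disclosure", ""),
    )
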