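"""Reference adult physiology and the default exposure scenario.

Ships the standard adult-man and adult-woman parameter sets (ICRP-style
reference values: body weight, blood volume, cardiac output, hepatic
weight and flow fractions) together with the derivation formulas that turn
them into a three-compartment flow-limited model: blood, liver, and a
lumped "others" compartment holding the rest of the body.

Derived values are stored unrounded; :func:`format_printed` reproduces the
rounded renderings used in published reference tables.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import pandas as pd

from .model import BloodPool, ExposureScenario, ModelMetadata, PBPKModel, Tissue

__all__ = [
    "ReferenceInputs",
    "REFERENCE_INPUTS",
    "derive_physiology",
    "build_reference_model",
    "default_scenario",
    "format_printed",
    "printed_reference_values",
    "reference_table",
    "write_reference_table",
]

# Exemplar chemical: hypothetical hydrophobic compound, high hepatic
# clearance; partition coefficients > 1 reflect preferential accumulation
# in fattier tissues relative to blood.
DEFAULT_PC_LIVER = 1.5
DEFAULT_PC_OTHERS = 3.0
DEFAULT_ER_LIVER = 0.70


@dataclass(frozen=True)
class ReferenceInputs:
    """Primitive reference inputs from which tissue weights and flows are
    derived.

    Fractions are of body weight (liver weight) and of cardiac output
    (liver blood flow, portal vein plus hepatic artery).
    """

    sex: str
    BW: float                    # kg
    liver_weight_fraction: float  # of BW, unitless
    V_blood: float               # L
    QC: float                    # L/min
    liver_flow_fraction: float   # of QC, unitless

    def __post_init__(self) -> None:
        if self.sex not in ("man", "woman"):
            raise ValueError(f"sex must be 'man' or 'woman', got {self.sex!r}")
        for label, v in (("BW", self.BW), ("V_blood", self.V_blood), ("QC", self.QC)):
            if not v > 0:
                raise ValueError(f"{label} must be > 0")
        for label, v in (
            ("liver_weight_fraction", self.liver_weight_fraction),
            ("liver_flow_fraction", self.liver_flow_fraction),
        ):
            if not 0 < v < 1:
                raise ValueError(f"{label} must lie in (0, 1)")


REFERENCE_INPUTS: dict[str, ReferenceInputs] = {
    "man": ReferenceInputs("man", BW=73.0, liver_weight_fraction=0.026,
                           V_blood=5.3, QC=6.5, liver_flow_fraction=0.255),
    "woman": ReferenceInputs("woman", BW=60.0, liver_weight_fraction=0.026,
                             V_blood=3.9, QC=5.9, liver_flow_fraction=0.270),
}


@dataclass(frozen=True)
class DerivedPhysiology:
    blood: BloodPool
    W_liver: float
    Q_liver_total: float
    W_others: float
    Q_others: float


def derive_physiology(inputs: ReferenceInputs) -> DerivedPhysiology:
    """Apply the closure formulas:

    W_liver = fraction * BW; W_blood = V_blood (density 1 kg/L);
    W_others = BW - W_liver - W_blood; Q_liver_total = flow_fraction * QC;
    Q_others = QC - Q_liver_total.

    Unrounded values are returned; weight and flow closure therefore hold
    exactly by construction.
    """
    W_liver = inputs.liver_weight_fraction * inputs.BW
    W_blood = inputs.V_blood
    W_others = inputs.BW - W_liver - W_blood
    Q_liver = inputs.liver_flow_fraction * inputs.QC
    Q_others = inputs.QC - Q_liver
    if not W_others > 0:
        raise ValueError(f"derived W_others = {W_others:.6g} kg is not positive")
    if not Q_others > 0:
        raise ValueError(f"derived Q_others = {Q_others:.6g} L/min is not positive")
    return DerivedPhysiology(
        blood=BloodPool(V_blood=inputs.V_blood, W_blood=W_blood, QC=inputs.QC),
        W_liver=W_liver,
        Q_liver_total=Q_liver,
        W_others=W_others,
        Q_others=Q_others,
    )


def build_reference_model(
    sex: str,
    *,
    PC_liver: float = DEFAULT_PC_LIVER,
    PC_others: float = DEFAULT_PC_OTHERS,
    ER_liver: float = DEFAULT_ER_LIVER,
    metadata: ModelMetadata | None = None,
) -> PBPKModel:
    """Reference three-compartment model for an adult man or woman.

    Initial amounts are 0 mg everywhere; partition coefficients and the
    hepatic extraction ratio default to the exemplar hydrophobic chemical
    but may be overridden per substance.
    """
    if sex not in REFERENCE_INPUTS:
        raise ValueError(
            f"unknown sex {sex!r}; accepted labels: {sorted(REFERENCE_INPUTS)}"
        )
    inputs = REFERENCE_INPUTS[sex]
    phys = derive_physiology(inputs)
    return PBPKModel(
        BW=inputs.BW,
        blood=phys.blood,
        tissues=(
            Tissue("liver", W=phys.W_liver, Q=phys.Q_liver_total, PC=PC_liver, ER=ER_liver),
            Tissue("others", W=phys.W_others, Q=phys.Q_others, PC=PC_others, ER=0.0),
        ),
        initial_amounts=(0.0, 0.0, 0.0),
        metadata=metadata or ModelMetadata(model_name=f"reference_{sex}"),
        closure_rtol=1e-9,
        name=f"reference_{sex}",
    )


def default_scenario() -> ExposureScenario:
    """Default intravenous exposure: 100 mg/min for the first 200 min of a
    400-min simulation, followed by 200 min of depuration."""
    return ExposureScenario(
        Dose=100.0,
        Time_start_simul=0.0,
        Time_end_simul=400.0,
        Time_start_expos=0.0,
        Time_end_expos=200.0,
    )


def format_printed(value: float, sig_figs: int = 3) -> str:
    """Render a value at a fixed number of significant figures, keeping
    trailing zeros (1.898 at 3 s.f. prints as ``1.90``, not ``1.9``)."""
    if value == 0:
        return "0"
    exp = math.floor(math.log10(abs(value)))
    rounded = round(value, sig_figs - 1 - exp)
    exp = math.floor(math.log10(abs(rounded)))  # rounding may bump the decade
    decimals = max(sig_figs - 1 - exp, 0)
    return f"{rounded:.{decimals}f}"


# Per-cell significant figures of the published reference table: derived
# weights and flows print at 3 s.f. except the woman's remainder weight,
# whose exact value 54.54 is rendered in full (4 s.f.).
_PRINT_SIG_FIGS = {("W_others", "woman"): 4}


def printed_reference_values() -> dict[tuple[str, str], str]:
    """Derived reference values rendered exactly as published, keyed by
    (parameter, sex)."""
    out: dict[tuple[str, str], str] = {}
    for sex, inputs in REFERENCE_INPUTS.items():
        phys = derive_physiology(inputs)
        for param, value in (
            ("W_liver", phys.W_liver),
            ("W_others", phys.W_others),
            ("Q_liver_total", phys.Q_liver_total),
            ("Q_others", phys.Q_others),
        ):
            out[(param, sex)] = format_printed(value, _PRINT_SIG_FIGS.get((param, sex), 3))
    return out


def reference_table() -> pd.DataFrame:
    """Derived physiology for both sexes as a tidy table (documentation
    parity with the packaged CSV)."""
    rows = []
    derived = {sex: derive_physiology(inp) for sex, inp in REFERENCE_INPUTS.items()}
    man, woman = derived["man"], derived["woman"]
    im, iw = REFERENCE_INPUTS["man"], REFERENCE_INPUTS["woman"]
    spec = [
        ("BW", im.BW, iw.BW, "kg", "reference body weight, European adults"),
        ("W_liver", man.W_liver, woman.W_liver, "kg", "0.026 * BW"),
        ("W_blood", man.blood.W_blood, woman.blood.W_blood, "kg", "equal to V_blood (density 1 kg/L)"),
        ("W_others", man.W_others, woman.W_others, "kg", "BW - W_liver - W_blood"),
        ("QC", im.QC, iw.QC, "L/min", "reference cardiac output"),
        ("Q_liver_total", man.Q_liver_total, woman.Q_liver_total, "L/min",
         "0.255 * QC (men), 0.270 * QC (women); portal vein + hepatic artery"),
        ("Q_others", man.Q_others, woman.Q_others, "L/min", "QC - Q_liver_total"),
        ("V_blood", im.V_blood, iw.V_blood, "L", "reference total blood volume"),
    ]
    for name, m, w, units, source in spec:
        rows.append({"parameter": name, "man": m, "woman": w, "units": units, "source": source})
    return pd.DataFrame(rows, columns=["parameter", "man", "woman", "units", "source"])


def write_reference_table(path) -> None:
    reference_table().to_csv(path, index=False)


def packaged_reference_csv() -> str:
    """Contents of the packaged reference-physiology CSV."""
    return (
        importlib.resources.files("pbpksim").joinpath("data/reference_physiology.csv").read_text()
    )
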