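"""Domain types and equations for flow-limited PBPK models.

A model consists of a central blood pool and N perfused tissue compartments.
Distribution is flow-limited: venous blood leaving a tissue is assumed to be
in equilibrium with the tissue at concentration ``C_tissue / PC_tissue``.
Elimination is first-pass hepatic-style extraction: a tissue with extraction
ratio ``ER > 0`` removes ``Q * ER * C_blood`` mg/min from the system.

State is carried as *amounts* (mg) per compartment, blood first, then
tissues in declaration order; concentrations (mg/L for blood, mg/kg for
tissues) are derived algebraically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Tissue",
    "BloodPool",
    "PBPKModel",
    "ExposureScenario",
    "ModelMetadata",
    "Finding",
    "dosing_rate",
    "concentrations",
    "amounts_from_concentrations",
    "rhs",
    "clearance_rate",
    "validate_model",
    "CONSTRUCTED_CLOSURE_RTOL",
    "USER_CLOSURE_RTOL",
]

# Models built from derivation formulas close essentially exactly; models
# typed in from rounded published tables get a looser band.
CONSTRUCTED_CLOSURE_RTOL = 1e-9
USER_CLOSURE_RTOL = 1e-3


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class Tissue:
    """One perfused peripheral compartment.

    Parameters
    ----------
    name : str
        Compartment identifier (lowercase tissue name, e.g. ``"liver"``).
    W : float
        Tissue weight, kg.
    Q : float
        Blood flow to the tissue, L/min.
    PC : float
        Tissue:blood partition coefficient, L/kg.
    ER : float
        Extraction ratio (fraction removed per pass), unitless in [0, 1].
    """

    name: str
    W: float
    Q: float
    PC: float
    ER: float = 0.0

    def __post_init__(self) -> None:
        _require(bool(self.name), "tissue name must be non-empty")
        _require(self.W > 0, f"tissue {self.name!r}: weight W must be > 0 kg")
        _require(self.Q > 0, f"tissue {self.name!r}: blood flow Q must be > 0 L/min")
        _require(self.PC > 0, f"tissue {self.name!r}: partition coefficient PC must be > 0")
        _require(0.0 <= self.ER <= 1.0, f"tissue {self.name!r}: extraction ratio ER must lie in [0, 1]")


@dataclass(frozen=True)
class BloodPool:
    """Central blood compartment.

    By convention blood weight equals blood volume numerically (density
    1 kg/L); both fields are kept so models with a different blood density
    remain expressible.
    """

    V_blood: float
    W_blood: float
    QC: float

    def __post_init__(self) -> None:
        _require(self.V_blood > 0, "blood volume V_blood must be > 0 L")
        _require(self.W_blood > 0, "blood weight W_blood must be > 0 kg")
        _require(self.QC > 0, "cardiac output QC must be > 0 L/min")


@dataclass(frozen=True)
class ModelMetadata:
    """Descriptive annotations attached to a model (authorship, provenance,
    license). Used by the reporting checklist; all fields optional except
    the model name."""

    model_name: str = ""
    code_version: str = ""
    article_citation: str = ""
    code_citation: str = ""
    authors: tuple = ()  # of (name, orcid-or-None, contact)
    license: str = ""
    sources: tuple = ()
    ai_tools_disclosure: str = ""


@dataclass(frozen=True)
class ExposureScenario:
    """Constant-rate intravenous infusion over a window inside the
    simulation interval. All times in minutes, rate in mg/min."""

    Dose: float
    Time_start_simul: float
    Time_end_simul: float
    Time_start_expos: float
    Time_end_expos: float

    def __post_init__(self) -> None:
        _require(self.Dose >= 0, "Dose must be >= 0 mg/min")
        _require(
            self.Time_start_simul <= self.Time_start_expos <= self.Time_end_expos <= self.Time_end_simul,
            "times must satisfy Time_start_simul <= Time_start_expos <= Time_end_expos <= Time_end_simul",
        )


@dataclass(frozen=True)
class PBPKModel:
    """Blood pool plus tissues, with initial amounts per compartment.

    ``initial_amounts`` is ordered blood first, then tissues in declaration
    order. Closure invariants (weights sum to body weight, flows sum to
    cardiac output) are enforced at the tolerance given by ``closure_rtol``.
    """

    BW: float
    blood: BloodPool
    tissues: tuple[Tissue, ...]
    initial_amounts: tuple[float, ...] = ()
    metadata: ModelMetadata = field(default_factory=ModelMetadata)
    closure_rtol: float = USER_CLOSURE_RTOL
    name: str = "pbpk_model"

    def __post_init__(self) -> None:
        tissues = tuple(self.tissues)
        object.__setattr__(self, "tissues", tissues)
        _require(len(tissues) >= 1, "model needs at least one tissue")
        init = tuple(self.initial_amounts) or (0.0,) * (1 + len(tissues))
        object.__setattr__(self, "initial_amounts", init)
        _require(
            len(init) == 1 + len(tissues),
            f"initial_amounts must have {1 + len(tissues)} entries (blood + tissues), got {len(init)}",
        )
        _require(all(a >= 0 for a in init), "initial amounts must be >= 0 mg")
        names = self.compartment_names
        _require(len(set(names)) == len(names), "compartment names must be unique")
        # Closure is deliberately NOT enforced here: validate_model reports
        # closure violations as findings so that inconsistent models can be
        # constructed, inspected and repaired.

    @property
    def compartment_names(self) -> tuple[str, ...]:
        return ("blood",) + tuple(t.name for t in self.tissues)

    @property
    def n_compartments(self) -> int:
        return 1 + len(self.tissues)

    def with_metadata(self, metadata: ModelMetadata) -> "PBPKModel":
        return replace(self, metadata=metadata)

    def total_extraction_flow(self) -> float:
        """Sum of Q_t * ER_t over tissues, L/min — the clearance per unit
        blood concentration."""
        return sum(t.Q * t.ER for t in self.tissues)


@dataclass(frozen=True)
class Finding:
    """One physiological-consistency violation; data, not an exception."""

    code: str
    message: str
    value: float | None = None
    tolerance: float | None = None
    severity: str = "error"


def dosing_rate(t: float, scenario: ExposureScenario) -> float:
    """Infusion rate at time ``t`` (mg/min).

    Zero outside the exposure window; the window is closed at both
    endpoints so the boundary instants count as dosed.
    """
    if not math.isfinite(t):
        raise ValueError("time must be finite")
    if scenario.Time_start_expos <= t <= scenario.Time_end_expos:
        return scenario.Dose
    return 0.0


def _denominators(model: PBPKModel) -> np.ndarray:
    return np.array([model.blood.V_blood] + [t.W for t in model.tissues])


def concentrations(state: Sequence[float], model: PBPKModel) -> np.ndarray:
    """Compartment concentrations from amounts.

    Blood concentration is ``A_blood / V_blood`` (mg/L); each tissue is
    ``A_tissue / W_tissue`` (mg/kg). Zero denominators are impossible for a
    constructed model (positivity is enforced at construction).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_compartments,):
        raise ValueError(f"state must have length {model.n_compartments}, got {state.shape}")
    return state / _denominators(model)


def amounts_from_concentrations(conc: Sequence[float], model: PBPKModel) -> np.ndarray:
    """Inverse of :func:`concentrations`."""
    conc = np.asarray(conc, dtype=float)
    if conc.shape != (model.n_compartments,):
        raise ValueError(f"concentration vector must have length {model.n_compartments}")
    return conc * _denominators(model)


def rhs(
    t: float,
    state: Sequence[float],
    model: PBPKModel,
    scenario: ExposureScenario,
) -> np.ndarray:
    """Net flow of chemical to each compartment, mg/min.

    dA_blood/dt  = sum_t Q_t (C_t/PC_t - C_blood) + Dosing(t)
    dA_tissue/dt = Q_t (C_blood - C_t/PC_t) - Q_t ER_t C_blood

    Inter-compartment terms cancel pairwise, so the components always sum
    to dosing minus clearance (the mass-balance identity).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_compartments,):
        raise ValueError(f"state must have length {model.n_compartments}, got {state.shape}")
    conc = state / _denominators(model)
    c_blood = conc[0]
    out = np.empty_like(state)
    blood_net = 0.0
    for i, tis in enumerate(model.tissues, start=1):
        venous = conc[i] / tis.PC  # venous blood leaving the tissue
        exchange = tis.Q * (c_blood - venous)
        out[i] = exchange - tis.Q * tis.ER * c_blood
        blood_net -= exchange
    out[0] = blood_net + dosing_rate(t, scenario)
    return out


def clearance_rate(state: Sequence[float], model: PBPKModel) -> float:
    """Total elimination rate, mg/min: sum over tissues of Q * ER * C_blood."""
    state = np.asarray(state, dtype=float)
    c_blood = state[0] / model.blood.V_blood
    return model.total_extraction_flow() * c_blood


def system_matrix(model: PBPKModel) -> np.ndarray:
    """Jacobian d(rhs)/d(amounts) — the system is linear in state, so this
    is exact and constant in time. Used for implicit integration and for
    the generic steady-state solve."""
    n = model.n_compartments
    denom = _denominators(model)
    M = np.zeros((n, n))
    for i, tis in enumerate(model.tissues, start=1):
        # d(out_i)/dA_blood and /dA_i
        M[i, 0] = tis.Q * (1.0 - tis.ER) / denom[0]
        M[i, i] = -tis.Q / (tis.PC * denom[i])
        M[0, 0] -= tis.Q / denom[0]
        M[0, i] = tis.Q / (tis.PC * denom[i])
    return M


def validate_model(model: PBPKModel) -> list[Finding]:
    """Physiological-consistency check; returns an empty list when the
    model is consistent.

    Checks weight closure (blood + tissues == body weight), flow closure
    (tissue flows == cardiac output), and parameter ranges. Violations are
    returned as :class:`Finding` records, never raised.
    """
    findings: list[Finding] = []
    tol = model.closure_rtol
    w_sum = model.blood.W_blood + sum(t.W for t in model.tissues)
    w_resid = abs(w_sum - model.BW) / max(abs(model.BW), 1e-300)
    if w_resid > tol:
        findings.append(
            Finding(
                "weight_closure",
                f"blood + tissue weights sum to {w_sum:.6g} kg but body weight is "
                f"{model.BW:.6g} kg (relative residual {w_resid:.3g} > {tol:g})",
                value=w_resid,
                tolerance=tol,
            )
        )
    q_sum = sum(t.Q for t in model.tissues)
    q_resid = abs(q_sum - model.blood.QC) / max(abs(model.blood.QC), 1e-300)
    if q_resid > tol:
        findings.append(
            Finding(
                "flow_closure",
                f"tissue blood flows sum to {q_sum:.6g} L/min but cardiac output is "
                f"{model.blood.QC:.6g} L/min (relative residual {q_resid:.3g} > {tol:g})",
                value=q_resid,
                tolerance=tol,
            )
        )
    # Range checks duplicate the constructor guards so that models built by
    # bypassing the dataclass (e.g. object.__setattr__ in tests, or future
    # deserialisers) still surface violations as data.
    for tis in model.tissues:
        if not (0.0 <= tis.ER <= 1.0):
            findings.append(
                Finding("range", f"tissue {tis.name!r}: ER={tis.ER} outside [0, 1]", value=tis.ER)
            )
        for label, val in (("W", tis.W), ("Q", tis.Q), ("PC", tis.PC)):
            if not val > 0:
                findings.append(
                    Finding("range", f"tissue {tis.name!r}: {label}={val} must be > 0", value=val)
                )
    for label, val in (
        ("V_blood", model.blood.V_blood),
        ("W_blood", model.blood.W_blood),
        ("QC", model.blood.QC),
        ("BW", model.BW),
    ):
        if not val > 0:
            findings.append(Finding("range", f"{label}={val} must be > 0", value=val))
    return findings
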