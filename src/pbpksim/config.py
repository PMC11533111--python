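"""Model and scenario definition from structured configuration files.

The file (JSON or YAML — YAML is a superset, so one loader serves both)
uses flat keys mirroring the standard code abbreviations::

    BW: 73
    V_blood: 5.3
    QC: 6.5
    W_liver: 1.898
    Q_liver: 1.6575       # Q_liver_total accepted as an alias
    PC_liver: 1.5
    ER_liver: 0.7
    W_others: 65.802
    Q_others: 4.8425
    PC_others: 3
    Dose: 100
    Time_start_simul: 0
    Time_end_simul: 400
    Time_start_expos: 0
    Time_end_expos: 200
    A_liver: 0            # optional initial amounts, default 0 mg

Tissues are discovered from the ``W_<name>`` keys (``W_blood`` excluded);
each tissue needs W, Q and PC, while ER defaults to 0.
"""

from __future__ import annotations

import yaml

from .model import (
    USER_CLOSURE_RTOL,
    BloodPool,
    ExposureScenario,
    ModelMetadata,
    PBPKModel,
    Tissue,
)

__all__ = ["load_model_config", "parse_model_config", "default_scenario_dict"]

_SCENARIO_KEYS = (
    "Dose", "Time_start_simul", "Time_end_simul", "Time_start_expos", "Time_end_expos",
)


def default_scenario_dict() -> dict:
    return {
        "Dose": 100.0, "Time_start_simul": 0.0, "Time_end_simul": 400.0,
        "Time_start_expos": 0.0, "Time_end_expos": 200.0,
    }


def parse_model_config(raw: dict) -> tuple[PBPKModel, ExposureScenario]:
    """Build (model, scenario) from a flat configuration mapping."""
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    cfg = dict(raw)

    def take(key, default=None):
        if key in cfg:
            return float(cfg[key])
        if default is None:
            raise ValueError(f"configuration key {key!r} is required")
        return float(default)

    BW = take("BW")
    V_blood = take("V_blood")
    W_blood = take("W_blood", V_blood)  # density-1 convention
    QC = take("QC")

    tissue_names = [
        k[len("W_"):] for k in cfg
        if k.startswith("W_") and k != "W_blood"
    ]
    if not tissue_names:
        raise ValueError("no tissues found (expected W_<tissue> keys)")

    tissues = []
    for name in tissue_names:
        q_key = f"Q_{name}"
        if q_key not in cfg and f"Q_{name}_total" in cfg:
            q_key = f"Q_{name}_total"  # published liver-flow spelling
        tissues.append(Tissue(
            name,
            W=take(f"W_{name}"),
            Q=take(q_key),
            PC=take(f"PC_{name}"),
            ER=take(f"ER_{name}", 0.0),
        ))

    initial = [take("A_blood", 0.0)] + [take(f"A_{n}", 0.0) for n in tissue_names]

    scenario_cfg = default_scenario_dict()
    for key in _SCENARIO_KEYS:
        if key in cfg:
            scenario_cfg[key] = float(cfg[key])
    scenario = ExposureScenario(**scenario_cfg)

    model = PBPKModel(
        BW=BW,
        blood=BloodPool(V_blood=V_blood, W_blood=W_blood, QC=QC),
        tissues=tuple(tissues),
        initial_amounts=tuple(initial),
        metadata=ModelMetadata(model_name=str(cfg.get("model_name", "user_model"))),
        closure_rtol=float(cfg.get("closure_rtol", USER_CLOSURE_RTOL)),
        name=str(cfg.get("model_name", "user_model")),
    )
    return model, scenario


def load_model_config(path) -> tuple[PBPKModel, ExposureScenario]:
    """Read a JSON or YAML model/scenario configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return parse_model_config(raw)
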