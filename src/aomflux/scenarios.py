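"""Scenario specifications: variant + objective + uptake constraints.

A :class:`ScenarioSpec` is a declarative description of one simulation:
which mechanistic variant to apply, which reaction to maximize, which
exchange fluxes to fix or bound, and parameter overrides.  The shipped
scenarios reproduce the reference ATP-maximization and growth conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .core_network import (
    ATP_DEMAND_ID,
    BIOMASS_ID,
    VARIANTS,
    apply_variant,
    build_core_model,
)
from .model import ModelError, StoichiometricModel

__all__ = ["ScenarioSpec", "BUILTIN_SCENARIOS", "build_scenario_model", "load_scenario"]


@dataclass
class ScenarioSpec:
    name: str
    variant: str = "confurcation"
    objective: str = ATP_DEMAND_ID
    #: exchange-id -> fixed value, or (lower, upper) bounds
    fixes: dict[str, float | tuple[float, float]] = field(default_factory=dict)
    #: overrides of the packaged default parameters
    parameters: dict[str, float] = field(default_factory=dict)
    #: release the NGAM lower bound (automatic when ATPM is the objective,
    #: so the maximized demand is a gross yield, not net of maintenance)
    release_ngam: bool | None = None
    notes: str = ""

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ModelError(
                f"scenario '{self.name}': unknown variant '{self.variant}'"
            )
        for key, val in self.fixes.items():
            vals = val if isinstance(val, (tuple, list)) else (val,)
            for x in vals:
                if not math.isfinite(x):
                    raise ModelError(
                        f"scenario '{self.name}': non-finite fix for '{key}'"
                    )
        for key, val in self.parameters.items():
            if not math.isfinite(val) or val < 0:
                raise ModelError(
                    f"scenario '{self.name}': parameter '{key}' must be finite and >= 0"
                )

    @property
    def ngam_released(self) -> bool:
        if self.release_ngam is not None:
            return self.release_ngam
        return self.objective == ATP_DEMAND_ID


def build_scenario_model(spec: ScenarioSpec) -> StoichiometricModel:
    """Build the core model, apply the variant, fixes and objective."""
    spec.validate()
    model = build_core_model(parameters=spec.parameters or None)
    model = apply_variant(model, spec.variant)
    if not model.has_reaction(spec.objective):
        raise ModelError(
            f"scenario '{spec.name}': objective '{spec.objective}' not in model"
        )
    model.objective_id = spec.objective
    for rid, val in spec.fixes.items():
        rxn = model.get_reaction(rid)
        if isinstance(val, (tuple, list)):
            rxn.lower_bound, rxn.upper_bound = float(val[0]), float(val[1])
        else:
            rxn.lower_bound = rxn.upper_bound = float(val)
    if spec.ngam_released:
        model.get_reaction(ATP_DEMAND_ID).lower_bound = 0.0
    return model


def _reference_uptake() -> float:
    from .defaults import default_parameters

    return default_parameters()["ch4_uptake"]


def BUILTIN_SCENARIOS() -> dict[str, ScenarioSpec]:
    u = _reference_uptake()
    return {
        "atp_max_confurcation": ScenarioSpec(
            name="atp_max_confurcation",
            variant="confurcation",
            objective=ATP_DEMAND_ID,
            fixes={"EX_ch4": -u},
            notes="reference ATP maximization, methane uptake fixed",
        ),
        "atp_max_rnf_swap": ScenarioSpec(
            name="atp_max_rnf_swap",
            variant="rnf_swap",
            objective=ATP_DEMAND_ID,
            fixes={"EX_ch4": -u},
            notes="HdrABC knocked out, pseudo-Rnf added, Mrp disabled",
        ),
        "growth_confurcation": ScenarioSpec(
            name="growth_confurcation",
            variant="confurcation",
            objective=BIOMASS_ID,
            fixes={"EX_ch4": (-u, 0.0)},
            notes="growth maximization with NGAM enforced",
        ),
    }


def load_scenario(path: str) -> ScenarioSpec:
    """Read a scenario from a YAML file (same fields as ScenarioSpec)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "name" not in data:
        raise ModelError(f"scenario file '{path}' must define at least 'name'")
    fixes = {
        k: tuple(v) if isinstance(v, list) else float(v)
        for k, v in (data.get("fixes") or {}).items()
    }
    spec = ScenarioSpec(
        name=data["name"],
        variant=data.get("variant", "confurcation"),
        objective=data.get("objective", ATP_DEMAND_ID),
        fixes=fixes,
        parameters={k: float(v) for k, v in (data.get("parameters") or {}).items()},
        release_ngam=data.get("release_ngam"),
        notes=data.get("notes", ""),
    )
    spec.validate()
    return spec
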