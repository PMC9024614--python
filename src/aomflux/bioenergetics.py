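"""Chemiosmotic bookkeeping: ion-translocation tallies and ATP yields.

The ledger multiplies each membrane enzyme's flux by its ions-per-turnover
translocation stoichiometry, outward positive.  The ATP synthase is the
gradient *consumer* and the passive sodium leak is not an enzyme-catalyzed
translocation, so neither carries a translocation record and neither enters
the tallies; ``atp_yield`` is instead read directly from the synthase flux
of the solution.  In the reference ATP-maximization scenario the two views
agree exactly: atp_yield x ions-per-ATP = total gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_network import ATP_SYNTHASE_ID
from .fba import FluxSolution, optimize
from .model import ModelError, StoichiometricModel
from .scenarios import ScenarioSpec, build_scenario_model

__all__ = ["IonLedger", "ScenarioResult", "tally_ions", "compare_scenarios"]


@dataclass
class IonLedger:
    """Per-enzyme and net translocated-ion fluxes (mmol gDW-1 h-1)."""

    #: reaction-id -> {"H+": signed ion flux, "Na+": ...}; outward positive
    per_reaction: dict[str, dict[str, float]] = field(default_factory=dict)
    net_H: float = 0.0
    net_Na: float = 0.0
    atp_yield: float = 0.0

    @property
    def total_gradient(self) -> float:
        return self.net_H + self.net_Na

    def rows(self) -> list[tuple[str, str, float]]:
        out = []
        for rid, ions in sorted(self.per_reaction.items()):
            for ion, flux in sorted(ions.items()):
                out.append((rid, ion, flux))
        return out


def tally_ions(model: StoichiometricModel, solution: FluxSolution) -> IonLedger:
    """Tally translocated ions of an optimal solution, outward positive.

    Per-reaction entries are flux x ions-per-turnover x direction sign for
    every reaction bearing a translocation record; inward-sourcing enzymes
    (Mtr, reversed HdrDE) come out negative.
    """
    if solution.status != "optimal":
        raise ModelError(f"cannot tally a solution with status '{solution.status}'")
    missing = [r.id for r in model.reactions if r.id not in solution.fluxes]
    if missing or len(solution.fluxes) != len(model.reactions):
        raise ModelError(
            f"solution does not match model (missing or extra reactions: {missing[:5]})"
        )

    per_reaction: dict[str, dict[str, float]] = {}
    net = {"H+": 0.0, "Na+": 0.0}
    for rxn in model.reactions:
        if not rxn.translocations:
            continue
        flux = solution.fluxes[rxn.id]
        entry = {}
        for t in rxn.translocations:
            ion_flux = flux * t.count * t.sign
            entry[t.ion] = entry.get(t.ion, 0.0) + ion_flux
            net[t.ion] += ion_flux
        per_reaction[rxn.id] = entry

    atp = solution.fluxes.get(ATP_SYNTHASE_ID, 0.0)
    return IonLedger(
        per_reaction=per_reaction,
        net_H=net["H+"],
        net_Na=net["Na+"],
        atp_yield=atp,
    )


@dataclass
class ScenarioResult:
    name: str
    solution: FluxSolution
    ledger: IonLedger | None
    notes: str = ""

    @property
    def atp_yield(self) -> float | None:
        return self.ledger.atp_yield if self.ledger else None


def run_scenario_solution(spec: ScenarioSpec, parsimonious: bool = True) -> ScenarioResult:
    """Build the scenario model, solve (parsimonious by default), tally ions."""
    model = build_scenario_model(spec)
    sol = optimize(model, parsimonious=parsimonious)
    ledger = tally_ions(model, sol) if sol.status == "optimal" else None
    return ScenarioResult(name=spec.name, solution=sol, ledger=ledger, notes=spec.notes)


def compare_scenarios(
    scenario_list: list[ScenarioSpec], parsimonious: bool = True
) -> tuple[list[ScenarioResult], dict[tuple[str, str], float]]:
    """Run each scenario and compute pairwise ATP-yield differences.

    Infeasible scenarios are kept in the result list with their status but
    excluded from the difference summary.
    """
    if len(scenario_list) < 2:
        raise ModelError("compare_scenarios needs at least two scenarios")
    results = [run_scenario_solution(s, parsimonious=parsimonious) for s in scenario_list]
    diffs: dict[tuple[str, str], float] = {}
    ok = [r for r in results if r.solution.status == "optimal"]
    for i, a in enumerate(ok):
        for b in ok[i + 1:]:
            diffs[(a.name, b.name)] = a.ledger.atp_yield - b.ledger.atp_yield
    return results, diffs
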