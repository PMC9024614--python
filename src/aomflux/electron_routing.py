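"""Electron-flow decomposition through the cytoplasmic redox loops.

Methane surrenders eight electrons on full oxidation to CO2.  They travel
as two-electron pairs through the CoM/CoB thiol, F420 and ferredoxin pools,
enter the membrane-soluble menaquinone pool via HdrDE, Fqo (or a pseudo-Rnf
variant), and leave to nitrate through the Nar complex (two electrons per
nitrate-to-nitrite reduction).  Accounting is annotation-driven: every
redox reaction declares its (n, donor, acceptor) transfers and the tracer
never infers electrons from formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fba import FluxSolution
from .model import ModelError, StoichiometricModel

__all__ = ["ElectronBalance", "electron_balance", "route_shares", "UNDEFINED"]

#: electrons released per methane fully oxidized to CO2
ELECTRONS_PER_CH4 = 8

#: marker for degenerate (both-zero) route shares
UNDEFINED = "undefined"

#: the cytoplasmic/membrane redox pools reported per loop
LOOPS = ("CoM-CoB", "F420", "Fd", "MQ")


@dataclass
class ElectronBalance:
    """Electron fluxes (mmol e- gDW-1 h-1) through the redox loops."""

    electrons_from_methane: float
    #: e- flux entering each pool
    per_loop: dict[str, float] = field(default_factory=dict)
    #: e- carried by the HdrDE-direct vs the HdrABC->Fqo oxidation route
    per_route: dict[str, float] = field(default_factory=dict)
    to_nitrate: float = 0.0
    acceptor_ratio: float | str = 0.0


def _require_annotations(model: StoichiometricModel) -> None:
    missing = []
    for rid in ("Nar",):
        if model.has_reaction(rid) and not model.get_reaction(rid).redox_transfers:
            missing.append(rid)
    annotated = [r for r in model.reactions if r.redox_transfers]
    if not annotated or missing:
        raise ModelError(
            f"model lacks redox-transfer annotations (missing on: {missing or 'all reactions'})"
        )


def electron_balance(model: StoichiometricModel, solution: FluxSolution) -> ElectronBalance:
    """Decompose an optimal solution into per-loop electron fluxes."""
    if solution.status != "optimal":
        raise ModelError(f"cannot trace a solution with status '{solution.status}'")
    _require_annotations(model)

    ch4_uptake = max(0.0, -solution.fluxes.get("EX_ch4", 0.0))
    per_loop = {loop: 0.0 for loop in LOOPS}
    to_nitrate = 0.0
    for rxn in model.reactions:
        flux = solution.fluxes[rxn.id]
        for t in rxn.redox_transfers:
            e_flux = t.n * flux
            if t.acceptor in per_loop:
                per_loop[t.acceptor] += e_flux
            if t.acceptor == "NO3":
                to_nitrate += e_flux

    hdr_de = solution.fluxes.get("HdrDE", 0.0) if model.has_reaction("HdrDE") else 0.0
    hdr_abc = solution.fluxes.get("HdrABC", 0.0) if model.has_reaction("HdrABC") else 0.0
    per_route = {"HdrDE": 2.0 * hdr_de, "HdrABC": 2.0 * hdr_abc}

    no3_uptake = max(0.0, -solution.fluxes.get("EX_no3", 0.0))
    ratio: float | str = UNDEFINED if ch4_uptake == 0 else no3_uptake / ch4_uptake

    return ElectronBalance(
        electrons_from_methane=ELECTRONS_PER_CH4 * ch4_uptake,
        per_loop=per_loop,
        per_route=per_route,
        to_nitrate=to_nitrate,
        acceptor_ratio=ratio,
    )


def route_shares(
    model: StoichiometricModel, solution: FluxSolution
) -> dict[str, float | str]:
    """Flux shares of the two heterodisulfide-oxidation routes.

    Returns ``{"hdrDE_share": x, "hdrABC_share": 1 - x}``; when both fluxes
    are zero the shares are reported as the ``undefined`` marker rather
    than NaN arithmetic.
    """
    if solution.status != "optimal":
        raise ModelError(f"cannot compute shares for status '{solution.status}'")
    de = solution.fluxes.get("HdrDE", 0.0) if model.has_reaction("HdrDE") else 0.0
    abc = solution.fluxes.get("HdrABC", 0.0) if model.has_reaction("HdrABC") else 0.0
    total = de + abc
    if total == 0:
        return {"hdrDE_share": UNDEFINED, "hdrABC_share": UNDEFINED}
    return {"hdrDE_share": de / total, "hdrABC_share": abc / total}


def electron_edge_list(
    model: StoichiometricModel, solution: FluxSolution
) -> list[tuple[str, str, str, float]]:
    """Edge list of the electron-flow graph: (reaction, donor, acceptor, e- flux).

    Zero-flux edges are dropped; suitable for plotting or TSV export.
    """
    if solution.status != "optimal":
        raise ModelError(f"cannot trace a solution with status '{solution.status}'")
    edges = []
    for rxn in model.reactions:
        flux = solution.fluxes[rxn.id]
        for t in rxn.redox_transfers:
            e_flux = t.n * flux
            if abs(e_flux) > 1e-9:
                edges.append((rxn.id, t.donor, t.acceptor, e_flux))
    return edges


def biomass_bound_electrons(solution: FluxSolution) -> float:
    """Electrons retained in biomass precursors.

    Computed as 8 x (methane uptake - net CO2 export); the lumped biomass
    drain has no elemental formula, so carbon not leaving as CO2 is counted
    as retained.
    """
    ch4 = max(0.0, -solution.fluxes.get("EX_ch4", 0.0))
    co2 = max(0.0, solution.fluxes.get("EX_co2", 0.0))
    return ELECTRONS_PER_CH4 * (ch4 - co2)
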