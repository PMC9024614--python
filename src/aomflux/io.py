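"""Model serialization (JSON dialect, SBML L3V1) and report assembly.

The JSON dialect is a faithful dump of the in-memory model: species with
formula/charge/compartment, reactions with stoichiometry, bounds,
translocation and redox-transfer annotations, the objective and the
parameter table.  SBML export goes through cobrapy (Level 3 Version 1 with
fbc bounds and objective); translocation and redox annotations ride in
reaction notes so a round trip preserves them.  Moiety pools need no
serialization at all — they are re-derived from the pseudo-element tags in
species formulas on load.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import pandas as pd

from .bioenergetics import ScenarioResult, run_scenario_solution
from .electron_routing import UNDEFINED, electron_balance, route_shares
from .model import (
    ModelError,
    Reaction,
    RedoxTransfer,
    Species,
    StoichiometricModel,
    Translocation,
)
from .scenarios import ScenarioSpec

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "write_json",
    "read_json",
    "export_sbml",
    "import_sbml",
    "write_flux_tsv",
    "write_ion_tsv",
    "write_electron_tsv",
    "run_scenario",
]

logger = logging.getLogger("aomflux")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "id": model.id,
        "compartments": dict(model.compartments),
        "objective": model.objective_id,
        "parameters": dict(model.parameters),
        "species": [asdict(s) for s in model.species],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "translocations": [asdict(t) for t in r.translocations],
                "redox_transfers": [asdict(t) for t in r.redox_transfers],
                "lumped": r.lumped,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(data: dict) -> StoichiometricModel:
    model = StoichiometricModel(
        id=data.get("id", "model"),
        compartments=dict(data.get("compartments", {"c": "cytoplasm", "e": "extracellular"})),
        objective_id=data.get("objective"),
        parameters=dict(data.get("parameters", {})),
        species=[Species(**s) for s in data["species"]],
        reactions=[
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -1000.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                subsystem=r.get("subsystem", ""),
                translocations=tuple(Translocation(**t) for t in r.get("translocations", [])),
                redox_transfers=tuple(RedoxTransfer(**t) for t in r.get("redox_transfers", [])),
                lumped=bool(r.get("lumped", False)),
            )
            for r in data["reactions"]
        ],
    )
    model.check_structure()
    return model


def write_json(model: StoichiometricModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str) -> StoichiometricModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# SBML Level 3 Version 1 (fbc) via cobrapy
# ---------------------------------------------------------------------------

def _encode_notes(rxn: Reaction) -> dict[str, str]:
    notes: dict[str, str] = {}
    if rxn.translocations:
        notes["translocation"] = ";".join(
            f"{t.ion}:{t.count:g}:{t.direction}" for t in rxn.translocations
        )
    if rxn.redox_transfers:
        notes["redox"] = ";".join(
            f"{t.n}:{t.donor}:{t.acceptor}" for t in rxn.redox_transfers
        )
    if rxn.lumped:
        notes["lumped"] = "true"
    return notes


def _decode_notes(notes: dict) -> tuple[tuple, tuple, bool]:
    trans, redox, lumped = (), (), False
    raw = notes.get("translocation")
    if raw:
        trans = tuple(
            Translocation(ion, float(count), direction)
            for ion, count, direction in (part.split(":") for part in str(raw).split(";"))
        )
    raw = notes.get("redox")
    if raw:
        redox = tuple(
            RedoxTransfer(int(n), donor, acceptor)
            for n, donor, acceptor in (part.split(":") for part in str(raw).split(";"))
        )
    if str(notes.get("lumped", "")).lower() == "true":
        lumped = True
    return trans, redox, lumped


def to_cobra(model: StoichiometricModel):
    """Convert to a cobrapy Model (used for SBML I/O and as an LP cross-check)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for sp in model.species:
        met = cobra.Metabolite(
            sp.id, formula=sp.formula or None, name=sp.name,
            charge=sp.charge, compartment=sp.compartment,
        )
        mets[sp.id] = met
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[sid]: coef for sid, coef in r.stoichiometry.items()})
        cr.notes.update(_encode_notes(r))
    if model.objective_id:
        cm.objective = model.objective_id
        cm.objective_direction = "max"
    return cm


def from_cobra(cm) -> StoichiometricModel:
    species = [
        Species(
            id=m.id, name=m.name or "", formula=m.formula or "",
            charge=int(m.charge or 0), compartment=m.compartment or "c",
        )
        for m in cm.metabolites
    ]
    compartments = {c: cm.compartments.get(c) or c for c in {s.compartment for s in species}}
    reactions = []
    for cr in cm.reactions:
        trans, redox, lumped = _decode_notes(cr.notes or {})
        reactions.append(Reaction(
            id=cr.id,
            name=cr.name or "",
            stoichiometry={m.id: float(coef) for m, coef in cr.metabolites.items()},
            lower_bound=float(cr.lower_bound),
            upper_bound=float(cr.upper_bound),
            subsystem=cr.subsystem or "",
            translocations=trans,
            redox_transfers=redox,
            lumped=lumped,
        ))
    objective_id = None
    for cr in cm.reactions:
        if cr.objective_coefficient:
            objective_id = cr.id
            break
    model = StoichiometricModel(
        id=cm.id or "model",
        species=species,
        reactions=reactions,
        compartments=compartments,
        objective_id=objective_id,
    )
    model.check_structure()
    return model


def export_sbml(model: StoichiometricModel, path: str) -> None:
    """Write the model as SBML Level 3 Version 1 with fbc bounds/objective."""
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), path)


def _precheck_sbml(path: str) -> None:
    """Raise informative errors for malformed XML or undeclared species."""
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ModelError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelError(f"'{path}' contains no SBML model")
    declared = {sbml_model.getSpecies(i).getId() for i in range(sbml_model.getNumSpecies())}
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        refs = [rxn.getReactant(j).getSpecies() for j in range(rxn.getNumReactants())]
        refs += [rxn.getProduct(j).getSpecies() for j in range(rxn.getNumProducts())]
        for sid in refs:
            if sid not in declared:
                raise ModelError(
                    f"reaction '{rxn.getId()}' references undeclared species '{sid}'"
                )


def import_sbml(path: str) -> StoichiometricModel:
    """Read an SBML L3V1 model; files without fbc bounds get +/-1000 defaults."""
    from cobra.io import read_sbml_model

    _precheck_sbml(path)
    return from_cobra(read_sbml_model(path))


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def _round6(x: float) -> float:
    return float(f"{x:.6f}") + 0.0


def write_flux_tsv(result: ScenarioResult, model: StoichiometricModel, path: str) -> None:
    rows = [
        (result.name, r.id, r.subsystem, _round6(result.solution.fluxes[r.id]))
        for r in model.reactions
    ]
    pd.DataFrame(rows, columns=["scenario", "reaction", "subsystem", "flux"]).to_csv(
        path, sep="\t", index=False
    )


def write_ion_tsv(result: ScenarioResult, path: str) -> None:
    ledger = result.ledger
    rows = []
    for rid, ion, ion_flux in ledger.rows():
        flux = result.solution.fluxes[rid]
        rows.append((result.name, rid, ion, _round6(flux), _round6(ion_flux)))
    for label, value in (
        ("net_H", ledger.net_H),
        ("net_Na", ledger.net_Na),
        ("total", ledger.total_gradient),
        ("ATP", ledger.atp_yield),
    ):
        rows.append((result.name, "summary", label, "", _round6(value)))
    pd.DataFrame(rows, columns=["scenario", "reaction", "ion", "flux", "ion_flux"]).to_csv(
        path, sep="\t", index=False
    )


def write_electron_tsv(result: ScenarioResult, model: StoichiometricModel, path: str) -> None:
    bal = electron_balance(model, result.solution)
    total = bal.electrons_from_methane
    rows = [("from_methane", _round6(total), 1.0 if total else "")]
    for loop, e_flux in sorted(bal.per_loop.items()):
        share = _round6(e_flux / total) if total else ""
        rows.append((loop, _round6(e_flux), share))
    rows.append(("to_nitrate", _round6(bal.to_nitrate),
                 _round6(bal.to_nitrate / total) if total else ""))
    pd.DataFrame(rows, columns=["loop", "e_flux", "share"]).to_csv(
        path, sep="\t", index=False
    )


def summary_dict(result: ScenarioResult, model: StoichiometricModel) -> dict:
    sol = result.solution
    out = {"scenario": result.name, "status": sol.status}
    if sol.status != "optimal":
        return out
    ledger = result.ledger
    bal = electron_balance(model, sol)
    ratio = bal.acceptor_ratio
    out.update({
        "objective_id": sol.objective_id,
        "objective": _round6(sol.objective_value),
        "net_H": _round6(ledger.net_H),
        "net_Na": _round6(ledger.net_Na),
        "total_gradient": _round6(ledger.total_gradient),
        "atp_yield": _round6(ledger.atp_yield),
        "acceptor_ratio": _round6(ratio) if ratio != UNDEFINED else UNDEFINED,
    })
    shares = route_shares(model, sol)
    if shares["hdrDE_share"] != UNDEFINED:
        out["hdrDE_share"] = _round6(shares["hdrDE_share"])
        out["hdrABC_share"] = _round6(shares["hdrABC_share"])
    return out


def run_scenario(
    spec: ScenarioSpec, outdir: str, parsimonious: bool = True, debug: bool = False
) -> ScenarioResult:
    """Run one scenario end to end and write its reports.

    Writes ``<name>_flux.tsv``, ``<name>_ions.tsv``, ``<name>_electrons.tsv``
    and ``<name>_summary.json`` under ``outdir``, plus a run log.  Raises
    :class:`ModelError` on invalid specs before any solve; an infeasible
    solve still writes the summary (with its status) so callers can exit
    nonzero.
    """
    spec.validate()
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, f"{spec.name}.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if debug else logging.INFO)
    try:
        logger.info("scenario %s: variant=%s objective=%s", spec.name, spec.variant, spec.objective)
        result = run_scenario_solution(spec, parsimonious=parsimonious)
        from .scenarios import build_scenario_model

        model = build_scenario_model(spec)
        logger.info("status=%s objective=%s", result.solution.status,
                    result.solution.objective_value)
        if result.solution.status == "optimal":
            for rid, flux in sorted(result.solution.fluxes.items()):
                logger.debug("flux %s = %.6f", rid, flux)
            write_flux_tsv(result, model, os.path.join(outdir, f"{spec.name}_flux.tsv"))
            write_ion_tsv(result, os.path.join(outdir, f"{spec.name}_ions.tsv"))
            write_electron_tsv(result, model, os.path.join(outdir, f"{spec.name}_electrons.tsv"))
        with open(os.path.join(outdir, f"{spec.name}_summary.json"), "w") as fh:
            json.dump(summary_dict(result, model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
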