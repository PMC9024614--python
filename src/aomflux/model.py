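"""Core data structures for compartmented stoichiometric models.

A :class:`StoichiometricModel` holds species, reactions with flux bounds and
optional ion-translocation metadata, and a single maximization objective.
The model is deliberately small and explicit: translocated ions are ordinary
extracellular species in reaction stoichiometry, so chemiosmotic coupling is
visible to the linear program, and the ``translocations`` records carried by
membrane enzymes are derived metadata that :func:`validate_model` checks
against the stoichiometry.

Conserved cofactor moieties (ferredoxin, F420, CoM, CoB, menaquinone,
H4MPT, MFR, CoA, ...) are encoded as pseudo-element symbols in species
formulas; elemental balance of every internal reaction then implies moiety
closure, and each pool is a left null-space vector of the internal
stoichiometric matrix.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Species",
    "Translocation",
    "RedoxTransfer",
    "Reaction",
    "StoichiometricModel",
    "ValidationReport",
    "parse_formula",
    "validate_model",
    "BIOCHEMICAL_ELEMENTS",
    "MOIETY_NAMES",
]

#: Element symbols treated as real chemistry; any other formula token is a
#: conserved-moiety tag (pseudo-element).
BIOCHEMICAL_ELEMENTS = frozenset(
    ["C", "H", "N", "O", "P", "S", "Na", "K", "Mg", "Fe", "Ni", "Co", "Se", "Zn"]
)

#: Human-readable names of the moiety tags used by the curated core model.
MOIETY_NAMES = {
    "Fd": "ferredoxin",
    "Ff": "F420",
    "Cm": "CoM",
    "Cb": "CoB",
    "Mq": "menaquinone",
    "Hm": "H4MPT",
    "Mf": "MFR",
    "Coa": "CoA",
    "Nd": "NADP",
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]*)(\d*)")


class ModelError(ValueError):
    """Raised for structurally invalid models or malformed inputs."""


def parse_formula(formula: str, species_id: str | None = None) -> dict[str, int]:
    """Parse an elemental formula string into a token -> count mapping.

    Tokens follow the usual ``Xx123`` convention; tokens outside
    :data:`BIOCHEMICAL_ELEMENTS` are conserved-moiety tags.  An empty string
    denotes a lumped species with no formula (exempt from balance checks).
    """
    if formula == "":
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            break
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        who = f" of species '{species_id}'" if species_id else ""
        raise ModelError(f"malformed formula '{formula}'{who}")
    return counts


@dataclass
class Species:
    """A metabolite in a compartment (``c`` = cytoplasm, ``e`` = extracellular)."""

    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "c"

    @property
    def elements(self) -> dict[str, int]:
        return parse_formula(self.formula, self.id)


@dataclass(frozen=True)
class Translocation:
    """Ions moved across the membrane per catalytic turnover of an enzyme."""

    ion: str  # "H+" or "Na+"
    count: float
    direction: str  # "outward" or "inward"

    def __post_init__(self) -> None:
        if self.ion not in ("H+", "Na+"):
            raise ModelError(f"unknown translocated ion '{self.ion}'")
        if self.direction not in ("outward", "inward"):
            raise ModelError(f"translocation direction must be outward/inward, got '{self.direction}'")
        if self.count < 0:
            raise ModelError("translocation count must be >= 0")

    @property
    def sign(self) -> int:
        """Outward positive, matching the additive gradient bookkeeping."""
        return 1 if self.direction == "outward" else -1


@dataclass(frozen=True)
class RedoxTransfer:
    """Electron-transfer annotation: n electrons from donor pool to acceptor pool."""

    n: int
    donor: str
    acceptor: str


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    translocations: tuple[Translocation, ...] = ()
    redox_transfers: tuple[RedoxTransfer, ...] = ()
    #: lumped reactions (biomass drain) are exempt from balance checks
    lumped: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction '{self.id}' has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction '{self.id}': lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_boundary(self) -> bool:
        """Exchange/demand reactions touch a single species."""
        return len(self.stoichiometry) == 1


@dataclass
class StoichiometricModel:
    """Compartmented species, reactions, and one maximization objective."""

    id: str = "model"
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: dict[str, str] = field(
        default_factory=lambda: {"c": "cytoplasm", "e": "extracellular"}
    )
    objective_id: str | None = None
    parameters: dict[str, float] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(f"unknown species '{sid}'")

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction '{rid}'")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def remove_reaction(self, rid: str) -> None:
        self.get_reaction(rid)  # raise if absent
        self.reactions = [r for r in self.reactions if r.id != rid]

    def copy(self) -> "StoichiometricModel":
        return copy.deepcopy(self)

    # -- structure -------------------------------------------------------
    def check_structure(self) -> None:
        """Raise on duplicate ids, undeclared species or compartments."""
        sids = self.species_ids()
        if len(set(sids)) != len(sids):
            dup = sorted({s for s in sids if sids.count(s) > 1})
            raise ModelError(f"duplicate species ids: {dup}")
        rids = self.reaction_ids()
        if len(set(rids)) != len(rids):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        declared = set(sids)
        for sp in self.species:
            if sp.compartment not in self.compartments:
                raise ModelError(
                    f"species '{sp.id}' in undeclared compartment '{sp.compartment}'"
                )
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - declared
            if missing:
                raise ModelError(
                    f"reaction '{rxn.id}' references undeclared species {sorted(missing)}"
                )
        if self.objective_id is not None and not self.has_reaction(self.objective_id):
            raise ModelError(f"objective reaction '{self.objective_id}' not in model")

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (species x reactions) plus row and column id orders."""
        sids = self.species_ids()
        rids = self.reaction_ids()
        index = {s: i for i, s in enumerate(sids)}
        S = np.zeros((len(sids), len(rids)))
        for j, rxn in enumerate(self.reactions):
            for sid, coef in rxn.stoichiometry.items():
                S[index[sid], j] = coef
        return S, sids, rids

    def moiety_pools(self) -> dict[str, dict[str, int]]:
        """Conserved-moiety pools derived from pseudo-element formula tags.

        Returns mapping ``tag -> {species_id: tag count}``.
        """
        pools: dict[str, dict[str, int]] = {}
        for sp in self.species:
            for element, count in sp.elements.items():
                if element not in BIOCHEMICAL_ELEMENTS:
                    pools.setdefault(element, {})[sp.id] = count
        return pools


@dataclass
class ValidationReport:
    """Outcome of mass/charge balance, moiety closure and dead-end checks."""

    elemental_imbalance: dict[str, dict[str, float]]
    charge_imbalance: dict[str, float]
    dead_end_species: list[str]
    moiety_pools: dict[str, bool]  # pool name -> closed
    translocation_mismatches: list[str]

    @property
    def passed(self) -> bool:
        return (
            not self.elemental_imbalance
            and not self.charge_imbalance
            and all(self.moiety_pools.values())
            and not self.translocation_mismatches
        )

    def summary(self) -> str:
        lines = [f"balanced: {not self.elemental_imbalance and not self.charge_imbalance}"]
        for rid, imb in sorted(self.elemental_imbalance.items()):
            lines.append(f"  element imbalance {rid}: {imb}")
        for rid, q in sorted(self.charge_imbalance.items()):
            lines.append(f"  charge imbalance {rid}: {q:+g}")
        closed = all(self.moiety_pools.values())
        lines.append(f"moiety pools closed: {closed} ({len(self.moiety_pools)} pools)")
        for name, ok in sorted(self.moiety_pools.items()):
            if not ok:
                lines.append(f"  open pool: {name}")
        for msg in self.translocation_mismatches:
            lines.append(f"  translocation mismatch: {msg}")
        if self.dead_end_species:
            lines.append(f"dead-end species: {sorted(self.dead_end_species)}")
        return "\n".join(lines)


def _ion_species_coeff(model: StoichiometricModel, rxn: Reaction, ion: str) -> float:
    """Net stoichiometric coefficient of the extracellular form of an ion."""
    target = {"H+": "h_e", "Na+": "na_e"}[ion]
    return rxn.stoichiometry.get(target, 0.0)


def validate_model(
    model: StoichiometricModel, tol: float = 1e-9
) -> ValidationReport:
    """Check elemental/charge balance, moiety-pool closure and dead ends.

    Exchange reactions, lumped drains (``lumped=True``) and species with an
    empty formula are exempt from the element/charge checks.  Moiety pools
    are derived from pseudo-element tags and checked as left null-space
    vectors of the internal stoichiometric matrix.  Reactions carrying
    translocation records are cross-checked against their extracellular ion
    stoichiometry.
    """
    if not model.reactions:
        raise ModelError("model has no reactions")
    model.check_structure()
    species = {s.id: s for s in model.species}

    elemental: dict[str, dict[str, float]] = {}
    charge: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.is_boundary or rxn.lumped:
            continue
        if any(species[sid].formula == "" for sid in rxn.stoichiometry):
            continue  # lumped species make the check undefined
        balance: dict[str, float] = {}
        q = 0.0
        for sid, coef in rxn.stoichiometry.items():
            sp = species[sid]
            q += coef * sp.charge
            for element, count in sp.elements.items():
                balance[element] = balance.get(element, 0.0) + coef * count
        bad = {e: v for e, v in balance.items() if abs(v) > tol}
        if bad:
            elemental[rxn.id] = bad
        if abs(q) > tol:
            charge[rxn.id] = q

    # Moiety pools: indicator (weighted by tag count) dotted with every
    # internal reaction column must vanish.
    pools: dict[str, bool] = {}
    for tag, members in model.moiety_pools().items():
        closed = True
        for rxn in model.reactions:
            if rxn.is_boundary:
                continue
            total = sum(
                coef * members.get(sid, 0) for sid, coef in rxn.stoichiometry.items()
            )
            if abs(total) > tol:
                closed = False
                break
        name = MOIETY_NAMES.get(tag, tag)
        pools[name] = closed

    # Dead ends: species only produced or only consumed by irreversible
    # reactions (reversible participation counts as both).
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions:
        for sid, coef in rxn.stoichiometry.items():
            if coef > 0 and rxn.upper_bound > 0 or coef < 0 and rxn.lower_bound < 0:
                producible.add(sid)
            if coef < 0 and rxn.upper_bound > 0 or coef > 0 and rxn.lower_bound < 0:
                consumable.add(sid)
    dead = [s.id for s in model.species if s.id not in producible or s.id not in consumable]

    mismatches: list[str] = []
    for rxn in model.reactions:
        if not rxn.translocations:
            continue
        for ion in ("H+", "Na+"):
            declared = sum(t.count * t.sign for t in rxn.translocations if t.ion == ion)
            actual = _ion_species_coeff(model, rxn, ion)
            if abs(declared - actual) > tol:
                mismatches.append(
                    f"{rxn.id}: {ion} record {declared:+g} vs stoichiometry {actual:+g}"
                )

    return ValidationReport(
        elemental_imbalance=elemental,
        charge_imbalance=charge,
        dead_end_species=dead,
        moiety_pools=pools,
        translocation_mismatches=mismatches,
    )
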