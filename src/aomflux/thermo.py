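"""Redox thermodynamics from midpoint potentials: DeltaG = -n F DeltaE.

Potentials are stored in mV and the Faraday constant as 0.09648 kJ mol-1
per electron per volt-scaled-to-mV (0.09648 kJ/eV), so a two-electron
transfer from F420 (-380 mV) to menaquinone (-80 mV) yields
-2 x 0.09648 x 300 = -57.888 kJ/mol.  No unit auto-detection is performed.

Per-reaction standard Gibbs energies can be supplied by the user in a
:class:`DeltaGTable` (the curated literature values for the full pathway
are not reconstructed here); the flux-weighted redox-cycle sum of the
nitrate-driven oxidation loop is then evaluated with the HdrDE/HdrABC
route weights taken from the flux solution (defaults 0.183/1.1 and
0.917/1.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .defaults import load_defaults
from .model import ModelError

__all__ = [
    "RedoxCouple",
    "DeltaGTable",
    "default_couples",
    "delta_g",
    "confurcation_delta_g",
    "redox_cycle_delta_g",
    "FARADAY_KJ_PER_MV",
]

#: Faraday constant, kJ mol-1 mV-1 per electron (i.e. 0.09648 kJ/eV)
FARADAY_KJ_PER_MV = 0.09648


@dataclass(frozen=True)
class RedoxCouple:
    """A redox half-couple with its midpoint potential E0' at pH 7."""

    name: str
    e0_prime_mv: float
    n_default: int = 2
    source: str = "literature"


def default_couples() -> dict[str, RedoxCouple]:
    """The packaged midpoint-potential table (mV).

    Contains ferredoxin -520, CoM-SH/CoB-SH -143, F420 -380, menaquinone
    -80 and methanophenazine -165; the NO3-/NO2- couple (+433) is a
    package-adopted standard value, flagged by its ``source`` field.
    """
    table = load_defaults()["redox_couples"]
    return {
        name: RedoxCouple(
            name=name,
            e0_prime_mv=float(entry["e0_prime_mv"]),
            n_default=int(entry["n_default"]),
            source=entry.get("source", "literature"),
        )
        for name, entry in table.items()
    }


def delta_g(n: int, donor: RedoxCouple, acceptor: RedoxCouple) -> float:
    """Standard Gibbs energy (kJ/mol) of an n-electron donor->acceptor transfer."""
    if n < 1:
        raise ModelError("electron count n must be >= 1")
    return -n * FARADAY_KJ_PER_MV * (acceptor.e0_prime_mv - donor.e0_prime_mv)


def confurcation_delta_g(couples: dict[str, RedoxCouple] | None = None) -> float:
    """Standard Gibbs energy of the HdrABC electron confurcation (kJ/mol).

    The confurcation moves two electron pairs onto two F420: one pair from
    the CoM-SH/CoB-SH thiols (uphill) and one from reduced ferredoxin
    (downhill); the composed DeltaG is the sum of the two pair terms and is
    positive at standard potentials.
    """
    couples = couples if couples is not None else default_couples()
    for name in ("CoM/CoB", "Fd", "F420"):
        if name not in couples:
            raise ModelError(f"missing redox couple '{name}'")
    thiols, fd, f420 = couples["CoM/CoB"], couples["Fd"], couples["F420"]
    return delta_g(2, thiols, f420) + delta_g(2, fd, f420)


class DeltaGTable:
    """Per-reaction standard Gibbs energies (kJ/mol) with provenance tags."""

    def __init__(self) -> None:
        self._entries: dict[str, tuple[float, str]] = {}

    def set(self, reaction_id: str, dg: float, provenance: str = "user-supplied") -> None:
        if provenance not in ("computed", "user-supplied"):
            raise ModelError(f"unknown provenance '{provenance}'")
        self._entries[reaction_id] = (float(dg), provenance)

    def set_computed(
        self, reaction_id: str, n: int, donor: RedoxCouple, acceptor: RedoxCouple
    ) -> float:
        dg = delta_g(n, donor, acceptor)
        self._entries[reaction_id] = (dg, "computed")
        return dg

    def __getitem__(self, reaction_id: str) -> float:
        if reaction_id not in self._entries:
            raise ModelError(f"DeltaG table has no entry for '{reaction_id}'")
        return self._entries[reaction_id][0]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self._entries

    def provenance(self, reaction_id: str) -> str:
        return self._entries[reaction_id][1]

    def items(self):
        return [(rid, dg, prov) for rid, (dg, prov) in sorted(self._entries.items())]

    # -- TSV I/O ---------------------------------------------------------
    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.items(), columns=["reaction", "dG_kJ_per_mol", "provenance"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "DeltaGTable":
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for _, row in df.iterrows():
            table.set(str(row["reaction"]), float(row["dG_kJ_per_mol"]),
                      str(row.get("provenance", "user-supplied")))
        return table


def default_cycle_weights() -> tuple[float, float]:
    w = load_defaults()["redox_cycle_weights"]
    d = float(w["denominator"])
    return float(w["w_de_numerator"]) / d, float(w["w_abc_numerator"]) / d


def redox_cycle_delta_g(
    table: DeltaGTable,
    w_de: float | None = None,
    w_abc: float | None = None,
) -> float:
    """Flux-weighted Gibbs energy of the complete redox cycle (kJ/mol).

    DG = DG_Mcr + DG_Mtr + w_de (DG_HdrDE + DG_Nar)
                         + w_abc (DG_HdrABC + DG_Fqo + DG_Nar)

    with the route weights defaulting to the reference flux shares
    0.183/1.1 (HdrDE) and 0.917/1.1 (HdrABC).
    """
    if w_de is None or w_abc is None:
        d_de, d_abc = default_cycle_weights()
        w_de = d_de if w_de is None else w_de
        w_abc = d_abc if w_abc is None else w_abc
    for rid in ("Mcr", "Mtr", "HdrDE", "HdrABC", "Fqo", "Nar"):
        if rid not in table:
            raise ModelError(f"DeltaG table has no entry for '{rid}'")
    return (
        table["Mcr"]
        + table["Mtr"]
        + w_de * (table["HdrDE"] + table["Nar"])
        + w_abc * (table["HdrABC"] + table["Fqo"] + table["Nar"])
    )


def couples_to_tsv(couples: dict[str, RedoxCouple], path: str) -> None:
    df = pd.DataFrame(
        [(c.name, c.e0_prime_mv, c.n_default, c.source) for c in couples.values()],
        columns=["name", "E0_prime_mV", "n", "source"],
    )
    df.to_csv(path, sep="\t", index=False)


def couples_from_tsv(path: str) -> dict[str, RedoxCouple]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        c = RedoxCouple(
            name=str(row["name"]),
            e0_prime_mv=float(row["E0_prime_mV"]),
            n_default=int(row["n"]),
            source=str(row["source"]) if "source" in row else "literature",
        )
        out[c.name] = c
    return out
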