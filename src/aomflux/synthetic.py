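"""Random balanced stoichiometric networks for engine-independent testing.

The generator emits models with the same structural features the curated
network relies on — a linear substrate-to-product backbone, closed cofactor
redox pairs wired into backbone steps, ion-pumping reoxidation reactions,
an ion-coupled ATP synthase — but with a maximum ATP flux known in closed
form by construction:

    max ATP = n_translocating x ions_per_pump x uptake_bound / ions_per_atp

Each cofactor pair is wired to exactly one backbone step, so every
reoxidation reaction turns over once per substrate consumed.  Elemental
bookkeeping mirrors the core model: each backbone intermediate carries two
hydrogens per not-yet-executed coupled step, cofactor pairs are
pseudo-element tagged (so moiety closure is checkable), and a terminal
acceptor picks up the electrons on reoxidation.  Every generated model
passes :func:`aomflux.model.validate_model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ModelError,
    Reaction,
    Species,
    StoichiometricModel,
    Translocation,
)

__all__ = ["GeneratorSpec", "generate", "perturb"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic network; generation is a pure function of this."""

    seed: int
    n_linear_steps: int = 4
    n_cofactor_pairs: int = 2
    n_translocating: int = 1
    uptake_bound: float = 3.0
    ions_per_pump: int = 2
    ions_per_atp: int = 2

    def validate(self) -> None:
        if min(self.n_linear_steps, self.n_cofactor_pairs, self.n_translocating) < 0:
            raise ModelError("generator counts must be >= 0")
        if self.uptake_bound < 0:
            raise ModelError("uptake bound must be >= 0")
        if self.n_cofactor_pairs > self.n_linear_steps:
            raise ModelError(
                f"impossible wiring: {self.n_cofactor_pairs} cofactor pairs "
                f"exceed {self.n_linear_steps} backbone steps"
            )
        if self.n_translocating > self.n_cofactor_pairs:
            raise ModelError(
                f"impossible wiring: {self.n_translocating} translocating reactions "
                f"exceed {self.n_cofactor_pairs} cofactor pairs"
            )

    @property
    def max_atp(self) -> float:
        """Closed-form maximum ATP flux of the generated model."""
        return self.n_translocating * self.ions_per_pump * self.uptake_bound / self.ions_per_atp


#: pseudo-element tags available for synthetic cofactor pairs
_TAGS = ["Qa", "Qb", "Qc", "Qd", "Qe", "Qf", "Qg", "Qh", "Qi", "Qj"]


def generate(spec: GeneratorSpec) -> StoichiometricModel:
    """Generate a balanced network with a known-by-construction ATP maximum."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k, p, t = spec.n_linear_steps, spec.n_cofactor_pairs, spec.n_translocating
    inf = 1000.0

    if p > len(_TAGS):
        raise ModelError(f"at most {len(_TAGS)} cofactor pairs supported")

    # which backbone steps (1..k) are coupled to a cofactor pair
    coupled_steps = sorted(rng.choice(np.arange(1, k + 1), size=p, replace=False))
    pair_of_step = {step: j for j, step in enumerate(coupled_steps)}
    # which pairs pump ions on reoxidation (random subset, deterministic in seed)
    pumping_pairs = set(rng.choice(np.arange(p), size=t, replace=False)) if p else set()

    species: list[Species] = []
    # backbone: hydrogen count = 2 x coupled steps still ahead
    remaining = [sum(1 for s in coupled_steps if s > i) for i in range(k + 1)]
    for i in range(k + 1):
        h = 2 * remaining[i]
        formula = f"CH{h}" if h else "C"
        species.append(Species(f"b{i}_c", f"backbone intermediate {i}", formula, 0, "c"))
    for j in range(p):
        tag = _TAGS[j]
        species.append(Species(f"cof{j}ox_c", f"cofactor {j} oxidized", tag, 0, "c"))
        species.append(Species(f"cof{j}red_c", f"cofactor {j} reduced", f"{tag}H2", 0, "c"))
    species += [
        Species("acc_c", "terminal acceptor", "O", 0, "c"),
        Species("acch2_c", "reduced acceptor", "OH2", 0, "c"),
        Species("h_c", "proton (cytoplasm)", "H", 1, "c"),
        Species("h_e", "proton (translocated)", "H", 1, "e"),
        Species("pi_c", "phosphate", "HPO4", -2, "c"),
        Species("atp_c", "ATP", "C10H12N5O13P3", -4, "c"),
        Species("adp_c", "ADP", "C10H12N5O10P2", -3, "c"),
        Species("h2o_c", "water", "H2O", 0, "c"),
    ]

    rxns: list[Reaction] = []
    for i in range(1, k + 1):
        stoich = {f"b{i-1}_c": -1.0, f"b{i}_c": 1.0}
        if i in pair_of_step:
            j = pair_of_step[i]
            stoich.update({f"cof{j}ox_c": -1.0, f"cof{j}red_c": 1.0})
        rxns.append(Reaction(f"STEP{i}", f"backbone step {i}", stoich, 0, inf, "backbone"))
    for j in range(p):
        stoich = {
            f"cof{j}red_c": -1.0, "acc_c": -1.0,
            f"cof{j}ox_c": 1.0, "acch2_c": 1.0,
        }
        trans: tuple[Translocation, ...] = ()
        if j in pumping_pairs:
            n_ions = float(spec.ions_per_pump)
            stoich.update({"h_c": -n_ions, "h_e": n_ions})
            trans = (Translocation("H+", n_ions, "outward"),)
        rxns.append(Reaction(
            f"REOX{j}", f"cofactor {j} reoxidation", stoich, 0, inf,
            "respiration", translocations=trans,
        ))
    q = float(spec.ions_per_atp)
    rxns.append(Reaction(
        "AtpSyn", f"ATP synthase ({q:g} ions per ATP)",
        {"adp_c": -1.0, "pi_c": -1.0, "h_e": -q, "atp_c": 1.0, "h2o_c": 1.0, "h_c": q - 1.0},
        0, inf, "oxidative phosphorylation",
    ))
    rxns.append(Reaction(
        "ATPM", "ATP demand",
        {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
        0, inf, "maintenance",
    ))
    for rid, sid, lb in [
        ("EX_sub", "b0_c", -spec.uptake_bound),
        ("EX_prod", f"b{k}_c", 0.0),
        ("EX_acc", "acc_c", -inf),
        ("EX_acch2", "acch2_c", 0.0),
        ("EX_h", "h_c", -inf),
        ("EX_pi", "pi_c", -inf),
        ("EX_h2o", "h2o_c", -inf),
    ]:
        rxns.append(Reaction(rid, f"exchange of {sid}", {sid: -1.0}, lb, inf, "exchange"))

    model = StoichiometricModel(
        id=f"synthetic_seed{spec.seed}",
        species=species,
        reactions=rxns,
        objective_id="ATPM",
        parameters={"ions_per_atp": q, "expected_max_atp": spec.max_atp},
    )
    model.check_structure()
    return model


def fixture_manifest(specs: list[GeneratorSpec], path: str) -> None:
    """Write a TSV manifest (seed, spec fields, expected objective) for fixtures."""
    import pandas as pd

    rows = [
        (
            s.seed, s.n_linear_steps, s.n_cofactor_pairs, s.n_translocating,
            s.uptake_bound, s.ions_per_pump, s.ions_per_atp, s.max_atp,
        )
        for s in specs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "seed", "n_linear_steps", "n_cofactor_pairs", "n_translocating",
            "uptake_bound", "ions_per_pump", "ions_per_atp", "expected_objective",
        ],
    ).to_csv(path, sep="\t", index=False)


def perturb(
    model: StoichiometricModel, seed: int, magnitude: float
) -> StoichiometricModel:
    """Randomly tighten flux bounds (never loosen them).

    Each reaction's interval shrinks inward by random fractions scaled by
    ``magnitude``; the maximized objective of the perturbed model is
    therefore never larger than the original's (possibly infeasible).
    ``magnitude`` 0 returns an identical model.
    """
    if magnitude < 0:
        raise ModelError("perturbation magnitude must be >= 0")
    out = model.copy()
    if magnitude == 0:
        return out
    rng = np.random.default_rng(seed)
    for rxn in out.reactions:
        width = rxn.upper_bound - rxn.lower_bound
        if width <= 0:
            continue
        shrink_lo = rng.uniform(0, magnitude) * width / 4
        shrink_hi = rng.uniform(0, magnitude) * width / 4
        lb = rxn.lower_bound + shrink_lo
        ub = rxn.upper_bound - shrink_hi
        if lb > ub:  # cap at the midpoint so bounds stay ordered
            lb = ub = (lb + ub) / 2
        rxn.lower_bound, rxn.upper_bound = lb, ub
    return out
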