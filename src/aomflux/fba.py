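"""Flux balance analysis: assemble S v = 0 with bounds and solve the LP.

The solver backend sits behind a single contract (:func:`solve_lp`), taking
a stoichiometric matrix, bounds and an objective vector and returning a
status, flux vector and objective value; scipy's HiGHS implementation backs
it by default.  :func:`optimize` adds the modeling layer: objective
selection, parsimonious (minimum total |v|) resolution of degenerate
optima, and feasibility-residual checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import ModelError, StoichiometricModel

__all__ = [
    "FluxSolution",
    "solve_lp",
    "optimize",
    "knockout",
    "growth_feasibility",
]

#: feasibility and optimality tolerance of the LP layer
LP_TOL = 1e-9


@dataclass
class FluxSolution:
    """Optimal flux vector with objective value and solver status."""

    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float = float("nan")
    status: str = "infeasible"  # optimal | infeasible | unbounded
    objective_id: str | None = None

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def residual(self, model: StoichiometricModel) -> float:
        """max |S v| over species; <= 1e-9 for any optimal solution."""
        S, _, rids = model.stoichiometric_matrix()
        v = np.array([self.fluxes[r] for r in rids])
        return float(np.max(np.abs(S @ v))) if len(v) else 0.0


def solve_lp(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    maximize: bool = True,
    extra_eq: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[str, np.ndarray | None, float]:
    """Solve max/min c.v s.t. S v = 0, lb <= v <= ub (HiGHS backend).

    ``extra_eq`` optionally appends equality rows (A, b).  Returns
    ``(status, v, objective)`` with status in optimal/infeasible/unbounded.
    """
    A_eq = S
    b_eq = np.zeros(S.shape[0])
    if extra_eq is not None:
        A_extra, b_extra = extra_eq
        A_eq = np.vstack([A_eq, A_extra])
        b_eq = np.concatenate([b_eq, b_extra])
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    if res.status == 0:
        return "optimal", res.x, sign * res.fun
    if res.status == 2:
        return "infeasible", None, float("nan")
    if res.status == 3:
        return "unbounded", None, float("inf")
    raise RuntimeError(f"LP solver failed: {res.message}")


def _bounds_arrays(model: StoichiometricModel) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return lb, ub


def optimize(
    model: StoichiometricModel,
    objective: str | None = None,
    parsimonious: bool = False,
) -> FluxSolution:
    """Maximize the objective reaction flux subject to S v = 0 and bounds.

    With ``parsimonious`` set, a second LP minimizes total absolute flux at
    the fixed optimal objective value, picking a unique, deterministic
    representative among alternate optima.  The objective value itself is
    invariant to the flag.
    """
    obj_id = objective if objective is not None else model.objective_id
    if obj_id is None:
        raise ModelError("no objective set")
    if not model.has_reaction(obj_id):
        raise ModelError(f"objective reaction '{obj_id}' not in model")

    S, _, rids = model.stoichiometric_matrix()
    lb, ub = _bounds_arrays(model)
    c = np.zeros(len(rids))
    j_obj = rids.index(obj_id)
    c[j_obj] = 1.0

    status, v, obj = solve_lp(S, lb, ub, c, maximize=True)
    if status != "optimal":
        return FluxSolution(status=status, objective_id=obj_id,
                            objective_value=obj if status == "unbounded" else float("nan"))

    if parsimonious:
        v = _parsimonious_fluxes(S, lb, ub, c, obj)

    fluxes = {rid: float(v[j]) for j, rid in enumerate(rids)}
    return FluxSolution(
        fluxes=fluxes,
        objective_value=float(obj),
        status="optimal",
        objective_id=obj_id,
    )


def _parsimonious_fluxes(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray, obj: float
) -> np.ndarray:
    """Stage two: min sum |v| with c.v fixed at the stage-one optimum.

    Fluxes are split v = p - q with p, q >= 0 so the problem stays linear.
    """
    n = S.shape[1]
    lb_p = np.maximum(lb, 0.0)
    ub_p = np.maximum(ub, 0.0)
    lb_q = np.maximum(-ub, 0.0)
    ub_q = np.maximum(-lb, 0.0)
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    # fix the objective value (small tolerance keeps the stage feasible)
    A_eq = np.vstack([A_eq, np.concatenate([c, -c])])
    b_eq = np.concatenate([b_eq, [obj]])
    res = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack(
            [np.concatenate([lb_p, lb_q]), np.concatenate([ub_p, ub_q])]
        ),
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    if res.status != 0:  # pragma: no cover - stage one guarantees feasibility
        raise RuntimeError(f"parsimonious stage failed: {res.message}")
    return res.x[:n] - res.x[n:]


def knockout(
    model: StoichiometricModel,
    reaction_ids: str | list[str],
    objective: str | None = None,
    parsimonious: bool = False,
) -> FluxSolution:
    """Zero the bounds of the listed reactions and re-optimize."""
    if isinstance(reaction_ids, str):
        reaction_ids = [reaction_ids]
    ko = model.copy()
    for rid in reaction_ids:
        rxn = ko.get_reaction(rid)  # KeyError on unknown id
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return optimize(ko, objective=objective, parsimonious=parsimonious)


def growth_feasibility(model: StoichiometricModel, min_growth: float = 1e-6) -> str:
    """'feasible' iff the maximum biomass flux reaches ``min_growth``."""
    from .core_network import BIOMASS_ID

    if not model.has_reaction(BIOMASS_ID):
        raise ModelError("model has no biomass reaction")
    sol = optimize(model, objective=BIOMASS_ID)
    if sol.status == "optimal" and sol.objective_value >= min_growth:
        return "feasible"
    return "infeasible"
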