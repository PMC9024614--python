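"""LP engine checks against brute-force vertex enumeration and invariants."""

import itertools

import numpy as np
import pytest

from aomflux import build_core_model, growth_feasibility, knockout, optimize
from aomflux.core_network import ATP_DEMAND_ID, apply_variant
from aomflux.model import ModelError, Reaction, Species, StoichiometricModel


def vertex_enumeration_max(S, lb, ub, c, tol=1e-9):
    """Independent oracle: maximize c.v over {S v = 0, lb <= v <= ub}.

    Enumerates basic feasible points by fixing every subset of n - rank(S)
    variables at a bound and solving the remaining square system.  Only
    viable for toy networks (n <= ~8).
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    n_fix = n - rank
    best = None
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for values in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(values) if fixed else np.zeros(m)
            A = S[:, free]
            v_free, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.linalg.norm(A @ v_free - rhs) > 1e-7:
                continue
            v = np.zeros(n)
            v[list(fixed)] = values
            v[free] = v_free
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            obj = float(c @ v)
            if best is None or obj > best:
                best = obj
    return best


def toy_chain(uptake=2.0):
    """A -> B -> C with uptake <= 2; C export is the objective."""
    return StoichiometricModel(
        species=[Species(s, formula="C") for s in ("a_c", "b_c", "c_c")],
        reactions=[
            Reaction("EX_a", stoichiometry={"a_c": -1}, lower_bound=-uptake, upper_bound=0),
            Reaction("r1", stoichiometry={"a_c": -1, "b_c": 1}, lower_bound=0, upper_bound=10),
            Reaction("r2", stoichiometry={"b_c": -1, "c_c": 1}, lower_bound=0, upper_bound=10),
            Reaction("EX_c", stoichiometry={"c_c": -1}, lower_bound=0, upper_bound=10),
        ],
        objective_id="EX_c",
    )


class TestToyNetworks:
    def test_chain_objective_matches_vertex_enumeration(self):
        m = toy_chain()
        sol = optimize(m)
        S, _, _ = m.stoichiometric_matrix()
        lb = np.array([r.lower_bound for r in m.reactions])
        ub = np.array([r.upper_bound for r in m.reactions])
        c = np.array([0.0, 0, 0, 1])
        oracle = vertex_enumeration_max(S, lb, ub, c)
        assert sol.objective_value == pytest.approx(2.0, abs=1e-8)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_random_toys_match_vertex_enumeration(self):
        """Objectives agree with the enumeration oracle on <=6-reaction toys."""
        from aomflux.fba import solve_lp

        rng = np.random.default_rng(42)
        agreements = 0
        for _ in range(25):
            m, n = 2, 6
            S = rng.integers(-2, 3, size=(m, n)).astype(float)
            lb = np.where(rng.random(n) < 0.5, 0.0, -rng.integers(1, 4, n).astype(float))
            ub = rng.integers(1, 5, n).astype(float)
            c = rng.integers(-1, 2, n).astype(float)
            status, _, obj = solve_lp(S, lb, ub, c, maximize=True)
            oracle = vertex_enumeration_max(S, lb, ub, c)
            if status == "optimal" and oracle is not None:
                assert obj == pytest.approx(oracle, abs=1e-8)
                agreements += 1
        assert agreements >= 10  # the comparison actually exercised solves

    def test_uptake_scaling_is_linear(self):
        full = optimize(toy_chain(uptake=2.0)).objective_value
        half = optimize(toy_chain(uptake=1.0)).objective_value
        assert half == pytest.approx(full / 2, abs=1e-9)


class TestCoreOptima:
    def test_atp_max_is_7_15(self, atp_max_solution):
        assert atp_max_solution.status == "optimal"
        assert atp_max_solution.objective_value == pytest.approx(7.15, abs=1e-6)

    def test_objective_invariant_to_parsimonious_flag(self, atp_max_model):
        plain = optimize(atp_max_model, objective=ATP_DEMAND_ID, parsimonious=False)
        pfba = optimize(atp_max_model, objective=ATP_DEMAND_ID, parsimonious=True)
        assert plain.objective_value == pytest.approx(pfba.objective_value, abs=1e-9)

    def test_feasibility_residual_below_1e9(self, atp_max_model, atp_max_solution):
        assert atp_max_solution.residual(atp_max_model) <= 1e-9

    def test_fluxes_within_bounds(self, atp_max_model, atp_max_solution):
        for r in atp_max_model.reactions:
            v = atp_max_solution.fluxes[r.id]
            assert r.lower_bound - 1e-9 <= v <= r.upper_bound + 1e-9

    def test_no_substrate_no_atp(self, core_model):
        m = core_model.copy()
        for r in m.reactions:
            if r.id.startswith("EX_"):
                r.lower_bound = r.upper_bound = 0.0
        m.get_reaction(ATP_DEMAND_ID).lower_bound = 0.0
        sol = optimize(m, objective=ATP_DEMAND_ID)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_bound_relaxation_never_decreases_objective(self, atp_max_model):
        base = optimize(atp_max_model, objective=ATP_DEMAND_ID).objective_value
        relaxed = atp_max_model.copy()
        ex = relaxed.get_reaction("EX_ch4")
        ex.lower_bound, ex.upper_bound = -2.0, 0.0
        assert optimize(relaxed, objective=ATP_DEMAND_ID).objective_value >= base - 1e-9

    def test_missing_objective_errors(self, core_model):
        m = core_model.copy()
        m.objective_id = None
        with pytest.raises(ModelError, match="objective"):
            optimize(m)


class TestKnockouts:
    def test_noop_knockout_preserves_objective(self, atp_max_model):
        base = optimize(atp_max_model, objective=ATP_DEMAND_ID).objective_value
        same = knockout(atp_max_model, [], objective=ATP_DEMAND_ID).objective_value
        assert same == pytest.approx(base, abs=1e-9)

    def test_hdrabc_knockout_abolishes_growth(self, core_model):
        sol = knockout(core_model, "HdrABC", objective="Biomass")
        assert sol.status == "infeasible" or sol.objective_value <= 1e-9

    def test_methane_exchange_knockout_zeroes_atp(self, core_model):
        m = core_model.copy()
        m.get_reaction(ATP_DEMAND_ID).lower_bound = 0.0
        sol = knockout(m, "EX_ch4", objective=ATP_DEMAND_ID)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_id_errors(self, core_model):
        with pytest.raises(KeyError, match="NotARxn"):
            knockout(core_model, "NotARxn")


class TestGrowthFeasibility:
    def test_confurcation_grows(self, core_model):
        assert growth_feasibility(core_model, 1e-6) == "feasible"

    def test_r1_variant_cannot_grow(self, core_model):
        assert growth_feasibility(apply_variant(core_model, "R1"), 1e-6) == "infeasible"

    def test_r2_with_fixed_acceptor_ratio_infeasible(self, core_model):
        m = apply_variant(core_model, "R2")
        ch4 = m.get_reaction("EX_ch4")
        ch4.lower_bound = ch4.upper_bound = -1.1
        no3 = m.get_reaction("EX_no3")
        no3.lower_bound = no3.upper_bound = -4.4
        assert optimize(m, objective=ATP_DEMAND_ID).status == "infeasible"

    def test_r3_decoupling_restores_growth(self, core_model):
        assert growth_feasibility(apply_variant(core_model, "R3"), 1e-6) == "feasible"


def test_unbounded_status():
    m = StoichiometricModel(
        species=[Species("a_c", formula="C")],
        reactions=[
            Reaction("EX_in", stoichiometry={"a_c": 1}, lower_bound=0, upper_bound=float("inf")),
            Reaction("EX_out", stoichiometry={"a_c": -1}, lower_bound=0, upper_bound=float("inf")),
        ],
        objective_id="EX_out",
    )
    assert optimize(m).status == "unbounded"
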