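"""Mass-balancing cascade: the four methods, additions, classification."""

import random
from fractions import Fraction
from itertools import product as iproduct

import numpy as np
import pytest

from gemcurate.fixtures import FixtureSpec, corrupt, generate_truth_network
from gemcurate.formula import parse_formula
from gemcurate.mass_balance import (
    BalanceProblem,
    apply_outcome,
    balance,
    classify_imbalance_report,
    imbalance_vector,
    solve_lp,
    solve_nullspace,
    solve_rref,
)
from gemcurate.model import ReactionEntity
from conftest import toy_network


def exhaustive_search(problem: BalanceProblem, cap: int = 10):
    """Oracle: minimal-sum strictly positive integer solution, coefficients <= cap."""
    n = len(problem.participants)
    M = np.array(
        [[float(c) for c in row] for row in problem.M]
    )  # participants x atoms
    grid = np.array(list(iproduct(range(1, cap + 1), repeat=n)))
    nets = grid @ M
    hits = grid[np.all(nets == 0, axis=1)]
    if len(hits) == 0:
        return None
    best = min(map(tuple, hits.tolist()), key=lambda t: (sum(t), t))
    return [Fraction(int(v)) for v in best]


def problem_from(net, rxn) -> BalanceProblem:
    return BalanceProblem.from_reaction(rxn, net)


class TestImbalanceVector:
    def test_balanced_combustion_is_zero(self):
        n = toy_network({"glc": "C6H12O6", "o2": "O2", "co2": "CO2", "h2o": "H2O"})
        r = ReactionEntity("r", substrates={"glc": 1, "o2": 6},
                           products={"co2": 6, "h2o": 6})
        n.add_reaction(r)
        assert imbalance_vector(problem_from(n, r)) == {}

    def test_missing_oxygen_detected(self):
        n = toy_network({"h2": "H2", "o2": "O2", "h2o": "H2O"})
        r = ReactionEntity("r", substrates={"h2": 1, "o2": 1}, products={"h2o": 1})
        n.add_reaction(r)
        assert imbalance_vector(problem_from(n, r)) == {"O": Fraction(1)}

    def test_empty_product_side_equals_substrate_totals(self):
        n = toy_network({"glc": "C6H12O6"})
        r = ReactionEntity("r", substrates={"glc": 2}, products={}, kind="exchange")
        n.add_reaction(r)
        assert imbalance_vector(problem_from(n, r)) == {
            "C": 12, "H": 24, "O": 12,
        }


class TestSolvers:
    def test_nullspace_water_formation(self):
        n = toy_network({"h2": "H2", "o2": "O2", "h2o": "H2O"})
        r = ReactionEntity("r", substrates={"h2": 1, "o2": 1}, products={"h2o": 1})
        n.add_reaction(r)
        p = problem_from(n, r)
        assert solve_nullspace(p) == [2, 1, 2] == exhaustive_search(p)

    def test_nullspace_scales_balanced_input(self):
        n = toy_network({"a": "C2H4", "b": "CH2"})
        r = ReactionEntity("r", substrates={"a": 3}, products={"b": 6})
        n.add_reaction(r)
        assert solve_nullspace(problem_from(n, r)) == [1, 2]

    def test_no_positive_solution_returns_none(self):
        n = toy_network({"cc": "C", "oo": "O"})
        r = ReactionEntity("r", substrates={"cc": 1}, products={"oo": 1})
        n.add_reaction(r)
        p = problem_from(n, r)
        assert solve_nullspace(p) is None
        assert solve_rref(p) is None
        assert solve_lp(p) is None
        assert exhaustive_search(p) is None

    def test_rref_two_dimensional_nullspace_minimal_sum(self):
        # two independent balanced sub-reactions written as one
        n = toy_network({"A": "H2", "B": "O", "C": "H2O", "D": "C", "E": "O2", "F": "CO2"})
        r = ReactionEntity("r", substrates={"A": 1, "B": 2, "D": 1, "E": 1},
                           products={"C": 1, "F": 1})
        n.add_reaction(r)
        p = problem_from(n, r)
        assert solve_nullspace(p) is None  # 2-dimensional nullspace
        got = solve_rref(p)
        assert got is not None
        assert got == exhaustive_search(p)

    def test_rref_agrees_with_nullspace_on_unique_problems(self):
        n = toy_network({"h2": "H2", "o2": "O2", "h2o": "H2O"})
        r = ReactionEntity("r", substrates={"h2": 1, "o2": 1}, products={"h2o": 1})
        n.add_reaction(r)
        p = problem_from(n, r)
        assert solve_rref(p) == solve_nullspace(p)

    def test_lp_handles_high_dimensional_nullspace(self):
        # four independent balanced pairs concatenated: rref gives up
        # (too many free variables), the LP still finds a positive balance
        comps = {}
        subs, prods = {}, {}
        for i, formula in enumerate(["H2", "O2", "N2", "C2"]):
            comps[f"s{i}"] = formula
            comps[f"p{i}a"] = formula[0]
            subs[f"s{i}"] = 1
            prods[f"p{i}a"] = 1
        n = toy_network(comps)
        r = ReactionEntity("r", substrates=subs, products=prods)
        n.add_reaction(r)
        p = problem_from(n, r)
        assert solve_nullspace(p) is None and solve_rref(p) is None
        x = solve_lp(p)
        assert x is not None and all(v > 0 for v in x)
        # exact balance re-check independent of the solver
        for a_idx in range(len(p.atoms)):
            assert sum(p.M[i][a_idx] * x[i] for i in range(len(x))) == 0

    def test_lp_accepts_balanced_input(self):
        n = toy_network({"a": "C2H4", "b": "CH2"})
        r = ReactionEntity("r", substrates={"a": 1}, products={"b": 2})
        n.add_reaction(r)
        x = solve_lp(problem_from(n, r))
        assert x is not None
        assert x[1] / x[0] == 2

    def test_solver_agreement_on_randomized_unique_problems(self):
        """nullspace, rref and lp agree up to scaling when the positive
        solution is unique (perturbed balanced reactions)."""
        rng = random.Random(17)
        net, _ = generate_truth_network(FixtureSpec(seed=17, n_reactions=30))
        checked = 0
        for r in net.reactions.values():
            if r.is_boundary or len(r.substrates) + len(r.products) < 3:
                continue
            bad = r.copy()
            side = bad.substrates if bad.substrates else bad.products
            key = sorted(side)[0]
            side[key] = side[key] + rng.randint(1, 3)
            p = problem_from(net, bad)
            ns = solve_nullspace(p)
            if ns is None:
                continue
            rr = solve_rref(p)
            lp = solve_lp(p)
            checked += 1

            def normed(vec):
                return [v / vec[0] for v in vec]

            if rr is not None:
                assert normed(rr) == normed(ns)
            if lp is not None:
                assert normed(lp) == pytest.approx([float(v) for v in normed(ns)])
        assert checked >= 5


class TestBalanceCascade:
    def test_already_balanced_untouched(self):
        n = toy_network({"glc": "C6H12O6", "o2": "O2", "co2": "CO2", "h2o": "H2O"})
        r = ReactionEntity("r", substrates={"glc": 1, "o2": 6},
                           products={"co2": 6, "h2o": 6})
        n.add_reaction(r)
        out = balance(r, n)
        assert out.status == "already_balanced" and out.method == "check"
        assert not out.new_coefficients and not out.added_species

    def test_deleted_water_restored_on_product_side(self):
        n = toy_network({"glc": "C6H12O6", "o2": "O2", "co2": "CO2", "h2o": "H2O"})
        r = ReactionEntity("r", substrates={"glc": 1, "o2": 6}, products={"co2": 6})
        n.add_reaction(r)
        out = balance(r, n)
        assert out.status == "rebalanced_with_additions"
        assert out.added_species == [("H2O", "product")]
        assert out.new_coefficients["__add:H2O:product"] == 6
        # original coefficients preserved (minimal perturbation)
        assert out.new_coefficients["o2"] == 6

    def test_additions_preserve_participants_and_direction(self):
        n = toy_network({"glc": "C6H12O6", "o2": "O2", "co2": "CO2", "h2o": "H2O"})
        r = ReactionEntity("r", substrates={"glc": 1, "o2": 6}, products={"co2": 6},
                           reversible=True)
        n.add_reaction(r)
        fixed = apply_outcome(r, balance(r, n), n)
        assert set(r.substrates) <= set(fixed.substrates)
        assert set(r.products) <= set(fixed.products)
        assert fixed.reversible == r.reversible

    def test_cascade_idempotent_after_apply(self):
        n = toy_network({"h2": "H2", "o2": "O2", "h2o": "H2O"})
        r = ReactionEntity("r", substrates={"h2": 1, "o2": 1}, products={"h2o": 1})
        n.add_reaction(r)
        out = balance(r, n)
        assert out.balanced
        fixed = apply_outcome(r, out, n)
        assert balance(fixed, n).status == "already_balanced"

    def test_glycan_blocks_balance_as_pseudo_atoms(self):
        n = toy_network({"g2": "(Gal)2", "g1": "(Gal)1", "g3": "(Gal)3"})
        r = ReactionEntity("r", substrates={"g2": 1, "g1": 1}, products={"g3": 1})
        n.add_reaction(r)
        assert balance(r, n).status == "already_balanced"

    def test_mixed_glycan_molecular_refused(self):
        n = toy_network({"g2": "(Gal)2", "w": "H2O", "g3": "(Gal)3"})
        r = ReactionEntity("r", substrates={"g2": 1, "w": 1}, products={"g3": 1})
        n.add_reaction(r)
        out = balance(r, n)
        assert out.status == "unbalanceable"
        assert out.reason == "mixed_glycan_molecular"

    def test_boundary_reactions_classified_exchange(self):
        n = toy_network({"glc": "C6H12O6"})
        for kind in ("exchange", "sink", "biomass"):
            r = ReactionEntity(f"r_{kind}", substrates={"glc": 1}, products={},
                               kind=kind)
            n.add_reaction(r)
            assert balance(r, n).reason == "exchange"

    def test_missing_formula_reason(self):
        n = toy_network({"a": "C2H4", "mystery": ""})
        r = ReactionEntity("r", substrates={"a": 1}, products={"mystery": 1})
        n.add_reaction(r)
        assert balance(r, n).reason == "missing_formula"

    def test_coupled_half_reactions_unbalanceable(self):
        # no candidate species carries C or N: unfixable by additions
        n = toy_network({"x": "C2N2", "y": "C2N"})
        r = ReactionEntity("r", substrates={"x": 1}, products={"y": 1})
        n.add_reaction(r)
        out = balance(r, n)
        assert out.status == "unbalanceable" and out.reason == "coupled"

    def test_generic_groups_protected_in_reference(self):
        n = toy_network({"pool": "C2R", "one": "C2"})
        r = ReactionEntity("r", substrates={"pool": 1}, products={"one": 1})
        n.add_reaction(r)
        out = balance(r, n, protect_generic_groups=True)
        assert out.status == "unbalanceable" and out.generic_protected
        # without protection, the cascade may modify the reaction
        out2 = balance(r, n, protect_generic_groups=False)
        assert out2.generic_protected is False

    def test_solution_satisfies_balance_exactly(self, small_fixture):
        """Any coefficients any solver returns satisfy M^T x = 0 (re-checked
        independently)."""
        spec, truth, catalogs, corrupted, truth_map = small_fixture
        for r in corrupted.reactions.values():
            out = balance(r, corrupted)
            if not out.balanced or out.status == "already_balanced":
                continue
            fixed = apply_outcome(r, out, corrupted.copy())
            net2 = corrupted.copy()
            for mid in list(fixed.substrates) + list(fixed.products):
                if mid not in net2.metabolites:
                    from gemcurate.mass_balance import CANDIDATE_SPECIES
                    from gemcurate.model import MetaboliteEntity
                    name = mid.split("@")[0]
                    net2.add_metabolite(
                        MetaboliteEntity(mid, name, "c", dict(CANDIDATE_SPECIES)[name])
                    )
            p = BalanceProblem.from_reaction(fixed, net2)
            assert imbalance_vector(p) == {}


class TestClassificationReport:
    def test_mixed_fixture_matches_ground_truth(self):
        n = toy_network({"glc": "C6H12O6", "co2": "CO2", "o2": "O2", "h2o": "H2O",
                         "x": "C2N2", "y": "C2N", "nof": ""})
        n.add_reaction(ReactionEntity("ok", substrates={"glc": 1, "o2": 6},
                                      products={"co2": 6, "h2o": 6}))
        n.add_reaction(ReactionEntity("ex1", substrates={"glc": 1}, products={},
                                      kind="exchange"))
        n.add_reaction(ReactionEntity("ex2", substrates={"co2": 1}, products={},
                                      kind="exchange"))
        n.add_reaction(ReactionEntity("nofr", substrates={"nof": 1},
                                      products={"co2": 1}))
        n.add_reaction(ReactionEntity("coup", substrates={"x": 1}, products={"y": 1}))
        report = classify_imbalance_report(n)
        reasons = report["unbalanceable_reasons"]
        assert reasons == {"exchange": 2, "missing_formula": 1, "coupled": 1}
        assert report["unbalanceable_fractions"]["exchange"] == pytest.approx(0.5)

    def test_all_balanced_network_empty_breakdown(self):
        n = toy_network({"a": "C2H4", "b": "CH2"})
        n.add_reaction(ReactionEntity("r", substrates={"a": 1}, products={"b": 2}))
        report = classify_imbalance_report(n)
        assert report["unbalanceable_reasons"] == {}
        assert report["statuses"] == {"already_balanced": 1}
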