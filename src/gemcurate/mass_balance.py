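"""Elemental mass balancing of metabolic reactions: a four-method cascade.

A reaction is written as an atom matrix ``M`` — one row per participant,
one column per atom (or pseudo-atom: glycan building block, generic
group), product rows negated — so a coefficient vector ``x > 0`` balances
the reaction exactly when ``Mᵀx = 0``. The cascade is:

1. **check** — the reaction's own coefficients already satisfy ``Mᵀx = 0``;
2. **nullspace** — exact rational nullspace of ``Mᵀ``; accepted when it is
   one-dimensional and admits a strictly positive vector, scaled to the
   smallest positive integers;
3. **rref** — when the nullspace has higher dimension, the reduced row
   echelon form parameterizes all solutions; free variables are enumerated
   over small integers (cap 20) and the strictly positive integer solution
   with the smallest coefficient sum is kept;
4. **lp** — a linear program minimizing the total absolute per-atom
   imbalance with coefficients bounded away from zero, for balances that
   only close at fractional stoichiometry.

If every method fails, candidate species (H⁺, H₂O, K⁺, Na⁺, Ca²⁺, Fe, R —
in that fixed order) are inserted on the substrate side, product side, or
both, at most two distinct species, re-running the cascade after each
insertion. Boundary reactions, mixed glycan/molecular reactions and
reactions with missing formulas are excluded up front; whatever remains
unbalanceable is classified as coupled (independent half-reactions written
as one). Reactions carrying generic R/X groups in a curated reference
model are reported but never modified — the composition of those groups
is reaction-specific and rewriting their stoichiometry is unsafe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import reduce
from itertools import combinations, product as iproduct
from math import gcd
from typing import Iterable, Optional

import numpy as np
import sympy
from scipy.optimize import linprog

from .formula import ElementComposition, parse_formula
from .model import MetabolicNetwork, ReactionEntity

__all__ = [
    "BalanceProblem",
    "BalanceOutcome",
    "CANDIDATE_SPECIES",
    "imbalance_vector",
    "solve_nullspace",
    "solve_rref",
    "solve_lp",
    "balance",
    "apply_outcome",
    "classify_imbalance_report",
]

#: addable species, tried in this order (composition, display name)
CANDIDATE_SPECIES: tuple[tuple[str, ElementComposition], ...] = (
    ("H+", parse_formula("H+")),
    ("H2O", parse_formula("H2O")),
    ("K+", parse_formula("K+")),
    ("Na+", parse_formula("Na+")),
    ("Ca2+", parse_formula("Ca2+")),
    ("Fe", parse_formula("Fe")),
    ("R", parse_formula("R")),
)

RREF_COEFF_CAP = 20
LP_EPSILON = 1e-3
LP_TOLERANCE = 1e-6
MAX_ADDED_SPECIES = 2


class MissingFormulaError(ValueError):
    pass


@dataclass(frozen=True)
class Participant:
    metabolite_id: str
    side: str  # substrate | product
    coefficient: Fraction
    composition: ElementComposition


@dataclass
class BalanceProblem:
    """Participants of one reaction plus the signed atom matrix ``M``."""

    participants: list[Participant]
    atoms: list[str]
    M: list[list[Fraction]]  # rows = participants, cols = atoms; products negated

    @classmethod
    def from_participants(cls, participants: Iterable[Participant]) -> "BalanceProblem":
        participants = list(participants)
        atoms = sorted({a for p in participants for a in p.composition.counts})
        M = []
        for p in participants:
            sign = 1 if p.side == "substrate" else -1
            M.append([sign * p.composition.counts.get(a, Fraction(0)) for a in atoms])
        return cls(participants, atoms, M)

    @classmethod
    def from_reaction(
        cls, r: ReactionEntity, network: MetabolicNetwork
    ) -> "BalanceProblem":
        parts = []
        for mid, side, coeff in r.participants():
            met = network.metabolites[mid]
            if met.composition.is_missing:
                raise MissingFormulaError(mid)
            parts.append(Participant(mid, side, coeff, met.composition))
        return cls.from_participants(parts)

    def coefficients(self) -> list[Fraction]:
        return [p.coefficient for p in self.participants]


@dataclass
class BalanceOutcome:
    """Result of the cascade for one reaction."""

    reaction_id: str
    status: str  # already_balanced | rebalanced | rebalanced_with_additions | unbalanceable
    method: str  # check | nullspace | rref | lp | none
    new_coefficients: dict[str, Fraction] = field(default_factory=dict)
    added_species: list[tuple[str, str]] = field(default_factory=list)  # (name, side)
    reason: str = "none"  # exchange | mixed_glycan_molecular | missing_formula | coupled | none
    generic_protected: bool = False

    @property
    def balanced(self) -> bool:
        return self.status != "unbalanceable"

    def to_dict(self) -> dict:
        return {
            "reaction_id": self.reaction_id,
            "status": self.status,
            "method": self.method,
            "new_coefficients": {k: str(v) for k, v in self.new_coefficients.items()},
            "added_species": [list(t) for t in self.added_species],
            "reason": self.reason,
            "generic_protected": self.generic_protected,
        }


# ---------------------------------------------------------------------------
# the four methods
# ---------------------------------------------------------------------------

def imbalance_vector(p: BalanceProblem) -> dict[str, Fraction]:
    """Signed per-atom net (substrates − products) under the given coefficients."""
    x = p.coefficients()
    net = {}
    for a_idx, atom in enumerate(p.atoms):
        total = sum(p.M[i][a_idx] * x[i] for i in range(len(x)))
        if total != 0:
            net[atom] = total
    return net


def _check(p: BalanceProblem) -> bool:
    return not imbalance_vector(p)


def _integerize(vec: list[Fraction]) -> list[Fraction]:
    """Scale a rational vector to the smallest positive integers."""
    denom_lcm = reduce(lambda acc, f: acc * f.denominator // gcd(acc, f.denominator), vec, 1)
    ints = [f * denom_lcm for f in vec]
    g = reduce(gcd, (abs(i.numerator) for i in ints if i != 0), 0)
    if g > 1:
        ints = [i / g for i in ints]
    return ints


def solve_nullspace(p: BalanceProblem) -> Optional[list[Fraction]]:
    """Unique strictly positive nullspace direction of ``Mᵀ`` (else None).

    A multi-dimensional nullspace defers to :func:`solve_rref`.
    """
    if not p.participants:
        return None
    Mt = sympy.Matrix([[row[a] for row in p.M] for a in range(len(p.atoms))])
    if len(p.atoms) == 0:
        return None
    basis = Mt.nullspace()
    if len(basis) != 1:
        return None
    vec = [Fraction(v.p, v.q) for v in basis[0]]
    if all(v > 0 for v in vec):
        return _integerize(vec)
    if all(v < 0 for v in vec):
        return _integerize([-v for v in vec])
    return None


def solve_rref(p: BalanceProblem, cap: int = RREF_COEFF_CAP) -> Optional[list[Fraction]]:
    """Minimal-sum strictly positive integer solution from the RREF parameterization.

    Free variables of the reduced system are enumerated over 1..cap (up to
    three of them); ties on the coefficient sum break lexicographically.
    """
    n = len(p.participants)
    if n == 0 or len(p.atoms) == 0:
        return None
    Mt = sympy.Matrix([[row[a] for row in p.M] for a in range(len(p.atoms))])
    rref, pivots = Mt.rref()
    free = [j for j in range(n) if j not in pivots]
    if not free or len(free) > 3:
        return None
    best: Optional[tuple] = None
    for values in iproduct(range(1, cap + 1), repeat=len(free)):
        x: list[Optional[Fraction]] = [None] * n
        for j, v in zip(free, values):
            x[j] = Fraction(v)
        ok = True
        for r_idx, j in enumerate(pivots):
            # pivot var = -sum(rref[r, free] * x[free])
            val = -sum(
                (Fraction(rref[r_idx, f].p, rref[r_idx, f].q) * x[f] for f in free),
                start=Fraction(0),
            )
            if val <= 0 or val.denominator != 1 or val > cap:
                ok = False
                break
            x[j] = val
        if not ok:
            continue
        key = (sum(x), tuple(x))
        if best is None or key < best[0]:
            best = (key, list(x))
    if best is None:
        return None
    return _integerize(best[1])


def solve_lp(
    p: BalanceProblem, epsilon: float = LP_EPSILON, tolerance: float = LP_TOLERANCE
) -> Optional[list[Fraction]]:
    """LP fallback: minimize Σ_atoms |net(atom)| subject to x ≥ ε.

    Absolute values are linearized with one auxiliary variable per atom.
    Accepted only when the optimum is ≤ ``tolerance``; the float solution
    is then rationalized and re-verified exactly.
    """
    n, k = len(p.participants), len(p.atoms)
    if n == 0 or k == 0:
        return None
    Mt = np.array(
        [[float(p.M[i][a]) for i in range(n)] for a in range(k)]
    )  # k x n
    # variables: x (n), t (k); minimize sum(t)
    c = np.concatenate([np.zeros(n), np.ones(k)])
    # Mt x - t <= 0 ; -Mt x - t <= 0
    A_ub = np.block([[Mt, -np.eye(k)], [-Mt, -np.eye(k)]])
    b_ub = np.zeros(2 * k)
    bounds = [(epsilon, None)] * n + [(0, None)] * k
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success or res.fun > tolerance:
        return None
    x = [Fraction(v).limit_denominator(1000) for v in res.x[:n]]
    # exact re-check after rationalization
    for a_idx in range(k):
        if sum(p.M[i][a_idx] * x[i] for i in range(n)) != 0:
            return None
    return x


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def _run_cascade(p: BalanceProblem) -> Optional[tuple[str, list[Fraction]]]:
    if _check(p):
        return ("check", p.coefficients())
    for method, solver in (("nullspace", solve_nullspace), ("rref", solve_rref), ("lp", solve_lp)):
        x = solver(p)
        if x is not None:
            return (method, x)
    return None


def _glycan_mix(parts: list[Participant]) -> bool:
    has_glycan = any(pt.composition.has_glycan_blocks() for pt in parts)
    has_plain = any(
        not pt.composition.has_glycan_blocks() and not pt.composition.is_missing
        for pt in parts
    )
    return has_glycan and has_plain


def balance(
    r: ReactionEntity,
    network: MetabolicNetwork,
    allow_additions: bool = True,
    protect_generic_groups: bool = True,
) -> BalanceOutcome:
    """Run the full cascade (with candidate-species insertion) on one reaction."""
    if r.is_boundary:
        return BalanceOutcome(r.id, "unbalanceable", "none", reason="exchange")
    try:
        problem = BalanceProblem.from_reaction(r, network)
    except MissingFormulaError:
        return BalanceOutcome(r.id, "unbalanceable", "none", reason="missing_formula")

    if _check(problem):
        return BalanceOutcome(r.id, "already_balanced", "check")

    if _glycan_mix(problem.participants):
        return BalanceOutcome(
            r.id, "unbalanceable", "none", reason="mixed_glycan_molecular"
        )

    generic = any(pt.composition.has_generic_groups() for pt in problem.participants)
    if generic and protect_generic_groups:
        # R/X composition is reaction-specific; never rewrite such reactions
        return BalanceOutcome(
            r.id, "unbalanceable", "none", reason="coupled", generic_protected=True
        )

    result = _run_cascade(problem)
    if result is not None:
        method, x = result
        return BalanceOutcome(
            r.id,
            "rebalanced",
            method,
            new_coefficients={
                pt.metabolite_id: c for pt, c in zip(problem.participants, x)
            },
        )

    if allow_additions:
        outcome = _try_additions(r, problem)
        if outcome is not None:
            return outcome

    return BalanceOutcome(r.id, "unbalanceable", "none", reason="coupled")


def _candidate_helps(comp: ElementComposition, imbalance: dict[str, Fraction]) -> bool:
    # a species can only help if it supplies at least one imbalanced atom
    return any(a in imbalance for a in comp.counts)


def _solve_fixed_originals(
    problem: BalanceProblem, additions: list[tuple[str, ElementComposition, str]]
) -> Optional[list[Fraction]]:
    """Coefficients for added species only, originals untouched (exact solve)."""
    labels: list[tuple[str, ElementComposition, int]] = []
    for name, comp, placement in additions:
        targets = ("substrate", "product") if placement == "both" else (placement,)
        for side in targets:
            labels.append((name, comp, 1 if side == "substrate" else -1))
    imb = imbalance_vector(problem)
    atoms = sorted(set(imb) | {a for _, comp, _ in labels for a in comp.counts})
    A = sympy.Matrix(
        [
            [sign * comp.counts.get(a, Fraction(0)) for _, comp, sign in labels]
            for a in atoms
        ]
    )
    b = sympy.Matrix([[-imb.get(a, Fraction(0))] for a in atoms])
    sol = sympy.linsolve((A, b))
    if not sol or len(sol.free_symbols) > 0:
        return None
    vec = list(sol.args[0])
    coeffs = [Fraction(v.p, v.q) for v in vec]
    if any(c <= 0 for c in coeffs):
        return None
    return coeffs


def _try_additions(
    r: ReactionEntity, problem: BalanceProblem
) -> Optional[BalanceOutcome]:
    imbalance = imbalance_vector(problem)
    sides = ("substrate", "product", "both")

    def attempt_fixed(
        additions: list[tuple[str, ElementComposition, str]]
    ) -> Optional[BalanceOutcome]:
        coeffs = _solve_fixed_originals(problem, additions)
        if coeffs is None:
            return None
        labels: list[tuple[str, str]] = []
        new_coefficients = {
            pt.metabolite_id: pt.coefficient for pt in problem.participants
        }
        i = 0
        for name, comp, placement in additions:
            targets = ("substrate", "product") if placement == "both" else (placement,)
            for side in targets:
                new_coefficients[f"__add:{name}:{side}"] = coeffs[i]
                labels.append((name, side))
                i += 1
        return BalanceOutcome(
            r.id,
            "rebalanced_with_additions",
            "nullspace",
            new_coefficients=new_coefficients,
            added_species=labels,
        )

    def attempt(additions: list[tuple[str, ElementComposition, str]]) -> Optional[BalanceOutcome]:
        parts = list(problem.participants)
        labels: list[tuple[str, str]] = []
        for name, comp, placement in additions:
            targets = ("substrate", "product") if placement == "both" else (placement,)
            for side in targets:
                parts.append(Participant(f"__add:{name}:{side}", side, Fraction(1), comp))
                labels.append((name, side))
        aug = BalanceProblem.from_participants(parts)
        result = _run_cascade(aug)
        if result is None:
            return None
        method, x = result
        coeffs = {pt.metabolite_id: c for pt, c in zip(aug.participants, x)}
        return BalanceOutcome(
            r.id,
            "rebalanced_with_additions",
            method,
            new_coefficients=coeffs,
            added_species=labels,
        )

    singles = [
        (name, comp)
        for name, comp in CANDIDATE_SPECIES
        if _candidate_helps(comp, imbalance)
    ]
    # pass 1: minimal perturbation — original coefficients held fixed
    for trial in (attempt_fixed, attempt):
        for name, comp in singles:
            for placement in sides:
                out = trial([(name, comp, placement)])
                if out is not None:
                    return out
        for (n1, c1), (n2, c2) in combinations(CANDIDATE_SPECIES, MAX_ADDED_SPECIES):
            if not (_candidate_helps(c1, imbalance) or _candidate_helps(c2, imbalance)):
                continue
            for pl1 in sides:
                for pl2 in sides:
                    out = trial([(n1, c1, pl1), (n2, c2, pl2)])
                    if out is not None:
                        return out
    return None


def apply_outcome(r: ReactionEntity, outcome: BalanceOutcome,
                  network: MetabolicNetwork) -> ReactionEntity:
    """Return a copy of ``r`` with the outcome's coefficients and additions applied.

    Added species are materialized as network metabolites (reused when a
    metabolite with the same name already exists in the reaction's
    compartment). Directionality and existing participants are preserved.
    """
    if not outcome.balanced or outcome.status == "already_balanced":
        return r.copy()
    new = r.copy()
    comp_id = None
    for mid in list(r.substrates) + list(r.products):
        comp_id = network.metabolites[mid].compartment_id
        break
    for key, coeff in outcome.new_coefficients.items():
        if key.startswith("__add:"):
            _, name, side = key.split(":", 2)
            comp = dict(CANDIDATE_SPECIES)[name]
            mid = _ensure_species(network, name, comp, comp_id)
            target = new.substrates if side == "substrate" else new.products
            target[mid] = target.get(mid, Fraction(0)) + coeff
        else:
            if key in new.substrates:
                new.substrates[key] = coeff
            elif key in new.products:
                new.products[key] = coeff
    return new


def _ensure_species(
    network: MetabolicNetwork, name: str, comp: ElementComposition, comp_id: str
) -> str:
    for met in network.metabolites.values():
        if met.compartment_id == comp_id and (
            met.name == name or met.composition == comp
        ):
            return met.id
    from .model import MetaboliteEntity

    mid = f"{name}@{comp_id}"
    if mid not in network.metabolites:
        network.add_metabolite(
            MetaboliteEntity(mid, name, comp_id, comp)
        )
    return mid


def classify_imbalance_report(
    network: MetabolicNetwork, allow_additions: bool = True
) -> dict:
    """Balance every reaction; tally statuses and unbalanceable reasons."""
    outcomes = {
        rid: balance(r, network, allow_additions=allow_additions)
        for rid, r in network.reactions.items()
    }
    statuses: dict[str, int] = {}
    reasons: dict[str, int] = {}
    for o in outcomes.values():
        statuses[o.status] = statuses.get(o.status, 0) + 1
        if o.status == "unbalanceable":
            reasons[o.reason] = reasons.get(o.reason, 0) + 1
    n_unbal = sum(reasons.values())
    return {
        "n_reactions": len(outcomes),
        "statuses": statuses,
        "unbalanceable_reasons": reasons,
        "unbalanceable_fractions": {
            k: v / n_unbal for k, v in reasons.items()
        } if n_unbal else {},
        "outcomes": {rid: o.to_dict() for rid, o in outcomes.items()},
    }
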