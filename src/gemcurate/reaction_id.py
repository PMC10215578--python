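"""Annotation-free reaction identification by substrate/product fingerprints.

A reaction's fingerprint is the pair of key sets (Sᵢ, Pᵢ) of its substrate
and product participants. Each participant contributes its first available
identifier in the priority order KEGG > ChEBI > HMDB > LipidMaps >
normalized name > neutralized formula; protons are excluded because their
presence merely reflects a source's protonation convention.

Two fingerprints are compared with four Jaccard indices (substrate vs
substrate, substrate vs product, product vs substrate, product vs product)
combined into a total score in [0, 2]; 2 is a perfect match. When either
reaction is reversible, the swapped orientation is also scored and the
better total kept. Identification against a reference catalog demands a
perfect match by default (the constraint can be relaxed to an argmax
above a floor); the matched reference donates EC numbers and
cross-references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .formula import format_formula
from .metabolite_id import neutralize_formula, normalize_name
from .model import MetaboliteEntity, MetabolicNetwork, ReactionEntity

__all__ = [
    "KEY_PRIORITY",
    "ReactionFingerprint",
    "PairScore",
    "ReferenceReaction",
    "participant_key",
    "fingerprint",
    "jaccard",
    "pair_score",
    "identify_reaction",
]

#: xref sources probed, in order, for a participant key.
KEY_PRIORITY = ("KEGG", "ChEBI", "HMDB", "LipidMaps")

PERFECT_TOTAL = 2.0
DEFAULT_RELAXED_FLOOR = 1.5


@dataclass(frozen=True)
class ReactionFingerprint:
    substrate_keys: frozenset[str]
    product_keys: frozenset[str]
    reversible: bool = False


@dataclass(frozen=True)
class PairScore:
    """The four pairwise Jaccard indices and their orientation totals."""

    ji_ss: float
    ji_sp: float
    ji_ps: float
    ji_pp: float

    @property
    def total_forward(self) -> float:
        return self.ji_ss + self.ji_pp

    @property
    def total_reverse(self) -> float:
        return self.ji_sp + self.ji_ps

    def total(self, either_reversible: bool) -> float:
        if either_reversible:
            return max(self.total_forward, self.total_reverse)
        return self.total_forward


@dataclass(frozen=True)
class ReferenceReaction:
    """Catalog entry: precomputed fingerprint plus donated annotation."""

    reaction_id: str
    fingerprint: ReactionFingerprint
    ec_numbers: frozenset[str] = frozenset()
    xrefs: Mapping[str, str] = field(default_factory=dict)


def _is_proton(m: MetaboliteEntity) -> bool:
    if m.composition.is_proton():
        return True
    return normalize_name(m.name) in {"h+", "proton", "h(+)"}


def participant_key(m: MetaboliteEntity) -> str:
    """First available key per the priority order; sentinel when nothing usable."""
    for source in KEY_PRIORITY:
        value = m.xrefs.get(source)
        if value:
            return f"{source}:{value}"
    name = normalize_name(m.name)
    if name:
        return f"name:{name}"
    if not m.composition.is_missing:
        return "formula:" + format_formula(neutralize_formula(m.composition))
    return f"__met:{m.id}"  # unique sentinel — never matches anything else


def fingerprint(r: ReactionEntity, network: MetabolicNetwork) -> ReactionFingerprint:
    """Fingerprint of ``r`` with protons dropped from both sides."""
    subs, prods = set(), set()
    for mid, side, _coeff in r.participants():
        met = network.metabolites[mid]
        if _is_proton(met):
            continue
        (subs if side == "substrate" else prods).add(participant_key(met))
    return ReactionFingerprint(frozenset(subs), frozenset(prods), r.reversible)


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|a∩b| / |a∪b|; two empty sets are identical (1), one empty is 0."""
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union


def pair_score(fp_a: ReactionFingerprint, fp_b: ReactionFingerprint) -> PairScore:
    return PairScore(
        ji_ss=jaccard(fp_a.substrate_keys, fp_b.substrate_keys),
        ji_sp=jaccard(fp_a.substrate_keys, fp_b.product_keys),
        ji_ps=jaccard(fp_a.product_keys, fp_b.substrate_keys),
        ji_pp=jaccard(fp_a.product_keys, fp_b.product_keys),
    )


def total_score(fp_a: ReactionFingerprint, fp_b: ReactionFingerprint) -> float:
    return pair_score(fp_a, fp_b).total(fp_a.reversible or fp_b.reversible)


@dataclass(frozen=True)
class ReactionMatch:
    query_id: str
    reference: ReferenceReaction
    score: float


def identify_reaction(
    r: ReactionEntity,
    network: MetabolicNetwork,
    catalog: Iterable[ReferenceReaction],
    require_perfect: bool = True,
    relaxed_floor: float = DEFAULT_RELAXED_FLOOR,
) -> Optional[ReactionMatch]:
    """Match ``r`` against a reference catalog by fingerprint score.

    With ``require_perfect`` only a total of exactly 2 counts; otherwise
    the argmax above ``relaxed_floor`` is returned. Ties are broken toward
    the lexicographically smallest reference id (with a warning when
    several references score a perfect 2 — duplicated catalog rows).
    """
    fp = fingerprint(r, network)
    best: Optional[ReferenceReaction] = None
    best_score = -1.0
    perfect_hits = 0
    for ref in catalog:
        score = total_score(fp, ref.fingerprint)
        if score == PERFECT_TOTAL:
            perfect_hits += 1
        if score > best_score or (
            score == best_score
            and best is not None
            and ref.reaction_id < best.reaction_id
        ):
            best, best_score = ref, score
    if perfect_hits > 1:
        warnings.warn(
            f"reaction {r.id}: {perfect_hits} perfect catalog matches; "
            f"keeping {best.reaction_id if best else '?'}"
        )
    if best is None:
        return None
    if require_perfect:
        if best_score == PERFECT_TOTAL:
            return ReactionMatch(r.id, best, best_score)
        return None
    if best_score >= relaxed_floor:
        return ReactionMatch(r.id, best, best_score)
    return None


def annotate_from_match(r: ReactionEntity, match: ReactionMatch) -> None:
    """Donate the matched reference's EC numbers and xrefs to ``r`` in place."""
    r.ec_numbers |= set(match.reference.ec_numbers)
    for source, value in match.reference.xrefs.items():
        r.xrefs.setdefault(source, value)
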