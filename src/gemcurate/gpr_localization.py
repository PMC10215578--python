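"""S-GPR construction, gene-record merging, localization, isoenzyme expansion.

Gene-association records are keyed by EC number and come from several
source catalogs. Records sharing a ``complex_group`` are subunits of one
complex (an AND node whose leaves carry protomer counts); distinct groups
and singleton genes are isoenzymes (children of a top-level OR). Records
from different sources frequently disagree on gene spelling; a bounded
Levenshtein merge (distance ≤ 1 on normalized symbols, guarded by Ensembl
identity) unifies them before the tree is built.

Subcellular locations are per-gene GO cellular-component sets. A
complex's location is the intersection of its subunits' locations; a
reaction's locations are the union over its isoenzyme branches. Isoenzyme
expansion then adds a compartment-local copy of each reaction to every
inferred compartment where the reaction does not already exist (existence
is tested with the Jaccard fingerprint identifier restricted to that
compartment), re-pointing participants to compartment-local metabolite
instances and restricting the copy's GPR to the genes that support that
compartment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .model import (
    GprNode,
    MetaboliteEntity,
    MetabolicNetwork,
    ReactionEntity,
    and_node,
    gene_leaf,
    or_node,
)
from .reaction_id import PERFECT_TOTAL, fingerprint, total_score

__all__ = [
    "GeneAssociationRecord",
    "LocationRecord",
    "ec_matches",
    "build_sgpr",
    "tolerant_merge",
    "sgpr_to_gpr",
    "reaction_locations",
    "expand_isoenzymes",
    "ExpansionReport",
]

log = logging.getLogger(__name__)

_EC_RE = re.compile(r"(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass(frozen=True)
class GeneAssociationRecord:
    ec: str
    gene_id: str
    complex_group: Optional[str] = None
    protomer_count: Optional[int] = None  # None = unknown (treated as 1)
    source: str = ""

    def __post_init__(self) -> None:
        if not _EC_RE.match(self.ec):
            raise ValueError(f"bad EC number {self.ec!r}")
        if self.protomer_count is not None and self.protomer_count < 1:
            raise ValueError("protomer_count must be >= 1 when known")


@dataclass(frozen=True)
class LocationRecord:
    gene_id: str
    compartments: frozenset[str]  # GO cellular-component accessions

    def __post_init__(self) -> None:
        if not self.compartments:
            raise ValueError(f"location record for {self.gene_id} has no compartments")


def ec_matches(pattern: str, ec: str) -> bool:
    """EC equality with trailing-dash wildcards (``1.1.1.-`` matches ``1.1.1.5``)."""
    p_parts = pattern.split(".")
    e_parts = ec.split(".")
    if len(p_parts) != 4 or len(e_parts) != 4:
        return False
    return all(p == "-" or p == e for p, e in zip(p_parts, e_parts))


# ---------------------------------------------------------------------------
# S-GPR construction
# ---------------------------------------------------------------------------

def build_sgpr(ec: str, records: Iterable[GeneAssociationRecord]) -> Optional[GprNode]:
    """AST for one EC: complexes as AND nodes, isoenzymes under an OR root.

    Conflicting protomer counts for the same (group, gene) keep the
    maximum and log the conflict. Returns None when no record matches.
    """
    relevant = [r for r in records if ec_matches(r.ec, ec) or ec_matches(ec, r.ec)]
    if not relevant:
        return None

    # (group, gene) -> protomer count; singletons get a per-gene group
    groups: dict[str, dict[str, int]] = {}
    for rec in relevant:
        group = rec.complex_group if rec.complex_group else f"__single:{rec.gene_id}"
        genes = groups.setdefault(group, {})
        count = rec.protomer_count if rec.protomer_count is not None else 1
        if rec.gene_id in genes and genes[rec.gene_id] != count:
            kept = max(genes[rec.gene_id], count)
            log.warning(
                "EC %s: conflicting protomer counts for %s in group %s "
                "(%d vs %d); keeping %d",
                ec, rec.gene_id, group, genes[rec.gene_id], count, kept,
            )
            genes[rec.gene_id] = kept
        else:
            genes[rec.gene_id] = max(genes.get(rec.gene_id, 1), count)

    branches = []
    for group in sorted(groups):
        genes = groups[group]
        leaves = [gene_leaf(g, genes[g]) for g in sorted(genes)]
        branches.append(leaves[0] if len(leaves) == 1 else and_node(*leaves))
    return branches[0] if len(branches) == 1 else or_node(*branches)


def sgpr_to_gpr(node: GprNode) -> GprNode:
    """Classical GPR: strip protomer counts from every leaf. Idempotent."""
    return node.strip_protomers()


# ---------------------------------------------------------------------------
# tolerant cross-source merging
# ---------------------------------------------------------------------------

def _normalize_symbol(s: str) -> str:
    return re.sub(r"\s+", "", s).casefold()


def _within_distance_1(a: str, b: str) -> bool:
    """Levenshtein distance ≤ 1 (equality, substitution, or indel)."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:  # one substitution allowed
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # a is shorter by one: one deletion from b
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def tolerant_merge(
    records: Iterable[GeneAssociationRecord],
    ensembl_map: Optional[Mapping[str, str]] = None,
) -> list[GeneAssociationRecord]:
    """Unify gene spellings across sources before S-GPR construction.

    A gene identifier merges into another when their normalized forms are
    within Levenshtein distance 1 and the target spelling has strictly
    more record support (a corrupted spelling is rarer than the canonical
    one) — unless both carry Ensembl ids and the ids differ (``HK1`` vs
    ``HK2`` stay distinct). An identifier within distance 1 of two
    different better-supported targets is ambiguous and left unmerged
    with a warning; equal support is also left alone.
    """
    records = list(records)
    ensembl_map = ensembl_map or {}
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.gene_id] = counts.get(rec.gene_id, 0) + 1
    # canonical candidates ordered by support then id
    canonical = sorted(counts, key=lambda g: (-counts[g], g))

    mapping: dict[str, str] = {}
    for gid in counts:
        targets = []
        for cand in canonical:
            if cand == gid or counts[cand] <= counts[gid]:
                continue  # only strictly better-supported spellings
            if not _within_distance_1(_normalize_symbol(gid), _normalize_symbol(cand)):
                continue
            e_g, e_c = ensembl_map.get(gid), ensembl_map.get(cand)
            if e_g and e_c and e_g != e_c:
                continue  # distinct Ensembl ids: never merge
            targets.append(cand)
        if len(targets) > 1:
            log.warning(
                "gene id %s is within distance 1 of several targets %s; not merged",
                gid, targets,
            )
        elif len(targets) == 1:
            mapping[gid] = targets[0]

    out = []
    for rec in records:
        target = mapping.get(rec.gene_id)
        out.append(replace(rec, gene_id=target) if target else rec)
    return out


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

def reaction_locations(
    ec: str,
    records: Iterable[GeneAssociationRecord],
    locations: Iterable[LocationRecord],
) -> set[str]:
    """GO compartments where the EC's catalytic units are present.

    Complex branch → intersection of subunit locations; isoenzyme branches
    contribute independently; result is the union over branches.
    """
    node = build_sgpr(ec, records)
    if node is None:
        return set()
    loc_by_gene: dict[str, frozenset[str]] = {}
    for rec in locations:
        loc_by_gene[rec.gene_id] = (
            loc_by_gene.get(rec.gene_id, frozenset()) | rec.compartments
        )
    return _node_locations(node, loc_by_gene, ec)


def _node_locations(
    node: GprNode, loc_by_gene: Mapping[str, frozenset[str]], ec: str
) -> set[str]:
    if node.node_kind == "gene":
        locs = loc_by_gene.get(node.gene_id)
        if locs is None:
            log.warning("EC %s: no location record for gene %s; branch skipped",
                        ec, node.gene_id)
            return set()
        return set(locs)
    child_sets = [_node_locations(c, loc_by_gene, ec) for c in node.children]
    if node.node_kind == "or":
        out: set[str] = set()
        for s in child_sets:
            out |= s
        return out
    # complex: common location of all subunits; a gene with no record
    # invalidates the branch (its location is unknown)
    if any(not s for s in child_sets):
        return set()
    common = set.intersection(*child_sets)
    if not common:
        log.warning("EC %s: complex subunits share no location", ec)
    return common


def _branches(node: GprNode) -> list[GprNode]:
    return list(node.children) if node.node_kind == "or" else [node]


# ---------------------------------------------------------------------------
# isoenzyme expansion
# ---------------------------------------------------------------------------

@dataclass
class ExpansionReport:
    reactions_added: int = 0
    metabolites_added: int = 0
    skipped_no_ec: int = 0
    details: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "reactions_added": self.reactions_added,
            "metabolites_added": self.metabolites_added,
            "skipped_no_ec": self.skipped_no_ec,
            "details": list(self.details),
        }


def expand_isoenzymes(
    network: MetabolicNetwork,
    assoc_records: Iterable[GeneAssociationRecord],
    loc_records: Iterable[LocationRecord],
) -> tuple[MetabolicNetwork, ExpansionReport]:
    """Add compartment-local copies of reactions wherever isoenzymes live.

    Never removes or alters existing entities: the output restricted to
    the input's ids equals the input. Compartments are resolved by GO
    term against the network's declared compartments; GO terms with no
    declared compartment are skipped with a warning.
    """
    assoc_records = list(assoc_records)
    loc_records = list(loc_records)
    out = network.copy()
    report = ExpansionReport()
    go_to_comp = {
        c.go_term: c.id for c in network.compartments.values() if c.go_term
    }
    loc_by_gene: dict[str, frozenset[str]] = {}
    for rec in loc_records:
        loc_by_gene[rec.gene_id] = (
            loc_by_gene.get(rec.gene_id, frozenset()) | rec.compartments
        )

    # fingerprints of existing reactions, bucketed by home compartment
    def home_compartments(r: ReactionEntity) -> set[str]:
        return {
            network.metabolites[mid].compartment_id for mid, _, _ in r.participants()
        }

    for rid in sorted(network.reactions):
        rxn = network.reactions[rid]
        if not rxn.ec_numbers:
            report.skipped_no_ec += 1
            continue
        go_locs: set[str] = set()
        for ec in sorted(rxn.ec_numbers):
            go_locs |= reaction_locations(ec, assoc_records, loc_records)
        target_comps = set()
        for go in go_locs:
            comp = go_to_comp.get(go)
            if comp is None:
                log.warning("reaction %s: GO %s matches no declared compartment",
                            rid, go)
                continue
            target_comps.add(comp)
        current = home_compartments(rxn)
        for comp in sorted(target_comps - current):
            copy_id = f"{rid}__{comp}"
            if copy_id in out.reactions:
                continue
            new_subs, new_prods, created = _repoint(out, rxn, comp)
            candidate = ReactionEntity(
                copy_id,
                name=rxn.name,
                substrates=new_subs,
                products=new_prods,
                reversible=rxn.reversible,
                ec_numbers=set(rxn.ec_numbers),
                kind=rxn.kind,
            )
            # existence check: perfect fingerprint match among reactions
            # living entirely in the target compartment
            fp = fingerprint(candidate, out)
            exists = False
            for other in out.reactions.values():
                if home_compartments_of(out, other) != {comp}:
                    continue
                if total_score(fp, fingerprint(other, out)) == PERFECT_TOTAL:
                    exists = True
                    break
            if exists:
                # roll back provisional metabolite instances we created
                for mid in created:
                    del out.metabolites[mid]
                continue
            candidate.gpr = _compartment_gpr(
                rxn, assoc_records, loc_by_gene, go_locs, comp, go_to_comp
            )
            out.add_reaction(candidate)
            report.reactions_added += 1
            report.metabolites_added += len(created)
            report.details.append(
                {"reaction": rid, "compartment": comp, "copy": copy_id,
                 "new_metabolites": sorted(created)}
            )
    return out, report


def home_compartments_of(network: MetabolicNetwork, r: ReactionEntity) -> set[str]:
    return {network.metabolites[mid].compartment_id for mid, _, _ in r.participants()}


def _repoint(
    out: MetabolicNetwork, rxn: ReactionEntity, comp: str
) -> tuple[dict, dict, list[str]]:
    """Participant maps re-pointed to compartment-local metabolite instances."""
    created: list[str] = []

    def local_id(mid: str) -> str:
        met = out.metabolites[mid]
        if met.compartment_id == comp:
            return mid
        # reuse an existing instance of the same compound in the target
        for other in out.metabolites.values():
            if other.compartment_id != comp:
                continue
            if other.name == met.name or (
                met.xrefs and any(
                    other.xrefs.get(s) == v for s, v in met.xrefs.items()
                )
            ):
                return other.id
        new_id = f"{mid}@{comp}"
        if new_id not in out.metabolites:
            out.add_metabolite(
                MetaboliteEntity(
                    new_id, met.name, comp, met.composition,
                    list(met.synonyms), dict(met.xrefs),
                )
            )
            created.append(new_id)
        return new_id

    subs = {local_id(m): c for m, c in rxn.substrates.items()}
    prods = {local_id(m): c for m, c in rxn.products.items()}
    return subs, prods, created


def _compartment_gpr(
    rxn: ReactionEntity,
    assoc_records: list[GeneAssociationRecord],
    loc_by_gene: Mapping[str, frozenset[str]],
    go_locs: set[str],
    comp: str,
    go_to_comp: Mapping[str, str],
) -> Optional[GprNode]:
    """GPR of a compartment copy: only the branches supporting that compartment."""
    comp_gos = {go for go, c in go_to_comp.items() if c == comp}
    branches_kept: list[GprNode] = []
    for ec in sorted(rxn.ec_numbers):
        node = build_sgpr(ec, assoc_records)
        if node is None:
            continue
        for branch in _branches(node):
            locs = _node_locations(branch, loc_by_gene, ec)
            if locs & comp_gos:
                branches_kept.append(branch)
    if not branches_kept:
        return None
    # dedupe identical branches
    unique: dict[str, GprNode] = {}
    for b in branches_kept:
        unique.setdefault(b.to_string(), b)
    nodes = list(unique.values())
    return nodes[0] if len(nodes) == 1 else or_node(*nodes)
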