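"""Network construction from pathway files, merging, and the consistency gate.

``build_database`` assembles a metabolic network from KGML pathway maps
(reactions with substrate/product compound references, reversibility and
EC links), deduplicating reactions shared between pathways by their
Jaccard fingerprint, enriching metabolites from the reference catalog,
building S-GPRs from EC-keyed gene associations, generating
per-compartment reaction copies, and mass-balancing everything.

``merge`` combines two networks after ``find_overlaps`` pairs equivalent
entities (metabolites by shared xref or name similarity within the same
compartment, reactions by perfect fingerprint score, genes by Ensembl
id). The merged size per entity class is |a| + |b| − |overlap|.

Stoichiometric consistency is the existence of a strictly positive
molecular-mass vector ``m`` with ``Nᵀm = 0`` over the internal reactions
(boundary reactions exchange mass with the environment by design and are
excluded). A merged network can lose consistency even when both inputs
are consistent, so ``merge_with_gate`` admits the incoming reactions in
deterministic batches, re-testing after each and quarantining any
reaction that introduces an inconsistency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from lxml import etree
from scipy.optimize import linprog, milp, Bounds, LinearConstraint

from .formula import ElementComposition
from .mass_balance import apply_outcome, balance
from .metabolite_id import (
    CatalogEntry,
    MatchConfig,
    enrich_annotations,
    similarity_score,
)
from .model import (
    Compartment,
    GeneEntity,
    MetaboliteEntity,
    MetabolicNetwork,
    ReactionEntity,
)
from .gpr_localization import (
    GeneAssociationRecord,
    LocationRecord,
    build_sgpr,
    expand_isoenzymes,
    tolerant_merge,
)
from .reaction_id import PERFECT_TOTAL, fingerprint, total_score

__all__ = [
    "OverlapReport",
    "ConsistencyResult",
    "read_kgml",
    "build_database",
    "find_overlaps",
    "merge",
    "test_stoichiometric_consistency",
    "merge_with_gate",
    "GATE_BATCH_SIZE",
]

log = logging.getLogger(__name__)

GATE_BATCH_SIZE = 50
_MASS_UPPER = 1e4


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------

@dataclass
class KgmlReaction:
    reaction_id: str
    substrates: list[str]  # KEGG compound ids
    products: list[str]
    reversible: bool
    ec_numbers: set[str]


def read_kgml(path: str | Path) -> list[KgmlReaction]:
    """Parse one KGML pathway map into its reaction list.

    Reactions reference compounds by entry; enzyme entries carry EC
    numbers and point back at reactions. Entries referencing unknown
    compounds are skipped with a warning.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    compounds: set[str] = set()
    rxn_ecs: dict[str, set[str]] = {}
    for entry in root.findall("entry"):
        etype = entry.get("type")
        name = entry.get("name", "")
        if etype == "compound":
            for token in name.split():
                compounds.add(token.removeprefix("cpd:"))
        elif etype == "enzyme":
            ecs = {t.removeprefix("ec:") for t in name.split() if t.startswith("ec:")}
            for token in (entry.get("reaction") or "").split():
                rxn_ecs.setdefault(token.removeprefix("rn:"), set()).update(ecs)
    out = []
    for rxn in root.findall("reaction"):
        rid = rxn.get("name", "").removeprefix("rn:")
        subs, prods, ok = [], [], True
        for side, bucket in (("substrate", subs), ("product", prods)):
            for el in rxn.findall(side):
                cid = el.get("name", "").removeprefix("cpd:")
                if cid not in compounds:
                    log.warning(
                        "%s: reaction %s references unknown compound %s; skipped",
                        path, rid, cid,
                    )
                    ok = False
                bucket.append(cid)
        if not ok or not rid:
            continue
        out.append(
            KgmlReaction(
                reaction_id=rid,
                substrates=subs,
                products=prods,
                reversible=rxn.get("type") == "reversible",
                ec_numbers=rxn_ecs.get(rid, set()),
            )
        )
    return out


DEFAULT_COMPARTMENTS = (
    Compartment("c", "cytosol", "GO:0005829"),
    Compartment("m", "mitochondrion", "GO:0005739"),
    Compartment("e", "extracellular region", "GO:0005576"),
)


def build_database(
    pathway_files: Iterable[str | Path],
    catalog: Iterable[CatalogEntry],
    assoc_records: Iterable[GeneAssociationRecord],
    loc_records: Iterable[LocationRecord],
    config: MatchConfig = MatchConfig(),
    compartments: Iterable[Compartment] = DEFAULT_COMPARTMENTS,
    home_compartment: str = "c",
) -> MetabolicNetwork:
    """The database-construction procedure over offline pathway files.

    Every pathway reaction appears once (fingerprint deduplication),
    metabolites are enriched from the catalog, S-GPRs attached per EC,
    isoenzyme compartment copies generated, and the balancing cascade is
    applied to every reaction.
    """
    catalog = list(catalog)
    assoc_records = tolerant_merge(list(assoc_records))
    loc_records = list(loc_records)
    by_kegg = {e.xrefs["KEGG"]: e for e in catalog if "KEGG" in e.xrefs}

    network = MetabolicNetwork("human_database")
    for comp in compartments:
        network.add_compartment(comp.copy())

    def ensure_met(cid: str) -> str:
        if cid in network.metabolites:
            return cid
        entry = by_kegg.get(cid)
        network.add_metabolite(
            MetaboliteEntity(
                id=cid,
                name=entry.names[0] if entry else cid,
                compartment_id=home_compartment,
                composition=entry.composition if entry else ElementComposition(),
                synonyms=list(entry.names[1:]) if entry else [],
                xrefs=dict(entry.xrefs) if entry else {"KEGG": cid},
            )
        )
        network.provenance[cid] = "kgml"
        return cid

    for path in pathway_files:
        for kr in read_kgml(path):
            if kr.reaction_id in network.reactions:
                continue
            for cid in kr.substrates + kr.products:
                ensure_met(cid)
            candidate = ReactionEntity(
                kr.reaction_id,
                substrates={c: Fraction(1) for c in kr.substrates},
                products={c: Fraction(1) for c in kr.products},
                reversible=kr.reversible,
                ec_numbers=set(kr.ec_numbers),
            )
            # cross-pathway dedup by fingerprint (ids can differ between maps)
            fp = fingerprint(candidate, network)
            if any(
                total_score(fp, fingerprint(other, network)) == PERFECT_TOTAL
                for other in network.reactions.values()
            ):
                continue
            candidate.gpr = _sgpr_for(candidate, assoc_records)
            network.add_reaction(candidate)
            network.provenance[kr.reaction_id] = "kgml"

    network, _ = enrich_annotations(network, catalog, config)
    network, _ = expand_isoenzymes(network, assoc_records, loc_records)
    for rid in list(network.reactions):
        outcome = balance(network.reactions[rid], network)
        if outcome.status in ("rebalanced", "rebalanced_with_additions"):
            network.reactions[rid] = apply_outcome(
                network.reactions[rid], outcome, network
            )
    return network


def _sgpr_for(r: ReactionEntity, assoc_records: list[GeneAssociationRecord]):
    for ec in sorted(r.ec_numbers):
        node = build_sgpr(ec, assoc_records)
        if node is not None:
            return node
    return None


# ---------------------------------------------------------------------------
# overlaps & merge
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    metabolite_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    reaction_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    gene_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "metabolites": len(self.metabolite_pairs),
            "reactions": len(self.reaction_pairs),
            "genes": len(self.gene_pairs),
        }

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "metabolite_pairs": [list(p) for p in self.metabolite_pairs],
            "reaction_pairs": [list(p) for p in self.reaction_pairs],
            "gene_pairs": [list(p) for p in self.gene_pairs],
        }


def find_overlaps(
    a: MetabolicNetwork, b: MetabolicNetwork, config: MatchConfig = MatchConfig()
) -> OverlapReport:
    """Equivalent-entity pairs between two networks, one-to-one.

    Metabolites pair on an exact shared xref (score 2, above any name
    score) or name similarity ≥ threshold, same compartment required;
    reactions on a perfect fingerprint total; genes on equal Ensembl ids.
    Pairing is greedy best-score-first with deterministic id tie-breaks.
    """
    report = OverlapReport()

    # metabolites: score all candidate pairs, then greedy one-to-one
    candidates: list[tuple[float, str, str, str]] = []
    b_by_comp: dict[str, list[MetaboliteEntity]] = {}
    for met in b.metabolites.values():
        b_by_comp.setdefault(met.compartment_id, []).append(met)
    comp_map = _compartment_map(a, b)
    for ma in a.metabolites.values():
        for mb in b_by_comp.get(comp_map.get(ma.compartment_id, ma.compartment_id), []):
            shared = [
                s for s, v in ma.xrefs.items() if v and b_xref(mb, s) == v
            ]
            if shared:
                candidates.append((2.0, ma.id, mb.id, f"xref:{shared[0]}"))
                continue
            score = max(
                (
                    similarity_score(na, nb, config)
                    for na in [ma.name, *ma.synonyms]
                    for nb in [mb.name, *mb.synonyms]
                ),
                default=0.0,
            )
            if score >= config.threshold:
                candidates.append((score, ma.id, mb.id, f"name:{score:.3f}"))
    used_a: set[str] = set()
    used_b: set[str] = set()
    for score, ida, idb, evidence in sorted(
        candidates, key=lambda t: (-t[0], t[1], t[2])
    ):
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        report.metabolite_pairs.append((ida, idb, evidence))

    # reactions: perfect fingerprint totals, greedy by id
    fps_a = {rid: fingerprint(r, a) for rid, r in a.reactions.items()}
    fps_b = {rid: fingerprint(r, b) for rid, r in b.reactions.items()}
    used_b_r: set[str] = set()
    for rid_a in sorted(fps_a):
        for rid_b in sorted(fps_b):
            if rid_b in used_b_r:
                continue
            if total_score(fps_a[rid_a], fps_b[rid_b]) == PERFECT_TOTAL:
                report.reaction_pairs.append((rid_a, rid_b, "fingerprint"))
                used_b_r.add(rid_b)
                break

    # genes: Ensembl identity; exact id equality as fallback when either
    # side lacks an Ensembl annotation
    ens_a = {g.ensembl: g.id for g in a.genes.values() if g.ensembl}
    used_a_g: set[str] = set()
    used_b_g: set[str] = set()
    for gb in sorted(b.genes.values(), key=lambda g: g.id):
        if gb.ensembl and gb.ensembl in ens_a:
            ga = ens_a[gb.ensembl]
            if ga not in used_a_g:
                report.gene_pairs.append((ga, gb.id, f"Ensembl:{gb.ensembl}"))
                used_a_g.add(ga)
                used_b_g.add(gb.id)
    for gb in sorted(b.genes.values(), key=lambda g: g.id):
        if gb.id in used_b_g or gb.id not in a.genes or gb.id in used_a_g:
            continue
        ga = a.genes[gb.id]
        if ga.ensembl and gb.ensembl and ga.ensembl != gb.ensembl:
            continue
        report.gene_pairs.append((ga.id, gb.id, "id"))
        used_a_g.add(ga.id)
        used_b_g.add(gb.id)
    return report


def b_xref(met: MetaboliteEntity, source: str) -> Optional[str]:
    return met.xrefs.get(source)


def _compartment_map(a: MetabolicNetwork, b: MetabolicNetwork) -> dict[str, str]:
    """a-compartment id → b-compartment id, matched by id or GO term."""
    out = {}
    b_by_go = {c.go_term: c.id for c in b.compartments.values() if c.go_term}
    for c in a.compartments.values():
        if c.id in b.compartments:
            out[c.id] = c.id
        elif c.go_term and c.go_term in b_by_go:
            out[c.id] = b_by_go[c.go_term]
    return out


def merge(
    a: MetabolicNetwork, b: MetabolicNetwork, overlaps: OverlapReport
) -> MetabolicNetwork:
    """Union of two networks with overlap elimination; ``a`` wins conflicts.

    Per overlap pair, a's entity is kept and enriched with b's xrefs,
    synonyms and EC numbers; b-only entities are added (renamed with the
    ``__db`` suffix on id collision) and b-only reactions are rewired onto
    the kept metabolites.
    """
    merged = a.copy()
    met_map = {idb: ida for ida, idb, _ in overlaps.metabolite_pairs}
    gene_map = {idb: ida for ida, idb, _ in overlaps.gene_pairs}
    rxn_overlap_b = {idb for _, idb, _ in overlaps.reaction_pairs}

    comp_map = {v: k for k, v in _compartment_map(a, b).items()}  # b comp -> a comp
    for comp in b.compartments.values():
        if comp.id not in comp_map:
            new_id = comp.id if comp.id not in merged.compartments else comp.id + "__db"
            merged.add_compartment(Compartment(new_id, comp.name, comp.go_term))
            comp_map[comp.id] = new_id

    for idb, mb in b.metabolites.items():
        if idb in met_map:
            kept = merged.metabolites[met_map[idb]]
            for s, v in mb.xrefs.items():
                kept.xrefs.setdefault(s, v)
            for syn in [mb.name, *mb.synonyms]:
                if syn != kept.name and syn not in kept.synonyms:
                    kept.synonyms.append(syn)
            continue
        new_id = idb if idb not in merged.metabolites else idb + "__db"
        met_map[idb] = new_id
        merged.add_metabolite(
            MetaboliteEntity(
                new_id, mb.name, comp_map.get(mb.compartment_id, mb.compartment_id),
                mb.composition, list(mb.synonyms), dict(mb.xrefs),
            )
        )

    for idb, gb in b.genes.items():
        if idb in gene_map:
            kept_g = merged.genes[gene_map[idb]]
            for s, v in gb.xrefs.items():
                kept_g.xrefs.setdefault(s, v)
            continue
        new_id = idb if idb not in merged.genes else idb + "__db"
        gene_map[idb] = new_id
        merged.add_gene(GeneEntity(new_id, gb.symbol, dict(gb.xrefs)))

    for idb, rb in b.reactions.items():
        if idb in rxn_overlap_b:
            kept_r = merged.reactions[
                next(ida for ida, i, _ in overlaps.reaction_pairs if i == idb)
            ]
            kept_r.ec_numbers |= rb.ec_numbers
            for s, v in rb.xrefs.items():
                kept_r.xrefs.setdefault(s, v)
            continue
        new_id = idb if idb not in merged.reactions else idb + "__db"
        new_r = rb.copy()
        new_r.id = new_id
        new_r.substrates = {met_map.get(m, m): c for m, c in rb.substrates.items()}
        new_r.products = {met_map.get(m, m): c for m, c in rb.products.items()}
        if new_r.gpr is not None:
            new_r.gpr = _remap_gpr(new_r.gpr, gene_map)
        merged.add_reaction(new_r)
    return merged


def _remap_gpr(node, gene_map: dict[str, str]):
    from dataclasses import replace

    if node.node_kind == "gene":
        return replace(node, gene_id=gene_map.get(node.gene_id, node.gene_id))
    return replace(
        node, children=tuple(_remap_gpr(c, gene_map) for c in node.children)
    )


# ---------------------------------------------------------------------------
# stoichiometric consistency
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyResult:
    consistent: bool
    inconsistent_metabolites: set[str] = field(default_factory=set)
    witness_masses: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "consistent": self.consistent,
            "inconsistent_metabolites": sorted(self.inconsistent_metabolites),
        }


def _internal_matrix(n: MetabolicNetwork) -> tuple[np.ndarray, list[str]]:
    S, met_ids, rxn_ids = n.stoichiometric_matrix()
    keep = [j for j, rid in enumerate(rxn_ids) if not n.reactions[rid].is_boundary]
    return S[:, keep], met_ids


def test_stoichiometric_consistency(n: MetabolicNetwork) -> ConsistencyResult:
    """Positive-mass-vector test over the internal reactions.

    Feasibility LP: find m with m ≥ 1 and Nᵀm = 0. When infeasible, a
    MILP maximizes the number of metabolites that can carry a mass ≥ 1;
    the complement is reported as the inconsistent set.
    """
    S, met_ids = _internal_matrix(n)
    n_met = len(met_ids)
    if n_met == 0 or S.shape[1] == 0:
        return ConsistencyResult(True, witness_masses={})
    res = linprog(
        c=np.ones(n_met),
        A_eq=S.T,
        b_eq=np.zeros(S.shape[1]),
        bounds=[(1.0, None)] * n_met,
        method="highs",
    )
    if res.status == 0:
        return ConsistencyResult(
            True, witness_masses=dict(zip(met_ids, res.x))
        )
    if res.status != 2:  # not "infeasible": numerical failure is fatal
        raise RuntimeError(f"consistency LP failed: {res.message}")

    # maximal consistent subset: m_i in [0, U], z_i binary, z_i <= m_i
    n_var = 2 * n_met
    c = np.concatenate([np.zeros(n_met), -np.ones(n_met)])
    A_eq = np.hstack([S.T, np.zeros((S.shape[1], n_met))])
    cons = [
        LinearConstraint(A_eq, 0.0, 0.0),
        LinearConstraint(
            np.hstack([-np.eye(n_met), np.eye(n_met)]), -np.inf, 0.0
        ),
    ]
    integrality = np.concatenate([np.zeros(n_met), np.ones(n_met)])
    bounds = Bounds(
        np.zeros(n_var),
        np.concatenate([np.full(n_met, _MASS_UPPER), np.ones(n_met)]),
    )
    mres = milp(c=c, constraints=cons, integrality=integrality, bounds=bounds)
    if not mres.success:
        raise RuntimeError(f"consistency MILP failed: {mres.message}")
    z = mres.x[n_met:]
    inconsistent = {met_ids[i] for i in range(n_met) if z[i] < 0.5}
    return ConsistencyResult(False, inconsistent_metabolites=inconsistent)


def merge_with_gate(
    a: MetabolicNetwork,
    b: MetabolicNetwork,
    config: MatchConfig = MatchConfig(),
    batch_size: int = GATE_BATCH_SIZE,
) -> tuple[MetabolicNetwork, dict]:
    """Consistency-gated merge: admit b's novel reactions in batches.

    After each batch the positive-mass test runs; reactions implicated in
    a new inconsistency are quarantined and the batch re-admitted without
    them. The returned network passes the consistency test.
    """
    overlaps = find_overlaps(a, b, config)
    full = merge(a, b, overlaps)
    novel = sorted(set(full.reactions) - set(a.reactions))

    gated = full.copy()
    for rid in novel:
        gated.remove_reaction(rid)

    quarantined: list[str] = []
    admitted: list[str] = []
    for start in range(0, len(novel), batch_size):
        batch = novel[start : start + batch_size]
        for rid in batch:
            gated.reactions[rid] = full.reactions[rid].copy()
        result = test_stoichiometric_consistency(gated)
        if result.consistent:
            admitted.extend(batch)
            continue
        # re-admit one by one, dropping the culprits
        for rid in batch:
            gated.remove_reaction(rid)
        for rid in batch:
            gated.reactions[rid] = full.reactions[rid].copy()
            if test_stoichiometric_consistency(gated).consistent:
                admitted.append(rid)
            else:
                gated.remove_reaction(rid)
                quarantined.append(rid)
    final = test_stoichiometric_consistency(gated)
    report = {
        "overlaps": overlaps.to_dict(),
        "admitted": admitted,
        "quarantined": quarantined,
        "final_consistent": final.consistent,
    }
    return gated, report
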