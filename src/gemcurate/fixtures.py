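"""Seeded synthetic fixtures with ground truth.

The generator builds a balanced, stoichiometrically consistent network —
a small glycolysis-like core plus randomly composed balanced reactions —
together with the reference catalogs (metabolites, reactions, gene
associations, gene locations) and KGML-style pathway files that the
curation pipeline consumes. Product compositions are constructed by
partitioning the substrates' summed atom vector, so every generated
internal reaction is elementally balanced by construction and the atomic
masses are a consistency witness.

``corrupt`` then injects the error classes the curation stages are meant
to repair — name typos, wrong cross-references, deleted balancing species
(H₂O/H⁺), duplicated metabolites under synonym names — and emits a truth
map. Each typo/xref entry carries a ``recoverable`` flag computed at
corruption time by re-scoring the corrupted record against the catalog
under the same LCS rules the identifier uses: an error is recoverable
exactly when the true entry is still the unique best match at the
configured threshold (name basis, or formula fallback).

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

from .catalogs import (
    write_gene_associations,
    write_gene_locations,
    write_metabolite_catalog,
    write_reaction_catalog,
)
from .formula import ElementComposition, parse_formula
from .gpr_localization import GeneAssociationRecord, LocationRecord, build_sgpr
from .metabolite_id import CatalogEntry, MatchConfig, identify_metabolite
from .model import (
    Compartment,
    GeneEntity,
    MetaboliteEntity,
    MetabolicNetwork,
    ReactionEntity,
)
from .reaction_id import ReferenceReaction, fingerprint
from .sbml_io import write_sbml

__all__ = ["FixtureSpec", "FixtureCatalogs", "generate_truth_network", "corrupt",
           "write_fixture", "find_internal_duplicates"]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_reactions: int = 40
    n_metabolites: int = 0  # 0 = derived from n_reactions
    typo_rate: float = 0.1
    wrong_xref_rate: float = 0.1
    imbalance_rate: float = 0.1
    duplicate_rate: float = 0.0
    include_glycans: bool = True
    include_exchanges: bool = True
    include_coupled: bool = True
    threshold: float = 0.82

    def __post_init__(self) -> None:
        for rate in (self.typo_rate, self.wrong_xref_rate, self.imbalance_rate,
                     self.duplicate_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_reactions < 4:
            raise ValueError("need at least 4 reactions")


@dataclass
class FixtureCatalogs:
    metabolites: list[CatalogEntry]
    reactions: list[ReferenceReaction]
    associations: list[GeneAssociationRecord]
    locations: list[LocationRecord]
    pathways: dict[str, list[str]]  # pathway name -> reaction ids


GO_CYTOSOL = "GO:0005829"
GO_MITO = "GO:0005739"
GO_EXTRA = "GO:0005576"

_CORE = [
    # id, name, synonyms, formula, charge
    ("glc", "D-glucose", ["dextrose", "grape sugar"], "C6H12O6", 0),
    ("g6p", "D-glucose 6-phosphate", ["glucose-6-P"], "C6H11O9P", -2),
    ("f6p", "D-fructose 6-phosphate", ["fructose-6-P"], "C6H11O9P2", -2),
    ("atp", "ATP", ["adenosine triphosphate"], "C10H12N5O13P3", -4),
    ("adp", "ADP", ["adenosine diphosphate"], "C10H12N5O10P2", -3),
    ("pyr", "pyruvate", ["2-oxopropanoate"], "C3H3O3", -1),
    ("lac", "(S)-lactate", ["L-lactate"], "C3H5O3", -1),
    ("nad", "NAD+", ["nicotinamide adenine dinucleotide"], "C21H26N7O14P2", -1),
    ("nadh", "NADH", ["reduced NAD"], "C21H27N7O14P2", -2),
    ("h2o", "water", ["H2O", "aqua"], "H2O", 0),
    ("h", "H+", ["proton"], "H", 1),
    ("pi", "phosphate", ["orthophosphate"], "HO4P", -2),
]

_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"


def _random_name(rng: random.Random, n_syllables: int = 5) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syllables)
    )


def _random_composition(rng: random.Random) -> dict[str, int]:
    comp = {"C": rng.randint(2, 12), "H": rng.randint(4, 24), "O": rng.randint(1, 8)}
    if rng.random() < 0.4:
        comp["N"] = rng.randint(1, 4)
    if rng.random() < 0.2:
        comp["P"] = rng.randint(1, 2)
    if rng.random() < 0.15:
        comp["S"] = 1
    return comp


def generate_truth_network(spec: FixtureSpec) -> tuple[MetabolicNetwork, FixtureCatalogs]:
    """Balanced, consistent truth network plus matching catalogs."""
    rng = random.Random(spec.seed)
    network = MetabolicNetwork(f"fixture_seed{spec.seed}")
    network.add_compartment(Compartment("c", "cytosol", GO_CYTOSOL))
    network.add_compartment(Compartment("m", "mitochondrion", GO_MITO))
    network.add_compartment(Compartment("e", "extracellular region", GO_EXTRA))

    entries: list[CatalogEntry] = []
    names_taken: set[str] = set()
    # id space offset by seed: compounds from different fixture seeds are
    # different compounds and must not share fabricated database ids
    kegg_serial = [(spec.seed % 90) * 10_000 + 100]

    def register(mid: str, name: str, synonyms: list[str], comp: ElementComposition,
                 lipid: bool = False) -> MetaboliteEntity:
        kegg_serial[0] += 1
        cid = f"C{kegg_serial[0]:05d}"
        xrefs = {
            "KEGG": cid,
            "ChEBI": f"CHEBI:{10000 + kegg_serial[0]}",
            "PubChem": str(500000 + kegg_serial[0]),
            "HMDB": f"HMDB{kegg_serial[0]:07d}",
            "InChIKey": f"IK{kegg_serial[0]:012d}X",
        }
        if lipid:
            xrefs["LipidMaps"] = f"LM{kegg_serial[0]:08d}"
        entries.append(
            CatalogEntry(f"CAT{kegg_serial[0]:05d}", tuple([name, *synonyms]), comp, xrefs)
        )
        # the model starts with a subset of the catalog's xrefs (enrichment
        # adds the rest)
        model_xrefs = {"KEGG": cid}
        if rng.random() < 0.5:
            model_xrefs["ChEBI"] = xrefs["ChEBI"]
        met = MetaboliteEntity(mid, name, "c", comp, list(synonyms), model_xrefs)
        network.add_metabolite(met)
        return met

    for mid, name, synonyms, formula, charge in _CORE:
        comp = parse_formula(formula)
        register(mid, name, synonyms, ElementComposition(comp.counts, charge))

    assoc: list[GeneAssociationRecord] = []
    locations: list[LocationRecord] = []
    gene_serial = [(spec.seed % 90) * 10_000]

    def make_genes(ec: str) -> None:
        """1–3 isoenzymes/complexes for one EC; some live in mitochondria."""
        n_branches = rng.choice([1, 1, 2, 2, 3])
        for b in range(n_branches):
            go = GO_CYTOSOL if (b == 0 or rng.random() < 0.6) else GO_MITO
            if rng.random() < 0.3:  # complex of 2 subunits
                group = f"CPLX_{ec}_{b}"
                for _ in range(2):
                    gene_serial[0] += 1
                    gid = f"GENE{gene_serial[0]:04d}"
                    network.add_gene(
                        GeneEntity(gid, gid, {"Ensembl": f"ENSG{gene_serial[0]:011d}"})
                    )
                    assoc.append(
                        GeneAssociationRecord(ec, gid, group, rng.randint(1, 4), "kegg")
                    )
                    locations.append(LocationRecord(gid, frozenset({go})))
            else:
                gene_serial[0] += 1
                gid = f"GENE{gene_serial[0]:04d}"
                network.add_gene(
                    GeneEntity(gid, gid, {"Ensembl": f"ENSG{gene_serial[0]:011d}"})
                )
                assoc.append(GeneAssociationRecord(ec, gid, None, 1, "kegg"))
                locations.append(LocationRecord(gid, frozenset({go})))

    refs: list[ReferenceReaction] = []
    rxn_serial = [0]

    def add_reaction(r: ReactionEntity, ec: Optional[str]) -> None:
        if ec:
            r.ec_numbers = {ec}
            make_genes(ec)
            r.gpr = build_sgpr(ec, assoc)
        network.add_reaction(r)

    def next_ec() -> str:
        rxn_serial[0] += 1
        i = rxn_serial[0]
        return f"{1 + i % 6}.{1 + i % 9}.{1 + i % 7}.{i}"

    # hand-written core reactions (all balanced, charge-consistent formulas
    # not required — only atoms are balanced)
    core_rxns = [
        ReactionEntity("HEX1", "hexokinase", {"glc": 1, "atp": 1},
                       {"g6p": 1, "adp": 1, "h": 1}),
        ReactionEntity("LDH", "lactate dehydrogenase", {"pyr": 1, "nadh": 1, "h": 1},
                       {"lac": 1, "nad": 1}, reversible=True),
    ]
    # fix hexokinase hydrogens: glc C6H12O6 + atp C10H12N5O13P3 ->
    # g6p C6H11O9P + adp C10H12N5O10P2 + h : H 24 = 24, P 3 = 3, O 19 = 19 ✓
    for r in core_rxns:
        add_reaction(r, next_ec())

    n_random = max(0, spec.n_reactions - len(network.reactions))
    substrate_pool = [m for m in network.metabolites if m not in ("h2o", "h")]

    for i in range(n_random):
        # substrates: one existing + sometimes water (so corruption can
        # delete it), products: fresh compounds partitioning the atom total
        subs: dict[str, Fraction] = {}
        s1 = rng.choice(substrate_pool)
        subs[s1] = Fraction(rng.randint(1, 2))
        if rng.random() < 0.5:
            s2 = rng.choice(substrate_pool)
            if s2 != s1:
                subs[s2] = Fraction(1)
        uses_water = rng.random() < 0.5
        if uses_water:
            subs["h2o"] = Fraction(1)
        total: dict[str, Fraction] = {}
        for mid, coeff in subs.items():
            for a, n in network.metabolites[mid].composition.counts.items():
                total[a] = total.get(a, Fraction(0)) + coeff * n
        # split into two products
        p1: dict[str, Fraction] = {}
        p2: dict[str, Fraction] = {}
        for a, n in total.items():
            k = rng.randint(0, int(n))
            if k:
                p1[a] = Fraction(k)
            if n - k:
                p2[a] = n - Fraction(k)
        if not p1 or not p2:  # degenerate split: single product
            p1, p2 = dict(total), {}
        prods: dict[str, Fraction] = {}
        for comp_counts in (p1, p2):
            if not comp_counts:
                continue
            name = _random_name(rng)
            while name in names_taken:
                name = _random_name(rng)
            names_taken.add(name)
            mid = f"met_{name}"
            register(mid, name, [name + " (synonym)"],
                     ElementComposition(comp_counts, 0),
                     lipid=rng.random() < 0.2)
            substrate_pool.append(mid)
            prods[mid] = Fraction(1)
        rid = f"RXN{1000 + i}"
        r = ReactionEntity(rid, f"reaction {rid}", subs, prods,
                           reversible=rng.random() < 0.3)
        add_reaction(r, next_ec())

    if spec.include_glycans:
        for mid, name, blocks in [
            ("glyA", "galactan dimer", 2), ("glyB", "galactan monomer", 1),
            ("glyC", "galactan trimer", 3),
        ]:
            register(mid, name, [], ElementComposition({"Gal": Fraction(blocks)}, 0))
        add_reaction(
            ReactionEntity("GLYELONG", "galactan elongation",
                           {"glyA": 1, "glyB": 1}, {"glyC": 1}),
            next_ec(),
        )

    if spec.include_coupled:
        # two half-reactions written as one; no candidate species carries
        # C or N, so this is unbalanceable by construction
        register("cplA", "couplinose", [], parse_formula("C2N2"))
        register("cplB", "decouplate", [], parse_formula("C2N1"))
        add_reaction(
            ReactionEntity("COUPLED", "concatenated half-reactions",
                           {"cplA": 1}, {"cplB": 1}),
            None,
        )

    if spec.include_exchanges:
        for mid in ("glc", "pyr"):
            ext = network.metabolites[mid]
            ext_id = f"{mid}@e"
            network.add_metabolite(
                MetaboliteEntity(ext_id, ext.name, "e", ext.composition,
                                 list(ext.synonyms), {})
            )
            network.add_reaction(
                ReactionEntity(f"EX_{mid}", f"{ext.name} exchange",
                               {ext_id: 1}, {}, reversible=True, kind="exchange")
            )
            network.add_reaction(
                ReactionEntity(f"T_{mid}", f"{ext.name} transport",
                               {ext_id: 1}, {mid: 1}, reversible=True)
            )

    # reaction reference catalog: fingerprints from the truth participants
    for rid, r in network.reactions.items():
        if r.is_boundary or not r.ec_numbers:
            continue
        refs.append(
            ReferenceReaction(
                reaction_id=f"REF_{rid}",
                fingerprint=fingerprint(r, network),
                ec_numbers=frozenset(r.ec_numbers),
                xrefs={"KEGG": f"R{90000 + len(refs)}"},
            )
        )

    # pathway partition: 3 KGML maps over internal cytosol reactions, with
    # deliberate sharing of the first two reactions across all maps
    internal = [
        rid for rid, r in network.reactions.items()
        if not r.is_boundary and all(
            network.metabolites[m].compartment_id == "c"
            for m, _, _ in r.participants()
        )
    ]
    shared = internal[:2]
    rest = internal[2:]
    third = max(1, len(rest) // 3)
    pathways = {
        "path1": shared + rest[:third],
        "path2": shared + rest[third : 2 * third],
        "path3": shared + rest[2 * third :],
    }

    network.validate()
    catalogs = FixtureCatalogs(entries, refs, assoc, locations, pathways)
    return network, catalogs


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def _typo(rng: random.Random, name: str) -> str:
    pos = rng.randrange(len(name))
    op = rng.choice(["sub", "del", "ins"])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if op == "sub":
        repl = rng.choice([c for c in alphabet if c != name[pos]])
        return name[:pos] + repl + name[pos + 1 :]
    if op == "del" and len(name) > 2:
        return name[:pos] + name[pos + 1 :]
    return name[:pos] + rng.choice(alphabet) + name[pos:]


def corrupt(
    network: MetabolicNetwork,
    catalogs: FixtureCatalogs,
    spec: FixtureSpec,
) -> tuple[MetabolicNetwork, list[dict]]:
    """Inject seeded errors; return the corrupted network and the truth map."""
    rng = random.Random(spec.seed + 1)
    out = network.copy()
    truth: list[dict] = []
    config = MatchConfig(threshold=spec.threshold)
    by_cat = {e.catalog_id: e for e in catalogs.metabolites}
    # metabolite id -> true catalog entry, via the KEGG xref it was built with
    cat_by_kegg = {e.xrefs["KEGG"]: e for e in catalogs.metabolites if "KEGG" in e.xrefs}

    mets = sorted(out.metabolites)
    for mid in mets:
        met = out.metabolites[mid]
        true_entry = cat_by_kegg.get(network.metabolites[mid].xrefs.get("KEGG", ""))
        if true_entry is None:
            continue
        if rng.random() < spec.typo_rate:
            original = met.name
            met.name = _typo(rng, met.name)
            met.synonyms = []  # synonyms would trivially restore the match
            truth.append({
                "kind": "typo", "metabolite": mid, "original_name": original,
                "corrupted_name": met.name, "catalog_id": true_entry.catalog_id,
            })
        if rng.random() < spec.wrong_xref_rate and "KEGG" in met.xrefs:
            old = met.xrefs["KEGG"]
            wrong = f"C9{rng.randint(1000, 9999)}"
            met.xrefs["KEGG"] = wrong
            truth.append({
                "kind": "wrong_xref", "metabolite": mid, "source": "KEGG",
                "correct": old, "wrong": wrong,
                "catalog_id": true_entry.catalog_id,
            })

    # recoverability: re-score the corrupted entity against the catalog with
    # the same rules the identifier applies
    for entry in truth:
        met = out.metabolites[entry["metabolite"]]
        match = identify_metabolite(met, catalogs.metabolites, config)
        entry["recoverable"] = bool(
            match.matched and match.catalog_id == entry["catalog_id"]
        )

    # imbalance: delete H2O/H+ participants from balanced internal reactions
    for rid in sorted(out.reactions):
        r = out.reactions[rid]
        if r.is_boundary:
            continue
        removable = [
            (mid, side)
            for mid, side, _ in r.participants()
            if mid in ("h2o", "h") and len(
                r.substrates if side == "substrate" else r.products
            ) > 1
        ]
        if removable and rng.random() < spec.imbalance_rate:
            mid, side = removable[0]
            (r.substrates if side == "substrate" else r.products).pop(mid)
            truth.append({
                "kind": "imbalance", "reaction": rid, "species": mid,
                "side": side, "recoverable": True,
            })

    # duplicates under synonym names (no shared xrefs: name evidence only);
    # if the original's name was typo-corrupted above, the pair may no
    # longer share evidence — such duplicates are marked unrecoverable
    from .metabolite_id import similarity_score

    for mid in mets:
        met = network.metabolites[mid]
        if not met.synonyms or rng.random() >= spec.duplicate_rate:
            continue
        dup_id = f"{mid}__dup"
        dup = MetaboliteEntity(dup_id, met.synonyms[0], met.compartment_id,
                               met.composition, [], {})
        out.add_metabolite(dup)
        original = out.metabolites[mid]
        evidence = max(
            similarity_score(a, b, config)
            for a in [original.name, *original.synonyms]
            for b in [dup.name]
        )
        truth.append({
            "kind": "duplicate", "original": mid, "duplicate": dup_id,
            "recoverable": evidence >= spec.threshold,
        })
    return out, truth


def find_internal_duplicates(
    network: MetabolicNetwork, config: MatchConfig = MatchConfig()
) -> list[tuple[str, str, str]]:
    """Same-compartment metabolite pairs that look like one compound.

    Evidence: an exactly shared xref value or name/synonym similarity at
    the configured threshold. Returns (id_a, id_b, evidence) with
    id_a < id_b.
    """
    from .metabolite_id import similarity_score

    mets = sorted(network.metabolites)
    pairs = []
    for i, ida in enumerate(mets):
        ma = network.metabolites[ida]
        for idb in mets[i + 1 :]:
            mb = network.metabolites[idb]
            if ma.compartment_id != mb.compartment_id:
                continue
            shared = [s for s, v in ma.xrefs.items() if v and mb.xrefs.get(s) == v]
            if shared:
                pairs.append((ida, idb, f"xref:{shared[0]}"))
                continue
            score = max(
                similarity_score(na, nb, config)
                for na in [ma.name, *ma.synonyms]
                for nb in [mb.name, *mb.synonyms]
            )
            if score >= config.threshold:
                pairs.append((ida, idb, f"name:{score:.3f}"))
    return pairs


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _write_kgml(path: Path, name: str, reactions: list[ReactionEntity],
                network: MetabolicNetwork) -> None:
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name="path:{name}" org="fix" number="0" title="{name}">',
    ]
    compounds: dict[str, int] = {}
    eid = 0
    for r in reactions:
        for mid, _, _ in r.participants():
            kegg = network.metabolites[mid].xrefs.get("KEGG", mid)
            if kegg not in compounds:
                eid += 1
                compounds[kegg] = eid
                lines.append(
                    f'  <entry id="{eid}" name="cpd:{kegg}" type="compound"/>'
                )
    for r in reactions:
        for ec in sorted(r.ec_numbers):
            eid += 1
            lines.append(
                f'  <entry id="{eid}" name="ec:{ec}" type="enzyme" '
                f'reaction="rn:{r.id}"/>'
            )
    for r in reactions:
        rtype = "reversible" if r.reversible else "irreversible"
        lines.append(f'  <reaction id="{eid + 1}" name="rn:{r.id}" type="{rtype}">')
        for mid in r.substrates:
            kegg = network.metabolites[mid].xrefs.get("KEGG", mid)
            lines.append(f'    <substrate id="{compounds[kegg]}" name="cpd:{kegg}"/>')
        for mid in r.products:
            kegg = network.metabolites[mid].xrefs.get("KEGG", mid)
            lines.append(f'    <product id="{compounds[kegg]}" name="cpd:{kegg}"/>')
        lines.append("  </reaction>")
        eid += 1
    lines.append("</pathway>")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fixture(
    out_dir: str | Path, spec: FixtureSpec
) -> tuple[MetabolicNetwork, MetabolicNetwork, FixtureCatalogs, list[dict]]:
    """Generate, corrupt and serialize a full fixture set under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_net, catalogs = generate_truth_network(spec)
    corrupted, truth_map = corrupt(truth_net, catalogs, spec)

    write_sbml(truth_net, out_dir / "truth_model.xml")
    write_sbml(corrupted, out_dir / "corrupted_model.xml")
    write_metabolite_catalog(catalogs.metabolites, out_dir / "metabolite_catalog.tsv")
    write_reaction_catalog(catalogs.reactions, out_dir / "reaction_catalog.tsv")
    write_gene_associations(catalogs.associations, out_dir / "gene_associations.tsv")
    write_gene_locations(catalogs.locations, out_dir / "gene_locations.tsv")
    kgml_dir = out_dir / "pathways"
    kgml_dir.mkdir(exist_ok=True)
    for pname, rids in catalogs.pathways.items():
        _write_kgml(
            kgml_dir / f"{pname}.xml", pname,
            [truth_net.reactions[r] for r in rids], truth_net,
        )
    (out_dir / "truth_map.json").write_text(
        json.dumps(truth_map, indent=1, sort_keys=True), encoding="utf-8"
    )
    return truth_net, corrupted, catalogs, truth_map
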