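"""Tabular reference catalogs (TSV with declared headers, UTF-8).

Four tables drive curation, mirroring what live database queries would
return; only this offline backend is implemented here, and the readers
double as the interface a live backend would have to satisfy.

* metabolite catalog: ``catalog_id, name, synonyms, formula, charge``
  plus one column per xref source (``KEGG``, ``ChEBI``, ...);
* reaction reference catalog: ``reaction_id, ec, reversible,
  substrate_keys, product_keys`` (key lists ``|``-separated);
* gene associations: ``ec, gene_id, complex_group, protomers, source``;
* gene locations: ``gene_id, go_terms`` (``|``-separated GO accessions).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .formula import ElementComposition, parse_formula
from .gpr_localization import GeneAssociationRecord, LocationRecord
from .metabolite_id import CatalogEntry
from .reaction_id import ReactionFingerprint, ReferenceReaction

__all__ = [
    "XREF_SOURCES",
    "read_metabolite_catalog",
    "write_metabolite_catalog",
    "read_reaction_catalog",
    "write_reaction_catalog",
    "read_gene_associations",
    "write_gene_associations",
    "read_gene_locations",
    "write_gene_locations",
]

XREF_SOURCES = ("KEGG", "ChEBI", "PubChem", "HMDB", "LipidMaps", "InChI", "InChIKey")

_FIXED_MET_COLS = ("catalog_id", "name", "synonyms", "formula", "charge")


def read_metabolite_catalog(path: str | Path) -> list[CatalogEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    xref_cols = [c for c in df.columns if c not in _FIXED_MET_COLS]
    for row in df.itertuples(index=False):
        d = row._asdict()
        comp = parse_formula(d["formula"])
        if d["charge"]:
            comp = ElementComposition(comp.counts, int(d["charge"]))
        names = [d["name"]] + [s for s in d["synonyms"].split("|") if s]
        entries.append(
            CatalogEntry(
                catalog_id=d["catalog_id"],
                names=tuple(names),
                composition=comp,
                xrefs={c: d[c] for c in xref_cols if d[c]},
            )
        )
    return entries


def write_metabolite_catalog(entries: Iterable[CatalogEntry], path: str | Path) -> None:
    from .formula import format_formula

    rows = []
    for e in entries:
        row = {
            "catalog_id": e.catalog_id,
            "name": e.names[0],
            "synonyms": "|".join(e.names[1:]),
            "formula": format_formula(ElementComposition(e.composition.counts, 0)),
            "charge": e.composition.charge,
        }
        for source in XREF_SOURCES:
            row[source] = e.xrefs.get(source, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reaction_catalog(path: str | Path) -> list[ReferenceReaction]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    refs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        refs.append(
            ReferenceReaction(
                reaction_id=d["reaction_id"],
                fingerprint=ReactionFingerprint(
                    substrate_keys=frozenset(
                        k for k in d["substrate_keys"].split("|") if k
                    ),
                    product_keys=frozenset(
                        k for k in d["product_keys"].split("|") if k
                    ),
                    reversible=d["reversible"].lower() in ("1", "true", "yes"),
                ),
                ec_numbers=frozenset(e for e in d["ec"].split("|") if e),
            )
        )
    return refs


def write_reaction_catalog(refs: Iterable[ReferenceReaction], path: str | Path) -> None:
    rows = [
        {
            "reaction_id": r.reaction_id,
            "ec": "|".join(sorted(r.ec_numbers)),
            "reversible": int(r.fingerprint.reversible),
            "substrate_keys": "|".join(sorted(r.fingerprint.substrate_keys)),
            "product_keys": "|".join(sorted(r.fingerprint.product_keys)),
        }
        for r in refs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_associations(path: str | Path) -> list[GeneAssociationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        GeneAssociationRecord(
            ec=d["ec"],
            gene_id=d["gene_id"],
            complex_group=d["complex_group"] or None,
            protomer_count=int(d["protomers"]) if d["protomers"] else None,
            source=d["source"],
        )
        for d in (row._asdict() for row in df.itertuples(index=False))
    ]


def write_gene_associations(
    records: Iterable[GeneAssociationRecord], path: str | Path
) -> None:
    rows = [
        {
            "ec": r.ec,
            "gene_id": r.gene_id,
            "complex_group": r.complex_group or "",
            "protomers": r.protomer_count if r.protomer_count is not None else "",
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_locations(path: str | Path) -> list[LocationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        LocationRecord(
            gene_id=d["gene_id"],
            compartments=frozenset(g for g in d["go_terms"].split("|") if g),
        )
        for d in (row._asdict() for row in df.itertuples(index=False))
    ]


def write_gene_locations(records: Iterable[LocationRecord], path: str | Path) -> None:
    rows = [
        {"gene_id": r.gene_id, "go_terms": "|".join(sorted(r.compartments))}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
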