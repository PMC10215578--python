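"""Fuzzy metabolite identification against a reference catalog.

Model metabolites are matched to catalog entries by the normalized
longest-common-substring (LCS) similarity of their names and synonyms;
when the best name score falls below the threshold the neutralized
molecular formula is tried instead. A match above the threshold donates
the catalog's cross-references: missing identifiers are added, wrong ones
corrected, and a per-source report tallies the changes.

Scores live in [0, 1]; 1 exactly when the normalized strings are equal,
so a threshold near 1 (default 0.82) tolerates single-character typos in
medium-length names while rejecting unrelated compounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from fractions import Fraction
from typing import Iterable, Optional

from .formula import ElementComposition, format_formula
from .model import MetaboliteEntity, MetabolicNetwork

__all__ = [
    "CatalogEntry",
    "MatchConfig",
    "MetaboliteMatch",
    "lcs_length",
    "normalize_name",
    "similarity_score",
    "neutralize_formula",
    "identify_metabolite",
    "enrich_annotations",
    "EnrichmentReport",
]

DEFAULT_THRESHOLD = 0.82

_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class CatalogEntry:
    """One reference-catalog compound: names, composition, cross-references."""

    catalog_id: str
    names: tuple[str, ...]
    composition: ElementComposition = field(default_factory=ElementComposition)
    xrefs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError(f"catalog entry {self.catalog_id} has no names")


@dataclass(frozen=True)
class MatchConfig:
    threshold: float = DEFAULT_THRESHOLD
    case_fold: bool = True
    use_formula: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


@dataclass(frozen=True)
class MetaboliteMatch:
    query_id: str
    catalog_id: Optional[str]
    score: float
    basis: str  # name | formula | none

    @property
    def matched(self) -> bool:
        return self.catalog_id is not None


def normalize_name(s: str, case_fold: bool = True) -> str:
    s = _WS.sub(" ", s).strip()
    return s.casefold() if case_fold else s


def lcs_length(a: str, b: str) -> int:
    """Length of the longest *contiguous* common substring of ``a`` and ``b``."""
    if not a or not b:
        return 0
    # autojunk disabled: the popularity heuristic miscounts long names
    return SequenceMatcher(None, a, b, autojunk=False).find_longest_match(
        0, len(a), 0, len(b)
    ).size


def similarity_score(a: str, b: str, config: MatchConfig = MatchConfig()) -> float:
    """Normalized LCS similarity: lcs / max(len); 1 iff normalized-equal."""
    a = normalize_name(a, config.case_fold)
    b = normalize_name(b, config.case_fold)
    if not a and not b:
        return 0.0
    denom = max(len(a), len(b))
    return lcs_length(a, b) / denom


def neutralize_formula(c: ElementComposition) -> ElementComposition:
    """Shift the composition to its neutral protonation state.

    GEM formulas differ between sources mostly by protonation, so charge
    is folded into the hydrogen count: an anion of charge −k gains k
    hydrogens, a cation loses them (clamped at zero). Idempotent.
    """
    if c.charge == 0:
        return c
    counts = dict(c.counts)
    h = counts.get("H", Fraction(0)) - c.charge
    if h < 0:
        h = Fraction(0)  # clamp: cation with too few hydrogens
    if h == 0:
        counts.pop("H", None)
    else:
        counts["H"] = h
    return ElementComposition(counts, 0)


def _formula_key(c: ElementComposition) -> str:
    return format_formula(neutralize_formula(c))


def identify_metabolite(
    m: MetaboliteEntity,
    catalog: Iterable[CatalogEntry],
    config: MatchConfig = MatchConfig(),
) -> MetaboliteMatch:
    """Best catalog match for one metabolite; name first, formula fallback.

    Ties are broken toward the lexicographically smallest catalog id so
    identification is deterministic regardless of catalog order.
    """
    catalog = list(catalog)
    best_id, best_score = None, -1.0
    query_names = [m.name, *m.synonyms]
    for entry in catalog:
        score = max(
            similarity_score(q, name, config)
            for q in query_names
            for name in entry.names
        )
        if score > best_score or (
            score == best_score and best_id is not None and entry.catalog_id < best_id
        ):
            best_id, best_score = entry.catalog_id, score
    if best_score >= config.threshold:
        return MetaboliteMatch(m.id, best_id, best_score, "name")

    if config.use_formula and not m.composition.is_missing:
        query_key = _formula_key(m.composition)
        fbest_id, fbest_score = None, -1.0
        for entry in catalog:
            if entry.composition.is_missing:
                continue
            score = similarity_score(query_key, _formula_key(entry.composition), config)
            if score > fbest_score or (
                score == fbest_score
                and fbest_id is not None
                and entry.catalog_id < fbest_id
            ):
                fbest_id, fbest_score = entry.catalog_id, score
        if fbest_score >= config.threshold:
            return MetaboliteMatch(m.id, fbest_id, fbest_score, "formula")

    return MetaboliteMatch(m.id, None, max(best_score, 0.0), "none")


@dataclass
class EnrichmentReport:
    """Per-source tallies of annotation changes plus a change log."""

    added: dict[str, int] = field(default_factory=dict)
    corrected: dict[str, int] = field(default_factory=dict)
    unchanged: dict[str, int] = field(default_factory=dict)
    matched: int = 0
    unmatched: int = 0
    changes: list[dict] = field(default_factory=list)

    def _bump(self, bucket: dict[str, int], source: str) -> None:
        bucket[source] = bucket.get(source, 0) + 1

    def to_dict(self) -> dict:
        return {
            "matched": self.matched,
            "unmatched": self.unmatched,
            "added": dict(self.added),
            "corrected": dict(self.corrected),
            "unchanged": dict(self.unchanged),
            "changes": list(self.changes),
        }


def enrich_annotations(
    network: MetabolicNetwork,
    catalog: Iterable[CatalogEntry],
    config: MatchConfig = MatchConfig(),
) -> tuple[MetabolicNetwork, EnrichmentReport]:
    """Correct and extend metabolite cross-references from the catalog.

    Returns a new network; for every matched metabolite, catalog xrefs
    absent from the model are added and conflicting ones replaced (each
    replacement logged with old and new values). Unmatched metabolites
    are left untouched.
    """
    catalog = list(catalog)
    by_id = {e.catalog_id: e for e in catalog}
    out = network.copy()
    report = EnrichmentReport()
    # (source, value, compartment) -> owning metabolite; enrichment must not
    # assign one identifier to two metabolites in the same compartment
    claimed: dict[tuple[str, str, str], str] = {}
    for met in out.metabolites.values():
        for source, value in met.xrefs.items():
            claimed.setdefault((source, value, met.compartment_id), met.id)
    for met in out.metabolites.values():
        match = identify_metabolite(met, catalog, config)
        if not match.matched:
            report.unmatched += 1
            continue
        report.matched += 1
        entry = by_id[match.catalog_id]
        for source, value in entry.xrefs.items():
            owner = claimed.get((source, value, met.compartment_id))
            if owner is not None and owner != met.id:
                report.changes.append(
                    {"metabolite": met.id, "source": source, "old": None,
                     "new": value, "skipped": f"collision with {owner}"}
                )
                continue
            old = met.xrefs.get(source)
            if old is None:
                met.xrefs[source] = value
                claimed[(source, value, met.compartment_id)] = met.id
                report._bump(report.added, source)
                report.changes.append(
                    {"metabolite": met.id, "source": source, "old": None, "new": value}
                )
            elif old != value:
                met.xrefs[source] = value
                claimed[(source, value, met.compartment_id)] = met.id
                report._bump(report.corrected, source)
                report.changes.append(
                    {"metabolite": met.id, "source": source, "old": old, "new": value}
                )
            else:
                report._bump(report.unchanged, source)
    return out, report
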