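"""In-memory representation of a metabolic network.

The container mirrors what an SBML level-3 ``fbc`` model stores —
metabolites, reactions, genes, compartments — plus the two extensions this
toolkit curates: glycan-block formulas (see :mod:`gemcurate.formula`) and
stoichiometric gene–protein–reaction rules (S-GPRs), i.e. GPR trees whose
gene leaves carry the number of protomers needed to assemble one
catalytically active unit.

Stoichiometric coefficients are exact rationals throughout; the
stoichiometric-matrix view renders them as floats only at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Iterator, Optional

import numpy as np

from .formula import ElementComposition

__all__ = [
    "GprNode",
    "gene_leaf",
    "and_node",
    "or_node",
    "parse_gpr",
    "MetaboliteEntity",
    "ReactionEntity",
    "GeneEntity",
    "Compartment",
    "MetabolicNetwork",
    "NetworkError",
]

REACTION_KINDS = ("internal", "exchange", "sink", "biomass")

_GO_RE = re.compile(r"GO:\d{7}$")


class NetworkError(ValueError):
    """Referential-integrity or invariant violation in a network."""


# ---------------------------------------------------------------------------
# GPR / S-GPR abstract syntax trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprNode:
    """Node of a (stoichiometric) gene–protein–reaction rule.

    ``and`` children are subunits of one complex, ``or`` children are
    isoenzymes. Gene leaves carry ``protomer_count`` — how many copies of
    the gene product enter one active unit (1 when unknown). Stripping the
    counts yields the classical Boolean GPR.
    """

    node_kind: str  # gene | and | or
    gene_id: str = ""
    protomer_count: int = 1
    children: tuple["GprNode", ...] = ()

    def __post_init__(self) -> None:
        if self.node_kind == "gene":
            if not self.gene_id:
                raise ValueError("gene node requires gene_id")
            if self.children:
                raise ValueError("gene nodes are leaves")
            if self.protomer_count < 1:
                raise ValueError("protomer_count must be >= 1")
        elif self.node_kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.node_kind} node needs >= 2 children")
        else:
            raise ValueError(f"bad node_kind {self.node_kind!r}")

    def genes(self) -> Iterator["GprNode"]:
        if self.node_kind == "gene":
            yield self
        else:
            for ch in self.children:
                yield from ch.genes()

    def gene_ids(self) -> set[str]:
        return {leaf.gene_id for leaf in self.genes()}

    def strip_protomers(self) -> "GprNode":
        """Classical GPR: every leaf's protomer count reset to 1. Idempotent."""
        if self.node_kind == "gene":
            return replace(self, protomer_count=1)
        return replace(self, children=tuple(c.strip_protomers() for c in self.children))

    def to_string(self, with_protomers: bool = True) -> str:
        return _render(self, with_protomers, parent=None)


def gene_leaf(gene_id: str, protomers: int = 1) -> GprNode:
    return GprNode("gene", gene_id=gene_id, protomer_count=protomers)


def _variadic(kind: str, children: Iterable[GprNode]) -> GprNode:
    """Build an and/or node, flattening same-kind children; singleton passes through."""
    flat: list[GprNode] = []
    for ch in children:
        if ch.node_kind == kind:
            flat.extend(ch.children)
        else:
            flat.append(ch)
    if not flat:
        raise ValueError("empty child list")
    if len(flat) == 1:
        return flat[0]
    return GprNode(kind, children=tuple(flat))


def and_node(*children: GprNode) -> GprNode:
    return _variadic("and", children)


def or_node(*children: GprNode) -> GprNode:
    return _variadic("or", children)


def _render(node: GprNode, with_protomers: bool, parent: Optional[str]) -> str:
    if node.node_kind == "gene":
        if with_protomers and node.protomer_count != 1:
            return f"{node.protomer_count}*{node.gene_id}"
        return node.gene_id
    sep = f" {node.node_kind} "
    body = sep.join(_render(c, with_protomers, node.node_kind) for c in node.children)
    # parenthesize whenever nested under another junction: "a or (b and c)"
    if parent is not None:
        return f"({body})"
    return body


_GPR_TOKEN_RE = re.compile(r"\(|\)|\band\b|\bor\b|\d+\s*\*|[A-Za-z0-9_.:-]+")


class GprParseError(ValueError):
    pass


def parse_gpr(text: str) -> Optional[GprNode]:
    """Parse a GPR/S-GPR string in the ``k*GENE and/or`` dialect.

    ``and`` binds tighter than ``or``; parentheses group explicitly.
    Returns ``None`` for an empty rule. Raises :class:`GprParseError` on
    malformed input.
    """
    tokens = _GPR_TOKEN_RE.findall(text or "")
    if "".join(_GPR_TOKEN_RE.sub("", text or "").split()):
        raise GprParseError(f"unparseable characters in GPR {text!r}")
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprNode:
        parts = [parse_and()]
        while peek() == "or":
            take()
            parts.append(parse_and())
        return _variadic("or", parts) if len(parts) > 1 else parts[0]

    def parse_and() -> GprNode:
        parts = [parse_atom()]
        while peek() == "and":
            take()
            parts.append(parse_atom())
        return _variadic("and", parts) if len(parts) > 1 else parts[0]

    def parse_atom() -> GprNode:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprParseError(f"missing ')' in GPR {text!r}")
            take()
            return node
        take()
        if tok.endswith("*"):
            count = int(tok[:-1].strip())
            gene = peek()
            if gene in (None, "(", ")", "and", "or"):
                raise GprParseError(f"multiplier without gene in {text!r}")
            take()
            return gene_leaf(gene, count)
        if tok in (")", "and", "or"):
            raise GprParseError(f"misplaced {tok!r} in GPR {text!r}")
        return gene_leaf(tok)

    node = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR {text!r}")
    return node


# ---------------------------------------------------------------------------
# Entities
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteEntity:
    id: str
    name: str
    compartment_id: str
    composition: ElementComposition = field(default_factory=ElementComposition)
    synonyms: list[str] = field(default_factory=list)
    xrefs: dict[str, str] = field(default_factory=dict)

    def copy(self) -> "MetaboliteEntity":
        return MetaboliteEntity(
            self.id, self.name, self.compartment_id, self.composition,
            list(self.synonyms), dict(self.xrefs),
        )


@dataclass
class ReactionEntity:
    id: str
    name: str = ""
    substrates: dict[str, Fraction] = field(default_factory=dict)
    products: dict[str, Fraction] = field(default_factory=dict)
    reversible: bool = False
    ec_numbers: set[str] = field(default_factory=set)
    gpr: Optional[GprNode] = None
    xrefs: dict[str, str] = field(default_factory=dict)
    kind: str = "internal"

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"bad reaction kind {self.kind!r}")
        self.substrates = {m: Fraction(c) for m, c in self.substrates.items()}
        self.products = {m: Fraction(c) for m, c in self.products.items()}
        for side in (self.substrates, self.products):
            for m, c in side.items():
                if c <= 0:
                    raise ValueError(f"non-positive coefficient for {m} in {self.id}")

    @property
    def is_boundary(self) -> bool:
        return self.kind in ("exchange", "sink", "biomass")

    def participants(self) -> Iterator[tuple[str, str, Fraction]]:
        for m, c in self.substrates.items():
            yield m, "substrate", c
        for m, c in self.products.items():
            yield m, "product", c

    def copy(self) -> "ReactionEntity":
        return ReactionEntity(
            self.id, self.name, dict(self.substrates), dict(self.products),
            self.reversible, set(self.ec_numbers), self.gpr, dict(self.xrefs),
            self.kind,
        )


@dataclass
class GeneEntity:
    id: str
    symbol: str = ""
    xrefs: dict[str, str] = field(default_factory=dict)

    @property
    def ensembl(self) -> Optional[str]:
        return self.xrefs.get("Ensembl")

    def copy(self) -> "GeneEntity":
        return GeneEntity(self.id, self.symbol, dict(self.xrefs))


@dataclass
class Compartment:
    id: str
    name: str = ""
    go_term: Optional[str] = None

    def __post_init__(self) -> None:
        if self.go_term is not None and not _GO_RE.match(self.go_term):
            raise ValueError(f"bad GO accession {self.go_term!r}")

    def copy(self) -> "Compartment":
        return Compartment(self.id, self.name, self.go_term)


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

class MetabolicNetwork:
    """Keyed collections of metabolites, reactions, genes and compartments.

    ``add_*`` methods enforce uniqueness; :meth:`validate` checks the full
    set of cross-references (reaction participants exist, gene leaves of
    every GPR exist, compartments declared).
    """

    def __init__(self, id: str = "model") -> None:
        self.id = id
        self.metabolites: dict[str, MetaboliteEntity] = {}
        self.reactions: dict[str, ReactionEntity] = {}
        self.genes: dict[str, GeneEntity] = {}
        self.compartments: dict[str, Compartment] = {}
        self.provenance: dict[str, str] = {}

    # -- construction -------------------------------------------------
    def add_compartment(self, c: Compartment) -> Compartment:
        if c.id in self.compartments:
            raise NetworkError(f"duplicate compartment {c.id}")
        self.compartments[c.id] = c
        return c

    def add_metabolite(self, m: MetaboliteEntity) -> MetaboliteEntity:
        if m.id in self.metabolites:
            raise NetworkError(f"duplicate metabolite {m.id}")
        if m.compartment_id not in self.compartments:
            raise NetworkError(
                f"metabolite {m.id} references unknown compartment {m.compartment_id}"
            )
        self.metabolites[m.id] = m
        return m

    def add_gene(self, g: GeneEntity) -> GeneEntity:
        if g.id in self.genes:
            raise NetworkError(f"duplicate gene {g.id}")
        self.genes[g.id] = g
        return g

    def add_reaction(self, r: ReactionEntity) -> ReactionEntity:
        if r.id in self.reactions:
            raise NetworkError(f"duplicate reaction {r.id}")
        for mid, _, _ in r.participants():
            if mid not in self.metabolites:
                raise NetworkError(f"reaction {r.id} references unknown metabolite {mid}")
        if r.gpr is not None:
            for gid in r.gpr.gene_ids():
                if gid not in self.genes:
                    self.genes[gid] = GeneEntity(gid, symbol=gid)
        self.reactions[r.id] = r
        return r

    def remove_reaction(self, rid: str) -> None:
        del self.reactions[rid]

    # -- views ---------------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """(S, metabolite ids, reaction ids): substrates negative, products positive."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        idx = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            r = self.reactions[rid]
            for mid, c in r.substrates.items():
                S[idx[mid], j] -= float(c)
            for mid, c in r.products.items():
                S[idx[mid], j] += float(c)
        return S, met_ids, rxn_ids

    # -- integrity ------------------------------------------------------
    def validate(self) -> None:
        for m in self.metabolites.values():
            if m.compartment_id not in self.compartments:
                raise NetworkError(
                    f"metabolite {m.id}: unknown compartment {m.compartment_id}"
                )
        for r in self.reactions.values():
            for mid, _, _ in r.participants():
                if mid not in self.metabolites:
                    raise NetworkError(f"reaction {r.id}: unknown metabolite {mid}")
            if r.gpr is not None:
                for gid in r.gpr.gene_ids():
                    if gid not in self.genes:
                        raise NetworkError(f"reaction {r.id}: unknown gene {gid}")
        seen: dict[tuple[str, str, str], str] = {}
        for m in self.metabolites.values():
            for source, value in m.xrefs.items():
                key = (source, value, m.compartment_id)
                other = seen.get(key)
                if other is not None and other != m.id:
                    raise NetworkError(
                        f"metabolites {other} and {m.id} share xref "
                        f"{source}:{value} in compartment {m.compartment_id}"
                    )
                seen.setdefault(key, m.id)

    def copy(self) -> "MetabolicNetwork":
        n = MetabolicNetwork(self.id)
        n.compartments = {k: v.copy() for k, v in self.compartments.items()}
        n.metabolites = {k: v.copy() for k, v in self.metabolites.items()}
        n.genes = {k: v.copy() for k, v in self.genes.items()}
        n.reactions = {k: v.copy() for k, v in self.reactions.items()}
        n.provenance = dict(self.provenance)
        return n

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicNetwork {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes, "
            f"{len(self.compartments)} compartments>"
        )
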