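"""SBML level-3 (fbc v2) reading and writing.

Networks are serialized through python-libsbml. Standard content maps onto
native SBML/fbc constructs: species with charge and chemical formula,
reactions with speciesReferences and reversibility, gene products with a
classical fbc gene-product association.

Two curation extensions have no SBML home and ride in per-entity
annotations (a small key–value vocabulary under the ``gemcurate``
namespace):

* glycan-block formulas such as ``(Gal)2(GlcNAc)1`` — the fbc
  ``chemicalFormula`` attribute only admits plain element strings, so the
  full formula string is kept in the annotation (and ``chemicalFormula``
  is set additionally whenever the formula is plain);
* S-GPR strings in the ``k*GENE`` dialect, alongside the classical GPR in
  fbc, preserving COBRA compatibility;
* exact rational stoichiometries (floats in the native speciesReferences,
  exact fractions in the annotation).

Compartment membership is a field of the metabolite, not an id suffix;
SBML ids are sanitized forms of the internal ids with the original id
recorded in the annotation, so round-trips preserve arbitrary internal
naming (e.g. the ``met@comp`` instances created by isoenzyme expansion).
"""

from __future__ import annotations

import re
import warnings
from fractions import Fraction

import libsbml
from lxml import etree

from .formula import ElementComposition, format_formula, parse_formula
from .model import (
    Compartment,
    GeneEntity,
    GprNode,
    GprParseError,
    MetaboliteEntity,
    MetabolicNetwork,
    NetworkError,
    ReactionEntity,
    parse_gpr,
)

__all__ = ["read_sbml", "write_sbml", "SbmlError"]

NS = "https://gemcurate.dev/ns"


class SbmlError(ValueError):
    """Fatal SBML read/write failure."""


_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    s = _SID_BAD.sub("_", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return prefix + s


def _set_kv(sbase, data: dict[str, str]) -> None:
    if not data:
        return
    items = "".join(
        f'<gc:kv key="{_xml_escape(k)}" value="{_xml_escape(v)}"/>'
        for k, v in data.items()
    )
    sbase.setAnnotation(f'<gc:data xmlns:gc="{NS}">{items}</gc:data>')


def _xml_escape(s: str) -> str:
    return (
        s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _get_kv(sbase) -> dict[str, str]:
    if not sbase.isSetAnnotation():
        return {}
    xml = sbase.getAnnotationString()
    try:
        root = etree.fromstring(xml.encode())
    except etree.XMLSyntaxError:
        return {}
    out = {}
    for kv in root.iter(f"{{{NS}}}kv"):
        out[kv.get("key", "")] = kv.get("value", "")
    return out


def _encode_side(side: dict[str, Fraction]) -> str:
    return ";".join(f"{m}={c.numerator}/{c.denominator}" for m, c in side.items())


def _decode_side(text: str) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    if not text:
        return out
    for item in text.split(";"):
        m, _, frac = item.partition("=")
        out[m] = Fraction(frac)
    return out


_XREF_PREFIX = "xref:"


def _xref_kv(xrefs: dict[str, str]) -> dict[str, str]:
    return {_XREF_PREFIX + src: val for src, val in xrefs.items()}


def _kv_xrefs(kv: dict[str, str]) -> dict[str, str]:
    return {
        k[len(_XREF_PREFIX):]: v for k, v in kv.items() if k.startswith(_XREF_PREFIX)
    }


_PLAIN_FORMULA = re.compile(r"[A-Za-z0-9]*$")


# ---------------------------------------------------------------------------
# write
# ---------------------------------------------------------------------------

def write_sbml(network: MetabolicNetwork, path: str) -> None:
    """Serialize ``network`` to SBML L3V1 + fbc v2 at ``path``."""
    network.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(_sid("", network.id))
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)

    for comp in network.compartments.values():
        c = model.createCompartment()
        c.setId(_sid("", comp.id))
        c.setName(comp.name or comp.id)
        c.setConstant(True)
        kv = {"id": comp.id}
        if comp.go_term:
            kv["go"] = comp.go_term
        _set_kv(c, kv)

    met_sid: dict[str, str] = {}
    for met in network.metabolites.values():
        s = model.createSpecies()
        # compartment suffix applied only here, at export
        sid = _sid("M_", f"{met.id}_{met.compartment_id}")
        met_sid[met.id] = sid
        s.setId(sid)
        s.setName(met.name)
        s.setCompartment(_sid("", met.compartment_id))
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
        splug = s.getPlugin("fbc")
        splug.setCharge(met.composition.charge)
        formula = format_formula(
            ElementComposition(met.composition.counts, 0)
        )
        if formula and _PLAIN_FORMULA.match(formula):
            splug.setChemicalFormula(formula)
        kv = {"id": met.id, "formula": format_formula(met.composition)}
        if met.synonyms:
            kv["synonyms"] = "|".join(met.synonyms)
        kv.update(_xref_kv(met.xrefs))
        if met.id in network.provenance:
            kv["provenance"] = network.provenance[met.id]
        _set_kv(s, kv)

    for gene in network.genes.values():
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", gene.id))
        gp.setLabel(gene.id)
        gp.setName(gene.symbol or gene.id)
        kv = {"id": gene.id, "symbol": gene.symbol}
        kv.update(_xref_kv(gene.xrefs))
        _set_kv(gp, kv)

    for rxn in network.reactions.values():
        r = model.createReaction()
        r.setId(_sid("R_", rxn.id))
        r.setName(rxn.name)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for mid, coeff in rxn.substrates.items():
            ref = r.createReactant()
            ref.setSpecies(met_sid[mid])
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for mid, coeff in rxn.products.items():
            ref = r.createProduct()
            ref.setSpecies(met_sid[mid])
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        kv = {
            "id": rxn.id,
            "kind": rxn.kind,
            "substrates": _encode_side(rxn.substrates),
            "products": _encode_side(rxn.products),
        }
        if rxn.ec_numbers:
            kv["ec"] = "|".join(sorted(rxn.ec_numbers))
        if rxn.gpr is not None:
            kv["sgpr"] = rxn.gpr.to_string(with_protomers=True)
            rplug = r.getPlugin("fbc")
            gpa = rplug.createGeneProductAssociation()
            infix = rxn.gpr.strip_protomers().to_string(with_protomers=False)
            gpa.setAssociation(_sid_gpr(infix), True, True)
        kv.update(_xref_kv(rxn.xrefs))
        if rxn.id in network.provenance:
            kv["provenance"] = network.provenance[rxn.id]
        _set_kv(r, kv)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SbmlError(f"failed to write SBML to {path}")


def _sid_gpr(infix: str) -> str:
    # rewrite gene ids in an infix GPR to their sanitized fbc ids
    def repl(m: re.Match) -> str:
        tok = m.group(0)
        if tok in ("and", "or"):
            return tok
        return _sid("G_", tok)

    return re.sub(r"[A-Za-z0-9_.:@-]+", repl, infix)


# ---------------------------------------------------------------------------
# read
# ---------------------------------------------------------------------------

def read_sbml(path: str) -> MetabolicNetwork:
    """Load an SBML L3+fbc file into a :class:`MetabolicNetwork`.

    Unparseable GPR strings degrade to a warning (the reaction loads with
    no GPR); invalid SBML or dangling species references are fatal.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        log = doc.getErrorLog()
        fatal = [
            log.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if log.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        if fatal:
            raise SbmlError("invalid SBML: " + "; ".join(fatal))
    model = doc.getModel()
    if model is None:
        raise SbmlError(f"no model element in {path}")

    network = MetabolicNetwork(model.getId() or "model")

    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        kv = _get_kv(c)
        network.add_compartment(
            Compartment(kv.get("id", c.getId()), c.getName(), kv.get("go") or None)
        )

    sid_to_mid: dict[str, str] = {}
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        kv = _get_kv(s)
        comp_sid = s.getCompartment()
        comp_id = next(
            (c.id for c in network.compartments.values() if _sid("", c.id) == comp_sid),
            comp_sid,
        )
        if comp_id not in network.compartments:
            raise SbmlError(f"species {s.getId()} in undeclared compartment {comp_sid}")
        if "formula" in kv:
            comp = parse_formula(kv["formula"])
        else:
            splug = s.getPlugin("fbc")
            text = splug.getChemicalFormula() if splug is not None else ""
            comp = parse_formula(text or "")
            charge = (
                splug.getCharge()
                if splug is not None and splug.isSetCharge()
                else 0
            )
            comp = ElementComposition(comp.counts, charge)
        mid = kv.get("id", s.getId())
        sid_to_mid[s.getId()] = mid
        met = MetaboliteEntity(
            id=mid,
            name=s.getName() or mid,
            compartment_id=comp_id,
            composition=comp,
            synonyms=kv.get("synonyms", "").split("|") if kv.get("synonyms") else [],
            xrefs=_kv_xrefs(kv),
        )
        network.add_metabolite(met)
        if "provenance" in kv:
            network.provenance[mid] = kv["provenance"]

    mplug = model.getPlugin("fbc")
    gp_label: dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            kv = _get_kv(gp)
            gid = kv.get("id", gp.getLabel() or gp.getId())
            gp_label[gp.getId()] = gid
            network.add_gene(GeneEntity(gid, kv.get("symbol", ""), _kv_xrefs(kv)))

    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        kv = _get_kv(r)
        rid = kv.get("id", r.getId())
        if "substrates" in kv:
            substrates = _decode_side(kv["substrates"])
            products = _decode_side(kv["products"])
            for mid in list(substrates) + list(products):
                if mid not in network.metabolites:
                    raise SbmlError(f"reaction {rid}: dangling species reference {mid}")
        else:
            substrates, products = {}, {}
            for j in range(r.getNumReactants()):
                ref = r.getReactant(j)
                if ref.getSpecies() not in sid_to_mid:
                    raise SbmlError(
                        f"reaction {rid}: dangling species reference {ref.getSpecies()}"
                    )
                substrates[sid_to_mid[ref.getSpecies()]] = Fraction(
                    ref.getStoichiometry()
                ).limit_denominator(10**6)
            for j in range(r.getNumProducts()):
                ref = r.getProduct(j)
                if ref.getSpecies() not in sid_to_mid:
                    raise SbmlError(
                        f"reaction {rid}: dangling species reference {ref.getSpecies()}"
                    )
                products[sid_to_mid[ref.getSpecies()]] = Fraction(
                    ref.getStoichiometry()
                ).limit_denominator(10**6)

        gpr: GprNode | None = None
        if "sgpr" in kv:
            try:
                gpr = parse_gpr(kv["sgpr"])
            except GprParseError as exc:
                warnings.warn(f"reaction {rid}: unparseable GPR ({exc})")
        else:
            rplug = r.getPlugin("fbc")
            if rplug is not None and rplug.isSetGeneProductAssociation():
                assoc = rplug.getGeneProductAssociation().getAssociation()
                infix = assoc.toInfix() if assoc is not None else ""
                for fbc_id, gid in gp_label.items():
                    infix = re.sub(rf"\b{re.escape(fbc_id)}\b", gid, infix)
                try:
                    gpr = parse_gpr(infix)
                except GprParseError as exc:
                    warnings.warn(f"reaction {rid}: unparseable GPR ({exc})")

        rxn = ReactionEntity(
            id=rid,
            name=r.getName(),
            substrates=substrates,
            products=products,
            reversible=r.getReversible(),
            ec_numbers=set(kv["ec"].split("|")) if kv.get("ec") else set(),
            gpr=gpr,
            xrefs=_kv_xrefs(kv),
            kind=kv.get("kind", "internal"),
        )
        try:
            network.add_reaction(rxn)
        except NetworkError as exc:
            raise SbmlError(str(exc)) from exc
        if "provenance" in kv:
            network.provenance[rid] = kv["provenance"]

    network.validate()
    return network
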