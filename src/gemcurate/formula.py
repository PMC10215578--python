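"""Molecular formulas with glycan building blocks and generic groups.

Chemical formulas in metabolic models are Hill-style element strings
(``C6H12O6``) optionally followed by a charge suffix (``H+``, ``Fe2+``,
``PO4 3-`` without the space). Two extensions beyond plain chemistry are
needed for curating genome-scale models:

* *glycan building blocks* — monosaccharide-like units written as
  parenthesized named tokens with multiplicities, e.g. ``(Gal)2(GlcNAc)1``.
  Treating each block as a pseudo-atom lets glycan elongation reactions be
  mass-balanced with the same machinery as ordinary reactions.
* *generic groups* — the single-letter tokens ``R`` and ``X`` standing for
  unspecified moieties (acyl chains, halides, pools).

Charge is carried separately from the element counts so that formulas can
be neutralized (protonation-state adjustment) without losing information.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

__all__ = [
    "ElementComposition",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "GENERIC_GROUP_TOKENS",
]

#: IUPAC element symbols (118 elements).
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

#: Generic-group pseudo-elements. "R" doubles as an addable radical species.
GENERIC_GROUP_TOKENS = frozenset({"R", "X"})


class FormulaError(ValueError):
    """Raised for malformed formula strings; names the offending span."""


@dataclass(frozen=True)
class ElementComposition:
    """Element (or pseudo-element) counts plus net charge.

    ``counts`` maps element symbols, generic-group tokens or glycan-block
    names to non-negative rational counts. An empty map is the
    representation of a *missing* formula (metabolites with no annotated
    composition); ``is_missing`` distinguishes it from an explicit vacuum.
    """

    counts: Mapping[str, Fraction] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for token, n in dict(self.counts).items():
            n = Fraction(n)
            if n < 0:
                raise ValueError(f"negative count for {token!r}: {n}")
            if n != 0:
                clean[token] = n
        object.__setattr__(self, "counts", clean)

    # -- predicates ---------------------------------------------------
    @property
    def is_missing(self) -> bool:
        return not self.counts

    def has_glycan_blocks(self) -> bool:
        return any(
            t not in ELEMENT_SYMBOLS and t not in GENERIC_GROUP_TOKENS
            for t in self.counts
        )

    def has_generic_groups(self) -> bool:
        return any(t in GENERIC_GROUP_TOKENS for t in self.counts)

    def is_proton(self) -> bool:
        return dict(self.counts) == {"H": Fraction(1)} and self.charge == 1

    # -- arithmetic ---------------------------------------------------
    def scaled(self, k: Fraction) -> "ElementComposition":
        k = Fraction(k)
        return ElementComposition(
            {t: n * k for t, n in self.counts.items()}, self.charge
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementComposition):
            return NotImplemented
        return dict(self.counts) == dict(other.counts) and self.charge == other.charge

    def __hash__(self) -> int:
        return hash((frozenset(self.counts.items()), self.charge))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementComposition({format_formula(self)!r})"


_COUNT_RE = re.compile(r"\d+")
# unambiguous charge tail: sign alone or sign followed by digits
_CHARGE_TAIL_RE = re.compile(r"(?P<sign>[+-])(?P<digits>\d*)$")
# monoatomic-ion shorthand where digits precede the sign: H+, Ca2+, Fe3+
_ION_RE = re.compile(r"(?P<elem>[A-Z][a-z]?)(?P<digits>\d*)(?P<sign>[+-])$")


def parse_formula(text: str) -> ElementComposition:
    """Parse a Hill-style formula into an :class:`ElementComposition`.

    Accepts element tokens with optional integer multiplicities, generic
    groups ``R``/``X``, parenthesized glycan blocks ``(Gal)2``, and a
    trailing charge suffix — a bare sign (``C3H3O3-``) or sign followed by
    digits (``SO4-2``). Monoatomic ions may use the conventional
    digits-before-sign form (``Ca2+``). The empty string yields the
    missing-formula composition.
    """
    text = text.strip()
    if not text:
        return ElementComposition({}, 0)

    ion = _ION_RE.fullmatch(text)
    if ion and ion.group("elem") in ELEMENT_SYMBOLS:
        mag = int(ion.group("digits") or 1)
        return ElementComposition(
            {ion.group("elem"): Fraction(1)},
            mag * (1 if ion.group("sign") == "+" else -1),
        )

    charge = 0
    m = _CHARGE_TAIL_RE.search(text)
    if m:
        digits = m.group("digits")
        charge = (int(digits) if digits else 1) * (1 if m.group("sign") == "+" else -1)
        text = text[: m.start()]

    counts: dict[str, Fraction] = {}
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "(":
            close = text.find(")", i)
            if close < 0:
                raise FormulaError(f"unclosed '(' at position {i} in {text!r}")
            token = text[i + 1 : close]
            if not token or not re.fullmatch(r"[A-Za-z][A-Za-z0-9]*", token):
                raise FormulaError(
                    f"bad glycan-block token {token!r} at position {i}"
                )
            i = close + 1
        elif ch.isupper():
            # greedy two-letter element first, else one letter
            token = None
            if i + 1 < n and text[i : i + 2] in ELEMENT_SYMBOLS:
                token = text[i : i + 2]
                i += 2
            elif ch in ELEMENT_SYMBOLS or ch in GENERIC_GROUP_TOKENS:
                token = ch
                i += 1
            else:
                raise FormulaError(
                    f"unknown element {text[i:i+2]!r} at position {i} in {text!r}"
                )
        else:
            raise FormulaError(f"unexpected character {ch!r} at position {i} in {text!r}")
        cm = _COUNT_RE.match(text, i)
        if cm:
            count = Fraction(int(cm.group()))
            i = cm.end()
        else:
            count = Fraction(1)
        counts[token] = counts.get(token, Fraction(0)) + count
    return ElementComposition(counts, charge)


def _hill_key(token: str) -> tuple:
    # Hill order: C, H, then alphabetical; glycan blocks after elements.
    if token == "C":
        return (0, "")
    if token == "H":
        return (1, "")
    if token in ELEMENT_SYMBOLS or token in GENERIC_GROUP_TOKENS:
        return (2, token)
    return (3, token)


def format_formula(c: ElementComposition) -> str:
    """Render a composition back to a formula string (Hill token order).

    Glycan-block tokens are parenthesized; integer counts of 1 are omitted
    for plain elements but kept explicit for blocks (matching the
    ``(Gal)2(GlcNAc)1`` convention). Inverse of :func:`parse_formula` up
    to token ordering.
    """
    if c.is_missing:
        return ""
    parts = []
    for token in sorted(c.counts, key=_hill_key):
        count = c.counts[token]
        if count.denominator != 1:
            raise ValueError(
                f"cannot render fractional count {count} for {token!r}"
            )
        k = count.numerator
        if token in ELEMENT_SYMBOLS or token in GENERIC_GROUP_TOKENS:
            parts.append(token if k == 1 else f"{token}{k}")
        else:
            parts.append(f"({token}){k}")
    if c.charge:
        sign = "+" if c.charge > 0 else "-"
        mag = abs(c.charge)
        body = "".join(parts)
        if mag == 1 and not re.fullmatch(r"[A-Z][a-z]?\d+", body):
            parts.append(sign)
        else:
            # explicit digits: a bare sign after "Xn" would read as the
            # monoatomic-ion shorthand (charge n) on re-parse
            parts.append(f"{sign}{mag}")
    return "".join(parts)
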