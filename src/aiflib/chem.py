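"""Elemental-formula arithmetic and electrospray ion m/z computation.

Monoisotopic masses are fixed in code (IUPAC values) so that theoretical
m/z values are reproducible to the fourth decimal without an external
mass table: e.g. trigonelline C7H7NO2 has monoisotopic mass 137.0477 Da
and its protonated ion [M+H]+ sits at 138.0550 Th.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "C13_C12_DELTA",
    "ElementalFormula",
    "AdductDescriptor",
    "InChIKeyText",
    "parse_formula",
    "monoisotopic_mass",
    "parse_adduct",
    "adduct_mz",
    "isotope_mz",
    "inchikey_first_block",
]

#: Monoisotopic atomic masses in Da of the supported elements.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "S": 31.97207069,
    "P": 30.97376151,
    "Cl": 34.96885271,
}

ELECTRON_MASS = 0.00054858
#: Mass added by protonation of a neutral molecule (H minus one electron).
PROTON_MASS = ELEMENT_MASSES["H"] - ELECTRON_MASS
#: Mass difference between carbon-13 and carbon-12.
C13_C12_DELTA = 13.0033548378 - 12.0

# Hill order: C, then H, then the rest alphabetically.
_HILL_TAIL = sorted(e for e in ELEMENT_MASSES if e not in ("C", "H"))
_HILL_ORDER = ["C", "H"] + _HILL_TAIL

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or chemically unsupported formula text."""


class AdductError(ValueError):
    """Malformed adduct name or infeasible neutral loss."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> atom-count multiset, e.g. ``{"C": 7, "H": 7, "N": 1, "O": 2}``.

    Zero counts are dropped on construction; two formulas compare equal
    iff their count mappings are equal. The empty formula is permitted
    only as an adduct gain/loss placeholder (``allow_empty`` paths use
    the module-level helpers).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for sym, n in self.counts.items():
            if sym not in ELEMENT_MASSES:
                raise FormulaError(f"unsupported element symbol: {sym!r}")
            if n < 0:
                raise FormulaError(f"negative atom count for {sym}: {n}")
            if n > 0:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    # -- algebra ---------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            left = merged.get(sym, 0) - n
            if left < 0:
                raise AdductError(
                    f"loss of {sym}{n} exceeds available atoms in {self}"
                )
            merged[sym] = left
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({sym: n * k for sym, n in self.counts.items()})

    def contains(self, other: "ElementalFormula") -> bool:
        return all(self.counts.get(s, 0) >= n for s, n in other.counts.items())

    def get(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    @property
    def atom_count(self) -> int:
        return sum(self.counts.values())

    @property
    def is_empty(self) -> bool:
        return not self.counts

    def __str__(self) -> str:
        parts = []
        for sym in _HILL_ORDER:
            n = self.counts.get(sym, 0)
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalFormula({str(self)!r})"


EMPTY_FORMULA = ElementalFormula({})


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation element/count string, e.g. ``"C7H7NO2"``.

    Repeated element symbols accumulate. Raises :class:`FormulaError`
    on an empty string, an unknown symbol, or stray characters.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos or not m.group(0):
            break
        sym, digits = m.group(1), m.group(2)
        if sym not in ELEMENT_MASSES:
            raise FormulaError(f"unsupported element symbol: {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"could not parse formula {text!r} at position {pos}")
    f = ElementalFormula(counts)
    if f.atom_count < 1:
        raise FormulaError(f"formula {text!r} has no atoms")
    return f


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic (exact) mass in Da: sum of per-element masses."""
    return sum(ELEMENT_MASSES[sym] * n for sym, n in f.counts.items())


# -- adducts -------------------------------------------------------------

# Both the ASCII hyphen and U+2212 MINUS SIGN are accepted in adduct names.
_MINUS_CHARS = "-−"
_ADDUCT_RE = re.compile(
    r"^\[M((?:[+\-−]\d*[A-Za-z][A-Za-z0-9]*)*)\](\d?)([+\-−])$"
)
_GROUP_RE = re.compile(r"([+\-−])(\d*)([A-Za-z][A-Za-z0-9]*)")


@dataclass(frozen=True)
class AdductDescriptor:
    """An electrospray adduct: gained and lost atoms plus a signed charge.

    ``name`` is the canonical bracket notation, e.g. ``"[M+H]+"`` or
    ``"[M+H-2H2O]+"``; multipliers expand (``2H2O`` means two waters).
    """

    name: str
    charge: int
    gained: ElementalFormula = EMPTY_FORMULA
    lost: ElementalFormula = EMPTY_FORMULA

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise AdductError("adduct charge must be nonzero")

    @property
    def net_formula_shift(self) -> float:
        """Mass gained minus mass lost, in Da."""
        return monoisotopic_mass(self.gained) - monoisotopic_mass(self.lost)

    def __str__(self) -> str:
        return self.name


def parse_adduct(name: str) -> AdductDescriptor:
    """Parse bracket adduct notation like ``"[M+H]+"`` or ``"[M+H−2H2O]+"``.

    The trailing sign gives the charge sign; an optional digit before it
    gives |charge| (default 1). Returns a descriptor whose ``name`` is
    the canonical ASCII form, so ``parse(format(x)) == x``.
    """
    m = _ADDUCT_RE.match(name.strip())
    if m is None:
        raise AdductError(f"malformed adduct name: {name!r}")
    groups_text, mult, sign = m.group(1), m.group(2), m.group(3)
    charge_mag = int(mult) if mult else 1
    if charge_mag < 1 or charge_mag > 2:
        raise AdductError(f"unsupported charge magnitude {charge_mag} in {name!r}")
    charge = charge_mag if sign == "+" else -charge_mag

    gained = EMPTY_FORMULA
    lost = EMPTY_FORMULA
    canonical_parts = []
    for op, count_txt, group in _GROUP_RE.findall(groups_text):
        k = int(count_txt) if count_txt else 1
        piece = parse_formula(group) * k
        if op == "+":
            gained = gained + piece
            canonical_parts.append(f"+{count_txt}{group}")
        else:
            lost = lost + piece
            canonical_parts.append(f"-{count_txt}{group}")
    canonical = "[M{}]{}{}".format(
        "".join(canonical_parts), mult if charge_mag > 1 else "", "+" if charge > 0 else "-"
    )
    return AdductDescriptor(name=canonical, charge=charge, gained=gained, lost=lost)


def adduct_mz(f: ElementalFormula, a: AdductDescriptor) -> float:
    """Theoretical m/z (Th) of formula ``f`` ionized as adduct ``a``.

    m/z = (M + gained - lost - charge * m_e) / |charge|; losses that
    exceed the available atoms of the combined molecule raise
    :class:`AdductError`.
    """
    ion = (f + a.gained) - a.lost  # raises if the loss is infeasible
    if ion.atom_count < 1:
        raise AdductError(f"adduct {a.name} leaves no atoms on {f}")
    mass = monoisotopic_mass(f) + a.net_formula_shift - a.charge * ELECTRON_MASS
    return mass / abs(a.charge)


def isotope_mz(mz: float, n: int) -> float:
    """m/z of the n-th carbon-13 isotopologue peak (n = 0 is identity)."""
    if n < 0:
        raise ValueError(f"isotope index must be >= 0, got {n}")
    return mz + n * C13_C12_DELTA


# -- InChIKeys -----------------------------------------------------------

_IK_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


@dataclass(frozen=True)
class InChIKeyText:
    """A 27-character InChIKey (14-10-1 uppercase blocks).

    The first block hashes the molecular skeleton, which is why library
    records of the same compound are grouped on it.
    """

    value: str

    def __post_init__(self) -> None:
        if not _IK_RE.match(self.value):
            raise ValueError(f"invalid InChIKey structure: {self.value!r}")

    @property
    def first_block(self) -> str:
        return self.value[:14]

    def __str__(self) -> str:
        return self.value


def inchikey_first_block(k: InChIKeyText | str) -> str:
    """First 14 characters of the key (the molecular-skeleton block)."""
    if isinstance(k, str):
        k = InChIKeyText(k)
    return k.first_block
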