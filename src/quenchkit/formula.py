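"""Molecular formula parsing and average molecular weights.

Formulas are accepted in the loose typography found in synthesis papers
("C_25_ H_25_ NO", unicode subscripts, stray whitespace) as well as plain
Hill-style strings ("C25H25NO"), with parenthesized groups and integer
multipliers.  Average molecular weights come from a compiled table of
IUPAC 2021 conventional atomic weights (3-4 decimals), which is all the
precision the downstream green-chemistry metrics need; monoisotopic masses,
adducts and charge states are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "Formula",
    "FormulaError",
    "ATOMIC_MASS",
    "parse_formula",
    "molecular_weight",
    "carbon_count",
    "hill_formula",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


# All IUPAC element symbols, used to distinguish "unknown element" from
# "element without a tabulated mass".
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

# IUPAC 2021 conventional atomic weights (g/mol), abridged to the elements
# that occur in small-molecule organic chemistry.
ATOMIC_MASS: Mapping[str, float] = MappingProxyType(
    {
        "H": 1.008,
        "B": 10.81,
        "C": 12.011,
        "N": 14.007,
        "O": 15.999,
        "F": 18.998,
        "Na": 22.990,
        "Mg": 24.305,
        "Al": 26.982,
        "Si": 28.085,
        "P": 30.974,
        "S": 32.06,
        "Cl": 35.45,
        "K": 39.098,
        "Ca": 40.078,
        "Mn": 54.938,
        "Fe": 55.845,
        "Co": 58.933,
        "Ni": 58.693,
        "Cu": 63.546,
        "Zn": 65.38,
        "Se": 78.971,
        "Br": 79.904,
        "Sn": 118.710,
        "I": 126.904,
        "Li": 6.94,
    }
)

_SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


def _normalize(text: str) -> str:
    """Strip typography: whitespace, underscores, unicode subscripts, dots."""
    return (
        text.translate(_SUBSCRIPT_DIGITS)
        .replace("_", "")
        .replace("·", "")  # middle dot sometimes used in hydrates
        .replace(" ", "")
        .replace("\t", "")
        .strip()
    )


def _parse_counts(s: str) -> dict[str, int]:
    stack: list[dict[str, int]] = [{}]
    i, n = 0, len(s)
    while i < n:
        ch = s[i]
        if ch == "(":
            stack.append({})
            i += 1
        elif ch == ")":
            i += 1
            j = i
            while j < n and s[j].isdigit():
                j += 1
            mult = int(s[i:j]) if j > i else 1
            if mult == 0:
                raise FormulaError(f"zero group multiplier at position {i} in {s!r}")
            group = stack.pop()
            if not stack:
                raise FormulaError(f"unbalanced ')' in {s!r}")
            for el, cnt in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + cnt * mult
            i = j
        elif ch.isupper():
            j = i + 1
            if j < n and s[j].islower():
                j += 1
            sym = s[i:j]
            if sym not in ELEMENT_SYMBOLS:
                raise FormulaError(f"unknown element symbol {sym!r} in {s!r}")
            i = j
            j = i
            while j < n and s[j].isdigit():
                j += 1
            cnt = int(s[i:j]) if j > i else 1
            if cnt == 0:
                raise FormulaError(f"zero multiplier for {sym!r} in {s!r}")
            stack[-1][sym] = stack[-1].get(sym, 0) + cnt
            i = j
        else:
            raise FormulaError(f"unexpected character {ch!r} at position {i} in {s!r}")
    if len(stack) != 1:
        raise FormulaError(f"unbalanced '(' in {s!r}")
    counts = stack[0]
    if not counts:
        raise FormulaError("empty formula")
    return counts


def _hill_order(counts: Mapping[str, int]) -> list[str]:
    """Hill convention: C first, H second, then alphabetical; no carbon ->
    everything alphabetical."""
    elements = sorted(counts)
    if "C" in counts:
        ordered = ["C"] + (["H"] if "H" in counts else [])
        ordered += [e for e in elements if e not in ("C", "H")]
        return ordered
    return elements


@dataclass(frozen=True)
class Formula:
    """A parsed molecular formula: immutable element->count map."""

    source_text: str
    counts: Mapping[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", MappingProxyType(dict(self.counts)))

    def hill(self) -> str:
        """Canonical Hill-order serialization (C, H, then alphabetical)."""
        return "".join(
            f"{el}{self.counts[el]}" if self.counts[el] != 1 else el
            for el in _hill_order(self.counts)
        )

    def molecular_weight(self, mass_table: Mapping[str, float] | None = None) -> float:
        return molecular_weight(self, mass_table)

    @property
    def carbon_count(self) -> int:
        return self.counts.get("C", 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, cnt in other.counts.items():
            merged[el] = merged.get(el, 0) + cnt
        f = Formula(source_text="", counts=merged)
        return Formula(source_text=f.hill(), counts=merged)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return dict(self.counts) == dict(other.counts)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.hill())

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a molecular formula string into a :class:`Formula`.

    Raises :class:`FormulaError` on empty input, unknown element symbols,
    zero multipliers, or unbalanced parentheses.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    normalized = _normalize(text)
    if not normalized:
        raise FormulaError("empty formula string")
    return Formula(source_text=text, counts=_parse_counts(normalized))


def molecular_weight(
    f: Formula, mass_table: Mapping[str, float] | None = None
) -> float:
    """Average molecular weight (g/mol) as sum(count * atomic mass)."""
    table = ATOMIC_MASS if mass_table is None else mass_table
    try:
        return sum(cnt * table[el] for el, cnt in f.counts.items())
    except KeyError as exc:
        raise FormulaError(
            f"no atomic mass tabulated for element {exc.args[0]!r}"
        ) from None


def carbon_count(f: Formula) -> int:
    """Number of carbon atoms in the formula (0 if none)."""
    return f.carbon_count


def hill_formula(f: Formula) -> str:
    return f.hill()
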