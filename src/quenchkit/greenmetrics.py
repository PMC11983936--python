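"""Green-chemistry metrics for stoichiometric reaction specifications.

Implements the standard definitions of the five mass-based greenness
metrics usually reported for a bench-scale synthesis:

* atom economy          AE  = 100 * MW(product) / sum_i nu_i * MW(reactant_i)
* process mass intensity PMI = (total input mass) / (product mass)
* E-factor              E   = PMI - 1   (waste mass per product mass)
* reaction mass efficiency RME = 100 * product mass / sum(reactant masses)
* carbon efficiency     CE  = 100 * (mol product * C_product)
                              / sum_i (mol reactant_i * C_i)

plus percent yield from the limiting reactant.  AE depends only on the
balanced equation; the rest need the masses actually weighed in.  By default
PMI counts reactants and catalyst but not recycled solvent, so that a
solvent run in closed loop does not dominate the intensity.  An element
balance audit (with implicit condensation water inferred when byproducts are
not listed) is attached to every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formula import ATOMIC_MASS, Formula, molecular_weight, parse_formula

__all__ = [
    "Species",
    "ReactionSpec",
    "GreenMetricsReport",
    "SpecificationError",
    "atom_economy",
    "percent_yield",
    "reaction_mass_efficiency",
    "carbon_efficiency",
    "process_mass_intensity",
    "e_factor",
    "element_balance",
    "green_report",
    "DEFAULT_PMI_ROLES",
]

ROLES = ("reactant", "catalyst", "solvent", "workup")
DEFAULT_PMI_ROLES = frozenset({"reactant", "catalyst"})


class SpecificationError(ValueError):
    """A reaction specification lacks the data a metric requires."""


def _as_formula(value: Formula | str | None) -> Formula | None:
    if value is None or isinstance(value, Formula):
        return value
    return parse_formula(value)


@dataclass
class Species:
    """One input species: a reactant, catalyst, solvent or workup chemical."""

    name: str
    formula: Formula | None = None
    equivalents: float = 1.0
    mass_g: float | None = None
    role: str = "reactant"

    def __post_init__(self) -> None:
        self.formula = _as_formula(self.formula)
        if self.role not in ROLES:
            raise SpecificationError(
                f"role {self.role!r} for {self.name!r} not in {ROLES}"
            )
        if self.equivalents <= 0:
            raise SpecificationError(f"equivalents must be > 0 for {self.name!r}")
        if self.role == "reactant" and self.formula is None:
            raise SpecificationError(f"reactant {self.name!r} must carry a formula")
        if self.mass_g is not None and self.mass_g < 0:
            raise SpecificationError(f"negative mass for {self.name!r}")

    def moles(self, mass_table: Mapping[str, float] | None = None) -> float | None:
        if self.mass_g is None or self.formula is None:
            return None
        return self.mass_g / molecular_weight(self.formula, mass_table)


@dataclass
class ReactionSpec:
    """A stoichiometric reaction description.

    ``byproduct_formulas=None`` means "infer condensation water from the
    element balance"; pass an explicit (possibly empty) list to override.
    """

    reactants: list[Species]
    product_formula: Formula
    auxiliaries: list[Species] = field(default_factory=list)
    product_mass_g: float | None = None
    byproduct_formulas: list[Formula] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.product_formula = _as_formula(self.product_formula)
        if self.byproduct_formulas is not None:
            self.byproduct_formulas = [
                _as_formula(f) for f in self.byproduct_formulas
            ]
        if not self.reactants:
            raise SpecificationError("at least one reactant is required")
        for sp in self.reactants:
            if sp.role != "reactant":
                raise SpecificationError(
                    f"{sp.name!r} in reactants list has role {sp.role!r}"
                )

    def limiting_reactant(
        self, mass_table: Mapping[str, float] | None = None
    ) -> Species:
        """Reactant with the smallest moles/equivalents ratio."""
        best: tuple[float, Species] | None = None
        for sp in self.reactants:
            mol = sp.moles(mass_table)
            if mol is None:
                continue
            extent = mol / sp.equivalents
            if best is None or extent < best[0]:
                best = (extent, sp)
        if best is None:
            raise SpecificationError(
                "no reactant has both a mass and a formula; cannot find "
                "the limiting reactant"
            )
        return best[1]


def atom_economy(
    spec: ReactionSpec, mass_table: Mapping[str, float] | None = None
) -> float:
    """Atom economy in percent; yield- and mass-independent."""
    denom = 0.0
    for sp in spec.reactants:
        if sp.formula is None:
            raise SpecificationError(f"reactant {sp.name!r} has no formula")
        denom += sp.equivalents * molecular_weight(sp.formula, mass_table)
    return 100.0 * molecular_weight(spec.product_formula, mass_table) / denom


def percent_yield(
    spec: ReactionSpec, mass_table: Mapping[str, float] | None = None
) -> float:
    """Percent yield relative to the limiting reactant (product stoich 1)."""
    if spec.product_mass_g is None:
        raise SpecificationError("product mass not given; yield unavailable")
    limiting = spec.limiting_reactant(mass_table)
    theoretical_mol = limiting.moles(mass_table) / limiting.equivalents
    obtained_mol = spec.product_mass_g / molecular_weight(
        spec.product_formula, mass_table
    )
    return 100.0 * obtained_mol / theoretical_mol


def reaction_mass_efficiency(spec: ReactionSpec) -> float:
    """RME in percent: product mass over total reactant mass."""
    if spec.product_mass_g is None:
        raise SpecificationError("product mass not given; RME unavailable")
    total = 0.0
    for sp in spec.reactants:
        if sp.mass_g is None:
            raise SpecificationError(f"reactant {sp.name!r} has no mass; RME unavailable")
        total += sp.mass_g
    return 100.0 * spec.product_mass_g / total


def carbon_efficiency(
    spec: ReactionSpec, mass_table: Mapping[str, float] | None = None
) -> float:
    """CE in percent: product carbon moles over total reactant carbon moles."""
    if spec.product_mass_g is None:
        raise SpecificationError("product mass not given; CE unavailable")
    product_c = spec.product_formula.carbon_count
    n_product = spec.product_mass_g / molecular_weight(spec.product_formula, mass_table)
    denom = 0.0
    for sp in spec.reactants:
        mol = sp.moles(mass_table)
        if mol is None:
            raise SpecificationError(
                f"reactant {sp.name!r} needs mass and formula; CE unavailable"
            )
        denom += mol * sp.formula.carbon_count
    if denom == 0:
        raise SpecificationError("no carbon in any reactant; CE undefined")
    return 100.0 * n_product * product_c / denom


def _included_mass(spec: ReactionSpec, include_roles: frozenset[str]) -> float:
    total = 0.0
    for sp in list(spec.reactants) + list(spec.auxiliaries):
        if sp.role not in include_roles:
            continue
        if sp.mass_g is None:
            raise SpecificationError(
                f"{sp.role} {sp.name!r} has no mass; PMI/E-factor unavailable"
            )
        total += sp.mass_g
    return total


def process_mass_intensity(
    spec: ReactionSpec, include_roles: Iterable[str] = DEFAULT_PMI_ROLES
) -> float:
    """PMI: total included input mass per unit product mass (>= RME bound)."""
    if not spec.product_mass_g:
        raise SpecificationError("product mass missing or zero; PMI unavailable")
    return _included_mass(spec, frozenset(include_roles)) / spec.product_mass_g


def e_factor(
    spec: ReactionSpec, include_roles: Iterable[str] = DEFAULT_PMI_ROLES
) -> float:
    """E-factor: waste mass per product mass; equals PMI - 1 on the same basis."""
    return process_mass_intensity(spec, include_roles) - 1.0


def element_balance(spec: ReactionSpec) -> dict:
    """Audit sum(nu_i * reactant counts) - product - byproducts.

    When ``byproduct_formulas`` is None the residual is checked against
    k * H2O (condensation water); the audit passes if the residual is exactly
    water, reporting the inferred count.
    """
    residual: dict[str, int] = {}

    def add(counts: Mapping[str, int], scale: float) -> None:
        for el, cnt in counts.items():
            residual[el] = residual.get(el, 0) + round(scale * cnt)

    for sp in spec.reactants:
        add(sp.formula.counts, sp.equivalents)
    add(spec.product_formula.counts, -1)
    inferred_water = None
    if spec.byproduct_formulas is not None:
        for f in spec.byproduct_formulas:
            add(f.counts, -1)
    residual = {el: c for el, c in residual.items() if c != 0}
    if spec.byproduct_formulas is None:
        h, o = residual.get("H", 0), residual.get("O", 0)
        if set(residual) <= {"H", "O"} and o > 0 and h == 2 * o:
            inferred_water = o
            residual = {}
    return {
        "balanced": not residual,
        "residual": residual,
        "inferred_water": inferred_water,
    }


@dataclass
class GreenMetricsReport:
    """The metric bundle for one reaction; uncomputable fields are None and
    the reason is listed in ``flags``."""

    name: str
    ae: float
    pmi: float | None = None
    ce: float | None = None
    rme: float | None = None
    e_factor: float | None = None
    yield_pct: float | None = None
    balance: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "AE": self.ae,
            "PMI": self.pmi,
            "CE": self.ce,
            "RME": self.rme,
            "E_factor": self.e_factor,
            "yield_pct": self.yield_pct,
            "element_balance": self.balance,
            "flags": list(self.flags),
        }

    def format_table(self) -> str:
        """One-decimal formatted row, matching how these tables are printed."""
        def fmt(x: float | None, nd: int = 1) -> str:
            return "-" if x is None else f"{x:.{nd}f}"

        header = f"{'Compound':<10}{'Yield%':>8}{'AE':>8}{'PMI':>8}{'CE':>8}{'RME':>8}{'E-factor':>10}"
        row = (
            f"{self.name or '-':<10}{fmt(self.yield_pct):>8}{fmt(self.ae):>8}"
            f"{fmt(self.pmi, 3):>8}{fmt(self.ce):>8}{fmt(self.rme):>8}{fmt(self.e_factor, 3):>10}"
        )
        return header + "\n" + row


def green_report(
    spec: ReactionSpec,
    mass_table: Mapping[str, float] | None = None,
    include_roles: Iterable[str] = DEFAULT_PMI_ROLES,
) -> GreenMetricsReport:
    """Compute every metric the specification supports; flag the rest."""
    table = ATOMIC_MASS if mass_table is None else mass_table
    report = GreenMetricsReport(name=spec.name, ae=atom_economy(spec, table))
    report.balance = element_balance(spec)
    if not report.balance["balanced"]:
        report.flags.append(f"element balance residual: {report.balance['residual']}")

    for attr, fn in (
        ("yield_pct", lambda: percent_yield(spec, table)),
        ("rme", lambda: reaction_mass_efficiency(spec)),
        ("ce", lambda: carbon_efficiency(spec, table)),
        ("pmi", lambda: process_mass_intensity(spec, include_roles)),
    ):
        try:
            setattr(report, attr, fn())
        except SpecificationError as exc:
            report.flags.append(f"{attr} unavailable: {exc}")
    if report.pmi is not None:
        report.e_factor = report.pmi - 1.0
    if report.yield_pct is not None and report.yield_pct > 100.0 + 1e-9:
        report.flags.append("yield exceeds 100%: check masses")
    if not (0.0 < report.ae <= 100.0 + 1e-9):
        report.flags.append("atom economy outside (0, 100]: check stoichiometry")
    return report
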