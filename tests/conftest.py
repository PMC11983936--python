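"""Shared fixtures: published characterization numbers and reaction builders.

The photophysical table (per-solvent absorption/emission maxima and molar
absorptivities of the acridine fluorophore) and the HRMS lines of the nine
synthesized products are frozen here as reference inputs for the tests.
"""

import pytest

from quenchkit.greenmetrics import ReactionSpec, Species

# solvent -> (short abs band nm, long abs band nm, emission nm, epsilon/1e4)
PHOTOPHYS_TABLE = {
    "Toluene": (291, 354, 430, 0.7409),
    "DCM": (268, 367, 434, 1.4883),
    "THF": (281, 363, 445, 3.9495),
    "ACN": (250, 358, 445, 1.5107),
    "DMF": (267, 367, 457, 1.4883),
    "DMSO": (263, 370, 462, 1.3464),
}

# (compound, formula, printed HRMS m/z, adduct sign: +1 for [M+H]+, -1 for [M-H]+)
HRMS_LINES = [
    ("3a", "C25H25NO", 356.2014, +1),
    ("3b", "C25H24ClNO", 390.1610, +1),
    ("3c", "C25H23Cl2NO", 424.1235, +1),
    ("3d", "C25H24N2O3", 401.1866, +1),
    ("3e", "C25H26N2O", 371.2079, +1),
    ("4a", "C38H32N2", 517.2630, +1),
    ("4b", "C38H30Cl2N2", 585.1867, +1),
    ("4c", "C38H28Cl4N2", 653.1075, -1),
    ("4d", "C38H30N4O4", 607.2344, +1),
]

# compound -> (aminoketone formula, its equivalents, product formula)
FRIEDLANDER_REACTIONS = {
    "3a": ("C13H11NO", 1, "C25H25NO"),
    "3b": ("C13H10ClNO", 1, "C25H24ClNO"),
    "3c": ("C13H9Cl2NO", 1, "C25H23Cl2NO"),
    "3d": ("C13H10N2O3", 1, "C25H24N2O3"),
    "4a": ("C13H11NO", 2, "C38H32N2"),
    "4b": ("C13H10ClNO", 2, "C38H30Cl2N2"),
    "4c": ("C13H9Cl2NO", 2, "C38H28Cl4N2"),
    "4d": ("C13H10N2O3", 2, "C38H30N4O4"),
}

DIONE = "C12H18O2"


def make_friedlander_spec(compound: str, masses: tuple | None = None) -> ReactionSpec:
    """Balanced condensation spec; ``masses`` = (amino_g, dione_g, product_g)."""
    amino_formula, equiv, product = FRIEDLANDER_REACTIONS[compound]
    amino_g = dione_g = product_g = None
    if masses is not None:
        amino_g, dione_g, product_g = masses
    return ReactionSpec(
        reactants=[
            Species("aminoketone", amino_formula, equivalents=equiv, mass_g=amino_g),
            Species("bicyclohexanedione", DIONE, equivalents=1, mass_g=dione_g),
        ],
        product_formula=product,
        product_mass_g=product_g,
        name=compound,
    )


@pytest.fixture
def friedlander_spec():
    return make_friedlander_spec
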