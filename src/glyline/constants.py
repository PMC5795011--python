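"""Monoisotopic constants shared across the package.

All masses are monoisotopic and in Da. Amino-acid residue masses come from
pyteomics but are restricted to the 20 standard letters: pyteomics also
assigns masses to O (pyrrolysine), U (selenocysteine) and J (Leu/Ile),
which would collide with the glycan letter codes used here.
"""

from pyteomics import mass as _pmass

PROTON: float = 1.007276
WATER: float = 18.010565

CARBAMIDOMETHYL: float = 57.02146  # fixed, on C
OXIDATION: float = 15.99491       # variable, on M
FUCOSE: float = 146.0579          # variable, on O (HexNAc)

STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

AA_RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in STANDARD_AA
}

#: Letters that may never be reused as glycan codes: the 20 amino acids plus
#: the hard-coded ambiguity letters B, X and Z.
RESERVED_LETTERS: frozenset[str] = frozenset(STANDARD_AA) | frozenset("BXZ")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula such as ``C8H13NO5``."""
    return float(_pmass.calculate_mass(formula=formula))
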