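"""Mass arithmetic and theoretical b/y ions over the mixed glycan+peptide alphabet.

A glycopeptide form is a database entry plus a concrete placement of
variable modifications (fucose on specific O residues, oxidation on specific
M residues); carbamidomethylation of cysteine is applied implicitly as a
fixed modification. Because the glycan is a linear N-terminal prefix, the
glycosidic Y-ladder of the real spectrum appears as the high-ordinal part of
the theoretical y series, and the glycan prefix b1-b3 reproduce the oxonium
ions (HexNAc 204.087, HexNAc-Hex 366.140, HexNAc-Hex-Neu5Ac 657.235 for
N-glycans). b ions that extend past b3 span the glycan/peptide junction and
are not observed in practice, so scoring uses only the y series and the b1-b3
prefix by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .constants import (
    AA_RESIDUE_MASS,
    CARBAMIDOMETHYL,
    FUCOSE,
    OXIDATION,
    PROTON,
    WATER,
)
from .database import GlycoPeptideEntry
from .glycans import GlycanAlphabet, default_alphabet

__all__ = [
    "ModificationDef",
    "GlycoPeptideForm",
    "TheoreticalIon",
    "neutral_mass",
    "precursor_mz",
    "fragment_ions",
    "scored_ions",
    "enumerate_fucoforms",
]

#: Fragments above this neutral mass also get a 2+ variant.
DOUBLE_CHARGE_MIN_MASS = 900.0


@dataclass(frozen=True)
class ModificationDef:
    name: str
    delta_mass: float
    target: str
    kind: Literal["fixed", "variable"]

    def __post_init__(self) -> None:
        if len(self.target) != 1:
            raise ValueError("target must be a single residue letter")
        if not np.isfinite(self.delta_mass):
            raise ValueError("delta_mass must be finite")


CARBAMIDOMETHYL_C = ModificationDef("Carbamidomethyl", CARBAMIDOMETHYL, "C", "fixed")
OXIDATION_M = ModificationDef("Oxidation", OXIDATION, "M", "variable")
FUCOSE_O = ModificationDef("Fucose", FUCOSE, "O", "variable")


@dataclass(frozen=True)
class GlycoPeptideForm:
    """A database entry with concrete variable-modification placements.

    Positions are 0-based indices into ``full_sequence``. The core HexNAc is
    the peptide-adjacent O, i.e. the last glycan residue: fucose there is
    "core" fucosylation, fucose on any other O is "antenna".
    """

    entry: GlycoPeptideEntry
    fucose_positions: tuple[int, ...] = ()
    oxidation_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seq = self.full_sequence
        if len(set(self.fucose_positions)) != len(self.fucose_positions):
            raise ValueError("duplicate fucose positions")
        if len(set(self.oxidation_positions)) != len(self.oxidation_positions):
            raise ValueError("duplicate oxidation positions")
        for i in self.fucose_positions:
            if seq[i] != "O":
                raise ValueError(f"fucose position {i} is {seq[i]!r}, not O")
        for i in self.oxidation_positions:
            if seq[i] != "M":
                raise ValueError(f"oxidation position {i} is {seq[i]!r}, not M")

    @property
    def full_sequence(self) -> str:
        return self.entry.full_sequence

    @property
    def n_fucose(self) -> int:
        return len(self.fucose_positions)

    @property
    def core_o_index(self) -> int:
        """Index of the peptide-adjacent (core) O; -1 if the glycan has no O."""
        return self.entry.glycan.sequence.rfind("O")

    def has_core_fucose(self) -> bool:
        return self.core_o_index in self.fucose_positions


@dataclass(frozen=True)
class TheoreticalIon:
    series: Literal["b", "y"]
    ordinal: int
    charge: int
    mz: float
    spans_glycan: bool


def _position_masses(form: GlycoPeptideForm, alphabet: GlycanAlphabet) -> np.ndarray:
    """Residue mass at every position of full_sequence, mods included."""
    seq = form.full_sequence
    n_gly = len(form.entry.glycan)
    masses = np.empty(len(seq))
    for i, ch in enumerate(seq):
        if i < n_gly:
            masses[i] = alphabet.residue_mass(ch)
        else:
            try:
                masses[i] = AA_RESIDUE_MASS[ch]
            except KeyError:
                raise ValueError(f"no residue mass defined for {ch!r}") from None
            if ch == "C":
                masses[i] += CARBAMIDOMETHYL
    for i in form.fucose_positions:
        masses[i] += FUCOSE
    for i in form.oxidation_positions:
        masses[i] += OXIDATION
    return masses


def neutral_mass(form: GlycoPeptideForm, alphabet: GlycanAlphabet | None = None) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas."""
    alphabet = alphabet or default_alphabet()
    return float(_position_masses(form, alphabet).sum() + WATER)


def precursor_mz(form: GlycoPeptideForm, z: int, alphabet: GlycanAlphabet | None = None) -> float:
    """(M + z·H+)/z for charge state z >= 1."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass(form, alphabet) + z * PROTON) / z


def fragment_ions(
    form: GlycoPeptideForm,
    charges: Sequence[int] = (1, 2),
    alphabet: GlycanAlphabet | None = None,
    double_charge_min_mass: float = DOUBLE_CHARGE_MIN_MASS,
) -> list[TheoreticalIon]:
    """All b and y ions of the full sequence at the requested charges.

    b_i = sum of the first i residues + proton; y_i = sum of the last i
    residues + water + proton. 2+ variants are emitted only for fragments
    whose neutral mass exceeds ``double_charge_min_mass`` (large
    glycan-retaining y ions are routinely doubly charged; small fragments
    are not). ``spans_glycan`` marks fragments containing >= 1 glycan residue.
    """
    alphabet = alphabet or default_alphabet()
    masses = _position_masses(form, alphabet)
    n = len(masses)
    n_gly = len(form.entry.glycan)
    prefix = np.cumsum(masses)
    total = prefix[-1]
    ions: list[TheoreticalIon] = []
    n_pep = n - n_gly
    for i in range(1, n):
        b_neutral = float(prefix[i - 1])  # residue sum; proton added per charge
        y_neutral = float(total - prefix[i - 1] + WATER)
        # a b_i ion contains glycan residues iff the glycan prefix is non-empty;
        # a y ion does iff it reaches past the peptide into the prefix.
        candidates = (
            ("b", i, b_neutral, n_gly > 0),
            ("y", n - i, y_neutral, (n - i) > n_pep),
        )
        for series, ordinal, neutral, spans in candidates:
            for z in charges:
                if z not in (1, 2):
                    continue
                if z == 2 and neutral <= double_charge_min_mass:
                    continue
                ions.append(
                    TheoreticalIon(
                        series=series,
                        ordinal=ordinal,
                        charge=z,
                        mz=(neutral + z * PROTON) / z,
                        spans_glycan=spans,
                    )
                )
    return ions


def scored_ions(
    form: GlycoPeptideForm,
    alphabet: GlycanAlphabet | None = None,
    max_b_ordinal: int = 3,
) -> list[TheoreticalIon]:
    """The ion subset used for matching and scoring.

    All y ions (1+, and 2+ above the double-charge threshold) plus the
    glycan-prefix b ions up to ``max_b_ordinal`` (the oxonium b1-b3).
    b ions that extend past the oxonium prefix span the glycan/peptide
    junction and are excluded: with the glycan prepended, genuine peptide
    b ions cannot be represented and are not observed in the linearized
    coordinate system.
    """
    n_gly = len(form.entry.glycan)
    limit = min(max_b_ordinal, n_gly)
    out = []
    for ion in fragment_ions(form, alphabet=alphabet):
        if ion.series == "y" or ion.ordinal <= limit:
            out.append(ion)
    return out


def enumerate_fucoforms(
    entry: GlycoPeptideEntry, max_fucose: int = 2, max_oxidation: int = 1
) -> list[GlycoPeptideForm]:
    """Every placement of <= max_fucose fucoses and <= max_oxidation oxidations.

    Fucose may sit on any O residue of the full sequence (eligible peptides
    contain no O, so in practice these are the glycan HexNAcs); oxidation on
    any M. The unmodified form is always included and comes first.
    """
    if max_fucose < 0 or max_oxidation < 0:
        raise ValueError("modification limits must be >= 0")
    seq = entry.full_sequence
    o_pos = [i for i, c in enumerate(seq) if c == "O"]
    m_pos = [i for i, c in enumerate(seq) if c == "M"]
    forms = []
    for k in range(0, max_fucose + 1):
        for fuc in itertools.combinations(o_pos, k):
            for j in range(0, max_oxidation + 1):
                for oxi in itertools.combinations(m_pos, j):
                    forms.append(
                        GlycoPeptideForm(
                            entry=entry, fucose_positions=fuc, oxidation_positions=oxi
                        )
                    )
    return forms
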