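"""Monosaccharide alphabet and linearized glycan sequences.

Monosaccharides are encoded as extra single-letter residue codes so that a
glycan can be written as a linear sequence and prepended to a peptide, turning
glycosidic Y-type cleavages into ordinary peptide y ions. The default alphabet
uses the three Latin letters left free once the 20 amino acids and the
hard-coded B, X, Z are excluded:

====  ====================  ============
code  residue               mass (Da)
====  ====================  ============
O     N-acetylhexosamine    203.0794
J     hexose (Gal, Man)     162.0528
U     Neu5Ac (sialic acid)  291.0954
====  ====================  ============

Fucose (deoxyhexose, +146.0579 Da) is not a residue letter but a variable
modification on O, which is what lets core- versus antenna-fucosylated forms
be distinguished after a search.

Residue masses are condensation (water-free) residues, exactly like
amino-acid residue masses, so peptide mass arithmetic extends unchanged to
the mixed glycan+peptide alphabet.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .constants import FUCOSE, RESERVED_LETTERS, formula_mass

__all__ = [
    "MonosaccharideDef",
    "GlycanAlphabet",
    "LinearGlycan",
    "GlycanLibrary",
    "InvalidGlycanError",
    "default_alphabet",
    "parse_linear_glycan",
    "glycan_composition",
    "glycan_mass",
    "canonical_sialylated_sequence",
    "generate_sialylated_library",
]


class InvalidGlycanError(ValueError):
    """A glycan sequence contains a character outside the alphabet."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"invalid glycan residue {char!r} at position {position}: "
            "not a code in the monosaccharide alphabet"
        )


@dataclass(frozen=True)
class MonosaccharideDef:
    """One monosaccharide residue letter.

    ``residue_mass`` is the monoisotopic condensation-residue mass in Da.
    When ``elemental_composition`` is given it is cross-checked against the
    stated mass to 1e-3 Da (tables print four decimals).
    """

    code: str
    name: str
    residue_mass: float
    elemental_composition: str | None = None

    def __post_init__(self) -> None:
        if len(self.code) != 1 or not self.code.isupper():
            raise ValueError(f"code must be a single uppercase letter, got {self.code!r}")
        if self.code in RESERVED_LETTERS:
            raise ValueError(
                f"code {self.code!r} collides with an amino-acid letter or B/X/Z"
            )
        if not self.residue_mass > 0:
            raise ValueError("residue_mass must be positive")
        if self.elemental_composition is not None:
            exact = formula_mass(self.elemental_composition)
            if abs(exact - self.residue_mass) > 1e-3:
                raise ValueError(
                    f"residue_mass {self.residue_mass} deviates from "
                    f"{self.elemental_composition} ({exact:.5f}) by more than 1e-3 Da"
                )


@dataclass(frozen=True)
class GlycanAlphabet:
    """A set of monosaccharide codes plus variable-monosaccharide deltas.

    ``variable_monosaccharides`` maps a modification name to a
    ``(delta_mass, target_code)`` pair, e.g. ``{"Fucose": (146.0579, "O")}``.
    """

    defs: tuple[MonosaccharideDef, ...]
    variable_monosaccharides: dict[str, tuple[float, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = [d.code for d in self.defs]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate monosaccharide codes")

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(d.code for d in self.defs)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def residue_mass(self, code: str) -> float:
        for d in self.defs:
            if d.code == code:
                return d.residue_mass
        raise KeyError(code)

    def get(self, code: str) -> MonosaccharideDef:
        for d in self.defs:
            if d.code == code:
                return d
        raise KeyError(code)


@dataclass(frozen=True)
class LinearGlycan:
    """A linearized glycan written prefix-first.

    The rightmost character is the residue attached to the peptide
    N-terminus (the core HexNAc for N-glycans); the leftmost characters form
    the b1/b2/b3 oxonium prefix.
    """

    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GlycanLibrary:
    """An ordered collection of uniquely named, unique-sequence glycans."""

    entries: list[LinearGlycan] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [g.name for g in self.entries]
        seqs = [g.sequence for g in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("glycan names must be unique within a library")
        if len(set(seqs)) != len(seqs):
            raise ValueError("glycan sequences must be unique within a library")

    def __iter__(self) -> Iterator[LinearGlycan]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> LinearGlycan:
        for g in self.entries:
            if g.name == name:
                return g
        raise KeyError(name)

    # -- plain-text round trip -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write ``name<TAB>sequence`` lines, UTF-8."""
        lines = ["# glyline glycan library: name<TAB>sequence"]
        lines += [f"{g.name}\t{g.sequence}" for g in self.entries]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path, alphabet: "GlycanAlphabet | None" = None) -> "GlycanLibrary":
        """Read a library file; '#' comment lines and blank lines are ignored."""
        alphabet = alphabet or default_alphabet()
        entries = []
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, _, seq = line.partition("\t")
            if not seq:
                raise ValueError(f"malformed library line (expected name<TAB>sequence): {raw!r}")
            entries.append(parse_linear_glycan(seq.strip(), alphabet, name=name.strip()))
        return cls(entries)


def default_alphabet() -> GlycanAlphabet:
    """The O/J/U alphabet with fucose as a variable monosaccharide on O."""
    return GlycanAlphabet(
        defs=(
            MonosaccharideDef("O", "N-acetylhexosamine", 203.0794, "C8H13NO5"),
            MonosaccharideDef("J", "Hexose", 162.0528, "C6H10O5"),
            MonosaccharideDef("U", "Neu5Ac", 291.0954, "C11H17NO8"),
        ),
        variable_monosaccharides={"Fucose": (FUCOSE, "O")},
    )


def parse_linear_glycan(
    text: str, alphabet: GlycanAlphabet | None = None, name: str | None = None
) -> LinearGlycan:
    """Validate ``text`` against the alphabet and wrap it as a LinearGlycan.

    Raises InvalidGlycanError naming the offending character and its 1-based
    position on the first residue outside the alphabet.
    """
    if not text:
        raise ValueError("glycan sequence must be non-empty")
    alphabet = alphabet or default_alphabet()
    for i, ch in enumerate(text, start=1):
        if ch not in alphabet:
            raise InvalidGlycanError(ch, i)
    return LinearGlycan(name=name if name is not None else text, sequence=text)


def glycan_composition(g: LinearGlycan) -> dict[str, int]:
    """Residue counts of a glycan; order-invariant, counts sum to len(g)."""
    return dict(Counter(g.sequence))


def glycan_mass(
    g: LinearGlycan, n_fucose: int = 0, alphabet: GlycanAlphabet | None = None
) -> float:
    """Sum of residue masses plus ``n_fucose`` fucose deltas.

    There is no water term: residue masses are condensation residues and the
    single water of the final glycopeptide belongs to the peptide backbone.
    The empty glycan has mass 0 (internal convenience).
    """
    alphabet = alphabet or default_alphabet()
    if n_fucose < 0:
        raise ValueError("n_fucose must be >= 0")
    if n_fucose:
        delta, target = alphabet.variable_monosaccharides["Fucose"]
        n_targets = g.sequence.count(target)
        if n_fucose > n_targets:
            raise ValueError(
                f"n_fucose={n_fucose} exceeds the {n_targets} {target} residues in {g.sequence!r}"
            )
    else:
        delta = 0.0
    return sum(alphabet.residue_mass(c) for c in g.sequence) + n_fucose * delta


# -- canonical sialylated N-glycan grammar ------------------------------------

_SIA_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra"}
_ANT_NAMES = {2: "bi", 3: "tri", 4: "tetra"}


def canonical_sialylated_sequence(antennae: int, sialylation: int) -> str:
    """Linear sequence of a complex-type sialylated N-glycan.

    Layout (left = furthest from the peptide):

    * one sialylated antenna written core-to-terminal, ``OJU`` — its prefixes
      reproduce the intense oxonium ions b1 (HexNAc), b2 (HexNAc-Hex) and
      b3 (HexNAc-Hex-Neu5Ac);
    * each remaining antenna written terminal-to-core, sialylated antennae
      (``UJO``) before asialo ones (``JO``), so successive y ions strip
      terminal residues in glycosidic-loss order;
    * the trimannosyl core ``JJJ``;
    * the chitobiose core ``OO``, whose final O attaches to the peptide.

    For the di-sialylated biantennary case this yields ``OJUUJOJJJOO``.
    """
    if not 2 <= antennae <= 4:
        raise ValueError("antennae must be in 2..4")
    if not 1 <= sialylation <= antennae:
        raise ValueError("sialylation must be in 1..antennae")
    return "OJU" + "UJO" * (sialylation - 1) + "JO" * (antennae - sialylation) + "JJJ" + "OO"


def generate_sialylated_library(
    antennae: Iterable[int] = (2, 3, 4), with_names: bool = True
) -> GlycanLibrary:
    """All (antennae, sialylation) combinations of the canonical grammar.

    The default range yields the nine mono- to tetra-sialylated bi-, tri- and
    tetra-antennary structures (2+3+4 combinations).
    """
    entries = []
    for a in antennae:
        for s in range(1, a + 1):
            seq = canonical_sialylated_sequence(a, s)
            name = (
                f"{_SIA_NAMES[s]}-sialylated {_ANT_NAMES[a]}antennary"
                if with_names
                else seq
            )
            entries.append(LinearGlycan(name=name, sequence=seq))
    return GlycanLibrary(entries)
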