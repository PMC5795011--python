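"""Custom glycoprotein/glycopeptide database construction.

Every retained peptide is combined with every glycan of the library; the
glycan sequence is prepended to the peptide N-terminus so the glycosidic
Y-ladder of the glycopeptide becomes the ordinary y-ion series of one linear
sequence. The combined entries are written as FASTA, either peptide-centric
(one record per glycopeptide, the default) or protein-centric (one record
per protein, its glycopeptides concatenated).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

from .digest import PeptideRecord, ProteinRecord, filter_peptides, tryptic_digest
from .constants import CARBAMIDOMETHYL, OXIDATION
from .glycans import GlycanAlphabet, GlycanLibrary, LinearGlycan, MonosaccharideDef

__all__ = [
    "GlycoPeptideEntry",
    "DatabaseStats",
    "build_database",
    "write_fasta",
    "read_fasta_entries",
    "export_mod_definitions",
    "read_alphabet_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlycoPeptideEntry:
    """One candidate: a glycan prepended to an eligible peptide.

    ``site_position`` is the primary (first) glycosylation site, 1-based
    within the peptide; ``site_positions`` lists them all. A peptide with
    several sequons still yields a single entry per glycan — the linear
    sequence is identical regardless of which sequon carries the glycan.
    """

    parent_accession: str
    peptide: PeptideRecord
    glycan: LinearGlycan
    site_position: int
    site_positions: tuple[int, ...]
    is_decoy: bool = False

    @property
    def full_sequence(self) -> str:
        return self.glycan.sequence + self.peptide.sequence

    @property
    def entry_id(self) -> str:
        return (
            f"{self.parent_accession}|{self.peptide.start}-{self.peptide.end}"
            f"|site{self.site_position}|{self.glycan.name}"
        )


@dataclass(frozen=True)
class DatabaseStats:
    n_proteins_in: int
    n_proteins_with_candidates: int
    n_glycopeptide_entries: int
    n_residues_total: int


def build_database(
    proteins: Sequence[ProteinRecord],
    library: GlycanLibrary,
    mode: Literal["N", "O"] = "N",
    centric: Literal["protein", "peptide"] = "peptide",
    min_len: int = 5,
    max_len: int = 30,
    missed_cleavages: int = 0,
    keil_rule: bool = True,
) -> tuple[list[GlycoPeptideEntry], DatabaseStats]:
    """Digest, filter and combine: one entry per (retained peptide x glycan).

    Entries are ordered by accession, then peptide start, then library order,
    so identical inputs give identical databases. An input with no eligible
    peptide yields an empty database with a warning, not an error.
    """
    if not proteins:
        raise ValueError("no input proteins")
    if not len(library):
        raise ValueError("empty glycan library")
    entries: list[GlycoPeptideEntry] = []
    proteins_with = 0
    for protein in sorted(proteins, key=lambda p: p.accession):
        peptides = tryptic_digest(protein, missed_cleavages, keil_rule)
        eligible = filter_peptides(peptides, min_len, max_len, require_site=mode)
        if eligible:
            proteins_with += 1
        for pep in eligible:
            sites = pep.n_sites if mode == "N" else pep.o_sites
            for glycan in library:
                entries.append(
                    GlycoPeptideEntry(
                        parent_accession=protein.accession,
                        peptide=pep,
                        glycan=glycan,
                        site_position=sites[0],
                        site_positions=tuple(sites),
                    )
                )
    if not entries:
        logger.warning("no eligible peptides: database is empty")
    stats = DatabaseStats(
        n_proteins_in=len(proteins),
        n_proteins_with_candidates=proteins_with,
        n_glycopeptide_entries=len(entries),
        n_residues_total=sum(len(e.full_sequence) for e in entries),
    )
    return entries, stats


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(
    entries: Sequence[GlycoPeptideEntry],
    path: str | Path,
    centric: Literal["protein", "peptide"] = "peptide",
) -> None:
    """Write the database as FASTA with 60-column sequence lines.

    peptide-centric: one record per entry, header
    ``>{accession}|{start}-{end}|site{site}|{glycan_name}``.
    protein-centric: one record per accession; the sequences of all its
    entries are concatenated into a single record.
    """
    lines: list[str] = []
    if centric == "peptide":
        for e in entries:
            lines.append(f">{e.entry_id}")
            lines.append(_wrap(e.full_sequence))
    elif centric == "protein":
        by_acc: dict[str, list[GlycoPeptideEntry]] = {}
        for e in entries:
            by_acc.setdefault(e.parent_accession, []).append(e)
        for acc, group in by_acc.items():
            lines.append(f">{acc} {len(group)} glycopeptides")
            lines.append(_wrap("".join(e.full_sequence for e in group)))
    else:
        raise ValueError("centric must be 'protein' or 'peptide'")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_database(path: str | Path, library: GlycanLibrary) -> list[GlycoPeptideEntry]:
    """Reconstruct entries from a peptide-centric database FASTA.

    The header grammar ``accession|start-end|siteN|glycan_name`` carries
    everything except the glycan/peptide boundary, which is resolved by
    looking the glycan name up in ``library``.
    """
    from .digest import find_n_glycosites, find_o_glycosites

    entries = []
    for header, seq in read_fasta_entries(path):
        acc, span, site, glycan_name = header.split("|", 3)
        glycan = library.get(glycan_name)
        if not seq.startswith(glycan.sequence):
            raise ValueError(
                f"record {header!r}: sequence does not start with glycan {glycan_name!r}"
            )
        pep_seq = seq[len(glycan.sequence):]
        start, _, end = span.partition("-")
        pep = PeptideRecord(
            parent_accession=acc,
            start=int(start),
            end=int(end),
            sequence=pep_seq,
            n_sites=tuple(find_n_glycosites(pep_seq)),
            o_sites=tuple(find_o_glycosites(pep_seq)),
        )
        primary = int(site.removeprefix("site"))
        sites = pep.n_sites if primary in pep.n_sites else pep.o_sites
        entries.append(
            GlycoPeptideEntry(
                parent_accession=acc,
                peptide=pep,
                glycan=glycan,
                site_position=primary,
                site_positions=tuple(sites) or (primary,),
            )
        )
    return entries


def read_fasta_entries(path: str | Path) -> list[tuple[str, str]]:
    """Read back a written database as (header, sequence) pairs."""
    pairs: list[tuple[str, str]] = []
    header, chunks = None, []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith(">"):
            if header is not None:
                pairs.append((header, "".join(chunks)))
            header, chunks = line[1:], []
        elif line.strip():
            chunks.append(line.strip())
    if header is not None:
        pairs.append((header, "".join(chunks)))
    return pairs


# -- modification / residue definition export ---------------------------------

_STANDARD_MODS: list[tuple[str, float, str, str]] = [
    ("Carbamidomethyl", CARBAMIDOMETHYL, "C", "fixed"),
    ("Oxidation", OXIDATION, "M", "variable"),
]


def export_mod_definitions(
    alphabet: GlycanAlphabet, xml_path: str | Path, tsv_path: str | Path
) -> None:
    """Write the alphabet as a unimod-style XML fragment plus a TSV.

    The XML fragment lists each residue letter with its monoisotopic mass and
    each modification (fucose on O, oxidation on M, carbamidomethyl on C) in
    a shape suitable for merging into a search engine's unimod.xml; bit-exact
    patching of a real unimod.xml is out of scope. The TSV carries the same
    data and round-trips through :func:`read_alphabet_tsv`.
    """
    mods = list(_STANDARD_MODS)
    for name, (delta, target) in alphabet.variable_monosaccharides.items():
        mods.insert(0, (name, delta, target, "variable"))

    root = ET.Element("glycan_residue_definitions")
    residues = ET.SubElement(root, "residues")
    for d in alphabet.defs:
        attrs = {"code": d.code, "title": d.name, "mono_mass": f"{d.residue_mass:.4f}"}
        if d.elemental_composition:
            attrs["composition"] = d.elemental_composition
        ET.SubElement(residues, "residue", attrs)
    modifications = ET.SubElement(root, "modifications")
    for name, delta, target, kind in mods:
        ET.SubElement(
            modifications,
            "mod",
            {"title": name, "delta_mono_mass": f"{delta:.5f}", "site": target, "kind": kind},
        )
    ET.indent(root)
    ET.ElementTree(root).write(xml_path, encoding="unicode", xml_declaration=True)

    lines = ["# kind\tcode_or_name\tname_or_target\tmass\tcomposition_or_kind"]
    for d in alphabet.defs:
        lines.append(
            f"residue\t{d.code}\t{d.name}\t{d.residue_mass!r}\t{d.elemental_composition or ''}"
        )
    for name, delta, target, kind in mods:
        lines.append(f"modification\t{name}\t{target}\t{delta!r}\t{kind}")
    Path(tsv_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_alphabet_tsv(path: str | Path) -> GlycanAlphabet:
    """Reconstruct a GlycanAlphabet from an exported TSV."""
    defs: list[MonosaccharideDef] = []
    variable: dict[str, tuple[float, str]] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, a, b, mass, extra = line.split("\t")
        if kind == "residue":
            defs.append(MonosaccharideDef(a, b, float(mass), extra or None))
        elif kind == "modification" and extra == "variable" and a not in ("Oxidation",):
            if b in {d.code for d in defs}:
                variable[a] = (float(mass), b)
    return GlycanAlphabet(defs=tuple(defs), variable_monosaccharides=variable)
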