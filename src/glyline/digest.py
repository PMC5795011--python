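"""In-silico tryptic digestion and glycosylation-site scanning.

Digestion follows trypsin specificity (cleavage C-terminal of K/R) with the
Keil rule (no cleavage before proline) applied by default, matching the
behaviour of mainstream search engines. Peptides are then scanned for the
N-glycosylation sequon N-x-T/S/C and for S/T residues (potential O-sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .constants import STANDARD_AA

__all__ = [
    "ProteinRecord",
    "PeptideRecord",
    "read_fasta",
    "tryptic_digest",
    "find_n_glycosites",
    "find_o_glycosites",
    "filter_peptides",
]

logger = logging.getLogger(__name__)

_STANDARD = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession}: empty sequence")


@dataclass(frozen=True)
class PeptideRecord:
    """A tryptic peptide with 1-based inclusive parent coordinates."""

    parent_accession: str
    start: int
    end: int
    sequence: str
    n_sites: tuple[int, ...] = field(default=())
    o_sites: tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA; accession = first header token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                accession=rec.id,
                description=rec.description,
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def _cleavage_points(sequence: str, keil_rule: bool) -> list[int]:
    """0-based indices *after* which trypsin cleaves."""
    points = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and not (keil_rule and sequence[i + 1] == "P"):
            points.append(i)
    return points


def tryptic_digest(
    protein: ProteinRecord, missed_cleavages: int = 0, keil_rule: bool = True
) -> list[PeptideRecord]:
    """Tryptic peptides of ``protein`` with up to ``missed_cleavages``.

    With 0 missed cleavages the peptides tile the protein exactly. Each
    peptide carries its N- and O-site positions (1-based within the peptide).
    """
    seq = protein.sequence
    cuts = [-1] + _cleavage_points(seq, keil_rule) + [len(seq) - 1]
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            start0, end0 = cuts[i] + 1, cuts[j]  # 0-based inclusive
            pep = seq[start0 : end0 + 1]
            peptides.append(
                PeptideRecord(
                    parent_accession=protein.accession,
                    start=start0 + 1,
                    end=end0 + 1,
                    sequence=pep,
                    n_sites=tuple(find_n_glycosites(pep)),
                    o_sites=tuple(find_o_glycosites(pep)),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def _seq_of(pep: "PeptideRecord | str") -> str:
    return pep.sequence if isinstance(pep, PeptideRecord) else pep


def find_n_glycosites(pep: "PeptideRecord | str", exclude_proline: bool = False) -> list[int]:
    """1-based positions of N in N-x-T/S/C sequons within the peptide.

    ``exclude_proline`` switches to the strict N-[^P]-[TSC] form; by default
    the x position is unrestricted.
    """
    seq = _seq_of(pep)
    sites = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 2] in "TSC":
            if exclude_proline and seq[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def find_o_glycosites(pep: "PeptideRecord | str") -> list[int]:
    """1-based positions of every S and T residue (candidate O-sites)."""
    seq = _seq_of(pep)
    return [i + 1 for i, aa in enumerate(seq) if aa in "ST"]


def filter_peptides(
    peptides: Iterable[PeptideRecord],
    min_len: int = 5,
    max_len: int = 30,
    require_site: str = "N",
) -> list[PeptideRecord]:
    """Keep peptides in the length window that carry at least one site.

    Peptides containing non-standard letters (B, J, O, U, X, Z) are dropped
    with a warning: those letters either collide with glycan codes or have
    no defined residue mass.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    if require_site not in ("N", "O"):
        raise ValueError("require_site must be 'N' or 'O'")
    kept = []
    for pep in peptides:
        if not min_len <= len(pep) <= max_len:
            continue
        if not set(pep.sequence) <= _STANDARD:
            bad = sorted(set(pep.sequence) - _STANDARD)
            logger.warning(
                "peptide %s %d-%d excluded: non-standard letters %s",
                pep.parent_accession, pep.start, pep.end, "".join(bad),
            )
            continue
        sites = pep.n_sites if require_site == "N" else pep.o_sites
        if sites:
            kept.append(pep)
    return kept
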