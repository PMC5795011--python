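"""Shared fixtures: alphabets, toy proteomes and glycopeptide forms.

All randomized inputs are generated here with fixed seeds; no data files
are shipped.
"""

from __future__ import annotations

import numpy as np
import pytest

from glyline import (
    GlycoPeptideForm,
    ProteinRecord,
    build_database,
    default_alphabet,
    generate_sialylated_library,
)

#: Amino-acid pool biased toward cleavage sites and sequons so that random
#: proteins yield a healthy number of eligible glycopeptides.
_AA_POOL = list("ACDEFGHIKLMNPQRSTVWYKRNNSTT")


@pytest.fixture(scope="session")
def alphabet():
    return default_alphabet()


@pytest.fixture(scope="session")
def library():
    return generate_sialylated_library()


@pytest.fixture(scope="session")
def toy_proteins():
    """Two handcrafted proteins with known tryptic N-glycopeptides."""
    return [
        ProteinRecord("P1", "P1 test", "MKQDQCIYNTTYLNVQRENGTISRLLNDSRVVNKTEWFK"),
        ProteinRecord("P2", "P2 test", "MAAANLTKGFDNMTKWWNVSHRK"),
    ]


@pytest.fixture(scope="session")
def toy_entries(toy_proteins, library):
    entries, _ = build_database(toy_proteins, library, mode="N")
    return entries


@pytest.fixture(scope="session")
def biantennary_form(toy_entries):
    """Unmodified di-sialylated biantennary glycopeptide QDQCIYNTTYLNVQR."""
    entry = next(
        e
        for e in toy_entries
        if e.peptide.sequence == "QDQCIYNTTYLNVQR"
        and e.glycan.sequence == "OJUUJOJJJOO"
    )
    return GlycoPeptideForm(entry=entry)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_POOL, size=length))


def random_proteome(seed: int, n_proteins: int, length: int = 120) -> list[ProteinRecord]:
    rng = np.random.default_rng(seed)
    return [
        ProteinRecord(f"RND{i:03d}", f"random protein {i}", random_protein(rng, length))
        for i in range(n_proteins)
    ]


@pytest.fixture(scope="session")
def random_entries(library):
    """A database of >= 200 glycopeptide entries from a random proteome."""
    proteins = random_proteome(seed=2024, n_proteins=18)
    entries, _ = build_database(proteins, library, mode="N")
    assert len(entries) >= 200
    return entries
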