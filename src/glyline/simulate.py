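"""Seedable generator of stepped-NCE-like composite glycopeptide MS2 spectra.

Stepped collision energy combines, in one composite spectrum, the
low-energy regime (dominated by the glycosidic Y-ladder: the intact peptide
plus a shrinking glycan), the high-energy regime (peptide-backbone y ions)
and the low-mass oxonium ions. The generator emits each regime as a peak
class with a fixed relative intensity, jitters m/z values with Gaussian
noise, and adds uniform random noise peaks kept clear of true peaks so that
ground truth stays unambiguous. It is a testing instrument: it makes no
attempt at physical fragmentation-efficiency modeling or isotope envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .database import GlycoPeptideEntry, build_database
from .digest import ProteinRecord
from .fragments import GlycoPeptideForm, neutral_mass, precursor_mz, scored_ions
from .glycans import GlycanAlphabet, GlycanLibrary, default_alphabet
from .spectra import Spectrum, write_mgf

__all__ = ["SimulationConfig", "simulate_spectrum", "make_fixture_dataset"]

#: Precursors heavier than this are simulated as 3+, lighter ones as 2+.
CHARGE3_MASS_THRESHOLD = 3000.0

#: Noise peaks are kept at least this far (Da) from every true peak.
NOISE_EXCLUSION_DA = 0.1


def _default_intensities() -> dict[str, float]:
    return {"oxonium": 100.0, "ladder": 60.0, "backbone": 30.0, "noise_max": 10.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the composite-spectrum generator.

    The three ``include_*`` switches select fragmentation regimes:
    glycosidic ladder (low NCE), peptide backbone (high NCE) and oxonium
    ions; the stepped-NCE composite is all three, which is the default.
    """

    seed: int = 0
    include_glycosidic_ladder: bool = True
    include_peptide_backbone: bool = True
    include_oxonium: bool = True
    mz_jitter_sd: float = 0.005
    n_noise_peaks: int = 30
    noise_mz_range: tuple[float, float] = (200.0, 2000.0)
    intensity_profile: dict[str, float] = field(default_factory=_default_intensities)

    def __post_init__(self) -> None:
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be >= 0")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")


def simulate_spectrum(
    form: GlycoPeptideForm,
    cfg: SimulationConfig,
    spectrum_id: str | None = None,
    rng: np.random.Generator | None = None,
    alphabet: GlycanAlphabet | None = None,
) -> tuple[Spectrum, dict]:
    """One composite MS2 spectrum of ``form`` plus its ground-truth record.

    True peaks are the scored theoretical ions of the form, partitioned into
    oxonium (glycan-prefix b1-b3), glycosidic-ladder (glycan-spanning y) and
    backbone (peptide-only y) classes; each class is included per the config
    flags. Deterministic for a fixed seed.
    """
    alphabet = alphabet or default_alphabet()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    profile = cfg.intensity_profile
    peaks: list[tuple[float, float]] = []
    for ion in scored_ions(form, alphabet):
        if ion.series == "b":
            cls, keep = "oxonium", cfg.include_oxonium
        elif ion.spans_glycan:
            cls, keep = "ladder", cfg.include_glycosidic_ladder
        else:
            cls, keep = "backbone", cfg.include_peptide_backbone
        if not keep:
            continue
        jitter = rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd else 0.0
        peaks.append((ion.mz + jitter, profile[cls]))
    true_mz = np.array([mz for mz, _ in peaks]) if peaks else np.empty(0)
    lo, hi = cfg.noise_mz_range
    n_added = 0
    while n_added < cfg.n_noise_peaks:
        mz = float(rng.uniform(lo, hi))
        if len(true_mz) and np.abs(true_mz - mz).min() < NOISE_EXCLUSION_DA:
            continue
        peaks.append((mz, float(rng.uniform(1.0, profile["noise_max"]))))
        n_added += 1
    mass = neutral_mass(form, alphabet)
    charge = 3 if mass > CHARGE3_MASS_THRESHOLD else 2
    sid = spectrum_id or f"sim|{form.entry.entry_id}|fuc{form.n_fucose}"
    spectrum = Spectrum(
        spectrum_id=sid,
        precursor_mz=precursor_mz(form, charge, alphabet),
        charge=charge,
        peaks=np.array(peaks).reshape(-1, 2),
    )
    if form.n_fucose == 0:
        fucose_class = "none"
    elif form.has_core_fucose():
        fucose_class = "core"
    else:
        fucose_class = "antenna"
    truth = {
        "spectrum_id": sid,
        "entry_id": form.entry.entry_id,
        "peptide": form.entry.peptide.sequence,
        "glycan_name": form.entry.glycan.name,
        "glycan_sequence": form.entry.glycan.sequence,
        "fucose_positions": ";".join(map(str, form.fucose_positions)),
        "oxidation_positions": ";".join(map(str, form.oxidation_positions)),
        "fucose_class": fucose_class,
        "charge": charge,
        "precursor_mz": spectrum.precursor_mz,
    }
    return spectrum, truth


def sample_forms(
    entries: Sequence[GlycoPeptideEntry],
    n: int,
    rng: np.random.Generator,
    fucose_fraction: float = 0.5,
) -> list[GlycoPeptideForm]:
    """Draw ``n`` forms from database entries, a fraction carrying one fucose.

    The fucose position is drawn uniformly over the glycan's O residues, so
    core- and antenna-fucosylated forms both occur.
    """
    forms = []
    for idx in rng.integers(0, len(entries), size=n):
        entry = entries[int(idx)]
        o_pos = [i for i, c in enumerate(entry.glycan.sequence) if c == "O"]
        if o_pos and rng.random() < fucose_fraction:
            fuc = (int(rng.choice(o_pos)),)
        else:
            fuc = ()
        forms.append(GlycoPeptideForm(entry=entry, fucose_positions=fuc))
    return forms


def make_fixture_dataset(
    proteins: Sequence[ProteinRecord],
    library: GlycanLibrary,
    n_spectra: int,
    cfg: SimulationConfig,
    out_dir: str | Path,
    mode: str = "N",
    fucose_fraction: float = 0.5,
) -> tuple[Path, Path, list[GlycoPeptideForm]]:
    """Simulate an MGF fixture with a ground-truth TSV.

    Forms are sampled from the database built from ``proteins`` x
    ``library``; one spectrum is simulated per form. Returns the MGF path,
    the truth-table path and the sampled forms.
    """
    if n_spectra < 1:
        raise ValueError("n_spectra must be >= 1")
    entries, _ = build_database(proteins, library, mode=mode)
    if not entries:
        raise ValueError("empty database: no eligible peptides")
    rng = np.random.default_rng(cfg.seed)
    forms = sample_forms(entries, n_spectra, rng, fucose_fraction)
    spectra, truths = [], []
    for i, form in enumerate(forms):
        spec, truth = simulate_spectrum(
            form, cfg, spectrum_id=f"sim_{i:04d}|{form.entry.entry_id}", rng=rng
        )
        spectra.append(spec)
        truths.append(truth)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mgf_path = out_dir / "spectra.mgf"
    truth_path = out_dir / "truth.tsv"
    write_mgf(spectra, mgf_path)
    pd.DataFrame(truths).to_csv(truth_path, sep="\t", index=False)
    return mgf_path, truth_path, forms
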