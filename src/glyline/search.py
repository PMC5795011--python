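"""Spectrum-to-glycopeptide matching, scoring, filtering and reporting.

This is an open stand-in for the commercial search stage: candidates are
selected by precursor mass (ppm tolerance), their scored theoretical ions
(y series + oxonium b1-b3) are matched against the peak list at a Da
tolerance, and each candidate receives an ion score of -10*log10(p), where p
is the binomial survival probability of matching at least as many ions by
chance. The numeric score is calibrated as a p-value bound, not as a clone
of any proprietary score; the conventional acceptance rules (score >= 25,
top-ranked match per spectrum, match probability < 0.001) are applied as
filters.

Fucose placement is read off the spectrum after acceptance: a peak 146.0579
Da above the peptide+HexNAc (Y1) ion marks core fucosylation, while a Y1
peak without that companion but with fucose-carrying larger y ions marks
antenna fucosylation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import FUCOSE, PROTON
from .database import GlycoPeptideEntry
from .digest import PeptideRecord, find_n_glycosites, find_o_glycosites
from .fragments import (
    DOUBLE_CHARGE_MIN_MASS,
    GlycoPeptideForm,
    TheoreticalIon,
    fragment_ions,
    neutral_mass,
    precursor_mz,
    scored_ions,
)
from .glycans import GlycanAlphabet, default_alphabet, glycan_composition
from .spectra import Spectrum

__all__ = [
    "PeakMatch",
    "GlycoPSM",
    "select_candidates",
    "match_peaks",
    "match_probability",
    "score_psm",
    "evaluate_candidate",
    "search_spectra",
    "rank_and_filter",
    "classify_fucose_site",
    "build_decoys",
    "summarize_by_composition",
    "write_report",
]

MAX_SCORE = 300.0


@dataclass(frozen=True)
class PeakMatch:
    ion: TheoreticalIon
    observed_mz: float
    intensity: float
    error_da: float


@dataclass
class GlycoPSM:
    """A scored glycopeptide-spectrum match."""

    spectrum_id: str
    form: GlycoPeptideForm
    score: float
    match_p: float
    n_matched_y: int
    n_matched_b: int
    precursor_error_ppm: float
    rank: int = 0
    fucose_class: Literal[
        "core", "antenna", "undetermined", "not_applicable"
    ] = "not_applicable"

    @property
    def is_decoy(self) -> bool:
        return self.form.entry.is_decoy


def select_candidates(
    spectrum: Spectrum,
    db: Sequence[GlycoPeptideForm],
    ppm: float = 10.0,
    alphabet: GlycanAlphabet | None = None,
    neutral_masses: np.ndarray | None = None,
) -> list[GlycoPeptideForm]:
    """Forms whose precursor m/z at the spectrum's charge lies within ±ppm.

    ``neutral_masses`` may carry precomputed neutral masses aligned with
    ``db`` to avoid recomputation across spectra.
    """
    if spectrum.charge is None:
        raise ValueError(f"spectrum {spectrum.spectrum_id}: charge unknown")
    z = spectrum.charge
    if neutral_masses is None:
        neutral_masses = np.array([neutral_mass(f, alphabet) for f in db])
    theo_mz = (neutral_masses + z * PROTON) / z
    err_ppm = (spectrum.precursor_mz - theo_mz) / theo_mz * 1e6
    return [f for f, e in zip(db, err_ppm) if abs(e) <= ppm]


def match_peaks(
    spectrum: Spectrum, ions: Sequence[TheoreticalIon], tol_da: float = 0.05
) -> list[PeakMatch]:
    """Greedy one-to-one assignment of peaks to theoretical ions.

    Peaks are visited in descending intensity; each peak is assigned to the
    closest still-unmatched ion within ±tol_da, so every ion receives at most
    its single most-intense compatible peak and every peak is consumed at
    most once.
    """
    if not ions or not len(spectrum.peaks):
        return []
    order = sorted(range(len(ions)), key=lambda i: ions[i].mz)
    ion_mz = [ions[i].mz for i in order]
    taken = [False] * len(ions)
    matches: list[PeakMatch] = []
    for p in np.argsort(-spectrum.intensity, kind="stable"):
        mz, inten = spectrum.peaks[p]
        lo = bisect.bisect_left(ion_mz, mz - tol_da)
        hi = bisect.bisect_right(ion_mz, mz + tol_da)
        best, best_err = -1, tol_da + 1.0
        for j in range(lo, hi):
            if taken[j]:
                continue
            err = abs(mz - ion_mz[j])
            if err < best_err:
                best, best_err = j, err
        if best >= 0:
            taken[best] = True
            ion = ions[order[best]]
            matches.append(
                PeakMatch(
                    ion=ion,
                    observed_mz=float(mz),
                    intensity=float(inten),
                    error_da=float(mz - ion.mz),
                )
            )
    return matches


def match_probability(
    matches: Sequence[PeakMatch],
    spectrum: Spectrum,
    ions_scored: Sequence[TheoreticalIon],
    tol_da: float = 0.05,
) -> float:
    """P(matching >= k of n scored ions by chance) under a binomial model.

    The per-ion chance probability q = 2*tol_da*density, with density
    estimated as the number of observed peaks inside the scored m/z range
    divided by the range width.
    """
    n = len(ions_scored)
    if n == 0:
        return 1.0
    k = len(matches)
    if k == 0:
        return 1.0
    mzs = [ion.mz for ion in ions_scored]
    lo, hi = min(mzs) - tol_da, max(mzs) + tol_da
    width = max(hi - lo, 2.0 * tol_da)
    in_range = int(np.count_nonzero((spectrum.mz >= lo) & (spectrum.mz <= hi)))
    q = 2.0 * tol_da * (in_range / width)
    q = min(max(q, 1e-12), 1.0 - 1e-12)
    return float(stats.binom.sf(k - 1, n, q))


def score_psm(
    matches: Sequence[PeakMatch],
    spectrum: Spectrum,
    ions_scored: Sequence[TheoreticalIon],
    tol_da: float = 0.05,
) -> float:
    """Ion score: -10*log10 of the chance-match probability, capped at 300."""
    p = match_probability(matches, spectrum, ions_scored, tol_da)
    if p <= 0.0:
        return MAX_SCORE
    return float(min(-10.0 * np.log10(p), MAX_SCORE))


def evaluate_candidate(
    spectrum: Spectrum,
    form: GlycoPeptideForm,
    tol_da: float = 0.05,
    alphabet: GlycanAlphabet | None = None,
    ions: Sequence[TheoreticalIon] | None = None,
) -> GlycoPSM:
    """Match and score one candidate form against one spectrum."""
    if ions is None:
        ions = scored_ions(form, alphabet)
    matches = match_peaks(spectrum, ions, tol_da)
    p = match_probability(matches, spectrum, ions, tol_da)
    score = MAX_SCORE if p <= 0 else float(min(-10.0 * np.log10(p), MAX_SCORE))
    z = spectrum.charge if spectrum.charge else 1
    theo = precursor_mz(form, z, alphabet)
    return GlycoPSM(
        spectrum_id=spectrum.spectrum_id,
        form=form,
        score=score,
        match_p=p,
        n_matched_y=sum(1 for m in matches if m.ion.series == "y"),
        n_matched_b=sum(1 for m in matches if m.ion.series == "b"),
        precursor_error_ppm=float((spectrum.precursor_mz - theo) / theo * 1e6),
    )


def rank_and_filter(
    psms: Iterable[GlycoPSM],
    min_score: float = 25.0,
    top_only: bool = True,
    p_threshold: float = 1e-3,
) -> list[GlycoPSM]:
    """Apply the acceptance rules: per-spectrum rank, score and probability.

    PSMs are ranked per spectrum by score (through the uncapped match
    probability, so candidates whose reported score saturates at the cap are
    still ordered), ties broken by smaller absolute precursor error then
    lexicographic full sequence. Accepted PSMs are the rank-1 hits (all
    ranks if ``top_only`` is False) with score >= min_score and chance-match
    probability below ``p_threshold``.
    """
    by_spectrum: dict[str, list[GlycoPSM]] = {}
    for psm in psms:
        by_spectrum.setdefault(psm.spectrum_id, []).append(psm)
    accepted: list[GlycoPSM] = []
    for group in by_spectrum.values():
        group.sort(
            key=lambda m: (
                m.match_p,
                -m.score,
                abs(m.precursor_error_ppm),
                m.form.full_sequence,
            )
        )
        for rank, psm in enumerate(group, start=1):
            psm.rank = rank
            if top_only and rank > 1:
                continue
            if psm.score >= min_score and psm.match_p < p_threshold:
                accepted.append(psm)
    return accepted


def _has_peak(spectrum: Spectrum, mz: float, tol_da: float) -> bool:
    i = np.searchsorted(spectrum.mz, mz - tol_da)
    return bool(i < len(spectrum.mz) and spectrum.mz[i] <= mz + tol_da)


def classify_fucose_site(
    psm: GlycoPSM,
    spectrum: Spectrum,
    tol_da: float = 0.05,
    alphabet: GlycanAlphabet | None = None,
) -> str:
    """Core vs antenna fucosylation from the Y1 region of the spectrum.

    Y1 is the peptide + core-HexNAc y ion (fucose-free). A peak 146.0579 Da
    above Y1 shows fucose on the core HexNAc; a Y1 peak lacking that
    companion, with at least one fucose-carrying larger y ion — or a
    fucose-shifted oxonium b1-b3 ion (e.g. HexNAc+Fuc at m/z 350.145), which
    covers fucose on the terminal antenna HexNAc that no y ion reaches —
    places the fucose on an antenna.
    """
    form = psm.form
    if form.n_fucose == 0:
        return "not_applicable"
    alphabet = alphabet or default_alphabet()
    entry = form.entry
    n_pep = len(entry.peptide.sequence)
    n = len(form.full_sequence)
    # Y1 of the fucose-free form (oxidation kept: it sits in the peptide part).
    bare = GlycoPeptideForm(
        entry=entry, fucose_positions=(), oxidation_positions=form.oxidation_positions
    )
    y1 = next(
        ion
        for ion in fragment_ions(bare, charges=(1,), alphabet=alphabet)
        if ion.series == "y" and ion.ordinal == n_pep + 1
    )
    y1_neutral = y1.mz - PROTON
    charges = (1, 2) if y1_neutral + FUCOSE > DOUBLE_CHARGE_MIN_MASS else (1,)
    core_peak = any(
        _has_peak(spectrum, (y1_neutral + FUCOSE + z * PROTON) / z, tol_da)
        for z in charges
    )
    if core_peak:
        return "core"
    y1_charges = (1, 2) if y1_neutral > DOUBLE_CHARGE_MIN_MASS else (1,)
    y1_peak = any(
        _has_peak(spectrum, (y1_neutral + z * PROTON) / z, tol_da) for z in y1_charges
    )
    if y1_peak:
        core_idx = form.core_o_index
        n_gly = len(form.entry.glycan)
        for ion in fragment_ions(form, alphabet=alphabet):
            if ion.series == "y":
                if ion.ordinal <= n_pep + 1:
                    continue
                span_start = n - ion.ordinal
                fuc_in_span = any(p >= span_start for p in form.fucose_positions)
            else:
                if ion.ordinal > min(3, n_gly):
                    continue
                fuc_in_span = any(
                    p < ion.ordinal and p != core_idx for p in form.fucose_positions
                )
            if fuc_in_span and _has_peak(spectrum, ion.mz, tol_da):
                return "antenna"
    return "undetermined"


def build_decoys(entries: Sequence[GlycoPeptideEntry]) -> list[GlycoPeptideEntry]:
    """Reversed-peptide decoys: C-terminal K/R stays in place, glycan unchanged.

    The decoy set has the same size and the same neutral masses as the
    target set (reversal permutes residues), which is what makes decoy
    counts usable as a false-discovery estimate.
    """
    decoys = []
    for e in entries:
        pep = e.peptide.sequence
        if pep[-1] in "KR":
            rev = pep[:-1][::-1] + pep[-1]
        else:
            rev = pep[::-1]
        n_sites = tuple(find_n_glycosites(rev))
        o_sites = tuple(find_o_glycosites(rev))
        decoy_pep = PeptideRecord(
            parent_accession=f"DECOY_{e.parent_accession}",
            start=e.peptide.start,
            end=e.peptide.end,
            sequence=rev,
            n_sites=n_sites,
            o_sites=o_sites,
        )
        decoys.append(
            GlycoPeptideEntry(
                parent_accession=f"DECOY_{e.parent_accession}",
                peptide=decoy_pep,
                glycan=e.glycan,
                site_position=e.site_position,
                site_positions=e.site_positions,
                is_decoy=True,
            )
        )
    return decoys


def search_spectra(
    spectra: Sequence[Spectrum],
    db: Sequence[GlycoPeptideForm],
    ppm: float = 10.0,
    tol_da: float = 0.05,
    min_score: float = 25.0,
    p_threshold: float = 1e-3,
    top_only: bool = True,
    classify_fucose: bool = True,
    alphabet: GlycanAlphabet | None = None,
) -> tuple[list[GlycoPSM], list[GlycoPSM]]:
    """Full pipeline: candidate selection, scoring, filtering, localization.

    Returns (accepted, all_psms). Spectra without a known charge are skipped.
    """
    alphabet = alphabet or default_alphabet()
    nm = np.array([neutral_mass(f, alphabet) for f in db])
    ion_cache: dict[int, list[TheoreticalIon]] = {}
    all_psms: list[GlycoPSM] = []
    spectra_by_id = {}
    for s in spectra:
        if s.charge is None:
            continue
        spectra_by_id[s.spectrum_id] = s
        for form in select_candidates(s, db, ppm, alphabet, neutral_masses=nm):
            ions = ion_cache.get(id(form))
            if ions is None:
                ions = scored_ions(form, alphabet)
                ion_cache[id(form)] = ions
            all_psms.append(evaluate_candidate(s, form, tol_da, alphabet, ions=ions))
    accepted = rank_and_filter(all_psms, min_score, top_only, p_threshold)
    if classify_fucose:
        for psm in accepted:
            psm.fucose_class = classify_fucose_site(
                psm, spectra_by_id[psm.spectrum_id], tol_da, alphabet
            )
    return accepted, all_psms


def _composition_str(form: GlycoPeptideForm) -> str:
    comp = glycan_composition(form.entry.glycan)
    return "".join(f"{c}{comp[c]}" for c in sorted(comp))


def summarize_by_composition(
    accepted: Sequence[GlycoPSM],
    ratios: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Tally accepted PSMs by glycan composition and fucose count.

    This is the segmentation by glycan structure irrespective of protein
    origin: identical compositions from different proteins fall in one
    group. When ``ratios`` maps spectrum ids to external quantitative
    ratios, the per-group median ratio is added.
    """
    rows = []
    for psm in accepted:
        rows.append(
            {
                "composition": _composition_str(psm.form),
                "n_fucose": psm.form.n_fucose,
                "spectrum_id": psm.spectrum_id,
            }
        )
    if not rows:
        cols = ["composition", "n_fucose", "count"]
        if ratios is not None:
            cols.append("median_ratio")
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    if ratios is not None:
        df["ratio"] = df["spectrum_id"].map(ratios)
        out = (
            df.groupby(["composition", "n_fucose"], as_index=False)
            .agg(count=("spectrum_id", "size"), median_ratio=("ratio", "median"))
        )
    else:
        out = df.groupby(["composition", "n_fucose"], as_index=False).agg(
            count=("spectrum_id", "size")
        )
    return out.sort_values(["composition", "n_fucose"], ignore_index=True)


REPORT_COLUMNS = [
    "spectrum_id",
    "accession",
    "peptide",
    "glycan_name",
    "glycan_sequence",
    "composition",
    "n_fucose",
    "fucose_class",
    "charge",
    "precursor_error_ppm",
    "score",
    "n_matched_y",
    "n_matched_b",
    "rank",
    "is_decoy",
]


def psms_to_frame(
    psms: Sequence[GlycoPSM], charges: dict[str, int] | None = None
) -> pd.DataFrame:
    rows = []
    for psm in psms:
        e = psm.form.entry
        rows.append(
            {
                "spectrum_id": psm.spectrum_id,
                "accession": e.parent_accession,
                "peptide": e.peptide.sequence,
                "glycan_name": e.glycan.name,
                "glycan_sequence": e.glycan.sequence,
                "composition": _composition_str(psm.form),
                "n_fucose": psm.form.n_fucose,
                "fucose_class": psm.fucose_class,
                "charge": charges.get(psm.spectrum_id) if charges else None,
                "precursor_error_ppm": psm.precursor_error_ppm,
                "score": psm.score,
                "n_matched_y": psm.n_matched_y,
                "n_matched_b": psm.n_matched_b,
                "rank": psm.rank,
                "is_decoy": psm.is_decoy,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(
    psms: Sequence[GlycoPSM],
    path: str | Path,
    charges: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Write the TSV identification report; returns the frame written."""
    df = psms_to_frame(psms, charges)
    df.to_csv(path, sep="\t", index=False)
    return df
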