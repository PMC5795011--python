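"""Candidate selection, peak matching, scoring, filtering and fucose placement."""

import numpy as np
import pytest
from scipy import stats as sps

from glyline import (
    GlycoPeptideForm,
    Spectrum,
    build_decoys,
    classify_fucose_site,
    match_peaks,
    neutral_mass,
    precursor_mz,
    rank_and_filter,
    scored_ions,
    select_candidates,
    summarize_by_composition,
    write_report,
)
from glyline.search import GlycoPSM, evaluate_candidate, match_probability, score_psm
from glyline.simulate import SimulationConfig, simulate_spectrum

NOISE_FREE = SimulationConfig(seed=1, mz_jitter_sd=0.0, n_noise_peaks=0)


def _spectrum_of(form, seed=1, **overrides):
    cfg_kwargs = dict(seed=seed, mz_jitter_sd=0.0, n_noise_peaks=0)
    cfg_kwargs.update(overrides)
    spectrum, _ = simulate_spectrum(form, SimulationConfig(**cfg_kwargs))
    return spectrum


class TestSelectCandidates:
    def test_exact_match_retained(self, toy_entries):
        forms = [GlycoPeptideForm(entry=e) for e in toy_entries]
        target = forms[4]
        s = Spectrum("s", precursor_mz(target, 3), 3, peaks=[(300.0, 1.0)])
        assert target in select_candidates(s, forms)

    def test_ppm_threshold(self, biantennary_form):
        forms = [biantennary_form]
        mz = precursor_mz(biantennary_form, 3)
        s = Spectrum("s", mz * (1 + 25e-6), 3, peaks=[(300.0, 1.0)])
        assert select_candidates(s, forms, ppm=10) == []
        assert select_candidates(s, forms, ppm=30) == forms

    def test_matches_brute_force_scan(self, random_entries):
        forms = [GlycoPeptideForm(entry=e) for e in random_entries[:150]]
        rng = np.random.default_rng(17)
        for _ in range(10):
            pick = forms[int(rng.integers(0, len(forms)))]
            z = 3
            obs = precursor_mz(pick, z) * (1 + float(rng.normal(0, 8e-6)))
            s = Spectrum("s", obs, z, peaks=[(300.0, 1.0)])
            fast = select_candidates(s, forms, ppm=10)
            slow = [
                f
                for f in forms
                if abs(obs - precursor_mz(f, z)) / precursor_mz(f, z) * 1e6 <= 10
            ]
            assert fast == slow

    def test_unknown_charge_rejected(self, biantennary_form):
        s = Spectrum("s", 1000.0, None, peaks=[(300.0, 1.0)])
        with pytest.raises(ValueError):
            select_candidates(s, [biantennary_form])


def _optimal_assignment_size(peak_mzs, ion_mzs, tol):
    """Exhaustive maximum one-to-one matching on tiny instances."""
    compatible = [
        [j for j, imz in enumerate(ion_mzs) if abs(pmz - imz) <= tol]
        for pmz in peak_mzs
    ]
    best = 0
    order = range(len(peak_mzs))
    def recurse(i, used, count):
        nonlocal best
        best = max(best, count)
        if i == len(peak_mzs):
            return
        recurse(i + 1, used, count)
        for j in compatible[i]:
            if j not in used:
                recurse(i + 1, used | {j}, count + 1)
    recurse(0, frozenset(), 0)
    return best


class TestMatchPeaks:
    def test_noise_free_spectrum_fully_annotated(self, biantennary_form):
        spectrum = _spectrum_of(biantennary_form)
        ions = scored_ions(biantennary_form)
        matches = match_peaks(spectrum, ions)
        assert len(matches) == len(ions)

    def test_out_of_tolerance_unmatched(self, biantennary_form):
        ions = scored_ions(biantennary_form)
        target = ions[0]
        s = Spectrum("s", 1000.0, 3, peaks=[(target.mz + 0.06, 100.0)])
        matched_ions = {
            (m.ion.series, m.ion.ordinal, m.ion.charge) for m in match_peaks(s, ions)
        }
        assert (target.series, target.ordinal, target.charge) not in matched_ions

    def test_each_peak_consumed_once(self, biantennary_form):
        ions = scored_ions(biantennary_form)
        s = Spectrum("s", 1000.0, 3, peaks=[(ions[0].mz, 100.0)])
        assert len(match_peaks(s, ions)) <= 1

    def test_count_equals_exhaustive_assignment(self):
        # well-separated random instances: greedy must equal the optimum
        rng = np.random.default_rng(23)
        for _ in range(20):
            ion_mzs = np.sort(rng.choice(np.arange(200, 2000, 0.25), 12, replace=False))
            keep = rng.random(12) < 0.6
            peak_mzs = ion_mzs[keep] + rng.uniform(-0.04, 0.04, keep.sum())
            extra = rng.uniform(200, 2000, 5)
            peak_mzs = np.concatenate([peak_mzs, extra])
            from glyline.fragments import TheoreticalIon

            ions = [
                TheoreticalIon("y", k + 1, 1, float(mz), False)
                for k, mz in enumerate(ion_mzs)
            ]
            peaks = np.column_stack([peak_mzs, rng.uniform(1, 100, len(peak_mzs))])
            s = Spectrum("s", 1000.0, 2, peaks=peaks)
            greedy = len(match_peaks(s, ions, tol_da=0.05))
            optimal = _optimal_assignment_size(peak_mzs, [i.mz for i in ions], 0.05)
            assert greedy == optimal

    def test_symmetric_tolerance(self, biantennary_form):
        ions = scored_ions(biantennary_form)
        for sign in (+1, -1):
            peaks = [(ion.mz + sign * 0.03, 10.0) for ion in ions]
            s = Spectrum("s", 1000.0, 3, peaks=peaks)
            assert len(match_peaks(s, ions)) == len(ions)


class TestScore:
    def test_no_matches_scores_zero(self, biantennary_form):
        ions = scored_ions(biantennary_form)
        s = Spectrum("s", 1000.0, 3, peaks=[(5000.0, 1.0)])
        assert score_psm([], s, ions) == 0.0

    def test_binomial_tail_oracle(self):
        # direct binomial-sum oracle for n=10, q=0.01, k=5
        n, q, k = 10, 0.01, 5
        p_oracle = sum(
            sps.binom.pmf(j, n, q) for j in range(k, n + 1)
        )
        assert sps.binom.sf(k - 1, n, q) == pytest.approx(p_oracle, rel=1e-9)

    def test_score_increases_with_matched_count(self, biantennary_form):
        ions = scored_ions(biantennary_form)
        scores = []
        rng = np.random.default_rng(5)
        noise = np.column_stack([rng.uniform(3000, 4000, 30), rng.uniform(1, 5, 30)])
        for k in (2, 5, 10, 20):
            peaks = np.vstack(
                [np.array([(ions[i].mz, 50.0) for i in range(k)]), noise]
            )
            s = Spectrum("s", 1000.0, 3, peaks=peaks)
            matches = match_peaks(s, ions)
            assert len(matches) == k
            scores.append(score_psm(matches, s, ions))
        assert scores == sorted(scores)
        assert all(s > 0 for s in scores)


def _mock_psm(spectrum_id, score, ppm=0.0, form=None):
    return GlycoPSM(
        spectrum_id=spectrum_id,
        form=form,
        score=score,
        match_p=10 ** (-score / 10.0),
        n_matched_y=0,
        n_matched_b=0,
        precursor_error_ppm=ppm,
    )


class TestRankAndFilter:
    def test_top_match_wins(self, biantennary_form):
        psms = [
            _mock_psm("s1", 35.0, form=biantennary_form),
            _mock_psm("s1", 20.0, form=biantennary_form),
        ]
        accepted = rank_and_filter(psms)
        assert len(accepted) == 1
        assert accepted[0].score == 35.0
        assert accepted[0].rank == 1

    def test_below_threshold_rejected(self, biantennary_form):
        psms = [_mock_psm("s1", 24.0, form=biantennary_form)]
        assert rank_and_filter(psms, min_score=25.0) == []

    def test_three_rules_against_oracle(self, random_entries):
        """Acceptance equals an independent re-evaluation of rank-1 +
        score >= 25 + p < 0.001 on a 50-PSM fixture."""
        rng = np.random.default_rng(31)
        forms = [GlycoPeptideForm(entry=e) for e in random_entries[:10]]
        psms = []
        for i in range(50):
            sid = f"s{int(rng.integers(0, 12))}"
            score = float(rng.uniform(0, 60))
            psms.append(
                _mock_psm(sid, score, ppm=float(rng.normal(0, 3)),
                          form=forms[int(rng.integers(0, len(forms)))])
            )
        accepted = rank_and_filter(psms)
        ids = {id(p) for p in accepted}
        # oracle: brute-force re-check of the three rules
        for sid in {p.spectrum_id for p in psms}:
            group = [p for p in psms if p.spectrum_id == sid]
            top = min(group, key=lambda m: (m.match_p, abs(m.precursor_error_ppm)))
            for p in group:
                should = (
                    p is top and p.score >= 25.0 and p.match_p < 1e-3
                )
                assert (id(p) in ids) == should


class TestFucoseClassification:
    @pytest.fixture
    def fucoforms(self, biantennary_form):
        entry = biantennary_form.entry
        core = entry.glycan.sequence.rfind("O")
        antenna = entry.glycan.sequence.find("O", 1)  # a mid-sequence antenna O
        return (
            GlycoPeptideForm(entry=entry, fucose_positions=(core,)),
            GlycoPeptideForm(entry=entry, fucose_positions=(antenna,)),
        )

    def test_core_fucose_detected(self, fucoforms):
        core_form, _ = fucoforms
        spectrum = _spectrum_of(core_form)
        psm = evaluate_candidate(spectrum, core_form)
        assert classify_fucose_site(psm, spectrum) == "core"

    def test_antenna_fucose_detected(self, fucoforms):
        _, antenna_form = fucoforms
        spectrum = _spectrum_of(antenna_form)
        psm = evaluate_candidate(spectrum, antenna_form)
        assert classify_fucose_site(psm, spectrum) == "antenna"

    def test_terminal_antenna_fucose_detected_via_oxonium(self, biantennary_form):
        form = GlycoPeptideForm(entry=biantennary_form.entry, fucose_positions=(0,))
        spectrum = _spectrum_of(form)
        psm = evaluate_candidate(spectrum, form)
        assert classify_fucose_site(psm, spectrum) == "antenna"

    def test_missing_y1_is_undetermined(self, fucoforms):
        _, antenna_form = fucoforms
        # drop the glycosidic ladder: no Y1, no fucose-bearing large y ions
        spectrum = _spectrum_of(antenna_form, include_glycosidic_ladder=False,
                                include_oxonium=False)
        psm = evaluate_candidate(spectrum, antenna_form)
        assert classify_fucose_site(psm, spectrum) == "undetermined"

    def test_no_fucose_not_applicable(self, biantennary_form):
        spectrum = _spectrum_of(biantennary_form)
        psm = evaluate_candidate(spectrum, biantennary_form)
        assert classify_fucose_site(psm, spectrum) == "not_applicable"


class TestDecoys:
    def test_reversal_keeps_cterm_kr(self, library):
        from glyline import ProteinRecord, build_database

        prot = ProteinRecord("T", "", "PEPTIDERNATAK")
        # force a peptide "PEPTIDER": digest cleaves after R
        entries, _ = build_database([prot], library, mode="O")
        entry = next(e for e in entries if e.peptide.sequence == "PEPTIDER")
        decoy = build_decoys([entry])[0]
        assert decoy.peptide.sequence == "EDITPEPR"
        assert decoy.is_decoy

    def test_mass_conserved_and_size_equal(self, toy_entries):
        decoys = build_decoys(toy_entries)
        assert len(decoys) == len(toy_entries)
        for target, decoy in zip(toy_entries, decoys):
            t = neutral_mass(GlycoPeptideForm(entry=target))
            d = neutral_mass(GlycoPeptideForm(entry=decoy))
            assert d == pytest.approx(t, abs=1e-9)


class TestSummaryAndReport:
    def _accepted(self, toy_entries):
        by_seq = {}
        for e in toy_entries:
            if e.glycan.sequence == "OJUUJOJJJOO":
                by_seq.setdefault(e.peptide.sequence, e)
        entries = list(by_seq.values())[:2]
        psms = []
        for i in range(3):
            psms.append(_mock_psm(f"s{i}", 40.0, form=GlycoPeptideForm(entry=entries[0])))
        fuc = GlycoPeptideForm(
            entry=entries[1], fucose_positions=(entries[1].glycan.sequence.rfind("O"),)
        )
        psms.append(_mock_psm("s3", 40.0, form=fuc))
        return psms

    def test_group_counts(self, toy_entries):
        table = summarize_by_composition(self._accepted(toy_entries))
        assert len(table) == 2
        counts = dict(zip(table["n_fucose"], table["count"]))
        assert counts == {0: 3, 1: 1}
        assert set(table["composition"]) == {"J5O4U2"}

    def test_counts_equal_brute_force_tally(self, toy_entries):
        accepted = self._accepted(toy_entries)
        table = summarize_by_composition(accepted)
        tally = {}
        for psm in accepted:
            from glyline.search import _composition_str

            key = (_composition_str(psm.form), psm.form.n_fucose)
            tally[key] = tally.get(key, 0) + 1
        for row in table.itertuples():
            assert tally[(row.composition, row.n_fucose)] == row.count

    def test_empty_input_empty_table(self):
        table = summarize_by_composition([])
        assert len(table) == 0

    def test_report_round_trip(self, toy_entries, tmp_path):
        import pandas as pd

        accepted = self._accepted(toy_entries)
        for psm in accepted:
            psm.rank = 1
        path = tmp_path / "report.tsv"
        df = write_report(accepted, path)
        assert len(df) == 4
        again = pd.read_csv(path, sep="\t")
        assert list(again.columns) == list(df.columns)
        assert len(again) == 4
        assert not again["is_decoy"].any()
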