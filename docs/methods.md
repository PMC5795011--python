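# Methods

## The model

glyline treats an intact glycopeptide as a single linear sequence over a mixed
alphabet: monosaccharide residue letters (O = HexNAc 203.0794 Da, J = hexose
162.0528 Da, U = Neu5Ac 291.0954 Da; all condensation residues, cross-checked
against the elemental compositions C8H13NO5, C6H10O5, C11H17NO8 to 1e-3 Da)
followed by amino acids. The glycan is attached at the peptide N-terminus via
the core HexNAc, which is the rightmost glycan letter. Under this encoding the
standard peptide fragment arithmetic applies unchanged:

* `neutral_mass = Σ residue masses + water + modification deltas`
* `b_i = Σ first i residues + proton`, `y_i = Σ last i residues + water + proton`
* complementarity `b_i + y_{n-i} = M + 2·proton` holds exactly by construction
  and is property-tested to 1e-6 Da.

Fixed and variable modifications use the community-standard monoisotopic
deltas: carbamidomethyl +57.02146 on every C (implicit), oxidation +15.99491
on M, fucose +146.0579 on O. Proton 1.007276 Da, water 18.010565 Da.
Amino-acid residue masses come from pyteomics, restricted to the 20 standard
letters because pyteomics also assigns masses to O/U/J (pyrrolysine,
selenocysteine, Leu/Ile ambiguity) that would collide with the sugar codes.

## Canonical linearization grammar

Only the worked biantennary example and qualitative criteria (cover the most
intense peaks; read like the glycosidic ladder) constrain the linear order, so
the package fixes a canonical grammar for complex-type sialylated N-glycans
with `a` antennae (2–4) and `s` sialic acids (1–`a`):

```
OJU  +  UJO·(s−1)  +  JO·(a−s)  +  JJJ  +  OO
```

The first antenna is written core→terminal so its prefixes generate the
oxonium b1/b2/b3 (204.087 / 366.140 / 657.235); every other antenna is written
terminal→core (sialylated first) so successive y ions strip residues in
glycosidic-loss order; `JJJ` is the trimannosyl core and `OO` the chitobiose
core. For (a=2, s=2) this reproduces `OJUUJOJJJOO`. All 9 combinations form
the shipped default library. Fucosylated or truncated structures are supplied
by the user as additional `name<TAB>sequence` lines; the grammar makes no
claim to cover them. The di-sialylated core-1 O-glycan is encoded `UUJO` by
default; the printed b1–b3 of such spectra fix only the `UJO` prefix of the
mono-sialylated form, so the di-sialylated order is a configurable convention,
not an inference.

Linkage, anomericity and topology are deliberately out of scope: two
topologies with identical composition and identical ladder behavior are
indistinguishable in this representation.

## Database construction

Tryptic digestion cleaves after K/R, by default not before P (Keil rule,
matching mainstream search engines; toggleable). Defaults: 0 missed
cleavages, peptide length 5–30 (both configurable; one published description
of the same pipeline cites 6–30 for a specific example — the stated method
value 5 is used). N-mode keeps peptides with an N-x-T/S/C sequon (x
unrestricted by default; strict N-[^P]-[TSC] available), O-mode keeps any
peptide with S or T. Peptides containing B/J/O/U/X/Z are excluded with a
warning: they collide with sugar codes or lack masses.

Each retained peptide × each library glycan yields one database entry; a
peptide with several sequons yields a single entry per glycan (the linear
sequence is identical wherever the glycan sits), recording all sequon
positions with the first as primary. Entries are ordered by accession,
peptide start, then library order, making FASTA output byte-reproducible.
The peptide-centric FASTA (one record per entry, header
`accession|start-end|siteN|glycan_name`) is the default; the protein-centric
variant concatenates each protein's entries into one record. Reversed-peptide
decoys (C-terminal K/R fixed, glycan unchanged) preserve precursor mass and
set size.

## Scoring

The probability-based ion scores of commercial search engines are
proprietary, so the package scores
a PSM by the binomial tail: with `n` scored theoretical ions, `k` of them
matched, and a per-ion chance probability `q = 2·tol·ρ` (ρ = observed peak
density over the scored m/z range, tol = 0.05 Da default), the match
probability is `p = P[Binom(n, q) ≥ k]` and the ion score `-10·log10(p)`,
reported capped at 300. Ranking uses the uncapped probability so saturated
scores still order; ties break on smaller absolute precursor error, then
lexicographic sequence, making search results seed-independent. Acceptance
keeps rank-1 hits with score ≥ 25 *and* p < 0.001 — both filters are applied
as published even though the p rule is the binding one between scores 25 and
30. Calibration is enforced by test: on pure uniform noise the rate of
candidates reaching p < 0.001 stays below 0.005 (measured ≈ 0.001 over 10,000
trials).

Scored ions are all y ions (1+, plus 2+ for fragments above 900 Da — large
glycan-retaining y ions are routinely doubly charged; threshold configurable)
and the glycan-prefix b1–b3. b ions beyond b3 span the glycan/peptide
junction and are excluded: with the glycan prepended, genuine peptide b ions
have no counterpart in the linear coordinate system.

Peak assignment is greedy in descending peak intensity, each peak consumed at
most once, each ion taking its closest compatible peak within ±tol. This is
not globally optimal in adversarial overlap cases; equivalence with an
exhaustive one-to-one assignment is asserted on small well-separated
instances, which is the regime the 0.05 Da tolerance puts real spectra in.

## Fucose localization

After acceptance, the classifier inspects the spectrum near Y1 (peptide +
core HexNAc, computed fucose-free): a peak at Y1 + 146.0579 (any scored
charge) ⇒ **core**; otherwise a bare Y1 peak plus at least one
fucose-carrying larger y ion, or a fucose-shifted oxonium b1–b3 (e.g.
HexNAc+Fuc at 350.145, needed when the fucose sits on the terminal antenna
HexNAc that no y ion covers) ⇒ **antenna**; otherwise **undetermined**. Forms
without fucose report **not_applicable**.

## The synthetic spectrum generator

The generator stands in for instrument data and emulates stepped-NCE
composite spectra by peak class: the glycosidic ladder (low-NCE regime,
relative intensity 60), peptide-backbone y ions (high-NCE regime, 30) and
oxonium b1–b3 (100), each class switchable to isolate a regime. Peaks are
jittered with Gaussian m/z noise (σ = 0.005 Da default, i.e. a tenth of the
fragment tolerance) and 30 uniform noise peaks (intensity 1–10) are added per
spectrum over 200–2000 m/z, rejected within ±0.1 Da of any true peak so
ground truth stays unambiguous. Precursor charge is 2+ below 3000 Da neutral
mass, else 3+; the precursor m/z is exact. Everything is deterministic under
the config seed.

What it does **not** model: fragmentation efficiency physics, isotope
envelopes, co-isolation/chimeric spectra, retention time, ETD/EThcD channels,
intensity variation within a class. Passing recovery tests therefore
demonstrates the correctness of the database/fragment/matching/scoring
machinery under controlled noise, not performance on real LC-MS data, where
peak density, missing ladder ions and co-eluting precursors are harsher.

## Problem sizes and test design

The pipeline-level checks run on synthetic data sized for quick desk
verification: rank-1 recovery uses 50 spectra against a 200-entry database
(expanded to ~1600 candidate fucoforms), recovering 100% noise-free and ≥ 90%
(measured 100%) at default noise; score calibration uses 10,000 noise-only
trials; fucose classification uses 50 constructed core/antenna fixtures
(measured ≥ 98% correct). Serum-scale published figures (hundreds of
glycoproteins, thousands of glycopeptide variants) require the original raw
data and are outside what synthetic fixtures can certify.

## Known limitations

* One glycan per peptide: multiply O-glycosylated forms are not enumerated.
* The fragment ladder treats the full-length y (peptide + entire glycan) as
  the precursor, not a fragment; the ladder has `len(glycan) − 1` positions.
* Fucose on the terminal antenna HexNAc is visible only through b1–b3.
* FDR is reported simply as decoy/target counts above threshold; no
  glycan/peptide-part-specific FDR decomposition is attempted.
* The binomial score assumes independent chance matches at uniform density;
  structured noise (e.g. another co-isolated glycopeptide) violates this and
  is not simulated.
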