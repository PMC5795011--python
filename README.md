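# glyline

Intact glycopeptide identification from MS2 spectra using **linearized glycan
sequences**: monosaccharides are encoded as extra single-letter residue codes,
glycans become linear sequences prepended to tryptic peptides, and glycopeptide
spectra are then matched with ordinary peptide b/y fragment arithmetic.

## Who this is for

Glycoproteomics analysts who have MS2 peak lists (MGF) of enriched intact
glycopeptides — N-linked sialylated glycopeptides from serum, O-glycopeptides
from standard glycoproteins — and want a transparent, scriptable pipeline for
building combinatorial glycopeptide databases, matching and scoring spectra,
and localizing fucose, without a commercial search engine.

## The encoding

Of the 26 Latin letters, 20 name amino acids and B/X/Z are reserved ambiguity
codes. The three remaining letters encode the basic sugar residues:

| code | residue                       | monoisotopic residue mass (Da) |
|------|-------------------------------|-------------------------------|
| O    | N-acetylhexosamine (GlcNAc/GalNAc) | 203.0794 |
| J    | hexose (Gal, Man)             | 162.0528 |
| U    | Neu5Ac (sialic acid)          | 291.0954 |

Fucose (deoxyhexose, +146.0579 Da) is a *variable modification on O*, which is
what later lets core- vs antenna-fucosylated forms be told apart.

A glycan is written as a linear sequence whose rightmost residue attaches to
the peptide N-terminus. For the di-sialylated biantennary N-glycan the
canonical sequence is `OJUUJOJJJOO`, so the glycopeptide is e.g.
`OJUUJOJJJOO`‑`QDQCIYNTTYLNVQR`. In this coordinate system:

* the glycosidic Y-ladder of the spectrum (peptide + k sugars) becomes the
  high-ordinal part of the ordinary **y** series;
* the intense low-mass oxonium ions become **b1/b2/b3** of the glycan prefix —
  HexNAc 204.087, HexNAc‑Hex 366.140, HexNAc‑Hex‑Neu5Ac 657.235 (and for
  sialylated O-glycans: Neu5Ac 292.103, Neu5Ac‑Hex 454.156);
* peptide backbone y ions close the identification at high collision energy,
  mirroring stepped-NCE composite spectra.

Candidates are filtered by precursor mass (10 ppm default), their scored ions
(all y plus the b1–b3 prefix) are matched at 0.05 Da, and each match gets an
ion score `-10·log10(p)` where `p` is the binomial survival probability of the
matched-ion count arising by chance. Accepted identifications are rank-1 hits
with score ≥ 25 and match probability < 0.001. The score is an open,
calibration-tested stand-in for proprietary probability-based ion scores; its
numeric values are not claimed to equal any other engine's.

## Worked example

```python
import glyline as gl

g = gl.parse_linear_glycan("OJUUJOJJJOO")
gl.glycan_composition(g)      # {'O': 4, 'J': 5, 'U': 2}  (HexNAc4 Hex5 NeuAc2)
gl.glycan_mass(g)             # 2204.7724 Da

prot = gl.ProteinRecord("A1AG1", "demo", "MKQDQCIYNTTYLNVQRENGTISRAAAK")
entries, stats = gl.build_database([prot], gl.generate_sialylated_library())
form = gl.GlycoPeptideForm(entry=next(
    e for e in entries
    if e.peptide.sequence == "QDQCIYNTTYLNVQR" and e.glycan.sequence == "OJUUJOJJJOO"))
gl.neutral_mass(form)         # 4119.6618 Da (carbamidomethyl-C applied)
gl.precursor_mz(form, 3)      # 1374.2279
[i.mz for i in gl.fragment_ions(form) if i.series == "b" and i.charge == 1][:3]
# [204.0867, 366.1395, 657.2349]  — the oxonium b1/b2/b3
```

End to end from the shell, with synthetic ground-truth spectra:

```bash
glydb make-library -o glycans.tsv          # the 9 canonical sialylated N-glycans
glydb build --fasta proteins.fa --glycans glycans.tsv --mode N -o glyco_db.fa
# -> 27 glycopeptide entries (618 residues) from 1/1 proteins

glysim make --fasta proteins.fa --glycans glycans.tsv -n 25 --seed 7 -o fixtures/
glysearch run --mgf fixtures/spectra.mgf --db glyco_db.fa --glycans glycans.tsv \
              --max-fucose 1 -o report.tsv --summary summary.json
# -> 25 accepted (0 decoy) of 78 scored candidates over 25 spectra
```

`report.tsv` then holds one row per accepted identification, e.g.

```text
peptide  glycan_name                    n_fucose  fucose_class    score
LLNDSR   tri-sialylated tetraantennary  1         antenna         300.0
ENGTISR  tri-sialylated tetraantennary  0         not_applicable  300.0
```

`fucose_class` reads the spectrum around the peptide+HexNAc (Y1) ion: a peak
146.0579 Da above Y1 means the fucose sits on the core HexNAc; a bare Y1 with
fucose-shifted larger y ions (or a shifted oxonium) places it on an antenna.
The JSON summary groups identifications by glycan composition and fucose
count, irrespective of the protein of origin.

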