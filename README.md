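# chitoseq

Tools for characterizing chitin deacetylases of carbohydrate esterase family
4 (CE4): mining candidate deacetylases from protein collections, sequencing
the *pattern of acetylation* of their chitooligosaccharide products from MS2
fragment ladders, and deriving activity metrics from acetate-release assays.

Chitooligosaccharides (CHOS) are β-1,4-linked oligomers of N-acetylglucosamine
(GlcNAc, **A**) and glucosamine (GlcN, **D**). A CE4 deacetylase converts A
units to D units; which positions it prefers — the pattern of acetylation
(P<sub>A</sub>), alongside the degree of polymerization (DP) and fraction of
acetylation (F<sub>A</sub> = n<sub>A</sub>/DP) — determines the biological
activity of the products. `chitoseq` covers the complete computational path:

* **`chitoseq.chos`** — exact mass arithmetic for A/D oligomers with an
  optional 2-aminoacridone (AMAC) reducing-end label attached by reductive
  amination (M = Σ residues + AMAC + H₂), composition assignment from MS1
  precursor masses.
* **`chitoseq.msannotate`** — Y/B glycosidic fragment ladders
  (Y<sub>k</sub> = Σ last k residues + AMAC + H₂ + H⁺), tolerance-based peak
  matching, exhaustive ranking of the C(DP, n<sub>D</sub>) positional isomers
  of a composition against an MS2 spectrum, soft per-position deacetylation
  frequencies (weights ∝ score^γ), and reducing/non-reducing end diagnostics
  (GlcNAc-AMAC m/z 416.18 vs GlcN-AMAC m/z 374.17).
* **`chitoseq.screen`** — the candidate-selection funnel: five conserved CE4
  motifs (T[FY]DD, H[ST]xxH, RxPY, DxxD[WY], LxH) scanned in order, gene
  completeness, a transparent signal-peptide heuristic (charged n-region,
  hydrophobic h-region, small-residue −3/−1 cleavage site; external predictor
  calls override), and a single-domain filter.
* **`chitoseq.kinetics`** — ASAR (substrate as acetyl-group concentration),
  deacetylation degree, acetate release rate and apparent rate constant
  k<sub>app</sub> = [acetate]/(t·[E]) from single-point assays.
* **`chitoseq.simulate`** — synthetic-data generators: a continuous-time
  Markov simulator of position-biased sequential deacetylation (independent
  exponential clocks, optional neighbor penalty via Gillespie), MS2 spectrum
  synthesis with m/z jitter and noise peaks, and protein collections with
  planted motifs/signal peptides/decoys and exact truth labels.
* **`chitoseq.pipeline` / CLI** — orchestrated runs with TSV/JSON reports;
  every report header states the orientation convention (non-reducing end →
  reducing end) and mass convention.

## Worked example

Sequencing a mono-deacetylated AMAC-labeled pentamer:

```python
from chitoseq import ChosPattern, Label, ion_mz, composition_from_mz
from chitoseq import rank_patterns, positional_support
from chitoseq.chos import Composition
from chitoseq.simulate import synth_spectrum

ion_mz(ChosPattern("AADAA", Label.AMAC))      # 1186.4887
composition_from_mz(1186.6, (5, 5), tol=0.5)  # [(5, Composition(nA=4, nD=1))]

spectrum = synth_spectrum({"AADAA+AMAC": 1.0})   # noiseless Y+B ladder
scores = rank_patterns(spectrum, Composition(4, 1))
scores[0].pattern.residues                    # 'AADAA'  (rank 1, unique)
scores[0].explained_fraction                  # 1.0
```

The m/z 1186.49 ion is assigned composition A4D1; its Y ladder
(416.18, 619.26, 780.33, 983.41, 1186.49) pins the single D to position 3,
because consecutive Y differences of 203.08 (A) or 161.07 (D) spell the
pattern from the reducing end.

Reconstructing the ten-substrate activity panel
(`chitoseq kinetics`, or `reproduce_table(reference_assays())`):

```
         substrate  asar_um  acetate_um  degree_percent  release_rate_nmol_min  k_app_per_s
         (GlcNAc)5  10000.0        95.8           0.960                   0.32         0.18
      acetyl xylan   9000.0      1696.7          18.900                   5.66         3.14
```

95.8 µM acetate from 10 000 µM acetyl groups in 30 min with 0.3 µM enzyme in
0.1 ml is a 0.96 % deacetylation degree, 0.32 nmol/min release and
k<sub>app</sub> = 0.18 s⁻¹.

Screening a synthetic 64-protein collection with planted truth
(`chitoseq simulate proteins` then `chitoseq screen`):

```
input           64
family_ce4      48
all_motifs      24
complete_gene   16
signal_peptide   5
single_domain    1
```

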