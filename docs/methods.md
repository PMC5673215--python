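# Methods

## Mass model

CHOS are modeled as ordered strings over {A, D} (GlcNAc / GlcN), written from
the non-reducing end to the reducing end; DP is bounded at 12. Masses are
additive in glycosidic residue masses: monoisotopic A = 203.0794 Da
(C₈H₁₃NO₅), D = 161.0688 Da (C₆H₁₁NO₄), so deacetylation is a −42.0106 Da
(C₂H₂O) step. An unlabeled oligomer adds one water (18.0106); an AMAC-labeled
oligomer adds AMAC (C₁₃H₁₀N₂O, 210.0793) + H₂ (2.0157) instead, because
reductive amination condenses away the reducing-end water and the subsequent
reduction adds two hydrogens. The label therefore shifts every pattern by a
constant +194.084 Da. Ions are protonated positive species,
(M + z·1.00728)/z; only z = 1 is used in practice since unit-resolution ion
traps report the singly charged species for DP ≤ 6. An average-mass table is
provided for completeness; at DP ≤ 12 the two conventions differ by well
under the 0.5 m/z matching tolerance, so the choice is not observable in
unit-resolution data. Default tolerance 0.5 m/z throughout, matching
unit-resolution trap data (scan range m/z 150–2000); composition assignment
from a precursor m/z enumerates all (DP, n_A, n_D) in range and returns those
within tolerance sorted by absolute error.

## MS2 pattern sequencing

Only glycosidic cleavages are modeled: Y ions (reducing-end fragments, which
retain the AMAC label; Y_k = Σ last k residues + AMAC + H₂ + H⁺) and B ions
(non-reducing oxocarbenium, Σ first k residues + H⁺), k = 1..DP and 1..DP−1
respectively. Cross-ring cleavages and C/Z/A/X ions are out of scope — the
labeled Y series is the diagnostic ladder, since consecutive Y differences
(203.08 or 161.07) spell the pattern from the reducing end.

Pattern inference is exhaustive: all C(DP, n_D) positional isomers of the
assigned composition are enumerated and scored against the spectrum. Each
ion is matched to the nearest peak within tolerance; one peak may support
several isobaric ions (positional isomers share many fragment masses, so
exclusive matching would discard evidence). `explained_fraction` is the share
of total spectral intensity carried by peaks matched by any ladder ion of the
candidate; the ranking score additionally down-weights peaks matched only by
B ions (default weight 0.25), keeping the Y series decisive. Ties break
lexicographically; scores are invariant to peak ordering and to positive
intensity rescaling.

Mixtures of isomers (the common case for enzymatic products) are handled by
soft weighting rather than spectral deconvolution: candidate weights
w_p ∝ score_p^γ (γ = 4 by default), normalized, and the per-position
deacetylation frequency is f_i = Σ_p w_p·[p_i = D], which sums to n_D
exactly. Because isomers share most of their ladders, wrong candidates retain
non-zero scores and the soft frequencies are deliberately conservative —
they recover rank orderings of positional preference reliably but are not
calibrated abundances (quantitative MS intensities of glycans are themselves
unreliable). An ambiguity flag is raised whenever the top two scores differ
by less than ε = 0.05, or when nothing matched (uniform fallback). End-state
diagnostics are reported separately: the Y1 pair GlcNAc-AMAC (416.18) vs
GlcN-AMAC (374.17) reads the reducing-end state directly, and the
Y_(DP−1) ion of composition (n_A, n_D−1) is the fingerprint of a
deacetylated non-reducing terminus (for A4D1 precursors, an A4-AMAC signal).

## Candidate screening

The funnel applies five per-protein predicates in a fixed order: CE4 family
tag (annotation-based; records without a family annotation pass, since family
membership cannot be inferred from sequence here), presence of all five CE4
motifs, gene completeness, signal peptide, single domain. Counts are monotone
non-increasing and the final set is order-independent (pure predicates).

Motifs use a restricted syntax (literal, bracketed set, `x` wildcard)
compiled to regular expressions; overlapping occurrences are all reported.
`R(P/x)PY` is read literally as R-any-P-Y and `LxH` as L-any-H. By default
the five motifs must additionally admit one non-overlapping occurrence each
in MT1→MT5 order along the sequence (greedy earliest-end chaining, which is
optimal), reflecting the conserved domain architecture; the ordering
requirement is configurable off.

Where annotations are absent, transparent sequence proxies apply:
completeness = starts with M and no internal stop; single domain = mature
length ≤ 400 aa (CE4 catalytic domains are ~200 aa, so 400 is permissive).
The signal-peptide heuristic requires a positively charged n-region (≥ 1 K/R
in residues 2–6), a hydrophobic h-region (an 8-residue window within
positions 6–25 with mean Kyte–Doolittle hydropathy ≥ 1.5), and a cleavage
position c ∈ [16, 35] whose −1 (residue c) and −3 (residue c−2) residues are
small (A/G/S/C/T), reporting the first qualifying c. This is a transparent
stand-in for dedicated HMM predictors, not a reimplementation of one;
external calls provided as annotations always take precedence, and sequences
shorter than 25 residues are called negative with reason "too short".

## Deacetylation simulator

Sequential deacetylation is modeled per molecule as independent exponential
clocks: position i converts A→D at first-order rate k_i (s⁻¹), optionally
specified by position class (non-reducing end / internal / reducing end). An
optional neighbor penalty ∈ (0, 1] multiplies a position's instantaneous
rate per already-deacetylated adjacent residue, capturing slower follow-up
deacetylations on partially converted chains; with the penalty active the
process is simulated by the Gillespie algorithm, otherwise conversion times
are drawn directly. With penalty 1 the closed form P_i(t) = 1 − exp(−k_i t)
serves as an independent oracle (agreement within 3 Monte-Carlo s.e. at
n = 10 000 is a tested property). Cumulative acetate equals the expected
number of conversions — an exact per-molecule bookkeeping identity. No
explicit enzyme-binding/subsite model is implied; the defaults encode only
the qualitative positional ordering (internal 1×10⁻³, non-reducing end
1×10⁻⁴, reducing end 2×10⁻⁵ s⁻¹ — internal preferred, reducing end hardly
touched), since true positional rate ratios are not quantified anywhere.

## Spectrum and protein generators

Spectrum synthesis places each mixture member's Y ladder at its abundance
(unit response factors — a convention, not a claim about instrument
response) and its B ladder scaled by 0.3, accumulates coinciding masses,
then applies Gaussian m/z jitter and uniform noise peaks under a fixed seed.
Generated spectra carry the theoretical precursor of their composition.

Protein collections are drawn uniformly over the 20 residues and then
*scrubbed*: any accidental occurrence of a CE4 motif is destroyed by
replacing its first residue with E (used literally by no motif, so the edit
always kills the hit and can never create one), making truth labels certain
under every seed. Categories then plant exactly the features they need:
ordered canonical motif instances (TFDD, HSTAH, RPPY, DAADW, LAH) with
20-residue spacing, a fixed 21-residue signal peptide satisfying all three
heuristic clauses with first cleavage at 21, incompleteness (no initiator M
plus an internal stop outside the motif region), and multi-domain decoys as
length > 400 aa. The default category counts (16 non-CE4, 24 motif-deficient
CE4, 8 incomplete, 11 without signal peptide, 4 multi-domain, 1 positive)
yield the funnel 64→48→24→16→5→1 by construction.

What the generators do *not* emulate: real CE4 sequence homology (decoys are
random backgrounds, so the motif scanner is tested for logic, not for
specificity against homologous non-CE4 deacetylases), isotope envelopes,
charge states > 1, chromatographic effects, and intensity response factors.
Passing tests therefore validate the analysis logic and its internal
consistency, not performance on any particular organism's proteome or
instrument.

## Activity metrics

ASAR converts every substrate to a common currency of acetyl-group
concentration; computed values are reported at 3 significant figures
(α/β-chitin: 5 mg/ml ÷ 203.19 g/mol × 10⁶ = 24 600 µM assuming one acetyl
per residue). For chitosan (F_A 0.64) and acetyl xylan (~50% acetylation by
MALDI-TOF) the published ASAR values (16 000 and 9 000 µM) are taken as
direct inputs because the residue-mass assumptions behind them are not
derivable; chitin's is recomputed. Degree = 100 × acetate/ASAR;
release rate = acetate (µM) × volume (ml)/time (min); k_app = acetate/
(time·[E]). The reaction volume defaults to 0.1 ml — the unique value that
reconciles µM acetate with the printed nmol/min column across the benchmark
panel. Report rounding: rates and k_app to 2 decimals (half-up); degrees use
value-dependent precision (3 decimals < 0.01 %, 2 decimals < 10 %, 1 decimal
above), matching scientific reporting practice for values spanning four
orders of magnitude. One benchmark cell (β-chitin release rate) is
internally inconsistent with this convention in its source and is reproduced
by the convention (0.00), not the printed anomaly (0.001).

## Problem sizes and numerical choices

Test and acceptance runs use: exhaustive isomer ranking for all patterns of
DP ≤ 6 (126 patterns); 1000 random sequences (length ≤ 500) for the
brute-force motif oracle; n = 10 000 molecules for simulator/closed-form
agreement (3 s.e. band); 100 seeds for jitter-recovery rates; 10 000
molecules and a 600 s time point for the end-to-end positional round trip.
These sizes give stable Monte-Carlo behavior while keeping the full suite in
a few seconds. Degenerate inputs are defined rather than left to chance:
empty spectra score all candidates 0 and flag ambiguity with a uniform
positional profile; empty collections yield an all-zero funnel; zero acetate
yields all-zero metrics; zero-rate positions never convert.

## Known limitations

Positional frequencies are soft, not deconvolved abundances; B ions of equal
composition are isobaric and contribute no positional information; the
signal-peptide heuristic trades sensitivity for transparency and should not
be used in place of a dedicated predictor on real data; the single-domain
length proxy will misclassify compact multi-domain proteins when no domain
annotation is supplied; the simulator's rate classes encode an ordering, not
measured constants.
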