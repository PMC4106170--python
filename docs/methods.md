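# Methods

## The model

The package rests on one empirical regularity: the chemical shift of a
backbone nucleus depends jointly on the residue type and on the local
secondary structure, and the dependence is large enough relative to
within-cell scatter to be informative. The averaged chemical shift (ACS)
table estimates that dependence non-parametrically as the pooled mean per
(atom, residue, secondary-structure) cell,

    C_k^i(j) = (1/N) Σ_N ω_k^i(j),

over a curated corpus of assigned shifts. Pooling is across all proteins'
residues (every observation weighs equally), not per-protein means of
means: the cell statistic is the mean of the N individual observations
routed to it. The table keeps, per cell, the mean (ppm), the observation
count, and the sample standard deviation; the SD is an auxiliary statistic
used for parameter-recovery checks and the missing-cell fallback, not part
of the encoding itself.

The acACS encoder converts a (sequence, secondary structure) pair into a
fixed-length vector. Each residue is replaced by its cell mean, giving a
numeric series S₁ … S_L per atom; the series is summarised by

    θ^i(λ) = (1/(L−λ)) Σ_{l=1}^{L−λ} (S_l − S_{l+λ})²,   0 < λ < L,

the mean squared difference at lag λ. Despite the field's name
"autocovariance", this is a variogram-style statistic: non-negative, zero
iff the series is λ-periodic on the matched positions, invariant to adding
a constant to the series, and scaling as a² when the series is scaled by a.
The λ = 0 slot is degenerate (θ(0) = 0 identically), so it carries the
series mean S̄^i instead — the only well-defined scalar reading of
"replace it by the average chemical shift". Blocks are emitted atom-by-atom
in the fixed order ¹⁵N, ¹³Cα, ¹Hα, ¹H_N (restricted to the selected
subset), giving |atoms| × (λ_max + 1) components, optionally followed by the
20-component AAC and 400-component DC composition blocks.

## Parameters that matter

- **λ_max** (default 12): the maximum lag. Must be smaller than the
  shortest sequence encoded. Larger λ probes longer-range alternation of
  structure but averages over fewer pairs (L − λ), so the high-lag terms
  are noisier for short proteins. 12 is the conventional working default.
- **atoms** (default all four): which nuclei contribute blocks. ¹³Cα and
  ¹Hα carry the strongest secondary-structure dependence; ¹H_N the weakest.
- **missing_policy** (default `cell_row_mean`): what a lookup does at a
  cell with no observations. `error` is strict; `cell_row_mean` substitutes
  the count-weighted mean of the same (atom, residue) across SS states
  (falling back to the atom-wide mean), which keeps proline-containing
  proteins encodable with ¹H_N; `zero` writes 0.0. The affected positions
  are always recorded on the returned series.
- **Curation**: minimum length 50 residues; identity screen at 40 %. The
  identity screen is greedy longest-first with global-alignment identity
  (matches / alignment columns, Biopython `PairwiseAligner`, match 1 /
  mismatch 0 / gap −1, −0.5). It is a deliberate simplification of CD-HIT
  so the pipeline is runnable end-to-end; it does not reproduce CD-HIT's
  word-filter clusters.
- **Classifier** (ablation harness): soft-margin SVM, RBF kernel, C = 1,
  γ = 1/n_features, features standardised to zero mean / unit variance
  using training-fold statistics only (fold-internal scaling; the held-out
  sample never touches the scaler). Jackknife means strict leave-one-out;
  stratified k-fold exists as an explicit alternative and is never
  substituted silently.

## The synthetic generator

The shift-corpus generator emulates a curated corpus of assigned backbone
shifts. Ground-truth cell means are approximate literature random-coil
values per residue (protons ≈ 4–8.5 ppm, ¹³Cα ≈ 45–63 ppm, ¹⁵N ≈ 109–135
ppm) plus conventional secondary-structure offsets with the standard signs
(helix: ¹³Cα +2.6, ¹Hα −0.35, ¹H_N −0.1, ¹⁵N −1.5 ppm; strand: −1.4, +0.40,
+0.2, +2.0). These reproduce the qualitative residue-by-structure pattern
of real averaged-shift tables; they are not a fit to any published table.
Each residue emits one draw per applicable atom from
Normal(true_mean, σ) with σ = 0.3 ppm by default — a single spread for all
atoms, chosen so that recovery tests have one known noise scale; real
corpora have atom-dependent and heavier-tailed scatter. Proline never emits
an amide proton. Secondary-structure strings are i.i.d. per position by
default; a sticky-Markov option produces realistic helix/strand run
lengths. Every draw is recorded in an emission log, so the star-file export
is a complete audit: parsing the export reproduces the log exactly.

The labeled-dataset generator draws each class's sequences and SS strings
from class-specific residue and SS distributions. The **SS-only signal**
preset gives both classes the identical (uniform) residue distribution and
SS distributions whose helix fractions differ by a configurable gap
(default 0.2, around a 0.35/0.25/0.40 H/E/C base): by construction, AAC and
DC carry no class information while the chemical-shift features do. The
**no-signal** preset makes the two classes identically distributed.

What passing these tests does *not* show about real data: real shift
corpora have referencing errors, missing assignments beyond proline,
neighbour-residue effects, and SS-prediction noise when the structure
string comes from a predictor rather than from coordinates; none of these
are simulated. The ablation result on synthetic data demonstrates that the
harness detects a structure-only signal when one exists — it is not a
reproduction of any external benchmark accuracy.

## Numerical and design choices

- Table builds sort observations into a canonical order before summation,
  so the build is exactly permutation-invariant (bit-identical tables from
  reordered input), and TSV serialisation writes full `repr` precision, so
  write → read is lossless.
- Merging corpora commutes with building: counts combine exactly, means to
  ≈ 1e-9 (floating-point summation order).
- θ(λ) is computed vectorised; an independent brute-force double-loop
  implementation lives in the test suite and the acceptance script, and the
  two agree to 1e-10 relative tolerance on randomised inputs.
- Non-standard residues (B, J, O, U, X, Z) are rejected with a
  position-listing error rather than silently coerced.
- No scaling is applied inside the encoder; standardisation is the
  evaluation harness's job, inside each training fold.
- Singleton cells get SD 0 (a defined value keeps serialisation total);
  empty cells serialise with empty mean/SD fields and load back as flagged
  missing.
- The 8-state → 3-state reduction maps {H, G, I} → H, {E, B} → E and
  everything else → C; an explicit `C` passes through, making the
  reduction idempotent on already-reduced strings. The grouping is
  configurable.
- CLI outputs are written to a temporary file and renamed on success, so a
  failed run never leaves a partial file.

## Evaluation protocol and problem sizes

Leave-one-out on pure-noise data with an RBF SVM is *below*-chance biased:
each training fold is imbalanced against the held-out sample's class, and
with no signal the classifier leans toward the fold majority. Accuracies
modestly below 50 % on the no-signal preset are therefore expected
behaviour, not a bug; the meaningful null check is that neither arm scores
significantly *above* chance.

The test suite and the acceptance script size their simulations to run in
seconds to a couple of minutes on one core: table parameter recovery uses
300 proteins of 120–180 residues (≈ 45 000 residues, ≈ 178 000
observations, ≥ 500 observations in every cell — enough for 4σ/√N bounds of
a few hundredths of a ppm), encoder-vs-oracle checks use 200 random
sequences up to length 90 with λ up to 20, and the ablation uses two
classes of 50 sequences of 60–120 residues. These sizes were chosen as the
smallest that make the statistical assertions sharp.

## Known limitations

- The ACS table conditions on (residue, SS) only; neighbour effects,
  ring-current shifts and referencing offsets are averaged into the cell
  noise.
- The identity screen is not CD-HIT; retained sets will differ from
  CD-HIT's on the same input.
- Secondary structure is a required input; the package neither runs DSSP
  nor predicts structure from sequence.
- Only the minimal one-loop-per-frame star dialect is parsed, not the full
  NMR-STAR grammar.
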