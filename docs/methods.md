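# Methods

## Overview

The pipeline identifies tryptic peptides from MS/MS fragmentation alone
under a wide precursor-mass window and validates the result set through
the physics of the delta-mass distribution and through null controls.
Every stage is a library function under `src/openps/`; the `analysis/`
scripts and `scripts/acceptance.py` are thin drivers.

## In-silico chemistry (`insilico`)

* **Digestion.** Cleavage after every K or R with no proline exception
  (the `[RK]|[X]` rule), fully tryptic, up to 3 missed cleavages by
  default. Search candidates are restricted to 5–50 residues.
* **Masses.** Residue monoisotopic masses are derived from elemental
  compositions and exact isotope masses (proton 1.00727646688 Da, water
  18.01056469 Da), so a peptide's [M+H]⁺ is consistent with the
  composition used for envelope prediction. The six default variable
  modifications are oxidation (+15.994915, M/W), +0.984016 at N/Q,
  dioxidation (+31.98983, M/W), +57.021464 at C, a C-terminal hydroxyl
  (+17.002735) and an N-terminal hydrogen (+1.007825). The two terminal
  masses are treated as variable modifications, not default termini; at
  most 2 variable modifications per peptide, one per site, with a
  256-variant cap per peptide.
* **Fragments.** Singly charged b/y ladders; b_i = prefix + proton,
  y_i = suffix + water + proton, so b_i + y_(n−i) = [M+H]⁺ + proton
  exactly (a tested invariant). Modification deltas ride with their
  prefix/suffix; terminal adducts ride with the b (N-term) or y (C-term)
  series.
* **Isotope envelope.** Exact convolution of per-element isotope
  distributions (¹³C 1.07 %, ²H 0.0115 %, ¹⁵N 0.364 %, ¹⁷O 0.038 %/¹⁸O
  0.205 %, ³³S 0.75 %/³⁴S 4.25 %; configurable), truncated at 99.99 %
  cumulative mass and renormalized. Offsets are treated as integers at a
  uniform 1.00335 Da spacing — the analysis operates at integer-Da
  resolution, so fine structure is irrelevant.
* **Delta envelope.** The isotope envelope (offsets ≥ 0) convolved with
  the hydrogen-rearrangement distribution (losses of 1–3 H at −1.00783
  Da each), truncated to [−3, +5] and renormalized. Default loss
  probabilities {−1: 0.06, −2: 0.03, −3: 0.015}: the rearrangement peaks
  are clearly visible but subordinate to the isotope peaks, matching the
  qualitative shape of high-resolution open-search delta-mass profiles;
  no published point estimates exist, so these are free parameters of
  the synthetic world and all envelope tests compare against the
  generator's own truth, not external peak heights.

## Synthetic data (`synthetic_data`)

The generator defines the study conditions; all tests run against its
ground truth.

* **Library.** Random proteins (default 40; lengths uniform 80–600;
  residue frequencies approximating the human proteome), accessions
  P0001…, gene symbols G0001…. The last 20 proteins carry zero
  abundance: they are searchable but never sampled, giving every
  replicate a built-in false-protein ground truth (an entrapment set).
* **Abundance.** Protein abundance is log-normal (σ = 0.8 in log₁₀),
  drawn deterministically from (seed, n_proteins) so an OIT-like and a
  LIT-like run of the same seed observe the same sample.
* **Spectra.** For each of n_spectra events: a protein is drawn ∝
  abundance, a tryptic peptide uniformly among its eligible peptides
  (6–30 residues, feasible at z ∈ {2,3} within 500–2000 m/z), a charge
  (2: 70 %, 3: 30 % among feasible), an isotopologue offset k from the
  peptide's isotope envelope, and a rearrangement loss from the default
  loss distribution. Observed precursor m/z = (mono [M+H]⁺ + k·1.00335 −
  loss·1.00783 − proton)/z + proton + Gaussian m/z error (σ 0.005 Da
  OIT-like, 0.2 Da LIT-like). Precursor intensity is a truncated log₁₀
  Gaussian per instrument (OIT-like 8 ± 0.8 over 6–10; LIT-like 5 ± 0.6
  over 4–7); the instruments' different intensity-sampling behavior is
  represented directly by these distributions. Fragments: a random
  20–60 % of the b/y ladder (≥ 3 peaks) with Gaussian m/z jitter
  (σ 0.15 Da) and log-normal intensities, plus 10 uniform noise peaks in
  150–2000 m/z.
* **Blank runs.** Noise-only peak lists; precursor intensity log-uniform
  over E2–E5 so a fraction survives the E3 filter and the analytical
  control genuinely participates downstream.
* **Random-MS/MS control.** Precursor m/z (clipped to 350–2000 at
  z ∈ {2,3}, i.e. 700–6000 Da neutral mass), charge, per-spectrum
  fragment counts, fragment m/z (clipped to 150–2000, z = 1) and all
  intensities are resampled from the empirical distributions of a
  template run, so the null is matched to the experiment.

What the generator does **not** emulate: chromatographic elution and
dynamic exclusion, fragment charge states above 1, correlated fragment
intensities, non-tryptic backgrounds, and real spectral libraries'
sequence homology. Passing tests therefore demonstrate that the
statistics behave as designed under the stated generative model, not
that the engine matches production search engines on real data.

## Search (`search`)

* Windows: wide = delta mass ∈ [−3, +5] Da (default; a symmetric ±3 is
  one config away), monoisotopic = ±0.1 Da. Spectra outside 500–2000
  m/z, with charge ∉ {2,3}, or below the E3 precursor-intensity
  threshold are not searched.
* Preprocessing keeps the 50 most intense fragment peaks and normalizes
  the apex to 100 — fixed for reproducibility.
* Matching is greedy in ascending ion m/z: each theoretical b/y ion
  takes the nearest not-yet-consumed peak within ±0.5 Da (ties to the
  lower-m/z peak), so no peak's intensity is counted twice. Hyperscore
  factorials are capped at 20! to avoid overflow.
* **p-values.** Candidate scores are histogrammed as log₁₀(1+H) in
  0.5-wide bins; the log₁₀ survival count is fit by least squares over
  the populated bins above the mode (survival ≥ 1; the mode bin itself
  joins the fit when fewer than two such bins exist, the sparse-null
  case where most candidates score zero) and the line — required to
  slope downward — is extrapolated to the candidate's score;
  p = min(1, e). Two refinements keep the null honest at desk scale:
  the evaluated candidate's own score is removed from the histogram
  (leave-one-out), and inside the engine each candidate's null excludes
  all candidates sharing a parent protein, because a true peptide's
  modified variants and missed-cleavage relatives share most of the
  fragment ladder and would otherwise flatten the fitted tail exactly
  when a spectrum contains a true match. With fewer than 2 usable tail
  bins the fallback is rank/n over the candidates. Measured on the
  default generator: > 95 % of confidently fragmented true spectra are
  accepted while blank and random-control acceptance stays at or below
  the 1 % implied by p ≤ 0.01.
* **BFPS.** One PSM per spectrum — highest hyperscore, ties broken by
  smaller |Δm| then lexicographic modified sequence — then the p ≤ 0.01
  filter.
* **Monoisotopic mode.** The pipeline's strict-mass condition is the
  |Δm| ≤ 0.1 Da slice of the wide-window result (one search, restricted
  afterwards), which makes the strict result an exact subset of the
  wide result by construction; a genuine ±0.1 Da candidate window is
  also available for the candidate-retrieval primitive.

## Delta-mass analysis (`deltamass`)

Histograms over [−3.5, +5.5] Da (bin 0.01 Da for OIT-like, 0.1 Da for
LIT-like); integer peaks at physical centers (k·1.00335 for k ≥ 0,
k·(−1.00783)… i.e. −1.00783 per lost H for k < 0; plain-integer centers
available). A peak is detected when its apex bin exceeds 5× the median
background bin count within ±0.5 Da (tolerance window excluded; the
background floor is 1 count so empty neighborhoods don't auto-detect).
Envelope agreement is the Pearson correlation between detected peak
mass fractions and the predicted delta envelope over the detected
support (undefined and flagged below 3 detected peaks); the
within-tolerance fraction is the share of all PSM delta masses within
±0.05 Da of some integer center.

## Protein statistics (`protein_stats`)

Spectral counts (observation frequencies) per (gene symbol, peptide
species) per source; random-control counts are rescaled by
(sample spectra / random spectra). The χ² statistic is one-sided —
(n − E)²/E when n exceeds E = max(blank + rescaled random, 1), else 0 —
and the gate passes at χ² ≥ 9. The gate is applied to gene-level
aggregated counts: at desk scale individual peptide species rarely
collect the ≥ 4 spectra a per-row gate with pseudo-expectation 1 would
demand, so per-row filtering (available via
`ProteinCallConfig.row_chi2_filter`) would starve true proteins; at the
scale where each species collects hundreds of spectra the two choices
coincide. The gene-symbol cumulative p-value is Fisher's method over
the accepted BFPS p-values (X = −2Σln pᵢ ~ χ²₂ₖ); q-values are
Benjamini–Hochberg step-up; acceptance requires the χ² pass, n ≥ 3
spectral counts, and q ≤ 0.01. Peptides shared by several gene symbols
are counted once, under the lexicographically smallest symbol.

## Comparisons (`compare`)

Venn overlaps on accepted gene-symbol sets; OLS of log₁₀ spectral
counts over gene symbols accepted in both conditions (slope, intercept,
adjusted R², F, p, residual SE — via statsmodels, verified against
closed-form normal equations); type-II error of a restricted analysis
as 1 − n_restricted/n_wide. The cross-instrument delta-mass *density*
regression is not implemented: what is regressed on what is
underdetermined, and the count regression carries the same comparison.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: 600 sample
spectra with matched controls per replicate (20 replicates for the FDR
check, 5 in the acceptance script) against 40-protein libraries, and
20,000 ground-truth spectra for envelope recovery (where no search is
needed, the generator's own assignments give the delta masses).
Degenerate inputs are handled explicitly: empty candidate sets yield no
PSM; all-identical score histograms fall back to rank p-values; empty
control counts use the pseudo-expectation floor of 1; correlation over
fewer than 3 detected peaks is flagged rather than computed. All
generators and the search are deterministic under a fixed seed, and
re-running the pipeline reproduces its output tables byte for byte.

## Known limitations

* The expectation-value calibration is approximate for spectra with few
  candidates; the rank fallback is conservative there.
* Hydrogen-rearrangement probabilities are free parameters; absolute
  peak heights in the delta-mass profile are meaningful only relative
  to the generator that produced them.
* Gene-symbol aggregation uses a deterministic single-assignment rule
  for shared peptides rather than protein-grouping parsimony.
* Fragment matching is z = 1 b/y only; a/c/x/z ions, neutral losses and
  multiply charged fragments are out of scope.
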