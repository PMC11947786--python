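# openps

Open-window peptide–spectrum matching with delta-mass validation,
random-spectrum null controls, and protein-level FDR — an end-to-end
analysis pipeline exercised on synthetic two-instrument MS/MS data.

## The problem

Shotgun proteomics engines usually demand an accurate precursor mass
before they will even score a fragmentation spectrum. That discards the
many precursors observed at non-monoisotopic masses: heavy-isotope
envelopes put real signal at +1 to +5 Da above the monoisotopic
[M+H]⁺ (≈ k × 1.00335 Da from k ¹³C substitutions), and gas-phase
hydrogen rearrangements shift tryptic peptide ions to −1…−3 Da
(≈ −k × 1.00783 Da). This package implements the alternative strategy:
identify peptides from the MS/MS fragments alone under a wide
(−3/+5 Da) precursor window, then *validate* the identifications two
ways —

* **biophysically**: the delta mass Δm = observed [M+H]⁺ − theoretical
  monoisotopic [M+H]⁺ of all accepted matches must concentrate at the
  integer-Da offsets predicted by convolving the peptides' isotope
  envelopes with the hydrogen-rearrangement distribution;
* **statistically**: observation frequencies are corrected against
  blank (noise-only) injections and a random-MS/MS control matched to
  the experimental spectra, with a one-sided χ² ≥ 9 gate, Fisher-combined
  gene-symbol p-values, and Benjamini–Hochberg q ≤ 0.01.

Matching uses the hyperscore: for a candidate peptide with b/y fragment
ladder matched to the spectrum within ±0.5 Da,

    H = (Σ matched intensities) × n_b! × n_y!

and the PSM p-value is the expectation value obtained by extrapolating
the linear right tail of log₁₀ survival of the spectrum's
candidate-score histogram to the candidate's score. Each spectrum is
assigned to its single best-fit peptide (BFPS) and matches with
p > 0.01 are discarded; an E3 physical filter (precursor intensity
≥ 1000 counts) is applied before any matching.

Because the original raw data are instrument-scale, the package ships a
first-class synthetic-data module emulating two instrument archetypes —
an orbital-trap-like instrument (OIT-like: σ(m/z) = 0.005 Da, log₁₀
intensity centered at E8 over E6–E10) and a linear-trap-like instrument
(LIT-like: σ(m/z) = 0.2 Da, centered at E5 over E4–E7) — with known
ground truth, so error rates are measured against truth rather than
assumed.

## Layout

    src/openps/          the library: io_formats, insilico, synthetic_data,
                         search, deltamass, protein_stats, compare
    analysis/            numbered drivers: 01_simulate … 05_compare
    scripts/acceptance.py  recomputes the headline numbers from scratch
    tests/               pytest suite (unit, property, end-to-end)

## Worked example

    python analysis/01_simulate.py
    python analysis/02_search.py
    python analysis/04_proteins.py
    python analysis/05_compare.py

which prints (seed 1, 40-protein library with 20 held-out proteins, 600
spectra per run):

    oit_like_s1 (SAMPLE): 352/600 spectra accepted at p <= 0.01 (128 monoisotopic)
    random_oit_like_s1 (RANDOM): 1/600 spectra accepted at p <= 0.01 (0 monoisotopic)
    blank_s1 (BLANK): 0/150 spectra accepted at p <= 0.01 (0 monoisotopic)
    ...
    oit_wide: 9 gene symbols accepted (n >= 3, chi2 >= 9, q <= 0.01) of 16 observed
    oit_mono: 5 gene symbols accepted (n >= 3, chi2 >= 9, q <= 0.01) of 13 observed
    ...
    OIT vs LIT log10-count regression over 9 shared gene symbols: slope 0.946,
    adjusted R^2 0.899, F = 72.6 on (1, 7) df, p = 6.08e-05

Reading: over half the sample spectra yield a confident identification
under the wide window while the random-spectrum and blank controls stay
at the sub-1% level expected from the p ≤ 0.01 threshold; restricting
to the monoisotopic mass (|Δm| ≤ 0.1 Da) keeps only a nested subset of
the identifications; and the two instrument archetypes quantify the
same proteins (log-count slope ≈ 1, highly significant). The delta-mass
profile of the accepted matches (`analysis/03_deltamass.py`) shows the
integer peaks at −3…+5 Da with near-perfect correlation to the
predicted envelope at OIT-like resolution, and a blurred 0…+2 Da hump
at LIT-like resolution.

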