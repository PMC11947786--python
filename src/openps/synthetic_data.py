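"""Seeded generators for everything the pipeline consumes.

Emulates two instrument archetypes observing tryptic digests of a small
protein library with log-normal protein abundance:

* OIT-like (orbital-trap-like): precursor m/z error sigma 0.005 Da,
  log10 precursor intensity Gaussian centered at E8 over E6-E10;
* LIT-like (linear-trap-like): precursor m/z error sigma 0.2 Da,
  log10 precursor intensity Gaussian centered at E5 over E4-E7.

Each sampled precursor carries an isotopologue offset k drawn from the
peptide's heavy-isotope envelope and a hydrogen-rearrangement loss drawn
from the configured loss probabilities, so the true delta mass is
k * 1.00335 - loss * 1.00783 Da. Fragment spectra are partial b/y
ladders with m/z jitter plus uniform noise peaks. Blank (noise-only)
runs and a random-spectrum statistical control (precursors 350-2000 m/z
at z = 2-3, i.e. 700-6000 Da neutral mass; z = 1 fragments in 150-2000
m/z, resampled from an experimental template) complete the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    H_ATOM,
    HUMAN_RESIDUE_FREQUENCY,
    ISOTOPE_SPACING,
    PROTON,
)
from .insilico import PeptideSpecies, digest, isotope_envelope, ladder_arrays
from .io_formats import ProteinRecord, Spectrum

INSTRUMENT_DEFAULTS = {
    # (precursor_mz_sigma, log10 intensity mean, sd, (lo, hi))
    "OIT_LIKE": (0.005, 8.0, 0.8, (6.0, 10.0)),
    "LIT_LIKE": (0.2, 5.0, 0.6, (4.0, 7.0)),
}


@dataclass
class SimConfig:
    """Study conditions for one simulated run."""

    seed: int = 0
    n_proteins: int = 40
    #: trailing proteins of the library carry zero abundance; they are
    #: searchable but never sampled, providing false-protein ground truth
    n_absent_proteins: int = 20
    protein_length: tuple = (80, 600)
    abundance_sigma: float = 0.8  # log10 spread of protein abundance
    instrument: str = "OIT_LIKE"
    n_spectra: int = 2000
    precursor_mz_sigma: float | None = None  # None -> instrument default
    fragment_mz_sigma: float = 0.15
    log10_intensity_mean: float | None = None
    log10_intensity_sd: float | None = None
    log10_intensity_range: tuple | None = None
    h_loss_probs: dict = field(
        default_factory=lambda: {-1: 0.06, -2: 0.03, -3: 0.015}
    )
    noise_peaks_per_spectrum: int = 10
    n_blank_spectra: int = 200
    charge_probs: dict = field(default_factory=lambda: {2: 0.7, 3: 0.3})
    # digestion/selection of generated peptides
    gen_max_missed: int = 1
    gen_length_range: tuple = (6, 30)
    precursor_mz_range: tuple = (500.0, 2000.0)
    fragment_retention: tuple = (0.2, 0.6)

    def instrument_params(self):
        mz_sigma, mean, sd, rng_ = INSTRUMENT_DEFAULTS[self.instrument]
        return (
            self.precursor_mz_sigma if self.precursor_mz_sigma is not None else mz_sigma,
            self.log10_intensity_mean if self.log10_intensity_mean is not None else mean,
            self.log10_intensity_sd if self.log10_intensity_sd is not None else sd,
            self.log10_intensity_range if self.log10_intensity_range is not None else rng_,
        )


@dataclass(frozen=True)
class GroundTruthEntry:
    spectrum_id: str
    peptide_key: str
    sequence: str
    gene_symbol: str
    accession: str
    mono_mh: float
    isotopologue_k: int
    h_loss: int  # number of hydrogens lost (0-3)
    charge: int

    @property
    def true_delta(self) -> float:
        return self.isotopologue_k * ISOTOPE_SPACING - self.h_loss * H_ATOM


@dataclass
class GroundTruth:
    """Per-spectrum truth for a simulated run, for recovery checks."""

    entries: list
    present_genes: frozenset
    run_id: str

    def by_spectrum(self) -> dict:
        return {e.spectrum_id: e for e in self.entries}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = list(HUMAN_RESIDUE_FREQUENCY)
    probs = np.array(list(HUMAN_RESIDUE_FREQUENCY.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def random_protein(rng: np.random.Generator, length: int, accession: str,
                   gene_symbol: str) -> ProteinRecord:
    return ProteinRecord(accession, gene_symbol, _random_sequence(rng, length))


def make_library(config: SimConfig) -> list[ProteinRecord]:
    """Random protein library: accessions P0001..., gene symbols G0001...

    Sequence lengths are uniform over ``protein_length`` and residues
    follow approximate human-proteome frequencies.
    """
    if config.n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    rng = np.random.default_rng([config.seed, 101])
    records = []
    lo, hi = config.protein_length
    for i in range(1, config.n_proteins + 1):
        length = int(rng.integers(lo, hi + 1))
        records.append(random_protein(rng, length, f"P{i:04d}", f"G{i:04d}"))
    return records


def protein_abundances(config: SimConfig) -> np.ndarray:
    """Log-normal abundance weights, deterministic in (seed, n_proteins).

    The same seed therefore yields the same protein abundances for an
    OIT-like and a LIT-like run, as when one sample is split across two
    instruments. The last ``n_absent_proteins`` get zero weight.
    """
    rng = np.random.default_rng([config.seed, 202])
    log_ab = rng.normal(0.0, config.abundance_sigma, size=config.n_proteins)
    w = 10.0 ** log_ab
    n_absent = min(config.n_absent_proteins, config.n_proteins - 1)
    if n_absent:
        w[config.n_proteins - n_absent :] = 0.0
    return w


def eligible_peptides(library, config: SimConfig) -> list[list[PeptideSpecies]]:
    """Per-protein tryptic peptides that can appear as 2+/3+ precursors
    inside the instrument's precursor m/z range."""
    lo_len, hi_len = config.gen_length_range
    mz_lo, mz_hi = config.precursor_mz_range
    out = []
    for protein in library:
        peps = []
        for pep in digest(protein, config.gen_max_missed):
            if not lo_len <= len(pep.sequence) <= hi_len:
                continue
            feasible = [
                z for z in (2, 3)
                if mz_lo <= (pep.mono_mh - PROTON) / z + PROTON <= mz_hi
            ]
            if feasible:
                peps.append(pep)
        out.append(peps)
    return out


def _truncated_log10_normal(rng, mean, sd, lo, hi, size):
    vals = rng.normal(mean, sd, size=size)
    bad = (vals < lo) | (vals > hi)
    while bad.any():
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (vals < lo) | (vals > hi)
    return 10.0 ** vals


def simulate_run(library, config: SimConfig, run_id: str | None = None):
    """Simulate one instrument run. Returns (spectra, ground_truth)."""
    mz_sigma, li_mean, li_sd, li_range = config.instrument_params()
    run_id = run_id or f"{config.instrument.lower()}_s{config.seed}"
    rng = np.random.default_rng([config.seed, 303, sum(map(ord, config.instrument))])

    weights = protein_abundances(config)
    per_protein = eligible_peptides(library, config)
    usable = np.array([w if peps else 0.0 for w, peps in zip(weights, per_protein)])
    if usable.sum() <= 0:
        raise ValueError("library digest yielded no eligible peptides")
    probs = usable / usable.sum()

    # cache envelopes per sequence; they depend only on composition
    env_cache: dict[str, np.ndarray] = {}

    loss_offsets = np.array([0, 1, 2, 3])
    loss_probs = np.array(
        [1.0 - sum(config.h_loss_probs.values())]
        + [config.h_loss_probs.get(-k, 0.0) for k in (1, 2, 3)]
    )

    charges = np.array(sorted(config.charge_probs))
    charge_p = np.array([config.charge_probs[z] for z in charges], dtype=float)
    charge_p = charge_p / charge_p.sum()

    intensities = _truncated_log10_normal(
        rng, li_mean, li_sd, li_range[0], li_range[1], config.n_spectra
    )

    mz_lo, mz_hi = config.precursor_mz_range
    ret_lo, ret_hi = config.fragment_retention
    spectra, entries = [], []
    for i in range(config.n_spectra):
        p_idx = int(rng.choice(len(library), p=probs))
        pep = per_protein[p_idx][int(rng.integers(len(per_protein[p_idx])))]
        feasible = [
            z for z in charges
            if mz_lo <= (pep.mono_mh - PROTON) / z + PROTON <= mz_hi
        ]
        if len(feasible) == 1:
            z = int(feasible[0])
        else:
            z = int(rng.choice(charges, p=charge_p))

        env = env_cache.get(pep.sequence)
        if env is None:
            env = isotope_envelope(pep.composition).as_array()
            env_cache[pep.sequence] = env
        k = int(rng.choice(len(env), p=env / env.sum()))
        loss = int(rng.choice(loss_offsets, p=loss_probs))

        true_mh = pep.mono_mh + k * ISOTOPE_SPACING - loss * H_ATOM
        prec_mz = (true_mh - PROTON) / z + PROTON + rng.normal(0.0, mz_sigma)

        ion_mz, _ = ladder_arrays(pep)
        n_ions = ion_mz.size
        retain = max(3, int(round(rng.uniform(ret_lo, ret_hi) * n_ions)))
        retain = min(retain, n_ions)
        keep = rng.choice(n_ions, size=retain, replace=False)
        frag_mz = ion_mz[keep] + rng.normal(0.0, config.fragment_mz_sigma, size=retain)
        frag_int = 10.0 ** rng.normal(1.5, 0.4, size=retain)
        noise_mz = rng.uniform(150.0, 2000.0, size=config.noise_peaks_per_spectrum)
        noise_int = 10.0 ** rng.normal(0.6, 0.3, size=config.noise_peaks_per_spectrum)

        sid = f"{run_id}:{i:06d}"
        spectra.append(
            Spectrum(
                spectrum_id=sid,
                run_id=run_id,
                instrument_label=config.instrument,
                run_kind="SAMPLE",
                precursor_mz=float(prec_mz),
                precursor_charge=z,
                precursor_intensity=float(intensities[i]),
                mz=np.concatenate([frag_mz, noise_mz]),
                intensity=np.concatenate([frag_int, noise_int]),
            )
        )
        entries.append(
            GroundTruthEntry(
                spectrum_id=sid,
                peptide_key=pep.key,
                sequence=pep.sequence,
                gene_symbol=sorted(pep.parent_genes)[0],
                accession=sorted(pep.parent_accessions)[0],
                mono_mh=pep.mono_mh,
                isotopologue_k=k,
                h_loss=loss,
                charge=z,
            )
        )
    present = frozenset(
        g.gene_symbol for g, w in zip(library, weights) if w > 0
    )
    return spectra, GroundTruth(entries=entries, present_genes=present, run_id=run_id)


def true_delta_masses(spectra, truth: GroundTruth) -> np.ndarray:
    """Delta masses of a simulated run under the true assignments:
    observed [M+H]+ (from precursor m/z and charge) minus the generated
    peptide's theoretical monoisotopic [M+H]+. Isolates the delta-mass
    physics from search performance."""
    by_id = truth.by_spectrum()
    deltas = []
    for s in spectra:
        e = by_id[s.spectrum_id]
        observed = (s.precursor_mz - PROTON) * s.precursor_charge + PROTON
        deltas.append(observed - e.mono_mh)
    return np.array(deltas)


def simulate_blank(config: SimConfig, run_id: str | None = None) -> list[Spectrum]:
    """Noise-only spectra emulating blank solvent injections.

    Precursor intensities are log-uniform over E2-E5, so a subset
    survives the downstream E3 intensity filter and genuinely exercises
    the analytical control.
    """
    run_id = run_id or f"blank_s{config.seed}"
    rng = np.random.default_rng([config.seed, 404])
    spectra = []
    for i in range(config.n_blank_spectra):
        n_peaks = max(5, config.noise_peaks_per_spectrum + int(rng.integers(-3, 12)))
        mz = rng.uniform(150.0, 2000.0, size=n_peaks)
        intensity = 10.0 ** rng.normal(0.6, 0.3, size=n_peaks)
        spectra.append(
            Spectrum(
                spectrum_id=f"{run_id}:{i:06d}",
                run_id=run_id,
                instrument_label=config.instrument,
                run_kind="BLANK",
                precursor_mz=float(rng.uniform(*config.precursor_mz_range)),
                precursor_charge=int(rng.choice([2, 3])),
                precursor_intensity=float(10.0 ** rng.uniform(2.0, 5.0)),
                mz=mz,
                intensity=intensity,
            )
        )
    return spectra


def generate_random_msms(n: int, template_run, seed: int,
                         run_id: str | None = None) -> list[Spectrum]:
    """Random-spectrum statistical control matched to a template run.

    Precursor m/z (clipped to 350-2000 at z = 2-3), per-spectrum
    fragment counts, fragment m/z (clipped to 150-2000 at z = 1) and all
    intensities are resampled from the empirical distributions of
    ``template_run``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not template_run:
        raise ValueError("template run is empty")
    rng = np.random.default_rng([seed, 505])
    run_id = run_id or f"random_s{seed}"

    prec_mz = np.array([s.precursor_mz for s in template_run])
    prec_int = np.array([s.precursor_intensity for s in template_run])
    charges_t = np.array([s.precursor_charge for s in template_run])
    counts = np.array([s.n_peaks for s in template_run])
    pool_mz = np.concatenate([s.mz for s in template_run])
    pool_int = np.concatenate([s.intensity for s in template_run])
    ok = (pool_mz >= 150.0) & (pool_mz <= 2000.0)
    pool_mz, pool_int = pool_mz[ok], pool_int[ok]

    spectra = []
    for i in range(n):
        j = int(rng.integers(len(template_run)))
        mzp = float(np.clip(prec_mz[j], 350.0, 2000.0))
        n_frag = max(1, int(counts[int(rng.integers(len(counts)))]))
        pick = rng.integers(pool_mz.size, size=n_frag)
        spectra.append(
            Spectrum(
                spectrum_id=f"{run_id}:{i:06d}",
                run_id=run_id,
                instrument_label=template_run[0].instrument_label,
                run_kind="RANDOM",
                precursor_mz=mzp,
                precursor_charge=int(charges_t[j]),
                precursor_intensity=float(prec_int[int(rng.integers(len(prec_int)))]),
                mz=pool_mz[pick],
                intensity=pool_int[pick],
            )
        )
    return spectra
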