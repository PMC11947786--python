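"""In-silico peptide chemistry.

Tryptic digestion (cleave after every K or R, no proline exception),
variable-modification expansion, monoisotopic [M+H]+ masses, b/y
fragment ladders, and isotope / delta-mass envelope prediction.

The delta-mass envelope is the pipeline's biophysical yardstick: the
convolution of a peptide population's heavy-isotope envelope (offsets
0,+1,+2,... Da, dominated by 13C) with the gas-phase hydrogen
rearrangement distribution (losses of 1-3 H, i.e. -1..-3 Da), truncated
to the -3..+5 Da window the open search accepts.
"""

from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    H_ATOM,
    ISOTOPE_ABUNDANCE,
    PROTON,
    RESIDUE_COMPOSITION,
    RESIDUE_MASS,
    WATER,
)
from .io_formats import ProteinRecord

logger = logging.getLogger(__name__)

N_TERM = "N-term"
C_TERM = "C-term"


@dataclass(frozen=True)
class Modification:
    name: str
    targets: frozenset
    delta_mass: float

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"{self.name}: empty target set")
        if not np.isfinite(self.delta_mass):
            raise ValueError(f"{self.name}: non-finite delta mass")


# The default variable-modification set: oxidation and di-oxidation of
# M/W, deamidation-type +1 at N/Q, +57.021464 at C, and the two terminal
# adducts (C-terminal hydroxyl, N-terminal hydrogen), all monoisotopic.
DEFAULT_MODIFICATIONS = (
    Modification("ox", frozenset("MW"), 15.994915),
    Modification("plus1", frozenset("NQ"), 0.984016),
    Modification("diox", frozenset("MW"), 31.98983),
    Modification("cys57", frozenset("C"), 57.021464),
    Modification("cterm_oh", frozenset({C_TERM}), 17.002735),
    Modification("nterm_h", frozenset({N_TERM}), 1.007825),
)


def peptide_composition(sequence: str) -> dict:
    """Elemental composition (C,H,N,O,S) of the neutral peptide."""
    comp = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}  # start from H2O
    for aa in sequence:
        try:
            rc = RESIDUE_COMPOSITION[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
        for el, n in rc.items():
            comp[el] += n
    return {el: n for el, n in comp.items() if n}


def mono_mh(sequence: str, modifications=()) -> float:
    """Monoisotopic [M+H]+ : residue masses + water + proton + mod deltas."""
    try:
        m = sum(RESIDUE_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    m += WATER + PROTON
    m += sum(mod.delta_mass for _, mod in modifications)
    return m


@dataclass(frozen=True)
class PeptideSpecies:
    """A (possibly modified) peptide with its theoretical mass.

    ``modifications`` holds ``(position, Modification)`` pairs where the
    position is a 1-based residue index or a terminus marker. The
    elemental composition is that of the unmodified backbone; the
    modification deltas are carried separately in ``mono_mh``.
    """

    sequence: str
    modifications: tuple = ()
    missed_cleavages: int = 0
    parent_accessions: frozenset = frozenset()
    parent_genes: frozenset = frozenset()

    @functools.cached_property
    def mono_mh(self) -> float:
        return mono_mh(self.sequence, self.modifications)

    @functools.cached_property
    def composition(self) -> dict:
        return peptide_composition(self.sequence)

    @functools.cached_property
    def key(self) -> str:
        """Canonical modified-sequence string, e.g. PEPT[ox@2]IDE-style."""
        if not self.modifications:
            return self.sequence
        tags = ",".join(
            f"{mod.name}@{pos}"
            for pos, mod in sorted(
                self.modifications, key=lambda pm: (str(pm[0]), pm[1].name)
            )
        )
        return f"{self.sequence}[{tags}]"


# ---------------------------------------------------------------------------
# Digestion

def cleavage_sites(sequence: str) -> list[int]:
    """Indices after which trypsin cuts: after every K or R."""
    return [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]


def digest(protein: ProteinRecord, max_missed: int = 3) -> list[PeptideSpecies]:
    """Fully tryptic peptides with 0..max_missed internal missed cleavages."""
    seq = protein.sequence
    bounds = [0] + cleavage_sites(seq)
    if bounds[-1] != len(seq):
        bounds.append(len(seq))
    peptides = []
    n = len(bounds)
    for i in range(n - 1):
        for j in range(i + 1, min(i + 2 + max_missed, n)):
            peptides.append(
                PeptideSpecies(
                    sequence=seq[bounds[i] : bounds[j]],
                    missed_cleavages=j - i - 1,
                    parent_accessions=frozenset({protein.accession}),
                    parent_genes=frozenset({protein.gene_symbol}),
                )
            )
    return peptides


# ---------------------------------------------------------------------------
# Variable modifications

def expand_modifications(
    peptide: PeptideSpecies,
    mod_set=DEFAULT_MODIFICATIONS,
    max_var_mods: int = 2,
    cap: int = 256,
) -> list[PeptideSpecies]:
    """The unmodified species plus every combination of <= max_var_mods
    variable modifications, one modification per site at most.

    Expansion past ``cap`` variants is truncated with a warning.
    """
    sites = []
    for mod in mod_set:
        if N_TERM in mod.targets:
            sites.append((N_TERM, mod))
        if C_TERM in mod.targets:
            sites.append((C_TERM, mod))
        for i, aa in enumerate(peptide.sequence, start=1):
            if aa in mod.targets:
                sites.append((i, mod))

    variants = [peptide]
    truncated = False
    for k in range(1, max_var_mods + 1):
        for combo in itertools.combinations(sites, k):
            positions = [pos for pos, _ in combo]
            if len(set(positions)) != len(positions):
                continue  # one modification per site
            if len(variants) >= cap:
                truncated = True
                break
            variants.append(
                PeptideSpecies(
                    sequence=peptide.sequence,
                    modifications=tuple(combo),
                    missed_cleavages=peptide.missed_cleavages,
                    parent_accessions=peptide.parent_accessions,
                    parent_genes=peptide.parent_genes,
                )
            )
        if truncated:
            break
    if truncated:
        logger.warning(
            "peptide %s: modification expansion truncated at %d variants",
            peptide.sequence, cap,
        )
    return variants


# ---------------------------------------------------------------------------
# Fragment ladders

def fragment_ladder(peptide: PeptideSpecies) -> list[tuple[str, int, float]]:
    """Singly charged b/y fragment ions.

    b_i = (first i residues) + proton; y_i = (last i residues) + water +
    proton. Position-localized modification deltas go with their prefix
    or suffix; terminal adducts go with b (N-term) or y (C-term) ions.
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("fragment ladder needs peptide length >= 2")
    res = np.array([RESIDUE_MASS[aa] for aa in seq])
    mod_at = np.zeros(n)
    nterm_delta = 0.0
    cterm_delta = 0.0
    for pos, mod in peptide.modifications:
        if pos == N_TERM:
            nterm_delta += mod.delta_mass
        elif pos == C_TERM:
            cterm_delta += mod.delta_mass
        else:
            mod_at[pos - 1] += mod.delta_mass
    prefix = np.cumsum(res + mod_at)
    ions = []
    for i in range(1, n):
        b = prefix[i - 1] + nterm_delta + PROTON
        y = (prefix[n - 1] - prefix[n - 1 - i]) + cterm_delta + WATER + PROTON
        ions.append(("b", i, b))
        ions.append(("y", i, y))
    return ions


def ladder_arrays(peptide: PeptideSpecies) -> tuple[np.ndarray, np.ndarray]:
    """Fragment m/z values merged and sorted ascending, with a boolean
    is_b flag per ion — the layout the scorer consumes."""
    ions = fragment_ladder(peptide)
    mz = np.array([m for _, _, m in ions])
    is_b = np.array([t == "b" for t, _, _ in ions])
    order = np.argsort(mz, kind="stable")
    return mz[order], is_b[order]


# ---------------------------------------------------------------------------
# Isotope and delta-mass envelopes

@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative abundance per integer isotopologue offset k >= 0."""

    offsets: dict

    def __post_init__(self):
        total = sum(self.offsets.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"envelope sums to {total}, not 1")
        if self.offsets.get(0, 0.0) <= 0:
            raise ValueError("monoisotopic abundance must be positive")

    def as_array(self, kmax: int | None = None) -> np.ndarray:
        kmax = max(self.offsets) if kmax is None else kmax
        arr = np.zeros(kmax + 1)
        for k, p in self.offsets.items():
            if k <= kmax:
                arr[k] = p
        return arr


@dataclass(frozen=True)
class DeltaEnvelope:
    """Predicted probability per integer delta-mass offset in -3..+5 Da."""

    offsets: dict

    def __post_init__(self):
        if any(k < -3 or k > 5 for k in self.offsets):
            raise ValueError("delta envelope support must lie in [-3, +5]")
        total = sum(self.offsets.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"delta envelope sums to {total}, not 1")

    def as_array(self) -> np.ndarray:
        """Probabilities at k = -3..+5 as a length-9 vector."""
        return np.array([self.offsets.get(k, 0.0) for k in range(-3, 6)])


def _element_envelope(n_atoms: int, dist: dict) -> np.ndarray:
    """Offset distribution of n_atoms i.i.d. atoms via repeated squaring."""
    base = np.zeros(max(dist) + 1)
    for k, p in dist.items():
        base[k] = p
    result = np.array([1.0])
    power = base
    n = n_atoms
    while n:
        if n & 1:
            result = np.convolve(result, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return result


def isotope_envelope(
    composition: dict,
    abundances: dict | None = None,
    cumulative_mass: float = 0.9999,
) -> IsotopeEnvelope:
    """Integer-offset heavy-isotope envelope of an elemental composition.

    Convolves the per-element isotope-abundance distributions and
    truncates once ``cumulative_mass`` of the probability is covered,
    renormalizing the retained offsets.
    """
    abundances = abundances or ISOTOPE_ABUNDANCE
    dist = np.array([1.0])
    for el, n in composition.items():
        if n < 0:
            raise ValueError(f"negative atom count for {el}")
        if n == 0:
            continue
        dist = np.convolve(dist, _element_envelope(n, abundances[el]))
    keep = int(np.searchsorted(np.cumsum(dist), cumulative_mass)) + 1
    dist = dist[:keep]
    dist = dist / dist.sum()
    return IsotopeEnvelope({k: float(p) for k, p in enumerate(dist) if p > 0})


def delta_envelope(envelope: IsotopeEnvelope, h_loss_probs: dict) -> DeltaEnvelope:
    """Convolve the isotope envelope with the H-rearrangement distribution.

    ``h_loss_probs`` maps offsets {-1,-2,-3} to probabilities; the
    remainder up to 1 is the probability of no rearrangement. The result
    is truncated to [-3, +5] and renormalized.
    """
    for k, p in h_loss_probs.items():
        if k not in (-1, -2, -3):
            raise ValueError(f"rearrangement offset {k} outside -1..-3")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    total_loss = sum(h_loss_probs.values())
    if total_loss > 1.0 + 1e-12:
        raise ValueError("h_loss_probs sum exceeds 1")
    loss = {0: 1.0 - total_loss, **h_loss_probs}
    out: dict[int, float] = {}
    for i, pi in envelope.offsets.items():
        for j, pj in loss.items():
            k = i + j
            if -3 <= k <= 5:
                out[k] = out.get(k, 0.0) + pi * pj
    norm = sum(out.values())
    return DeltaEnvelope({k: p / norm for k, p in sorted(out.items())})
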