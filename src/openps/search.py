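"""Peptide-spectrum matching under monoisotopic or wide precursor windows.

The engine retrieves candidate peptides whose theoretical [M+H]+ lies
within the configured delta-mass window of the observed [M+H]+
(reconstructed from precursor m/z and charge), scores each candidate
with a hyperscore — the summed intensity of matched b/y fragments times
the factorials of the matched b- and y-ion counts — and converts the
score to an expectation-style p-value by extrapolating the linear right
tail of the log10 survival function of the spectrum's candidate-score
histogram. Each spectrum is then assigned to its single best-fit
peptide (best fit per spectrum, BFPS) and PSMs above the p threshold
are discarded.

An E3 physical filter (precursor intensity >= 1000 counts) limits
type I error before any matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import PROTON
from .insilico import (
    DEFAULT_MODIFICATIONS,
    PeptideSpecies,
    digest,
    expand_modifications,
    ladder_arrays,
)
from .io_formats import Spectrum

FACTORIAL_CAP = math.factorial(20)


@dataclass(frozen=True)
class SearchConfig:
    window_mode: str = "WIDE"  # WIDE: [-3, +5] Da; MONO: [-0.1, +0.1] Da
    window_lo: float | None = None
    window_hi: float | None = None
    fragment_tol: float = 0.5
    min_precursor_intensity: float = 1000.0
    max_psm_p: float = 0.01
    charges: tuple = (2, 3)
    precursor_mz_range: tuple = (500.0, 2000.0)
    top_peaks: int = 50
    max_missed: int = 3
    min_length: int = 5
    max_length: int = 50
    max_var_mods: int = 2
    mod_variant_cap: int = 256

    def window(self) -> tuple[float, float]:
        if self.window_lo is not None and self.window_hi is not None:
            return self.window_lo, self.window_hi
        if self.window_mode == "WIDE":
            return -3.0, 5.0
        if self.window_mode == "MONO":
            return -0.1, 0.1
        raise ValueError(f"unknown window mode {self.window_mode!r}")


@dataclass(frozen=True)
class PSM:
    spectrum_id: str
    run_id: str
    instrument_label: str
    run_kind: str
    peptide_key: str
    sequence: str
    gene_symbol: str
    charge: int
    observed_mh: float
    mono_mh: float
    delta_mass: float
    hyperscore: float
    n_b: int
    n_y: int
    p_value: float


PSM_FIELDS = [
    "spectrum_id", "run_id", "instrument_label", "run_kind", "peptide_key",
    "sequence", "gene_symbol", "charge", "observed_mh", "mono_mh",
    "delta_mass", "hyperscore", "n_b", "n_y", "p_value",
]


class PeptideIndex:
    """Peptide species sorted by theoretical [M+H]+ for range queries.

    Fragment ladders are precomputed per species so repeated scoring
    never re-derives them.
    """

    def __init__(self, species: list[PeptideSpecies]):
        uniq: dict[str, PeptideSpecies] = {}
        for sp in species:
            prev = uniq.get(sp.key)
            if prev is None:
                uniq[sp.key] = sp
            else:
                uniq[sp.key] = replace(
                    prev,
                    parent_accessions=prev.parent_accessions | sp.parent_accessions,
                    parent_genes=prev.parent_genes | sp.parent_genes,
                )
        self.species = sorted(uniq.values(), key=lambda s: (s.mono_mh, s.key))
        self.masses = np.array([s.mono_mh for s in self.species])
        self.groups = ["|".join(sorted(s.parent_accessions)) for s in self.species]
        self._ladders = [None] * len(self.species)

    def __len__(self):
        return len(self.species)

    def query(self, lo: float, hi: float) -> list[int]:
        """Indices of species with mono [M+H]+ in [lo, hi]."""
        i = int(np.searchsorted(self.masses, lo, side="left"))
        j = int(np.searchsorted(self.masses, hi, side="right"))
        return list(range(i, j))

    def ladder(self, idx: int):
        lad = self._ladders[idx]
        if lad is None:
            lad = ladder_arrays(self.species[idx])
            self._ladders[idx] = lad
        return lad


def build_index(
    library,
    config: SearchConfig = SearchConfig(),
    mod_set=DEFAULT_MODIFICATIONS,
) -> PeptideIndex:
    """Digest a protein library and expand variable modifications."""
    species = []
    for protein in library:
        for pep in digest(protein, config.max_missed):
            if not config.min_length <= len(pep.sequence) <= config.max_length:
                continue
            species.extend(
                expand_modifications(
                    pep, mod_set, config.max_var_mods, config.mod_variant_cap
                )
            )
    return PeptideIndex(species)


def observed_mh(spectrum: Spectrum) -> float:
    """[M+H]+ reconstructed from precursor m/z and charge."""
    z = spectrum.precursor_charge
    if z not in (2, 3):
        raise ValueError(f"unsupported precursor charge {z}")
    return (spectrum.precursor_mz - PROTON) * z + PROTON


def intensity_filter(spectrum: Spectrum, config: SearchConfig) -> bool:
    """The E3 physical filter on precursor (parent-ion) intensity."""
    return spectrum.precursor_intensity >= config.min_precursor_intensity


def candidates(spectrum: Spectrum, index: PeptideIndex,
               config: SearchConfig) -> list[PeptideSpecies]:
    """Species whose delta mass (observed - theoretical) is in-window."""
    lo, hi = config.window()
    mh = observed_mh(spectrum)
    return [index.species[i] for i in index.query(mh - hi, mh - lo)]


def preprocess_peaks(spectrum: Spectrum, top_peaks: int = 50):
    """Keep the most intense fragments; normalize the apex to 100."""
    mz, intensity = spectrum.mz, spectrum.intensity
    if mz.size == 0:
        return mz, intensity
    if mz.size > top_peaks:
        keep = np.sort(np.argpartition(intensity, -top_peaks)[-top_peaks:])
        mz, intensity = mz[keep], intensity[keep]
    peak_max = intensity.max()
    if peak_max > 0:
        intensity = intensity * (100.0 / peak_max)
    return mz, intensity


def _capped_factorial(n: int) -> int:
    return math.factorial(min(n, 20))


def hyperscore_from_ladder(peaks_mz, peaks_int, ions_mz, ions_is_b,
                           tol: float) -> tuple[float, int, int]:
    """Score one candidate against preprocessed peaks.

    Ions are processed in ascending m/z; each is matched greedily to the
    nearest not-yet-consumed peak within ``tol`` so no observed peak's
    intensity is counted twice. Returns (hyperscore, n_b, n_y) with
    hyperscore = (sum of matched intensities) * n_b! * n_y!, factorials
    capped at 20!.
    """
    if peaks_mz.size == 0 or ions_mz.size == 0:
        return 0.0, 0, 0
    # Fast path: assign every ion its nearest peak within tol ignoring
    # consumption; valid (identical to the greedy scan) whenever no peak
    # is claimed twice, which is the overwhelmingly common case.
    pos0 = np.searchsorted(peaks_mz, ions_mz)
    left = np.clip(pos0 - 1, 0, peaks_mz.size - 1)
    right = np.clip(pos0, 0, peaks_mz.size - 1)
    d_left = np.abs(ions_mz - peaks_mz[left])
    d_right = np.abs(peaks_mz[right] - ions_mz)
    take_left = d_left <= d_right
    nearest = np.where(take_left, left, right)
    dist = np.where(take_left, d_left, d_right)
    hit = dist <= tol
    claimed = nearest[hit]
    if claimed.size == np.unique(claimed).size:
        if claimed.size == 0:
            return 0.0, 0, 0
        n_b = int(np.sum(ions_is_b[hit]))
        n_y = int(claimed.size - n_b)
        total = float(peaks_int[claimed].sum())
        return total * _capped_factorial(n_b) * _capped_factorial(n_y), n_b, n_y
    consumed = np.zeros(peaks_mz.size, dtype=bool)
    total = 0.0
    n_b = n_y = 0
    pos = np.searchsorted(peaks_mz, ions_mz)
    for i in range(ions_mz.size):
        ion = ions_mz[i]
        best = -1
        best_d = tol
        j = pos[i] - 1
        while j >= 0 and ion - peaks_mz[j] <= tol:
            if not consumed[j]:
                d = ion - peaks_mz[j]
                if d <= best_d:
                    best, best_d = j, d
                break  # nearest unconsumed on the left found
            j -= 1
        j = pos[i]
        while j < peaks_mz.size and peaks_mz[j] - ion <= tol:
            if not consumed[j]:
                d = peaks_mz[j] - ion
                if d < best_d:
                    best, best_d = j, d
                break  # nearest unconsumed on the right found
            j += 1
        if best >= 0:
            consumed[best] = True
            total += peaks_int[best]
            if ions_is_b[i]:
                n_b += 1
            else:
                n_y += 1
    if n_b + n_y == 0:
        return 0.0, 0, 0
    score = total * _capped_factorial(n_b) * _capped_factorial(n_y)
    return float(score), n_b, n_y


def hyperscore(spectrum: Spectrum, peptide: PeptideSpecies, charge: int,
               config: SearchConfig) -> tuple[float, int, int]:
    """Convenience wrapper: preprocess the spectrum and score one peptide."""
    peaks_mz, peaks_int = preprocess_peaks(spectrum, config.top_peaks)
    ions_mz, ions_is_b = ladder_arrays(peptide)
    return hyperscore_from_ladder(peaks_mz, peaks_int, ions_mz, ions_is_b,
                                  config.fragment_tol)


# ---------------------------------------------------------------------------
# Expectation-style p-values from the candidate-score histogram

@dataclass(frozen=True)
class ScoreHistogram:
    """Histogram of a spectrum's candidate scores on a log10(1+score) axis."""

    edges: np.ndarray
    counts: np.ndarray
    scores: np.ndarray  # raw hyperscores, for the rank fallback

    @property
    def n(self) -> int:
        return int(self.scores.size)


def score_histogram(scores, bin_width: float = 0.5) -> ScoreHistogram:
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty candidate score set")
    t = np.log10(1.0 + scores)
    upper = max(t.max() + bin_width, bin_width)
    edges = np.arange(0.0, upper + bin_width, bin_width)
    counts, _ = np.histogram(t, bins=edges)
    return ScoreHistogram(edges=edges, counts=counts, scores=scores)


def psm_p_value(hyperscore: float, histogram: ScoreHistogram) -> float:
    """Expectation-style p-value of a hyperscore.

    The log10 survival count of the candidate-score histogram is fit by
    least squares over its linear right tail — the populated bins above
    the histogram mode with survival count >= 1 (the mode bin itself
    joins the fit when fewer than 2 such bins exist, which happens for
    sparse nulls where most candidates score zero). The query's own
    occurrence is first removed from the histogram (leave-one-out), so a
    candidate never contributes to its own null and an isolated
    top-score bin cannot distort the tail. The fitted line must slope
    downward; extrapolating it to the query score gives the expected
    number of candidates at or above that score, and p = min(1, e).
    With no usable fit the fallback is the rank of the score among the
    candidates divided by the number of candidates.
    """
    if histogram.counts.sum() == 0:
        raise ValueError("empty histogram")
    t = np.log10(1.0 + max(hyperscore, 0.0))
    counts = histogram.counts.astype(float).copy()
    if np.any(histogram.scores == hyperscore):
        own = int(np.searchsorted(histogram.edges, t, side="right")) - 1
        if 0 <= own < counts.size and counts[own] > 0:
            counts[own] -= 1
    fit = fit_survival_tail(histogram.edges, counts)
    if fit is not None:
        slope, intercept = fit
        e = 10.0 ** (intercept + slope * t)
        return float(min(1.0, max(e, 1e-300)))
    # rank fallback: fraction of candidates scoring at least this high
    rank = int(np.sum(histogram.scores >= hyperscore))
    return max(rank, 1) / histogram.n


def fit_survival_tail(edges, counts):
    """Least-squares line through log10 survival over the histogram's
    right tail (populated bins above the mode with survival >= 1).
    When fewer than 2 such bins exist — sparse nulls where most
    candidates score zero — the mode bin itself joins the fit. Returns
    (slope, intercept) or None when no usable fit exists or the fitted
    slope is not negative."""
    counts = np.asarray(counts, dtype=float)
    survival = counts[::-1].cumsum()[::-1]
    mode = int(np.argmax(counts))
    centers = 0.5 * (np.asarray(edges)[:-1] + np.asarray(edges)[1:])
    tail = [
        i for i in range(mode + 1, counts.size)
        if counts[i] > 0 and survival[i] >= 1
    ]
    if len(tail) < 2 and counts[mode] > 0 and survival[mode] >= 1:
        tail = [mode] + tail
    if len(tail) < 2:
        return None
    x = centers[tail]
    y = np.log10(survival[tail])
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        return None
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    if slope >= 0:
        return None
    return slope, intercept


# ---------------------------------------------------------------------------
# Searching runs and BFPS selection

def _psm_sort_key(psm: PSM):
    return (-psm.hyperscore, abs(psm.delta_mass), psm.peptide_key)


def best_fit_per_spectrum(psms, max_psm_p: float | None = 0.01) -> list[PSM]:
    """Keep one PSM per spectrum — highest hyperscore, ties broken by
    smaller |delta mass| then lexicographic modified sequence — then
    drop survivors with p above ``max_psm_p`` (None disables the filter)."""
    best: dict[tuple, PSM] = {}
    for psm in psms:
        key = (psm.run_id, psm.spectrum_id)
        cur = best.get(key)
        if cur is None or _psm_sort_key(psm) < _psm_sort_key(cur):
            best[key] = psm
    out = [p for p in best.values() if max_psm_p is None or p.p_value <= max_psm_p]
    return sorted(out, key=lambda p: (p.run_id, p.spectrum_id))


_FACT_TABLE = np.array(
    [float(math.factorial(min(i, 20))) for i in range(64)]
)


def _score_all_candidates(peaks_mz, peaks_int, ladders, tol):
    """Vectorized greedy scoring of many candidates against one spectrum.

    Uses the contention-free nearest-peak assignment for every candidate
    at once and falls back to the exact greedy scan only for candidates
    where two ions claim the same peak.
    """
    n_cand = len(ladders)
    scores = np.zeros(n_cand)
    n_b = np.zeros(n_cand, dtype=int)
    n_y = np.zeros(n_cand, dtype=int)
    if peaks_mz.size == 0 or n_cand == 0:
        return scores, n_b, n_y
    lens = np.array([lad[0].size for lad in ladders])
    ids = np.repeat(np.arange(n_cand), lens)
    ions_mz = np.concatenate([lad[0] for lad in ladders])
    ions_is_b = np.concatenate([lad[1] for lad in ladders])

    npk = peaks_mz.size
    pos = np.searchsorted(peaks_mz, ions_mz)
    left = np.clip(pos - 1, 0, npk - 1)
    right = np.clip(pos, 0, npk - 1)
    d_left = np.abs(ions_mz - peaks_mz[left])
    d_right = np.abs(peaks_mz[right] - ions_mz)
    take_left = d_left <= d_right
    nearest = np.where(take_left, left, right)
    dist = np.where(take_left, d_left, d_right)
    hit = dist <= tol

    hit_ids = ids[hit]
    hit_peaks = nearest[hit]
    key = hit_ids.astype(np.int64) * npk + hit_peaks
    uniq, cnt = np.unique(key, return_counts=True)
    contended = np.unique(uniq[cnt > 1] // npk)

    n_b = np.bincount(hit_ids[ions_is_b[hit]], minlength=n_cand)
    n_y = np.bincount(hit_ids[~ions_is_b[hit]], minlength=n_cand)
    totals = np.bincount(hit_ids, weights=peaks_int[hit_peaks], minlength=n_cand)
    scores = totals * _FACT_TABLE[np.minimum(n_b, 63)] * _FACT_TABLE[np.minimum(n_y, 63)]
    scores[(n_b + n_y) == 0] = 0.0

    for c in contended:
        s, nb, ny = hyperscore_from_ladder(
            peaks_mz, peaks_int, ladders[c][0], ladders[c][1], tol
        )
        scores[c], n_b[c], n_y[c] = s, nb, ny
    return scores, n_b.astype(int), n_y.astype(int)


def _group_excluded_p_values(scores: np.ndarray, groups: list,
                             bin_width: float = 0.5) -> np.ndarray:
    """Expectation p-values where each candidate's null excludes every
    candidate from the same group (its parent proteins).

    Modified variants and missed-cleavage relatives of one peptide share
    much of their fragment ladder and therefore score together; leaving
    them in the null would flatten the fitted tail exactly when a
    spectrum has a true match. One tail fit is done per distinct group
    on the histogram of all other candidates' scores.
    """
    t = np.log10(1.0 + scores)
    upper = max(t.max() + bin_width, bin_width)
    edges = np.arange(0.0, upper + bin_width, bin_width)
    total_counts, _ = np.histogram(t, bins=edges)
    bins_of = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                      total_counts.size - 1)
    group_arr = np.asarray(groups)
    n = scores.size
    p = np.empty(n)
    for grp in set(groups):
        members = np.flatnonzero(group_arr == grp)
        if not np.any(scores[members] > 0):
            p[members] = 1.0  # nothing matched; trivially consistent with null
            continue
        counts = total_counts.astype(float).copy()
        np.subtract.at(counts, bins_of[members], 1.0)
        fit = fit_survival_tail(edges, counts)
        for m in members:
            if fit is None:
                # rank among all candidates, the degenerate-histogram fallback
                p[m] = np.sum(scores >= scores[m]) / n
            else:
                slope, intercept = fit
                e = 10.0 ** (intercept + slope * t[m])
                p[m] = min(1.0, max(e, 1e-300))
    return p


def search_spectrum(spectrum: Spectrum, index: PeptideIndex,
                    config: SearchConfig) -> list[PSM]:
    """All in-window candidate PSMs of one spectrum, with p-values."""
    lo, hi = config.window()
    mh = observed_mh(spectrum)
    idxs = index.query(mh - hi, mh - lo)
    if not idxs:
        return []
    peaks_mz, peaks_int = preprocess_peaks(spectrum, config.top_peaks)
    ladders = [index.ladder(i) for i in idxs]
    scores, ions_b, ions_y = _score_all_candidates(
        peaks_mz, peaks_int, ladders, config.fragment_tol
    )
    p_values = _group_excluded_p_values(scores, [index.groups[i] for i in idxs])
    psms = []
    for pos, i in enumerate(idxs):
        sp = index.species[i]
        n_b, n_y = int(ions_b[pos]), int(ions_y[pos])
        psms.append(
            PSM(
                spectrum_id=spectrum.spectrum_id,
                run_id=spectrum.run_id,
                instrument_label=spectrum.instrument_label,
                run_kind=spectrum.run_kind,
                peptide_key=sp.key,
                sequence=sp.sequence,
                gene_symbol=min(sp.parent_genes) if sp.parent_genes else "",
                charge=spectrum.precursor_charge,
                observed_mh=mh,
                mono_mh=sp.mono_mh,
                delta_mass=mh - sp.mono_mh,
                hyperscore=float(scores[pos]),
                n_b=n_b,
                n_y=n_y,
                p_value=float(p_values[pos]),
            )
        )
    return psms


def search_run(spectra, index: PeptideIndex, config: SearchConfig = SearchConfig(),
               bfps: bool = True) -> list[PSM]:
    """Search a run end to end.

    Spectra failing the E3 intensity filter, carrying unsupported
    charges, or outside the precursor m/z range are not searched. With
    ``bfps`` (default) the result is one best-fit PSM per spectrum,
    filtered at the configured p threshold.
    """
    mz_lo, mz_hi = config.precursor_mz_range
    all_psms: list[PSM] = []
    for spectrum in spectra:
        if spectrum.precursor_charge not in config.charges:
            continue
        if not mz_lo <= spectrum.precursor_mz <= mz_hi:
            continue
        if not intensity_filter(spectrum, config):
            continue
        all_psms.extend(search_spectrum(spectrum, index, config))
    if bfps:
        return best_fit_per_spectrum(all_psms, config.max_psm_p)
    return all_psms


def filter_monoisotopic(psms, tol: float = 0.1) -> list[PSM]:
    """Restrict accepted PSMs to the monoisotopic slice |delta mass| <= tol.

    The monoisotopic analysis is the wide-window search restricted to
    near-zero delta masses, which makes the strict-mass result an exact
    subset of the wide-window result by construction.
    """
    return [p for p in psms if abs(p.delta_mass) <= tol]
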