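"""Delta-mass distribution analysis.

The delta mass of a PSM is observed [M+H]+ minus theoretical
monoisotopic [M+H]+. Under an open (wide-window) search of real
peptides its distribution concentrates at integer-Da offsets: +k Da
peaks from k heavy-isotope substitutions (spacing 1.00335 Da) and
-1..-3 Da peaks from hydrogen rearrangements (spacing 1.00783 Da).
This module histograms delta masses, detects the integer peaks in
[-3, +5], and quantifies agreement with a predicted delta envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import H_ATOM, ISOTOPE_SPACING
from .insilico import DeltaEnvelope

RANGE_LO, RANGE_HI = -3.5, 5.5


@dataclass(frozen=True)
class DetectedPeak:
    k: int                 # integer offset, -3..+5
    center: float          # physical (or plain-integer) peak center, Da
    apex: float            # bin center of the highest bin near `center`
    height: float          # count in that bin
    mass_fraction: float   # fraction of all PSMs within center +/- tol
    detected: bool


@dataclass
class DeltaMassProfile:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_input: int
    n_dropped: int
    peaks: list = field(default_factory=list)
    envelope_correlation: float | None = None
    within_tolerance_fraction: float | None = None
    correlation_defined: bool = True

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _as_deltas(psms) -> np.ndarray:
    arr = np.asarray(
        [p.delta_mass if hasattr(p, "delta_mass") else float(p) for p in psms],
        dtype=float,
    )
    return arr


def integer_center(k: int, physical: bool = True) -> float:
    """Expected delta-mass position of integer offset k.

    Physical centers sit at multiples of the 13C spacing for k > 0 and
    the hydrogen-atom mass for k < 0; the plain-integer mode uses k Da.
    """
    if not physical:
        return float(k)
    if k >= 0:
        return k * ISOTOPE_SPACING
    return k * H_ATOM


def delta_histogram(psms, bin_width: float = 0.01) -> DeltaMassProfile:
    """Histogram delta masses over [-3.5, +5.5] Da.

    Default bin width suits OIT-like precision; use ~0.1 Da for
    LIT-like runs. PSMs outside the range are dropped (counted).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    deltas = _as_deltas(psms)
    if deltas.size == 0:
        raise ValueError("no PSMs to histogram")
    n_bins = int(np.ceil((RANGE_HI - RANGE_LO) / bin_width))
    edges = RANGE_LO + bin_width * np.arange(n_bins + 1)
    inside = (deltas >= RANGE_LO) & (deltas <= edges[-1])
    counts, _ = np.histogram(deltas[inside], bins=edges)
    return DeltaMassProfile(
        bin_edges=edges,
        counts=counts.astype(float),
        n_input=int(deltas.size),
        n_dropped=int(deltas.size - inside.sum()),
    )


def detect_integer_peaks(
    profile: DeltaMassProfile,
    tol: float = 0.05,
    min_ratio: float = 5.0,
    physical_centers: bool = True,
) -> DeltaMassProfile:
    """Find the integer-Da peaks at k = -3..+5.

    For each k the apex is the highest bin within ``tol`` of the peak
    center; a peak counts as detected when that bin exceeds ``min_ratio``
    times the median bin count of the surrounding +/-0.5 Da background
    (the tol window excluded). The mass fraction is the share of all
    input PSMs within ``tol`` of the center.
    """
    centers = profile.bin_centers
    total = profile.n_input
    peaks = []
    for k in range(-3, 6):
        c = integer_center(k, physical_centers)
        win = np.abs(centers - c) <= tol
        bg = (np.abs(centers - c) <= 0.5) & ~win
        if not win.any():
            peaks.append(DetectedPeak(k, c, np.nan, 0.0, 0.0, False))
            continue
        sub = profile.counts[win]
        apex_i = int(np.argmax(sub))
        height = float(sub[apex_i])
        apex = float(centers[win][apex_i])
        frac = float(sub.sum() / total) if total else 0.0
        background = float(np.median(profile.counts[bg])) if bg.any() else 0.0
        detected = height > min_ratio * max(background, 1.0)
        peaks.append(DetectedPeak(k, c, apex, height, frac, bool(detected)))
    return replace(profile, peaks=peaks)


def envelope_agreement(
    profile: DeltaMassProfile, predicted: DeltaEnvelope
) -> tuple[float, float]:
    """Pearson correlation between detected peak mass fractions and the
    predicted envelope over the detected support, plus the fraction of
    all PSM delta masses lying within tolerance of some integer center.

    With fewer than 3 detected peaks the correlation is undefined
    (returned as NaN and flagged on the profile).
    """
    if not profile.peaks:
        raise ValueError("run detect_integer_peaks first")
    within = float(sum(p.mass_fraction for p in profile.peaks))
    det = [p for p in profile.peaks if p.detected]
    if len(det) < 3:
        profile.correlation_defined = False
        corr = float("nan")
    else:
        obs = np.array([p.mass_fraction for p in det])
        pred = np.array([predicted.offsets.get(p.k, 0.0) for p in det])
        obs = obs / obs.sum()
        s = pred.sum()
        if s > 0:
            pred = pred / s
        if np.ptp(obs) == 0 or np.ptp(pred) == 0:
            profile.correlation_defined = False
            corr = float("nan")
        else:
            corr = float(np.corrcoef(obs, pred)[0, 1])
            profile.correlation_defined = True
    profile.envelope_correlation = corr
    profile.within_tolerance_fraction = within
    return corr, within
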