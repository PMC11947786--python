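import numpy as np
import pytest

from openps.constants import PROTON
from openps.insilico import PeptideSpecies
from openps.io_formats import Spectrum
from openps.search import (
    PSM,
    PeptideIndex,
    ScoreHistogram,
    SearchConfig,
    best_fit_per_spectrum,
    build_index,
    candidates,
    filter_monoisotopic,
    hyperscore_from_ladder,
    intensity_filter,
    observed_mh,
    preprocess_peaks,
    psm_p_value,
    score_histogram,
    search_run,
)


def make_spectrum(mz_prec, charge=2, intensity=1e8, peaks_mz=(200.0,), peaks_int=(10.0,)):
    return Spectrum(
        spectrum_id="s1", run_id="r1", instrument_label="OIT_LIKE",
        run_kind="SAMPLE", precursor_mz=mz_prec, precursor_charge=charge,
        precursor_intensity=intensity, mz=np.array(peaks_mz),
        intensity=np.array(peaks_int),
    )


class TestObservedMh:
    def test_worked_example(self):
        s = make_spectrum(667.840, charge=2)
        assert observed_mh(s) == pytest.approx(1334.672724, abs=1e-6)

    def test_inverse_of_generator_formula(self):
        mono = 1500.123456
        for z in (2, 3):
            mz = (mono - PROTON) / z + PROTON
            assert observed_mh(make_spectrum(mz, charge=z)) == pytest.approx(
                mono, abs=1e-9
            )

    def test_invalid_charge_rejected(self):
        s = make_spectrum(700.0, charge=2)
        s.precursor_charge = 1
        with pytest.raises(ValueError):
            observed_mh(s)


class TestCandidates:
    def test_window_arithmetic(self, index_small):
        sp = index_small.species[len(index_small) // 2]
        mono = sp.mono_mh
        z = 2

        def spectrum_at(delta):
            return make_spectrum((mono + delta - PROTON) / z + PROTON, charge=z)

        wide = SearchConfig(window_mode="WIDE")
        assert sp in candidates(spectrum_at(2.95), index_small, wide)
        assert sp not in candidates(spectrum_at(5.1), index_small, wide)
        assert sp in candidates(spectrum_at(-2.95), index_small, wide)
        assert sp not in candidates(spectrum_at(-3.1), index_small, wide)
        mono_cfg = SearchConfig(window_mode="MONO")
        assert sp in candidates(spectrum_at(0.05), index_small, mono_cfg)
        assert sp not in candidates(spectrum_at(0.15), index_small, mono_cfg)

    def test_mono_candidates_nest_within_wide(self, index_small):
        s = make_spectrum(800.123, charge=2)
        mono_set = {c.key for c in candidates(s, index_small, SearchConfig(window_mode="MONO"))}
        wide_set = {c.key for c in candidates(s, index_small, SearchConfig(window_mode="WIDE"))}
        assert mono_set <= wide_set

    def test_empty_index(self):
        idx = PeptideIndex([])
        s = make_spectrum(800.0)
        assert candidates(s, idx, SearchConfig()) == []

    def test_index_query_equals_linear_scan(self, index_small, rng):
        masses = index_small.masses
        for _ in range(500):
            lo = float(rng.uniform(masses.min() - 50, masses.max()))
            hi = lo + float(rng.uniform(0, 30))
            got = index_small.query(lo, hi)
            expected = [int(i) for i in np.flatnonzero((masses >= lo) & (masses <= hi))]
            assert got == expected


class TestIntensityFilter:
    @pytest.mark.parametrize("intensity,expected", [(999, False), (1000, True), (1e8, True)])
    def test_e3_threshold(self, intensity, expected):
        s = make_spectrum(700.0, intensity=intensity)
        assert intensity_filter(s, SearchConfig()) is expected


def oracle_greedy_hyperscore(peaks_mz, peaks_int, ions_mz, ions_is_b, tol):
    """Independent reimplementation: process ions ascending; claim the
    nearest unconsumed peak within tol (ties to the lower m/z peak)."""
    import math

    order = np.argsort(ions_mz, kind="stable")
    consumed = set()
    total, n_b, n_y = 0.0, 0, 0
    for i in order:
        cand = [
            (abs(peaks_mz[j] - ions_mz[i]), peaks_mz[j], j)
            for j in range(len(peaks_mz))
            if j not in consumed and abs(peaks_mz[j] - ions_mz[i]) <= tol
        ]
        if not cand:
            continue
        _, _, j = min(cand)
        consumed.add(j)
        total += peaks_int[j]
        if ions_is_b[i]:
            n_b += 1
        else:
            n_y += 1
    if n_b + n_y == 0:
        return 0.0, 0, 0
    return total * math.factorial(min(n_b, 20)) * math.factorial(min(n_y, 20)), n_b, n_y


class TestHyperscore:
    def test_no_matches(self):
        s, nb, ny = hyperscore_from_ladder(
            np.array([500.0]), np.array([10.0]),
            np.array([100.0, 200.0]), np.array([True, False]), 0.5,
        )
        assert (s, nb, ny) == (0.0, 0, 0)

    def test_direct_formula(self):
        # matched intensities {40, 35, 25}: two b ions, one y ion
        peaks_mz = np.array([100.0, 200.0, 300.0])
        peaks_int = np.array([40.0, 35.0, 25.0])
        ions_mz = np.array([100.1, 199.9, 300.2])
        ions_is_b = np.array([True, True, False])
        s, nb, ny = hyperscore_from_ladder(peaks_mz, peaks_int, ions_mz, ions_is_b, 0.5)
        assert s == pytest.approx(100.0 * 2 * 1)
        assert (nb, ny) == (2, 1)

    def test_intensity_linearity(self):
        peaks_mz = np.array([100.0, 200.0])
        peaks_int = np.array([40.0, 35.0])
        ions_mz = np.array([100.0, 200.0])
        ions_is_b = np.array([True, False])
        s1, nb1, ny1 = hyperscore_from_ladder(peaks_mz, peaks_int, ions_mz, ions_is_b, 0.5)
        s2, nb2, ny2 = hyperscore_from_ladder(peaks_mz, 2 * peaks_int, ions_mz, ions_is_b, 0.5)
        assert s2 == pytest.approx(2 * s1)
        assert (nb1, ny1) == (nb2, ny2)

    def test_matches_independent_greedy_oracle(self, rng):
        for _ in range(500):
            n_peaks = int(rng.integers(1, 30))
            n_ions = int(rng.integers(1, 40))
            peaks_mz = np.sort(rng.uniform(100, 1200, n_peaks))
            peaks_int = rng.uniform(1, 100, n_peaks)
            ions_mz = np.sort(rng.uniform(100, 1200, n_ions))
            ions_is_b = rng.random(n_ions) < 0.5
            got = hyperscore_from_ladder(peaks_mz, peaks_int, ions_mz, ions_is_b, 0.5)
            expected = oracle_greedy_hyperscore(peaks_mz, peaks_int, ions_mz, ions_is_b, 0.5)
            assert got[1:] == expected[1:]
            assert got[0] == pytest.approx(expected[0], rel=1e-12)

    def test_preprocess_keeps_top_peaks_normalized(self, rng):
        s = make_spectrum(
            700.0,
            peaks_mz=tuple(np.sort(rng.uniform(150, 2000, 80))),
            peaks_int=tuple(rng.uniform(1, 500, 80)),
        )
        mz, intensity = preprocess_peaks(s, top_peaks=50)
        assert mz.size == 50
        assert intensity.max() == pytest.approx(100.0)
        assert np.all(np.diff(mz) >= 0)


class TestPsmPValue:
    def test_degenerate_identical_scores(self):
        hist = score_histogram(np.full(20, 50.0))
        assert psm_p_value(50.0, hist) == pytest.approx(1.0)

    def test_geometric_tail_matches_regression_oracle(self):
        # survival halves per unit of t: geometric candidate scores
        rng = np.random.default_rng(0)
        t = rng.geometric(0.5, size=200).astype(float)  # t in {1, 2, ...}
        scores = 10.0 ** t - 1.0
        hist = score_histogram(scores, bin_width=1.0)
        query = float(scores.max())
        got = psm_p_value(query, hist)
        # oracle: identical leave-one-out histogram, np.polyfit regression
        tq = np.log10(1.0 + query)
        counts = hist.counts.astype(float).copy()
        own = np.searchsorted(hist.edges, tq, side="right") - 1
        counts[own] -= 1
        survival = counts[::-1].cumsum()[::-1]
        mode = int(np.argmax(counts))
        centers = 0.5 * (hist.edges[:-1] + hist.edges[1:])
        sel = [i for i in range(mode + 1, len(counts)) if counts[i] > 0 and survival[i] >= 1]
        slope, intercept = np.polyfit(centers[sel], np.log10(survival[sel]), 1)
        expected = min(1.0, 10.0 ** (intercept + slope * tq))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_score(self):
        rng = np.random.default_rng(1)
        scores = 10.0 ** rng.exponential(1.0, size=300)
        hist = score_histogram(scores)
        queries = np.linspace(0, np.max(scores) * 10, 50)
        ps = [psm_p_value(q, hist) for q in queries]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_histogram_rejected(self):
        hist = ScoreHistogram(
            edges=np.array([0.0, 1.0]), counts=np.array([0]), scores=np.array([])
        )
        with pytest.raises(ValueError):
            psm_p_value(1.0, hist)


def _psm(spectrum_id, peptide_key, hyperscore, delta=0.0, p=0.001):
    return PSM(
        spectrum_id=spectrum_id, run_id="r", instrument_label="OIT_LIKE",
        run_kind="SAMPLE", peptide_key=peptide_key, sequence=peptide_key,
        gene_symbol="G", charge=2, observed_mh=1000.0, mono_mh=1000.0 - delta,
        delta_mass=delta, hyperscore=hyperscore, n_b=1, n_y=1, p_value=p,
    )


class TestBestFitPerSpectrum:
    def test_single_candidate(self):
        psm = _psm("s1", "PEPK", 100.0)
        assert best_fit_per_spectrum([psm], None) == [psm]

    def test_highest_score_kept(self):
        kept = best_fit_per_spectrum(
            [_psm("s1", "AAAK", 150.0), _psm("s1", "CCCK", 200.0)], None
        )
        assert [p.peptide_key for p in kept] == ["CCCK"]

    def test_p_filter_applied_after_selection(self):
        psms = [_psm("s1", "AAAK", 150.0, p=0.5), _psm("s2", "CCCK", 200.0, p=0.005)]
        kept = best_fit_per_spectrum(psms, 0.01)
        assert [p.spectrum_id for p in kept] == ["s2"]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            psms = [
                _psm(
                    f"s{int(rng.integers(3))}",
                    f"P{int(rng.integers(5))}K",
                    float(rng.choice([100.0, 200.0, 300.0])),
                    delta=float(rng.choice([-1.0, 0.0, 0.5, 2.0])),
                )
                for _ in range(n)
            ]
            got = best_fit_per_spectrum(psms, None)
            # oracle: per spectrum, max by (score, -|delta|, reversed key)
            expected = {}
            for p in psms:
                cur = expected.get(p.spectrum_id)
                key = (-p.hyperscore, abs(p.delta_mass), p.peptide_key)
                if cur is None or key < (-cur.hyperscore, abs(cur.delta_mass), cur.peptide_key):
                    expected[p.spectrum_id] = p
            assert {(p.spectrum_id, p.peptide_key) for p in got} == {
                (p.spectrum_id, p.peptide_key) for p in expected.values()
            }


class TestEndToEnd:
    def test_accepted_psms_point_at_generated_peptides(
        self, run_small, index_small
    ):
        spectra, truth = run_small
        psms = search_run(spectra, index_small)
        assert psms  # the run yields accepted identifications
        by_id = truth.by_spectrum()
        correct = sum(1 for p in psms if by_id[p.spectrum_id].sequence == p.sequence)
        assert correct / len(psms) >= 0.95

    def test_monoisotopic_restriction_is_subset(self, run_small, index_small):
        spectra, _ = run_small
        psms = search_run(spectra, index_small)
        mono = filter_monoisotopic(psms)
        assert {(p.spectrum_id, p.peptide_key) for p in mono} <= {
            (p.spectrum_id, p.peptide_key) for p in psms
        }
        assert all(abs(p.delta_mass) <= 0.1 for p in mono)

    def test_parameter_recovery_of_well_sampled_peptides(self):
        """Peptides generated with >= 5 spectra are recovered (appear among
        the accepted wide-window PSMs) at >= 95% under default conditions."""
        import collections

        from openps.synthetic_data import SimConfig, make_library, simulate_run

        sim = SimConfig(seed=3, n_spectra=2000)
        library = make_library(sim)
        index = build_index(library)
        spectra, truth = simulate_run(library, sim)
        psms = search_run(spectra, index)
        generated = collections.Counter(e.sequence for e in truth.entries)
        rich = {seq for seq, c in generated.items() if c >= 5}
        recovered = {p.sequence for p in psms}
        assert rich
        assert len(rich & recovered) / len(rich) >= 0.95

    def test_low_intensity_spectra_not_searched(self, run_small, index_small):
        spectra, _ = run_small
        dim = []
        for s in spectra[:5]:
            d = Spectrum(
                spectrum_id=s.spectrum_id, run_id=s.run_id,
                instrument_label=s.instrument_label, run_kind=s.run_kind,
                precursor_mz=s.precursor_mz, precursor_charge=s.precursor_charge,
                precursor_intensity=500.0, mz=s.mz, intensity=s.intensity,
            )
            dim.append(d)
        assert search_run(dim, index_small) == []
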