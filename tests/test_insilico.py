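import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pyt_mass
from scipy import stats

from openps.constants import ISOTOPE_ABUNDANCE, PROTON, VALID_RESIDUES
from openps.insilico import (
    DEFAULT_MODIFICATIONS,
    IsotopeEnvelope,
    Modification,
    PeptideSpecies,
    delta_envelope,
    digest,
    expand_modifications,
    fragment_ladder,
    isotope_envelope,
    mono_mh,
)
from openps.io_formats import ProteinRecord

RESIDUES = sorted(VALID_RESIDUES)
seq_strategy = st.text(alphabet=RESIDUES, min_size=5, max_size=60)


def brute_force_digest(sequence, max_missed):
    """Independent oracle: enumerate all cleavage-site windows."""
    cuts = [0] + [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    out = set()
    for i, j in itertools.combinations(range(len(cuts)), 2):
        if j - i - 1 <= max_missed:
            out.add((sequence[cuts[i]:cuts[j]], j - i - 1))
    return out


class TestDigest:
    @pytest.mark.parametrize(
        "seq,max_missed,expected",
        [
            ("AKLRGM", 0, {"AK", "LR", "GM"}),
            ("AKLRGM", 1, {"AK", "LR", "GM", "AKLR", "LRGM"}),
            ("GMAW", 3, {"GMAW"}),
        ],
    )
    def test_examples(self, seq, max_missed, expected):
        protein = ProteinRecord("P1", "G1", seq)
        got = {p.sequence for p in digest(protein, max_missed)}
        assert got == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seq=seq_strategy, max_missed=st.integers(0, 3))
    def test_matches_brute_force_enumeration(self, seq, max_missed):
        protein = ProteinRecord("P1", "G1", seq)
        got = {(p.sequence, p.missed_cleavages) for p in digest(protein, max_missed)}
        assert got == brute_force_digest(seq, max_missed)

    def test_no_proline_exception(self):
        # [RK]|[X] cleaves before proline too
        got = {p.sequence for p in digest(ProteinRecord("P", "G", "AKPGR"), 0)}
        assert got == {"AK", "PGR"}


class TestMonoMh:
    def test_glycine(self):
        assert mono_mh("G") == pytest.approx(76.039305, abs=1e-6)

    def test_diglycine(self):
        assert mono_mh("GG") == pytest.approx(133.060769, abs=1e-6)

    def test_agrees_with_elemental_composition_oracle(self, rng):
        # pyteomics sums exact isotope masses from the composition
        for _ in range(1000):
            seq = "".join(rng.choice(RESIDUES, size=int(rng.integers(2, 40))))
            expected = pyt_mass.calculate_mass(sequence=seq) + PROTON
            assert mono_mh(seq) == pytest.approx(expected, abs=1e-6)

    def test_modification_additivity(self):
        pep = PeptideSpecies("AMKNW")
        mods = (
            (2, DEFAULT_MODIFICATIONS[0]),
            (4, DEFAULT_MODIFICATIONS[1]),
        )
        modded = PeptideSpecies("AMKNW", modifications=mods)
        delta = sum(m.delta_mass for _, m in mods)
        assert modded.mono_mh - pep.mono_mh == pytest.approx(delta, abs=1e-9)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            mono_mh("AXK")


class TestExpandModifications:
    ox = Modification("ox", frozenset("MW"), 15.994915)

    def test_single_oxidation_site(self):
        species = expand_modifications(PeptideSpecies("AMK"), (self.ox,), 2)
        assert len(species) == 2
        diff = species[1].mono_mh - species[0].mono_mh
        assert diff == pytest.approx(15.994915, abs=1e-9)

    def test_no_applicable_targets_gives_terminal_variants_only(self):
        species = expand_modifications(PeptideSpecies("AGK"), DEFAULT_MODIFICATIONS, 1)
        # unmodified + N-term and C-term adducts; no residue targets in AGK
        # (G is a target of no modification; the cys57 mod targets C residues)
        keys = {s.key for s in species}
        assert "AGK" in keys
        assert len(species) == 3

    def test_subset_enumeration(self):
        species = expand_modifications(PeptideSpecies("MWK"), (self.ox,), 2)
        # brute force: subsets of {M@1, W@2} of size <= 2
        assert len(species) == 4
        deltas = sorted(
            round(s.mono_mh - PeptideSpecies("MWK").mono_mh, 6) for s in species
        )
        assert deltas == [0.0, 15.994915, 15.994915, 31.98983]

    def test_cap_truncates(self, caplog):
        pep = PeptideSpecies("MWMWMWMWMWMWMWMW")
        with caplog.at_level("WARNING"):
            species = expand_modifications(pep, DEFAULT_MODIFICATIONS, 2, cap=10)
        assert len(species) == 10
        assert any("truncated" in r.message for r in caplog.records)


class TestFragmentLadder:
    def test_y1_of_gg_equals_mono_mh_of_g(self):
        ions = {(t, i): mz for t, i, mz in fragment_ladder(PeptideSpecies("GG"))}
        assert ions[("y", 1)] == pytest.approx(mono_mh("G"), abs=1e-9)

    def test_complementarity_identity(self, rng):
        # b_i + y_(n-i) = mono [M+H]+ + proton, for every random ladder
        for _ in range(500):
            seq = "".join(rng.choice(RESIDUES, size=int(rng.integers(2, 30))))
            pep = PeptideSpecies(seq)
            ions = {(t, i): mz for t, i, mz in fragment_ladder(pep)}
            n = len(seq)
            for i in range(1, n):
                total = ions[("b", i)] + ions[("y", n - i)]
                assert total == pytest.approx(pep.mono_mh + PROTON, abs=1e-9)

    def test_modified_residue_localized_to_suffix(self):
        ox = Modification("ox", frozenset("MW"), 15.994915)
        plain = {(t, i): mz for t, i, mz in fragment_ladder(PeptideSpecies("AMK"))}
        modded = {
            (t, i): mz
            for t, i, mz in fragment_ladder(
                PeptideSpecies("AMK", modifications=((2, ox),))
            )
        }
        assert modded[("y", 2)] - plain[("y", 2)] == pytest.approx(15.994915, abs=1e-9)
        assert modded[("b", 1)] == pytest.approx(plain[("b", 1)], abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fragment_ladder(PeptideSpecies("G"))


class TestIsotopeEnvelope:
    def test_monoisotopic_element(self):
        env = isotope_envelope({"P": 1})
        assert env.offsets == {0: 1.0}

    def test_single_carbon(self):
        env = isotope_envelope({"C": 1})
        assert env.offsets[0] == pytest.approx(0.9893, abs=1e-4)
        assert env.offsets[1] == pytest.approx(0.0107, abs=1e-4)

    def test_c100_matches_binomial_oracle(self):
        env = isotope_envelope({"C": 100}, cumulative_mass=1.0 - 1e-15)
        p13 = ISOTOPE_ABUNDANCE["C"][1]
        for k in range(6):
            expected = stats.binom.pmf(k, 100, p13)
            assert env.offsets[k] == pytest.approx(expected, abs=1e-9)

    def test_normalization_random_compositions(self, rng):
        for _ in range(50):
            comp = {
                el: int(rng.integers(0, 80))
                for el in ("C", "H", "N", "O", "S")
            }
            comp["C"] += 1
            env = isotope_envelope(comp)
            assert sum(env.offsets.values()) == pytest.approx(1.0, abs=1e-9)
            assert env.offsets[0] > 0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            isotope_envelope({"C": -1})


class TestDeltaEnvelope:
    def test_identity_convolution(self):
        env = isotope_envelope({"C": 60, "H": 100, "N": 15, "O": 20})
        de = delta_envelope(env, {})
        trunc = {k: v for k, v in env.offsets.items() if k <= 5}
        norm = sum(trunc.values())
        for k, v in trunc.items():
            assert de.offsets[k] == pytest.approx(v / norm, abs=1e-12)

    def test_point_mass_convolution(self):
        de = delta_envelope(IsotopeEnvelope({0: 1.0}), {-1: 0.3})
        assert de.offsets == pytest.approx({-1: 0.3, 0: 0.7})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        weights=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=7),
        l1=st.floats(0, 0.3), l2=st.floats(0, 0.3), l3=st.floats(0, 0.3),
    )
    def test_matches_exhaustive_double_sum(self, weights, l1, l2, l3):
        w = np.array(weights) / np.sum(weights)
        env = IsotopeEnvelope({k: float(p) for k, p in enumerate(w)})
        losses = {-1: l1, -2: l2, -3: l3}
        de = delta_envelope(env, losses)
        # oracle: exhaustive convolution over (i, j) pairs
        loss_full = {0: 1 - (l1 + l2 + l3), -1: l1, -2: l2, -3: l3}
        raw = {}
        for i, pi in env.offsets.items():
            for j, pj in loss_full.items():
                if -3 <= i + j <= 5:
                    raw[i + j] = raw.get(i + j, 0.0) + pi * pj
        norm = sum(raw.values())
        for k, v in raw.items():
            assert de.offsets[k] == pytest.approx(v / norm, abs=1e-12)

    def test_mean_shifts_down_with_heavier_losses(self):
        env = isotope_envelope({"C": 60, "H": 100, "N": 15, "O": 20})

        def mean(de):
            return sum(k * p for k, p in de.offsets.items())

        means = [
            mean(delta_envelope(env, {-1: x, -2: x / 2, -3: x / 4}))
            for x in (0.0, 0.05, 0.1, 0.2)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_invalid_probability_rejected(self):
        env = IsotopeEnvelope({0: 1.0})
        with pytest.raises(ValueError):
            delta_envelope(env, {-1: 1.5})
        with pytest.raises(ValueError):
            delta_envelope(env, {-1: 0.8, -2: 0.3})
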