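"""Monoisotopic masses, elemental compositions and isotope abundances.

All masses are in daltons. Residue masses are derived from elemental
compositions and exact isotope masses so that peptide masses stay
consistent with the compositions used for isotope-envelope prediction.
"""

from __future__ import annotations

# Exact masses of the lightest isotope of each element (Da).
ELEMENT_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.97207100,
}

#: Proton (charge carrier) mass used in all m/z arithmetic.
PROTON = 1.00727646688
#: Hydrogen atom mass; a hydrogen-rearrangement loss shifts mass by -1 H.
H_ATOM = ELEMENT_MASS["H"]
#: Water, added to the residue-mass sum of a peptide.
WATER = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]
#: 13C - 12C spacing; the integer-Da isotopologue ladder uses this step.
ISOTOPE_SPACING = 1.0033548378

# Residue elemental compositions (the 20 standard amino acids, as residues,
# i.e. minus one water relative to the free amino acid).
RESIDUE_COMPOSITION = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

VALID_RESIDUES = frozenset(RESIDUE_COMPOSITION)


def _comp_mass(comp: dict) -> float:
    return sum(ELEMENT_MASS[el] * n for el, n in comp.items())


#: Monoisotopic residue masses (Da), derived from composition.
RESIDUE_MASS = {aa: _comp_mass(c) for aa, c in RESIDUE_COMPOSITION.items()}

# Per-element isotope-abundance distributions: integer nominal-mass offset
# of each isotope above the lightest one -> natural abundance (IUPAC values;
# overridable through configuration).
ISOTOPE_ABUNDANCE = {
    "H": {0: 0.999885, 1: 0.000115},
    "C": {0: 0.9893, 1: 0.0107},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425, 4: 0.0001},
    # monoisotopic elements occasionally present in compositions
    "P": {0: 1.0},
}

# Approximate residue frequencies of the human proteome, used by the
# synthetic library generator.
HUMAN_RESIDUE_FREQUENCY = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.060,
}
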