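"""Physical constants and amino-acid chemistry tables.

Monoisotopic element masses follow CODATA/NIST; isotope abundances are IUPAC
representative natural abundances. All masses in Da.
"""

from __future__ import annotations

import numpy as np

PROTON = 1.007276466
# Mass difference between consecutive isotopologue peaks (C13 - C12 dominates
# peptide isotope envelopes); used for precursor isotope-error offsets.
NEUTRON_DELTA = 1.00335483507

# Monoisotopic masses of the elements occurring in unmodified peptides.
ELEMENT_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

WATER = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]

# Natural isotope abundance, indexed by neutron excess over the lightest
# isotope. S has no mass-35 isotope, hence the explicit zero.
ISOTOPE_ABUNDANCE = {
    "H": np.array([0.999885, 0.000115]),
    "C": np.array([0.9893, 0.0107]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
}

# Residue elemental compositions (peptide-bond residues, i.e. minus water).
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


def _mass_of(composition: dict[str, int]) -> float:
    return sum(ELEMENT_MASS[e] * n for e, n in composition.items())


RESIDUE_MASS = {aa: _mass_of(c) for aa, c in RESIDUE_COMPOSITION.items()}

# Unimod-consistent modification masses.
MOD_CARBAMIDOMETHYL = 57.021464
MOD_OXIDATION = 15.994915
MOD_ACETYL = 42.010565
MOD_CYSTEINYLATION = 119.004099

# Elemental compositions of the known modifications, keyed by mass delta
# (matched within 1 mDa when building isotope envelopes of modified peptides).
MOD_COMPOSITION = {
    MOD_CARBAMIDOMETHYL: {"C": 2, "H": 3, "N": 1, "O": 1},
    MOD_OXIDATION: {"O": 1},
    MOD_ACETYL: {"C": 2, "H": 2, "O": 1},
    MOD_CYSTEINYLATION: {"C": 3, "H": 5, "N": 1, "O": 2, "S": 1},
}

# Global UniProt amino-acid frequencies; used by the synthetic proteome
# generator to emit realistic random sequences.
AA_FREQUENCIES = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

# Additive retention coefficients (hydrophobicity-flavoured, arbitrary units);
# shared default of the baseline RT predictor and the synthetic RT model.
RT_COEFFICIENTS = {
    "A": 1.1, "R": -2.0, "N": -1.6, "D": -1.3, "C": 0.8,
    "Q": -1.4, "E": -1.1, "G": -0.7, "H": -2.1, "I": 7.4,
    "L": 8.1, "K": -3.2, "M": 5.0, "F": 9.0, "P": 1.9,
    "S": -0.9, "T": 0.4, "W": 9.5, "Y": 4.2, "V": 4.5,
}

# Default per-charge linear ion-mobility model 1/K0 = a_z + b_z * (m/z);
# plausible trapped-ion-mobility magnitudes for peptide ions.
IM_COEFFICIENTS = {
    1: (0.60, 4.5e-4),
    2: (0.45, 5.5e-4),
    3: (0.43, 6.0e-4),
    4: (0.42, 6.3e-4),
}
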