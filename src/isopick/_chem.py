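"""Atomic masses, isotope abundances, residue masses and the averagine composition.

Monoisotopic masses and isotopic abundances follow the IUPAC standard tables;
the averagine composition is Senko's average amino-acid residue
(C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per 111.1254 Da).
"""

from __future__ import annotations

PROTON_MASS = 1.0072765  # Da, mass of H+
WATER_MASS = 18.010565  # Da, monoisotopic H2O

# monoisotopic mass of the lightest isotope, per element
MONO_MASS = {
    "C": 12.0,
    "H": 1.007825032,
    "N": 14.003074005,
    "O": 15.994914620,
    "S": 31.972071174,
}

# relative abundances indexed by neutron excess (0, +1, +2, ...)
ISOTOPE_ABUNDANCE = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
}

# Senko averagine: average elemental composition of one amino-acid residue
AVERAGINE_COMPOSITION = {
    "C": 4.9384,
    "H": 7.7583,
    "N": 1.3577,
    "O": 1.4773,
    "S": 0.0417,
}
AVERAGINE_MASS = 111.1254  # Da per averagine residue

# standard monoisotopic residue masses of the 20 proteinogenic amino acids
RESIDUE_MASS = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

# carbamidomethylation of cysteine (iodoacetamide alkylation), +C2H3NO
CARBAMIDOMETHYL_MASS = 57.021464


def deamidation_mass_shift() -> float:
    """Mass increase upon deamidation of an Asn/Gln residue.

    Hydrolysis of the side-chain carboxamide replaces -NH2 by -OH, so the
    shift is (O + H) - (N + 2 H), computed from atomic masses.
    """
    return (MONO_MASS["O"] + MONO_MASS["H"]) - (MONO_MASS["N"] + 2 * MONO_MASS["H"])
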