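"""Shared constants: amino-acid alphabets and the Atchley factor table."""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetical. This is the canonical column
#: order for PSSM tracks and feature catalogs throughout the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Padding symbol for window positions that fall outside the protein.
PAD: str = "X"

#: Window alphabet: the 20 amino acids plus the padding symbol.
WINDOW_ALPHABET: str = AMINO_ACIDS + PAD

#: Column order used by PSI-BLAST when printing ASCII PSSMs.
PSIBLAST_COLUMN_ORDER: str = "ARNDCQEGHILKMFPSTVYW"

#: Secondary-structure states (3-state) and solvent-accessibility states
#: (2-state), alphabetical -- the catalog detail order.
SS_STATES: tuple[str, ...] = ("helix", "other", "strand")
SA_STATES: tuple[str, ...] = ("buried", "exposed")

#: One-hot bit layouts used for encoding: helix=100, strand=010, other=001
#: over (helix, strand, other); buried=10, exposed=01 over (buried, exposed).
SS_ONEHOT: dict[str, dict[str, float]] = {
    "helix": {"helix": 1.0, "strand": 0.0, "other": 0.0},
    "strand": {"helix": 0.0, "strand": 1.0, "other": 0.0},
    "other": {"helix": 0.0, "strand": 0.0, "other": 1.0},
}
SA_ONEHOT: dict[str, dict[str, float]] = {
    "buried": {"buried": 1.0, "exposed": 0.0},
    "exposed": {"buried": 0.0, "exposed": 1.0},
}

#: Names of the five Atchley amino-acid factors, alphabetical (catalog order).
ATCHLEY_FACTOR_NAMES: tuple[str, ...] = (
    "codon_diversity",
    "electrostatic_charge",
    "molecular_volume",
    "polarity",
    "secondary_structure",
)

# Atchley et al. multivariate summaries of AAindex: five numeric factors per
# amino acid. Row order alphabetical; column order (F1..F5) =
# (polarity, secondary structure, molecular volume, codon diversity,
#  electrostatic charge).
_ATCHLEY_F1_TO_F5: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

# Factor-name -> F-index mapping (F1=polarity, F2=secondary structure,
# F3=molecular volume, F4=codon diversity, F5=electrostatic charge).
_FACTOR_INDEX: dict[str, int] = {
    "polarity": 0,
    "secondary_structure": 1,
    "molecular_volume": 2,
    "codon_diversity": 3,
    "electrostatic_charge": 4,
}

#: Atchley factor lookup: ATCHLEY_FACTORS[aa][factor_name] -> float.
#: The padding symbol 'X' maps to 0.0 for every factor.
ATCHLEY_FACTORS: dict[str, dict[str, float]] = {
    aa: {name: vals[_FACTOR_INDEX[name]] for name in ATCHLEY_FACTOR_NAMES}
    for aa, vals in _ATCHLEY_F1_TO_F5.items()
}
ATCHLEY_FACTORS[PAD] = {name: 0.0 for name in ATCHLEY_FACTOR_NAMES}

#: Background amino-acid frequencies (approximate UniProt composition),
#: alphabetical order; used by the synthetic generator. Sums to 1.
BACKGROUND_AA_FREQS: np.ndarray = np.array(
    [
        0.0826,  # A
        0.0137,  # C
        0.0546,  # D
        0.0672,  # E
        0.0386,  # F
        0.0708,  # G
        0.0228,  # H
        0.0593,  # I
        0.0582,  # K
        0.0965,  # L
        0.0241,  # M
        0.0406,  # N
        0.0474,  # P
        0.0394,  # Q
        0.0553,  # R
        0.0660,  # S
        0.0535,  # T
        0.0687,  # V
        0.0110,  # W
        0.0297,  # Y
    ]
)
BACKGROUND_AA_FREQS = BACKGROUND_AA_FREQS / BACKGROUND_AA_FREQS.sum()
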