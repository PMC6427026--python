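"""Per-residue scales and physical constants.

All scales are keyed by one-letter amino-acid code (the 20 standard
residues). Unknown letters are rejected by the functions that consume
these tables rather than silently defaulted.
"""

from __future__ import annotations

#: Boltzmann constant, J/K (CODATA 2018, exact by SI definition).
BOLTZMANN_JK = 1.380649e-23

#: Kyte-Doolittle hydropathy. Positive = hydrophobic.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: AGGRESCAN per-residue aggregation propensity (a3v). Hot-spot threshold
#: on the 5-residue windowed average (a4v) is -0.02.
AGGRESCAN_A3V: dict[str, float] = {
    "I": 1.822, "F": 1.754, "V": 1.594, "L": 1.380, "Y": 1.159, "W": 1.037,
    "M": 0.910, "C": 0.604, "A": -0.036, "T": -0.159, "S": -0.294,
    "P": -0.334, "G": -0.535, "K": -0.931, "H": -1.033, "Q": -1.231,
    "R": -1.240, "N": -1.302, "E": -1.412, "D": -1.836,
}
AGGRESCAN_THRESHOLD = -0.02

#: Expected packing density (mean heavy-atom contacts within 8 A) used by
#: packing-density amyloidogenicity scans; residues whose 5-residue windowed
#: value exceeds 21.4 in runs of >= 5 are flagged.
PACKING_DENSITY: dict[str, float] = {
    "A": 19.90, "R": 19.48, "N": 19.06, "D": 18.82, "C": 22.20, "Q": 19.48,
    "E": 18.99, "G": 19.11, "H": 20.53, "I": 22.48, "L": 22.04, "K": 18.52,
    "M": 21.87, "F": 22.00, "P": 17.43, "S": 19.51, "T": 20.22, "W": 21.92,
    "Y": 21.31, "V": 22.47,
}
PACKING_DENSITY_THRESHOLD = 21.4

#: Side-chain formal charge at pH 7. Histidine treated as neutral.
RESIDUE_CHARGE: dict[str, int] = {
    **{aa: 0 for aa in KYTE_DOOLITTLE},
    "D": -1, "E": -1, "K": +1, "R": +1,
}

#: Bondi van der Waals radii (A) for the heavy elements found in proteins.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
                               "H": 1.20, "P": 1.80}
DEFAULT_VDW = 1.70

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Backbone heavy-atom names (everything else is treated as side chain).
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element symbol (A)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)
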