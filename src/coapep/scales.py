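"""Per-residue scales and constants used throughout the package.

All scales are keyed by one-letter amino acid codes of the 20 standard
residues.  Units are stated per table; dimensionless unless noted.
"""

from __future__ import annotations

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in AA_THREE.items()}

# Side-chain formal charge at neutral pH (units of e); histidine treated as
# neutral, termini assumed capped (acetyl/amide) so only side chains count.
RESIDUE_CHARGE = {aa: 0.0 for aa in AA_ALPHABET}
RESIDUE_CHARGE.update({"K": +1.0, "R": +1.0, "D": -1.0, "E": -1.0})

# Kyte-Doolittle hydropathy (dimensionless; positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Chou-Fasman beta-sheet conformational propensities P_beta (dimensionless).
BETA_PROPENSITY = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}

# Canonical distance (Angstrom) from the C-alpha to the side-chain centroid,
# used to place centroid pseudo-atoms on the idealized scaffold.  Values are
# rounded averages over rotamer libraries; glycine has no side chain.
SIDECHAIN_CENTROID_DISTANCE = {
    "G": 0.0, "A": 1.5, "S": 1.9, "C": 2.0, "T": 1.9, "V": 2.0,
    "P": 1.9, "I": 2.3, "L": 2.6, "N": 2.5, "D": 2.5, "M": 2.9,
    "Q": 3.1, "E": 3.1, "K": 3.5, "R": 4.1, "H": 3.2, "F": 3.4,
    "Y": 3.8, "W": 3.9,
}

# Dielectric class of a residue environment used by the variable internal
# dielectric Coulomb model: side chains that carry a formal charge, polar
# uncharged side chains, and nonpolar side chains.
POLAR_UNCHARGED = frozenset("STNQYHW")


def dielectric_class(aa: str) -> str:
    """Return ``charged``, ``polar`` or ``nonpolar`` for a residue code."""
    if RESIDUE_CHARGE[aa] != 0.0:
        return "charged"
    if aa in POLAR_UNCHARGED:
        return "polar"
    return "nonpolar"
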