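"""Amino-acid lookup tables: letter codes, masses, volumes, classes."""

from __future__ import annotations

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Phosphorylated / modified residue names mapped to the parent amino acid.
MODIFIED_PARENT = {
    "SEP": "S",   # phosphoserine
    "TPO": "T",   # phosphothreonine
    "PTR": "Y",   # phosphotyrosine
    "NEP": "H",   # N1-phosphohistidine
    "HIP": "H",   # N3-phosphohistidine
    "PHD": "D",   # aspartyl phosphate
    "CSP": "C",   # S-phosphocysteine
    "MSE": "M",   # selenomethionine (common crystallographic substitution)
}

CANONICAL = set(THREE_TO_ONE.values())

#: Average residue masses in Da (monoisotopic masses are not needed here;
#: these are the standard average residue masses within a peptide chain).
RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
    "X": 110.0,
}

#: Mean residue volumes in Å³ (Zamyatnin-style averages); used to derive
#: single-sphere radii for the coarse-grained SASA model.
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
    "X": 120.0,
}

#: Kyte-Doolittle-positive (hydrophobic) residues.
HYDROPHOBIC = frozenset("AVLIMFWC")
#: Polar / charged residues (complement of hydrophobic, minus Gly/Pro).
CHARGED = frozenset("DEKRH")

#: Van der Waals radii by element (Å), a single published table (Bondi).
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


def coarse_radius(aa: str) -> float:
    """Single-sphere radius (Å) of a residue from its mean volume."""
    vol = RESIDUE_VOLUME.get(aa, RESIDUE_VOLUME["X"])
    return float((3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0))
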