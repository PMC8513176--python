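"""Amino-acid lookup tables shared across the package.

Feature vectors, probability profiles and class compositions are all indexed
by the 20 standard one-letter codes in alphabetical order (``AA_ALPHABET``).
"""

from __future__ import annotations

#: One-letter codes of the 20 standard amino acids, alphabetical.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ALPHABET)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Chemically modified residues with an unambiguous standard parent.
#: Anything not listed here and not standard is rejected at parse time.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "CSO": "CYS", "CME": "CYS", "OCS": "CYS", "SEC": "CYS",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "HYP": "PRO", "MLY": "LYS", "KCX": "LYS", "PYL": "LYS",
    "HIC": "HIS", "NEP": "HIS",
    "FME": "MET",
}

#: Theoretical maximum accessible surface areas (Å², Tien et al. style),
#: used to normalise SASA into relative solvent accessibility.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Default hydropathy-guided three-class partition used by the linker
#: predictor (configurable through ClassScheme).
DEFAULT_CLASS_OF_AA: dict[str, str] = {}
for _a in "AVLIMFCW":
    DEFAULT_CLASS_OF_AA[_a] = "hydrophobic"
for _a in "RKDENQH":
    DEFAULT_CLASS_OF_AA[_a] = "hydrophilic"
for _a in "GPSTY":
    DEFAULT_CLASS_OF_AA[_a] = "neutral"

CLASS_NAMES: tuple[str, str, str] = ("hydrophilic", "hydrophobic", "neutral")
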