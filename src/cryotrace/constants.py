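"""Shared amino-acid code tables.

The single source of truth for the 1..20 integer codes used by the amino-acid
label mask, the 24-channel predicted-structure encoding and the amino-acid
decoder head.  Codes follow alphabetical order of the 1-letter codes
(A=1 ... Y=20); 0 always means "no amino acid".
"""

from __future__ import annotations

# 1-letter codes, alphabetical
AA_LETTERS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: letter -> 1..20 integer label (0 is reserved for background / unknown)
AA_CODE: dict[str, int] = {aa: i + 1 for i, aa in enumerate(AA_LETTERS)}

#: 1..20 -> letter
AA_FROM_CODE: dict[int, str] = {i + 1: aa for i, aa in enumerate(AA_LETTERS)}

#: 0-based channel index within a 20-vector of amino-acid probabilities
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_LETTERS)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: residue letter used for anything outside the 20 canonical types
UNKNOWN_AA = "X"

BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")

#: channel order of the 24-channel predicted-structure encoding
ENCODING_CHANNELS: tuple[str, ...] = ("CA", "N", "C", "O") + AA_LETTERS
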