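"""Amino-acid tables shared across modules."""

from __future__ import annotations

from Bio.Align import substitution_matrices

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}
STANDARD_RESIDUES = tuple(ONE_TO_THREE.values())

# column order of the PSI-BLAST ASCII position-specific scoring matrix
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
BLOSUM62_DIAGONAL = {aa: int(_BLOSUM62[aa, aa]) for aa in PSSM_ALPHABET}
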