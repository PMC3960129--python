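"""Amino-acid alphabets and index maps shared across the package."""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: backbone atom names excluded from side-chain geometric centers
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


def is_standard(code3: str) -> bool:
    return code3.upper() in THREE_TO_ONE
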