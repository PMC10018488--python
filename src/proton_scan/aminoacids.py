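"""Standard amino-acid tables and the fixed mutation alphabet.

The scan alphabet is fixed (alphabetical one-letter order) so that mutation
lists and score tables are byte-reproducible across runs.
"""

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


def one_letter(aa3: str) -> str:
    """Map a three-letter residue name to its one-letter code, 'X' if non-standard."""
    return AA3_TO_1.get(aa3.upper(), "X")
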