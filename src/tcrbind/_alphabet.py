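"""Shared amino-acid alphabet constants."""

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_SET = frozenset(AMINO_ACIDS)

#: Token joining CDR3a and CDR3b into a single TCR-side sequence.
CONNECTION_TOKEN = ":"


def is_standard(seq: str) -> bool:
    """True if every character is one of the 20 standard residues."""
    return bool(seq) and all(c in AA_SET for c in seq)
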