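"""Amino-acid alphabets used throughout the package.

Peptide windows live over a 21-letter alphabet: the 20 standard amino acids
plus ``O``, the terminal-gap symbol used to pad windows that extend past a
protein terminus. Feature order everywhere follows the alphabet order below.
"""

#: 20 standard amino acids, in the canonical feature order.
ALPHABET20 = "ACDEFGHIKLMNPQRSTVWY"

#: Terminal-gap padding symbol (the 21st letter).
GAP = "O"

#: Full 21-letter window alphabet: standard residues plus the gap symbol.
ALPHABET21 = ALPHABET20 + GAP

#: Letter -> index over the 21-letter alphabet.
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET21)}

#: Ambiguity / non-standard codes that make the 21-symbol encoders
#: ill-defined; windows containing them are excluded with a warning.
NON_STANDARD = frozenset("BJXZU")


def is_standard_window(peptide: str) -> bool:
    """True if every letter of *peptide* belongs to the 21-letter alphabet."""
    return all(c in AA_INDEX for c in peptide)
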