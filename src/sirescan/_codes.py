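"""Integer codon encoding shared by the scanner and the simulator.

Codons over {A,C,G,T} are packed into 0..63 (base-4, A=0, C=1, G=2, T=3);
the gap codon ``---`` is code 64. Anything else is invalid.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
GAP_CODON = "---"
GAP_CODE = 64
N_CODES = 65

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon string -> amino acid one-letter code, with '*' for stops.
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"

ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def codon_to_code(codon: str) -> int:
    """Pack a codon string into its integer code (gap codon -> 64)."""
    if codon == GAP_CODON:
        return GAP_CODE
    try:
        return (
            16 * BASE_INDEX[codon[0]]
            + 4 * BASE_INDEX[codon[1]]
            + BASE_INDEX[codon[2]]
        )
    except (KeyError, IndexError):
        raise ValueError(f"invalid codon {codon!r}") from None


CODE_TO_CODON = tuple(
    ALL_CODONS[i] if i < 64 else GAP_CODON for i in range(N_CODES)
)


def base_at(code: int, position: int) -> str:
    """Base of a packed codon at codon position 1, 2 or 3."""
    return CODE_TO_CODON[code][position - 1]


def translate_code(code: int) -> str:
    return GENETIC_CODE[CODE_TO_CODON[code]]


#: AA_BY_CODE[c] is the amino acid of codon code c ('*' for stops).
AA_BY_CODE = tuple(translate_code(c) for c in range(64))

#: integer amino-acid class per codon code (equal iff synonymous).
_AA_CLASSES = sorted(set(AA_BY_CODE))
AA_INDEX_BY_CODE = np.array([_AA_CLASSES.index(a) for a in AA_BY_CODE],
                            dtype=np.int8)


def encode_codon_row(codons: list[str]) -> np.ndarray:
    """Encode one sequence (list of codon strings) as a uint8 vector."""
    return np.fromiter(
        (codon_to_code(c) for c in codons), dtype=np.uint8, count=len(codons)
    )


def decode_codon_row(codes: np.ndarray) -> list[str]:
    return [CODE_TO_CODON[c] for c in codes]
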