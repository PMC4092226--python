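"""Small sequence utilities shared across the package.

Genomes and sequencer reads live in DNA space (ACGT); the folding and
target engines work in RNA space (ACGU). Conversion is a plain T<->U
swap — small-RNA reads are sequenced from cDNA of the RNA strand, so no
strand flip is involved.
"""

from __future__ import annotations

import numpy as np

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")

#: integer encoding used by the folding engines
BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
CODE_BASE = "ACGU"


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(RNA_COMPLEMENT)[::-1]


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA string as an int8 array (A=0, C=1, G=2, U=3).

    Raises ValueError on any character outside ACGU (after T->U
    normalisation) — the folding engines have no wildcard handling.
    """
    s = to_rna(seq)
    try:
        return np.array([BASE_CODE[b] for b in s], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message check only
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence {s[:30]!r}...") from None


def decode_rna(codes) -> str:
    return "".join(CODE_BASE[c] for c in codes)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
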