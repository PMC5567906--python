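"""Shared nucleotide-string helpers.

All pipeline stages work on DNA-alphabet uppercase strings internally
(U is normalised to T on input); RNA is materialised only at the folding
boundary.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")

DNA_ALPHABET = frozenset("ACGT")


def normalize(seq: str) -> str:
    """Uppercase and map U->T so catalog lookups are alphabet-insensitive."""
    return seq.upper().replace("U", "T")


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= DNA_ALPHABET


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return _LETTERS[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
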