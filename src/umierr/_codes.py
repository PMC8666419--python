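"""Integer base codes shared across the package.

Window observations are stored as small integer matrices so that consensus
calling can be vectorised. Codes 0-3 are the four nucleotides, 4 marks a
base deleted relative to the reference (a first-class consensus symbol),
and 5 marks a reference position not covered by the read pair.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 0, 1, 2, 3
DEL = 4
NOCOV = 5

BASES = "ACGT"
SYMBOLS = "ACGT-"  # DEL rendered as '-'

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([T, G, C, A], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as an int8 array; raises on other symbols."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGT symbol {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    """Decode an array of codes 0-4 back to an A/C/G/T/- string."""
    lut = np.frombuffer(SYMBOLS.encode("ascii"), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.int8)].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes]


def revcomp(seq: str) -> str:
    return decode(complement_codes(encode(seq))[::-1])


def phred_to_prob(q) -> np.ndarray:
    """Per-base error probability 10^(-Q/10)."""
    return np.power(10.0, -np.asarray(q, dtype=np.float64) / 10.0)
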