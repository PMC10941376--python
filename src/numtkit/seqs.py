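"""Nucleotide encoding helpers used throughout the package.

Bases are encoded A=0, C=1, G=2, T=3, N=4 in uint8 arrays; all heavy
numerics work on these codes.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement under the same code: A<->T, C<->G, N->N
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (unknown chars -> N)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def reverse_complement(seq):
    """Reverse-complement a string or a code array."""
    if isinstance(seq, str):
        return decode(COMPLEMENT[encode(seq)][::-1])
    return COMPLEMENT[np.asarray(seq, dtype=np.uint8)][::-1]


def base_frequencies(codes: np.ndarray) -> np.ndarray:
    """Frequencies of A, C, G, T among non-N positions."""
    counts = np.bincount(codes, minlength=5)[:4].astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return counts / total
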