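"""Low-level nucleotide sequence helpers used throughout the toolkit."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte-level base codes: A=0, C=1, G=2, T=3, anything else = 4
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case

_CODE_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, other=4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _CODE_BASE[np.minimum(codes, 4)].tobytes().decode("ascii")


def random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    """Random nucleotide string with the requested expected GC content."""
    gc = gc_fraction / 2.0
    at = (1.0 - gc_fraction) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return decode(codes)


def circular_slice(seq: str, start: int, length: int) -> str:
    """Substring of a circular sequence, wrapping past the origin if needed."""
    n = len(seq)
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    return seq[start:] + seq[: (start + length) % n]
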