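"""Nucleotide codec helpers shared across modules.

Sequences are held as numpy uint8 arrays over {0, 1, 2, 3} = {A, C, G, T}
internally; strings only at the I/O boundary.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement under the 0..3 code: A<->T, C<->G
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string (case-insensitive) as a uint8 array."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = chr(int(np.frombuffer(seq.encode(), dtype=np.uint8)[arr > 3][0]))
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode()


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Percent identity of two equal-length encoded sequences."""
    if a.shape != b.shape:
        raise ValueError("sequences differ in length; ungapped identity undefined")
    if a.size == 0:
        raise ValueError("empty sequences")
    return 100.0 * float(np.count_nonzero(a == b)) / a.size
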