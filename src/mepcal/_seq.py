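"""Small DNA helpers shared across modules: base <-> code maps, k-mer codes.

Base mapping is A,C,G,T = 0,1,2,3 (big-endian digits when rendering symbol
values), fixed for interoperability.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_LUT = np.full(256, -1, dtype=np.int64)
for _b, _i in BASE_TO_CODE.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


class InvalidSequenceError(ValueError):
    pass


def seq_to_codes(seq: str) -> np.ndarray:
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise InvalidSequenceError(f"non-ACGT character {bad!r} in sequence")
    return arr


def codes_to_seq(codes) -> str:
    codes = np.asarray(codes)
    return "".join(BASES[int(c)] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return codes_to_seq(rng.integers(0, 4, size=length))


def kmer_codes(codes: np.ndarray, k: int = 5) -> np.ndarray:
    """Sliding-window k-mer codes along the last axis (base-4 big-endian)."""
    codes = np.asarray(codes)
    n = codes.shape[-1]
    if n < k:
        raise InvalidSequenceError(f"sequence shorter than k={k}")
    out = np.zeros(codes.shape[:-1] + (n - k + 1,), dtype=np.int64)
    for i in range(k):
        out = out * 4 + codes[..., i: n - k + 1 + i]
    return out


def kmer_to_string(code: int, k: int = 5) -> str:
    digits = []
    for _ in range(k):
        digits.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(digits))


def string_to_kmer(s: str) -> int:
    code = 0
    for ch in s:
        code = (code << 2) | BASE_TO_CODE[ch]
    return code
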