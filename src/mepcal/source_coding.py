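"""Byte-level canonical Huffman source coding.

The container is self-describing: magic, version, original length, the
canonical code-length table (one byte per symbol) and the packed bit body,
so decompression needs no side information.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

MAGIC = b"MEPH"
_VERSION = 1


class CorruptInputError(ValueError):
    """Raised when a compressed container fails structural validation."""


@dataclass
class HuffmanModel:
    code_table: dict[int, str]   # symbol -> bitstring
    H: float                     # empirical source entropy, bits/byte
    L: float                     # mean code length, bits/byte


def _code_lengths(freqs: dict[int, int]) -> dict[int, int]:
    """Huffman code lengths via the standard heap construction."""
    if len(freqs) == 1:
        return {next(iter(freqs)): 1}
    heap = [(f, [s]) for s, f in freqs.items()]
    lengths = {s: 0 for s in freqs}
    heapq.heapify(heap)
    while len(heap) > 1:
        f1, s1 = heapq.heappop(heap)
        f2, s2 = heapq.heappop(heap)
        for s in s1 + s2:
            lengths[s] += 1
        heapq.heappush(heap, (f1 + f2, s1 + s2))
    return lengths


def _canonical_codes(lengths: dict[int, int]) -> dict[int, str]:
    """Assign canonical codes: sorted by (length, symbol), incrementing."""
    code = 0
    prev_len = 0
    table = {}
    for sym in sorted(lengths, key=lambda s: (lengths[s], s)):
        ln = lengths[sym]
        code <<= (ln - prev_len)
        table[sym] = format(code, f"0{ln}b")
        code += 1
        prev_len = ln
    return table


def compress(payload: bytes) -> tuple[bytes, HuffmanModel]:
    """Compress ``payload``; returns (container, model with H and L)."""
    if len(payload) == 0:
        raise ValueError("payload must be non-empty")
    counts = np.bincount(np.frombuffer(payload, dtype=np.uint8), minlength=256)
    freqs = {int(s): int(c) for s, c in enumerate(counts) if c > 0}
    n = len(payload)
    probs = np.array(list(freqs.values())) / n
    H = float(-(probs * np.log2(probs)).sum())
    lengths = _code_lengths(freqs)
    table = _canonical_codes(lengths)
    L = sum(freqs[s] * lengths[s] for s in freqs) / n

    len_table = bytes(lengths.get(s, 0) for s in range(256))
    bits = bytearray()
    acc = 0
    nacc = 0
    body = bytearray()
    for b in payload:
        code = table[b]
        for ch in code:
            acc = (acc << 1) | (ch == "1")
            nacc += 1
            if nacc == 8:
                body.append(acc)
                acc = 0
                nacc = 0
    if nacc:
        body.append(acc << (8 - nacc))
    header = (MAGIC + bytes([_VERSION]) + len(payload).to_bytes(8, "big")
              + len_table)
    return header + bytes(body), HuffmanModel(table, H, L)


def decompress(container: bytes) -> bytes:
    """Exact inverse of :func:`compress`."""
    if len(container) < 4 + 1 + 8 + 256:
        raise CorruptInputError("container shorter than its header")
    if container[:4] != MAGIC:
        raise CorruptInputError("bad magic")
    if container[4] != _VERSION:
        raise CorruptInputError(f"unsupported version {container[4]}")
    n = int.from_bytes(container[5:13], "big")
    lengths = {s: container[13 + s] for s in range(256) if container[13 + s]}
    body = container[13 + 256:]
    if n == 0:
        return b""
    if not lengths:
        raise CorruptInputError("empty code table for non-empty payload")
    # Kraft check guards against corrupted tables
    kraft = sum(2.0 ** -ln for ln in lengths.values())
    if kraft > 1.0 + 1e-9:
        raise CorruptInputError("code-length table violates the Kraft bound")
    table = _canonical_codes(lengths)
    decode = {code: sym for sym, code in table.items()}
    max_len = max(lengths.values())
    out = bytearray()
    cur = ""
    for byte in body:
        for bit in format(byte, "08b"):
            cur += bit
            if cur in decode:
                out.append(decode[cur])
                cur = ""
                if len(out) == n:
                    return bytes(out)
            elif len(cur) > max_len:
                raise CorruptInputError("undecodable bit sequence")
    raise CorruptInputError("bit body exhausted before declared length")
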