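"""Comparison codec: interleaved binary BCH(255,207) blocks at 2 bit/base.

Each block carries 207 information bits, 48 BCH parity bits (narrow-sense,
t = 6, generator from the minimal polynomials of alpha^1..alpha^12 over
GF(2^8) with primitive polynomial 0x11D) and one overall even-parity bit:
256 bits = 128 bases. The scheme corrects up to 6 substituted bits per
block but has no synchronization mechanism at all — any single inserted or
deleted base changes the sequence length and defeats it, which is precisely
the failure mode the anchored codec is built to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._gf256 import EXP, LOG, ORDER, gf_mul
from ._seq import BASES, seq_to_codes
from .rs import RSDecodeError, _berlekamp_massey

INFO_BITS = 207
CODE_BITS = 255
BLOCK_BITS = 256          # codeword + 1 even-parity bit
BLOCK_BASES = 128
T_CORRECT = 6
BASELINE_BLOCKS = 224     # block count of the packaged 5,564-byte comparison

_LEN_HEADER = 8           # payload length prefix, bytes


class BchIndelError(Exception):
    """Sequence length incompatible with the block structure (indel)."""


class BchDecodeFailure(Exception):
    pass


def _generator_poly() -> np.ndarray:
    """Binary generator polynomial (degree 48), highest degree first."""
    cosets = []
    seen = set()
    for i in range(1, 2 * T_CORRECT + 1):
        if i in seen:
            continue
        coset = set()
        x = i
        while x not in coset:
            coset.add(x)
            x = (x * 2) % ORDER
        seen |= coset
        cosets.append(sorted(coset))
    g = [1]
    for coset in cosets:
        m = [1]
        for s in coset:                       # minimal poly of alpha^s
            root = int(EXP[s])
            nxt = [0] * (len(m) + 1)
            for d, c in enumerate(m):
                nxt[d] ^= gf_mul(c, root)
                nxt[d + 1] ^= c
            m = nxt
        m = m[::-1]                           # highest degree first
        assert all(c in (0, 1) for c in m)
        gg = np.zeros(len(g) + len(m) - 1, dtype=np.int64)
        for d1, c1 in enumerate(g):
            if c1:
                for d2, c2 in enumerate(m):
                    if c2:
                        gg[d1 + d2] ^= 1
        g = list(gg)
    assert len(g) - 1 == CODE_BITS - INFO_BITS
    return np.array(g, dtype=np.int64)


_GEN = _generator_poly()


@dataclass
class BchReport:
    n_blocks: int
    corrected_bits: list[int]
    parity_ok: list[bool]
    failed_blocks: list[int]

    @property
    def success(self) -> bool:
        return not self.failed_blocks


def _bits_from_bytes(data: bytes) -> np.ndarray:
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8)).astype(np.int64)


def _encode_block(info: np.ndarray) -> np.ndarray:
    """207 info bits -> 256-bit block (codeword + even-parity bit)."""
    rem = np.concatenate([info, np.zeros(CODE_BITS - INFO_BITS, np.int64)])
    for i in range(INFO_BITS):
        if rem[i]:
            rem[i:i + _GEN.size] ^= _GEN
    cw = np.concatenate([info, rem[INFO_BITS:]])
    parity = int(cw.sum() & 1)                # make total weight even
    return np.concatenate([cw, [parity]])


def bch_encode(payload: bytes, n_blocks: int | None = None) -> str:
    """Encode a payload (with an 8-byte length prefix) into DNA.

    ``n_blocks`` may exceed the minimum needed; extra capacity is
    zero-padded. The packaged baseline comparison pins 224 blocks for the
    5,564-byte payload (128 x 224 = 28,672 bases).
    """
    if len(payload) == 0:
        raise ValueError("payload must be non-empty")
    framed = len(payload).to_bytes(_LEN_HEADER, "big") + payload
    bits = _bits_from_bytes(framed)
    need = -(-bits.size // INFO_BITS)
    blocks = max(need, n_blocks or 0)
    padded = np.zeros(blocks * INFO_BITS, dtype=np.int64)
    padded[: bits.size] = bits
    out_codes = np.empty(blocks * BLOCK_BASES, dtype=np.int64)
    for b in range(blocks):
        block = _encode_block(padded[b * INFO_BITS:(b + 1) * INFO_BITS])
        pairs = block.reshape(BLOCK_BASES, 2)
        out_codes[b * BLOCK_BASES:(b + 1) * BLOCK_BASES] = \
            pairs[:, 0] * 2 + pairs[:, 1]
    return "".join(BASES[c] for c in out_codes)


def _syndromes(cw: np.ndarray) -> np.ndarray:
    """S_j = c(alpha^j) for j = 1..2t, with c[0] the x^254 coefficient."""
    set_pos = np.nonzero(cw)[0]
    if set_pos.size == 0:
        return np.zeros(2 * T_CORRECT, dtype=np.int64)
    degs = CODE_BITS - 1 - set_pos
    j = np.arange(1, 2 * T_CORRECT + 1)[:, None]
    terms = EXP[(j * degs[None, :]) % ORDER]
    return np.bitwise_xor.reduce(terms, axis=1)


def _decode_block(block: np.ndarray) -> tuple[np.ndarray, int, bool]:
    """Correct up to 6 bit errors; returns (info bits, n_corrected, parity_ok)."""
    cw = block[:CODE_BITS].copy()
    synd = _syndromes(cw)
    n_corr = 0
    if synd.any():
        sigma = _berlekamp_massey([int(s) for s in synd], 2 * T_CORRECT)
        deg = len(sigma) - 1
        lam = np.array(sigma, dtype=np.int64)
        t_idx = np.arange(lam.size)
        e_i = (-(CODE_BITS - 1 - np.arange(CODE_BITS))) % ORDER
        terms = EXP[(LOG[lam][None, :] + t_idx[None, :] * e_i[:, None]) % ORDER]
        terms = np.where(lam[None, :] == 0, 0, terms)
        vals = np.bitwise_xor.reduce(terms, axis=1)
        roots = np.nonzero(vals == 0)[0]
        if roots.size != deg:
            raise BchDecodeFailure("locator degree/root mismatch")
        cw[roots] ^= 1
        if _syndromes(cw).any():
            raise BchDecodeFailure("syndrome recheck failed")
        n_corr = int(roots.size)
    parity_ok = int(cw.sum() + block[CODE_BITS]) % 2 == 0
    return cw[:INFO_BITS], n_corr, parity_ok


def bch_decode(dna: str) -> tuple[bytes, BchReport]:
    """Decode a BCH-coded DNA sequence; substitution-only channel.

    Raises BchIndelError when the length is not a whole number of 128-base
    blocks (the baseline cannot resynchronize after an indel).
    """
    if len(dna) == 0 or len(dna) % BLOCK_BASES != 0:
        raise BchIndelError(
            f"length {len(dna)} is not a multiple of {BLOCK_BASES} bases; "
            "an indel breaks the block structure")
    codes = seq_to_codes(dna)
    blocks = len(dna) // BLOCK_BASES
    bits = np.empty(blocks * BLOCK_BITS, dtype=np.int64)
    bits[0::2] = codes >> 1
    bits[1::2] = codes & 1
    info = np.empty(blocks * INFO_BITS, dtype=np.int64)
    corrected, parity, failed = [], [], []
    for b in range(blocks):
        block = bits[b * BLOCK_BITS:(b + 1) * BLOCK_BITS]
        try:
            ib, n_corr, p_ok = _decode_block(block)
        except (BchDecodeFailure, RSDecodeError):
            failed.append(b)
            ib, n_corr, p_ok = block[:INFO_BITS], -1, False
        info[b * INFO_BITS:(b + 1) * INFO_BITS] = ib
        corrected.append(n_corr)
        parity.append(p_ok)
    report = BchReport(blocks, corrected, parity, failed)
    nbytes = info.size // 8
    data = np.packbits(info[: nbytes * 8].astype(np.uint8)).tobytes()
    true_len = int.from_bytes(data[:_LEN_HEADER], "big")
    if true_len > len(data) - _LEN_HEADER:
        raise BchDecodeFailure("corrupted length header")
    return data[_LEN_HEADER:_LEN_HEADER + true_len], report
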