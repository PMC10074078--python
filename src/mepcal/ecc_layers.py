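"""The three error-correction layers of the codec.

* primary: E interleaved RS(N+G, N) codewords per block, one byte per group
  per codeword, so any N intact groups of a block recover its payload;
* fountain: a seeded systematic random-linear fountain over GF(2^8) that
  expands each group's E information bytes into a surplus of candidate
  packets (the screening layer picks which survive);
* tertiary: one RS(E+M, E) codeword per group over the retained packets,
  absorbing the substitutions and indel erasures the symbol caller reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._gf256 import gf_matmul, gf_solve, gf_matrix_rank
from .codec_profile import CodecProfile
from .rs import RSCodec, RSDecodeError


class UnrecoverablePayloadError(Exception):
    def __init__(self, failed_groups):
        self.failed_groups = list(failed_groups)
        super().__init__(
            f"primary layer unrecoverable; failed groups: {self.failed_groups}")


class InsufficientPacketsError(Exception):
    pass


class GroupUndecodableError(Exception):
    pass


@dataclass
class Packet:
    group_id: int
    esi: int
    symbols: np.ndarray          # bytes_per_set base-256 values
    selected: bool = False


# -- primary layer ----------------------------------------------------------

def _primary_codec(profile: CodecProfile) -> RSCodec:
    return RSCodec(profile.N + profile.G, profile.N)


def primary_encode(payload_symbols, profile: CodecProfile) -> np.ndarray:
    """(n_blocks*N*E,) payload bytes -> (groups_total, E) group payloads."""
    p = profile
    sym = np.asarray(payload_symbols, dtype=np.int64)
    if sym.shape != (p.n_blocks * p.N * p.E,):
        raise ValueError(
            f"expected {p.n_blocks * p.N * p.E} payload symbols, got {sym.shape}")
    rs = _primary_codec(p)
    out = np.empty((p.groups_total, p.E), dtype=np.int64)
    per_block = p.N + p.G
    for b in range(p.n_blocks):
        data = sym[b * p.N * p.E:(b + 1) * p.N * p.E].reshape(p.N, p.E)
        if p.G == 0:
            out[b * per_block:(b + 1) * per_block] = data
            continue
        codewords = rs.encode_many(data.T)          # (E, N+G)
        out[b * per_block:(b + 1) * per_block] = codewords.T
    return out


def primary_decode(group_symbols, erased_groups, profile: CodecProfile
                   ) -> np.ndarray:
    """Recover the payload from per-group bytes with group-level erasures.

    Succeeds iff every block retains at least N of its N+G groups (pure
    erasures). Residual substitution-like damage — a group that decoded at
    the tertiary layer but carries wrong bytes — is additionally corrected
    or detected per interleaved codeword within 2e + f <= G.
    """
    p = profile
    groups = np.asarray(group_symbols, dtype=np.int64)
    if groups.shape != (p.groups_total, p.E):
        raise ValueError("group_symbols must be (groups_total, E)")
    erased = set(int(g) for g in erased_groups)
    per_block = p.N + p.G
    failed_blocks = [b for b in range(p.n_blocks)
                     if sum(1 for g in erased
                            if b * per_block <= g < (b + 1) * per_block) > p.G]
    if failed_blocks:
        raise UnrecoverablePayloadError(sorted(erased))
    rs = _primary_codec(p)
    out = np.empty(p.n_blocks * p.N * p.E, dtype=np.int64)
    for b in range(p.n_blocks):
        lo = b * per_block
        block = groups[lo:lo + per_block]
        block_erasures = [g - lo for g in erased if lo <= g < lo + per_block]
        codewords = block.T                               # (E, N+G)
        if p.G == 0:
            data = block[: p.N]
        elif not block_erasures and not _any_syndromes(codewords, rs):
            data = block[: p.N]
        else:
            rows = []
            try:
                for cw in codewords:
                    msg, _, _ = rs.decode(cw, block_erasures)
                    rows.append(msg)
            except RSDecodeError as exc:
                raise UnrecoverablePayloadError(sorted(erased)) from exc
            data = np.stack(rows).T                       # (N, E) -> groups
        out[b * p.N * p.E:(b + 1) * p.N * p.E] = data.reshape(-1)
    return out


def _any_syndromes(codewords: np.ndarray, rs: RSCodec) -> bool:
    """Vectorized check whether any of the (m, n) codewords has a nonzero
    syndrome (i.e. is not a valid RS codeword)."""
    from ._gf256 import EXP, LOG, ORDER
    c = np.asarray(codewords, dtype=np.int64)
    terms = EXP[(LOG[c][:, None, :] + rs._synd_pow[None, :, :]) % ORDER]
    terms = np.where(c[:, None, :] == 0, 0, terms)
    return bool(np.bitwise_xor.reduce(terms, axis=2).any())


# -- fountain layer ---------------------------------------------------------

def fountain_coefficients(profile: CodecProfile, seed: int, group_id: int
                          ) -> np.ndarray:
    """(fountain_expansion, packets_kept) GF(2^8) coefficient matrix.

    The first ``packets_kept`` rows are the identity (systematic packets);
    the rest are pseudorandom rows, deterministic in (seed, group_id), with
    all-zero rows patched to keep every candidate informative.
    """
    p = profile
    kept = p.packets_kept
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        group_id, 0xF0]))
    coeffs = np.zeros((p.fountain_expansion, kept), dtype=np.int64)
    coeffs[:kept] = np.eye(kept, dtype=np.int64)
    extra = p.fountain_expansion - kept
    if extra:
        block = rng.integers(0, 256, size=(extra, kept), dtype=np.int64)
        zero_rows = ~block.any(axis=1)
        if zero_rows.any():
            block[zero_rows, 0] = 1
        coeffs[kept:] = block
    return coeffs


def fountain_symbols(group_payload, coeffs, profile: CodecProfile
                     ) -> np.ndarray:
    """Apply coefficient rows to a group payload: (m, kept) -> (m, set bytes)."""
    p = profile
    payload = np.asarray(group_payload, dtype=np.int64)
    if payload.shape != (p.E,):
        raise ValueError(f"group payload must have {p.E} symbols")
    sys_packets = payload.reshape(p.packets_kept, p.bytes_per_set)
    return gf_matmul(np.asarray(coeffs, dtype=np.int64), sys_packets)


def fountain_expand(group_payload, profile: CodecProfile, seed: int = 0,
                    group_id: int = 0) -> list[Packet]:
    """All candidate packets of a group, in ESI order (deterministic)."""
    coeffs = fountain_coefficients(profile, seed, group_id)
    syms = fountain_symbols(group_payload, coeffs, profile)
    return [Packet(group_id=group_id, esi=e, symbols=syms[e])
            for e in range(len(syms))]


def fountain_invert(packets: list[Packet], profile: CodecProfile,
                    seed: int = 0) -> np.ndarray:
    """Recover a group payload from >= packets_kept packets with known ESIs."""
    p = profile
    kept = p.packets_kept
    if len(packets) < kept:
        raise InsufficientPacketsError(
            f"need at least {kept} packets, got {len(packets)}")
    gid = packets[0].group_id
    all_coeffs = fountain_coefficients(profile, seed, gid)
    rows = np.stack([all_coeffs[pk.esi] for pk in packets])
    vals = np.stack([np.asarray(pk.symbols, dtype=np.int64) for pk in packets])
    # choose an independent subset of rows (greedy by rank)
    chosen = []
    for i in range(len(rows)):
        trial = chosen + [i]
        if gf_matrix_rank(rows[trial]) == len(trial):
            chosen.append(i)
        if len(chosen) == kept:
            break
    if len(chosen) < kept:
        raise InsufficientPacketsError(
            "packet coefficient matrix is singular; need more packets")
    A = rows[chosen]
    B = vals[chosen]
    sys_packets = gf_solve(A, B)
    return sys_packets.reshape(-1)


def selection_invertible(esis, profile: CodecProfile, seed: int,
                         group_id: int) -> bool:
    coeffs = fountain_coefficients(profile, seed, group_id)
    rows = coeffs[np.asarray(list(esis), dtype=int)]
    return gf_matrix_rank(rows) == profile.packets_kept


# -- tertiary layer ---------------------------------------------------------

def _tertiary_codec(profile: CodecProfile) -> RSCodec:
    return RSCodec(profile.E + profile.M, profile.E)


def tertiary_encode(retained, profile: CodecProfile) -> np.ndarray:
    """E retained information bytes -> E+M codeword (RS(240,160) for WC53)."""
    p = profile
    retained = np.asarray(retained, dtype=np.int64)
    if retained.shape != (p.E,):
        raise ValueError(f"retained symbols must have length {p.E}")
    if p.M == 0:
        return retained.copy()
    return _tertiary_codec(p).encode(retained)


def tertiary_decode(received, erasures, profile: CodecProfile
                    ) -> tuple[np.ndarray, dict]:
    """Decode one group codeword; succeeds whenever 2e + f <= M.

    Returns (E information bytes, report) or raises GroupUndecodableError,
    which the caller turns into a group-level erasure for the primary layer.
    """
    p = profile
    received = np.asarray(received, dtype=np.int64)
    if received.shape != (p.E + p.M,):
        raise ValueError(f"received word must have length {p.E + p.M}")
    if p.M == 0:
        if len(list(erasures)):
            raise GroupUndecodableError("no tertiary redundancy for erasures")
        return received.copy(), {"errors": 0, "erasures": 0}
    try:
        msg, n_err, n_eras = _tertiary_codec(p).decode(received, erasures)
    except RSDecodeError as exc:
        raise GroupUndecodableError(str(exc)) from exc
    return msg, {"errors": n_err, "erasures": n_eras}
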