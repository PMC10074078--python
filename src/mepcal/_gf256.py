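"""Arithmetic over GF(2^8) with primitive polynomial x^8+x^4+x^3+x^2+1 (0x11D).

Log/antilog tables plus the vectorized helpers the Reed-Solomon and fountain
layers need. Elements are ints in [0, 255]; arrays are numpy integer arrays.
"""

from __future__ import annotations

import numpy as np

PRIM = 0x11D
ORDER = 255

# EXP is doubled so EXP[log a + log b] never needs an explicit modulo for
# products of two elements.
EXP = np.zeros(512, dtype=np.int64)
LOG = np.zeros(256, dtype=np.int64)
_x = 1
for _i in range(ORDER):
    EXP[_i] = _x
    LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= PRIM
EXP[ORDER : 2 * ORDER] = EXP[:ORDER]
EXP[2 * ORDER :] = 1
LOG[0] = 0  # sentinel; callers must mask zeros themselves


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(EXP[LOG[a] + LOG[b]])


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(256)")
    if a == 0:
        return 0
    return int(EXP[(LOG[a] - LOG[b]) % ORDER])


def gf_inv(a: int) -> int:
    if a == 0:
        raise ZeroDivisionError("zero has no inverse in GF(256)")
    return int(EXP[ORDER - LOG[a]])


def gf_pow(a: int, n: int) -> int:
    if a == 0:
        return 0 if n != 0 else 1
    return int(EXP[(LOG[a] * n) % ORDER])


def gf_mul_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise product of two arrays (broadcasting allowed)."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    out = EXP[LOG[a] + LOG[b]]
    return np.where((a == 0) | (b == 0), 0, out)


def gf_scale_vec(a: np.ndarray, s: int) -> np.ndarray:
    if s == 0:
        return np.zeros_like(np.asarray(a, dtype=np.int64))
    a = np.asarray(a, dtype=np.int64)
    out = EXP[LOG[a] + LOG[s]]
    return np.where(a == 0, 0, out)


def gf_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Matrix product over GF(256): (m,k) @ (k,n) -> (m,n) via XOR-reduce."""
    A = np.asarray(A, dtype=np.int64)
    B = np.asarray(B, dtype=np.int64)
    prod = gf_mul_vec(A[:, :, None], B[None, :, :])
    return np.bitwise_xor.reduce(prod, axis=1)


def gf_solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B over GF(256) by Gaussian elimination.

    A is (n,n), B is (n,) or (n,m). Raises LinAlgError on singular A.
    """
    A = np.array(A, dtype=np.int64)
    B = np.array(B, dtype=np.int64)
    one_d = B.ndim == 1
    if one_d:
        B = B[:, None]
    n = A.shape[0]
    for col in range(n):
        piv = col + int(np.argmax(A[col:, col] != 0))
        if A[piv, col] == 0:
            raise np.linalg.LinAlgError("singular GF(256) matrix")
        if piv != col:
            A[[col, piv]] = A[[piv, col]]
            B[[col, piv]] = B[[piv, col]]
        inv = gf_inv(int(A[col, col]))
        A[col] = gf_scale_vec(A[col], inv)
        B[col] = gf_scale_vec(B[col], inv)
        mask = (A[:, col] != 0) & (np.arange(n) != col)
        if mask.any():
            factors = A[mask, col]
            A[mask] ^= gf_mul_vec(factors[:, None], A[col][None, :])
            B[mask] ^= gf_mul_vec(factors[:, None], B[col][None, :])
    return B[:, 0] if one_d else B


def gf_matrix_rank(A: np.ndarray) -> int:
    A = np.array(A, dtype=np.int64)
    rows, cols = A.shape
    rank = 0
    for col in range(cols):
        if rank == rows:
            break
        sub = A[rank:, col]
        nz = np.nonzero(sub)[0]
        if nz.size == 0:
            continue
        piv = rank + int(nz[0])
        if piv != rank:
            A[[rank, piv]] = A[[piv, rank]]
        inv = gf_inv(int(A[rank, col]))
        A[rank] = gf_scale_vec(A[rank], inv)
        mask = (A[:, col] != 0) & (np.arange(rows) != rank)
        if mask.any():
            A[mask] ^= gf_mul_vec(A[mask, col][:, None], A[rank][None, :])
        rank += 1
    return rank


# -- polynomial helpers (coefficient lists, highest degree first) -----------

def poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a == 0:
            continue
        for j, b in enumerate(q):
            if b:
                out[i + j] ^= gf_mul(a, b)
    return out


def poly_eval(p: list[int] | np.ndarray, x: int) -> int:
    y = 0
    for c in p:
        y = gf_mul(y, x) ^ int(c)
    return y
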