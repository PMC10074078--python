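"""Systematic Reed-Solomon codec over GF(2^8) with errors-and-erasures decoding.

Codewords are arrays of length n <= 255 whose first k entries are the message
(highest-degree coefficients first). Generator roots are alpha^1..alpha^(n-k)
(fcr = 1, generator element alpha = 2). Decoding uses Forney syndromes +
Berlekamp-Massey + Chien search + the Forney value formula, so a codeword is
recovered whenever 2*errors + erasures <= n - k.
"""

from __future__ import annotations

import numpy as np

from ._gf256 import EXP, LOG, ORDER, gf_div, gf_inv, gf_mul, gf_pow, poly_mul


class RSDecodeError(Exception):
    """Raised when the received word is outside the code's correction radius."""


class RSCodec:
    def __init__(self, n: int, k: int):
        if not (0 < k <= n <= ORDER):
            raise ValueError(f"invalid RS parameters n={n}, k={k}")
        self.n = n
        self.k = k
        self.nsym = n - k
        gen = [1]
        for j in range(1, self.nsym + 1):
            gen = poly_mul(gen, [1, gf_pow(2, j)])
        self._gen = gen  # highest degree first
        # syndrome exponent table: _synd_pow[j-1, i] = (j * (n-1-i)) mod 255
        j = np.arange(1, self.nsym + 1)[:, None]
        p = (self.n - 1 - np.arange(self.n))[None, :]
        self._synd_pow = (j * p) % ORDER

    # -- encoding -----------------------------------------------------------

    def encode(self, msg) -> np.ndarray:
        msg = np.asarray(msg, dtype=np.int64)
        if msg.shape != (self.k,):
            raise ValueError(f"message must have length {self.k}")
        if self.nsym == 0:
            return msg.copy()
        rem = list(msg) + [0] * self.nsym
        for i in range(self.k):
            c = rem[i]
            if c:
                for j in range(1, len(self._gen)):
                    rem[i + j] ^= gf_mul(int(self._gen[j]), int(c))
        out = np.concatenate([msg, np.array(rem[self.k:], dtype=np.int64)])
        return out

    def encode_many(self, msgs: np.ndarray) -> np.ndarray:
        """Encode rows of a (m, k) array -> (m, n)."""
        msgs = np.asarray(msgs, dtype=np.int64)
        return np.stack([self.encode(row) for row in msgs])

    # -- decoding -----------------------------------------------------------

    def syndromes(self, received: np.ndarray) -> np.ndarray:
        r = np.asarray(received, dtype=np.int64)
        terms = EXP[(LOG[r][None, :] + self._synd_pow) % ORDER]
        terms = np.where(r[None, :] == 0, 0, terms)
        return np.bitwise_xor.reduce(terms, axis=1)

    def decode(self, received, erasures=()) -> tuple[np.ndarray, int, int]:
        """Return (message, n_errors_corrected, n_erasures_corrected).

        `erasures` are array indices whose symbols are unreliable (their
        values are ignored). Raises RSDecodeError beyond 2e + f <= n - k.
        """
        r = np.array(received, dtype=np.int64)
        if r.shape != (self.n,):
            raise ValueError(f"received word must have length {self.n}")
        erasures = sorted(set(int(e) for e in erasures))
        if any(e < 0 or e >= self.n for e in erasures):
            raise ValueError("erasure index out of range")
        f = len(erasures)
        if f > self.nsym:
            raise RSDecodeError(
                f"{f} erasures exceed correction capacity {self.nsym}")
        r[erasures] = 0
        synd = self.syndromes(r)
        if not synd.any():
            return r[: self.k], 0, f

        S = [int(s) for s in synd]  # S[j] = syndrome for root alpha^(j+1)
        # erasure locator Gamma(z), low degree first
        gamma = [1]
        X_eras = [gf_pow(2, self.n - 1 - e) for e in erasures]
        for X in X_eras:
            gamma = _poly_mul_low(gamma, [1, X])
        # Forney syndromes T = S(z) * Gamma(z) mod z^nsym; entries at index
        # >= f are pure error power-sums, which is what Berlekamp-Massey needs
        T = _poly_mul_low(S, gamma)[: self.nsym]
        sigma = _berlekamp_massey(T[f:], self.nsym - f)
        lam = _poly_mul_low(sigma, gamma)
        deg = len(lam) - 1
        # Chien search over all positions (vectorized)
        lam_a = np.array(lam, dtype=np.int64)
        t = np.arange(lam_a.size)
        e_i = (-(self.n - 1 - np.arange(self.n))) % ORDER
        terms = EXP[(LOG[lam_a][None, :] + t[None, :] * e_i[:, None]) % ORDER]
        terms = np.where(lam_a[None, :] == 0, 0, terms)
        vals = np.bitwise_xor.reduce(terms, axis=1)
        roots_idx = np.nonzero(vals == 0)[0].tolist()
        if len(roots_idx) != deg:
            raise RSDecodeError("errata locator degree/root mismatch")
        omega = _poly_mul_low(S, lam)[: self.nsym]
        lam_deriv = [lam[t] for t in range(1, len(lam), 2)]
        # formal derivative: sum over odd t of lam_t z^(t-1) -> even powers
        for i in roots_idx:
            Xi = gf_pow(2, self.n - 1 - i)
            Xi_inv = gf_inv(Xi)
            num = _poly_eval_low(omega, Xi_inv)
            den = _poly_eval_even(lam_deriv, Xi_inv)
            if den == 0:
                raise RSDecodeError("Forney denominator zero")
            r[i] ^= gf_div(num, den)
        if self.syndromes(r).any():
            raise RSDecodeError("correction failed syndrome recheck")
        n_err = len([i for i in roots_idx if i not in erasures])
        if 2 * n_err + f > self.nsym:
            raise RSDecodeError("beyond 2e + f bound")
        return r[: self.k], n_err, f

    def decode_erasures_many(self, received: np.ndarray,
                             erasures) -> np.ndarray:
        """Erasure-only decode of many words sharing one erasure pattern.

        `received` is (m, n); returns (m, k). Used by the primary layer where
        whole groups are flagged erased, so every interleaved codeword shares
        the same erasure set.
        """
        received = np.asarray(received, dtype=np.int64)
        erasures = sorted(set(int(e) for e in erasures))
        if not erasures:
            return received[:, : self.k].copy()
        if len(erasures) > self.nsym:
            raise RSDecodeError(
                f"{len(erasures)} erased positions exceed capacity {self.nsym}")
        out = np.empty((received.shape[0], self.k), dtype=np.int64)
        for m, row in enumerate(received):
            out[m], _, _ = self.decode(row, erasures)
        return out


# -- low-degree-first polynomial helpers ------------------------------------

def _poly_mul_low(p, q):
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a == 0:
            continue
        la = LOG[a]
        for j, b in enumerate(q):
            if b:
                out[i + j] ^= int(EXP[la + LOG[b]])
    return out


def _poly_eval_low(p, x):
    y = 0
    for c in reversed(p):
        y = gf_mul(y, x) ^ int(c)
    return y


def _poly_eval_even(coeffs, x):
    """Evaluate sum_i coeffs[i] * x^(2i)."""
    x2 = gf_mul(x, x)
    y = 0
    for c in reversed(coeffs):
        y = gf_mul(y, x2) ^ int(c)
    return y


def _berlekamp_massey(T, max_2e):
    """Minimal LFSR for sequence T; error count limited to max_2e // 2."""
    C = [1]
    B = [1]
    L = 0
    m = 1
    b = 1
    for nn in range(len(T)):
        d = T[nn]
        for i in range(1, L + 1):
            if i < len(C) and C[i]:
                d ^= gf_mul(C[i], T[nn - i])
        if d == 0:
            m += 1
        elif 2 * L <= nn:
            old = C[:]
            coef = gf_div(d, b)
            C = _poly_add_low(C, _poly_shift_scale(B, m, coef))
            L = nn + 1 - L
            B = old
            b = d
            m = 1
        else:
            C = _poly_add_low(C, _poly_shift_scale(B, m, gf_div(d, b)))
            m += 1
    if L > max_2e // 2:
        raise RSDecodeError("too many errors for remaining capacity")
    return C[: L + 1]


def _poly_add_low(p, q):
    n = max(len(p), len(q))
    out = [0] * n
    for i, c in enumerate(p):
        out[i] ^= c
    for i, c in enumerate(q):
        out[i] ^= c
    while len(out) > 1 and out[-1] == 0:
        out.pop()
    return out


def _poly_shift_scale(p, shift, s):
    return [0] * shift + [gf_mul(c, s) for c in p]
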