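"""Codec parameter space, layout arithmetic and coding-density computation.

A profile fixes the layered layout: payload bytes are grouped into encoding
groups of ``E`` information bytes plus ``M`` tertiary Reed-Solomon repair
bytes; each group is rendered as ``(E+M)/(S*R/4)`` encoding sets of ``S`` DNA
symbols, every DNA symbol being ``R`` bases preceded by one leading (anchor)
base; 5-bp set indices and a 10-bp group index delimit the pieces. Across
groups, a primary interleaved RS layer adds ``G`` repair groups per block of
``N`` information groups.

The default configuration ("WC53": S=10, R=4, E=160, M=80, N=35, G=3) stores
a 5,564-byte payload in 50,540 bases at 0.886 bit/base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

GF8_MAX_CODEWORD = 255
_DEFAULT_G_RATIO = 3 / 35  # primary repair ratio of the default configuration
_MAX_N = 235  # keeps N + G <= 255 under the default G ratio


class ProfileError(ValueError):
    """Signalled for parameter sets that violate the layout invariants."""


@dataclass
class CodecProfile:
    S: int = 10                  # DNA symbols per encoding set
    R: int = 4                   # bases of payload per leading base
    E: int = 160                 # information bytes per encoding group
    M: int = 80                  # tertiary repair bytes per group
    N: int = 35                  # information groups per primary block
    G: int = 3                   # repair groups per primary block
    n_blocks: int = 1            # primary blocks (each N+G groups)
    set_index_len: int = 5       # I_s, bases
    group_index_len: int = 10    # I_g, bases
    packets_kept: int = 16       # packets retained per group after screening
    fountain_expansion: int = 6384  # candidate packets generated per group
    symbol_bits: int = 8
    leading_base: str = "A"
    payload_bytes: int | None = None
    padding: int | None = None

    def __post_init__(self):
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def bytes_per_unit(self) -> int:
        """Base-256 numbers per DNA symbol (R bases at 2 bit/base)."""
        return self.R // 4

    @property
    def bytes_per_set(self) -> int:
        return self.S * self.bytes_per_unit

    @property
    def sets_per_group(self) -> int:
        return (self.E + self.M) // self.bytes_per_set

    @property
    def info_sets_per_group(self) -> int:
        return self.E // self.bytes_per_set

    @property
    def units_per_group(self) -> int:
        return self.sets_per_group * self.S

    @property
    def groups_total(self) -> int:
        return self.n_blocks * (self.N + self.G)

    @property
    def payload_capacity(self) -> int:
        """Payload bytes the profile can hold (before padding)."""
        return self.n_blocks * self.N * self.E

    def validate(self) -> None:
        p = self
        for name in ("S", "R", "E", "M", "N", "G", "n_blocks",
                     "set_index_len", "group_index_len", "packets_kept",
                     "fountain_expansion"):
            v = getattr(p, name)
            if not isinstance(v, int):
                raise ProfileError(f"{name} must be an integer")
        for name in ("S", "R", "E", "N", "n_blocks", "packets_kept",
                     "fountain_expansion"):
            if getattr(p, name) <= 0:
                raise ProfileError(f"{name} must be strictly positive")
        if p.M < 0 or p.G < 0:
            raise ProfileError("M and G must be non-negative")
        if p.symbol_bits != 8:
            raise ProfileError("only 8-bit information symbols are supported")
        if p.R % 4 != 0:
            raise ProfileError("R must be a multiple of 4 for 8-bit symbols")
        if p.E != p.packets_kept * p.S * p.bytes_per_unit:
            raise ProfileError(
                "E must equal packets_kept * S * (R/4) "
                f"(got E={p.E}, expected {p.packets_kept * p.S * p.bytes_per_unit})")
        if (p.E + p.M) % p.bytes_per_set != 0:
            raise ProfileError("E + M must be divisible by the set payload size")
        if p.E + p.M > GF8_MAX_CODEWORD:
            raise ProfileError(
                f"E + M = {p.E + p.M} exceeds the GF(2^8) codeword limit 255")
        if p.N + p.G > GF8_MAX_CODEWORD:
            raise ProfileError(
                f"N + G = {p.N + p.G} exceeds the GF(2^8) codeword limit 255")
        if p.fountain_expansion < p.packets_kept:
            raise ProfileError("fountain_expansion must be >= packets_kept")
        if p.leading_base not in "ACGT":
            raise ProfileError("leading_base must be one of A, C, G, T")
        if p.payload_bytes is not None:
            if p.payload_bytes < 1:
                raise ProfileError("payload must contain at least one byte")
            if p.payload_capacity < p.payload_bytes:
                raise ProfileError("N*E capacity smaller than padded payload")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CodecProfile":
        return cls(**d)


@dataclass
class LayoutReport:
    groups_total: int
    sets_per_group: int
    set_len: int
    group_len: int
    total_len: int
    payload_fraction: float
    leading_fraction: float
    index_fraction: float
    rs_fraction: float


@dataclass
class DensityResult:
    d: float
    d_N: float
    d_E: float
    d_S: float
    d_R: float


def make_profile(payload_bytes: int, **overrides) -> CodecProfile:
    """Build a profile sized for ``payload_bytes`` of (compressed) payload.

    Defaults reproduce the WC53 configuration; any field can be overridden.
    Payloads needing more than 235 information groups are split into several
    primary blocks so every RS codeword stays within GF(2^8).
    """
    if not isinstance(payload_bytes, int) or payload_bytes < 1:
        raise ProfileError("payload_bytes must be a positive integer")
    params = dict(S=10, R=4, packets_kept=16, set_index_len=5,
                  group_index_len=10, symbol_bits=8, leading_base="A")
    params.update(overrides)
    u = params["R"] // 4 if params["R"] % 4 == 0 else 0
    if u == 0:
        raise ProfileError("R must be a multiple of 4 for 8-bit symbols")
    params.setdefault("E", params["packets_kept"] * params["S"] * u)
    params.setdefault("M", params["E"] // 2)
    params.setdefault("fountain_expansion", 399 * params["packets_kept"])
    E = params["E"]
    needed_groups = math.ceil(payload_bytes / E)
    if "N" in params:
        N = params["N"]
        params.setdefault("n_blocks", math.ceil(needed_groups / N))
    else:
        if needed_groups <= _MAX_N:
            N = needed_groups
            params["n_blocks"] = 1
        else:
            N = _MAX_N
            params["n_blocks"] = math.ceil(needed_groups / N)
        params["N"] = N
    params.setdefault("G", max(1, round(N * _DEFAULT_G_RATIO)))
    prof = CodecProfile(payload_bytes=payload_bytes, padding=0, **params)
    prof.padding = prof.payload_capacity - payload_bytes
    return prof


def wc53_profile(payload_bytes: int = 5564) -> CodecProfile:
    """The default configuration used throughout the structural checks."""
    return make_profile(payload_bytes)


def layout_lengths(profile: CodecProfile) -> LayoutReport:
    p = profile
    set_len = p.set_index_len + p.S * (p.R + 1)
    group_len = p.sets_per_group * set_len
    total_len = p.groups_total * (group_len + p.group_index_len)
    payload_b = p.n_blocks * p.N * p.E * 4
    leading_b = p.groups_total * p.units_per_group
    index_b = p.groups_total * (p.group_index_len
                                + p.sets_per_group * p.set_index_len)
    rs_b = (p.n_blocks * p.G * p.E + p.groups_total * p.M) * 4
    assert payload_b + leading_b + index_b + rs_b == total_len
    return LayoutReport(
        groups_total=p.groups_total,
        sets_per_group=p.sets_per_group,
        set_len=set_len,
        group_len=group_len,
        total_len=total_len,
        payload_fraction=payload_b / total_len,
        leading_fraction=leading_b / total_len,
        index_fraction=index_b / total_len,
        rs_fraction=rs_b / total_len,
    )


def coding_density(profile: CodecProfile) -> DensityResult:
    """Payload bits per base: d = 2 * L/(L+I_g) * d_N * d_E * d_S * d_R.

    The set-index term counts I_s in symbol slots of (R+1) bases, which makes
    the closed form agree exactly with padded-payload-bits / total-length.
    """
    p = profile
    rep = layout_lengths(p)
    d_N = p.N / (p.N + p.G)
    d_E = p.E / (p.E + p.M)
    d_R = p.R / (p.R + 1)
    d_S = p.S / (p.S + p.set_index_len / (p.R + 1))
    group_factor = rep.group_len / (rep.group_len + p.group_index_len)
    d = 2.0 * group_factor * d_N * d_E * d_S * d_R
    return DensityResult(d=d, d_N=d_N, d_E=d_E, d_S=d_S, d_R=d_R)
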