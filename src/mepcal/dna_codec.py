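"""Symbol-to-DNA transcoding, interval-index codebooks, assembly, sidecar.

Every base-256 symbol becomes four bases (A,C,G,T = 0,1,2,3, big-endian) and
every DNA symbol of R bases is preceded by one leading (anchor) base. Sets
are prefixed by 5-bp indices, groups by 10-bp indices; index codebooks are
generated from the run seed under the screening motif rules with pairwise
edit distance >= 2, and stored in the sidecar together with the per-group
selected fountain ESIs — everything the decoder needs.

``encode`` runs the whole encoder chain: optional source coding, padding,
primary RS, per-group fountain expansion + screening + tertiary RS, and
final emission.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import BASES, codes_to_seq, seq_to_codes
from .codec_profile import (CodecProfile, ProfileError, layout_lengths,
                            make_profile)
from .ecc_layers import (fountain_coefficients, fountain_symbols,
                         primary_encode, selection_invertible, tertiary_encode)
from .screening import (GOLDEN_GATE_MOTIFS, KmerCurrentModel, KmerErrorTable,
                        ScreenConfig, calibrate_thresholds, find_bio_hits,
                        screen_codes_batch)
from . import source_coding

logger = logging.getLogger(__name__)

SIDECAR_VERSION = 1


class AnchorError(ValueError):
    """A body does not carry the expected anchor pattern (decoder territory)."""


class CodebookError(RuntimeError):
    pass


@dataclass
class IndexCodebook:
    set_indices: list[str]
    group_indices: list[str]
    min_pairwise_edit_distance: int = 2


@dataclass
class InformationDNA:
    sequence: str
    profile: CodecProfile


@dataclass
class Sidecar:
    profile: CodecProfile
    codebook: IndexCodebook
    selected_esis: list[list[int]]   # per group, packets_kept ESIs in order
    stored_len: int                  # bytes fed to the symbol layer
    compressed: bool
    seed: int
    version: int = SIDECAR_VERSION

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "profile": self.profile.to_dict(),
            "set_indices": self.codebook.set_indices,
            "group_indices": self.codebook.group_indices,
            "min_pairwise_edit_distance":
                self.codebook.min_pairwise_edit_distance,
            "selected_esis": self.selected_esis,
            "stored_len": self.stored_len,
            "compressed": self.compressed,
            "seed": self.seed,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Sidecar":
        d = json.loads(text)
        if d.get("version") != SIDECAR_VERSION:
            raise ValueError(f"unsupported sidecar version {d.get('version')}")
        return cls(
            profile=CodecProfile.from_dict(d["profile"]),
            codebook=IndexCodebook(d["set_indices"], d["group_indices"],
                                   d["min_pairwise_edit_distance"]),
            selected_esis=[list(map(int, row)) for row in d["selected_esis"]],
            stored_len=int(d["stored_len"]),
            compressed=bool(d["compressed"]),
            seed=int(d["seed"]),
        )

    def profile_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.profile.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# -- symbol <-> DNA ---------------------------------------------------------

def render_bodies(symbols: np.ndarray, profile: CodecProfile) -> np.ndarray:
    """(m, bytes_per_set) symbol rows -> (m, S*(R+1)) base-code rows."""
    p = profile
    symbols = np.atleast_2d(np.asarray(symbols, dtype=np.int64))
    if ((symbols < 0) | (symbols > 255)).any():
        raise ValueError("symbol values must lie in [0, 255]")
    m = symbols.shape[0]
    u = p.bytes_per_unit
    # bytes -> base-4 digits, big-endian
    shifts = np.array([6, 4, 2, 0])
    digits = (symbols[:, :, None] >> shifts) & 3          # (m, bytes, 4)
    digits = digits.reshape(m, p.S, u * 4)                # per DNA symbol
    body = np.empty((m, p.S, p.R + 1), dtype=np.int64)
    body[:, :, 0] = BASES.index(p.leading_base)
    body[:, :, 1:] = digits
    return body.reshape(m, p.S * (p.R + 1))


def symbols_to_dna(symbols, profile: CodecProfile) -> str:
    """One set of bytes_per_set symbols -> its anchored 50-bp (WC53) body."""
    symbols = np.asarray(symbols, dtype=np.int64)
    if symbols.shape != (profile.bytes_per_set,):
        raise ValueError(
            f"expected {profile.bytes_per_set} symbols, got {symbols.shape}")
    return codes_to_seq(render_bodies(symbols, profile)[0])


def dna_to_symbols(body: str, profile: CodecProfile) -> np.ndarray:
    """Exact inverse of symbols_to_dna for an error-free body."""
    p = profile
    expected = p.S * (p.R + 1)
    if len(body) != expected:
        raise AnchorError(f"body length {len(body)} != expected {expected}")
    codes = seq_to_codes(body).reshape(p.S, p.R + 1)
    anchor = BASES.index(p.leading_base)
    if (codes[:, 0] != anchor).any():
        raise AnchorError("leading-base anchor mismatch")
    digits = codes[:, 1:].reshape(p.S, p.bytes_per_unit, 4)
    weights = np.array([64, 16, 4, 1])
    return (digits * weights).sum(axis=2).reshape(-1)


# -- index codebooks --------------------------------------------------------

def _index_ok(seq: str, config: ScreenConfig) -> bool:
    return len(find_bio_hits(seq, config)) == 0


def generate_codebook(profile: CodecProfile, seed: int,
                      config: ScreenConfig, min_dist: int = 2,
                      max_tries: int = 20000) -> IndexCodebook:
    """Seeded index strings obeying motif rules and pairwise edit distance."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        0xC0]))

    def build(count: int, length: int) -> list[str]:
        out: list[str] = []
        for _ in range(max_tries):
            cand = codes_to_seq(rng.integers(0, 4, size=length))
            if not _index_ok(cand, config):
                continue
            if all(edlib.align(cand, other, mode="NW")["editDistance"]
                   >= min_dist for other in out):
                out.append(cand)
                if len(out) == count:
                    return out
        raise CodebookError(
            f"could not draw {count} indices of length {length} with "
            f"pairwise edit distance >= {min_dist}")

    return IndexCodebook(
        set_indices=build(profile.sets_per_group, profile.set_index_len),
        group_indices=build(profile.groups_total, profile.group_index_len),
        min_pairwise_edit_distance=min_dist,
    )


# -- packet selection (fountain + screening) --------------------------------

def default_screen_config(error_table: KmerErrorTable,
                          current_model: KmerCurrentModel,
                          profile: CodecProfile, seed: int,
                          n_random: int = 10000) -> ScreenConfig:
    body_len = profile.S * (profile.R + 1)
    err_thr, snr_thr = calibrate_thresholds(error_table, current_model,
                                            n_random=n_random, seed=seed,
                                            body_len=body_len)
    banned = np.zeros(1024, dtype=bool)
    banned[error_table.worst_kmers(64)] = True
    return ScreenConfig(error_rate_threshold=err_thr, snr_threshold=snr_thr,
                        banned_kmers=banned, motif_list=GOLDEN_GATE_MOTIFS)


def select_packets(group_payload: np.ndarray, profile: CodecProfile,
                   seed: int, group_id: int, config: ScreenConfig,
                   error_table: KmerErrorTable,
                   current_model: KmerCurrentModel) -> tuple[list[int], np.ndarray]:
    """Choose packets_kept candidate packets for one group.

    Candidates are tested in ascending ESI order; the first passing ones are
    retained. If fewer than packets_kept candidates pass all five filters,
    filters are relaxed in reverse priority order (bio first) with a logged
    warning. The selected set is verified to be fountain-invertible.
    """
    p = profile
    kept = p.packets_kept
    coeffs = fountain_coefficients(p, seed, group_id)
    syms = fountain_symbols(group_payload, coeffs, p)       # (expansion, bytes)
    bodies = render_bodies(syms, p)
    masks = screen_codes_batch(bodies, config, error_table, current_model)
    pass14 = (masks["error_rate"] & masks["snr"]
              & masks["banned_kmer"] & masks["gc"])

    def pick(candidate_mask: np.ndarray, check_bio: bool) -> list[int]:
        chosen: list[int] = []
        for esi in np.nonzero(candidate_mask)[0]:
            if check_bio and find_bio_hits(codes_to_seq(bodies[esi]), config):
                continue
            chosen.append(int(esi))
            if len(chosen) == kept:
                break
        return chosen

    selected = pick(pass14, check_bio=True)
    if len(selected) < kept:
        relax_order = [
            ("bio", pass14),
            ("gc", masks["error_rate"] & masks["snr"] & masks["banned_kmer"]),
            ("banned_kmer", masks["error_rate"] & masks["snr"]),
            ("snr", masks["error_rate"]),
            ("error_rate", np.ones(len(bodies), dtype=bool)),
        ]
        for dropped, mask in relax_order:
            selected = pick(mask, check_bio=False)
            if len(selected) >= kept:
                logger.debug(
                    "group %d: relaxed screening (dropped %s and below) to "
                    "retain %d packets", group_id, dropped, kept)
                select_packets.last_relaxed = dropped
                break
        else:
            raise CodebookError(
                f"group {group_id}: cannot retain {kept} packets")
    # guarantee the selected set inverts the fountain layer
    while not selection_invertible(selected, p, seed, group_id):
        pool = [e for e in np.nonzero(pass14)[0] if e not in selected]
        if not pool:
            pool = [e for e in range(len(bodies)) if e not in selected]
        selected[-1] = int(pool[0])
    retained = syms[selected].reshape(-1)                   # E bytes
    return selected, retained


# -- emission ---------------------------------------------------------------

def emit(group_codewords: np.ndarray, profile: CodecProfile,
         codebook: IndexCodebook) -> str:
    """Assemble the information DNA from per-group (E+M)-byte codewords."""
    p = profile
    cw = np.asarray(group_codewords, dtype=np.int64)
    if cw.shape != (p.groups_total, p.E + p.M):
        raise ValueError("group codewords must be (groups_total, E+M)")
    bps = p.bytes_per_set
    parts: list[str] = []
    for gid in range(p.groups_total):
        parts.append(codebook.group_indices[gid])
        sets = cw[gid].reshape(p.sets_per_group, bps)
        bodies = render_bodies(sets, p)
        for s in range(p.sets_per_group):
            parts.append(codebook.set_indices[s])
            parts.append(codes_to_seq(bodies[s]))
    seq = "".join(parts)
    assert len(seq) == layout_lengths(p).total_len
    return seq


# -- the full encoder chain -------------------------------------------------

@dataclass
class EncodeResult:
    dna: InformationDNA
    sidecar: Sidecar
    huffman: source_coding.HuffmanModel | None


def encode(payload: bytes, profile: CodecProfile | None = None,
           seed: int = 0, compress: bool = True,
           tables: tuple[KmerCurrentModel, KmerErrorTable] | None = None,
           screen_config: ScreenConfig | None = None,
           calibration_n: int = 10000) -> EncodeResult:
    """Encode a binary payload into information DNA plus its sidecar."""
    if len(payload) == 0:
        raise ValueError("payload must be non-empty")
    huff = None
    if compress:
        stored, huff = source_coding.compress(payload)
    else:
        stored = bytes(payload)
    if profile is None:
        profile = make_profile(len(stored))
    elif profile.payload_capacity < len(stored):
        raise ProfileError(
            f"profile capacity {profile.payload_capacity} < payload "
            f"{len(stored)} bytes")
    p = profile
    symbols = np.zeros(p.payload_capacity, dtype=np.int64)
    symbols[: len(stored)] = np.frombuffer(stored, dtype=np.uint8)

    groups_payload = primary_encode(symbols, p)             # (groups, E)

    if tables is None:
        from .error_model import make_fixtures
        tables = make_fixtures(seed)
    current_model, error_table = tables
    if screen_config is None:
        screen_config = default_screen_config(error_table, current_model, p,
                                              seed, n_random=calibration_n)

    selected_all: list[list[int]] = []
    codewords = np.empty((p.groups_total, p.E + p.M), dtype=np.int64)
    n_relaxed = 0
    for gid in range(p.groups_total):
        select_packets.last_relaxed = None
        selected, retained = select_packets(
            groups_payload[gid], p, seed, gid, screen_config,
            error_table, current_model)
        n_relaxed += select_packets.last_relaxed is not None
        selected_all.append(selected)
        codewords[gid] = tertiary_encode(retained, p)
    if n_relaxed:
        logger.warning("screening relaxed for %d of %d groups (not enough "
                       "candidates passed all five filters)", n_relaxed,
                       p.groups_total)

    codebook = generate_codebook(p, seed, screen_config)
    seq = emit(codewords, p, codebook)
    sidecar = Sidecar(profile=p, codebook=codebook,
                      selected_esis=selected_all, stored_len=len(stored),
                      compressed=compress, seed=seed)
    return EncodeResult(InformationDNA(seq, p), sidecar, huff)
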