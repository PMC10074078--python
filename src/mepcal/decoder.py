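"""Decoder: segmentation, anchor-based indel calling, erasure-aware RS chain.

The corrupted information DNA is first segmented by locating every interval
index near its expected position (minimum edit distance, ties toward the
expected offset). Each set body is then aligned against the ideal anchored
template — one leading base followed by R wildcard bases per DNA symbol — by
global edit-distance alignment; symbols whose template span aligns without
insertions or deletions are called, spacing expansions/contractions erase
the affected symbols only. Called symbols feed the tertiary RS decoder per
group (2e + f <= M), recovered groups feed the fountain inversion, and the
primary interleaved RS layer repairs missing groups (>= N per block).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import BASES, seq_to_codes
from .codec_profile import CodecProfile, layout_lengths
from .dna_codec import Sidecar
from .ecc_layers import (GroupUndecodableError, Packet, UnrecoverablePayloadError,
                         fountain_invert, primary_decode, tertiary_decode)
from . import source_coding

_EQUALITIES = [("N", b) for b in "ACGT"]


class DecodeError(Exception):
    """Unrecoverable payload; carries the binding constraint."""


@dataclass
class Boundary:
    kind: str            # "group" | "set"
    group: int
    set_pos: int         # -1 for group boundaries
    start: int
    end: int             # exclusive
    edit_distance: int
    low_confidence: bool


@dataclass
class SegmentMap:
    boundaries: list[Boundary]
    group_spans: list[tuple[int, int]]
    set_spans: list[list[tuple[int, int]]]      # per group, per set
    set_low_confidence: list[list[bool]]


@dataclass
class SymbolCall:
    serial: int                   # 1..S within the set
    absolute_serial: int          # 1..units_per_group within the group
    value: tuple | None           # bytes of the DNA symbol, None if erased
    edits: int = 0                # anchor/flank edits supporting the call


@dataclass
class DecodeReport:
    group_decodable: list[int]
    group_erasures: list[int]
    group_errors: list[int]
    tertiary_used: bool = False
    fountain_used: bool = False
    primary_used: bool = False
    success: bool = False
    payload_len: int = 0
    failure: str | None = None


# -- segmentation -----------------------------------------------------------

def _locate(seq: str, index: str, expected: int, window: int
            ) -> tuple[int, int, int]:
    """Best (start, end, distance) for `index` near `expected` in `seq`."""
    lo = max(0, expected - window)
    hi = min(len(seq), expected + window + len(index))
    target = seq[lo:hi]
    if not target:
        return expected, expected + len(index), len(index)
    aln = edlib.align(index, target, mode="HW", task="locations")
    dist = aln["editDistance"]
    best = None
    for s, e in aln["locations"]:
        s = 0 if s is None else s
        cand = (abs(lo + s - expected), lo + s, lo + e + 1)
        if best is None or cand < best:
            best = cand
    return best[1], best[2], dist


def segment(seq: str, sidecar: Sidecar) -> SegmentMap:
    """Locate every group/set index near its expected position.

    Segmentation is hierarchical so damage cannot cascade: the 10-bp group
    indices are strong landmarks that re-anchor the global indel drift, and
    set indices are searched relative to their own group with a local drift
    that resets at every group boundary. Drift is only updated from
    confidently matched indices (small edit distance); an index matched
    worse than half its length is flagged low-confidence and placed at its
    expected position.
    """
    p = sidecar.profile
    rep = layout_lengths(p)
    if abs(len(seq) - rep.total_len) > 0.05 * rep.total_len:
        raise DecodeError(
            f"sequence length {len(seq)} deviates more than 5% from the "
            f"expected {rep.total_len}")
    cb = sidecar.codebook
    set_len = rep.set_len
    boundaries: list[Boundary] = []
    drift = 0
    last_anchor_design = 0
    group_accept = max(2, p.group_index_len // 3)      # drift-update gate
    set_accept = max(1, p.set_index_len // 4)
    for gid in range(p.groups_total):
        design = gid * (p.group_index_len + rep.group_len)
        gap = max(1, design - last_anchor_design)
        w = max(10, math.ceil(3 * math.sqrt(gap * 0.02)))
        start, end, dist = _locate(seq, cb.group_indices[gid],
                                   design + drift, w)
        low = dist > p.group_index_len // 2
        if dist <= group_accept:
            drift = start - design
            last_anchor_design = design
        elif low:
            start, end = design + drift, design + drift + p.group_index_len
        g_bound = Boundary("group", gid, -1, start, end, dist, low)
        boundaries.append(g_bound)
        # set indices: local search anchored at this group's index end
        gstart = g_bound.end
        ldrift = 0
        last_rel = 0
        for s in range(p.sets_per_group):
            rel = s * set_len
            gap = max(1, rel - last_rel)
            w = max(8, math.ceil(3 * math.sqrt(gap * 0.02)))
            exp = gstart + rel + ldrift
            start, end, dist = _locate(seq, cb.set_indices[s], exp, w)
            low = dist > p.set_index_len // 2
            if dist <= set_accept:
                ldrift = start - (gstart + rel)
                last_rel = rel
            elif low:
                start, end = exp, exp + p.set_index_len
            boundaries.append(Boundary("set", gid, s, start, end, dist, low))

    group_spans = []
    set_spans: list[list[tuple[int, int]]] = []
    set_low: list[list[bool]] = []
    n_b = len(boundaries)
    for i, b in enumerate(boundaries):
        nxt = boundaries[i + 1].start if i + 1 < n_b else len(seq)
        if b.kind == "group":
            group_spans.append((b.start, nxt))  # provisional; fixed below
            set_spans.append([])
            set_low.append([])
        else:
            set_spans[-1].append((b.end, max(b.end, nxt)))
            set_low[-1].append(b.low_confidence)
    # group span ends at the next group boundary (or sequence end)
    fixed = []
    for gid in range(p.groups_total):
        start = group_spans[gid][0]
        end = group_spans[gid + 1][0] if gid + 1 < p.groups_total else len(seq)
        fixed.append((start, end))
    return SegmentMap(boundaries, fixed, set_spans, set_low)


# -- symbol calling ---------------------------------------------------------

def call_symbols(set_body: str, profile: CodecProfile,
                 set_pos: int = 0, conservative: bool = False
                 ) -> list[SymbolCall]:
    """Anchor-parsimony symbol calls for one segmented set body.

    The body is globally aligned to the ideal template (anchor + R wildcard
    bases per symbol); a symbol is called only when its whole template span
    aligns indel-free, so one miscalled indel can never corrupt calls outside
    this set.

    In ``conservative`` mode a symbol is additionally required to be pinned
    between two verified leading bases (its own anchor and the next symbol's
    anchor both matching exactly), trading extra erasures for fewer wrong
    calls; the decoder uses it as a second pass on groups that fail the
    tertiary layer.
    """
    p = profile
    S, R = p.S, p.R
    span = R + 1
    expected_len = S * span
    base_serial = set_pos * S
    if abs(len(set_body) - expected_len) > S:
        return [SymbolCall(k + 1, base_serial + k + 1, None)
                for k in range(S)]
    template = (p.leading_base + "N" * R) * S
    aln = edlib.align(template, set_body, mode="NW", task="path",
                      additionalEqualities=_EQUALITIES)
    codes = seq_to_codes(set_body)
    tgt_idx = np.full(expected_len, -1, dtype=np.int64)
    erased = np.zeros(S, dtype=bool)
    edits = np.zeros(S, dtype=np.int64)
    tpos = bpos = 0
    num = 0
    for ch in aln["cigar"]:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
            continue
        n, op = num, ch
        num = 0
        if op in "=X":
            for _ in range(n):
                tgt_idx[tpos] = bpos
                if op == "X":
                    edits[tpos // span] += 1
                tpos += 1
                bpos += 1
        elif op == "I":   # template base with no body base: deletion in DNA
            for _ in range(n):
                erased[tpos // span] = True
                edits[tpos // span] += 1
                tpos += 1
        elif op == "D":   # body base with no template slot: inserted base
            unit = min(tpos // span, S - 1)
            erased[unit] = True
            edits[unit] += 1
            if tpos % span == 0 and 0 < tpos < expected_len:
                # insertion sits between two symbols: both are suspect
                erased[tpos // span - 1] = True
            bpos += n
    if conservative:
        # a unit is kept only when pinned between two exactly-matching
        # anchors ("normal spacing"); edits[] counts anchor mismatches
        anchor_bad = np.zeros(S + 1, dtype=bool)
        for k in range(S):
            anchor_bad[k] = edits[k] > 0 or tgt_idx[k * span] < 0
        anchor_bad[S] = False  # body end stands in for the trailing anchor
        for k in range(S):
            if anchor_bad[k] or anchor_bad[k + 1]:
                erased[k] = True
    calls = []
    weights = np.array([64, 16, 4, 1])
    for k in range(S):
        if erased[k]:
            calls.append(SymbolCall(k + 1, base_serial + k + 1, None,
                                    int(edits[k])))
            continue
        sl = tgt_idx[k * span:(k + 1) * span]
        if (sl < 0).any():
            calls.append(SymbolCall(k + 1, base_serial + k + 1, None,
                                    int(edits[k])))
            continue
        payload = codes[sl[1:]]
        digits = payload.reshape(p.bytes_per_unit, 4)
        value = tuple(int(v) for v in (digits * weights).sum(axis=1))
        calls.append(SymbolCall(k + 1, base_serial + k + 1, value,
                                int(edits[k])))
    return calls


def resolve_conflicts(calls: list[SymbolCall]) -> list[SymbolCall]:
    """Resolve duplicate serials within one set by anchor-context likelihood.

    Among candidates sharing a serial, the one whose own and flanking leading
    bases needed the fewest edits is kept; symmetric ties erase them all.
    """
    by_serial: dict[int, list[SymbolCall]] = {}
    for c in calls:
        by_serial.setdefault(c.serial, []).append(c)
    out = []
    for serial in sorted(by_serial):
        group = by_serial[serial]
        if len(group) == 1:
            out.append(group[0])
            continue
        best = min(c.edits for c in group)
        winners = [c for c in group if c.edits == best]
        if len(winners) == 1:
            out.append(winners[0])
        else:
            tmpl = group[0]
            out.append(SymbolCall(tmpl.serial, tmpl.absolute_serial, None,
                                  best))
    return out


# -- full decode ------------------------------------------------------------

def decode(seq: str, sidecar: Sidecar) -> tuple[bytes, DecodeReport]:
    """Restore the payload from a (possibly corrupted) information DNA."""
    p = sidecar.profile
    seg = segment(seq, sidecar)
    u = p.bytes_per_unit
    n_cw = p.E + p.M
    report = DecodeReport(group_decodable=[0] * p.groups_total,
                          group_erasures=[0] * p.groups_total,
                          group_errors=[0] * p.groups_total)
    group_payloads = np.zeros((p.groups_total, p.E), dtype=np.int64)
    erased_groups = []
    def collect(gid: int, conservative: bool):
        received = np.zeros(n_cw, dtype=np.int64)
        erasures = []
        for s in range(p.sets_per_group):
            if seg.set_low_confidence[gid][s]:
                # boundary not trustworthy: the whole set is an erasure
                lo = s * p.bytes_per_set
                erasures.extend(range(lo, lo + p.bytes_per_set))
                continue
            lo, hi = seg.set_spans[gid][s]
            body = seq[lo:hi]
            calls = resolve_conflicts(
                call_symbols(body, p, set_pos=s, conservative=conservative))
            for c in calls:
                slot0 = (c.absolute_serial - 1) * u
                if c.value is None:
                    erasures.extend(range(slot0, slot0 + u))
                else:
                    received[slot0: slot0 + u] = c.value
        return received, erasures

    for gid in range(p.groups_total):
        received, erasures = collect(gid, conservative=False)
        try:
            try:
                info, stats = tertiary_decode(received, erasures, p)
            except GroupUndecodableError:
                # second pass: stricter anchor pinning turns the ambiguous
                # calls that defeated the first pass into erasures
                received, erasures = collect(gid, conservative=True)
                info, stats = tertiary_decode(received, erasures, p)
            report.group_decodable[gid] = 1
            report.group_erasures[gid] = stats["erasures"]
            report.group_errors[gid] = stats["errors"]
            if stats["errors"] or stats["erasures"]:
                report.tertiary_used = True
        except GroupUndecodableError:
            erased_groups.append(gid)
            report.group_erasures[gid] = len(erasures)
            continue
        esis = sidecar.selected_esis[gid]
        packets = [Packet(gid, esi,
                          info[i * p.bytes_per_set:(i + 1) * p.bytes_per_set])
                   for i, esi in enumerate(esis)]
        if any(esi >= p.packets_kept for esi in esis):
            report.fountain_used = True
        group_payloads[gid] = fountain_invert(packets, p, seed=sidecar.seed)
    try:
        symbols = primary_decode(group_payloads, erased_groups, p)
    except UnrecoverablePayloadError as exc:
        report.failure = str(exc)
        return b"", report
    if erased_groups:
        report.primary_used = True
    stored = symbols[: sidecar.stored_len].astype(np.uint8).tobytes()
    if sidecar.compressed:
        try:
            payload = source_coding.decompress(stored)
        except source_coding.CorruptInputError as exc:
            report.failure = f"source decoding failed: {exc}"
            return b"", report
    else:
        payload = stored
    report.success = True
    report.payload_len = len(payload)
    return payload, report
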