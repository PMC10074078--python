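"""Segmentation, anchor-based symbol calling and the erasure-aware chain."""

import numpy as np
import pytest

from mepcal.codec_profile import layout_lengths, wc53_profile
from mepcal.decoder import (DecodeError, SymbolCall, call_symbols, decode,
                            resolve_conflicts, segment)
from mepcal.dna_codec import symbols_to_dna
from mepcal.error_model import ErrorSpec, inject_errors


# symbols whose rendered digits contain no 'A' (digit 0), so single-indel
# alignments have a unique parsimony optimum
_NO_A_SYMBOLS = [85, 106, 170, 255, 90, 165, 107, 214, 171, 86]


class TestSegmentation:
    def test_error_free_boundaries_exact(self, wc53_encoded):
        seq = wc53_encoded.dna.sequence
        seg = segment(seq, wc53_encoded.sidecar)
        rep = layout_lengths(wc53_encoded.dna.profile)
        for b in seg.boundaries:
            assert b.edit_distance == 0
            assert not b.low_confidence
        for gid, (start, end) in enumerate(seg.group_spans):
            assert start == gid * (rep.group_len + 10)

    def test_single_deletion_shifts_downstream_boundaries(self, wc53_encoded):
        seq = wc53_encoded.dna.sequence
        rep = layout_lengths(wc53_encoded.dna.profile)
        cut = rep.group_len + 10 + 600              # inside group 1
        mutated = seq[:cut] + seq[cut + 1:]
        seg = segment(mutated, wc53_encoded.sidecar)
        assert seg.group_spans[0][0] == 0
        for gid in range(2, 38):
            expect = gid * (rep.group_len + 10) - 1
            assert seg.group_spans[gid][0] == expect

    def test_length_guard(self, wc53_encoded):
        with pytest.raises(DecodeError):
            segment("ACGT" * 100, wc53_encoded.sidecar)

    def test_boundaries_recovered_at_one_percent(self, wc53_encoded):
        seq = wc53_encoded.dna.sequence
        rep = layout_lengths(wc53_encoded.dna.profile)
        recovered = 0
        n_seeds = 6
        for sd in range(n_seeds):
            mutated, _ = inject_errors(seq, ErrorSpec(rate=0.01, seed=sd))
            seg = segment(mutated, wc53_encoded.sidecar)
            good = sum(1 for b in seg.boundaries
                       if b.kind == "group" and not b.low_confidence)
            recovered += good == 38
        assert recovered >= 0.95 * n_seeds


class TestSymbolCalling:
    def test_intact_body_all_called(self):
        p = wc53_profile()
        body = symbols_to_dna(_NO_A_SYMBOLS, p)
        calls = call_symbols(body, p, set_pos=2)
        assert [c.serial for c in calls] == list(range(1, 11))
        assert [c.absolute_serial for c in calls] == list(range(21, 31))
        assert [c.value[0] for c in calls] == _NO_A_SYMBOLS

    def test_every_single_deletion_confined(self):
        """Exhaustive over the 50 positions: damage (erasure or miscall) is
        confined to the unit holding the deletion and its immediate
        neighbours; everything else is called with the correct value."""
        p = wc53_profile()
        body = symbols_to_dna(_NO_A_SYMBOLS, p)
        for pos in range(50):
            mutated = body[:pos] + body[pos + 1:]
            calls = call_symbols(mutated, p)
            unit = pos // 5
            n_damaged = 0
            for c in calls:
                k = c.serial - 1
                ok = c.value is not None and \
                    c.value[0] == _NO_A_SYMBOLS[k]
                if abs(k - unit) > 1:
                    assert ok, pos
                elif not ok:
                    n_damaged += 1
            assert n_damaged >= 1, pos              # the indel is never silent

    def test_every_single_insertion_confined(self):
        p = wc53_profile()
        body = symbols_to_dna(_NO_A_SYMBOLS, p)
        for pos in range(51):
            for base in "ACGT":
                mutated = body[:pos] + base + body[pos:]
                calls = call_symbols(mutated, p)
                unit = min(pos // 5, 9)
                for c in calls:
                    k = c.serial - 1
                    ok = c.value is not None and \
                        c.value[0] == _NO_A_SYMBOLS[k]
                    if abs(k - unit) > 1:
                        assert ok, (pos, base)

    def test_far_off_length_erases_whole_set(self):
        p = wc53_profile()
        calls = call_symbols("ACGT" * 5, p)         # 20 bp vs expected 50
        assert all(c.value is None for c in calls)

    def test_anchor_substitution_does_not_erase(self):
        p = wc53_profile()
        body = symbols_to_dna(_NO_A_SYMBOLS, p)
        mutated = "G" + body[1:]                    # substituted anchor 0
        calls = call_symbols(mutated, p)
        assert calls[0].value[0] == _NO_A_SYMBOLS[0]
        assert calls[0].edits == 1

    def test_conservative_mode_requires_pinned_anchors(self):
        p = wc53_profile()
        body = symbols_to_dna(_NO_A_SYMBOLS, p)
        mutated = "G" + body[1:]
        calls = call_symbols(mutated, p, conservative=True)
        assert calls[0].value is None               # unpinned -> erased
        assert sum(c.value is not None for c in calls) == 9


class TestConflictResolution:
    def test_no_duplicates_identity(self):
        calls = [SymbolCall(1, 1, (5,), 0), SymbolCall(2, 2, (9,), 1)]
        assert resolve_conflicts(calls) == calls

    def test_duplicate_resolved_by_fewest_edits(self):
        calls = [SymbolCall(3, 3, (5,), 0), SymbolCall(3, 3, (9,), 2)]
        out = resolve_conflicts(calls)
        assert len(out) == 1
        assert out[0].value == (5,)

    def test_symmetric_tie_erases_both(self):
        calls = [SymbolCall(3, 3, (5,), 1), SymbolCall(3, 3, (9,), 1)]
        out = resolve_conflicts(calls)
        assert len(out) == 1
        assert out[0].value is None


class TestFullDecode:
    def test_error_free_reports_no_corrections(self, wc53_payload,
                                               wc53_encoded):
        out, rep = decode(wc53_encoded.dna.sequence, wc53_encoded.sidecar)
        assert out == wc53_payload
        assert rep.success
        assert sum(rep.group_decodable) == 38
        assert sum(rep.group_errors) == 0
        assert sum(rep.group_erasures) == 0
        assert not rep.primary_used

    def test_one_percent_errors_exact_restoration(self, wc53_payload,
                                                  wc53_encoded):
        seq = wc53_encoded.dna.sequence
        for sd in range(4):
            mutated, _ = inject_errors(seq, ErrorSpec(rate=0.01, seed=sd))
            out, rep = decode(mutated, wc53_encoded.sidecar)
            assert out == wc53_payload
            assert rep.success

    def test_three_corrupted_groups_recovered_by_primary(self, wc53_payload,
                                                         wc53_encoded):
        seq = wc53_encoded.dna.sequence
        rep_len = layout_lengths(wc53_encoded.dna.profile)
        rng = np.random.default_rng(17)
        chars = np.array(list("ACGT"))
        s = list(seq)
        for gid in (4, 19, 33):                     # scramble three groups
            lo = gid * (rep_len.group_len + 10) + 10
            for i in range(lo, lo + rep_len.group_len):
                s[i] = str(rng.choice(chars))
        out, rep = decode("".join(s), wc53_encoded.sidecar)
        assert out == wc53_payload
        assert rep.primary_used
        assert sum(rep.group_decodable) >= 35

    def test_decoder_deterministic(self, wc53_encoded):
        seq = wc53_encoded.dna.sequence
        mutated, _ = inject_errors(seq, ErrorSpec(rate=0.015, seed=9))
        a = decode(mutated, wc53_encoded.sidecar)
        b = decode(mutated, wc53_encoded.sidecar)
        assert a[0] == b[0]
        assert a[1] == b[1]
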