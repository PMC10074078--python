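"""The three coding layers: erasure bounds, fountain inversion, determinism."""

import itertools

import numpy as np
import pytest

from mepcal.codec_profile import CodecProfile, wc53_profile
from mepcal.ecc_layers import (GroupUndecodableError, InsufficientPacketsError,
                               Packet, UnrecoverablePayloadError,
                               fountain_coefficients, fountain_expand,
                               fountain_invert, primary_decode, primary_encode,
                               tertiary_decode, tertiary_encode)


@pytest.fixture(scope="module")
def toy3():
    """N=2, G=1, E=2 toy for exhaustive erasure patterns."""
    return CodecProfile(S=1, R=4, E=2, M=0, N=2, G=1, packets_kept=2,
                        fountain_expansion=8)


class TestPrimaryLayer:
    def test_wc53_symbol_counts(self):
        p = wc53_profile()
        rng = np.random.default_rng(0)
        payload = rng.integers(0, 256, 5600)
        groups = primary_encode(payload, p)
        assert groups.shape == (38, 160)
        assert groups.size == 6080                 # 480 repair symbols added
        # systematic: first 35 groups carry the payload verbatim
        assert np.array_equal(groups[:35].reshape(-1), payload)

    def test_no_redundancy_identity(self):
        p = CodecProfile(S=1, R=4, E=2, M=0, N=2, G=0, packets_kept=2,
                         fountain_expansion=8)
        payload = np.arange(4) + 10
        groups = primary_encode(payload, p)
        assert np.array_equal(groups.reshape(-1), payload)

    def test_exhaustive_single_group_erasure(self, toy3):
        rng = np.random.default_rng(1)
        payload = rng.integers(0, 256, 4)
        groups = primary_encode(payload, toy3)
        for erased in range(3):
            damaged = groups.copy()
            damaged[erased] = 0
            out = primary_decode(damaged, [erased], toy3)
            assert np.array_equal(out, payload)

    def test_too_many_erasures_fail(self, toy3):
        rng = np.random.default_rng(2)
        payload = rng.integers(0, 256, 4)
        groups = primary_encode(payload, toy3)
        for pair in itertools.combinations(range(3), 2):
            with pytest.raises(UnrecoverablePayloadError):
                primary_decode(groups, list(pair), toy3)

    def test_wc53_any_35_groups_suffice(self):
        p = wc53_profile()
        rng = np.random.default_rng(3)
        payload = rng.integers(0, 256, 5600)
        groups = primary_encode(payload, p)
        for _ in range(5):
            erased = rng.choice(38, 3, replace=False)
            damaged = groups.copy()
            damaged[erased] = 0
            assert np.array_equal(primary_decode(damaged, erased, p), payload)
        with pytest.raises(UnrecoverablePayloadError):
            primary_decode(groups, [0, 1, 2, 3], p)   # 34 of 38 intact

    def test_unflagged_bad_group_detected_or_corrected(self):
        """A group that lies (wrong bytes, not flagged) is handled by the
        primary error-correction budget instead of corrupting the payload."""
        p = wc53_profile()
        rng = np.random.default_rng(4)
        payload = rng.integers(0, 256, 5600)
        groups = primary_encode(payload, p)
        damaged = groups.copy()
        damaged[11] ^= rng.integers(1, 256, 160)   # one silent bad group
        out = primary_decode(damaged, [], p)       # e=1, 2e <= G=3
        assert np.array_equal(out, payload)


class TestFountainLayer:
    def test_wc53_expansion_counts(self):
        p = wc53_profile()
        rng = np.random.default_rng(5)
        group = rng.integers(0, 256, 160)
        packets = fountain_expand(group, p, seed=0, group_id=0)
        assert len(packets) == 6384
        assert sum(len(pk.symbols) for pk in packets) == 63840

    def test_systematic_prefix_is_identity_partition(self):
        p = wc53_profile()
        rng = np.random.default_rng(6)
        group = rng.integers(0, 256, 160)
        packets = fountain_expand(group, p, seed=0, group_id=2)
        sys_syms = np.concatenate([pk.symbols for pk in packets[:16]])
        assert np.array_equal(sys_syms, group)

    def test_toy_every_packet_pair_inverts(self):
        """E=4, S=2: brute force over all candidate pairs."""
        p = CodecProfile(S=2, R=4, E=4, M=0, N=1, G=1, packets_kept=2,
                         fountain_expansion=24)
        rng = np.random.default_rng(7)
        group = rng.integers(0, 256, 4)
        packets = fountain_expand(group, p, seed=1, group_id=0)
        coeffs = fountain_coefficients(p, 1, 0)
        n_ok = n_pairs = 0
        for a, b in itertools.combinations(range(24), 2):
            n_pairs += 1
            try:
                out = fountain_invert([packets[a], packets[b]], p, seed=1)
                assert np.array_equal(out, group)
                n_ok += 1
            except InsufficientPacketsError:
                pass
        assert n_ok / n_pairs > 0.95               # singular pairs are rare

    def test_random_16_subsets_invert_mostly(self):
        p = wc53_profile()
        rng = np.random.default_rng(8)
        group = rng.integers(0, 256, 160)
        packets = fountain_expand(group, p, seed=2, group_id=0)
        ok = 0
        trials = 120
        for _ in range(trials):
            chosen = rng.choice(len(packets), 16, replace=False)
            try:
                out = fountain_invert([packets[i] for i in chosen], p, seed=2)
                ok += np.array_equal(out, group)
            except InsufficientPacketsError:
                pass
        assert ok / trials >= 0.99

    def test_insufficient_packets_raise(self):
        p = wc53_profile()
        packets = fountain_expand(np.zeros(160, dtype=int), p, 0, 0)
        with pytest.raises(InsufficientPacketsError):
            fountain_invert(packets[:15], p, seed=0)

    def test_deterministic_given_seed_and_group(self):
        p = wc53_profile()
        rng = np.random.default_rng(9)
        group = rng.integers(0, 256, 160)
        a = fountain_expand(group, p, seed=3, group_id=5)
        b = fountain_expand(group, p, seed=3, group_id=5)
        assert all(np.array_equal(x.symbols, y.symbols) for x, y in zip(a, b))
        c = fountain_expand(group, p, seed=3, group_id=6)
        assert not all(np.array_equal(x.symbols, y.symbols)
                       for x, y in zip(a[16:], c[16:]))


class TestTertiaryLayer:
    def test_wc53_codeword_shape(self):
        p = wc53_profile()
        rng = np.random.default_rng(10)
        retained = rng.integers(0, 256, 160)
        cw = tertiary_encode(retained, p)
        assert cw.shape == (240,)
        assert np.array_equal(cw[:160], retained)  # systematic

    def test_identity_when_m_zero(self):
        p = CodecProfile(S=2, R=4, E=4, M=0, N=1, G=1, packets_kept=2,
                         fountain_expansion=8)
        retained = np.array([1, 2, 3, 4])
        assert np.array_equal(tertiary_encode(retained, p), retained)

    def test_decode_at_erasure_bound(self):
        p = wc53_profile()
        rng = np.random.default_rng(11)
        retained = rng.integers(0, 256, 160)
        cw = tertiary_encode(retained, p)
        r = cw.copy()
        erased = rng.choice(240, 80, replace=False)
        r[erased] = 0
        out, stats = tertiary_decode(r, erased, p)
        assert np.array_equal(out, retained)
        assert stats["erasures"] == 80

    def test_error_erasure_frontier_grid(self):
        """Success iff 2e + f <= M, checked on a grid of (e, f)."""
        p = wc53_profile()
        rng = np.random.default_rng(12)
        retained = rng.integers(0, 256, 160)
        cw = tertiary_encode(retained, p)
        for e, f in [(0, 80), (10, 60), (20, 40), (40, 0), (0, 81),
                     (10, 61), (41, 0), (30, 21)]:
            r = cw.copy()
            pos = rng.choice(240, e + f, replace=False)
            for q in pos[:e]:
                r[q] ^= rng.integers(1, 256)
            r[pos[e:]] = 0
            if 2 * e + f <= 80:
                out, _ = tertiary_decode(r, pos[e:], p)
                assert np.array_equal(out, retained)
            else:
                with pytest.raises(GroupUndecodableError):
                    tertiary_decode(r, pos[e:], p)


def test_encode_chain_inverts_on_clean_input(toy3):
    """primary + fountain + tertiary chain is self-inverse without errors."""
    rng = np.random.default_rng(13)
    p = CodecProfile(S=5, R=4, E=10, M=10, N=3, G=1, packets_kept=2,
                     fountain_expansion=40)
    payload = rng.integers(0, 256, p.N * p.E)
    groups = primary_encode(payload, p)
    recovered_groups = np.empty_like(groups)
    for gid in range(p.groups_total):
        packets = fountain_expand(groups[gid], p, seed=4, group_id=gid)
        esis = [0, 5]                              # one systematic, one not
        retained = np.concatenate([packets[e].symbols for e in esis])
        cw = tertiary_encode(retained, p)
        info, _ = tertiary_decode(cw, [], p)
        pks = [Packet(gid, e, info[i * p.bytes_per_set:
                                   (i + 1) * p.bytes_per_set])
               for i, e in enumerate(esis)]
        recovered_groups[gid] = fountain_invert(pks, p, seed=4)
    out = primary_decode(recovered_groups, [], p)
    assert np.array_equal(out, payload)
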