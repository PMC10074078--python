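"""The five packet filters, the SNR kernel and threshold calibration."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from mepcal._seq import random_seq, revcomp
from mepcal.screening import (KmerCurrentModel, KmerErrorTable, ScreenConfig,
                              calibrate_thresholds, find_bio_hits,
                              gc_fraction, load_current_model,
                              load_error_table, low_complexity_score,
                              neg_log_overlap, predicted_error_rate,
                              save_current_model, save_error_table,
                              screen_packet, snr)


@pytest.fixture(scope="module")
def config(tables):
    model, table = tables
    err_thr, snr_thr = calibrate_thresholds(table, model, n_random=4000,
                                            seed=5)
    banned = np.zeros(1024, dtype=bool)
    banned[table.worst_kmers(64)] = True
    return ScreenConfig(error_rate_threshold=err_thr, snr_threshold=snr_thr,
                        banned_kmers=banned)


class TestGaussianOverlap:
    def test_identical_distributions_full_overlap(self):
        assert neg_log_overlap(5.0, 2.0, 5.0, 2.0) == 0.0

    def test_unit_normals_two_apart(self):
        # A = 2*Phi(-1): the documented closed form for equal sigmas
        expect = -math.log(2 * norm.cdf(-1))
        assert neg_log_overlap(0, 1, 2, 1) == pytest.approx(expect, rel=1e-9)
        assert neg_log_overlap(0, 1, 2, 1) == pytest.approx(1.148, abs=1e-3)

    @pytest.mark.parametrize("mu1,s1,mu2,s2", [
        (0, 1, 1, 2), (100, 2, 103, 3.2), (0, 1, 0, 3), (70, 1.5, 85, 3.5)])
    def test_unequal_sigmas_vs_quadrature(self, mu1, s1, mu2, s2):
        a = quad(lambda x: min(norm.pdf(x, mu1, s1), norm.pdf(x, mu2, s2)),
                 min(mu1, mu2) - 12 * max(s1, s2),
                 max(mu1, mu2) + 12 * max(s1, s2), limit=300)[0]
        assert neg_log_overlap(mu1, s1, mu2, s2) == \
            pytest.approx(-math.log(a), rel=1e-6)

    def test_far_apart_grows_without_bound(self):
        small = neg_log_overlap(0, 1, 5, 1)
        large = neg_log_overlap(0, 1, 50, 1)
        assert large > small > 0
        assert neg_log_overlap(0, 1, 5000, 1) >= 700  # capped, not inf/nan


class TestPerSequenceStatistics:
    def test_constant_table_gives_constant_rate(self):
        table = KmerErrorTable(np.full(1024, 0.1))
        assert predicted_error_rate("ACGTACGTAC", table) == pytest.approx(0.1)

    def test_window_count_on_50bp(self, tables):
        _, table = tables
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 50)
        from mepcal._seq import kmer_codes, seq_to_codes
        wins = kmer_codes(seq_to_codes(seq))
        assert wins.size == 46
        assert predicted_error_rate(seq, table) == \
            pytest.approx(table.rates[wins].mean())

    def test_hand_computed_7bp_mean(self):
        rates = np.zeros(1024)
        from mepcal._seq import string_to_kmer
        seq = "ACGTACG"
        for w, r in zip(["ACGTA", "CGTAC", "GTACG"], [0.1, 0.2, 0.6]):
            rates[string_to_kmer(w)] = r
        table = KmerErrorTable(rates)
        assert predicted_error_rate(seq, table) == pytest.approx(0.3)

    def test_snr_zero_for_constant_model(self):
        model = KmerCurrentModel(np.full(1024, 100.0), np.full(1024, 2.0))
        rng = np.random.default_rng(1)
        assert snr(random_seq(rng, 50), model) == pytest.approx(0.0)

    def test_snr_is_mean_pairwise_neglog(self, tables):
        model, _ = tables
        seq = "ACGTACGTA"           # 5 windows, 4 adjacent pairs
        from mepcal._seq import kmer_codes, seq_to_codes
        wins = kmer_codes(seq_to_codes(seq))
        manual = np.mean([neg_log_overlap(model.mean[wins[i]],
                                          model.std[wins[i]],
                                          model.mean[wins[i + 1]],
                                          model.std[wins[i + 1]])
                          for i in range(4)])
        assert snr(seq, model) == pytest.approx(manual, rel=1e-9)


class TestBioFilter:
    def test_golden_gate_motif_hit(self, config):
        seq = "AT" * 10 + "GGTCTC" + "CA" * 12
        hits = find_bio_hits(seq, config)
        assert any(h[0] == "motif" and h[2] == "GGTCTC" for h in hits)

    def test_reverse_complement_motif_hit(self, config):
        seq = "AT" * 10 + "GAGACC" + "CA" * 12      # revcomp of GGTCTC
        hits = find_bio_hits(seq, config)
        assert any(h[0] == "motif" and h[2] == "GAGACC" for h in hits)

    def test_homopolymer_is_low_complexity(self, config):
        hits = find_bio_hits("A" * 50, config)
        assert any(h[0] == "low_complexity" for h in hits)
        assert low_complexity_score("A" * 50) == pytest.approx(0.0)

    def test_orf_detected_on_either_strand(self, config):
        rng = np.random.default_rng(6)
        # 75 nt ORF: ATG + 23 non-stop codons + TAA
        body = "ATG" + "GCT" * 23 + "TAA"
        pad = "CC" * 10
        fwd = pad + body + pad
        assert any(h[0] == "orf" for h in find_bio_hits(fwd, config))
        rev = pad + revcomp(body) + pad
        assert any(h[0] == "orf" for h in find_bio_hits(rev, config))
        assert not any(h[0] == "orf"
                       for h in find_bio_hits(pad + "ATG" + "GCT" * 5 + "TAA"
                                              + pad, config))


class TestScreenPacket:
    def test_banned_kmer_fails_filter3(self, tables, config):
        model, table = tables
        from mepcal._seq import kmer_to_string
        worst = kmer_to_string(int(table.worst_kmers(64)[0]))
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = random_seq(rng, 20) + worst + random_seq(rng, 25)
            v = screen_packet(seq, config, table, model, diagnostic=True)
            assert ("banned_kmer" in [f[0] for f in v.failed_filters])

    def test_gc_bounds(self, tables, config):
        model, table = tables
        seq38 = "G" * 19 + "A" * 31                 # GC 0.38
        v = screen_packet(seq38, config, table, model, diagnostic=True)
        assert "gc" in [f[0] for f in v.failed_filters]
        rng = np.random.default_rng(8)
        seq50 = "".join(rng.permutation(list("GC" * 13 + "AT" * 12)))
        v = screen_packet(seq50, config, table, model, diagnostic=True)
        assert "gc" not in [f[0] for f in v.failed_filters]

    def test_pass_verdict_consistency_and_idempotence(self, tables, config):
        model, table = tables
        rng = np.random.default_rng(9)
        seen_pass = False
        for _ in range(300):
            seq = random_seq(rng, 50)
            v1 = screen_packet(seq, config, table, model)
            v2 = screen_packet(seq, config, table, model)
            assert v1.passed == v2.passed
            assert v1.failed_filters == v2.failed_filters
            assert v1.passed == (len(v1.failed_filters) == 0)
            seen_pass |= v1.passed
        assert seen_pass


class TestCalibration:
    def test_pass_fraction_is_40_percent(self, tables):
        """At calibrated thresholds, 40% +- 1.5% of random 50-mers pass
        filters 1 and 2 respectively (10,000-sequence calibration)."""
        model, table = tables
        err_thr, snr_thr = calibrate_thresholds(table, model,
                                                n_random=10000, seed=21)
        rng = np.random.default_rng(22)
        n = 10000
        rates = np.array([predicted_error_rate(random_seq(rng, 50), table)
                          for _ in range(2000)])
        snrs = np.array([snr(random_seq(rng, 50), model)
                         for _ in range(2000)])
        assert (rates <= err_thr).mean() == pytest.approx(0.40, abs=0.03)
        assert (snrs >= snr_thr).mean() == pytest.approx(0.40, abs=0.03)

    def test_determinism(self, tables):
        model, table = tables
        a = calibrate_thresholds(table, model, n_random=2000, seed=3)
        b = calibrate_thresholds(table, model, n_random=2000, seed=3)
        assert a == b

    def test_degenerate_constant_table(self, tables):
        model, _ = tables
        table = KmerErrorTable(np.full(1024, 0.25))
        err_thr, _ = calibrate_thresholds(table, model, n_random=1000, seed=1)
        # every sequence has the same predicted rate; the tie rule keeps all
        assert err_thr == pytest.approx(0.25)
        assert predicted_error_rate("ACGTACGT", table) <= err_thr


def test_table_tsv_roundtrip(tables, tmp_path):
    model, table = tables
    save_current_model(model, tmp_path / "cm.tsv")
    save_error_table(table, tmp_path / "et.tsv")
    m2 = load_current_model(tmp_path / "cm.tsv")
    t2 = load_error_table(tmp_path / "et.tsv")
    assert np.allclose(m2.mean, model.mean, atol=1e-4)
    assert np.allclose(m2.std, model.std, atol=1e-4)
    assert np.allclose(t2.rates, table.rates, rtol=1e-5)
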