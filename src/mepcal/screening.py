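"""The five sequential packet filters and their threshold calibration.

Candidate packet bodies are screened, in order, for (1) predicted sequencing
error rate from a 5-mer error-frequency table, (2) ionic-current
signal-to-noise ratio from a 5-mer pore model, (3) presence of the 64 most
error-prone 5-mers, (4) GC fraction within [0.40, 0.60], and (5) potential
biological activity (ORFs, forbidden motifs and their reverse complements,
low-complexity stretches).

Thresholds for filters 1-2 are calibrated so that 60% of uniformly random
sequences of the body length are discarded by each filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import (InvalidSequenceError, kmer_codes, kmer_to_string, revcomp,
                   seq_to_codes)

K = 5
N_KMERS = 4 ** K

GOLDEN_GATE_MOTIFS = ("GGTCTC", "GAAGAC", "CGTCTC")  # BsaI, BbsI, BsmBI

_SQRT2 = math.sqrt(2.0)
_NEGLOG_CAP = 745.0  # -log of the smallest positive double


class TableError(ValueError):
    pass


@dataclass
class KmerCurrentModel:
    """Per-5-mer ionic-current mean and standard deviation (pA-like units)."""
    mean: np.ndarray
    std: np.ndarray
    k: int = K
    _pair_cache: np.ndarray | None = field(default=None, repr=False,
                                           compare=False)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != (N_KMERS,) or self.std.shape != (N_KMERS,):
            raise TableError(f"current model needs {N_KMERS} entries")
        if not (self.std > 0).all():
            raise TableError("current model standard deviations must be > 0")

    def pair_neglog_overlap(self) -> np.ndarray:
        """(1024, 4) table of -ln A for window w followed by base b.

        The successor window of w given next base b is (w mod 4^(k-1))*4 + b,
        so only 4096 adjacent pairs exist; they are computed once and cached.
        """
        if self._pair_cache is None:
            tab = np.empty((N_KMERS, 4), dtype=float)
            for w in range(N_KMERS):
                for b in range(4):
                    w2 = (w % (4 ** (self.k - 1))) * 4 + b
                    tab[w, b] = neg_log_overlap(
                        self.mean[w], self.std[w], self.mean[w2], self.std[w2])
            self._pair_cache = tab
        return self._pair_cache


@dataclass
class KmerErrorTable:
    """Per-5-mer empirical error frequency."""
    rates: np.ndarray
    provenance: str = "fixture"

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (N_KMERS,):
            raise TableError(f"error table needs {N_KMERS} entries")
        if ((self.rates < 0) | (self.rates > 1)).any():
            raise TableError("error rates must lie in [0, 1]")

    def worst_kmers(self, n: int = 64) -> np.ndarray:
        """Codes of the n highest-error 5-mers (ties broken by code)."""
        order = np.lexsort((np.arange(N_KMERS), -self.rates))
        return np.sort(order[:n])


@dataclass
class ScreenConfig:
    error_rate_threshold: float
    snr_threshold: float
    banned_kmers: np.ndarray          # bool mask over 1024 5-mer codes
    gc_bounds: tuple[float, float] = (0.40, 0.60)
    motif_list: tuple[str, ...] = GOLDEN_GATE_MOTIFS
    orf_min_len: int = 75
    low_complexity_threshold: float = 1.2
    low_complexity_window: int = 16


@dataclass
class ScreenVerdict:
    passed: bool
    failed_filters: list

    def __post_init__(self):
        assert self.passed == (len(self.failed_filters) == 0)


# -- Gaussian overlap (filter 2 kernel) -------------------------------------

def _log_tail(z: float) -> float:
    """log P(Z >= z) for standard normal, accurate in the far tail."""
    p = 0.5 * math.erfc(z / _SQRT2)
    if p > 0.0:
        return math.log(p)
    # asymptotic expansion for z beyond erfc underflow (~z > 38)
    return -0.5 * z * z - math.log(z * math.sqrt(2 * math.pi))


def neg_log_overlap(mu1: float, s1: float, mu2: float, s2: float) -> float:
    """-ln of the overlap area of two Gaussian densities.

    The overlap A = integral of min(f1, f2) is assembled from tail masses at
    the crossing points of the two densities, using erfc so that nearly
    disjoint pairs keep full relative accuracy instead of underflowing.
    """
    if mu1 == mu2 and s1 == s2:
        return 0.0
    if abs(s1 - s2) < 1e-12 * max(s1, s2):
        # single crossing at the midpoint: A = 2 * Phi(-|dmu| / (2 sigma))
        z = abs(mu1 - mu2) / (2.0 * s1)
        log_a = math.log(2.0) + _log_tail(z)
        return min(_NEGLOG_CAP, -log_a)
    # two crossings x1 < x2 from equating the log densities
    a = 1.0 / s1 ** 2 - 1.0 / s2 ** 2
    b = -2.0 * (mu1 / s1 ** 2 - mu2 / s2 ** 2)
    c = (mu1 ** 2 / s1 ** 2 - mu2 ** 2 / s2 ** 2
         - 2.0 * math.log(s2 / s1))
    disc = b * b - 4.0 * a * c
    disc = max(disc, 0.0)
    r1 = (-b - math.sqrt(disc)) / (2.0 * a)
    r2 = (-b + math.sqrt(disc)) / (2.0 * a)
    x1, x2 = min(r1, r2), max(r1, r2)

    def logpdf(x, mu, s):
        return -0.5 * ((x - mu) / s) ** 2 - math.log(s)

    def seg_mass(lo, hi, mu, s):
        """P(lo <= X <= hi) for X ~ N(mu, s), with open infinities."""
        if lo is None:
            return 0.5 * math.erfc((mu - hi) / (s * _SQRT2))
        if hi is None:
            return 0.5 * math.erfc((lo - mu) / (s * _SQRT2))
        zlo, zhi = (lo - mu) / s, (hi - mu) / s
        if zlo >= 0:  # right tail: difference of survival functions
            return max(0.0, 0.5 * (math.erfc(zlo / _SQRT2)
                                   - math.erfc(zhi / _SQRT2)))
        if zhi <= 0:
            return max(0.0, 0.5 * (math.erfc(-zhi / _SQRT2)
                                   - math.erfc(-zlo / _SQRT2)))
        return max(0.0, 0.5 * (math.erf(zhi / _SQRT2) - math.erf(zlo / _SQRT2)))

    total = 0.0
    for lo, hi, probe in (((None, x1, x1 - 1.0)),
                          ((x1, x2, 0.5 * (x1 + x2))),
                          ((x2, None, x2 + 1.0))):
        use_first = logpdf(probe, mu1, s1) <= logpdf(probe, mu2, s2)
        mu, s = (mu1, s1) if use_first else (mu2, s2)
        total += seg_mass(lo, hi, mu, s)
    if total <= 0.0:
        return _NEGLOG_CAP
    return min(_NEGLOG_CAP, -math.log(min(total, 1.0)))


# -- per-sequence statistics ------------------------------------------------

def predicted_error_rate(seq: str, error_table: KmerErrorTable) -> float:
    """Mean 5-mer error frequency over all |seq|-4 windows."""
    codes = seq_to_codes(seq)
    if codes.size < K:
        raise InvalidSequenceError("sequence shorter than the 5-mer window")
    return float(error_table.rates[kmer_codes(codes, K)].mean())


def snr(seq: str, current_model: KmerCurrentModel) -> float:
    """Signal-to-noise ratio: mean -ln(overlap) over adjacent window pairs."""
    codes = seq_to_codes(seq)
    if codes.size < K + 1:
        raise InvalidSequenceError("sequence shorter than two 5-mer windows")
    wins = kmer_codes(codes, K)
    tab = current_model.pair_neglog_overlap()
    return float(tab[wins[:-1], codes[K:]].mean())


def gc_fraction(seq: str) -> float:
    codes = seq_to_codes(seq)
    return float(((codes == 1) | (codes == 2)).mean())


# -- filter 5: biological activity ------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _orf_hits(seq: str, min_len: int):
    hits = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            start = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i:i + 3]
                if codon == "ATG" and start is None:
                    start = i
                elif codon in _STOPS and start is not None:
                    if i + 3 - start >= min_len:
                        hits.append(("orf", start if strand == "+"
                                     else len(seq) - (i + 3), f"{strand}{frame}"))
                    start = None
    return hits


def low_complexity_score(seq: str, window: int = 16) -> float:
    """Minimum sliding-window dinucleotide entropy (bits)."""
    codes = seq_to_codes(seq)
    if codes.size < 2:
        return 4.0
    din = codes[:-1] * 4 + codes[1:]
    w = min(window - 1, din.size)  # dinucleotides per window
    best = math.inf
    for i in range(din.size - w + 1):
        counts = np.bincount(din[i:i + w], minlength=16)
        p = counts[counts > 0] / w
        best = min(best, float(-(p * np.log2(p)).sum()))
    return best


def find_bio_hits(seq: str, config: ScreenConfig) -> list:
    """ORFs, forbidden motifs (plus reverse complements), low complexity."""
    hits = []
    if len(seq) >= config.orf_min_len:
        hits.extend(_orf_hits(seq, config.orf_min_len))
    seen = set()
    for motif in config.motif_list:
        for m in (motif, revcomp(motif)):
            if m in seen:
                continue
            seen.add(m)
            start = seq.find(m)
            while start != -1:
                hits.append(("motif", start, m))
                start = seq.find(m, start + 1)
    score = low_complexity_score(seq, config.low_complexity_window)
    if score < config.low_complexity_threshold:
        hits.append(("low_complexity", 0, f"entropy={score:.3f}"))
    return hits


# -- calibration and the combined filter ------------------------------------

def calibrate_thresholds(error_table: KmerErrorTable,
                         current_model: KmerCurrentModel,
                         n_random: int = 10000, seed: int = 0,
                         body_len: int = 50) -> tuple[float, float]:
    """Empirical 60%-discard thresholds over uniformly random sequences.

    Filter 1 passes sequences with predicted error rate <= the returned
    40th percentile; filter 2 passes SNR >= the returned 60th percentile.
    """
    if n_random < 1000:
        raise ValueError("calibration needs at least 1000 random sequences")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n_random, body_len))
    wins = kmer_codes(codes, K)
    rates = error_table.rates[wins].mean(axis=1)
    pair_tab = current_model.pair_neglog_overlap()
    snrs = pair_tab[wins[:, :-1], codes[:, K:]].mean(axis=1)
    err_thr = float(np.quantile(rates, 0.40))
    snr_thr = float(np.quantile(snrs, 0.60))
    return err_thr, snr_thr


FILTER_NAMES = ("error_rate", "snr", "banned_kmer", "gc", "bio")


def screen_packet(packet_dna: str, config: ScreenConfig,
                  error_table: KmerErrorTable,
                  current_model: KmerCurrentModel,
                  expected_len: int | None = None,
                  diagnostic: bool = False) -> ScreenVerdict:
    """Apply filters 1-5 in order to a full set body (anchors included).

    Short-circuits on the first failure unless ``diagnostic`` is set.
    """
    if expected_len is not None and len(packet_dna) != expected_len:
        raise InvalidSequenceError(
            f"packet body length {len(packet_dna)} != expected {expected_len}")
    failed = []
    rate = predicted_error_rate(packet_dna, error_table)
    if rate > config.error_rate_threshold:
        failed.append(("error_rate", f"{rate:.5f} > "
                       f"{config.error_rate_threshold:.5f}"))
        if not diagnostic:
            return ScreenVerdict(False, failed)
    r_snr = snr(packet_dna, current_model)
    if r_snr < config.snr_threshold:
        failed.append(("snr", f"{r_snr:.4f} < {config.snr_threshold:.4f}"))
        if not diagnostic:
            return ScreenVerdict(False, failed)
    wins = kmer_codes(seq_to_codes(packet_dna), K)
    bad = np.nonzero(config.banned_kmers[wins])[0]
    if bad.size:
        failed.append(("banned_kmer",
                       kmer_to_string(int(wins[bad[0]]))))
        if not diagnostic:
            return ScreenVerdict(False, failed)
    gc = gc_fraction(packet_dna)
    if not (config.gc_bounds[0] <= gc <= config.gc_bounds[1]):
        failed.append(("gc", f"{gc:.3f} outside {config.gc_bounds}"))
        if not diagnostic:
            return ScreenVerdict(False, failed)
    hits = find_bio_hits(packet_dna, config)
    if hits:
        failed.append(("bio", hits[0]))
    return ScreenVerdict(len(failed) == 0, failed)


def screen_codes_batch(codes: np.ndarray, config: ScreenConfig,
                       error_table: KmerErrorTable,
                       current_model: KmerCurrentModel) -> dict:
    """Vectorized filters 1-4 over a (m, body_len) code array.

    Returns per-filter pass masks; filter 5 is evaluated lazily by callers
    on the (few) survivors. Used by the encoder's packet-selection loop.
    """
    wins = kmer_codes(codes, K)
    rates = error_table.rates[wins].mean(axis=1)
    pair_tab = current_model.pair_neglog_overlap()
    snrs = pair_tab[wins[:, :-1], codes[:, K:]].mean(axis=1)
    gc = ((codes == 1) | (codes == 2)).mean(axis=1)
    return {
        "error_rate": rates <= config.error_rate_threshold,
        "snr": snrs >= config.snr_threshold,
        "banned_kmer": ~config.banned_kmers[wins].any(axis=1),
        "gc": (gc >= config.gc_bounds[0]) & (gc <= config.gc_bounds[1]),
    }


# -- TSV interfaces ---------------------------------------------------------

def save_current_model(model: KmerCurrentModel, path) -> None:
    with open(path, "w") as fh:
        for w in range(N_KMERS):
            fh.write(f"{kmer_to_string(w)}\t{model.mean[w]:.4f}"
                     f"\t{model.std[w]:.4f}\n")


def load_current_model(path) -> KmerCurrentModel:
    mean = np.zeros(N_KMERS)
    std = np.zeros(N_KMERS)
    seen = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            kmer, m, s = line.split("\t")
            from ._seq import string_to_kmer
            w = string_to_kmer(kmer.strip())
            mean[w] = float(m)
            std[w] = float(s)
            seen += 1
    if seen != N_KMERS:
        raise TableError(f"current model TSV has {seen} rows, need {N_KMERS}")
    return KmerCurrentModel(mean, std)


def save_error_table(table: KmerErrorTable, path) -> None:
    with open(path, "w") as fh:
        for w in range(N_KMERS):
            fh.write(f"{kmer_to_string(w)}\t{table.rates[w]:.6g}\n")


def load_error_table(path, provenance: str = "user-supplied") -> KmerErrorTable:
    rates = np.zeros(N_KMERS)
    seen = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            kmer, r = line.split("\t")
            from ._seq import string_to_kmer
            rates[string_to_kmer(kmer.strip())] = float(r)
            seen += 1
    if seen != N_KMERS:
        raise TableError(f"error table TSV has {seen} rows, need {N_KMERS}")
    return KmerErrorTable(rates, provenance)
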