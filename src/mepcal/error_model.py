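"""Controlled error injection, error-pattern profiling and fixture tables.

``inject_errors`` reproduces the pseudo-sequence construction used for the
robustness sweeps: independent per-base errors at a given rate, split among
substitutions, insertions and deletions. ``profile_errors`` recovers an
empirical error profile (substitution matrix, indel lengths, per-site track,
5-mer context rates) by aligning reads against a reference. ``make_fixtures``
builds the seeded synthetic 5-mer current/error tables that stand in for a
sequencer's own calibration data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import codes_to_seq, revcomp, seq_to_codes
from .screening import K, N_KMERS, KmerCurrentModel, KmerErrorTable


@dataclass
class ErrorSpec:
    rate: float
    proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("error rate must lie in [0, 1]")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError("class proportions must be non-negative")


@dataclass
class ErrorProfile:
    substitution_matrix: np.ndarray       # (4,4) counts, ref -> read
    insertion_lengths: np.ndarray         # histogram, index = length
    deletion_lengths: np.ndarray
    per_site_errors: np.ndarray           # (ref_len, 3) sub/ins/del counts
    per_site_coverage: np.ndarray
    kmer_error_table: KmerErrorTable
    totals: dict                          # class totals and rates
    n_reads_used: int = 0
    n_reads_skipped: int = 0

    def dispersion(self) -> dict:
        """Variance/mean ratio of per-site counts (1.0 under Poisson)."""
        cov = self.per_site_coverage > 0
        out = {}
        names = ("substitution", "insertion", "deletion")
        for i, name in enumerate(names):
            x = self.per_site_errors[cov, i]
            out[name] = float(x.var() / x.mean()) if x.size and x.mean() > 0 \
                else float("nan")
        tot = self.per_site_errors[cov].sum(axis=1)
        out["total"] = float(tot.var() / tot.mean()) if tot.size and \
            tot.mean() > 0 else float("nan")
        return out


# -- injection --------------------------------------------------------------

def inject_errors_codes(codes: np.ndarray, rate: float, proportions,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, dict]:
    """Inject mixed errors into a base-code array; returns (codes, counts)."""
    n = codes.size
    if rate <= 0.0 or n == 0:
        return codes.copy(), {"substitution": 0, "insertion": 0, "deletion": 0}
    hit = np.nonzero(rng.random(n) < rate)[0]
    if hit.size == 0:
        return codes.copy(), {"substitution": 0, "insertion": 0, "deletion": 0}
    cls = rng.choice(3, size=hit.size, p=list(proportions))
    sub_shift = rng.integers(1, 4, size=hit.size)
    ins_base = rng.integers(0, 4, size=hit.size)
    out = []
    prev = 0
    counts = [0, 0, 0]
    for j, pos in enumerate(hit):
        out.append(codes[prev:pos])
        c = cls[j]
        counts[c] += 1
        if c == 0:      # substitution to a uniformly random *different* base
            out.append(np.array([(codes[pos] + sub_shift[j]) % 4]))
        elif c == 1:    # insertion of one uniform base after the position
            out.append(np.array([codes[pos], ins_base[j]]))
        # c == 2: deletion; emit nothing
        prev = pos + 1
    out.append(codes[prev:])
    return np.concatenate(out), {"substitution": counts[0],
                                 "insertion": counts[1],
                                 "deletion": counts[2]}


def inject_errors(seq: str, spec: ErrorSpec) -> tuple[str, dict]:
    """Inject pseudorandom mixed errors into a DNA string."""
    rng = np.random.default_rng(spec.seed)
    codes, counts = inject_errors_codes(seq_to_codes(seq), spec.rate,
                                        spec.proportions, rng)
    return codes_to_seq(codes), counts


# -- profiling --------------------------------------------------------------

_CIGAR_OPS = frozenset("=XID")


def _parse_cigar(cigar: str):
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            yield num, ch
            num = 0


def profile_errors(reads, reference: str, max_norm_distance: float = 0.45,
                   try_reverse: bool = True) -> ErrorProfile:
    """Profile error patterns of reads against a reference sequence.

    Each read is located in the reference by infix edit-distance alignment;
    alignment events are classified and attributed to reference positions and
    their centred 5-mer contexts. Reads with normalized distance above
    ``max_norm_distance`` on both strands are skipped.
    """
    ref = reference.upper()
    ref_codes = seq_to_codes(ref)
    L = len(ref)
    sub = np.zeros((4, 4), dtype=np.int64)
    ins_len = np.zeros(64, dtype=np.int64)
    del_len = np.zeros(64, dtype=np.int64)
    site = np.zeros((L, 3), dtype=np.int64)
    cover = np.zeros(L, dtype=np.int64)
    used = skipped = 0
    aligned_bases = 0
    for read in reads:
        read = read.upper().replace("N", "A") if "N" in read else read.upper()
        best = None
        for candidate in ((read, revcomp(read)) if try_reverse else (read,)):
            aln = edlib.align(candidate, ref, mode="HW", task="path")
            if best is None or aln["editDistance"] < best[0]["editDistance"]:
                best = (aln, candidate)
        aln, oriented = best
        if len(oriented) == 0 or \
                aln["editDistance"] / len(oriented) > max_norm_distance:
            skipped += 1
            continue
        used += 1
        rpos = aln["locations"][0][0]  # reference cursor
        qpos = 0
        q_codes = seq_to_codes(oriented)
        for n, op in _parse_cigar(aln["cigar"]):
            if op == "=":
                cover[rpos:rpos + n] += 1
                rpos += n
                qpos += n
                aligned_bases += n
            elif op == "X":
                cover[rpos:rpos + n] += 1
                for t in range(n):
                    sub[ref_codes[rpos + t], q_codes[qpos + t]] += 1
                    site[rpos + t, 0] += 1
                rpos += n
                qpos += n
                aligned_bases += n
            elif op == "I":  # bases present in the read, absent in reference
                ins_len[min(n, 63)] += 1
                site[min(rpos, L - 1), 1] += 1
                qpos += n
            elif op == "D":  # reference bases missing from the read
                del_len[min(n, 63)] += 1
                cover[rpos:rpos + n] += 1
                site[rpos, 2] += 1
                rpos += n
    # attribute error events to the 5-mer centred on each site
    kmer_events = np.zeros(N_KMERS, dtype=np.int64)
    kmer_cover = np.zeros(N_KMERS, dtype=np.int64)
    half = K // 2
    if L >= K:
        from ._seq import kmer_codes
        centres = kmer_codes(ref_codes, K)  # window i covers sites i..i+4
        ev = site.sum(axis=1)
        for i in range(centres.size):
            c = i + half
            kmer_events[centres[i]] += ev[c]
            kmer_cover[centres[i]] += cover[c]
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(kmer_cover > 0, kmer_events / np.maximum(kmer_cover, 1),
                         0.0)
    totals = {
        "substitution": int(sub.sum()),
        "insertion": int(ins_len.sum()),
        "deletion": int(del_len.sum()),
        "aligned_bases": int(aligned_bases),
    }
    denom = max(aligned_bases, 1)
    totals["substitution_rate"] = totals["substitution"] / denom
    totals["insertion_rate"] = totals["insertion"] / denom
    totals["deletion_rate"] = totals["deletion"] / denom
    totals["total_rate"] = (totals["substitution"] + totals["insertion"]
                            + totals["deletion"]) / denom
    return ErrorProfile(
        substitution_matrix=sub,
        insertion_lengths=ins_len,
        deletion_lengths=del_len,
        per_site_errors=site,
        per_site_coverage=cover,
        kmer_error_table=KmerErrorTable(np.clip(rates, 0.0, 1.0),
                                        provenance="profiled"),
        totals=totals,
        n_reads_used=used,
        n_reads_skipped=skipped,
    )


# -- fixtures ---------------------------------------------------------------

def make_fixtures(seed: int = 0) -> tuple[KmerCurrentModel, KmerErrorTable]:
    """Deterministic synthetic 5-mer tables.

    Current means are uniform on [70, 130] (pA-like) with per-k-mer standard
    deviations on [1.5, 3.5]; error rates are log-normal (median 3%, shape
    0.8) clipped to [0, 1], reproducing the right-skewed hotspot structure of
    nanopore context-dependent error frequencies.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        0xF1]))
    mean = rng.uniform(70.0, 130.0, size=N_KMERS)
    std = rng.uniform(1.5, 3.5, size=N_KMERS)
    rates = np.clip(rng.lognormal(np.log(0.03), 0.8, size=N_KMERS), 0.0, 1.0)
    return KmerCurrentModel(mean, std), KmerErrorTable(rates, "fixture")
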