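"""Density-robustness trade-off model and optimal parameter selection.

The decodability statistic r-bar = r - theta (valid minus invalid symbol
ratio after anchor-based symbol calling) is simulated as a function of the
set size S, the symbol/anchor length ratio R and the post-assembly error
rate epsilon. Per (S, R, epsilon) node, r-bar is approximately Gaussian;
cubic trivariate polynomial surfaces are fitted to its mean and standard
deviation. A group decodes when r-bar >= d_E = E/(E+M), so fixing
(d_E - mu)/sigma = -2.33 gives a per-group success probability of 0.99,
which caps d_N = N/(N+G) at 0.99; the optimizer then maximizes the coding
density over candidate (S, R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import BASES, codes_to_seq
from .codec_profile import CodecProfile, ProfileError, coding_density
from .error_model import inject_errors_codes

Z_FEASIBLE = 2.33           # standard-normal quantile fixing P(decode) = 0.99
D_N_MAX = 0.99
DEFAULT_S = (5, 10, 20, 40, 100)
DEFAULT_R = (2, 3, 4, 6, 8)
GF8_BYTE_BUDGET = 255       # tertiary codeword limit, bytes per group


class InsufficientGridError(ValueError):
    pass


class InfeasibleAtEpsilonError(RuntimeError):
    pass


@dataclass
class RbarSample:
    S: int
    R: int
    eps: float
    rbar: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    symbols_per_sim: int = 2400


@dataclass
class TradeoffSurfaces:
    exponents: np.ndarray        # (n_terms, 3) powers of (R, S, eps)
    mu_coeffs: np.ndarray
    sigma_coeffs: np.ndarray
    mu_residual_sd: float
    sigma_residual_sd: float
    domain: dict
    symbols_per_sim: int = 2400

    def evaluate(self, R: float, S: float, eps: float) -> tuple[float, float]:
        terms = np.prod(np.array([R, S, eps], dtype=float)
                        ** self.exponents, axis=1)
        return float(terms @ self.mu_coeffs), float(terms @ self.sigma_coeffs)


@dataclass
class CandidateChoice:
    S: int
    R: int
    mu: float
    sigma: float
    d_E: float
    d_N: float
    density: float               # continuous model density (Eq. of merit)
    feasible: bool
    profile: CodecProfile | None = None
    realized_density: float | None = None
    rounding_loss: float | None = None


@dataclass
class OptimalChoice:
    best: CandidateChoice
    candidates: list[CandidateChoice]
    eps: float
    feasibility_p: float         # model P(r-bar >= d_E), 0.99 by construction

    def best_realized(self) -> CandidateChoice:
        """Feasible candidate with the highest density after rounding to a
        concrete profile (R a multiple of 4, integral packet counts)."""
        realizable = [c for c in self.candidates
                      if c.feasible and c.profile is not None]
        if not realizable:
            raise InfeasibleAtEpsilonError("no realizable candidate")
        return max(realizable, key=lambda c: c.realized_density)


# -- simulation -------------------------------------------------------------

def _call_units(body: str, S: int, R: int, leading: str = "A"):
    """Alignment-based unit caller for arbitrary R (simulation variant).

    Returns a list of length S with the called R-base tuple or None
    (erased). Mirrors the decoder's anchor-parsimony rule.
    """
    span = R + 1
    L = S * span
    if abs(len(body) - L) > S:
        return [None] * S
    template = (leading + "N" * R) * S
    aln = edlib.align(template, body, mode="NW", task="path",
                      additionalEqualities=[("N", b) for b in BASES])
    tgt = np.full(L, -1, dtype=np.int64)
    erased = np.zeros(S, dtype=bool)
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
                tgt[tpos] = bpos
                tpos += 1
                bpos += 1
        elif op == "I":
            for _ in range(n):
                erased[tpos // span] = True
                tpos += 1
        else:  # "D"
            unit = min(tpos // span, S - 1)
            erased[unit] = True
            if tpos % span == 0 and 0 < tpos < L:
                erased[tpos // span - 1] = True
            bpos += n
    out = []
    for k in range(S):
        sl = tgt[k * span + 1:(k + 1) * span]
        if erased[k] or (sl < 0).any():
            out.append(None)
        else:
            out.append(tuple(body[i] for i in sl))
    return out


def simulate_rbar(S: int, R: int, eps: float, n_sims: int = 1000,
                  symbols_per_sim: int = 2400, seed: int = 0) -> RbarSample:
    """Monte-Carlo draws of r-bar for one (S, R, epsilon) node.

    Each simulation synthesizes symbols_per_sim anchored DNA symbols (in
    sets of S), injects mixed errors at rate eps, runs the symbol caller
    against ground truth and records r (valid ratio: correct bases at the
    correct serial) and theta (called-but-wrong ratio).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    if symbols_per_sim % S:
        raise ValueError("symbols_per_sim must be a multiple of S")
    rng = np.random.default_rng(np.random.SeedSequence(
        [seed & 0x7FFFFFFF, S, R, int(round(eps * 1e6))]))
    n_sets = symbols_per_sim // S
    span = R + 1
    leading = "A"
    r_out = np.empty(n_sims)
    t_out = np.empty(n_sims)
    anchor_idx = np.arange(0, S * span, span)
    for sim in range(n_sims):
        valid = invalid = 0
        payload = rng.integers(0, 4, size=(n_sets, S * span))
        payload[:, anchor_idx] = 0  # leading base 'A'
        for body_codes in payload:
            truth = codes_to_seq(body_codes)
            mutated, _ = inject_errors_codes(body_codes, eps,
                                             (1 / 3, 1 / 3, 1 / 3), rng)
            calls = _call_units(codes_to_seq(mutated), S, R, leading)
            for k, call in enumerate(calls):
                if call is None:
                    continue
                true_unit = tuple(truth[k * span + 1:(k + 1) * span])
                if call == true_unit:
                    valid += 1
                else:
                    invalid += 1
        r_out[sim] = valid / symbols_per_sim
        t_out[sim] = invalid / symbols_per_sim
    return RbarSample(S, R, eps, r_out - t_out, r_out, t_out,
                      symbols_per_sim=symbols_per_sim)


# -- surface fitting --------------------------------------------------------

def _design(nodes: np.ndarray, exponents: np.ndarray) -> np.ndarray:
    return np.prod(nodes[:, None, :] ** exponents[None, :, :], axis=2)


def _cubic_exponents() -> np.ndarray:
    exps = [(i, j, k) for i in range(4) for j in range(4) for k in range(4)
            if i + j + k <= 3]
    return np.array(sorted(exps), dtype=float)


def fit_surfaces(samples: list[RbarSample]) -> TradeoffSurfaces:
    """Least-squares cubic fits of node means and standard deviations."""
    nodes = np.array([[s.R, s.S, s.eps] for s in samples], dtype=float)
    mus = np.array([s.rbar.mean() for s in samples])
    sds = np.array([s.rbar.std(ddof=1) for s in samples])
    exps = _cubic_exponents()
    X = _design(nodes, exps)
    if np.linalg.matrix_rank(X) < exps.shape[0]:
        raise InsufficientGridError(
            "design matrix is rank-deficient; widen the (R, S, eps) grid")
    mu_c, mu_res, *_ = np.linalg.lstsq(X, mus, rcond=None)
    sd_c, sd_res, *_ = np.linalg.lstsq(X, sds, rcond=None)
    dof = max(1, len(samples) - exps.shape[0])
    mu_rsd = math.sqrt(float(mu_res[0]) / dof) if mu_res.size else 0.0
    sd_rsd = math.sqrt(float(sd_res[0]) / dof) if sd_res.size else 0.0
    return TradeoffSurfaces(
        exponents=exps, mu_coeffs=mu_c, sigma_coeffs=sd_c,
        mu_residual_sd=mu_rsd, sigma_residual_sd=sd_rsd,
        domain={"R": (nodes[:, 0].min(), nodes[:, 0].max()),
                "S": (nodes[:, 1].min(), nodes[:, 1].max()),
                "eps": (nodes[:, 2].min(), nodes[:, 2].max())},
        symbols_per_sim=int(round(float(np.mean(
            [s.symbols_per_sim for s in samples])))))


# -- optimization -----------------------------------------------------------

def _model_density(S: int, R: int, d_E: float, d_N: float,
                   I_g: int, I_s: int) -> float:
    d_R = R / (R + 1)
    d_S = S / (S + I_s / (R + 1))
    T = max(1, (4 * GF8_BYTE_BUDGET) // (S * R))  # sets per group (byte cap)
    group_len = T * (I_s + S * (R + 1))
    return 2.0 * group_len / (group_len + I_g) * d_N * d_E * d_S * d_R


def _realize(S: int, R: int, mu: float, sigma: float,
             sim_units: int) -> tuple[CodecProfile, float] | None:
    """Round the continuous choice to a feasible profile (R multiple of 4).

    The tertiary redundancy of the realized profile is budgeted against the
    per-group spread of r-bar: the fitted sigma describes simulations of
    ``sim_units`` DNA symbols, while a group carries only T*S of them, so
    sigma is rescaled by sqrt(sim_units / group_units) before applying the
    2.33-sigma feasibility margin.
    """
    if R % 4:
        return None
    u = R // 4
    T = max(1, (4 * GF8_BYTE_BUDGET) // (S * R))
    group_units = T * S
    sigma_group = sigma * math.sqrt(max(1.0, sim_units / group_units))
    d_E = mu - Z_FEASIBLE * sigma_group
    if d_E <= 0:
        return None
    kept = int(d_E * T)
    if kept < 1:
        return None
    try:
        prof = CodecProfile(S=S, R=R, E=kept * S * u, M=(T - kept) * S * u,
                            N=99, G=1, packets_kept=kept,
                            fountain_expansion=max(64, 40 * kept))
    except ProfileError:
        return None
    return prof, coding_density(prof).d


def optimize(eps: float, surfaces: TradeoffSurfaces, I_g: int = 10,
             I_s: int = 5, candidate_S=DEFAULT_S, candidate_R=DEFAULT_R
             ) -> OptimalChoice:
    """Pick (S, R, d_N, d_E) maximizing the model coding density at eps."""
    lo, hi = surfaces.domain["eps"]
    if not (lo <= eps <= hi):
        raise ValueError(f"eps={eps} outside the fitted domain [{lo}, {hi}]")
    cands: list[CandidateChoice] = []
    for S in candidate_S:
        for R in candidate_R:
            mu, sigma = surfaces.evaluate(R, S, eps)
            sigma = max(sigma, 1e-6)
            d_E = mu - Z_FEASIBLE * sigma
            feasible = 0.0 < d_E < 1.0
            d_E_c = min(max(d_E, 0.0), 1.0)
            dens = _model_density(S, R, d_E_c, D_N_MAX, I_g, I_s) \
                if feasible else 0.0
            cand = CandidateChoice(S=S, R=R, mu=mu, sigma=sigma, d_E=d_E_c,
                                   d_N=D_N_MAX, density=dens,
                                   feasible=feasible)
            if feasible:
                realized = _realize(S, R, mu, sigma,
                                    surfaces.symbols_per_sim)
                if realized is not None:
                    cand.profile, cand.realized_density = realized
                    cand.rounding_loss = dens - cand.realized_density
            cands.append(cand)
    feas = [c for c in cands if c.feasible]
    if not feas:
        raise InfeasibleAtEpsilonError(
            f"no candidate achieves d_E > 0 at eps={eps}")
    best = max(feas, key=lambda c: c.density)
    from scipy.stats import norm
    p = float(norm.sf(-Z_FEASIBLE))
    return OptimalChoice(best=best, candidates=cands, eps=eps,
                         feasibility_p=p)


def density_envelope(eps_values, surfaces: TradeoffSurfaces, **kw
                     ) -> np.ndarray:
    """Maximal model density at each error rate (the envelope curve)."""
    out = np.empty(len(eps_values))
    for i, e in enumerate(eps_values):
        try:
            out[i] = optimize(e, surfaces, **kw).best.density
        except InfeasibleAtEpsilonError:
            out[i] = 0.0
    return out
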