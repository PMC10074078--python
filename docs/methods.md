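# Methods

## The layered code and its assumptions

The codec assumes its input is a single assembled consensus sequence of the
information DNA — not raw reads. Consensus construction (basecalling,
assembly) is upstream; the residual error rate of that consensus, ε, is the
channel parameter all robustness statements refer to. Errors are modelled as
independent per-base events split among substitutions, insertions and
deletions (the simulator's default is the equal three-way split used for
all robustness sweeps).

Three properties are load-bearing:

* **Indel confinement.** Every DNA symbol (R bases) is preceded by a leading
  base, so each encoding set of S symbols carries a strict anchor pattern of
  period R+1. The symbol caller aligns the observed set body to this
  template by global edit-distance alignment in which the non-anchor
  positions are wildcards; a symbol is called only if its whole span aligned
  indel-free. Because alignment is per set, a miscalled indel can never
  alter calls outside its set — the property the exhaustive single-indel
  test checks.
* **Erasures are cheaper than errors.** Indel-affected symbols are erased;
  a tertiary RS(E+M, E) codeword per group decodes whenever 2e + f ≤ M.
  Substitutions inside symbol payload bases are invisible to the caller and
  surface as RS errors (cost 2); indels surface as erasures (cost 1).
* **Group-level erasure coding.** Groups that fail the tertiary layer are
  erased at the primary layer: E interleaved RS(N+G, N) codewords, one byte
  per group per codeword, recover the payload from any N intact groups per
  block. The primary decoder also runs full errors-and-erasures decoding per
  interleaved codeword, so a group that decoded locally but carries wrong
  bytes (an undetected tertiary miscorrection) is corrected or detected
  within 2e + f ≤ G instead of silently corrupting the payload.

Payloads needing more than 255 groups are arranged in consecutive primary
blocks of N+G ≤ 255 groups, each with its own interleaved codewords; this
keeps all arithmetic in GF(2⁸). The per-block structure is this package's
choice; a single larger-field codeword would behave equivalently in the
pure-erasure regime.

The fountain layer is a seeded systematic random-linear code over GF(2⁸):
candidate packet i ≥ packets_kept is a pseudorandom linear combination of
the systematic packets, deterministic in (seed, group). The encoder verifies
that the finally selected packet set is invertible and swaps in the next
passing candidate if it is not, so decoding from exactly packets_kept
packets is guaranteed by construction. Selected packet IDs are recorded in
the sidecar; the format gives the decoder no in-band way to learn them.

## Decoder numerics

* **Segmentation** is hierarchical so damage cannot cascade. The 10-bp group
  indices are located first (edit-distance search in a window around the
  expected position, ties toward the expected offset) and re-anchor the
  global indel drift whenever they match with distance ≤ ⌈I_g/3⌉. Set
  indices are searched relative to their own group's index with a local
  drift that resets at each group and updates only on matches with distance
  ≤ ⌈I_s/4⌉. A boundary matched worse than half its index length is
  low-confidence: it is placed at its expected position and the set behind
  it is treated as a whole-set erasure. Window width is
  max(8, ⌈3·√(0.02·gap)⌉) around the expected position — three standard
  deviations of accumulated indel drift at a 2% indel rate, floored.
* **Symbol calling** parses the alignment path: template positions mapped
  1:1 survive; an alignment insertion or deletion erases the symbol whose
  span it touches (an insertion exactly between two symbols erases both
  neighbours). If a group fails the tertiary bound, its sets are re-called
  in a conservative second pass that additionally requires each symbol to be
  pinned between two exactly matching anchors; this trades extra erasures
  for fewer wrong calls and can only help a group that already failed.
* **Conflict resolution**: duplicate serials keep the candidate whose anchor
  context needed fewest edits; symmetric ties erase all candidates.

## Screening

Filters run in fixed order: predicted error rate, SNR, banned 5-mers, GC,
biological activity. Thresholds for filters 1–2 are the empirical
60%-discard points over 10,000 uniformly random sequences of the body
length. The SNR kernel computes the overlap area of two Gaussians exactly
from their crossing points using erfc, so nearly disjoint current
distributions keep full relative accuracy (capped at −ln A = 745, the
double-precision floor). Whether that integral is evaluated analytically or
numerically is a free choice; the closed form was picked for determinism and
speed, and is validated against quadrature in the tests.

Screening applies to the anchored body including leading bases and excludes
the set index (indices are generated separately under the same motif rules).
Only the information packets are screened; tertiary parity sets are emitted
as-is. If fewer than packets_kept candidates pass all five filters, filters
are relaxed in reverse priority order (biological activity first) with a
logged warning — with 50-bp bodies this is rare, but for long bodies the
banned-5-mer filter alone rejects almost everything (a 180-bp body has 176
windows against 64 banned 5-mers), so encoding with large S·R profiles
routinely runs relaxed. ORF detection uses ATG-to-in-frame-stop on both
strands with a 75-nt minimum (the common ORF-finder default); low
complexity is a sliding-window dinucleotide-entropy score (window 16,
threshold 1.2 bits) standing in for masker-style heuristics; the motif list
defaults to the three Golden-Gate sites plus reverse complements, and users
supply recombination-site lists as plain text.

## Fixture tables

The packaged 5-mer tables are synthetic and seeded: current means uniform on
[70, 130] with per-k-mer standard deviations on [1.5, 3.5] (the scale of
pore-model tables), and error rates log-normal (median 3%, shape 0.8,
clipped to [0, 1]) to reproduce the right-skewed hotspot structure of
context-dependent nanopore error frequencies. They emulate the *structure*
of an empirical calibration, not any instrument's values: tests passing
against fixtures show the machinery is correct, not that thresholds are
tuned for a particular flowcell. Real tables can be supplied as TSV
(`kmer<TAB>mean<TAB>stdev`, `kmer<TAB>rate`) or derived from data with the
error profiler.

The error simulator draws per-base events independently; real nanopore
errors are burstier (homopolymer-linked, context-dependent), so real
consensus sequences at a nominal ε are somewhat harder than simulated ones.
The profiler recovers exactly the quantities the simulator takes as input,
which is what the inject→profile recovery test closes.

## Trade-off model

r̄ = r − θ is simulated per (S, R, ε) node by synthesizing anchored sets,
injecting errors and running the symbol caller against ground truth; a
symbol is valid only if both value and serial are correct. Node means and
standard deviations are fitted with trivariate cubic polynomials (20 terms);
the design matrix must have full rank, which requires at least four distinct
values per axis.

Two variance scales matter and are kept distinct deliberately. The fitted σ
describes r̄ over a whole simulation (2,400 symbols by default, matching the
convention under which the ~1.6 bit/base envelope at ε ≈ 0.3% is quoted);
decodability, however, is a per-group event over only T·S symbols, with
√-scale larger spread. The optimizer therefore reports the model density
from the simulation-scale σ, but when rounding to a concrete profile it
rescales σ by √(sim_units/group_units) before applying the 2.33σ margin,
then floors packets_kept — without this, realized profiles lose several
percent of groups at the target ε and the G = 1 primary budget cannot
absorb them. Realized profiles use N = 99, G = 1 (d_N = 0.99 exactly), R
restricted to multiples of 4, and E+M ≤ 255; the rounding loss against the
continuous model is reported.

## Problem sizes in the test suite

The suite uses sizes chosen to exercise every mechanism at full fidelity:
the robustness sweep runs the complete 0.25%–3.0% grid with 20 replicates
per rate on the full 50,540-bp encoding; the indel-confinement check is
exhaustive (every deletion and insertion position) on a 390-bp toy profile;
the trade-off grid is 4×4×4 nodes × 60 simulations of 400 symbols, with a
500-simulation node of 2,400 symbols for the distributional checks; the
large-payload decode check uses a 20,000-byte payload (one full primary
block of ~100 groups with the optimizer-realized profile) at 0.28% mixed
errors. Monte-Carlo tolerances in the tests are set at 2–3 standard errors
of the corresponding estimate.

## Known limitations

* The decoder requires the sidecar (profile, index codebooks, selected
  packet IDs); there is no blind-decoding mode.
* Huffman coding is byte-oriented; entropy/length statistics depend on the
  payload and are reported, not asserted against any particular corpus.
* The BCH baseline's block count is a free parameter above the minimum; the
  packaged comparison pins 224 blocks for the 5,564-byte payload.
* R must be a multiple of 4 in the full codec (8-bit symbols at 2
  bit/base); other R values are supported in the trade-off simulation only.
* Screening can only reject candidates the fountain expansion offers; with
  very restrictive tables the relaxation path weakens filter guarantees
  rather than failing the encode.
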