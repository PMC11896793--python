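# Methods

## Problem and model

`oligotiler` tiles a target DNA sequence (A/C/G/T only) with single-stranded
oligomers for polymerase chain assembly.  The tiling is gapless and
alternating-strand: odd-numbered oligomers lie on the top strand, even ones on
the bottom; consecutive oligomers intersect in exactly one annealing overlap,
the first oligomer starts at position 1 and the last ends at the target's end,
so the first and last oligomers can double as amplification primers.  Under
this topology a junction between a top oligomer and the following bottom
oligomer is a 3′–3′ extension junction, and the next junction is 5′–5′; the
union of all oligomers covers the target exactly once.

Assembly fidelity is modeled by a five-term penalty per oligomer,

    score = |T_t − T_c| + 1_T + GC_clamp + R_within + R_between,

an unweighted sum (weights of 1 on every term).  A faultless oligomer scores
exactly 0, which the acceptance suite asserts.

* **Overlap Tm deviation.**  `T_c` is the overlap's duplex melting
  temperature from the unified nearest-neighbor parameter set: enthalpy and
  entropy are sums over adjacent base-pair stacks plus terminal initiation
  terms, and

      Tm(°C) = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15 + 16.6·log₁₀[Na⁺],

  with R = 1.987 cal/(mol·K), ΔH in kcal/mol, ΔS in cal/(mol·K).
  Self-complementary overlaps use C_T/1 and the symmetry entropy correction.
  The deviation is taken as an absolute value: a hotter-than-target overlap is
  just as much a defect as a colder one, and without the absolute value the
  zero-score law for faultless oligomers would be false.  The parameter table
  ships as a plain-text TSV (`src/oligotiler/data/nn_unified_v1.tsv`) so it is
  inspectable and swappable.
* **3′-terminal thymine.**  The indicator is evaluated on the oligomer's own
  strand 5′→3′ — the physical terminus a polymerase extends.
* **GC clamp.**  The penalty is the *excess* of G/C over an allowance of 3 in
  the terminal five bases of the overlap, oriented with the scoring
  oligomer's strand.  A raw G/C count would make a zero score unreachable
  (nearly every overlap contains G/C); the ≤ 3-in-5 allowance is the standard
  primer-design guideline.  An alternative reading — counting G/C runs of
  length ≥ 4 anywhere in the overlap — was considered and not implemented.
* **Repeats.**  Both repeat terms count *positions covered* by risky k-mers,
  not k-mer types, so the penalty scales with the length of the dangerous
  region, and a k-mer is always identified with its reverse complement
  (canonical key): mis-annealing happens between complementary strands.
  `R_within` uses k = 8 by default (a 10-mer can only repeat inside an
  oligomer carrying ≥ 20 nt of repetitive content, so a smaller k catches
  shorter self-annealing seeds); `R_between` uses k = 10.  Both are
  configurable.

## The greedy designer

At each cursor the designer enumerates every (oligomer length L, next-overlap
length V) pair with L in [min_oligo_len, max_oligo_len], V in
[min_overlap_len, max_overlap_len], V < L, scores each candidate, and commits
the winner; the next cursor is the start of the committed overlap.  Selection
is two-stage:

1. **Suitability.**  Candidates whose overlap GC content lies inside
   [gc_low, gc_high] (default 40–60%) are preferred.  Only when no candidate
   qualifies does selection fall back to the full grid — the next-best-fit
   rule: an imperfect design is returned rather than no design.  GC content
   appears in no penalty term, so this preference is the only mechanism
   enforcing the GC band.
2. **Score with a tolerance-width tie.**  Within the chosen pool the minimum
   penalty total wins, but totals within `tm_tolerance` (default 2.5 °C) of
   the minimum are treated as equivalent — a score gap smaller than the
   user's own acceptable Tm half-width is not a meaningful preference — and
   equivalent candidates resolve toward the **longer oligomer** (fewer
   oligomers per assembly), then the smaller total, the overlap Tm closest to
   target, and the smaller overlap start.  Exact floating-point score ties
   essentially never occur, so without the equivalence width a
   longer-oligomer preference would be dead code; with it, a 520 bp
   GC-balanced target under the classic worked-example settings (max oligomer
   50 nt, overlap 15–20 bp, target 56 °C) is covered by 20 oligomers in the
   median — the published count for a target of that size.

A terminal-feasibility guard (memoized reachability over the remaining
suffix) rejects candidates that would strand a remainder no oligomer can
legally finish; the final oligomer may be shorter than `min_oligo_len` but
never shorter than `min_overlap_len + 5`.  Tm-deviation and clamp terms are
evaluated on the overlap being chosen at each step (the oligomer's next
overlap); the final oligomer, having no successor, is scored on its preceding
overlap.  During construction `R_between` is counted against all previously
committed non-adjacent overlaps (clusters do not exist yet); after tiling,
repeat-sharing junctions are segregated and every oligomer is re-scored with
`R_between` confined to its final cluster.

The designer is fully deterministic — no randomness anywhere — and identical
inputs give identical designs.  Internally all candidate terms are computed
from precomputed prefix sums and canonical k-mer arrays over the reference;
these agree exactly with the public per-sequence functions (tested), they
only remove redundant recomputation from the candidate grid.

## Cluster segregation

Consecutive oligomers are grouped left to right; adding an oligomer brings
its left junction into the open group, and if that junction shares a
canonical 10-mer with any non-adjacent junction already in the group, the
group is closed so that the offending junction starts the new group.
Adjacent junctions are never compared (with default windows they can even
share reference sequence through a short middle oligomer).  The partition's
defining property — zero shared canonical k-mers between non-adjacent
overlaps within any group — is asserted directly in the tests.  Clusters are
annotated in the order sheet and report; whether they are pooled separately
at the bench is the user's call.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| max_oligo_len / min_oligo_len | 50 / 30 | nt | worked-example maximum; minimum keeps ≥ 10 nt of unique sequence beyond the longest overlap |
| max_overlap_len / min_overlap_len | 20 / 15 | bp | worked-example maximum; overlaps < 15 bp rarely reach a 56 °C target |
| target_overlap_tm | 56.0 | °C | worked-example target |
| tm_tolerance | 2.5 | °C | flag threshold for error-prone oligomers and the score-equivalence width in selection; never rejects candidates |
| gc_low / gc_high | 40 / 60 | % | preferred overlap GC band |
| repeat_len_between / repeat_len_within | 10 / 8 | bp | see Repeats above |
| oligo_conc | 2.5e-7 | M | common oligo-pool working concentration (250 nM total strand) |
| monovalent_salt | 0.1 | M | places a 20-mer 50%-GC overlap at ≈ 56 °C, self-consistent with pairing 20 bp overlaps with a 56 °C target; configurable to match any vendor calculator |

## Synthetic data

The fixtures module generates references with an exact base composition (the
G+C count is fixed to the target percentage up to rounding, split evenly
between G and C, likewise A and T, then shuffled with a seeded NumPy
generator), so realized GC is within 1/length of the target and every
sequence reproduces bit-for-bit across platforms.  Motifs can be planted at
fixed positions to create controlled repeat structure.  These fixtures
emulate composition and repeat content only: real genic sequence has codon
structure, GC skew, homopolymer runs and biological repeat families that
uniform shuffles do not, so passing tests demonstrate the engine's
correctness and calibration on composition-matched targets, not performance
on any particular genome.  The published worked example runs on a real 520 bp
M13 bacteriophage fragment; `scripts/fetch_m13.py` downloads it for users
with network access, while the test suite uses a synthetic 520 bp
GC-balanced stand-in and checks the median oligomer count over twelve seeds
(20), since a single synthetic sequence is not that fragment.

## Numerical and degenerate-input choices

* Ambiguity codes are rejected, not resolved: the thermodynamics are defined
  only for A/C/G/T.
* Coordinates are 0-based half-open internally; the CSV order sheet is
  1-based inclusive, sequences always 5′→3′ on the oligomer's own strand;
  Tm and GC are exported at two decimals and the CSV round-trips through
  `read_design_csv` (a second write is byte-identical).
* A reference shorter than `min_oligo_len` is an input error; one that fits
  in a single oligomer yields a one-oligomer, zero-overlap design.
* Verification is advisory: cross-overlap conflicts are reported sorted by
  severity (shared base pairs, descending) and never fail a design; only a
  reconstruction mismatch gives a nonzero CLI exit.
* `reoptimize` keeps oligomers before the chosen index byte-identical and
  re-runs the same deterministic construction from the fixed left context,
  so re-running with unchanged parameters is a no-op.

## Problem sizes used in the test and acceptance runs

Unit tests run on 45–800 nt synthetic references; the acceptance suite uses
the prescribed sizes — 100 references of 200–2,000 nt at 30–70% GC for the
reconstruction round-trip, 1,000 random 8–40-mers against the Tm oracle, 500
random sequences (≤ 100 nt) against the quadratic repeat oracle, twelve
520 bp references for the worked-example count, and a 600 bp reference for
the overlap-GC band.

## Known limitations

* Greedy left-to-right selection with an exhaustive per-step grid is not
  globally optimal tiling; a dynamic-programming variant is a possible
  extension, deliberately out of scope.
* No Mg²⁺/dNTP salt correction, dangling-end or mismatch thermodynamics.
* No secondary-structure (hairpin/self-dimer ΔG) screening — repeat coverage
  is a sequence-level proxy for self-annealing risk.
* Repeat matching is exact; mismatch-tolerant cross-hybridization is not
  modeled.
* No codon optimization; the input sequence is tiled as given.
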