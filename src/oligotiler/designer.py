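"""Greedy penalty-scored tiling of a target sequence into assembly oligomers.

The target is covered gaplessly by alternating-strand oligomers (odd
ordinals on the top strand, even on the bottom); adjacent oligomers
intersect in an annealing overlap whose duplex Tm drives correct assembly.
At each cursor position every admissible (oligomer length, next-overlap
length) pair is enumerated and scored with the penalty

    score = |T_t - T_c| + 1_T + GC_clamp + R_within + R_between

where T_t/T_c are the target and calculated overlap Tm, 1_T indicates a
3'-terminal thymine on the oligomer's own strand, GC_clamp is the excess of
G/C in the overlap's terminal five bases, and R_within / R_between count
base pairs covered by repeated k-mers inside the oligomer / shared between
junction overlaps.  A theoretically faultless oligomer scores 0.

Candidates whose overlap GC content falls inside the preferred band
(default 40-60%) are preferred; when none qualifies the next-best fit (the
minimum-score candidate overall) is returned rather than failing.  After
tiling, repeat-sharing junctions are segregated into sub-pool clusters and
every oligomer is re-scored with R_between evaluated inside its cluster.

The whole procedure is deterministic: identical inputs give identical
designs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from functools import lru_cache

from . import repeatscan, thermo
from .repeatscan import ClusterPartition, RepeatReport
from .seqio import SequenceRecord, reverse_complement
from .thermo import NNParameterTable, ThermoConditions

#: Shortest admissible final oligomer, expressed as slack beyond the
#: minimum overlap it must still carry.
FINAL_OLIGO_SLACK = 5


class ParameterError(ValueError):
    """Design parameters violate their invariants."""


class DesignError(RuntimeError):
    """The target cannot be tiled under the given parameters."""


@dataclass(frozen=True)
class DesignParams:
    """All user-tunable design knobs.

    Lengths are in nucleotides, temperatures in degrees Celsius.  The
    defaults mirror the published worked-example conditions: oligomers up
    to 50 nt, overlaps 15-20 bp, target overlap Tm 56 degC.  ``tm_tolerance``
    is the half-width of the acceptable Tm window; it only flags oligomers
    as error-prone in reports and never rejects the best candidate.
    """

    max_oligo_len: int = 50
    min_oligo_len: int = 30
    max_overlap_len: int = 20
    min_overlap_len: int = 15
    target_overlap_tm: float = 56.0
    tm_tolerance: float = 2.5
    gc_low: float = 40.0
    gc_high: float = 60.0
    repeat_len_between: int = repeatscan.DEFAULT_REPEAT_LEN_BETWEEN
    repeat_len_within: int = repeatscan.DEFAULT_REPEAT_LEN_WITHIN
    thermo: ThermoConditions = field(default_factory=ThermoConditions)

    def __post_init__(self) -> None:
        if self.min_overlap_len < 5:
            raise ParameterError("min_overlap_len must be >= 5")
        if self.max_overlap_len < self.min_overlap_len:
            raise ParameterError("max_overlap_len must be >= min_overlap_len")
        if self.max_overlap_len >= self.max_oligo_len:
            raise ParameterError("max_overlap_len must be < max_oligo_len")
        if self.min_oligo_len < self.min_overlap_len + 5:
            raise ParameterError("min_oligo_len must be >= min_overlap_len + 5")
        if self.max_oligo_len < self.min_oligo_len:
            raise ParameterError("max_oligo_len must be >= min_oligo_len")
        if self.gc_low >= self.gc_high:
            raise ParameterError("gc_low must be < gc_high")
        if self.tm_tolerance <= 0:
            raise ParameterError("tm_tolerance must be > 0")

    @property
    def min_final_len(self) -> int:
        """Shortest admissible final oligomer."""
        return self.min_overlap_len + FINAL_OLIGO_SLACK


@dataclass(frozen=True)
class Oligomer:
    """One tile of the target: odd ordinals top strand, even bottom.

    ``ref_start``/``ref_end`` are 0-based half-open top-strand coordinates;
    ``sequence`` is the oligomer's own strand 5'->3' (for bottom-strand
    oligomers the reverse complement of the reference slice).
    """

    index: int
    strand: str  # "top" | "bottom"
    ref_start: int
    ref_end: int
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be top|bottom, got {self.strand!r}")
        if self.ref_end - self.ref_start != len(self.sequence):
            raise ValueError(f"oligomer {self.index}: extent and sequence disagree")

    def top_strand_sequence(self) -> str:
        """The oligomer rendered on the top (reference) strand."""
        return (
            self.sequence if self.strand == "top" else reverse_complement(self.sequence)
        )


@dataclass(frozen=True)
class Overlap:
    """Annealing region shared by adjacent oligomers left_index/right_index.

    ``sequence`` is the top-strand rendering of the shared region; ``tm`` is
    the calculated duplex Tm (T_c) and ``gc`` the GC percentage.
    """

    left_index: int
    right_index: int
    ref_start: int
    ref_end: int
    sequence: str
    tm: float
    gc: float


@dataclass(frozen=True)
class ScoreBreakdown:
    """The five penalty components; total is their unweighted sum."""

    tm_dev: float
    three_prime_t: int
    gc_clamp: int
    r_within: int
    r_between: int

    @property
    def total(self) -> float:
        return (
            self.tm_dev
            + self.three_prime_t
            + self.gc_clamp
            + self.r_within
            + self.r_between
        )


@dataclass
class AssemblyDesign:
    """The ordered oligomer set plus scores, clusters and repeat report."""

    reference: SequenceRecord
    params: DesignParams
    oligomers: list[Oligomer]
    overlaps: list[Overlap]
    scores: list[ScoreBreakdown]
    clusters: ClusterPartition
    repeat_report: RepeatReport

    def overlap_after(self, index: int) -> Overlap | None:
        """The overlap between oligomer *index* and its successor."""
        if 1 <= index <= len(self.overlaps):
            return self.overlaps[index - 1]
        return None

    def overlap_before(self, index: int) -> Overlap | None:
        if index >= 2:
            return self.overlaps[index - 2]
        return None

    @property
    def n_oligomers(self) -> int:
        return len(self.oligomers)


# ---------------------------------------------------------------------------
# candidate enumeration and scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    """A scored (oligomer extent, next-overlap extent) choice at a cursor.

    Terminal candidates (the oligomer ends exactly at the reference end)
    have no next overlap; their overlap_tm/gc report the preceding overlap
    the score was evaluated on (NaN for a single-oligomer design).
    """

    oligo_start: int
    oligo_end: int
    overlap_start: int | None
    overlap_end: int | None
    overlap_tm: float
    overlap_gc: float
    score: ScoreBreakdown

    @property
    def oligo_len(self) -> int:
        return self.oligo_end - self.oligo_start


def _own_strand(reference: str, start: int, end: int, ordinal: int) -> str:
    seq = reference[start:end]
    return seq if ordinal % 2 == 1 else reverse_complement(seq)


class _RefScorer:
    """Precomputed per-reference tables for fast candidate scoring.

    All penalty components are exact (they agree with the public
    thermo/repeatscan functions applied to the corresponding slices); the
    tables only remove redundant recomputation from the candidate grid:
    stack enthalpy/entropy and GC prefix sums give O(1) overlap Tm and GC,
    and canonical k-mer arrays give linear-time repeat scans.
    """

    def __init__(self, reference: str, params: DesignParams, table: NNParameterTable):
        self.ref = reference
        self.params = params
        self.table = table
        n = len(reference)
        self.n = n
        self.rc = reverse_complement(reference) if n else ""

        gc_pref = [0] * (n + 1)
        for i, base in enumerate(reference):
            gc_pref[i + 1] = gc_pref[i] + (1 if base in "GC" else 0)
        self.gc_pref = gc_pref

        dimer = {}
        for a in "ACGT":
            for b in "ACGT":
                dimer[a + b] = table.lookup(a + b)
        h_pref = [0.0] * n
        s_pref = [0.0] * n
        for i in range(n - 1):
            dh, ds = dimer[reference[i : i + 2]]
            h_pref[i + 1] = h_pref[i] + dh
            s_pref[i + 1] = s_pref[i] + ds
        self.h_pref = h_pref
        self.s_pref = s_pref

        self._canon_between = self._canonical_array(params.repeat_len_between)
        self._canon_within = self._canonical_array(params.repeat_len_within)
        self._rwithin_cache: dict[tuple[int, int], int] = {}

        import math as _math

        cond = params.thermo
        self._log_ct4 = thermo.GAS_CONSTANT * _math.log(cond.oligo_conc / 4.0)
        self._log_ct1 = thermo.GAS_CONSTANT * _math.log(cond.oligo_conc)
        self._salt_term = 16.6 * _math.log10(cond.monovalent_salt)

    def _canonical_array(self, k: int) -> list[str]:
        n = self.n
        if n < k:
            return []
        ref, rc = self.ref, self.rc
        return [
            min(ref[i : i + k], rc[n - i - k : n - i]) for i in range(n - k + 1)
        ]

    # -- thermodynamics ---------------------------------------------------
    def tm(self, s: int, e: int) -> float:
        ref = self.ref
        dh = self.h_pref[e - 1] - self.h_pref[s]
        ds = self.s_pref[e - 1] - self.s_pref[s]
        for terminal in (ref[s], ref[e - 1]):
            ih, is_ = (
                self.table.init_gc if terminal in "GC" else self.table.init_at
            )
            dh += ih
            ds += is_
        if ref[s:e] == self.rc[self.n - e : self.n - s]:  # self-complementary
            dh += self.table.symmetry[0]
            ds += self.table.symmetry[1]
            log_term = self._log_ct1
        else:
            log_term = self._log_ct4
        return 1000.0 * dh / (ds + log_term) - 273.15 + self._salt_term

    def gc(self, s: int, e: int) -> float:
        return 100.0 * (self.gc_pref[e] - self.gc_pref[s]) / (e - s)

    # -- sequence rules ---------------------------------------------------
    def three_prime_t(self, s: int, e: int, ordinal: int) -> int:
        # own-strand 3' terminus: top = last reference base, bottom = the
        # complement of the first reference base.
        if ordinal % 2 == 1:
            return 1 if self.ref[e - 1] == "T" else 0
        return 1 if self.ref[s] == "A" else 0

    def gc_clamp(self, s: int, e: int, ordinal: int) -> int:
        # terminal 5 bases of the overlap in the oligomer's own orientation;
        # GC counts are strand-symmetric, only the window end differs.
        w = thermo.GC_CLAMP_WINDOW
        if ordinal % 2 == 1:
            count = self.gc_pref[e] - self.gc_pref[e - w]
        else:
            count = self.gc_pref[s + w] - self.gc_pref[s]
        return max(0, count - thermo.GC_CLAMP_ALLOWANCE)

    # -- repeats ----------------------------------------------------------
    def r_within(self, s: int, e: int) -> int:
        cached = self._rwithin_cache.get((s, e))
        if cached is not None:
            return cached
        k = self.params.repeat_len_within
        length = e - s
        result = 0
        if length >= k + 1:
            window = self._canon_within[s : e - k + 1]
            counts: dict[str, int] = {}
            for key in window:
                counts[key] = counts.get(key, 0) + 1
            if any(c >= 2 for c in counts.values()):
                covered = [False] * length
                for offset, key in enumerate(window):
                    if counts[key] >= 2:
                        for pos in range(offset, offset + k):
                            covered[pos] = True
                result = sum(covered)
        self._rwithin_cache[(s, e)] = result
        return result

    def overlap_kmers(self, s: int, e: int) -> list[str]:
        k = self.params.repeat_len_between
        if e - s < k:
            return []
        return self._canon_between[s : e - k + 1]

    def r_between(
        self,
        s: int,
        e: int,
        earlier_index: dict[str, set[int]],
        earlier_extents: list[tuple[int, int]],
    ) -> int:
        """Summed shared-repeat coverage of overlap [s, e) against each
        earlier junction whose k-mer index it hits."""
        hits: set[int] = set()
        for key in self.overlap_kmers(s, e):
            found = earlier_index.get(key)
            if found:
                hits.update(found)
        if not hits:
            return 0
        k = self.params.repeat_len_between
        seq = self.ref[s:e]
        return sum(
            repeatscan.shared_repeat_bp(
                seq, self.ref[cs:ce], k
            )
            for j, (cs, ce) in enumerate(earlier_extents)
            if j in hits
        )

    def score(
        self,
        ordinal: int,
        oligo_start: int,
        oligo_end: int,
        scored_overlap: tuple[int, int] | None,
        earlier_index: dict[str, set[int]] | None = None,
        earlier_extents: list[tuple[int, int]] | None = None,
    ) -> tuple[ScoreBreakdown, float, float]:
        """Penalty components for one candidate.

        ``scored_overlap`` is the overlap the Tm/clamp terms are evaluated
        on (the candidate's next overlap; for the terminal oligomer its
        preceding overlap).  ``earlier_*`` describe the committed junctions
        at index distance >= 2, against which the first-pass R_between of
        the candidate overlap is counted.
        """
        if scored_overlap is None:
            tm_dev, clamp = 0.0, 0
            ov_tm = ov_gc = float("nan")
            r_between = 0
        else:
            s, e = scored_overlap
            ov_tm = self.tm(s, e)
            ov_gc = self.gc(s, e)
            tm_dev = abs(self.params.target_overlap_tm - ov_tm)
            clamp = self.gc_clamp(s, e, ordinal)
            r_between = (
                self.r_between(s, e, earlier_index, earlier_extents)
                if earlier_index
                else 0
            )
        score = ScoreBreakdown(
            tm_dev=tm_dev,
            three_prime_t=self.three_prime_t(oligo_start, oligo_end, ordinal),
            gc_clamp=clamp,
            r_within=self.r_within(oligo_start, oligo_end),
            r_between=r_between,
        )
        return score, ov_tm, ov_gc


def _earlier_index(
    scorer: _RefScorer, earlier_extents: list[tuple[int, int]]
) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for j, (s, e) in enumerate(earlier_extents):
        for key in scorer.overlap_kmers(s, e):
            index.setdefault(key, set()).add(j)
    return index


def enumerate_candidates(
    reference: str,
    cursor: int,
    params: DesignParams,
    prev_overlap_end: int = 0,
    *,
    ordinal: int = 1,
    committed_overlaps: list[tuple[int, int]] | None = None,
    table: NNParameterTable = thermo.DEFAULT_NN_TABLE,
    scorer: "_RefScorer | None" = None,
) -> list[Candidate]:
    """All scored (length, next-overlap) choices at *cursor*.

    Exhaustive over oligomer lengths L in [min_oligo_len, max_oligo_len] and
    next-overlap lengths V in [min_overlap_len, max_overlap_len] with V < L
    and the oligomer inside the reference.  An oligomer reaching exactly the
    reference end is emitted as a terminal candidate (no next overlap, and
    admitted down to min_overlap_len + 5 nt); its Tm/clamp terms are
    evaluated on the preceding overlap [cursor, prev_overlap_end).
    """
    if scorer is None:
        scorer = _RefScorer(reference, params, table)
    n = len(reference)
    if cursor >= n:
        raise DesignError(f"cursor {cursor} beyond reference end {n}")
    committed = committed_overlaps or []
    # committed junctions are 1..ordinal-1; the candidate junction is
    # `ordinal`, so only junctions up to ordinal-2 (distance >= 2) count.
    earlier = committed[:-1] if committed else []
    earlier_index = _earlier_index(scorer, earlier) if earlier else None
    prev_overlap = (cursor, prev_overlap_end) if prev_overlap_end > cursor else None
    prev_v = prev_overlap_end - cursor

    candidates: list[Candidate] = []
    rem = n - cursor
    # terminal candidate: covers the remainder exactly
    if rem <= params.max_oligo_len and rem >= params.min_final_len and rem > prev_v:
        score, _, _ = scorer.score(ordinal, cursor, n, prev_overlap)
        if prev_overlap is not None:
            s, e = prev_overlap
            ov_tm = scorer.tm(s, e)
            ov_gc = scorer.gc(s, e)
        else:
            ov_tm = ov_gc = float("nan")
        candidates.append(
            Candidate(
                oligo_start=cursor,
                oligo_end=n,
                overlap_start=None,
                overlap_end=None,
                overlap_tm=ov_tm,
                overlap_gc=ov_gc,
                score=score,
            )
        )
    for length in range(params.min_oligo_len, params.max_oligo_len + 1):
        end = cursor + length
        if end >= n:
            break  # the exact-fit case was handled as terminal above
        if end <= prev_overlap_end:
            continue  # must extend past the previous oligomer
        for v in range(params.min_overlap_len, params.max_overlap_len + 1):
            if v >= length:
                break
            ov_extent = (end - v, end)
            score, ov_tm, ov_gc = scorer.score(
                ordinal, cursor, end, ov_extent, earlier_index, earlier
            )
            candidates.append(
                Candidate(
                    oligo_start=cursor,
                    oligo_end=end,
                    overlap_start=ov_extent[0],
                    overlap_end=ov_extent[1],
                    overlap_tm=ov_tm,
                    overlap_gc=ov_gc,
                    score=score,
                )
            )
    return candidates


# ---------------------------------------------------------------------------
# terminal-feasibility guard
# ---------------------------------------------------------------------------


def _feasibility(params: DesignParams):
    """Memoized test that a reference suffix can still be tiled.

    ``feasible(rem, prev_v)`` is true when a suffix of length *rem* can be
    covered by oligomers obeying the length windows, given that the next
    oligomer must extend strictly past the already-fixed overlap of length
    *prev_v*, and the final oligomer must be at least min_overlap_len + 5
    long.  Used to reject greedy choices that would strand an untileable
    remainder (effectively redistributing length into the last steps).
    """

    @lru_cache(maxsize=None)
    def feasible(rem: int, prev_v: int) -> bool:
        if rem <= 0:
            return False
        if rem <= params.max_oligo_len and rem >= params.min_final_len and rem > prev_v:
            return True
        for length in range(params.min_oligo_len, params.max_oligo_len + 1):
            if length <= prev_v or length >= rem:
                continue
            for v in range(params.min_overlap_len, params.max_overlap_len + 1):
                if v >= length:
                    break
                if feasible(rem - (length - v), v):
                    return True
        return False

    return feasible


# ---------------------------------------------------------------------------
# greedy construction
# ---------------------------------------------------------------------------


def _select(candidates: list[Candidate], params: DesignParams) -> Candidate:
    """Pick the winning candidate.

    Candidates whose overlap GC lies in [gc_low, gc_high] are preferred;
    when none does, the next-best fit is taken from the full set.  Within
    the chosen pool the minimum penalty total wins.  Penalty totals within
    ``tm_tolerance`` of the minimum are treated as equivalent (a score gap
    smaller than the acceptable Tm half-width is not meaningful), and such
    ties break toward the longer oligomer — fewer oligomers per assembly —
    then the smaller total, the overlap Tm closest to target, and the
    smaller overlap start.
    """

    def gc_suitable(c: Candidate) -> bool:
        if c.overlap_start is None:
            return True  # terminal candidates add no new overlap to judge
        return params.gc_low <= c.overlap_gc <= params.gc_high

    pool = [c for c in candidates if gc_suitable(c)] or candidates
    best_total = min(c.score.total for c in pool)
    near = [c for c in pool if c.score.total <= best_total + params.tm_tolerance]

    def key(c: Candidate):
        tm_gap = (
            abs(c.overlap_tm - params.target_overlap_tm)
            if not math.isnan(c.overlap_tm)
            else 0.0
        )
        return (
            -c.oligo_len,
            c.score.total,
            tm_gap,
            c.overlap_start if c.overlap_start is not None else -1,
        )

    return min(near, key=key)


def _tile(
    reference: str,
    params: DesignParams,
    table: NNParameterTable,
    *,
    extents: list[tuple[int, int]] | None = None,
    junctions: list[tuple[int, int]] | None = None,
    cursor: int = 0,
    prev_overlap_end: int = 0,
    ordinal: int = 1,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Greedy left-to-right tiling, optionally continuing a fixed prefix.

    Returns (oligomer extents, junction overlap extents), 0-based half-open
    on the top strand.
    """
    n = len(reference)
    feasible = _feasibility(params)
    scorer = _RefScorer(reference, params, table)
    extents = list(extents or [])
    junctions = list(junctions or [])
    while True:
        candidates = enumerate_candidates(
            reference,
            cursor,
            params,
            prev_overlap_end,
            ordinal=ordinal,
            committed_overlaps=junctions,
            table=table,
            scorer=scorer,
        )
        viable = []
        for c in candidates:
            if c.overlap_start is None:
                viable.append(c)  # terminal: ends the tiling
                continue
            rem = n - c.overlap_start  # suffix the next oligomer must cover
            if feasible(rem, c.overlap_end - c.overlap_start):
                viable.append(c)
        if not viable:
            raise DesignError(
                f"no admissible oligomer at position {cursor}: the remainder "
                "cannot be tiled under the given length windows"
            )
        best = _select(viable, params)
        extents.append((best.oligo_start, best.oligo_end))
        if best.overlap_start is None:
            return extents, junctions
        junctions.append((best.overlap_start, best.overlap_end))
        prev_overlap_end = best.oligo_end
        cursor = best.overlap_start
        ordinal += 1


def _cluster_r_between(
    overlap_seqs: list[str], clusters: ClusterPartition, k: int
) -> list[int]:
    """Per-junction shared-repeat coverage, scoped to the final clusters."""
    per_junction = [0] * len(overlap_seqs)
    for first, last in clusters.groups:
        members = [j for j in range(first, last) if 1 <= j <= len(overlap_seqs)]
        for j in members:
            total = 0
            for m in members:
                if abs(j - m) >= 2:
                    total += repeatscan.shared_repeat_bp(
                        overlap_seqs[j - 1], overlap_seqs[m - 1], k
                    )
            per_junction[j - 1] = total
    return per_junction


def _assembly_conflicts(overlap_seqs: list[str], k: int) -> list[tuple[int, int, str]]:
    pairs: list[tuple[int, int, str]] = []
    for j in range(1, len(overlap_seqs) + 1):
        for m in range(j + 2, len(overlap_seqs) + 1):
            for kmer in sorted(
                repeatscan.shared_kmers(overlap_seqs[j - 1], overlap_seqs[m - 1], k)
            ):
                pairs.append((j, m, kmer))
    return pairs


def _finalize(
    reference: SequenceRecord,
    params: DesignParams,
    extents: list[tuple[int, int]],
    junctions: list[tuple[int, int]],
    table: NNParameterTable,
) -> AssemblyDesign:
    """Build oligomer/overlap objects, segregate clusters and re-score."""
    ref = reference.residues
    oligomers = [
        Oligomer(
            index=i,
            strand="top" if i % 2 == 1 else "bottom",
            ref_start=s,
            ref_end=e,
            sequence=_own_strand(ref, s, e, i),
            name=f"{reference.id}_oligo_{i:03d}",
        )
        for i, (s, e) in enumerate(extents, start=1)
    ]
    overlaps = []
    for j, (s, e) in enumerate(junctions, start=1):
        seq = ref[s:e]
        overlaps.append(
            Overlap(
                left_index=j,
                right_index=j + 1,
                ref_start=s,
                ref_end=e,
                sequence=seq,
                tm=thermo.melting_temperature(seq, params.thermo, table),
                gc=thermo.gc_content(seq),
            )
        )

    overlap_seqs = [o.sequence for o in overlaps]
    k = params.repeat_len_between
    clusters = (
        repeatscan.segregate(overlap_seqs, k)
        if overlaps
        else ClusterPartition(groups=[(1, len(oligomers))])
    )
    junction_between = _cluster_r_between(overlap_seqs, clusters, k)
    conflict_pairs = _assembly_conflicts(overlap_seqs, k)

    n = len(oligomers)
    scores: list[ScoreBreakdown] = []
    r_within_list: list[int] = []
    r_between_list: list[int] = []
    for oligo in oligomers:
        if oligo.index < n:
            scored_ov = overlaps[oligo.index - 1]
        else:
            scored_ov = overlaps[-1] if overlaps else None
        if scored_ov is None:
            tm_dev, clamp = 0.0, 0
        else:
            tm_dev = abs(params.target_overlap_tm - scored_ov.tm)
            ov_own = (
                scored_ov.sequence
                if oligo.strand == "top"
                else reverse_complement(scored_ov.sequence)
            )
            clamp = thermo.gc_clamp_excess(ov_own)
        r_within = repeatscan.repeats_within(oligo.sequence, params.repeat_len_within)
        # R_between inside the final cluster: this oligomer's junctions,
        # counted only when the junction lies wholly within its cluster.
        r_between = 0
        cid = clusters.cluster_of(oligo.index)
        for j in (oligo.index - 1, oligo.index):
            if 1 <= j <= len(overlaps):
                if clusters.cluster_of(j) == clusters.cluster_of(j + 1) == cid:
                    r_between += junction_between[j - 1]
        scores.append(
            ScoreBreakdown(
                tm_dev=tm_dev,
                three_prime_t=thermo.three_prime_thymine(oligo.sequence),
                gc_clamp=clamp,
                r_within=r_within,
                r_between=r_between,
            )
        )
        r_within_list.append(r_within)
        r_between_list.append(r_between)

    report = RepeatReport(
        r_within=r_within_list,
        r_between=r_between_list,
        conflict_pairs=conflict_pairs,
    )
    return AssemblyDesign(
        reference=reference,
        params=params,
        oligomers=oligomers,
        overlaps=overlaps,
        scores=scores,
        clusters=clusters,
        repeat_report=report,
    )


def design(
    reference: SequenceRecord,
    params: DesignParams | None = None,
    *,
    table: NNParameterTable = thermo.DEFAULT_NN_TABLE,
) -> AssemblyDesign:
    """Design the full alternating-strand oligomer set for *reference*."""
    params = params if params is not None else DesignParams()
    if len(reference) < params.min_oligo_len:
        raise ValueError(
            f"reference ({len(reference)} nt) shorter than min_oligo_len "
            f"({params.min_oligo_len} nt)"
        )
    extents, junctions = _tile(reference.residues, params, table)
    return _finalize(reference, params, extents, junctions, table)


def score_oligomer(
    oligo: Oligomer,
    next_overlap: Overlap | None,
    all_overlaps: list[Overlap],
    params: DesignParams,
    *,
    prev_overlap: Overlap | None = None,
    table: NNParameterTable = thermo.DEFAULT_NN_TABLE,
) -> ScoreBreakdown:
    """Penalty breakdown for a single oligomer.

    Tm-deviation and GC-clamp terms are evaluated on *next_overlap*; the
    final oligomer (next_overlap None) is evaluated on *prev_overlap*
    instead.  R_between counts shared-repeat coverage of the oligomer's
    junction overlap(s) against every non-adjacent overlap in
    *all_overlaps* (pass the overlaps of its cluster to score within a
    cluster, or of the whole assembly for a first-pass score).
    """
    scored = next_overlap if next_overlap is not None else prev_overlap
    if scored is None:
        tm_dev, clamp = 0.0, 0
    else:
        tm_dev = abs(params.target_overlap_tm - scored.tm)
        ov_own = (
            scored.sequence
            if oligo.strand == "top"
            else reverse_complement(scored.sequence)
        )
        clamp = thermo.gc_clamp_excess(ov_own)
    k = params.repeat_len_between
    r_between = 0
    own_junctions = [ov for ov in (prev_overlap, next_overlap) if ov is not None]
    for junction in own_junctions:
        for other in all_overlaps:
            if abs(other.left_index - junction.left_index) >= 2:
                r_between += repeatscan.shared_repeat_bp(
                    junction.sequence, other.sequence, k
                )
    return ScoreBreakdown(
        tm_dev=tm_dev,
        three_prime_t=thermo.three_prime_thymine(oligo.sequence),
        gc_clamp=clamp,
        r_within=repeatscan.repeats_within(oligo.sequence, params.repeat_len_within),
        r_between=r_between,
    )


def reoptimize(
    design_: AssemblyDesign, index: int, overrides: dict | None = None
) -> AssemblyDesign:
    """Re-design oligomers ``index..n`` keeping 1..index-1 fixed.

    *overrides* is a partial set of :class:`DesignParams` fields (lengths,
    Tm bounds...); the merged parameters must satisfy the usual invariants.
    The input design is not modified.
    """
    n = design_.n_oligomers
    if not 1 <= index <= n:
        raise IndexError(f"oligomer index {index} out of range 1..{n}")
    try:
        params = (
            dataclasses.replace(design_.params, **overrides)
            if overrides
            else design_.params
        )
    except TypeError as exc:
        raise ParameterError(str(exc)) from None

    table = thermo.DEFAULT_NN_TABLE
    if index == 1:
        kept_extents: list[tuple[int, int]] = []
        kept_junctions: list[tuple[int, int]] = []
        cursor = prev_overlap_end = 0
    else:
        kept_extents = [(o.ref_start, o.ref_end) for o in design_.oligomers[: index - 1]]
        kept_junctions = [
            (ov.ref_start, ov.ref_end) for ov in design_.overlaps[: index - 1]
        ]
        cursor = design_.oligomers[index - 1].ref_start
        prev_overlap_end = design_.oligomers[index - 2].ref_end
    extents, junctions = _tile(
        design_.reference.residues,
        params,
        table,
        extents=kept_extents,
        junctions=kept_junctions,
        cursor=cursor,
        prev_overlap_end=prev_overlap_end,
        ordinal=index,
    )
    return _finalize(design_.reference, params, extents, junctions, table)
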