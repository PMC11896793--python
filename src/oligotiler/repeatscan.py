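"""Repeat detection and sub-pool segregation.

Mis-annealing happens between complementary strands, so every k-mer is
identified with its reverse complement (the *canonical* key).  Two kinds of
repeat risk are measured:

* within an oligomer — a k-mer whose canonical key occurs twice inside the
  same oligomer can fold back or self-anneal;
* between overlaps — two junction overlaps sharing a canonical k-mer can
  cross-hybridize during assembly and scramble the junction order.

Counts are reported as *base pairs covered* by risky k-mers, so the penalty
scales with the length of the dangerous region.  Consecutive oligomers are
segregated into clusters (sub-pools) such that no two non-adjacent overlaps
within a cluster share a canonical k-mer of the configured length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import reverse_complement, validate_dna

DEFAULT_REPEAT_LEN_BETWEEN = 10
DEFAULT_REPEAT_LEN_WITHIN = 8


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _canonical_kmers(seq: str, k: int) -> list[str]:
    return [canonical_kmer(seq[i : i + k]) for i in range(len(seq) - k + 1)]


def _check_k(k: int) -> None:
    if k < 2:
        raise ValueError(f"repeat length k must be >= 2, got {k}")


def repeats_within(seq: str, k: int = DEFAULT_REPEAT_LEN_WITHIN) -> int:
    """Bases of *seq* covered by a k-mer occurring >= 2 times (canonically).

    A k-mer and its reverse complement count as the same key, so a motif
    followed elsewhere by its complement is flagged just like a direct
    repeat.
    """
    _check_k(k)
    seq = validate_dna(seq)
    if len(seq) < k + 1:
        return 0
    keys = _canonical_kmers(seq, k)
    counts: dict[str, int] = {}
    for key in keys:
        counts[key] = counts.get(key, 0) + 1
    covered = [False] * len(seq)
    for start, key in enumerate(keys):
        if counts[key] >= 2:
            for pos in range(start, start + k):
                covered[pos] = True
    return sum(covered)


def shared_repeat_bp(
    overlap_a: str, overlap_b: str, k: int = DEFAULT_REPEAT_LEN_BETWEEN
) -> int:
    """Bases of *overlap_a* covered by a canonical k-mer also in *overlap_b*.

    Symmetric in which k-mers are shared; the position count is reported for
    the first argument.
    """
    _check_k(k)
    overlap_a = validate_dna(overlap_a)
    overlap_b = validate_dna(overlap_b)
    if len(overlap_a) < k or len(overlap_b) < k:
        return 0
    keys_b = set(_canonical_kmers(overlap_b, k))
    covered = [False] * len(overlap_a)
    for start in range(len(overlap_a) - k + 1):
        if canonical_kmer(overlap_a[start : start + k]) in keys_b:
            for pos in range(start, start + k):
                covered[pos] = True
    return sum(covered)


def shared_kmers(overlap_a: str, overlap_b: str, k: int) -> set[str]:
    """Canonical k-mers present in both overlaps."""
    _check_k(k)
    if len(overlap_a) < k or len(overlap_b) < k:
        return set()
    return set(_canonical_kmers(overlap_a, k)) & set(_canonical_kmers(overlap_b, k))


@dataclass(frozen=True)
class RepeatReport:
    """Per-oligomer repeat statistics for a design.

    ``conflict_pairs`` lists non-adjacent junctions whose overlaps share a
    canonical k-mer, as (left oligomer ordinal of junction A, left oligomer
    ordinal of junction B, shared k-mer).
    """

    r_within: list[int]
    r_between: list[int]
    conflict_pairs: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.r_within) or any(v < 0 for v in self.r_between):
            raise ValueError("repeat counts must be non-negative")
        for a, b, _ in self.conflict_pairs:
            if abs(a - b) < 2:
                raise ValueError(
                    "conflict pairs must involve non-adjacent junctions "
                    f"(got {a} and {b})"
                )


@dataclass(frozen=True)
class ClusterPartition:
    """Ordered partition of oligomers 1..n into contiguous clusters.

    ``groups`` holds 1-based inclusive (first, last) oligomer ordinals;
    groups are consecutive, disjoint and cover every oligomer exactly once.
    """

    groups: list[tuple[int, int]]

    def __post_init__(self) -> None:
        expected_start = 1
        for first, last in self.groups:
            if first != expected_start or last < first:
                raise ValueError(f"groups are not contiguous at oligomer {first}")
            expected_start = last + 1

    @property
    def n_oligomers(self) -> int:
        return self.groups[-1][1] if self.groups else 0

    def cluster_of(self, index: int) -> int:
        """1-based cluster id of oligomer *index*."""
        for cid, (first, last) in enumerate(self.groups, start=1):
            if first <= index <= last:
                return cid
        raise IndexError(f"oligomer {index} not covered by partition")


def segregate(
    overlaps: list[str], k: int = DEFAULT_REPEAT_LEN_BETWEEN
) -> ClusterPartition:
    """Greedy left-to-right segregation of n = len(overlaps)+1 oligomers.

    The current cluster is extended while no non-adjacent overlap pair
    inside it shares a canonical k-mer; at the first violation a new cluster
    starts at the left oligomer of the offending junction, so the conflicting
    overlap lies wholly in the new cluster.
    """
    _check_k(k)
    n = len(overlaps) + 1
    if n == 1:
        return ClusterPartition(groups=[(1, 1)])
    kmer_sets = [
        set(_canonical_kmers(validate_dna(ov), k)) if len(ov) >= k else set()
        for ov in overlaps
    ]
    groups: list[tuple[int, int]] = []
    group_start = 1
    for i in range(2, n + 1):
        # adding oligomer i brings junction i-1 (1-based overlap index)
        j = i - 1
        conflict = any(
            kmer_sets[j - 1] & kmer_sets[m - 1]
            for m in range(group_start, j - 1)  # |j - m| >= 2 within the group
        )
        if conflict:
            groups.append((group_start, j - 1))
            group_start = j
    groups.append((group_start, n))
    return ClusterPartition(groups=groups)
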