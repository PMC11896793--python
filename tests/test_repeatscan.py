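"""Canonical k-mer repeat detection and cluster segregation.

The oracle here is a quadratic all-pairs substring comparison that knows
nothing about the package's hashing of canonical keys.
"""

import random

import pytest

from oligotiler import (
    ClusterPartition,
    RepeatReport,
    repeats_within,
    segregate,
    shared_repeat_bp,
)

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(seq):
    return seq.translate(_COMP)[::-1]


def oracle_repeats_within(seq, k):
    """Position coverage by k-mers occurring twice, O(n^2) comparisons."""
    n = len(seq)
    covered = set()
    for a in range(n - k + 1):
        kmer_a = seq[a : a + k]
        for b in range(n - k + 1):
            if b == a:
                continue
            kmer_b = seq[b : b + k]
            if kmer_a == kmer_b or kmer_a == _rc(kmer_b):
                covered.update(range(a, a + k))
                break
    return len(covered)


def oracle_shared_bp(seq_a, seq_b, k):
    covered = set()
    for a in range(len(seq_a) - k + 1):
        kmer_a = seq_a[a : a + k]
        for b in range(len(seq_b) - k + 1):
            kmer_b = seq_b[b : b + k]
            if kmer_a == kmer_b or kmer_a == _rc(kmer_b):
                covered.update(range(a, a + k))
                break
    return len(covered)


def random_seq(rng, lo, hi):
    return "".join(rng.choice("ACGT") for _ in range(rng.randint(lo, hi)))


class TestRepeatsWithin:
    def test_tandem_four_mer_covers_everything(self):
        assert repeats_within("ACGTACGT", k=4) == 8

    def test_reverse_complement_halves_share_a_key(self):
        # AAAAA and TTTTT collapse to one canonical 5-mer
        assert repeats_within("AAAAATTTTT", k=5) == 10

    def test_distinct_kmers_give_zero(self):
        rng = random.Random(0)
        for _ in range(20):
            seq = random_seq(rng, 30, 50)
            if oracle_repeats_within(seq, 10) == 0:
                assert repeats_within(seq, 10) == 0

    def test_matches_quadratic_oracle(self):
        rng = random.Random(42)
        for _ in range(150):
            seq = random_seq(rng, 10, 100)
            k = rng.randint(2, 10)
            assert repeats_within(seq, k) == oracle_repeats_within(seq, k), (seq, k)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            repeats_within("ACGT", k=1)


class TestSharedRepeatBp:
    def test_identical_overlaps_fully_covered(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert shared_repeat_bp(seq, seq, k=10) == 20

    def test_planted_motif_coverage(self):
        rng = random.Random(1)
        motif = "GGATCCGGATC"  # 11 bp: two overlapping canonical 10-mers
        while True:
            a = random_seq(rng, 40, 40)
            b = random_seq(rng, 40, 40)
            a_planted = a[:10] + motif + a[21:]
            b_planted = b[:20] + motif + b[31:]
            if (
                oracle_shared_bp(a_planted, b_planted, 10) == 11
            ):  # no accidental extra sharing
                assert shared_repeat_bp(a_planted, b_planted, k=10) == 11
                break

    def test_matches_quadratic_oracle(self):
        rng = random.Random(43)
        for _ in range(100):
            a = random_seq(rng, 10, 80)
            b = random_seq(rng, 10, 80)
            k = rng.randint(2, 10)
            assert shared_repeat_bp(a, b, k) == oracle_shared_bp(a, b, k)

    def test_no_common_kmer_gives_zero(self):
        assert shared_repeat_bp("A" * 20, "G" * 20, k=10) == 0


class TestSegregate:
    def test_distinct_overlaps_single_group(self):
        rng = random.Random(9)
        overlaps = []
        while len(overlaps) < 6:
            cand = random_seq(rng, 20, 20)
            if all(oracle_shared_bp(cand, o, 10) == 0 for o in overlaps):
                overlaps.append(cand)
        part = segregate(overlaps, k=10)
        assert part.groups == [(1, 7)]

    def test_conflict_between_overlaps_1_and_3_splits_before_3(self):
        rng = random.Random(10)
        motif = "GGATCCGGAT"
        base = [random_seq(rng, 20, 20) for _ in range(4)]
        base[0] = motif + base[0][10:]
        base[2] = base[2][:10] + motif
        # ensure no other accidental conflicts
        assert oracle_shared_bp(base[0], base[2], 10) > 0
        part = segregate(base, k=10)
        assert part.groups[0] == (1, 2)
        assert part.groups[1][0] == 3

    def test_single_oligomer(self):
        assert segregate([], k=10).groups == [(1, 1)]

    def test_partition_property_no_shared_kmers_within_groups(self):
        """Defining property: recomputing shared bp over all non-adjacent
        pairs within every group yields zero."""
        rng = random.Random(11)
        for _ in range(20):
            overlaps = [random_seq(rng, 18, 22) for _ in range(12)]
            # plant a few conflicts
            for _ in range(rng.randint(0, 3)):
                i, j = rng.sample(range(12), 2)
                overlaps[j] = overlaps[i][:10] + overlaps[j][10:]
            part = segregate(overlaps, k=10)
            for first, last in part.groups:
                members = [j for j in range(first, last) if j <= len(overlaps)]
                for x in members:
                    for y in members:
                        if abs(x - y) >= 2:
                            assert (
                                shared_repeat_bp(
                                    overlaps[x - 1], overlaps[y - 1], 10
                                )
                                == 0
                            )

    def test_never_splits_without_conflict(self):
        """A group boundary implies the first overlap of the new group
        conflicts with an overlap of the previous group."""
        rng = random.Random(12)
        overlaps = [random_seq(rng, 20, 20) for _ in range(10)]
        overlaps[5] = overlaps[1][:10] + overlaps[5][10:]
        part = segregate(overlaps, k=10)
        for (f1, l1), (f2, _) in zip(part.groups, part.groups[1:]):
            j = f2  # first junction wholly inside the new group
            assert any(
                oracle_shared_bp(overlaps[j - 1], overlaps[m - 1], 10) > 0
                for m in range(f1, j - 1)
            )


class TestReportTypes:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            RepeatReport(r_within=[-1], r_between=[0])

    def test_adjacent_conflict_pairs_rejected(self):
        with pytest.raises(ValueError):
            RepeatReport(
                r_within=[0], r_between=[0], conflict_pairs=[(1, 2, "ACGTACGTAC")]
            )

    def test_partition_must_be_contiguous(self):
        with pytest.raises(ValueError):
            ClusterPartition(groups=[(1, 2), (4, 5)])
        assert ClusterPartition(groups=[(1, 2), (3, 5)]).cluster_of(4) == 2
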