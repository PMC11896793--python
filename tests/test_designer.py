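"""The greedy tiling engine: scoring, enumeration, design, re-design."""

import dataclasses
import math

import pytest

from oligotiler import (
    DesignParams,
    ParameterError,
    ScoreBreakdown,
    design,
    enumerate_candidates,
    fixtures,
    reoptimize,
    score_oligomer,
)
from oligotiler.verify import reconstruct


def make_ref(length, seed, gc=50.0):
    return fixtures.random_sequence(
        fixtures.FixtureSpec(length=length, seed=seed, gc_target=gc)
    )


class TestDesignParams:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"min_overlap_len": 3},
            {"max_overlap_len": 10},
            {"max_overlap_len": 60},
            {"min_oligo_len": 18},
            {"gc_low": 70.0},
            {"tm_tolerance": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, overrides):
        with pytest.raises(ParameterError):
            DesignParams(**overrides)


class TestScoreBreakdown:
    def test_total_is_sum_of_components(self):
        s = ScoreBreakdown(
            tm_dev=1.5, three_prime_t=1, gc_clamp=2, r_within=3, r_between=4
        )
        assert s.total == pytest.approx(11.5)

    def test_zero_iff_all_components_zero(self):
        zero = ScoreBreakdown(0.0, 0, 0, 0, 0)
        assert zero.total == 0.0
        nonzero = ScoreBreakdown(0.0, 1, 0, 0, 0)
        assert nonzero.total > 0.0


class TestScoreOligomer:
    def test_two_degree_deviation_plus_terminal_thymine_scores_three(self):
        """Direct substitution: tm_dev 2 + 1_T 1 with clean other terms."""
        for seed in range(1, 30):
            d = design(make_ref(400, seed))
            for oligo, ov in zip(d.oligomers[:-1], d.overlaps):
                base = score_oligomer(oligo, ov, [], d.params)
                if (
                    oligo.sequence.endswith("T")
                    and base.gc_clamp == 0
                    and base.r_within == 0
                ):
                    shifted = dataclasses.replace(
                        d.params, target_overlap_tm=ov.tm + 2
                    )
                    score = score_oligomer(oligo, ov, [], shifted)
                    assert score.total == pytest.approx(3.0)
                    return
        raise AssertionError("no clean 3'-T oligomer found across seeds")

    def test_duplicated_eight_mer_costs_its_coverage(self, default_design):
        """An oligomer carrying a duplicated 8-mer pays r_within equal to
        the covered bases (16 for two disjoint copies)."""
        from oligotiler.designer import Oligomer

        seq = "ATGCATTG" + "CCGA" + "ATGCATTG" + "ACCGTAACGT"
        oligo = Oligomer(
            index=1, strand="top", ref_start=0, ref_end=len(seq), sequence=seq
        )
        score = score_oligomer(oligo, None, [], default_design.params)
        assert score.r_within == 16

    def test_final_oligomer_scored_on_preceding_overlap(self, default_design):
        d = default_design
        last = d.oligomers[-1]
        prev = d.overlaps[-1]
        score = score_oligomer(last, None, [], d.params, prev_overlap=prev)
        assert score.tm_dev == pytest.approx(
            abs(d.params.target_overlap_tm - prev.tm)
        )


class TestEnumerateCandidates:
    def test_grid_cardinality(self):
        ref = make_ref(200, 3).residues
        params = DesignParams(
            min_oligo_len=40, max_oligo_len=50, min_overlap_len=15, max_overlap_len=20
        )
        cands = enumerate_candidates(ref, 0, params)
        assert len(cands) == 11 * 6

    def test_terminal_candidate_when_only_final_fits(self):
        ref = make_ref(200, 3).residues
        params = DesignParams(
            min_oligo_len=40, max_oligo_len=50, min_overlap_len=15, max_overlap_len=20
        )
        # cursor so that the remainder (45 nt) can only be the last oligomer
        cands = enumerate_candidates(ref, 155, params, prev_overlap_end=175)
        terminal = [c for c in cands if c.overlap_start is None]
        assert terminal and terminal[0].oligo_end == 200

    def test_all_scores_finite(self):
        ref = make_ref(200, 4).residues
        for c in enumerate_candidates(ref, 0, DesignParams()):
            assert math.isfinite(c.score.total)

    def test_widening_windows_never_raises_minimum_score(self):
        """Monotone parameter response: a superset grid cannot have a
        larger minimum candidate score."""
        ref = make_ref(400, 5).residues
        narrow = DesignParams(
            min_oligo_len=35, max_oligo_len=45, min_overlap_len=16, max_overlap_len=18
        )
        wide = DesignParams(
            min_oligo_len=30, max_oligo_len=55, min_overlap_len=15, max_overlap_len=22
        )
        for cursor in (0, 60, 120):
            lo_narrow = min(
                c.score.total for c in enumerate_candidates(ref, cursor, narrow)
            )
            lo_wide = min(
                c.score.total for c in enumerate_candidates(ref, cursor, wide)
            )
            assert lo_wide <= lo_narrow + 1e-12


class TestDesign:
    def test_sixty_nt_reference_gives_two_oligomers(self):
        ref = make_ref(60, 6)
        params = DesignParams(
            min_oligo_len=40, max_oligo_len=50, min_overlap_len=15, max_overlap_len=20
        )
        d = design(ref, params)
        assert d.n_oligomers == 2

    def test_reconstruction_round_trip(self):
        for seed, length, gc in [(1, 200, 35.0), (2, 747, 50.0), (3, 1200, 65.0)]:
            ref = make_ref(length, seed, gc)
            d = design(ref)
            assert reconstruct(d) == ref.residues

    def test_strand_alternation_and_gapless_coverage(self, default_design):
        d = default_design
        assert d.oligomers[0].ref_start == 0
        assert d.oligomers[-1].ref_end == len(d.reference)
        for oligo in d.oligomers:
            assert oligo.strand == ("top" if oligo.index % 2 == 1 else "bottom")
        for left, right, ov in zip(d.oligomers, d.oligomers[1:], d.overlaps):
            assert (ov.ref_start, ov.ref_end) == (right.ref_start, left.ref_end)
            assert right.ref_start < left.ref_end  # genuine overlap

    def test_length_windows_respected(self, default_design):
        d = default_design
        p = d.params
        for oligo in d.oligomers[:-1]:
            assert p.min_oligo_len <= len(oligo.sequence) <= p.max_oligo_len
        assert len(d.oligomers[-1].sequence) >= p.min_overlap_len + 5
        for ov in d.overlaps:
            assert p.min_overlap_len <= len(ov.sequence) <= p.max_overlap_len

    def test_stored_scores_conserve_totals(self, default_design):
        for score in default_design.scores:
            assert score.total == pytest.approx(
                score.tm_dev
                + score.three_prime_t
                + score.gc_clamp
                + score.r_within
                + score.r_between
            )

    def test_determinism(self):
        ref = make_ref(400, 8)
        d1 = design(ref)
        d2 = design(ref)
        assert [(o.ref_start, o.ref_end) for o in d1.oligomers] == [
            (o.ref_start, o.ref_end) for o in d2.oligomers
        ]

    def test_too_short_reference_rejected(self):
        with pytest.raises(ValueError):
            design(make_ref(20, 9))


class TestReoptimize:
    def test_idempotence_without_overrides(self, default_design):
        d = default_design
        again = reoptimize(d, 5)
        assert [(o.ref_start, o.ref_end) for o in again.oligomers] == [
            (o.ref_start, o.ref_end) for o in d.oligomers
        ]

    def test_locality_prefix_untouched(self, default_design):
        d = default_design
        redesigned = reoptimize(d, 4, {"max_overlap_len": 18})
        for a, b in zip(redesigned.oligomers[:3], d.oligomers[:3]):
            assert a.sequence == b.sequence
            assert (a.ref_start, a.ref_end) == (b.ref_start, b.ref_end)
        assert reconstruct(redesigned) == d.reference.residues

    def test_last_oligomer_only(self, default_design):
        d = default_design
        n = d.n_oligomers
        redesigned = reoptimize(d, n)
        assert [(o.ref_start, o.ref_end) for o in redesigned.oligomers[: n - 1]] == [
            (o.ref_start, o.ref_end) for o in d.oligomers[: n - 1]
        ]

    def test_original_design_not_modified(self, default_design):
        d = default_design
        before = [(o.ref_start, o.ref_end) for o in d.oligomers]
        reoptimize(d, 2, {"max_overlap_len": 19})
        assert [(o.ref_start, o.ref_end) for o in d.oligomers] == before

    def test_invalid_override_rejected(self, default_design):
        with pytest.raises(ParameterError):
            reoptimize(default_design, 2, {"min_overlap_len": 2})

    def test_index_out_of_range(self, default_design):
        with pytest.raises(IndexError):
            reoptimize(default_design, 0)
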