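"""Assembly-verification statistics: frame-shift rates, kappa, clones,
break-points, repeat masking and coverage correlation."""

import math

import numpy as np
import pytest

from framefix.asmqc import (
    BestHit,
    CloneParams,
    ConcordanceScore,
    ReadAln,
    RepeatParams,
    clone_coverage,
    concordance,
    find_breakpoints,
    frameshift_stats,
    pearson,
    repeat_mask,
)
from framefix.seqio import AlignmentRow, PafRow


def _row(qid, qstart, qend, transcript, sid="s"):
    send = sum(1 for c in transcript if c != "D")
    return AlignmentRow(
        qid=qid, sid=sid, qstart=qstart, qend=qend, strand="+",
        sstart=0, send=send, raw_score=50, bit_score=20.0, pident=95.0,
        transcript=transcript,
    )


class TestFrameshiftStats:
    def test_zero_events(self):
        rows = [_row("a", 0, 999, "=" * 333)]
        st = frameshift_stats(rows)
        assert st.per_sequence["a"] == pytest.approx(1000 * 0 / 999)

    def test_events_per_kb(self):
        """3 events over 1500 aligned bases -> 2.0 per kb."""
        t = "/" + "=" * 498 + "/"  # 2+1494+2 = 1498 bases, 2 events
        rows = [
            _row("a", 0, 1498, t),
            _row("a", 1498, 1500, "/", sid="s2"),  # +2 bases, 1 event
        ]
        st = frameshift_stats(rows)
        assert st.per_sequence["a"] == pytest.approx(2.0)

    def test_union_not_double_counted(self):
        """Overlapping alignments count aligned bases once."""
        rows = [
            _row("a", 0, 1000, "/" + "=" * 332 + "/"),
            _row("a", 0, 1000, "=" * 332 + "//", sid="s2"),
        ]
        st = frameshift_stats(rows)
        assert st.per_sequence["a"] == pytest.approx(4.0)

    def test_cohort_mean_sd(self):
        rows = [
            _row("a", 0, 1000, "/" + "=" * 332 + "/"),            # 2 per kb
            _row("b", 0, 1000, "///" + "=" * 330 + "\\", sid="s2"),  # 4 per kb
        ]
        st = frameshift_stats(rows)
        assert st.mean == pytest.approx(3.0)
        assert st.sd == pytest.approx(math.sqrt(2.0))

    def test_linearity_in_events(self):
        one = frameshift_stats([_row("a", 0, 1000, "/" + "=" * 332 + "/")])
        two = frameshift_stats([_row("a", 0, 1000, "///" + "=" * 330 + "\\")])
        assert two.per_sequence["a"] == pytest.approx(2 * one.per_sequence["a"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            frameshift_stats([])


class TestConcordance:
    def test_perfect_tiling(self):
        cs = concordance(100, {"c1": 100}, [BestHit("c1", 100, 100.0, (0, 100))])
        assert (cs.c1, cs.c2, cs.c3, cs.c4) == (1.0, 1.0, 1.0, 1.0)
        assert cs.kappa == 1.0

    def test_kappa_is_mean(self):
        cs = ConcordanceScore(c1=1.0, c2=0.9, c3=0.8, c4=0.5)
        assert cs.kappa == pytest.approx(0.8)

    def test_empty_overlap_bin(self):
        """A bin with no alignments degrades to kappa = 0, not an error."""
        cs = concordance(100, {"c1": 50, "c2": 50}, [])
        assert (cs.c1, cs.c2, cs.c3, cs.c4) == (0.0, 0.0, 0.0, 0.0)
        assert cs.kappa == 0.0

    def test_partial_bin(self):
        """One of two contigs aligns over half the LR contig at 90%."""
        cs = concordance(200, {"c1": 100, "c2": 100}, [BestHit("c1", 100, 90.0, (0, 100))])
        assert cs.c1 == pytest.approx(0.5)
        assert cs.c2 == pytest.approx(0.9)
        assert cs.c3 == pytest.approx(0.5)
        assert cs.c4 == pytest.approx(0.5)

    def test_components_bounded(self):
        """Over-long hits are clipped so every component stays in [0, 1]."""
        cs = concordance(50, {"c1": 40}, [BestHit("c1", 60, 100.0, (0, 50))])
        assert 0.0 <= cs.c1 <= 1.0 and cs.kappa <= 1.0

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            concordance(100, {}, [])

    def test_duplicate_hits_rejected(self):
        hits = [BestHit("c1", 10, 99.0, (0, 10)), BestHit("c1", 20, 99.0, (10, 30))]
        with pytest.raises(ValueError):
            concordance(100, {"c1": 50}, hits)


def _pair(rid, s, e, contig="c", rl=20, left_strand="+", right_strand="-"):
    return [
        ReadAln(rid, 1, contig, s, s + rl, left_strand),
        ReadAln(rid, 2, contig, e - rl, e, right_strand),
    ]


class TestCloneCoverage:
    def test_tiling_clones_cover_everything(self):
        alns = []
        for i, s in enumerate(range(0, 900, 100)):
            alns += _pair(f"p{i}", s, s + 150)
        profile = clone_coverage(alns, "c", 1000)
        assert profile.min() >= 1 or (profile[:950].min() >= 1)
        assert profile[50] >= 1

    def test_same_orientation_invalid(self):
        alns = _pair("p0", 100, 400, left_strand="+", right_strand="+")
        profile = clone_coverage(alns, "c", 1000)
        assert profile.sum() == 0

    def test_outward_facing_invalid(self):
        alns = _pair("p0", 100, 400, left_strand="-", right_strand="+")
        assert clone_coverage(alns, "c", 1000).sum() == 0

    def test_span_800_rejected_799_accepted(self):
        """'distance below 800' is strict: span 800 invalid, 799 valid."""
        at_limit = clone_coverage(_pair("p0", 0, 800), "c", 1000)
        assert at_limit.sum() == 0
        below = clone_coverage(_pair("p0", 0, 799), "c", 1000)
        assert below[0] == 1 and below[798] == 1 and below[799] == 0

    def test_unpaired_read_warns_and_skips(self):
        lone = [ReadAln("p0", 1, "c", 0, 50, "+")]
        with pytest.warns(UserWarning, match="mate"):
            profile = clone_coverage(lone, "c", 100)
        assert profile.sum() == 0

    def test_additive_and_monotone(self):
        """Coverage is additive over clones; removing one never raises it."""
        a = _pair("p0", 0, 300)
        b = _pair("p1", 200, 600)
        both = clone_coverage(a + b, "c", 1000)
        only_a = clone_coverage(a, "c", 1000)
        only_b = clone_coverage(b, "c", 1000)
        assert np.array_equal(both, only_a + only_b)
        assert (both >= only_a).all()


class TestBreakpoints:
    def test_positive_profile_clean(self):
        assert find_breakpoints(np.ones(100)) == []

    def test_internal_zero_run(self):
        profile = np.ones(10000)
        profile[4000:4500] = 0
        (bp,) = find_breakpoints(profile, "c")
        assert (bp.start, bp.end, bp.terminal) == (4000, 4500, False)

    def test_terminal_runs_flagged(self):
        profile = np.zeros(100)
        (bp,) = find_breakpoints(profile, "c")
        assert (bp.start, bp.end) == (0, 100) and bp.terminal

    def test_mixed_runs(self):
        profile = np.ones(100)
        profile[:10] = 0
        profile[40:60] = 0
        bps = find_breakpoints(profile)
        assert [(b.start, b.end, b.terminal) for b in bps] == [
            (0, 10, True),
            (40, 60, False),
        ]


def _self_hit(qs, qe, ts, te, length=10000, name="c", strand="+"):
    span = max(qe - qs, te - ts)
    return PafRow(name, length, qs, qe, strand, name, length, ts, te, span, span, 60)


class TestRepeatMask:
    def test_trivial_self_hit_only(self):
        mask, rate = repeat_mask([_self_hit(0, 10000, 0, 10000)])
        assert mask == [] and rate == 0.0

    def test_two_copy_repeat(self):
        """Two identical 1 kb copies masked via one off-diagonal self-hit."""
        rows = [_self_hit(0, 10000, 0, 10000), _self_hit(2000, 3000, 7000, 8000)]
        mask, rate = repeat_mask(rows)
        assert mask == [(2000, 3000), (7000, 8000)]
        assert rate == pytest.approx(20.0)

    def test_below_length_threshold_ignored(self):
        rows = [_self_hit(0, 10000, 0, 10000), _self_hit(2000, 2499, 7000, 7499)]
        _, rate = repeat_mask(rows)
        assert rate == 0.0
        _, rate500 = repeat_mask(
            [_self_hit(0, 10000, 0, 10000), _self_hit(2000, 2500, 7000, 7500)]
        )
        assert rate500 == pytest.approx(10.0)

    def test_strand_symmetric_masking(self):
        """Both the query and the target interval of a hit are masked."""
        rows = [_self_hit(0, 10000, 0, 10000), _self_hit(100, 700, 9000, 9600, strand="-")]
        mask, _ = repeat_mask(rows)
        assert (100, 700) in mask and (9000, 9600) in mask

    def test_custom_threshold(self):
        rows = [_self_hit(0, 10000, 0, 10000), _self_hit(0, 300, 5000, 5300)]
        _, rate = repeat_mask(rows, RepeatParams(min_alignment_length=200))
        assert rate == pytest.approx(6.0)

    def test_no_rows_rejected(self):
        with pytest.raises(ValueError):
            repeat_mask([])


class TestPearson:
    def test_affine_line(self):
        xs = [1.0, 2.0, 5.0, 9.0]
        assert pearson([(x, 2 * x + 1) for x in xs]) == pytest.approx(1.0)

    def test_anticorrelated(self):
        xs = [1.0, 2.0, 3.0]
        assert pearson([(x, -x) for x in xs]) == pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = pearson(list(zip(x, y)))
        assert pearson(list(zip(y, x))) == pytest.approx(r)
        assert pearson(list(zip(3 * x + 2, y))) == pytest.approx(r)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([(1.0, 2.0), (1.0, 3.0)])
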