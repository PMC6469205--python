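"""Frame-shift DP alignment vs a brute-force oracle, plus range-culling."""

import numpy as np
import pytest

from _oracle import best_local_score
from framefix.fsalign import (
    CullingParams,
    FrameshiftAlignment,
    ScoringScheme,
    align_frameshift,
    range_cull,
    rescore,
)
from framefix.seqio import AlignmentRow, NucleotideRecord, ProteinRecord, ValidationError

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_instance(rng):
    q = "".join(rng.choice(list("ACGT"), rng.integers(3, 13)))
    s = "".join(rng.choice(list(AA20), rng.integers(1, 5)))
    return q, s


class TestAlign:
    def test_exact_two_codon_match(self, scheme):
        """ATGGCT vs MA aligns codon-for-codon with no events."""
        hits = align_frameshift(NucleotideRecord("q", "ATGGCT"), ProteinRecord("p", "MA"))
        (h,) = hits
        assert h.row.transcript == "=="
        assert h.raw_score == scheme.score("M", "M") + scheme.score("A", "A")
        assert h.events == [] and h.row.pident == 100.0

    def test_query_too_short(self):
        assert align_frameshift(NucleotideRecord("q", "AT"), ProteinRecord("p", "MA")) == []

    def test_deletion_instance_matches_oracle(self, scheme):
        """MAK encoded as ATGGCTAAG with one base deleted.

        At the default penalty (15) the local optimum is a single codon
        without events — a one-event bridge costs more than the flank it
        gains — and the DP must agree with the enumeration oracle.
        """
        q, s = "ATGGTAAG", "MAK"
        (h,) = align_frameshift(NucleotideRecord("q", q), ProteinRecord("p", s), scheme)
        assert h.raw_score == best_local_score(q, s, scheme)
        assert h.n_frameshifts == 0

    def test_deletion_bridged_at_low_penalty(self):
        """With a small penalty the one-event full-span alignment wins."""
        cheap = ScoringScheme(frameshift_penalty=2)
        (h,) = align_frameshift(
            NucleotideRecord("q", "ATGGTAAG"), ProteinRecord("p", "MAK"), cheap
        )
        assert h.n_frameshifts == 1
        assert h.events == [(3, "/")]
        assert h.raw_score == (
            cheap.score("M", "M") + cheap.score("X", "A") + cheap.score("K", "K") - 2
        )

    def test_oracle_equivalence_sample(self, scheme):
        """DP optimum equals exhaustive enumeration on random tiny instances."""
        rng = np.random.default_rng(42)
        for _ in range(80):
            q, s = _random_instance(rng)
            hits = align_frameshift(NucleotideRecord("q", q), ProteinRecord("p", s), scheme)
            got = hits[0].raw_score if hits else 0
            assert got == best_local_score(q, s, scheme), (q, s)

    def test_score_monotone_in_penalty(self):
        """Raising F never raises the optimal score; at F -> inf the result
        equals 3-frame local alignment without shifts (0-event oracle)."""
        rng = np.random.default_rng(7)
        for _ in range(15):
            q, s = _random_instance(rng)
            prev = None
            for f in (1, 5, 15, 40):
                sch = ScoringScheme(frameshift_penalty=f)
                hits = align_frameshift(NucleotideRecord("q", q), ProteinRecord("p", s), sch)
                score = hits[0].raw_score if hits else 0
                if prev is not None:
                    assert score <= prev
                prev = score
            huge = ScoringScheme(frameshift_penalty=10**6)
            hits = align_frameshift(NucleotideRecord("q", q), ProteinRecord("p", s), huge)
            score = hits[0].raw_score if hits else 0
            assert score == best_local_score(q, s, huge, max_events=0)

    def test_minus_strand_coordinates(self, scheme):
        """A reverse-complemented query aligns on '-' with forward coords."""
        from framefix.fsalign import reverse_complement

        fwd = "ATGGCTAAG"
        rc = NucleotideRecord("q", reverse_complement(fwd))
        (h,) = align_frameshift(rc, ProteinRecord("p", "MAK"), scheme, both_strands=True)
        assert h.row.strand == "-"
        assert (h.row.qstart, h.row.qend) == (0, 9)
        assert rescore(h, rc, ProteinRecord("p", "MAK"), scheme) == h.raw_score

    def test_events_recoverable_from_noisy_read(self, scheme):
        """An indel inside a long alignment is bridged as one event whose
        replayed score matches, and the transcript audit holds."""
        from framefix.simulate import SimConfig, simulate_reads, simulate_reference

        cfg = SimConfig(seed=3, n_genes=1, gene_length_aa=(80, 80),
                        read_length=(240, 240), n_reads=5,
                        indel_rate=0.01, substitution_rate=0.0)
        dna, prot = simulate_reference(cfg)
        reads, truths = simulate_reads(dna, cfg)
        for read, truth in zip(reads, truths):
            hits = align_frameshift(read, prot[0], scheme, both_strands=True)
            assert hits, read.id
            h = hits[0]
            h.row.validate()
            assert rescore(h, read, prot[0], scheme) == h.raw_score
            assert h.n_frameshifts == h.row.n_frameshifts()


class TestRescore:
    def test_self_consistency(self, scheme):
        q = NucleotideRecord("q", "ATGGCTAAGTTT")
        p = ProteinRecord("p", "MAKF")
        (h,) = align_frameshift(q, p, scheme)
        assert rescore(h, q, p, scheme) == h.raw_score

    def test_frameshift_term(self):
        """A transcript with one '/' includes exactly one -F term."""
        cheap = ScoringScheme(frameshift_penalty=2)
        q = NucleotideRecord("q", "ATGGTAAG")
        p = ProteinRecord("p", "MAK")
        (h,) = align_frameshift(q, p, cheap)
        assert h.row.transcript.count("/") == 1
        no_penalty = cheap.score("M", "M") + cheap.score("X", "A") + cheap.score("K", "K")
        assert rescore(h, q, p, cheap) == no_penalty - cheap.frameshift_penalty

    def test_corrupted_transcript_rejected(self, scheme):
        q = NucleotideRecord("q", "ATGGCT")
        p = ProteinRecord("p", "MA")
        (h,) = align_frameshift(q, p, scheme)
        bad = AlignmentRow(**{**h.row.__dict__, "transcript": "="})
        with pytest.raises(ValidationError):
            rescore(bad, q, p, scheme)


def _aln(qstart, qend, score, qid="q", sid="s"):
    row = AlignmentRow(
        qid=qid, sid=sid, qstart=qstart, qend=qend, strand="+",
        sstart=0, send=max(1, (qend - qstart) // 3), raw_score=score,
        bit_score=0.0, pident=90.0, transcript="",
    )
    return FrameshiftAlignment(row=row)


class TestRangeCull:
    def test_single_alignment_retained(self):
        a = _aln(0, 100, 50)
        assert range_cull([a]) == [a]

    @pytest.mark.parametrize(
        "a_span,a_score,b_span,b_score,a_survives",
        [
            ((0, 100), 80, (0, 100), 100, False),   # full overlap, 80 < 90
            ((0, 100), 95, (0, 100), 100, True),    # 95 >= 90% of 100
            ((0, 100), 50, (60, 200), 100, True),   # overlap 40% < 50%
            ((0, 100), 89, (0, 100), 100, False),   # just below the 90% line
        ],
    )
    def test_fifty_ninety_rule(self, a_span, a_score, b_span, b_score, a_survives):
        a = _aln(*a_span, a_score, sid="sA")
        b = _aln(*b_span, b_score, sid="sB")
        kept = range_cull([a, b])
        assert b in kept
        assert (a in kept) == a_survives

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            range_cull([_aln(0, 10, 5, qid="q1"), _aln(0, 10, 5, qid="q2")])

    def test_subset_idempotence_and_witness(self):
        """Output is a subset in input order; re-culling is the identity;
        every culled alignment has a retained witness meeting both thresholds."""
        rng = np.random.default_rng(5)
        params = CullingParams()
        for _ in range(30):
            alns = []
            for i in range(rng.integers(1, 12)):
                a = int(rng.integers(0, 500))
                b = a + int(rng.integers(10, 300))
                alns.append(_aln(a, b, int(rng.integers(1, 200)), sid=f"s{i}"))
            kept = range_cull(alns, params)
            assert [x for x in alns if x in kept] == kept
            assert range_cull(kept, params) == kept
            for a in alns:
                if a in kept:
                    continue
                witnesses = [
                    b for b in kept
                    if min(a.qend, b.qend) - max(a.qstart, b.qstart)
                    >= params.cover_fraction * (a.qend - a.qstart)
                    and a.raw_score < params.score_fraction * b.raw_score
                ]
                assert witnesses, "culled alignment lacks a retained witness"
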