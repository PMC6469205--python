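r"""Frame-shift-aware local DNA-to-protein alignment.

Long nanopore reads carry frequent single-base insertions and deletions.
In a translated alignment such an error shifts the reading frame, and an
aligner that is blind to this truncates or fragments the alignment. The
dynamic programme here instead allows a codon column to consume 2 or 4
query bases instead of 3, paying a fixed frame-shift penalty ``F`` once per
event (default 15). A 2-base column is written ``/`` in the transcript
(frame decrease — a base was lost from the read) and a 4-base column ``\``
(frame increase — a base was gained); downstream correction turns these
events into N insertions that restore the frame.

Scoring
-------
* codon columns score ``BLOSUM62(translate(codon), residue)``; any codon
  containing N translates to X, and X scores -1 against everything.
* a 2-base column is N-padded on the 5' side before translation (hence
  always X), a 4-base column translates its last 3 bases; both subtract F.
* affine gaps: a gap in the subject consumes 3 query bases per column, a
  gap in the query consumes 1 residue; cost ``gap_open + k * gap_extend``.
* local (Smith-Waterman) semantics: scores floor at 0, traceback from the
  global maximum. Suboptimal hits are produced by repeated traceback with
  already-reported query intervals masked out.

The heavy O(n*m) recurrence is JIT-compiled with numba; everything else is
plain Python operating on :class:`framefix.seqio.AlignmentRow`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .seqio import (
    AlignmentRow,
    NucleotideRecord,
    ProteinRecord,
    QUERY_CONSUMPTION,
    SUBJECT_CONSUMPTION,
    ValidationError,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_X = _AA_INDEX["X"]

_NEG_INF = -(10**15)


def _standard_codon_table() -> dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    codons = dict(table.forward_table)
    for stop in table.stop_codons:
        codons[stop] = "*"
    return codons


_CODON_TO_AA = _standard_codon_table()


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing N yields X."""
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"codon must have 3 bases, got {codon!r}")
    if "N" in codon:
        return "X"
    try:
        return _CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"unknown codon {codon!r}") from None


_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def default_matrix() -> np.ndarray:
    """BLOSUM62 over :data:`AA_ALPHABET` with the X row/column forced to -1."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            mat[i, j] = int(blosum[a][b])
    mat[_X, :] = -1
    mat[:, _X] = -1
    return mat


@dataclass
class ScoringScheme:
    """Scores and penalties of the frame-shift alignment DP.

    ``frameshift_penalty`` is subtracted once per frame-shift event, not per
    base of shift. ``lam``/``k`` are the gapped BLOSUM62 Karlin-Altschul
    constants used only to report bit scores.
    """

    matrix: np.ndarray = field(default_factory=default_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    frameshift_penalty: int = 15
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0 or self.frameshift_penalty <= 0:
            raise ValueError("all penalties must be positive")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[_AA_INDEX[a], _AA_INDEX[b]])

    def bit_score(self, raw: int) -> float:
        return (self.lam * raw - math.log(self.k)) / math.log(2)


@dataclass
class FrameshiftAlignment:
    """An :class:`AlignmentRow` plus its frame-shift events.

    ``events`` hold absolute forward-strand query offsets of the first
    (leftmost) base of each shifted codon, with kind ``'/'`` (2-base codon)
    or ``'\\'`` (4-base codon), sorted by offset.
    """

    row: AlignmentRow
    events: list[tuple[int, str]] = field(default_factory=list)

    @property
    def qid(self) -> str:
        return self.row.qid

    @property
    def sid(self) -> str:
        return self.row.sid

    @property
    def qstart(self) -> int:
        return self.row.qstart

    @property
    def qend(self) -> int:
        return self.row.qend

    @property
    def raw_score(self) -> int:
        return self.row.raw_score

    @property
    def n_frameshifts(self) -> int:
        return len(self.events)


@dataclass
class CullingParams:
    """Range-culling thresholds: drop A only if a retained B covers at least
    ``cover_fraction`` of A's query interval and A scores below
    ``score_fraction`` of B."""

    cover_fraction: float = 0.5
    score_fraction: float = 0.9

    def __post_init__(self) -> None:
        for v in (self.cover_fraction, self.score_fraction):
            if not 0.0 < v <= 1.0:
                raise ValueError("fractions must be in (0, 1]")


@njit(cache=True)
def _fs_dp(aa3, subj, S, go, ge, fpen, x_idx, mask_cum):  # pragma: no cover - JIT
    n = aa3.shape[0] - 1
    m = subj.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int64)
    F = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i][j - 1] - go - ge
            if E[i][j - 1] - ge > e:
                e = E[i][j - 1] - ge
            E[i][j] = e
            f = _NEG_INF
            if i >= 3 and mask_cum[i] - mask_cum[i - 3] == 0:
                f = H[i - 3][j] - go - ge
                if F[i - 3][j] - ge > f:
                    f = F[i - 3][j] - ge
            F[i][j] = f
            best = 0
            sj = subj[j - 1]
            if i >= 3 and aa3[i] >= 0 and mask_cum[i] - mask_cum[i - 3] == 0:
                v = H[i - 3][j - 1] + S[aa3[i], sj]
                if v > best:
                    best = v
            if i >= 2 and mask_cum[i] - mask_cum[i - 2] == 0:
                v = H[i - 2][j - 1] + S[x_idx, sj] - fpen
                if v > best:
                    best = v
            if i >= 4 and aa3[i] >= 0 and mask_cum[i] - mask_cum[i - 4] == 0:
                v = H[i - 4][j - 1] + S[aa3[i], sj] - fpen
                if v > best:
                    best = v
            if e > best:
                best = e
            if f > best:
                best = f
            H[i][j] = best
    return H, E, F


def _encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def _encode_codons(seq: str) -> np.ndarray:
    """aa3[i] = alphabet index of translate(seq[i-3:i]) for i >= 3, else -1."""
    n = len(seq)
    aa3 = np.full(n + 1, -1, dtype=np.int64)
    for i in range(3, n + 1):
        aa3[i] = _AA_INDEX[translate_codon(seq[i - 3 : i])]
    return aa3


def _traceback(H, E, F, aa3, subj, scheme, mask_cum, i, j):
    """Rebuild one local alignment ending at (i, j).

    Tie-break order at each cell: codon match, 2-base shift, 4-base shift,
    gap in query, gap in subject — i.e. match > frame-shift > gap, smaller
    query consumption first within the frame-shift pair.
    """
    S = scheme.matrix
    go, ge, fpen = scheme.gap_open, scheme.gap_extend, scheme.frameshift_penalty
    ops: list[str] = []
    events: list[tuple[int, str]] = []
    state = "H"
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            sj = subj[j - 1]
            if (
                i >= 3
                and aa3[i] >= 0
                and mask_cum[i] - mask_cum[i - 3] == 0
                and h == H[i - 3][j - 1] + S[aa3[i], sj]
            ):
                ops.append("=" if aa3[i] == sj else "X")
                i -= 3
                j -= 1
            elif (
                i >= 2
                and mask_cum[i] - mask_cum[i - 2] == 0
                and h == H[i - 2][j - 1] + S[_X, sj] - fpen
            ):
                ops.append("/")
                events.append((i - 2, "/"))
                i -= 2
                j -= 1
            elif (
                i >= 4
                and aa3[i] >= 0
                and mask_cum[i] - mask_cum[i - 4] == 0
                and h == H[i - 4][j - 1] + S[aa3[i], sj] - fpen
            ):
                ops.append("\\")
                events.append((i - 4, "\\"))
                i -= 4
                j -= 1
            elif h == E[i][j]:
                state = "E"
            elif h == F[i][j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed to reproduce DP score")
        elif state == "E":
            ops.append("I")
            if E[i][j] == H[i][j - 1] - go - ge:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # state == "F"
            ops.append("D")
            if F[i][j] == H[i - 3][j] - go - ge:
                i -= 3
                state = "H"
            else:
                i -= 3
    ops.reverse()
    events.reverse()
    return i, j, "".join(ops), events


def _align_one_orientation(seq, subj_codes, scheme, max_hits, min_score):
    """All hits on one query orientation, via repeated masked traceback.

    Returns tuples of (raw, qstart, qend, sstart, send, transcript, events)
    with coordinates in the given orientation.
    """
    n = len(seq)
    if n < 3:
        return []
    aa3 = _encode_codons(seq)
    mask = np.zeros(n + 1, dtype=np.int64)  # cumulative count of masked bases < i
    hits = []
    while len(hits) < max_hits:
        H, E, F = _fs_dp(
            aa3,
            subj_codes,
            scheme.matrix,
            np.int64(scheme.gap_open),
            np.int64(scheme.gap_extend),
            np.int64(scheme.frameshift_penalty),
            np.int64(_X),
            mask,
        )
        flat = int(np.argmax(H))
        bi, bj = divmod(flat, H.shape[1])
        raw = int(H[bi, bj])
        if raw < min_score:
            break
        qstart, sstart, transcript, events = _traceback(
            H, E, F, aa3, subj_codes, scheme, mask, bi, bj
        )
        hits.append((raw, qstart, bi, sstart, bj, transcript, events))
        # mask the reported query span and redo the DP for the next hit
        per_base = np.zeros(n, dtype=np.int64)
        for a, b in [(h[1], h[2]) for h in hits]:
            per_base[a:b] = 1
        mask = np.concatenate(([0], np.cumsum(per_base)))
    return hits


def align_frameshift(
    query: NucleotideRecord,
    subject: ProteinRecord,
    scheme: ScoringScheme | None = None,
    both_strands: bool = False,
    max_hits: int = 1,
    min_score: int = 1,
) -> list[FrameshiftAlignment]:
    """Locally align DNA against a protein, allowing frame-shift columns.

    Returns up to ``max_hits`` alignments with raw score >= ``min_score``,
    sorted by descending score (ties: ascending qstart, then sid). With
    ``both_strands`` the reverse complement is aligned too and coordinates
    are reported on the forward strand with ``strand='-'``.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if len(query.seq) < 3:
        return []
    subj_codes = _encode_protein(subject.seq)
    if subj_codes.shape[0] < 1:
        return []
    n = len(query.seq)

    oriented: list[tuple] = []
    for strand in ("+", "-") if both_strands else ("+",):
        seq = query.seq if strand == "+" else reverse_complement(query.seq)
        for raw, qs, qe, ss, se, transcript, events in _align_one_orientation(
            seq, subj_codes, scheme, max_hits, min_score
        ):
            if strand == "-":
                qs, qe = n - qe, n - qs
                events = sorted(
                    (n - (off + QUERY_CONSUMPTION[kind]), kind) for off, kind in events
                )
            oriented.append((raw, qs, qe, ss, se, strand, transcript, events))

    oriented.sort(key=lambda t: (-t[0], t[1], t[5]))
    out = []
    for raw, qs, qe, ss, se, strand, transcript, events in oriented[:max_hits]:
        n_res_cols = sum(1 for c in transcript if c != "D")
        pident = 100.0 * transcript.count("=") / len(transcript) if transcript else 0.0
        row = AlignmentRow(
            qid=query.id,
            sid=subject.id,
            qstart=qs,
            qend=qe,
            strand=strand,
            sstart=ss,
            send=se,
            raw_score=raw,
            bit_score=scheme.bit_score(raw),
            pident=pident,
            transcript=transcript,
        )
        row.validate()
        out.append(FrameshiftAlignment(row=row, events=list(events)))
    return out


def rescore(
    alignment: FrameshiftAlignment | AlignmentRow,
    query: NucleotideRecord,
    subject: ProteinRecord,
    scheme: ScoringScheme | None = None,
) -> int:
    """Recompute an alignment's raw score by replaying its transcript.

    Serves as an audit of the DP output: the replayed score must equal the
    reported ``raw_score`` for a well-formed alignment. Raises
    :class:`ValidationError` when the transcript does not fit the sequences.
    """
    if scheme is None:
        scheme = ScoringScheme()
    row = alignment.row if isinstance(alignment, FrameshiftAlignment) else alignment
    row.validate()
    seq = query.seq if row.strand == "+" else reverse_complement(query.seq)
    qs = row.qstart if row.strand == "+" else len(seq) - row.qend
    qe = row.qend if row.strand == "+" else len(seq) - row.qstart
    if qe > len(seq) or row.send > len(subject.seq):
        raise ValidationError("alignment coordinates exceed sequence lengths")

    score = 0
    i, j = qs, row.sstart
    prev = ""
    for op in row.transcript:
        res = subject.seq[j] if SUBJECT_CONSUMPTION[op] else None
        if op in "=X":
            aa = translate_codon(seq[i : i + 3])
            if (op == "=") != (aa == res):
                raise ValidationError(
                    f"transcript op {op!r} inconsistent with codon {seq[i:i+3]} vs {res}"
                )
            score += scheme.score(aa, res)
        elif op == "/":
            score += scheme.score("X", res) - scheme.frameshift_penalty
        elif op == "\\":
            aa = translate_codon(seq[i + 1 : i + 4])
            score += scheme.score(aa, res) - scheme.frameshift_penalty
        elif op == "I":
            score -= scheme.gap_extend + (scheme.gap_open if prev != "I" else 0)
        elif op == "D":
            score -= scheme.gap_extend + (scheme.gap_open if prev != "D" else 0)
        i += QUERY_CONSUMPTION[op]
        j += SUBJECT_CONSUMPTION[op]
        prev = op
    return score


def range_cull(
    alignments: Sequence[FrameshiftAlignment],
    params: CullingParams | None = None,
) -> list[FrameshiftAlignment]:
    """Positionally aware filtering of one query's alignments.

    Alignments are considered in descending raw score (ties: ascending
    qstart, then sid). A is culled iff some already-retained B overlaps at
    least ``cover_fraction`` of A's query interval and A's score is below
    ``score_fraction`` of B's. The retained set is returned in input order.
    """
    if params is None:
        params = CullingParams()
    if not alignments:
        return []
    qids = {a.qid for a in alignments}
    if len(qids) > 1:
        raise ValueError(f"range_cull expects a single query, got {sorted(qids)}")

    order = sorted(
        range(len(alignments)),
        key=lambda ix: (-alignments[ix].raw_score, alignments[ix].qstart, alignments[ix].sid),
    )
    retained: set[int] = set()
    for ix in order:
        a = alignments[ix]
        alen = a.qend - a.qstart
        culled = False
        for jx in retained:
            b = alignments[jx]
            overlap = max(0, min(a.qend, b.qend) - max(a.qstart, b.qstart))
            if overlap >= params.cover_fraction * alen and (
                a.raw_score < params.score_fraction * b.raw_score
            ):
                culled = True
                break
        if not culled:
            retained.add(ix)
    return [alignments[ix] for ix in sorted(retained)]
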