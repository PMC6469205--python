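"""Assembly-verification statistics for long-read metagenome assemblies.

Five independent checks of an assembly, each usable on its own:

* :func:`frameshift_stats` — frame-shift events per kilobase of aligned
  sequence, the indel-error proxy that motivates correction;
* :func:`concordance` — the concordance score kappa between a bin of
  short-read contigs and a long-read contig (mean of four [0,1] components);
* :func:`clone_coverage` / :func:`find_breakpoints` — paired-read "clone"
  coverage of a contig and its zero-coverage runs, which flag potential
  assembly break-points;
* :func:`repeat_mask` — fraction of a contig inside long (>= 500 bp)
  non-trivial self-alignments;
* :func:`pearson` — plain sample correlation, used to compare long-read
  and short-read coverage across bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._intervals import complement, merge, union_length
from .seqio import AlignmentRow, FRAMESHIFT_SYMBOLS, PafRow

# ---------------------------------------------------------------------------
# frame-shifts per kilobase


@dataclass
class FrameshiftStats:
    """Frame-shift events per kb of aligned sequence, per query and cohort.

    ``sd`` is the sample standard deviation (n-1 denominator), ``None``
    for cohorts of one.
    """

    per_sequence: dict[str, float]
    mean: float
    sd: float | None


def frameshift_stats(rows: Iterable[AlignmentRow]) -> FrameshiftStats:
    """events x 1000 / aligned bases, per query sequence.

    Aligned bases are the union length of each query's alignment intervals,
    so overlapping alignments are not double-counted. Queries with zero
    aligned bases cannot occur (every row spans >= 1 base); an empty row
    set is an error.
    """
    events: dict[str, int] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for row in rows:
        events[row.qid] = events.get(row.qid, 0) + row.n_frameshifts()
        intervals.setdefault(row.qid, []).append((row.qstart, row.qend))
    if not events:
        raise ValueError("no alignments: frame-shift rate undefined")
    per_seq = {
        qid: 1000.0 * events[qid] / union_length(intervals[qid]) for qid in events
    }
    values = np.array(list(per_seq.values()))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return FrameshiftStats(per_sequence=per_seq, mean=float(values.mean()), sd=sd)


# ---------------------------------------------------------------------------
# concordance score


@dataclass
class BestHit:
    """The single best alignment of one bin contig on the long-read contig.

    ``pident`` is in percent (0-100); ``lr_interval`` is the half-open
    interval covered on the long-read contig.
    """

    contig_id: str
    alignment_length: int
    pident: float
    lr_interval: tuple[int, int]


@dataclass
class ConcordanceScore:
    """Four [0,1] components and their mean kappa.

    c1: mean over bin contigs of best-hit alignment length / contig length
        (contigs without a hit contribute 0);
    c2: mean identity (as a fraction) of the best hits, 0 if there are none;
    c3: fraction of the long-read contig covered by aligned bin contigs;
    c4: fraction of bin contigs with at least one alignment.
    """

    c1: float
    c2: float
    c3: float
    c4: float

    @property
    def kappa(self) -> float:
        return (self.c1 + self.c2 + self.c3 + self.c4) / 4.0


def concordance(
    lr_length: int,
    contig_lengths: Mapping[str, int],
    hits: Sequence[BestHit],
) -> ConcordanceScore:
    """Concordance kappa between a bin of contigs and one long-read contig.

    ``hits`` must already be reduced to at most one (best) hit per
    contig/contig pair; per-contig ratios are clipped at 1 so every
    component stays in [0, 1].
    """
    if not contig_lengths:
        raise ValueError("empty bin")
    if lr_length <= 0:
        raise ValueError("long-read contig length must be positive")
    unknown = [h.contig_id for h in hits if h.contig_id not in contig_lengths]
    if unknown:
        raise ValueError(f"hits reference contigs outside the bin: {unknown}")
    seen = [h.contig_id for h in hits]
    if len(seen) != len(set(seen)):
        raise ValueError("expected at most one best hit per bin contig")

    n = len(contig_lengths)
    c1 = sum(min(1.0, h.alignment_length / contig_lengths[h.contig_id]) for h in hits) / n
    c2 = float(np.mean([h.pident / 100.0 for h in hits])) if hits else 0.0
    c3 = min(1.0, union_length([h.lr_interval for h in hits]) / lr_length) if hits else 0.0
    c4 = len(hits) / n
    return ConcordanceScore(c1=c1, c2=c2, c3=c3, c4=c4)


# ---------------------------------------------------------------------------
# clone coverage and break-points


@dataclass(frozen=True)
class ReadAln:
    """Placement of one read of a pair on a contig (forward-strand coords)."""

    read_id: str
    mate: int  # 1 or 2
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class CloneParams:
    """A read pair is a valid clone iff both mates hit the same contig, in
    forward-reverse orientation facing inward, with outer span strictly
    below ``max_insert`` (default 800)."""

    max_insert: int = 800
    require_proper_orientation: bool = True

    def __post_init__(self) -> None:
        if self.max_insert <= 0:
            raise ValueError("max_insert must be positive")


def _is_valid_clone(a: ReadAln, b: ReadAln, params: CloneParams) -> tuple[int, int] | None:
    """Outer span of a valid clone, or None."""
    if a.contig != b.contig:
        return None
    left, right = (a, b) if a.start <= b.start else (b, a)
    if params.require_proper_orientation:
        if not (left.strand == "+" and right.strand == "-"):
            return None
    span = (left.start, max(left.end, right.end))
    if span[1] - span[0] >= params.max_insert:
        return None
    return span


def clone_coverage(
    alignments: Iterable[ReadAln],
    contig: str,
    contig_length: int,
    params: CloneParams | None = None,
) -> np.ndarray:
    """Per-position clone coverage of one contig.

    Each valid clone increments coverage over its full outer span (clipped
    to the contig). Reads whose mate is missing are skipped with a warning.
    """
    if params is None:
        params = CloneParams()
    pairs: dict[str, dict[int, ReadAln]] = {}
    for aln in alignments:
        pairs.setdefault(aln.read_id, {})[aln.mate] = aln

    diff = np.zeros(contig_length + 1, dtype=np.int64)
    n_unpaired = 0
    for read_id, mates in pairs.items():
        if len(mates) != 2:
            n_unpaired += 1
            continue
        span = _is_valid_clone(mates[1], mates[2], params)
        if span is None or mates[1].contig != contig:
            continue
        a, b = max(0, span[0]), min(contig_length, span[1])
        if a < b:
            diff[a] += 1
            diff[b] -= 1
    if n_unpaired:
        warnings.warn(f"skipped {n_unpaired} read(s) without a resolvable mate")
    return np.cumsum(diff[:-1])


@dataclass(frozen=True)
class Breakpoint:
    """A maximal zero-clone-coverage run; ``terminal`` marks runs touching a
    contig end, where zero coverage is expected (clones cannot span ends)."""

    contig_id: str
    start: int
    end: int
    terminal: bool = False


def find_breakpoints(profile: np.ndarray, contig_id: str = "") -> list[Breakpoint]:
    """Maximal zero-coverage runs of a clone-coverage profile."""
    profile = np.asarray(profile)
    n = len(profile)
    if n == 0:
        raise ValueError("empty coverage profile")
    out = []
    for start, end in complement([(i, i + 1) for i in np.nonzero(profile > 0)[0]], 0, n):
        out.append(
            Breakpoint(
                contig_id=contig_id,
                start=start,
                end=end,
                terminal=(start == 0 or end == n),
            )
        )
    return out


# ---------------------------------------------------------------------------
# repeat masking


@dataclass
class RepeatParams:
    """Only self-alignments of length >= ``min_alignment_length`` (default
    500) mark repeat regions."""

    min_alignment_length: int = 500

    def __post_init__(self) -> None:
        if self.min_alignment_length <= 0:
            raise ValueError("min_alignment_length must be positive")


def repeat_mask(
    self_alignments: Iterable[PafRow],
    params: RepeatParams | None = None,
) -> tuple[list[tuple[int, int]], float]:
    """Repeat intervals and repeat rate (%) from a contig's self-alignment.

    Uses only rows with query == target, excluding the trivial full-length
    identity hit. A qualifying alignment masks both its query and its
    target interval (repeats are symmetric). Returns the merged mask and
    100 x masked / contig length.
    """
    if params is None:
        params = RepeatParams()
    rows = [r for r in self_alignments if r.qname == r.tname]
    length = None
    intervals: list[tuple[int, int]] = []
    for r in rows:
        length = r.qlen
        trivial = (
            r.qstart == r.tstart and r.qend == r.tend
            and r.qstart == 0 and r.qend == r.qlen and r.strand == "+"
        )
        if trivial:
            continue
        if r.qend - r.qstart >= params.min_alignment_length:
            intervals.append((r.qstart, r.qend))
            intervals.append((r.tstart, r.tend))
    if length is None:
        raise ValueError("no self-alignment rows: contig length unknown")
    mask = merge(intervals) if intervals else []
    rate = 100.0 * union_length(mask) / length if mask else 0.0
    return mask, rate


# ---------------------------------------------------------------------------
# coverage correlation


def pearson(pairs: Sequence[tuple[float, float]]) -> float:
    """Sample Pearson correlation of (x, y) pairs."""
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y)[0])
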