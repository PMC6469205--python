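r"""Frame-shift correction of DNA sequences from frame-shift alignments.

Given a read's frame-shift alignments, correction proceeds in two steps:

1. greedily select a maximal set of pairwise non-overlapping alignments on
   the query (descending raw score, ties by ascending qstart then subject
   id), and
2. at every frame-shift event of a selected alignment, insert unspecified
   nucleotides into the read: one ``N`` for a frame decrease (``/``, the
   2-base codon becomes a full codon) and ``NN`` for a frame increase
   (``\``, the 4-base codon becomes two full codons).

The insertion point is the first (leftmost, forward-strand) base of the
shifted codon, so the frame downstream of every event is restored on both
strands. Corrected sequences carry a monotone old->new coordinate map and
the list of inserted positions, making the correction exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fsalign import FrameshiftAlignment
from .seqio import NucleotideRecord

DEFAULT_SUFFIX = "_corrected"

#: bases inserted per event kind
INSERTION_SIZE = {"/": 1, "\\": 2}


@dataclass
class CorrectionPlan:
    """Selected non-overlapping alignments and the N insertions they imply.

    ``insertions`` is a list of ``(query_offset, n)`` with n=1 for a frame
    decrease and n=2 for a frame increase, sorted by ascending offset.
    """

    selected: list[FrameshiftAlignment] = field(default_factory=list)
    insertions: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class CorrectedSequence:
    """A corrected read plus the bookkeeping to invert the correction.

    ``coord_map[i]`` is the corrected offset of original position ``i``
    (strictly monotone); ``inserted_positions`` are the corrected offsets
    of the inserted N characters, so deleting them restores the original.
    """

    id: str
    seq: str
    coord_map: np.ndarray
    inserted_positions: list[int]
    n_inserted: int

    def invert(self) -> str:
        """Remove the inserted characters, restoring the original sequence."""
        drop = set(self.inserted_positions)
        return "".join(c for i, c in enumerate(self.seq) if i not in drop)


def _check_single_query(alignments: Sequence[FrameshiftAlignment]) -> None:
    qids = {a.qid for a in alignments}
    if len(qids) > 1:
        raise ValueError(f"alignments span multiple queries: {sorted(qids)}")


def select_nonoverlapping(
    alignments: Sequence[FrameshiftAlignment],
) -> list[FrameshiftAlignment]:
    """Greedy maximal set of non-overlapping alignments for one query.

    Alignments are taken in descending raw score (ties: ascending qstart,
    then subject id); one is kept iff its query interval shares no position
    with any kept alignment (half-open, so abutting intervals are
    compatible). The result is sorted by qstart.
    """
    _check_single_query(alignments)
    order = sorted(alignments, key=lambda a: (-a.raw_score, a.qstart, a.sid))
    kept: list[FrameshiftAlignment] = []
    for a in order:
        if all(a.qend <= b.qstart or a.qstart >= b.qend for b in kept):
            kept.append(a)
    kept.sort(key=lambda a: a.qstart)
    return kept


def build_plan(alignments: Sequence[FrameshiftAlignment]) -> CorrectionPlan:
    """Select alignments and turn their events into an insertion list."""
    selected = select_nonoverlapping(alignments)
    insertions = sorted(
        (offset, INSERTION_SIZE[kind]) for a in selected for offset, kind in a.events
    )
    return CorrectionPlan(selected=selected, insertions=insertions)


def apply_corrections(
    record: NucleotideRecord,
    plan: CorrectionPlan,
    suffix: str = DEFAULT_SUFFIX,
) -> CorrectedSequence:
    """Insert N/NN at every planned offset of ``record``.

    Insertions are applied from the highest offset downward so earlier
    offsets are unaffected; the inserted bases land immediately before the
    original base at each offset.
    """
    n = len(record.seq)
    for offset, size in plan.insertions:
        if not 0 <= offset < n:
            raise ValueError(f"insertion offset {offset} outside [0, {n})")
        if size not in (1, 2):
            raise ValueError(f"insertion size must be 1 or 2, got {size}")

    seq = record.seq
    for offset, size in sorted(plan.insertions, reverse=True):
        seq = seq[:offset] + "N" * size + seq[offset:]

    shift = np.zeros(n + 1, dtype=np.int64)
    for offset, size in plan.insertions:
        shift[offset] += size
    coord_map = np.arange(n, dtype=np.int64) + np.cumsum(shift)[:-1] if n else np.arange(0)
    inserted = [
        int(coord_map[offset]) - size + delta
        for offset, size in plan.insertions
        for delta in range(size)
    ]
    total = sum(size for _, size in plan.insertions)
    return CorrectedSequence(
        id=record.id + suffix,
        seq=seq,
        coord_map=coord_map,
        inserted_positions=sorted(inserted),
        n_inserted=total,
    )


def correct_all(
    records: Sequence[NucleotideRecord],
    alignments: Iterable[FrameshiftAlignment],
    *,
    assignments: Mapping[str, str] | None = None,
    drop_unaligned: bool = False,
    suffix: str = DEFAULT_SUFFIX,
) -> list[CorrectedSequence] | dict[str, list[CorrectedSequence]]:
    """Correct every record that has alignments.

    Unaligned records are passed through unchanged (empty plan) unless
    ``drop_unaligned``. With ``assignments`` (read id -> taxon id, e.g. from
    :func:`framefix.taxbin.bin_reads`) the output is grouped per taxon the
    way taxon-specific corrected files are produced; reads without an
    assignment land under the key ``"unassigned"``.
    """
    by_read: dict[str, list[FrameshiftAlignment]] = {}
    for a in alignments:
        by_read.setdefault(a.qid, []).append(a)

    known = {r.id for r in records}
    missing = sorted(set(by_read) - known)
    if missing:
        raise ValueError(f"alignments reference unknown read ids: {missing}")

    out: list[CorrectedSequence] = []
    for rec in records:
        alns = by_read.get(rec.id)
        if not alns:
            if drop_unaligned:
                continue
            out.append(apply_corrections(rec, CorrectionPlan(), suffix=""))
            continue
        out.append(apply_corrections(rec, build_plan(alns), suffix=suffix))

    if assignments is None:
        return out
    grouped: dict[str, list[CorrectedSequence]] = {}
    for rec, cor in zip([r for r in records if not (drop_unaligned and r.id not in by_read)], out):
        taxon = assignments.get(rec.id, "unassigned")
        grouped.setdefault(taxon, []).append(cor)
    return grouped
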