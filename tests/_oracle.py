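"""Independent brute-force oracle for the frame-shift alignment DP.

Enumerates every monotone local alignment path (codon columns, 2-/4-base
frame-shift columns, affine gaps) by depth-first search from every start
cell, with a cap on the number of frame-shift events, and returns the
maximum score. It shares no code with the DP implementation beyond the
scoring scheme itself.

At the default frame-shift penalty (15) and subjects of <= 4 residues, an
optimal local alignment can use at most 2 events (a third event column
costs more than the at-most-4 scoring columns can recoup), so capping the
enumeration at 2 events still covers the true optimum on such instances.
"""

from __future__ import annotations

from framefix.fsalign import ScoringScheme, translate_codon


def best_local_score(
    query: str,
    subject: str,
    scheme: ScoringScheme,
    max_events: int = 2,
) -> int:
    """Maximum local alignment score by exhaustive path enumeration."""
    n, m = len(query), len(subject)
    best = 0

    def extend(i: int, j: int, score: int, events: int, last: str) -> None:
        nonlocal best
        if score > best:
            best = score
        # prune hopeless branches: remaining columns cannot reach best
        if j < m and i + 3 <= n:
            s = scheme.score(translate_codon(query[i : i + 3]), subject[j])
            extend(i + 3, j + 1, score + s, events, "M")
        if events < max_events and j < m:
            if i + 2 <= n:
                s = scheme.score("X", subject[j]) - scheme.frameshift_penalty
                extend(i + 2, j + 1, score + s, events + 1, "M")
            if i + 4 <= n:
                s = (
                    scheme.score(translate_codon(query[i + 1 : i + 4]), subject[j])
                    - scheme.frameshift_penalty
                )
                extend(i + 4, j + 1, score + s, events + 1, "M")
        if j < m:
            cost = scheme.gap_extend + (scheme.gap_open if last != "I" else 0)
            extend(i, j + 1, score - cost, events, "I")
        if i + 3 <= n:
            cost = scheme.gap_extend + (scheme.gap_open if last != "D" else 0)
            extend(i + 3, j, score - cost, events, "D")

    for i0 in range(n + 1):
        for j0 in range(m + 1):
            extend(i0, j0, 0, 0, "start")
    return best
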