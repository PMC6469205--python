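"""Small bundled example datasets."""

from __future__ import annotations

#: Mean long-read and short-read coverage of the longest contig in each of
#: 14 genome bins recovered from an enrichment-bioreactor metagenome that
#: was sequenced on both platforms from the same DNA aliquot. The two
#: coverage estimates are strongly linearly related (Pearson r ~ 0.9988),
#: the expected behaviour when both libraries sample the same community.
BIN_COVERAGE_LR_SR: list[tuple[str, float, float]] = [
    ("B1", 57.3, 117.5),
    ("B2", 384.2, 707.8),
    ("B3", 48.8, 107.6),
    ("B4", 25.1, 56.2),
    ("B5", 52.1, 109.9),
    ("B6", 29.5, 56.1),
    ("B7", 38.7, 90.2),
    ("B8", 32.7, 60.5),
    ("B9", 10.2, 23.2),
    ("B10", 14.1, 27.7),
    ("B11", 15.4, 22.3),
    ("B12", 37.1, 66.0),
    ("B13", 17.6, 28.7),
    ("B14", 13.3, 18.9),
]


def bin_coverage_pairs() -> list[tuple[float, float]]:
    """The 14 (long-read coverage, short-read coverage) pairs."""
    return [(lr, sr) for _, lr, sr in BIN_COVERAGE_LR_SR]
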