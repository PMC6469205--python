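"""Seeded synthetic-data generators with ground truth.

Every generator is a pure function of its parameters and seed, and emits
the truth needed for parameter-recovery tests:

* :func:`simulate_reference` — random coding genes (fixed ATG start, no
  in-frame stops) and their exact translations;
* :func:`simulate_reads` — long reads drawn from the genes with iid
  per-base substitutions and *single-base* indels, the dominant nanopore
  error mode that causes frame-shifts (multi-base indels are deliberately
  excluded so frame-restoration truth stays exact);
* :func:`simulate_tiling_bin` — a long-read contig plus a bin of short-read
  contigs tiling it at a chosen identity and coverage, with the
  analytically expected concordance score;
* :func:`simulate_clone_pairs` — inward-facing read-pair placements on a
  contig whose clone spans avoid a designated gap, so the gap is recovered
  as the unique zero-clone-coverage break-point.

No quality scores and uniform codon usage: the algorithms under test use
neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .asmqc import BestHit, ConcordanceScore, ReadAln
from .fsalign import reverse_complement, translate_codon
from .seqio import NucleotideRecord, ProteinRecord

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SimConfig:
    """Parameters of the read simulation.

    Defaults emulate a long-read sequencing run after basecalling: 1%
    single-base indels and 1% substitutions per base, 2 kb reads, genes
    long enough (>= 700 aa) that a read fits inside one gene.
    """

    seed: int = 0
    n_genes: int = 3
    gene_length_aa: tuple[int, int] = (700, 750)
    indel_rate: float = 0.01
    substitution_rate: float = 0.01
    read_length: tuple[int, int] = (2000, 2000)
    n_reads: int = 200

    def __post_init__(self) -> None:
        for rate in (self.indel_rate, self.substitution_rate):
            if not 0.0 <= rate <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")
        if self.n_genes <= 0 or self.n_reads < 0:
            raise ValueError("counts must be positive")
        for lo, hi in (self.gene_length_aa, self.read_length):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")


@dataclass
class ReadTruth:
    """Provenance and injected errors of one simulated read.

    ``events`` hold (position in the emitted read, kind) with kind one of
    ``ins``/``del``/``sub``; for a deletion the position is where the lost
    base would have been.
    """

    read_id: str
    gene_id: str
    strand: str
    gene_interval: tuple[int, int]
    events: list[tuple[int, str]] = field(default_factory=list)

    def n_indels(self) -> int:
        return sum(1 for _, kind in self.events if kind in ("ins", "del"))


def simulate_reference(
    config: SimConfig,
) -> tuple[list[NucleotideRecord], list[ProteinRecord]]:
    """Random coding genes and their translations (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    dna_records, protein_records = [], []
    lo, hi = config.gene_length_aa
    for g in range(config.n_genes):
        n_aa = int(rng.integers(lo, hi + 1))
        codons = ["ATG"] + [
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_aa - 1)
        ]
        dna = "".join(codons)
        protein = "".join(translate_codon(c) for c in codons)
        dna_records.append(NucleotideRecord(f"gene{g}", dna))
        protein_records.append(ProteinRecord(f"gene{g}", protein))
    return dna_records, protein_records


def _mutate_read(template: str, rng: np.random.Generator, config: SimConfig):
    """Apply iid substitutions and single-base indels; returns (seq, events)."""
    out: list[str] = []
    events: list[tuple[int, str]] = []
    half_indel = config.indel_rate / 2.0
    for base in template:
        r = rng.random()
        if r < half_indel:  # deletion: base lost from the read
            events.append((len(out), "del"))
            continue
        if r < config.indel_rate:  # insertion of a random base before this one
            events.append((len(out), "ins"))
            out.append(str(rng.choice(_BASES)))
        if rng.random() < config.substitution_rate:
            choices = [b for b in "ACGT" if b != base]
            events.append((len(out), "sub"))
            out.append(choices[int(rng.integers(0, 3))])
        else:
            out.append(base)
    return "".join(out), events


def simulate_reads(
    reference: Sequence[NucleotideRecord],
    config: SimConfig,
) -> tuple[list[NucleotideRecord], list[ReadTruth]]:
    """Draw error-injected reads from random gene intervals and strands."""
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.read_length
    reads, truths = [], []
    for k in range(config.n_reads):
        gene = reference[int(rng.integers(0, len(reference)))]
        length = int(rng.integers(lo, hi + 1))
        if length > len(gene.seq):
            raise ValueError(
                f"read length {length} exceeds gene {gene.id} length {len(gene.seq)}"
            )
        start = int(rng.integers(0, len(gene.seq) - length + 1))
        template = gene.seq[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            template = reverse_complement(template)
        seq, events = _mutate_read(template, rng, config)
        read_id = f"read{k}"
        reads.append(NucleotideRecord(read_id, seq))
        truths.append(
            ReadTruth(
                read_id=read_id,
                gene_id=gene.id,
                strand=strand,
                gene_interval=(start, start + length),
                events=events,
            )
        )
    return reads, truths


# ---------------------------------------------------------------------------
# concordance fixture


@dataclass
class TilingBinFixture:
    lr: NucleotideRecord
    contigs: list[NucleotideRecord]
    contig_lengths: dict[str, int]
    hits: list[BestHit]
    expected: ConcordanceScore


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def simulate_tiling_bin(
    lr_length: int = 50_000,
    n_contigs: int = 10,
    identity: float = 1.0,
    coverage_fraction: float = 1.0,
    seed: int = 0,
    n_unrelated: int = 0,
) -> TilingBinFixture:
    """A long-read contig tiled by a bin of short-read contigs.

    Related contigs are abutting windows over the first
    ``coverage_fraction`` of the contig, point-mutated at rate
    ``1 - identity``; unrelated contigs are random sequence with no hit.
    ``expected`` is the concordance score implied by the construction
    parameters alone: c1 = c4 = related fraction, c2 = identity,
    c3 = coverage_fraction. The emitted ``hits`` use realized per-window
    identities, so the measured kappa matches ``expected`` up to sampling
    noise (exactly, at identity 1.0).
    """
    if not 0.8 <= identity <= 1.0:
        raise ValueError("identity must be in [0.8, 1.0]")
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    lr = NucleotideRecord("lr_contig", _random_dna(rng, lr_length))

    covered = max(n_contigs, round(coverage_fraction * lr_length))
    bounds = np.linspace(0, covered, n_contigs + 1).astype(int)
    contigs, hits = [], []
    for c in range(n_contigs):
        a, b = int(bounds[c]), int(bounds[c + 1])
        window = list(lr.seq[a:b])
        n_mut = 0
        if identity < 1.0:
            mutate = rng.random(b - a) < (1.0 - identity)
            for pos in np.nonzero(mutate)[0]:
                alt = [x for x in "ACGT" if x != window[pos]]
                window[pos] = alt[int(rng.integers(0, 3))]
            n_mut = int(mutate.sum())
        cid = f"sr_contig{c}"
        contigs.append(NucleotideRecord(cid, "".join(window)))
        hits.append(
            BestHit(
                contig_id=cid,
                alignment_length=b - a,
                pident=100.0 * (1.0 - n_mut / (b - a)),
                lr_interval=(a, b),
            )
        )
    mean_len = max(1, covered // n_contigs)
    for u in range(n_unrelated):
        contigs.append(NucleotideRecord(f"sr_unrelated{u}", _random_dna(rng, mean_len)))

    total = n_contigs + n_unrelated
    related = n_contigs / total
    expected = ConcordanceScore(
        c1=related, c2=identity, c3=coverage_fraction, c4=related
    )
    return TilingBinFixture(
        lr=lr,
        contigs=contigs,
        contig_lengths={c.id: len(c.seq) for c in contigs},
        hits=hits,
        expected=expected,
    )


# ---------------------------------------------------------------------------
# clone-pair fixture


def simulate_clone_pairs(
    contig: str = "lr_contig",
    contig_length: int = 10_000,
    gap_interval: tuple[int, int] | None = None,
    n_pairs: int = 2000,
    insert_range: tuple[int, int] = (300, 800),
    read_length: int = 150,
    seed: int = 0,
) -> list[ReadAln]:
    """Inward-facing read-pair placements whose clone spans avoid a gap.

    Clone spans are sampled uniformly within each contig segment outside
    ``gap_interval`` (no clone spans the gap); insert sizes are uniform in
    ``insert_range`` (half-open, so the default stays strictly below the
    800 validity cutoff). One boundary-flush clone is additionally anchored
    at each end of each segment so the zero-coverage run recovered
    downstream equals the gap exactly rather than up to sampling jitter.
    """
    lo, hi = insert_range
    if not 0 < lo < hi <= contig_length:
        raise ValueError("insert_range must satisfy 0 < lo < hi <= contig_length")
    if gap_interval is not None:
        g0, g1 = gap_interval
        if not 0 <= g0 < g1 <= contig_length:
            raise ValueError("gap_interval must lie within the contig")
        segments = [s for s in ((0, g0), (g1, contig_length)) if s[1] > s[0]]
    else:
        segments = [(0, contig_length)]
    segments = [s for s in segments if s[1] - s[0] >= lo]
    if not segments:
        raise ValueError("no segment can hold the minimum insert size")

    rng = np.random.default_rng(seed)
    spans: list[tuple[int, int]] = []
    for a, b in segments:  # anchored boundary clones
        L = min(hi - 1, b - a)
        spans.append((a, a + L))
        spans.append((b - L, b))
    seg_lens = np.array([b - a for a, b in segments], dtype=float)
    probs = seg_lens / seg_lens.sum()
    n_random = max(0, n_pairs - len(spans))
    for ix in rng.choice(len(segments), size=n_random, p=probs):
        a, b = segments[ix]
        L = int(rng.integers(lo, min(hi, b - a + 1)))
        s = a + int(rng.integers(0, (b - a) - L + 1))
        spans.append((s, s + L))

    out: list[ReadAln] = []
    for i, (s, e) in enumerate(spans):
        rl = min(read_length, (e - s) // 2)
        rid = f"clone{i}"
        out.append(ReadAln(rid, 1, contig, s, s + rl, "+"))
        out.append(ReadAln(rid, 2, contig, e - rl, e, "-"))
    return out
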