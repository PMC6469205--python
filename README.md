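# framefix

Frame-shift-aware translated alignment and assembly verification for
long-read metagenomes.

Nanopore long reads (and, to a lesser degree, the contigs assembled from
them) carry frequent single-base insertions and deletions. In a
DNA-to-protein alignment each such error shifts the reading frame, which
cripples every downstream tool that relies on translated alignments —
genome quality estimation, annotation, taxonomic binning. `framefix`
implements the computational core of a pipeline for such data:

* **frame-shift-aware local DNA-to-protein alignment** — a Smith-Waterman
  style dynamic programme whose codon columns may consume 2 or 4 query
  bases instead of 3, paying a fixed penalty *F* (default 15) once per
  event. A 2-base column is written `/` (frame decrease) and a 4-base
  column `\` (frame increase) in the alignment transcript;
* **frame-shift correction** — greedy selection of a maximal set of
  non-overlapping alignments per read, then insertion of `N` at each `/`
  and `NN` at each `\`, restoring a single reading frame while keeping an
  exact, invertible coordinate map;
* **range-culling** — positionally aware hit filtering: an alignment is
  dropped only if a retained alignment covers ≥ 50% of its query span and
  out-scores it by more than 10%;
* **interval-union LCA binning** — a read is assigned to the deepest taxon
  whose subtree's alignments cover ≥ 51% of the read's aligned bases
  (union of query intervals), with aligned-base bin counts and a
  genus-level Shannon index *H* = −Σ pᵢ ln pᵢ;
* **assembly verification** — frame-shift events per kilobase of aligned
  sequence; the concordance score κ = (c₁+c₂+c₃+c₄)/4 between a bin of
  short-read contigs and a long-read contig; paired-read clone coverage
  (inward-facing mates, insert < 800 bp) and its zero-coverage
  break-points; repeat rates from ≥ 500 bp self-alignments; Pearson
  correlation of long-read vs short-read coverage;
* **synthetic data** — seeded generators for coding references,
  indel-corrupted reads, tiling bins and clone pairs, each with ground
  truth, so every statistic above can be validated by parameter recovery.

The package is a library: `import framefix` and call functions; the
`examples/` directory holds one short narrative script per capability.

## Worked example

```python
import framefix as ff
from framefix.seqio import NucleotideRecord

cfg = ff.SimConfig(seed=7, n_genes=1, gene_length_aa=(700, 700),
                   read_length=(2000, 2000), n_reads=1, indel_rate=0.01)
dna, prot = ff.simulate_reference(cfg)
reads, truths = ff.simulate_reads(dna, cfg)

hits = ff.align_frameshift(reads[0], prot[0], both_strands=True)
plan = ff.build_plan(hits)
cor = ff.apply_corrections(reads[0], plan)
rehits = ff.align_frameshift(NucleotideRecord(cor.id, cor.seq), prot[0],
                             both_strands=True)
```

Running `python examples/align_and_correct.py` (the same computation)
prints:

```
read read0: 15 indels injected (- strand)
alignment: q[2,2005) score 3253, 9 frame-shift events
corrected: inserted 16 N bases (2005 -> 2021 bp)
re-alignment of corrected read: 0 events, score 3283
```

The read carried 15 single-base indels; the aligner bridged them as 9
frame-shift events (nearby indels merge — see `docs/methods.md`),
correction inserted 16 N bases at those events, and the corrected read
re-aligns with zero events: its translation is back in one frame.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main results from scratch: the coverage
correlation across the bundled 14-bin dataset, a full
simulate → align → correct → re-align pipeline with frame-shift-per-kb
statistics before and after correction, LCA binning with a Shannon
summary, and the tiling-bin and clone-coverage fixtures, then writes its
JSON result file to `--out`.

## Layout

```
src/framefix/
  seqio.py       FASTA / alignment-TSV / PAF / taxonomy-table I/O
  fsalign.py     frame-shift DP, re-scoring, range-culling
  fscorrect.py   alignment selection, N insertion, coordinate maps
  taxbin.py      taxonomy tree, interval-union LCA, Shannon index
  asmqc.py       frame-shift stats, kappa, clones, break-points, repeats
  simulate.py    seeded generators with ground truth
  datasets.py    bundled 14-bin coverage dataset
docs/methods.md  models, conventions, numerical choices, limitations
examples/        one runnable narrative script per capability
```
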