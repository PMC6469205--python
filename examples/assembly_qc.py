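"""Assembly-verification statistics on constructed inputs.

Computes the concordance score kappa for a bin tiling a long-read contig,
the repeat rate of a contig with a duplicated segment, and the long-read
vs short-read coverage correlation on the bundled 14-bin dataset.
"""

import framefix as ff
from framefix.seqio import PafRow

# concordance: 10 short-read contigs perfectly tiling a 30 kb contig
fix = ff.simulate_tiling_bin(lr_length=30000, n_contigs=10, identity=0.98,
                             coverage_fraction=0.9, seed=1)
cs = ff.concordance(len(fix.lr.seq), fix.contig_lengths, fix.hits)
print(f"concordance: c1={cs.c1:.3f} c2={cs.c2:.3f} c3={cs.c3:.3f} "
      f"c4={cs.c4:.3f} -> kappa={cs.kappa:.3f}")
# kappa near 1 = the bin's contigs tile the contig at high identity

# repeat rate: a 10 kb contig whose 2-3 kb segment recurs at 7-8 kb
def self_hit(qs, qe, ts, te, L=10000):
    return PafRow("c", L, qs, qe, "+", "c", L, ts, te, qe - qs, qe - qs, 60)

rows = [self_hit(0, 10000, 0, 10000),      # trivial diagonal, ignored
        self_hit(2000, 3000, 7000, 8000)]  # a real 1 kb repeat pair
mask, rate = ff.repeat_mask(rows)
print(f"repeat mask {mask} -> repeat rate {rate:.1f}%")

# coverage correlation across the 14 bundled genome bins
r = ff.pearson(ff.datasets.bin_coverage_pairs())
print(f"LR vs SR coverage over 14 bins: Pearson r = {r:.4f}")
# r near 1: both sequencing platforms sample the community evenly
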