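"""Detect assembly break-points from paired-read clone coverage.

Simulates 2000 read-pair clones on a 10 kb contig whose spans avoid the
interval [4000, 4500) — emulating a mis-joined region no clone crosses —
and recovers that interval as the unique zero-coverage break-point.
"""

import framefix as ff

alns = ff.simulate_clone_pairs(contig_length=10000, gap_interval=(4000, 4500),
                               n_pairs=2000, insert_range=(300, 800), seed=4)
profile = ff.clone_coverage(alns, "lr_contig", 10000,
                            ff.CloneParams(max_insert=800))
print(f"clone coverage: min={profile.min()} max={profile.max()} "
      f"mean={profile.mean():.1f}")

for bp in ff.find_breakpoints(profile, "lr_contig"):
    tag = " (terminal)" if bp.terminal else ""
    print(f"potential break-point: [{bp.start}, {bp.end}){tag}")
# a zero-coverage stretch away from the contig ends is a candidate
# assembly error; terminal runs are expected (clones cannot span an end)
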