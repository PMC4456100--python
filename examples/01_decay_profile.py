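"""H3K9me3 decay around TEs, against the matched random-segment null.

Simulates a genome with silenced TE insertions, profiles the repressive-mark
density in 1-kb windows over every clean intergenic 10-kb flank, and
contrasts the observed profile with random TE-size segments matched in
length, chromosome, and 4-Mb locality bin.
"""
import numpy as np

import tespread as ts
from tespread.genome import intergenic_intervals

cfg = ts.SynthConfig(seed=11, stages=("embryo_0_4h",))
ds = ts.simulate_dataset(cfg)
track = ts.clamp_track(ds.tracks[0])
mask = intergenic_intervals(ds.annotation)

profile = ts.te_flank_decay_profile(ds.annotation.tes, track, mask)
null = ts.matched_null_ensemble(
    ds.annotation.tes, ds.annotation, track, mask, n_reps=100, seed=cfg.seed
)
lo, hi = null.window_percentile_band("median")

print(f"{profile.n_flanks} clean intergenic flanks from {len(ds.annotation.tes)} TEs")
print("window(kb)  median  null 2.5-97.5%")
for i in range(10):
    print(f"  {i}-{i + 1:<8}{profile.median[i]:.4f}  [{lo[i]:.4f}, {hi[i]:.4f}]")
p = ts.window_contrast(profile, 1, 10)
print(f"window 1 vs window 10, Mann-Whitney U two-sided p = {p:.3g}")
print(
    "The median density decays toward background with distance from the TE\n"
    "edge; windows near TEs sit far above the matched-null band, the\n"
    "signature of heterochromatin spreading from silenced insertions."
)
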