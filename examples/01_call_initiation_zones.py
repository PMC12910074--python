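"""Call class-stratified replication initiation zones on a synthetic genome.

Simulates the two origin-mapping assays (an early-S arrested-fork track and a
mid/late track on a genome whose early territory has already replicated),
calls IZs with the class-specific thresholds (50% / 25% / 5% of the top bins)
and checks the calls against the planted origins.
"""

import pandas as pd

from repliczone import IZCallingConfig, IZSet, IntervalSet, call_izs
from repliczone.simulate import (SimConfig, callable_origins, evaluate_recovery,
                                 simulate_calling_tracks)

cfg = SimConfig(seed=7)                      # 3 x 20 Mb, ~120 planted origins
tracks, truth = simulate_calling_tracks(cfg)
print(f"planted origins: {truth.origins.groupby('rt_class').size().to_dict()}")

call_cfg = IZCallingConfig(rng_seed=7)
no_blacklist = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
early, prov = call_izs(tracks["early"], truth.domains, no_blacklist, call_cfg,
                       classes=("early",))
midlate, _ = call_izs(tracks["midlate"], truth.domains, no_blacklist, call_cfg,
                      classes=("mid", "late"))
izs = IZSet.union([early, midlate])
print(f"called IZs:      {izs.df.groupby('rt_class').size().to_dict()}")
print(f"early-class threshold used: {prov['per_class']['early']['threshold']:.1f} BPM")

# recovery against the callable planted origins (mid/late origins inside the
# 500 kb exclusion buffer cannot legitimately be reported and are not counted)
stats = evaluate_recovery(izs, callable_origins(truth), tolerance=20_000)
for cls, s in stats.items():
    print(f"{cls:>5}: recall {s['recall']:.2f}  precision {s['precision']:.2f} "
          f"(n_truth={s['n_truth']})")
# recall/precision ~1.0 here: at 40x depth the arrested-fork peaks of even
# 10%-efficient late origins stand far above the Poisson background
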