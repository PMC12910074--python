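# repliczone

Analysis of DNA replication initiation zones (IZs) from binned nascent-DNA
coverage tracks (EdU-seq / Repli-seq style data), for researchers studying
how origin-firing efficiency shapes the replication-timing (RT) program.

The package implements, as a tested reusable library:

* **Class-stratified IZ calling.** The genome is partitioned into early/mid/
  late RT domains (loaded from an external caller's BED or computed by a
  simplified six-fraction classifier). On a BPM-normalized track binned at
  1 kb, a class-specific threshold is set at a fraction *f*<sub>class</sub> of
  the mean of that class's top-10 bins — *f* = 50%, 25%, 5% for early, mid,
  late, the stricter late cutoff compensating the lower peak-to-background
  ratio. Above-threshold runs form broad regions; within each region, bins at
  or above the region median define candidate IZs; candidates are filtered
  against a blacklist, centers refined to the signal-weighted centroid, and
  mid/late calls within 500 kb of an earlier-replicating domain are discarded
  (signal there could come from incoming forks rather than initiation).
  chrY calls are dropped, and a seeded generator produces matched random
  control positions ≥ 50 kb from every IZ center.
* **Fork-speed estimation.** Averaged signal profiles around isolated IZs
  (≥ 100 kb from any other IZ) across a pulse time course; the half-maximum
  front of the profile at the 2 h reference gives the starting point and
  speed<sub>t</sub> = (front<sub>t</sub> − front<sub>ref</sub>)/(t − ref).
* **IZ-centric statistics.** log2(BPM+1) S-phase time courses with per-class
  medians, local-background-subtracted central signal (mean of the outer
  100 kb of the plotted window subtracted from the central 1 kb bin),
  Wilcoxon rank-sum comparisons, nearest TSS/TTS/enhancer distances, and
  TPM decile stratification with fraction-by-decile occupancy.
* **Paired-condition residual regression.** Per IZ, signal is the mean BPM
  over ±5 kb around the center in OCT4-ON and OCT4-OFF conditions;
  `residual = log2(ON) − log2(OFF) = log2(ON/OFF)` is regressed per RT class
  on log2(ON), testing the null that the slope is zero (t test, n−2 df).
* **A stochastic S-phase simulator.** Planted RT-domain blocks and origins;
  exponential class-specific firing times (truncated at the 9 h S-phase
  length), bidirectional forks at constant speed with passive replication by
  the nearest incoming fork; closed-form expected labeling for any EdU pulse
  window, validated against a per-cell Monte-Carlo simulation; six-fraction
  sorted output; blacklist artifact spikes; paired ON/OFF tracks with a
  planted class-dependent depletion effect.

## Worked example

```python
import pandas as pd
from repliczone import IZCallingConfig, IZSet, IntervalSet, call_izs
from repliczone.simulate import (SimConfig, callable_origins,
                                 evaluate_recovery, simulate_calling_tracks)

tracks, truth = simulate_calling_tracks(SimConfig(seed=7))
cfg = IZCallingConfig(rng_seed=7)
empty = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
early, _ = call_izs(tracks["early"], truth.domains, empty, cfg, classes=("early",))
midlate, _ = call_izs(tracks["midlate"], truth.domains, empty, cfg,
                      classes=("mid", "late"))
izs = IZSet.union([early, midlate])
print(izs.df.groupby("rt_class").size().to_dict())
print(evaluate_recovery(izs, callable_origins(truth), tolerance=20_000))
```

prints

```
{'early': 43, 'late': 19, 'mid': 18}
{'early': {'n_truth': 43, 'n_called': 43, 'recall': 1.0, 'precision': 1.0},
 'mid':   {'n_truth': 18, 'n_called': 18, 'recall': 1.0, 'precision': 1.0},
 'late':  {'n_truth': 19, 'n_called': 19, 'recall': 1.0, 'precision': 1.0}}
```

i.e. on the default synthetic genome (3 × 20 Mb, ~120 planted origins with
firing efficiencies 0.8/0.4/0.1) every callable planted origin — those the
blacklist/exclusion rules allow to be reported — is recovered with a center
within ±20 kb, and nothing spurious is called. The `examples/` directory has
one short script per capability (IZ calling, fork speed, residual
regression, signal statistics, full pipeline); each prints the numbers it
computes and a line on what they mean.

A thin CLI wraps the same functions for shell use:

```bash
repliczone run --out-dir demo_run --seed 7          # full demo pipeline
repliczone simulate --out-dir sim --seed 7          # synthetic dataset
repliczone call-izs --track sim/edu_calling_early.bpm.bedgraph \
    --genome sim/genome.tsv --domains sim/domains.bed \
    --blacklist sim/blacklist.bed --classes early --out-prefix calls
```

Real data enter the same way: bedGraph coverage tracks, a labeled domain BED
(e.g. from an external RT-domain caller, via `repliczone domains-load`), and
a blacklist BED.

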