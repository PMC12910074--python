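# Methods

## Signal model and conventions

All analyses operate on `BinnedTrack` objects: per-chromosome fixed-width bin
arrays of non-negative coverage, either raw counts or BPM (bins per million:
value × 10⁶ / genome-wide sum, so every BPM track sums to 10⁶ regardless of
sequencing depth). Coordinates are 0-based half-open throughout; a partial
terminal bin is kept and weighted by its true bp width in every mean.
Rebinning from bedGraph uses the coverage-weighted mean, with weights stored
as bin fractions so that a bin covered by a single interval reads back its
value bit-for-bit.

## IZ calling

Calling is stratified by replication-timing class because the same absolute
signal means different things in early and late territory: late assays have
intrinsically lower peak-to-background ratios. Stages, in order:

1. **Bin assignment.** 1 kb bins belong to the domain containing their
   midpoint. When a blacklist is supplied, blacklisted bins are masked here —
   before thresholding — because a handful of artifact bins at ~50× the real
   peak level would otherwise set the class reference level and suppress all
   genuine calls. Domains are split at masked bins so no region spans one.
2. **Class threshold.** `fraction × mean(top-k bins of the class)`, with
   k = 10 and fractions 0.50 / 0.25 / 0.05 for early / mid / late. The top-k
   mean (rather than the single maximum) keeps the reference level robust to
   isolated spikes; k is configurable. Thresholds are genome-wide per class,
   not per chromosome. A non-positive reference level (empty or fully masked
   class) yields no calls rather than calling everything.
3. **Broad regions.** Maximal runs of above-threshold bins; runs separated
   by at most `merge_gap` (2 kb) of sub-threshold signal are fused. Regions
   never cross a domain boundary, so no IZ straddles two classes.
4. **Refinement.** Within each broad region, bins at or above the region
   median are retained (ties inclusive, so constant regions survive); each
   retained run of ≥ `min_width` (2) bins becomes one candidate IZ. The
   2-bin minimum suppresses single-bin shot noise, which matters because any
   single stray read can exceed the late-class threshold.
5. **Blacklist filter.** Candidates sharing ≥ 1 bp with a blacklist interval
   are discarded (logged); with masking in stage 1 this is a safety net.
6. **Center refinement.** The signal-weighted centroid of the IZ's bins
   (bin midpoints as positions), snapped to the nearest point of the
   `refine_resolution` grid (1 kb; numpy round, ties to even) and clipped
   into the interval; zero-signal IZs fall back to the geometric midpoint.
   A centroid on the coverage track replaces alignment-level summit
   refinement because this artifact starts from tracks, not alignments, and
   downstream steps only need a stable center.
7. **Exclusion zone.** Mid IZs whose center is < 500 kb from any early
   domain, and late IZs < 500 kb from any early or mid domain, are
   discarded: forks initiated in the earlier neighbour can travel that far
   within the labeling window (≈ 5 h at ~108 kb/h), so nearer signal cannot
   be distinguished from passive replication. Distance is measured center to
   nearest domain bp.
8. **chrY drop and controls.** Configurable chromosome drop list (default
   chrY). Control regions: 10⁷ uniform 1-bp candidates on the retained
   chromosomes, positions within ±50 kb of any refined IZ center removed,
   survivors shuffled, first 1000 kept. One named seed governs the sampling.

Every stage logs its discard count into a provenance record emitted with the
calls.

## Fork speed

Isolated IZs (center ≥ 100 kb from every other IZ center) are profiled
±500 kb at 1 kb resolution per time point; per-offset means are averaged
across IZs (accumulated in sorted center order so the result is exactly
permutation invariant) and the lowest per-offset mean is subtracted as
background. The fork front of a profile is, per side, the first offset
beyond that side's maximum where the profile drops below `level_fraction`
(default 0.5) of the profile maximum, with the crossing linearly
interpolated between grid points; left and right fronts are averaged
(bidirectional forks assumed symmetric), and per-side values are available.
Taking the first crossing outward from the peak rather than the outermost
above-threshold offset makes the front robust to shoulders contributed by
neighbouring zones and adjacent domains at later time points. Speeds are
front displacements from the 2 h reference profile divided by elapsed time;
negative displacements are floored at zero with a warning. The ±500 kb flank
caps measurable fronts, so estimates saturate once forks have travelled
≈ 450 kb from their origin (≈ 6 h at 108 kb/h past the reference).

## RT-domain classification

The six-fraction classifier computes, per 10 kb bin, the signal-weighted
mean fraction index T = Σk·s_k / Σs_k (k = 1..6) after a centered moving
average (default 5 bins = 50 kb) and thresholds T at 2.5 / 4.5 (splitting
the six fractions 2/2/2). Two adaptive modes exist because fixed cutpoints
assume classes sit centered in "their" fractions, which passive replication
violates: `"tercile"` cuts at the genome-wide 1/3 and 2/3 quantiles of T
(assumes balanced class shares), `"kmeans"` at the midpoints of
deterministic 1-D 3-means. Bins below a signal floor (default 10% of the
genome-mean total) take the label of the nearest valid bin. This classifier
is a deliberately simple stand-in for wavelet-based domain callers; for real
data, an external caller's labeled BED via `load_domains` is the recommended
route.

## Residual regression

Signals are window means over ±5 kb around each IZ center in both
conditions; IZs whose window leaves the chromosome are dropped from both.
With pseudocount ε = 0.01 BPM (configurable, recorded),
residual = log2(ON+ε) − log2(OFF+ε), and per class an OLS fit of
residual ~ log2(ON+ε) is tested against a zero slope (t distribution,
n−2 df). Known caveat, reported rather than corrected: regressing a
difference on one of its terms produces a positive slope under independent
measurement noise alone; `null_slope_calibration` ships the corresponding
null simulation (noise-free predictor: rejection calibrates to α) so
observed slopes can be judged against that baseline.

## The simulator

The generator emulates the statistical structure the analysis assumes, not
sequencing reads:

* **Genome.** 3 × 20 Mb chromosomes, 1 kb bins. Domain blocks of uniform
  0.5–3 Mb length in a graded early–mid–late–mid ripple (mid blocks halved
  since mid appears twice per cycle, keeping class shares ≈ 1/3 each). The
  graded adjacency is deliberate: with a uniform fork speed, an abrupt
  early|late junction would be passively over-replicated hundreds of kb into
  the late block, which real genomes avoid by grading their timing.
* **Firing.** Each planted origin fires at g1 + T, T ~ Exp(λ_class)
  conditioned on T ≤ 9 h (S length). Defaults λ = 1.5 / 0.35 / 0.08 h⁻¹ for
  early/mid/late reproduce early firing within ~2 h of release and late
  firing continuing to the end of S; G1 is 1.5 h. The memoryless law is a
  modeling choice — no firing-time distribution is identifiable from bulk
  tracks — and its heavy tail is the main reason class timing distributions
  overlap.
* **Replication.** Forks move bidirectionally at 108 kb/h; a bin replicates
  at the first arrival over all origins on its chromosome, so passive
  replication is inherent. P(bin unreplicated at s) is the product of
  per-origin truncated-exponential survivals shifted by travel time, giving
  closed-form pulse-window labeling probabilities; a per-cell Monte-Carlo
  implementation of the same model (inversion sampling, explicit minima)
  validates it bin by bin.
* **Reads.** Expected labeling (+ a flat background fraction, default 0.002)
  is scaled so the genome-wide mean reads/bin equals the depth (default 40)
  and Poisson sampled per library; tracks are then BPM-normalized, exactly
  as real libraries of different depths are made comparable.
* **Calling assays.** The origin-mapping tracks are modeled
  phenomenologically as triangular arrested-fork peaks (half-width 10 kb)
  whose amplitude is the class firing efficiency (0.8 / 0.4 / 0.1 — the
  fraction of cells contributing nascent DNA at the origin during the
  assay): one track with only early origins active, one with early territory
  already replicated and mid/late origins peaked.
* **Six-fraction sorting.** S phase is cut at the five time points where the
  genome-wide expected replicated fraction reaches 1/6 … 5/6; fraction k's
  expected signal per 10 kb bin is the probability of replicating inside
  window k. The six windows tile all of S, so expected fractions sum to 1
  per bin.
* **OCT4-ON/OFF pairs.** Per-IZ rate heterogeneity (log-normal, σ = 0.5 in
  log2) spreads within-class strength; ON amplitude is the firing
  probability by the assay time (1 h into S). The planted depletion effect
  is per-IZ: δ_i = β_class · (x_i − x̄_class) + β_class with x = log2
  amplitude, so the class-mean rate attenuation is 2^(−β_class) *and* the
  planted residual-vs-log2(ON) slope of each class equals β_class (defaults
  0.05 / 0.2 / 0.6). Both tracks carry multiplicative log-normal noise
  (σ = 0.2 in log2) before Poisson sampling. A separate direct generator
  (`simulate_paired_signals`) draws from the regression model itself for
  controlled slope-recovery checks.
* **Artifacts and features.** Blacklist spikes: constant 50×-maximum
  intervals (3 kb) at random positions with the matching BED. Enhancers are
  planted around origins at class-specific offset scales (5/25/75 kb,
  closest to early), TSS/TTS pairs uniformly with log-normal gene lengths.

All outputs are bit-for-bit reproducible from (config, seed); every stage
derives its generator stream from the one config seed.

### What the simulator does not emulate

No read-level effects (GC bias, mappability, duplicates), no fine-scale
chromatin structure, no cell-to-cell variation in fork speed, no
origin-licensing depletion, and domain labels are hard blocks while real RT
is continuous. Passing tests therefore certify the pipeline's logic and its
statistical calibration on data matching its assumptions — not performance
on real libraries, where upstream alignment and normalization choices
dominate.

## Measured behaviour and limitations

* IZ recovery on the default conditions (efficiencies 0.8/0.4/0.1, 40×
  depth): recall and precision 1.0 for all classes at ±20 kb tolerance,
  measured against the callable planted origins (mid/late origins inside the
  500 kb exclusion buffer cannot legitimately be reported and are excluded
  from the denominator).
* Fork speeds 30/60/108 kb/h are recovered within a few percent from
  2/4/6 h pulses; the hydroxyurea configuration (speed × 0.5) recovers a
  0.49–0.50 speed ratio.
* Planted-label recovery of the six-fraction domain classifier is ≈ 78% at
  the default simulation scale under every thresholding mode: the
  exponential firing tails overlap class timing, and bins near domain
  boundaries genuinely replicate with the earlier class (transition zones),
  so their planted label is not expressed in the observable. Under
  well-separated timing (2–3 Mb domains on 40 Mb chromosomes, 100 kb origin
  spacing, rates 4.0/0.45/0.05 h⁻¹, 30 kb/h forks, tercile thresholds)
  recovery is 95–96% genome-wide. Treat the classifier as a convenience, not
  a domain caller.
* The Monte-Carlo/closed-form agreement criterion is applied as "≤ 1% of
  bins beyond 3 SE and max |z| ≤ 5": the maximum of ~1000 null z-scores
  routinely exceeds 3, so a literal per-bin 3 SE bound on the maximum would
  reject a correct implementation most of the time.
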