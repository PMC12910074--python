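# Full-pipeline configuration with the package defaults spelled out.
# Run with:  repliczone run --out-dir demo_run --seed 7 --config run_config.yaml

seed: 7
timecourse_times: [2, 4, 6]
reference_time_h: 2.0        # profile used as the fork-front starting point
isolation_distance: 100000   # IZs closer than this to any other IZ are not
                             # used for fork-speed profiles
oct4_half_width: 5000        # +/- window around IZ centers for paired signal

sim:
  chrom_count: 3
  chrom_length: 20000000
  bin_size: 1000
  domain_min_bp: 500000      # replication-timing domain block lengths
  domain_max_bp: 3000000
  iz_spacing: {early: 300000, mid: 500000, late: 600000}
  firing_rate_per_h: {early: 1.5, mid: 0.35, late: 0.08}
  firing_efficiency: {early: 0.8, mid: 0.4, late: 0.1}
  s_phase_length_h: 9.0
  g1_length_h: 1.5
  fork_speed_kb_h: 108.0
  hu_speed_factor: 0.5       # hydroxyurea mode multiplies fork speed by this
  hu_rate_factor: 1.0
  pulse_width_h: 0.5         # EdU added 30 min before each harvest
  depth_mean_reads: 40.0     # mean reads per bin per library
  background_fraction: 0.002
  call_peak_halfwidth: 10000 # arrested-fork peak half-width in calling assays
  oct4_beta: {early: 0.05, mid: 0.2, late: 0.6}
  oct4_noise_sigma: 0.2
  oct4_rate_spread: 0.5
  oct4_time_after_s_h: 1.0
  blacklist_n: 4
  blacklist_width: 3000
  blacklist_amplitude: 50.0
  enhancer_offset_scale: {early: 5000, mid: 25000, late: 75000}
  seed: 7

calling:
  bin_size: 1000
  class_fractions: {early: 0.50, mid: 0.25, late: 0.05}  # of the top-bin level
  highest_bins_k: 10         # bins defining the class reference level
  merge_gap: 2000            # sub-threshold gap fused within one broad region
  min_width: 2               # minimum IZ width in bins
  refine_resolution: 1000    # summit (centroid) snapping grid
  exclusion_distance: 500000 # mid/late calls this close to earlier domains
                             # are discarded (incoming-fork buffer)
  control_candidates: 10000000
  control_flank: 50000       # exclusion around IZ centers for controls
  control_n: 1000
  rng_seed: 7
  drop_chroms: [chrY]
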