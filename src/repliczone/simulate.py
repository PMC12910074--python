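"""Ground-truthed stochastic S-phase simulator.

The generator plants a block-structured genome of early/mid/late
replication-timing domains hosting discrete initiation zones (origins), and
produces the track types the analysis consumes:

* EdU pulse time courses: each origin fires at g1 + T with T drawn from an
  exponential law with a class-specific rate (truncated at the S-phase
  length, i.e. conditioned on firing within S), forks then progress
  bidirectionally at a constant speed, and a bin is replicated at the first
  arrival among all origins on the chromosome (passive replication by
  incoming forks included). The probability that a bin's replication time
  falls inside a pulse window has a closed form as a product of per-origin
  survival functions; read counts are Poisson draws around it.
* class-specific "calling" tracks: the arrested-fork assays used for IZ
  mapping, modeled as sharp triangular peaks whose amplitude is the class
  firing efficiency (the fraction of cells in which the origin produced
  nascent DNA during the assay).
* six-fraction sorted S-phase (Repli-seq-like) tracks, by splitting S phase
  at genome-wide equal-replicated-fraction boundaries.
* paired OCT4-ON / OCT4-OFF tracks with a planted class-dependent effect:
  stronger zones of a class lose proportionally more firing upon depletion,
  so the planted residual-regression slope of each class equals beta_class.
* blacklist-style artifact spikes and TSS/TTS/enhancer feature sets.

Domain adjacency is graded (early-mid-late-mid ripple): with a uniform fork
speed, an abrupt early|late junction would be passively over-replicated deep
into the late block, which real genomes avoid by grading their timing.

Sequencing depth is the mean read count per bin across the genome for each
library; tracks are returned raw and are BPM-normalized by the pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import RT_CLASSES, BinnedTrack, Genome, IntervalSet, PointFeatureSet
from .iz_calling import EXCLUDED_BY, IZSet, _distance_to_intervals
from .rt_domains import RTDomainMap
from .track_io import bpm_normalize

#: domain label sequence repeated along each chromosome
RIPPLE = ("early", "mid", "late", "mid")


@dataclass
class SimConfig:
    chrom_count: int = 3
    chrom_length: int = 20_000_000
    bin_size: int = 1000
    domain_min_bp: int = 500_000
    domain_max_bp: int = 3_000_000
    class_proportions: dict = field(
        default_factory=lambda: {"early": 1 / 3, "mid": 1 / 3, "late": 1 / 3})
    iz_spacing: dict = field(
        default_factory=lambda: {"early": 300_000, "mid": 500_000, "late": 600_000})
    firing_rate_per_h: dict = field(
        default_factory=lambda: {"early": 1.5, "mid": 0.35, "late": 0.08})
    firing_efficiency: dict = field(
        default_factory=lambda: {"early": 0.8, "mid": 0.4, "late": 0.1})
    s_phase_length_h: float = 9.0
    g1_length_h: float = 1.5
    fork_speed_kb_h: float = 108.0
    hu_speed_factor: float = 0.5
    hu_rate_factor: float = 1.0
    pulse_width_h: float = 0.5
    depth_mean_reads: float = 40.0
    background_fraction: float = 0.002
    call_peak_halfwidth: int = 10_000
    oct4_beta: dict = field(
        default_factory=lambda: {"early": 0.05, "mid": 0.2, "late": 0.6})
    oct4_noise_sigma: float = 0.2
    oct4_rate_spread: float = 0.5
    oct4_time_after_s_h: float = 1.0
    blacklist_n: int = 4
    blacklist_width: int = 3000
    blacklist_amplitude: float = 50.0
    enhancer_offset_scale: dict = field(
        default_factory=lambda: {"early": 5_000, "mid": 25_000, "late": 75_000})
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(r <= 0 for r in self.firing_rate_per_h.values()):
            raise ValueError("firing rates must be > 0")
        if self.fork_speed_kb_h <= 0:
            raise ValueError("fork speed must be > 0")


@dataclass
class SimulationTruth:
    """Everything needed to recompute every expected signal."""

    genome: Genome
    domains: RTDomainMap
    origins: pd.DataFrame  # chrom, pos, rt_class, lam, efficiency, strength
    fork_speed_kb_h: float
    beta: dict
    seed: int
    config: SimConfig

    def origins_for(self, chrom: str) -> pd.DataFrame:
        return self.origins[self.origins["chrom"] == chrom]

    def to_json(self, path) -> None:
        payload = {
            "genome": {c: int(self.genome.chrom_lengths[c])
                       for c in self.genome.chrom_names},
            "domains": self.domains.intervals.df.to_dict(orient="list"),
            "origins": self.origins.to_dict(orient="list"),
            "fork_speed_kb_h": self.fork_speed_kb_h,
            "beta": self.beta,
            "seed": self.seed,
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genome = Genome.from_dict(payload["genome"])
        domains = RTDomainMap(
            IntervalSet(pd.DataFrame(payload["domains"]), genome=genome),
            payload["config"]["bin_size"])
        return cls(genome, domains, pd.DataFrame(payload["origins"]),
                   payload["fork_speed_kb_h"], payload["beta"], payload["seed"],
                   SimConfig(**payload["config"]))


# ---------------------------------------------------------------------------
# genome planting

def plant_genome(config: SimConfig) -> SimulationTruth:
    """Plant domains and origins; deterministic in config.seed."""
    rng = np.random.default_rng([config.seed, 0])
    names = tuple(f"chr{i + 1}" for i in range(config.chrom_count))
    genome = Genome(names, {n: config.chrom_length for n in names})
    dom_rows = []
    ori_rows = []
    for ci, chrom in enumerate(names):
        pos = 0
        k = rng.integers(0, len(RIPPLE))  # random phase per chromosome
        while pos < config.chrom_length:
            label = RIPPLE[k % len(RIPPLE)]
            k += 1
            length = rng.uniform(config.domain_min_bp, config.domain_max_bp)
            if label == "mid":
                # mid appears twice per ripple cycle; halve its blocks so the
                # default class proportions stay ~ 1/3 each
                length = max(config.domain_min_bp / 2, length / 2)
            end = min(config.chrom_length, int(pos + length))
            dom_rows.append((chrom, pos, end, label))
            spacing = config.iz_spacing[label]
            p = pos + rng.uniform(0.3, 1.0) * spacing
            while p < end - config.call_peak_halfwidth:
                if p > pos + config.call_peak_halfwidth:
                    ori_rows.append((chrom, int(p), label))
                p += spacing * rng.uniform(0.7, 1.3)
            pos = end
    domains = RTDomainMap(
        IntervalSet(pd.DataFrame(dom_rows, columns=["chrom", "start", "end", "label"]),
                    genome=genome), config.bin_size)
    origins = pd.DataFrame(ori_rows, columns=["chrom", "pos", "rt_class"])
    origins["lam"] = origins["rt_class"].map(config.firing_rate_per_h)
    origins["efficiency"] = origins["rt_class"].map(config.firing_efficiency)
    origins["strength"] = 2.0 ** rng.normal(0.0, config.oct4_rate_spread, len(origins))
    return SimulationTruth(genome, domains, origins, config.fork_speed_kb_h,
                           dict(config.oct4_beta), config.seed, config)


# ---------------------------------------------------------------------------
# replication-time law

def _trunc_exp_sf(u: np.ndarray, lam: float, L: float) -> np.ndarray:
    """P(T > u) for T ~ Exp(lam) conditioned on T <= L (origin fires within S)."""
    u = np.asarray(u, dtype=float)
    denom = 1.0 - math.exp(-lam * L)
    core = (np.exp(-lam * np.clip(u, 0.0, L)) - math.exp(-lam * L)) / denom
    return np.where(u <= 0, 1.0, np.where(u >= L, 0.0, core))


def replication_survival(truth: SimulationTruth, chrom: str, times,
                         hu: bool = False,
                         bin_centers: np.ndarray | None = None) -> np.ndarray:
    """P(bin not yet replicated at each time) for every bin of ``chrom``.

    Times are hours after release (mitotic exit); S phase starts at
    g1_length_h. Returns an (n_bins, n_times) array. The product form follows
    from independent origin firing with nearest-arrival-first replication.
    """
    cfg = truth.config
    times = np.atleast_1d(np.asarray(times, dtype=float))
    v = cfg.fork_speed_kb_h * 1000.0 * (cfg.hu_speed_factor if hu else 1.0)
    rate_scale = cfg.hu_rate_factor if hu else 1.0
    if bin_centers is None:
        n = truth.genome.n_bins(chrom, cfg.bin_size)
        bin_centers = (np.arange(n) + 0.5) * cfg.bin_size
    S = np.ones((len(bin_centers), len(times)))
    t = times[None, :]
    for row in truth.origins_for(chrom).itertuples(index=False):
        arrival = np.abs(bin_centers - row.pos)[:, None] / v
        u = t - cfg.g1_length_h - arrival
        S *= _trunc_exp_sf(u, row.lam * rate_scale, cfg.s_phase_length_h)
    return S


def expected_labeling(truth: SimulationTruth, t0: float, t1: float,
                      hu: bool = False) -> dict[str, np.ndarray]:
    """Per-bin probability of being replicated during (t0, t1], per chromosome."""
    out = {}
    for chrom in truth.genome.chrom_names:
        S = replication_survival(truth, chrom, [t0, t1], hu=hu)
        out[chrom] = S[:, 0] - S[:, 1]
    return out


def monte_carlo_labeling(truth: SimulationTruth, chrom: str, t0: float, t1: float,
                         n_cells: int = 10_000, hu: bool = False,
                         region: tuple[int, int] | None = None,
                         seed: int = 12345) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell simulation of the same firing model; (fraction, stderr) per bin.

    Independent of the closed form: firing times are drawn per cell by
    inversion of the truncated exponential, replication times are explicit
    minima over origins, and labeling is counted.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    v = cfg.fork_speed_kb_h * 1000.0 * (cfg.hu_speed_factor if hu else 1.0)
    rate_scale = cfg.hu_rate_factor if hu else 1.0
    start, end = region or (0, truth.genome.chrom_lengths[chrom])
    b0, b1 = start // cfg.bin_size, math.ceil(end / cfg.bin_size)
    centers = (np.arange(b0, b1) + 0.5) * cfg.bin_size
    oris = truth.origins_for(chrom)
    pos = oris["pos"].to_numpy(float)
    lam = oris["lam"].to_numpy(float) * rate_scale
    L = cfg.s_phase_length_h
    arrival = np.abs(centers[:, None] - pos[None, :]) / v  # bins x origins
    counts = np.zeros(len(centers))
    for _ in range(n_cells):
        u = rng.random(len(pos))
        T = -np.log(1.0 - u * (1.0 - np.exp(-lam * L))) / lam  # truncated exp
        R = cfg.g1_length_h + np.min(T[None, :] + arrival, axis=1)
        counts += (t0 < R) & (R <= t1)
    frac = counts / n_cells
    se = np.sqrt(frac * (1 - frac) / n_cells)
    return frac, se


# ---------------------------------------------------------------------------
# track assembly

def _tracks_from_probability(truth: SimulationTruth, probs: dict[str, np.ndarray],
                             rng: np.random.Generator,
                             bin_size: int | None = None) -> BinnedTrack:
    """Poisson read counts at the depth's genome-mean, as a raw-count track."""
    cfg = truth.config
    bin_size = bin_size or cfg.bin_size
    mean_p = float(np.mean(np.concatenate(list(probs.values()))))
    scale = cfg.depth_mean_reads / mean_p if mean_p > 0 else 0.0
    data = {c: rng.poisson(scale * probs[c]).astype(float)
            for c in truth.genome.chrom_names}
    return BinnedTrack(truth.genome, bin_size, data, units="raw_count")


def simulate_edu_timecourse(config: SimConfig, times=(2, 4, 6, 8, 10, 12),
                            hu: bool = False, normalize: bool = True
                            ) -> tuple[dict[float, BinnedTrack], SimulationTruth]:
    """EdU pulse tracks (EdU added pulse_width_h before each harvest time)."""
    truth = plant_genome(config)
    cfg = config
    tracks = {}
    for k, t in enumerate(times):
        probs = expected_labeling(truth, t - cfg.pulse_width_h, t, hu=hu)
        for chrom in probs:
            probs[chrom] = probs[chrom] + cfg.background_fraction
        rng = np.random.default_rng([cfg.seed, 1, k, int(hu)])
        track = _tracks_from_probability(truth, probs, rng)
        tracks[float(t)] = bpm_normalize(track) if normalize else track
    return tracks, truth


def _peak_profile(truth: SimulationTruth, classes, amplitude_col: str
                  ) -> dict[str, np.ndarray]:
    """Triangular arrested-fork peaks for origins of the given classes."""
    cfg = truth.config
    hw = cfg.call_peak_halfwidth
    out = {}
    for chrom in truth.genome.chrom_names:
        n = truth.genome.n_bins(chrom, cfg.bin_size)
        centers = (np.arange(n) + 0.5) * cfg.bin_size
        p = np.zeros(n)
        oris = truth.origins_for(chrom)
        for row in oris[oris["rt_class"].isin(classes)].itertuples(index=False):
            d = np.abs(centers - row.pos)
            amp = getattr(row, amplitude_col)
            p += amp * np.clip(1.0 - d / hw, 0.0, None)
        out[chrom] = np.clip(p, 0.0, 1.0)
    return out


def simulate_calling_tracks(config: SimConfig, normalize: bool = True
                            ) -> tuple[dict[str, BinnedTrack], SimulationTruth]:
    """The two class-mapping assays: an early-origin track (HU from release,
    harvested in early S) and a mid/late track (early territory already
    replicated before labeling). Returns {"early": ..., "midlate": ...}."""
    truth = plant_genome(config)
    cfg = config
    tracks = {}
    for key, classes, sub in (("early", ("early",), 2), ("midlate", ("mid", "late"), 3)):
        probs = _peak_profile(truth, classes, "efficiency")
        for chrom in probs:
            probs[chrom] = probs[chrom] + cfg.background_fraction
        rng = np.random.default_rng([cfg.seed, sub])
        track = _tracks_from_probability(truth, probs, rng)
        tracks[key] = bpm_normalize(track) if normalize else track
    return tracks, truth


def simulate_repliseq(config: SimConfig, resolution_factor: int = 10,
                      normalize: bool = True
                      ) -> tuple[list[BinnedTrack], SimulationTruth]:
    """Six sorted-fraction tracks at resolution_factor x bin_size (10 kb).

    S phase is split at the five time points where the genome-wide expected
    replicated fraction reaches 1/6 .. 5/6; fraction k's expected signal per
    bin is the probability of replicating inside window k.
    """
    truth = plant_genome(config)
    cfg = config
    # locate equal-replicated-fraction boundaries on a coarse time grid,
    # using every 7th bin as a genome subsample
    # all origins fire by g1 + S length; the last bin replicated lies at most
    # ~one origin spacing from its nearest origin
    max_reach = max(cfg.iz_spacing.values())
    t_end = cfg.g1_length_h + cfg.s_phase_length_h + \
        max_reach / (cfg.fork_speed_kb_h * 1000.0)
    grid = np.arange(cfg.g1_length_h, t_end + 0.1, 0.1)
    mean_S = np.zeros(len(grid))
    n_sub = 0
    for chrom in truth.genome.chrom_names:
        n = truth.genome.n_bins(chrom, cfg.bin_size)
        centers = ((np.arange(0, n, 7) + 0.5) * cfg.bin_size)
        S = replication_survival(truth, chrom, grid, bin_centers=centers)
        mean_S += S.sum(axis=0)
        n_sub += len(centers)
    mean_F = 1.0 - mean_S / n_sub
    bounds = [float(np.interp(k / 6, mean_F, grid)) for k in range(1, 6)]
    edges = [0.0] + bounds + [t_end + 1.0]
    coarse = cfg.bin_size * resolution_factor
    frac_probs: list[dict[str, np.ndarray]] = [dict() for _ in range(6)]
    for chrom in truth.genome.chrom_names:
        S = replication_survival(truth, chrom, edges)
        n_coarse = truth.genome.n_bins(chrom, coarse)
        for k in range(6):
            p = S[:, k] - S[:, k + 1]
            pad = n_coarse * resolution_factor - len(p)
            if pad:
                p = np.concatenate([p, np.zeros(pad)])
            frac_probs[k][chrom] = p.reshape(n_coarse, resolution_factor).mean(axis=1) \
                + cfg.background_fraction
    tracks = []
    for k in range(6):
        rng = np.random.default_rng([cfg.seed, 4, k])
        track = _tracks_from_probability(truth, frac_probs[k], rng, bin_size=coarse)
        tracks.append(bpm_normalize(track) if normalize else track)
    return tracks, truth


def simulate_oct4_pair(config: SimConfig, normalize: bool = True
                       ) -> tuple[BinnedTrack, BinnedTrack, SimulationTruth]:
    """Paired OCT4-ON / OCT4-OFF tracks at a fixed early-S time point.

    ON amplitude of origin i is its firing probability by the assay time
    under its own rate lam_i = lam_class x strength_i. The planted depletion
    effect is per-IZ: delta_i = beta_class x (log2 amp_i - class mean), so the
    residual-vs-log2(ON) slope planted in each class is beta_class; class-mean
    firing is additionally attenuated by 2^-beta_class. Both tracks carry
    multiplicative log-normal noise before Poisson sampling.
    """
    truth = plant_genome(config)
    cfg = config
    dt = cfg.oct4_time_after_s_h
    oris = truth.origins.copy()
    lam_i = oris["lam"].to_numpy(float) * oris["strength"].to_numpy(float)
    amp_on = 1.0 - np.exp(-lam_i * dt)
    x = np.log2(amp_on)
    beta = oris["rt_class"].map(cfg.oct4_beta).to_numpy(float)
    xc = pd.Series(x).groupby(oris["rt_class"].values).transform("mean").to_numpy()
    delta = beta * (x - xc) + beta  # slope beta_class + class-mean attenuation
    amp_off = np.clip(amp_on * 2.0 ** (-delta), 0.0, 1.0)
    oris["amp_on"] = amp_on
    oris["amp_off"] = amp_off
    truth.origins = oris
    out = []
    for j, col in enumerate(("amp_on", "amp_off")):
        probs = _peak_profile(truth, RT_CLASSES, col)
        rng = np.random.default_rng([cfg.seed, 5, j])
        for chrom in probs:
            noise = 2.0 ** rng.normal(0.0, cfg.oct4_noise_sigma, len(probs[chrom]))
            probs[chrom] = probs[chrom] * noise + cfg.background_fraction
        track = _tracks_from_probability(truth, probs, rng)
        out.append(bpm_normalize(track) if normalize else track)
    return out[0], out[1], truth


def simulate_paired_signals(n_per_class: dict[str, int], slopes: dict[str, float],
                            sigma: float = 0.2, seed: int = 13) -> pd.DataFrame:
    """Paired per-IZ signals drawn directly from the residual-regression model.

    For each class, log2 ON ~ N(2, 1), residual = slope x (log2 ON) + N(0,
    sigma), OFF = ON / 2^residual. Useful as a controlled recovery target for
    the regression fit (the track-level generator adds fork/Poisson effects).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n in n_per_class.items():
        log2_on = rng.normal(2.0, 1.0, n)
        residual = slopes[cls] * log2_on + rng.normal(0.0, sigma, n)
        on = 2.0 ** log2_on
        off = on / 2.0 ** residual
        for o, f in zip(on, off):
            rows.append((cls, o, f))
    return pd.DataFrame(rows, columns=["rt_class", "signal_on", "signal_off"])


# ---------------------------------------------------------------------------
# artifacts and features

def plant_blacklist_artifacts(track: BinnedTrack, n: int = 4, width: int = 3000,
                              amplitude: float = 50.0, seed: int = 0
                              ) -> tuple[BinnedTrack, IntervalSet]:
    """Inject constant high spikes at random intervals; emit the matching
    blacklist BED. ``amplitude`` is relative to the track's maximum value."""
    out = track.copy()
    rows = []
    if n > 0:
        rng = np.random.default_rng([seed, 6])
        peak = max(max(arr.max() for arr in track.data.values()), 1.0)
        chroms = track.genome.chrom_names
        lengths = np.array([track.genome.chrom_lengths[c] for c in chroms], float)
        ci = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
        for i in range(n):
            chrom = chroms[ci[i]]
            start = int(rng.uniform(width, lengths[ci[i]] - 2 * width))
            start -= start % track.bin_size
            end = start + width
            b0, b1 = start // track.bin_size, end // track.bin_size
            out.data[chrom][b0:b1] = amplitude * peak
            rows.append((chrom, start, end))
    blacklist = (IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                             genome=track.genome) if rows
                 else IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"])))
    return out, blacklist


def make_feature_sets(truth: SimulationTruth, seed: int = 0,
                      fixed_enhancer_offset: int | None = None,
                      genes_per_mb: float = 10.0) -> PointFeatureSet:
    """TSS/TTS/enhancer point features tied to the planted origins.

    Enhancers are placed around origins at class-specific offset scales
    (closer to early zones), recovering the planted proximity ordering;
    ``fixed_enhancer_offset`` plants every enhancer at exactly that distance
    instead. Genes (TSS/TTS pairs) are uniform with log-normal lengths.
    """
    cfg = truth.config
    rng = np.random.default_rng([seed, 7])
    rows = []
    for row in truth.origins.itertuples(index=False):
        length = truth.genome.chrom_lengths[row.chrom]
        if fixed_enhancer_offset is not None:
            offs = [fixed_enhancer_offset * (1 if rng.random() < 0.5 else -1)]
        else:
            scale = cfg.enhancer_offset_scale[row.rt_class]
            offs = rng.normal(0, scale, 2)
        for off in offs:
            pos = int(np.clip(row.pos + off, 0, length - 1))
            rows.append((row.chrom, pos, "enhancer_midpoint"))
    for chrom in truth.genome.chrom_names:
        length = truth.genome.chrom_lengths[chrom]
        n_genes = int(genes_per_mb * length / 1e6)
        starts = rng.uniform(0, length, n_genes)
        glens = np.exp(rng.normal(np.log(30_000), 0.6, n_genes))
        for s, gl in zip(starts, glens):
            tss = int(np.clip(s, 0, length - 1))
            tts = int(np.clip(s + gl, 0, length - 1))
            rows.append((chrom, tss, "TSS"))
            rows.append((chrom, tts, "TTS"))
    return PointFeatureSet(pd.DataFrame(rows, columns=["chrom", "pos", "kind"]),
                           truth.genome)


# ---------------------------------------------------------------------------
# truth-aware evaluation

def callable_origins(truth: SimulationTruth,
                     exclusion_distance: int = 500_000,
                     blacklist: IntervalSet | None = None,
                     drop_chroms: tuple = ("chrY",)) -> pd.DataFrame:
    """Planted origins that the calling rules allow to be reported: not on a
    dropped chromosome, not in the blacklist, and (mid/late) at least the
    exclusion distance from every earlier-replicating domain."""
    keep = []
    for row in truth.origins.itertuples(index=False):
        if row.chrom in drop_chroms:
            keep.append(False)
            continue
        if blacklist is not None and blacklist.overlaps_point(row.chrom, int(row.pos)):
            keep.append(False)
            continue
        ok = True
        for cls in EXCLUDED_BY[row.rt_class]:
            doms = truth.domains.of_class(cls).for_chrom(row.chrom)
            if _distance_to_intervals(int(row.pos), doms) < exclusion_distance:
                ok = False
                break
        keep.append(ok)
    return truth.origins[np.array(keep, dtype=bool)].reset_index(drop=True)


def evaluate_recovery(izs: IZSet, expected: pd.DataFrame,
                      tolerance: int = 20_000) -> dict:
    """Recall/precision of called IZs against expected (callable) origins,
    matched by class and center distance <= tolerance."""
    per_class = {}
    for cls in RT_CLASSES:
        truth_cls = expected[expected["rt_class"] == cls]
        called = izs.df[izs.df["rt_class"] == cls]
        n_truth, n_called = len(truth_cls), len(called)
        hits_t = 0
        for row in truth_cls.itertuples(index=False):
            sub = called[called["chrom"] == row.chrom]
            if len(sub) and (np.abs(sub["center"] - row.pos) <= tolerance).any():
                hits_t += 1
        hits_c = 0
        for row in called.itertuples(index=False):
            sub = truth_cls[truth_cls["chrom"] == row.chrom]
            if len(sub) and (np.abs(sub["pos"] - row.center) <= tolerance).any():
                hits_c += 1
        per_class[cls] = {
            "n_truth": n_truth, "n_called": n_called,
            "recall": hits_t / n_truth if n_truth else float("nan"),
            "precision": hits_c / n_called if n_called else float("nan"),
        }
    return per_class
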