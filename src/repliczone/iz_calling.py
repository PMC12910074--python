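"""Class-stratified replication initiation-zone (IZ) calling.

The caller works on a BPM-normalized nascent-DNA coverage track binned at
1 kb, stratified by replication-timing class:

1. bins are assigned to early/mid/late territory by their midpoint;
2. a class-specific threshold is set as a fraction (50% / 25% / 5% for
   early / mid / late) of the mean of the top-k bins of that class, the
   stricter late cutoff compensating the lower peak-to-background ratio of
   late domains;
3. maximal runs of above-threshold bins (runs separated by at most
   ``merge_gap`` of sub-threshold signal are fused, never crossing a domain
   boundary) form broad regions;
4. within each broad region only bins at or above the region median are
   retained, and each retained run of at least ``min_width`` bins becomes a
   candidate IZ;
5. candidates overlapping the blacklist are discarded; centers are refined
   to the signal-weighted centroid; mid/late IZs closer than the exclusion
   distance (500 kb) to any earlier-replicating domain are discarded, as
   their signal could come from incoming forks rather than initiation;
6. chrY calls are dropped.

A seeded generator of matched random control positions (uniform 1-bp
positions at least 50 kb from every refined IZ center) accompanies the calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import RT_CLASSES, BinnedTrack, Genome, IntervalSet, PointFeatureSet
from .rt_domains import RTDomainMap

#: which earlier classes exclude calls of a given class
EXCLUDED_BY = {"early": (), "mid": ("early",), "late": ("early", "mid")}


@dataclass
class IZCallingConfig:
    bin_size: int = 1000
    class_fractions: dict = field(
        default_factory=lambda: {"early": 0.50, "mid": 0.25, "late": 0.05})
    highest_bins_k: int = 10
    merge_gap: int = 2000
    min_width: int = 2
    refine_resolution: int = 1000
    exclusion_distance: int = 500_000
    control_candidates: int = 10_000_000
    control_flank: int = 50_000
    control_n: int = 1000
    rng_seed: int = 0
    drop_chroms: tuple = ("chrY",)

    def __post_init__(self):
        for cls, frac in self.class_fractions.items():
            if not 0 < frac <= 1:
                raise ValueError(f"class fraction for {cls} must be in (0, 1]")
        if self.exclusion_distance < 0:
            raise ValueError("exclusion_distance must be >= 0")
        if self.control_n > self.control_candidates:
            raise ValueError("control_n cannot exceed control_candidates")


class IZSet:
    """Called IZ intervals with class, refined center and score (mean BPM)."""

    COLUMNS = ["chrom", "start", "end", "center", "rt_class", "score"]

    def __init__(self, df: pd.DataFrame, genome: Genome | None = None):
        df = df.copy().reset_index(drop=True)
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing column {col}")
        bad = (df["center"] < df["start"]) | (df["center"] >= df["end"])
        if bad.any():
            raise ValueError("IZ centers must lie within [start, end)")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self.genome = genome

    def __len__(self):
        return len(self.df)

    def of_class(self, rt_class: str) -> "IZSet":
        return IZSet(self.df[self.df["rt_class"] == rt_class], self.genome)

    def centers(self) -> PointFeatureSet:
        recs = [(r.chrom, int(r.center), "IZ_center")
                for r in self.df.itertuples(index=False)]
        return PointFeatureSet(pd.DataFrame(recs, columns=["chrom", "pos", "kind"]),
                               self.genome)

    def write_bed(self, path) -> None:
        out = self.df.copy()
        out["name"] = [f"IZ_{r.rt_class}_{i}" for i, r in
                       enumerate(out.itertuples(index=False))]
        out[["chrom", "start", "end", "name", "score", "rt_class", "center"]].to_csv(
            path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed(cls, path, genome: Genome | None = None) -> "IZSet":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score",
                                "rt_class", "center"],
                         dtype={"chrom": str, "rt_class": str})
        return cls(df, genome)

    @classmethod
    def empty(cls, genome=None) -> "IZSet":
        return cls(pd.DataFrame(columns=cls.COLUMNS), genome)

    @classmethod
    def union(cls, sets: list["IZSet"]) -> "IZSet":
        frames = [s.df for s in sets if len(s)]
        genome = next((s.genome for s in sets if s.genome is not None), None)
        if not frames:
            return cls.empty(genome)
        return cls(pd.concat(frames, ignore_index=True), genome)


def bin_and_extract(track: BinnedTrack, domains: RTDomainMap, rt_class: str,
                    blacklist: IntervalSet | None = None):
    """Per-domain lists of (bin start bp, signal) for bins whose midpoint lies
    in a domain of ``rt_class``.

    Returns a list with one entry per contiguous stretch of usable bins:
    ``(chrom, positions ndarray, signal ndarray)``; broad-region calling never
    fuses across entries, so no IZ straddles two classes. When a blacklist is
    given, bins overlapping it are masked out here so that artifact spikes
    cannot contaminate the class reference level, and each domain is split at
    the masked bins.
    """
    bs = track.bin_size
    out = []
    for dom in domains.of_class(rt_class).df.itertuples(index=False):
        arr = track.data[dom.chrom]
        # bin i has midpoint i*bs + bs/2; require start <= midpoint < end
        first = int(np.ceil((dom.start - bs / 2) / bs))
        last = int(np.ceil((dom.end - bs / 2) / bs))  # exclusive
        first = max(first, 0)
        last = min(last, len(arr))
        if last <= first:
            continue
        keep = np.ones(last - first, dtype=bool)
        if blacklist is not None and len(blacklist):
            sub = blacklist.for_chrom(dom.chrom)
            for bl in sub.itertuples(index=False):
                b0 = max(first, int(bl.start) // bs)
                b1 = min(last, int(np.ceil(bl.end / bs)))
                if b1 > b0:
                    keep[b0 - first:b1 - first] = False
        for s, e in _runs(keep):
            positions = np.arange(first + s, first + e) * bs
            out.append((dom.chrom, positions, arr[first + s:first + e].copy()))
    if not out:
        warnings.warn(f"no bins in {rt_class} territory")
    return out


def class_threshold(class_bins, fraction: float, k: int = 10) -> float:
    """Threshold = fraction x mean of the top-k bin signals of the class."""
    signals = np.concatenate([sig for _, _, sig in class_bins]) if class_bins else np.array([])
    if signals.size == 0:
        return np.inf
    if signals.size < k:
        warnings.warn(f"fewer than {k} bins in class; using max as reference")
        return fraction * float(signals.max())
    top = np.sort(signals)[-k:]
    return fraction * float(top.mean())


def _runs(mask: np.ndarray):
    """(start, end) index pairs of maximal True runs."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def call_broad_regions(class_bins, threshold: float, merge_gap: int,
                       bin_size: int = 1000) -> IntervalSet:
    """Maximal runs of above-threshold bins, fusing runs separated by at most
    ``merge_gap`` bp of sub-threshold bins; never crosses a domain interval."""
    gap_bins = merge_gap // bin_size
    rows = []
    for chrom, positions, signal in class_bins:
        runs = _runs(signal >= threshold)
        merged = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= gap_bins:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            rows.append((chrom, int(positions[s]), int(positions[e - 1]) + bin_size))
    if not rows:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def refine_to_izs(track: BinnedTrack, broad_regions: IntervalSet,
                  min_width: int = 2) -> IntervalSet:
    """Second refining step: within each broad region keep bins at or above
    the region median; each retained run of >= min_width bins is one candidate."""
    bs = track.bin_size
    rows = []
    for reg in broad_regions.df.itertuples(index=False):
        b0, b1 = int(reg.start) // bs, int(np.ceil(reg.end / bs))
        sig = track.data[reg.chrom][b0:b1]
        med = np.median(sig)
        for s, e in _runs(sig >= med):
            if e - s >= min_width:
                rows.append((reg.chrom, (b0 + s) * bs, (b0 + e) * bs))
    if not rows:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def filter_blacklist(izs: IntervalSet, blacklist: IntervalSet) -> tuple[IntervalSet, int]:
    """Discard candidates sharing >= 1 bp with any blacklist interval.

    Returns (kept, n_discarded)."""
    keep = []
    for row in izs.df.itertuples(index=False):
        sub = blacklist.for_chrom(row.chrom)
        hit = ((sub["start"] < row.end) & (row.start < sub["end"])).any()
        keep.append(not hit)
    kept = izs.df[np.array(keep, dtype=bool)] if len(izs) else izs.df
    return IntervalSet(kept) if len(kept) else _empty_intervals(), int(len(izs) - len(kept))


def _empty_intervals() -> IntervalSet:
    return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))


def refine_center(track: BinnedTrack, chrom: str, start: int, end: int,
                  resolution: int = 1000) -> int:
    """Signal-weighted centroid of the bins in [start, end), snapped to the
    ``resolution`` grid (nearest grid point); zero-signal regions fall back to
    the geometric midpoint."""
    bs = track.bin_size
    b0, b1 = start // bs, int(np.ceil(end / bs))
    sig = track.data[chrom][b0:b1]
    mids = (np.arange(b0, b1) + 0.5) * bs
    total = sig.sum()
    if total <= 0:
        center = (start + end) / 2
    else:
        center = float(np.dot(sig, mids) / total)
    snapped = int(np.round(center / resolution)) * resolution
    return int(np.clip(snapped, start, end - 1))


def _distance_to_intervals(pos: int, intervals: pd.DataFrame) -> float:
    """bp distance from a point to the nearest covered bp of any interval."""
    if intervals.empty:
        return np.inf
    starts = intervals["start"].values
    ends = intervals["end"].values
    inside = (starts <= pos) & (pos < ends)
    if inside.any():
        return 0.0
    d = np.where(pos < starts, starts - pos, pos - (ends - 1))
    return float(d.min())


def apply_exclusion_zone(izs: IZSet, domains: RTDomainMap,
                         distance: int = 500_000) -> tuple[IZSet, int]:
    """Drop mid IZs < ``distance`` from any early domain, and late IZs
    < ``distance`` from any early or mid domain (center-to-nearest-bp).

    Forks initiated in earlier-replicating neighbours can travel this far
    within the labeling window, so closer mid/late signal is ambiguous."""
    keep = []
    for row in izs.df.itertuples(index=False):
        excluded = EXCLUDED_BY[row.rt_class]
        ok = True
        for cls in excluded:
            doms = domains.of_class(cls).for_chrom(row.chrom)
            if _distance_to_intervals(int(row.center), doms) < distance:
                ok = False
                break
        keep.append(ok)
    mask = np.array(keep, dtype=bool) if len(izs) else np.array([], dtype=bool)
    kept = izs.df[mask] if len(izs) else izs.df
    return IZSet(kept, izs.genome), int(len(izs) - mask.sum())


def call_izs(track: BinnedTrack, domains: RTDomainMap, blacklist: IntervalSet,
             config: IZCallingConfig, classes: tuple = RT_CLASSES
             ) -> tuple[IZSet, dict]:
    """Run the full calling pipeline; returns (IZSet, provenance log).

    ``classes`` restricts calling to a subset (the assay design may dedicate
    one track to early and another to mid/late territory); results from
    separate invocations can be combined with :meth:`IZSet.union`.
    """
    if track.units != "BPM":
        raise ValueError("track must be BPM-normalized")
    provenance: dict = {"config": asdict(config), "classes": list(classes),
                        "per_class": {}}
    all_rows = []
    for rt_class in classes:
        log: dict = {}
        class_bins = bin_and_extract(track, domains, rt_class, blacklist=blacklist)
        thr = class_threshold(class_bins, config.class_fractions[rt_class],
                              config.highest_bins_k)
        log["threshold"] = None if np.isinf(thr) else thr
        if not np.isfinite(thr) or thr <= 0:
            warnings.warn(f"non-positive reference level for class {rt_class}; "
                          "no calls made")
            provenance["per_class"][rt_class] = dict(
                log, n_broad_regions=0, n_candidates=0,
                n_blacklist_discarded=0, n_exclusion_discarded=0,
                n_final_before_chrom_drop=0)
            all_rows.append(pd.DataFrame(columns=IZSet.COLUMNS))
            continue
        broad = call_broad_regions(class_bins, thr, config.merge_gap, config.bin_size)
        log["n_broad_regions"] = len(broad)
        cands = refine_to_izs(track, broad, config.min_width)
        log["n_candidates"] = len(cands)
        cands, n_black = filter_blacklist(cands, blacklist)
        log["n_blacklist_discarded"] = n_black
        rows = []
        for row in cands.df.itertuples(index=False):
            center = refine_center(track, row.chrom, int(row.start), int(row.end),
                                   config.refine_resolution)
            score = float(np.mean(track.data[row.chrom]
                                  [int(row.start) // track.bin_size:
                                   int(np.ceil(row.end / track.bin_size))]))
            rows.append((row.chrom, int(row.start), int(row.end), center,
                         rt_class, score))
        class_izs = IZSet(pd.DataFrame(rows, columns=IZSet.COLUMNS), track.genome)
        class_izs, n_excl = apply_exclusion_zone(class_izs, domains,
                                                 config.exclusion_distance)
        log["n_exclusion_discarded"] = n_excl
        log["n_final_before_chrom_drop"] = len(class_izs)
        all_rows.append(class_izs.df)
        provenance["per_class"][rt_class] = log
    df = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame(
        columns=IZSet.COLUMNS)
    n_before = len(df)
    df = df[~df["chrom"].isin(config.drop_chroms)]
    provenance["n_dropped_chrom"] = int(n_before - len(df))
    izs = IZSet(df, track.genome)
    provenance["n_total"] = len(izs)
    provenance["counts"] = {c: int((df["rt_class"] == c).sum()) for c in classes}
    for cls, flag in (("blacklist_checked", True), ("exclusion_checked", True)):
        izs.df[cls] = flag
    return izs, provenance


def generate_control_regions(genome: Genome, izs: IZSet, config: IZCallingConfig
                             ) -> PointFeatureSet:
    """Seeded random control positions far from every refined IZ center.

    Uniform 1-bp candidate positions (``control_candidates`` of them, on the
    chromosomes not in ``drop_chroms``) are filtered against the
    ``[center - control_flank, center + control_flank]`` extension of every
    IZ center, shuffled, and the first ``control_n`` survivors returned.
    """
    rng = np.random.default_rng(config.rng_seed)
    chroms = [c for c in genome.chrom_names if c not in config.drop_chroms]
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.float64)
    probs = lengths / lengths.sum()
    n = int(config.control_candidates)
    chrom_idx = rng.choice(len(chroms), size=n, p=probs)
    pos = (rng.random(n) * lengths[chrom_idx]).astype(np.int64)
    keep = np.ones(n, dtype=bool)
    for ci, chrom in enumerate(chroms):
        centers = izs.df.loc[izs.df["chrom"] == chrom, "center"].to_numpy(np.int64)
        if centers.size == 0:
            continue
        centers = np.sort(centers)
        sel = chrom_idx == ci
        p = pos[sel]
        j = np.searchsorted(centers, p)
        d_right = np.where(j < centers.size, centers[np.minimum(j, centers.size - 1)] - p,
                           np.iinfo(np.int64).max)
        d_left = np.where(j > 0, p - centers[np.maximum(j - 1, 0)],
                          np.iinfo(np.int64).max)
        keep[sel] = np.minimum(d_left, d_right) > config.control_flank
    survivors = np.flatnonzero(keep)
    if survivors.size < config.control_n:
        raise ValueError(
            f"only {survivors.size} control candidates survive exclusion; "
            f"{config.control_n} required")
    order = rng.permutation(survivors.size)[: config.control_n]
    chosen = survivors[order]
    df = pd.DataFrame({"chrom": [chroms[i] for i in chrom_idx[chosen]],
                       "pos": pos[chosen], "kind": "control"})
    return PointFeatureSet(df, genome)
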