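"""Averaged nascent-DNA profiles around IZ centers and fork-speed estimation.

Fork speed is read from how the averaged profile of isolated IZs (>= 100 kb
from any other IZ, so the signal reflects a single pair of diverging forks)
spreads over a labeling time course: the profile at the reference time point
(2 h by default) provides the starting front, and

    speed_t = (front_t - front_ref) / (t - ref)   [kb/h]

The front of a profile is the outermost offset at which the profile reaches
``level_fraction`` of its maximum (half-maximum by default), located by
inverse linear interpolation between grid points, averaged over both sides
(bidirectional forks are assumed symmetric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinnedTrack
from .iz_calling import IZSet, refine_center


@dataclass
class AveragedProfile:
    """Background-subtracted mean signal by offset around a set of centers."""

    offsets: np.ndarray          # bp, -flank .. +flank step bin_size
    mean_signal: np.ndarray      # BPM, min subtracted
    background: float            # the subtracted constant (lowest mean bin)
    n_regions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset_bp": self.offsets, "mean_signal": self.mean_signal,
                             "n_regions": self.n_regions})


@dataclass
class ForkSpeedSeries:
    reference_time_h: float
    times_h: list[float]
    front_kb: dict[float, float]
    speed_kb_per_h: dict[float, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, self.front_kb[t], self.speed_kb_per_h.get(t, np.nan))
                for t in self.times_h]
        return pd.DataFrame(rows, columns=["time_h", "front_kb", "speed_kb_h"])


def select_isolated_izs(izs: IZSet, min_distance: int = 100_000) -> IZSet:
    """Keep IZs whose center is >= min_distance from every other IZ center."""
    df = izs.df
    keep = np.ones(len(df), dtype=bool)
    for chrom, grp in df.groupby("chrom", sort=False):
        centers = grp["center"].to_numpy(np.int64)
        if centers.size < 2:
            continue
        order = np.argsort(centers)
        sorted_c = centers[order]
        gaps_left = np.diff(sorted_c, prepend=sorted_c[0] - 2 * min_distance)
        gaps_right = np.diff(sorted_c, append=sorted_c[-1] + 2 * min_distance)
        ok_sorted = (gaps_left >= min_distance) & (gaps_right >= min_distance)
        ok = np.empty_like(ok_sorted)
        ok[order] = ok_sorted
        keep[grp.index] = ok
    return IZSet(df[keep], izs.genome)


def averaged_profile(track: BinnedTrack, centers, flank: int = 500_000,
                     bin_size: int | None = None) -> AveragedProfile:
    """Per-offset mean of the track around each center, minus the lowest
    per-offset mean (the background level).

    ``centers`` is a PointFeatureSet, an IZSet, or a list of (chrom, pos).
    Centers whose full flank does not fit in the chromosome are dropped with
    a warning.
    """
    bin_size = bin_size or track.bin_size
    if bin_size != track.bin_size:
        raise ValueError("profile bin size must equal the track bin size")
    # accumulate in sorted order so the result is exactly invariant under
    # permutation of the input centers (float addition is not associative)
    pairs = sorted(_as_center_pairs(centers))
    n_off = flank // bin_size
    offsets = np.arange(-n_off, n_off + 1) * bin_size
    acc = np.zeros(len(offsets))
    used = 0
    for chrom, pos in pairs:
        cbin = int(pos) // bin_size
        arr = track.data[chrom]
        if cbin - n_off < 0 or cbin + n_off >= len(arr):
            warnings.warn(f"center {chrom}:{pos} lacks full flank; dropped")
            continue
        acc += arr[cbin - n_off: cbin + n_off + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable centers (all lack the full flank)")
    mean = acc / used
    background = float(mean.min())
    return AveragedProfile(offsets, mean - background, background, used)


def _as_center_pairs(centers):
    if isinstance(centers, IZSet):
        return [(r.chrom, int(r.center)) for r in centers.df.itertuples(index=False)]
    if hasattr(centers, "df"):  # PointFeatureSet
        return [(r.chrom, int(r.pos)) for r in centers.df.itertuples(index=False)]
    return [(c, int(p)) for c, p in centers]


def refine_profile_center(track: BinnedTrack, chrom: str, start: int, end: int,
                          resolution: int = 10_000) -> int:
    """Centroid center refinement at coarse (10 kb) resolution."""
    return refine_center(track, chrom, start, end, resolution)


def estimate_front(profile: AveragedProfile, level_fraction: float = 0.5) -> float:
    """Distance (kb) from the center to the threshold crossing of the front.

    Per side, the front is the first offset beyond that side's maximum at
    which the profile drops below ``level_fraction`` x max (of the whole
    profile), with the crossing interpolated linearly between adjacent grid
    points; the two sides are averaged. Taking the first crossing outward
    from the peak (rather than the outermost above-threshold offset) makes
    the estimate robust to far shoulders contributed by neighbouring zones
    and domains.
    """
    sig = profile.mean_signal
    peak = float(sig.max())
    if peak <= 0:
        raise ValueError("flat profile: no positive maximum")
    thr = level_fraction * peak
    mid = len(sig) // 2
    fronts = []
    for side in (+1, -1):
        vals = sig[mid:] if side > 0 else sig[mid::-1]
        offs = np.abs(profile.offsets[mid:] if side > 0 else profile.offsets[mid::-1])
        above = np.flatnonzero(vals >= thr)
        if above.size == 0:
            fronts.append(0.0)
            continue
        m = int(np.argmax(vals))
        below = np.flatnonzero(vals[m:] < thr)
        if below.size == 0:
            fronts.append(float(offs[-1]))
            continue
        k = m + below[0] - 1  # last point at/above threshold before the drop
        v0, v1 = vals[k], vals[k + 1]
        frac = (v0 - thr) / (v0 - v1) if v0 > v1 else 0.0
        fronts.append(float(offs[k] + frac * (offs[k + 1] - offs[k])))
    return float(np.mean(fronts)) / 1000.0


def fork_speed(timecourse: dict[float, BinnedTrack], isolated_izs,
               reference_time: float = 2.0, flank: int = 500_000,
               level_fraction: float = 0.5) -> ForkSpeedSeries:
    """Estimate fork speed from profile spreading across a pulse time course.

    ``timecourse`` maps hours after release to the BPM track of that pulse.
    The same IZ set is profiled at every time point; speeds are reported for
    t > reference_time; negative displacements are floored at 0 with warning.
    """
    if reference_time not in timecourse:
        raise ValueError(f"missing reference time point {reference_time}")
    times = sorted(timecourse)
    fronts = {}
    for t in times:
        prof = averaged_profile(timecourse[t], isolated_izs, flank=flank)
        fronts[t] = estimate_front(prof, level_fraction)
    series = ForkSpeedSeries(reference_time, times, fronts)
    for t in times:
        if t <= reference_time:
            continue
        disp = fronts[t] - fronts[reference_time]
        if disp < 0:
            warnings.warn(f"negative front displacement at t={t}; floored at 0")
            disp = 0.0
        series.speed_kb_per_h[t] = disp / (t - reference_time)
    return series
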