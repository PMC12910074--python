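"""Replication-timing (RT) domain maps: early / mid / late genome partitions.

A map is either loaded from an external caller's labeled BED output (the
route used for real data) or computed by a simplified six-fraction
classifier. The classifier assigns each 10 kb bin the signal-weighted mean
fraction index T = sum(k * s_k) / sum(s_k) over sorted S-phase fractions
k = 1..6 after moving-average smoothing, then thresholds T into the three
classes. It is a deliberate simplification of wavelet-based domain callers:
it preserves the pipeline contract (a labeled, non-overlapping partition)
without reproducing their smoothing machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RT_CLASSES, BinnedTrack, Genome, IntervalSet


@dataclass
class RTDomainMap:
    """Non-overlapping labeled intervals partitioning the classified genome."""

    intervals: IntervalSet
    resolution: int

    def __post_init__(self):
        df = self.intervals.df
        bad = set(df["label"]) - set(RT_CLASSES)
        if bad:
            raise ValueError(f"labels outside {RT_CLASSES}: {sorted(bad)}")
        for chrom in self.intervals.chroms():
            sub = self.intervals.for_chrom(chrom)
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ValueError(f"overlapping domains on {chrom}")

    def of_class(self, rt_class: str) -> IntervalSet:
        df = self.intervals.df
        return IntervalSet(df[df["label"] == rt_class], genome=self.intervals.genome)

    def class_of_position(self, chrom: str, pos: int) -> str | None:
        sub = self.intervals.for_chrom(chrom)
        hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
        if hit.empty:
            return None
        return str(hit.iloc[0]["label"])

    def write_bed(self, path) -> None:
        self.intervals.write_bed(path)


def _merge_adjacent(df: pd.DataFrame) -> pd.DataFrame:
    """Fuse touching/overlapping same-label intervals (input sorted per chrom)."""
    rows = []
    for (chrom,), grp in df.groupby(["chrom"], sort=False):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.label == cur[3] and row.start <= cur[2]:
                cur[2] = max(cur[2], row.end)
            else:
                if cur is not None:
                    rows.append(tuple(cur))
                cur = [chrom, row.start, row.end, row.label]
        if cur is not None:
            rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def load_domains(bed_path, resolution: int, label_map: dict | None = None,
                 genome: Genome | None = None) -> RTDomainMap:
    """Load an external caller's labeled BED as an :class:`RTDomainMap`.

    ``label_map`` translates the caller's labels (e.g. ES/MS/LS) onto
    early/mid/late. Adjacent same-label intervals are fused; overlapping
    differently-labeled intervals are an error.
    """
    ivs = IntervalSet.read_bed(bed_path, genome=genome)
    df = ivs.df
    if "label" not in df.columns:
        raise ValueError("BED file needs a 4th (label) column")
    if label_map:
        unknown = sorted(set(df["label"]) - set(label_map))
        if unknown:
            raise ValueError(f"labels not in mapping: {unknown}")
        df = df.assign(label=df["label"].map(label_map))
    unknown = sorted(set(df["label"]) - set(RT_CLASSES))
    if unknown:
        raise ValueError(f"unmappable labels: {unknown}")
    # overlap check before merging: differently-labeled overlap is an error
    for chrom in df["chrom"].unique():
        sub = df[df["chrom"] == chrom]
        prev_end, prev_label = None, None
        for row in sub.itertuples(index=False):
            if prev_end is not None and row.start < prev_end and row.label != prev_label:
                raise ValueError(f"overlapping differently-labeled intervals on {chrom}")
            prev_end, prev_label = max(prev_end or 0, row.end), row.label
    merged = _merge_adjacent(df[["chrom", "start", "end", "label"]])
    return RTDomainMap(IntervalSet(merged, genome=genome), resolution)


def _moving_average(arr: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return arr
    kernel = np.ones(window)
    num = np.convolve(arr, kernel, mode="same")
    den = np.convolve(np.ones_like(arr), kernel, mode="same")
    return num / den


def _nearest_fill(labels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Assign invalid positions the label of the nearest valid position."""
    if valid.all():
        return labels
    if not valid.any():
        raise ValueError("no bins above the signal floor")
    idx = np.flatnonzero(valid)
    pos = np.arange(len(labels))
    nearest = idx[np.clip(np.searchsorted(idx, pos), 0, len(idx) - 1)]
    before = idx[np.clip(np.searchsorted(idx, pos) - 1, 0, len(idx) - 1)]
    pick = np.where(np.abs(nearest - pos) < np.abs(pos - before), nearest, before)
    out = labels.copy()
    out[~valid] = labels[pick[~valid]]
    return out


def _kmeans_cutpoints(values: np.ndarray, n_iter: int = 50) -> tuple[float, float]:
    """Deterministic 1-D 3-means on T; cutpoints at midpoints of sorted means."""
    means = np.quantile(values, [1 / 6, 3 / 6, 5 / 6])
    for _ in range(n_iter):
        assign = np.argmin(np.abs(values[:, None] - means[None, :]), axis=1)
        new = np.array([values[assign == k].mean() if (assign == k).any() else means[k]
                        for k in range(3)])
        if np.allclose(new, means):
            break
        means = np.sort(new)
    return float((means[0] + means[1]) / 2), float((means[1] + means[2]) / 2)


def classify_domains(fractions: list[BinnedTrack], smoothing_window: int = 5,
                     thresholds: tuple[float, float] | str = (2.5, 4.5),
                     signal_floor_fraction: float = 0.1) -> RTDomainMap:
    """Classify early/mid/late domains from six sorted S-phase fraction tracks.

    All tracks must be BPM-normalized and share genome and bin size. Per bin,
    T = sum(k * s_k) / sum(s_k) over smoothed fractions k = 1..6; labels are
    early (T < thresholds[0]), mid, late (T >= thresholds[1]). The default
    fixed cutpoints split the six fractions 2/2/2; ``thresholds="tercile"``
    instead places the cutpoints at the genome-wide 1/3 and 2/3 quantiles of
    T (assumes roughly balanced class shares but adapts to how passive
    replication compresses the observed timing range), and
    ``thresholds="kmeans"`` uses deterministic 1-D 3-means. Bins whose total
    signal is below ``signal_floor_fraction`` times the genome-mean total are
    labeled by nearest-neighbor fill. Contiguous same-label bins are merged.
    """
    if len(fractions) != 6:
        raise ValueError("expected six fraction tracks")
    ref = fractions[0]
    for tr in fractions:
        if tr.genome is not ref.genome and tr.genome != ref.genome:
            raise ValueError("fraction tracks have mismatched genomes")
        if tr.bin_size != ref.bin_size:
            raise ValueError("fraction tracks have mismatched bin sizes")
        if tr.units != "BPM":
            raise ValueError("fraction tracks must be BPM-normalized")
    genome_total = np.concatenate([
        np.sum([tr.data[c] for tr in fractions], axis=0) for c in ref.genome.chrom_names])
    floor = signal_floor_fraction * genome_total.mean()
    if isinstance(thresholds, str):
        all_T = []
        for chrom in ref.genome.chrom_names:
            sm = np.array([_moving_average(tr.data[chrom], smoothing_window)
                           for tr in fractions])
            tot = sm.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                all_T.append(((np.arange(1, 7)[:, None] * sm).sum(axis=0) / tot)[tot > 0])
        pooled = np.concatenate(all_T)
        if thresholds == "tercile":
            lo, hi = np.quantile(pooled, [1 / 3, 2 / 3])
        elif thresholds == "kmeans":
            lo, hi = _kmeans_cutpoints(pooled)
        else:
            raise ValueError(f"unknown threshold mode {thresholds!r}")
    else:
        lo, hi = thresholds
    rows = []
    bs = ref.bin_size
    for chrom in ref.genome.chrom_names:
        smoothed = np.array([_moving_average(tr.data[chrom], smoothing_window)
                             for tr in fractions])
        total = smoothed.sum(axis=0)
        k = np.arange(1, 7)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            T = (k * smoothed).sum(axis=0) / total
        labels = np.where(T < lo, 0, np.where(T < hi, 1, 2))
        raw_total = np.sum([tr.data[chrom] for tr in fractions], axis=0)
        labels = _nearest_fill(labels, (raw_total >= floor) & (total > 0))
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(labels)]))
        length = ref.genome.chrom_lengths[chrom]
        for s, e in zip(starts, ends):
            rows.append((chrom, s * bs, min(e * bs, length), RT_CLASSES[labels[s]]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return RTDomainMap(IntervalSet(df, genome=ref.genome), ref.bin_size)
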