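"""Reading, writing, normalising and querying binned coverage tracks.

bedGraph (4-column, whitespace separated) is the reference dialect; bigWig
input is supported behind the same contract when pyBigWig is installed.
Rebinning onto the working bin grid uses the coverage-weighted mean, so a
track read at any bin size agrees with per-bp averaging.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import BinnedTrack, Genome, IntervalSet, PointFeatureSet

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_bigwig",
    "bpm_normalize",
    "extract_signal",
]


def _deposit(num: np.ndarray, den: np.ndarray, start: int, end: int,
             value: float, bin_size: int) -> None:
    """Add value*overlap (and overlap) of [start, end) onto each bin.

    Weights are bin fractions (a fully covered bin has weight exactly 1.0) so
    a bin covered by a single interval reads back its value bit-for-bit."""
    b0, b1 = start // bin_size, (end - 1) // bin_size
    if b0 == b1:
        w = (end - start) / bin_size
        num[b0] += value * w
        den[b0] += w
        return
    left = ((b0 + 1) * bin_size - start) / bin_size
    right = (end - b1 * bin_size) / bin_size
    num[b0] += value * left
    den[b0] += left
    num[b1] += value * right
    den[b1] += right
    if b1 - b0 > 1:
        num[b0 + 1:b1] += value
        den[b0 + 1:b1] += 1.0


def read_bedgraph(path, genome: Genome, bin_size: int,
                  on_unknown_chrom: str = "error") -> BinnedTrack:
    """Read a 4-column bedGraph into a :class:`BinnedTrack`.

    Intervals are rebinned by coverage-weighted mean; uncovered bins are 0.
    ``on_unknown_chrom`` is ``"error"`` or ``"skip"`` (skip with warning).
    Units are raw_count unless the (optional) track header declares BPM.
    """
    units = "raw_count"
    skip = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("track"):
        skip = 1
        if "BPM" in first:
            units = "BPM"
    df = (pd.read_csv(path, sep=r"\s+", header=None, comment="#", skiprows=skip,
                      names=["chrom", "start", "end", "value"],
                      dtype={"chrom": str}, float_precision="round_trip")
          if _has_data(path) else None)
    track = BinnedTrack.zeros(genome, bin_size, units=units)
    if df is None or df.empty:
        return track
    numerators = {c: np.zeros_like(track.data[c]) for c in genome.chrom_names}
    denominators = {c: np.zeros_like(track.data[c]) for c in genome.chrom_names}
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        chrom = row.chrom
        if chrom not in genome:
            if on_unknown_chrom == "skip":
                warnings.warn(f"skipping line {line_no}: unknown chromosome {chrom}")
                continue
            raise ValueError(f"unknown chromosome {chrom} at line {line_no}")
        if row.end > genome.chrom_lengths[chrom] or row.start < 0:
            raise ValueError(
                f"coordinates beyond {chrom} length at line {line_no}: "
                f"{row.start}-{row.end}")
        _deposit(numerators[chrom], denominators[chrom],
                 int(row.start), int(row.end), float(row.value), bin_size)
    for chrom in genome.chrom_names:
        den = denominators[chrom]
        covered = den > 0
        track.data[chrom][covered] = numerators[chrom][covered] / den[covered]
    return track


def _has_data(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("track", "#")):
                return True
    return False


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a track as bedGraph; zero runs are omitted, equal-value runs fused.

    Reading the file back at the same bin size reproduces the values exactly.
    """
    with open(path, "w") as fh:
        if track.units == "BPM":
            fh.write('track type=bedGraph units=BPM\n')
        for chrom in track.genome.chrom_names:
            arr = track.data[chrom]
            length = track.genome.chrom_lengths[chrom]
            if len(arr) == 0:
                continue
            # run-length encode equal adjacent values
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s * track.bin_size}"
                         f"\t{min(e * track.bin_size, length)}\t{float(v)!r}\n")


def read_bigwig(path, genome: Genome, bin_size: int) -> BinnedTrack:
    """Optional bigWig reader (requires pyBigWig); same contract as bedGraph."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("bigWig support requires pyBigWig") from exc
    track = BinnedTrack.zeros(genome, bin_size)
    with pyBigWig.open(str(path)) as bw:
        for chrom in genome.chrom_names:
            if chrom not in bw.chroms():
                continue
            n = genome.n_bins(chrom, bin_size)
            vals = bw.stats(chrom, 0, genome.chrom_lengths[chrom], nBins=n, type="mean")
            arr = np.array([v if v is not None else 0.0 for v in vals])
            track.data[chrom] = arr
    return track


def bpm_normalize(track: BinnedTrack) -> BinnedTrack:
    """Bins-per-million normalisation: value_i * 1e6 / sum of all values.

    The genome-wide sum of the returned track is exactly 1e6 (up to float
    rounding); units become BPM.
    """
    if track.units == "BPM":
        raise ValueError("track is already BPM-normalized")
    total = track.total()
    if total <= 0:
        raise ValueError("cannot normalize empty track")
    out = track.copy()
    for chrom in out.data:
        out.data[chrom] = out.data[chrom] * (1e6 / total)
    out.units = "BPM"
    return out


def _interval_mean(track: BinnedTrack, chrom: str, start: int, end: int) -> float:
    """Coverage-weighted mean of bin values over [start, end)."""
    if end <= start:
        raise ValueError("zero-length interval")
    bs = track.bin_size
    arr = track.data[chrom]
    b0, b1 = start // bs, (end - 1) // bs
    if b0 == b1:
        return float(arr[b0])
    weights = np.full(b1 - b0 + 1, float(bs))
    weights[0] = (b0 + 1) * bs - start
    weights[-1] = end - b1 * bs
    vals = arr[b0:b1 + 1]
    return float(np.average(vals, weights=weights))


def extract_signal(track: BinnedTrack, records, half_width: int | None = None) -> np.ndarray:
    """Mean signal per record of an :class:`IntervalSet` or :class:`PointFeatureSet`.

    Point records are expanded to ``[pos - half_width, pos + half_width)``
    (clipped to the chromosome). Returns one coverage-weighted mean per record,
    in record order of the underlying frame.
    """
    if isinstance(records, PointFeatureSet):
        if half_width is None or half_width <= 0:
            raise ValueError("half_width required for point features")
        out = np.empty(len(records))
        for i, row in enumerate(records.df.itertuples(index=False)):
            length = track.genome.chrom_lengths[row.chrom]
            s = max(0, row.pos - half_width)
            e = min(length, row.pos + half_width)
            out[i] = _interval_mean(track, row.chrom, s, e)
        return out
    if isinstance(records, IntervalSet):
        out = np.empty(len(records))
        for i, row in enumerate(records.df.itertuples(index=False)):
            out[i] = _interval_mean(track, row.chrom, int(row.start), int(row.end))
        return out
    raise TypeError("records must be an IntervalSet or PointFeatureSet")
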