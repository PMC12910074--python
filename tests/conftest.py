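import numpy as np
import pandas as pd
import pytest

from repliczone.core import Genome, BinnedTrack, IntervalSet
from repliczone.iz_calling import IZSet


@pytest.fixture
def genome():
    # chrB length is not a multiple of 1 kb: exercises partial terminal bins
    return Genome.from_dict({"chrA": 100_000, "chrB": 50_500})


@pytest.fixture
def empty_blacklist():
    return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))


def make_track(genome, bin_size=1000, fill=0.0, units="raw_count", data=None):
    track = BinnedTrack.zeros(genome, bin_size, units=units)
    for chrom in genome.chrom_names:
        track.data[chrom][:] = fill
    if data:
        for chrom, arr in data.items():
            track.data[chrom][: len(arr)] = arr
    return track


def truth_izset(truth, rt_class=None):
    """Planted origins as an IZSet (2 kb intervals centered on each origin)."""
    oris = truth.origins
    if rt_class is not None:
        oris = oris[oris["rt_class"] == rt_class]
    df = oris.copy()
    df["start"] = df["pos"] - 1000
    df["end"] = df["pos"] + 1000
    df["center"] = df["pos"]
    df["score"] = 1.0
    return IZSet(df[["chrom", "start", "end", "center", "rt_class", "score"]],
                 truth.genome)


def bruteforce_interval_mean(per_bp: np.ndarray, start: int, end: int) -> float:
    return float(per_bp[start:end].mean())


def per_bp_from_track(track, chrom):
    """Expand a binned track to a per-bp array (oracle helper)."""
    length = track.genome.chrom_lengths[chrom]
    out = np.empty(length)
    bs = track.bin_size
    for i, v in enumerate(track.data[chrom]):
        out[i * bs: min((i + 1) * bs, length)] = v
    return out
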