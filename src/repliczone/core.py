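"""Core data carriers: genomes, binned signal tracks, interval and point sets.

Coordinates are 0-based, half-open everywhere (BED convention). A
:class:`BinnedTrack` stores one fixed-width signal array per chromosome; the
terminal bin of a chromosome may be partial and is weighted by its true bp
width wherever means are taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RT_CLASSES = ("early", "mid", "late")


@dataclass(frozen=True)
class Genome:
    """An ordered set of chromosomes with lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: Mapping[str, int]

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for name in self.chrom_names:
            length = self.chrom_lengths[name]
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int]) -> "Genome":
        return cls(tuple(lengths), dict(lengths))

    @classmethod
    def read_tsv(cls, path) -> "Genome":
        df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"],
                         comment="#", dtype={"chrom": str, "length": np.int64})
        return cls.from_dict(dict(zip(df["chrom"], df["length"])))

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.chrom_lengths[chrom] / bin_size)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-bin signal (raw counts or BPM)."""

    genome: Genome
    bin_size: int
    data: dict[str, np.ndarray]
    units: str = "raw_count"

    @classmethod
    def zeros(cls, genome: Genome, bin_size: int, units: str = "raw_count") -> "BinnedTrack":
        data = {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chrom_names}
        return cls(genome, bin_size, data, units)

    def validate(self) -> None:
        for chrom in self.genome.chrom_names:
            arr = self.data[chrom]
            if len(arr) != self.genome.n_bins(chrom, self.bin_size):
                raise ValueError(f"array length mismatch on {chrom}")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"non-finite or negative values on {chrom}")

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.genome, self.bin_size,
                           {c: a.copy() for c, a in self.data.items()}, self.units)

    def bin_widths(self, chrom: str) -> np.ndarray:
        """True bp width of each bin; only the terminal bin may be partial."""
        n = len(self.data[chrom])
        widths = np.full(n, float(self.bin_size))
        widths[-1] = self.genome.chrom_lengths[chrom] - (n - 1) * self.bin_size
        return widths

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.data[chrom][pos // self.bin_size])


class IntervalSet:
    """Sorted records of (chrom, start, end[, label, score]), half-open."""

    COLUMNS = ["chrom", "start", "end"]

    def __init__(self, df: pd.DataFrame, genome: Genome | None = None):
        df = df.copy().reset_index(drop=True)
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing column {col}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise ValueError("intervals must satisfy 0 <= start < end")
        if genome is not None:
            for chrom, grp in df.groupby("chrom"):
                if chrom not in genome:
                    raise ValueError(f"unknown chromosome {chrom}")
                if (grp["end"] > genome.chrom_lengths[chrom]).any():
                    raise ValueError(f"interval beyond end of {chrom}")
        order = [c for c in df["chrom"].unique()]
        df["chrom"] = pd.Categorical(df["chrom"], categories=sorted(order), ordered=True)
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        self.df = df
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    @classmethod
    def from_records(cls, records: Iterable[tuple], columns=None, genome=None) -> "IntervalSet":
        columns = columns or cls.COLUMNS
        return cls(pd.DataFrame(list(records), columns=columns), genome=genome)

    @classmethod
    def read_bed(cls, path, genome: Genome | None = None) -> "IntervalSet":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        names = ["chrom", "start", "end", "label", "score", "strand"][: df.shape[1]]
        df.columns = names
        return cls(df, genome=genome)

    def write_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        sub = self.for_chrom(chrom)
        return bool(((sub["start"] <= pos) & (pos < sub["end"])).any())

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())


POINT_KINDS = ("TSS", "TTS", "enhancer_midpoint", "IZ_center", "control")


class PointFeatureSet:
    """Records of (chrom, pos, kind); kind is free-form but conventionally
    one of TSS / TTS / enhancer_midpoint / IZ_center / control."""

    def __init__(self, df: pd.DataFrame, genome: Genome | None = None):
        df = df.copy().reset_index(drop=True)
        for col in ("chrom", "pos", "kind"):
            if col not in df.columns:
                raise ValueError(f"missing column {col}")
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 0).any():
            raise ValueError("positions must be >= 0")
        if genome is not None:
            for chrom, grp in df.groupby("chrom"):
                if chrom not in genome:
                    raise ValueError(f"unknown chromosome {chrom}")
                if (grp["pos"] >= genome.chrom_lengths[chrom]).any():
                    raise ValueError(f"position beyond end of {chrom}")
        self.df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[tuple], genome=None) -> "PointFeatureSet":
        return cls(pd.DataFrame(list(records), columns=["chrom", "pos", "kind"]), genome)

    @classmethod
    def read_tsv(cls, path, genome: Genome | None = None) -> "PointFeatureSet":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "kind"],
                         comment="#", dtype={"chrom": str, "kind": str})
        return cls(df, genome=genome)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def of_kind(self, kind: str) -> "PointFeatureSet":
        return PointFeatureSet(self.df[self.df["kind"] == kind], self.genome)
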