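"""End-to-end pipeline orchestration with config snapshot and provenance.

A run goes: simulate (or load) tracks and domain map -> call class-stratified
IZs -> control regions -> time-course medians and fork speed -> paired-
condition residual regression, writing every stage's tables plus a manifest
(seeds, parameter snapshot, output checksums). Re-running with the same
config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import IntervalSet
from .fork_dynamics import fork_speed, select_isolated_izs
from .iz_calling import IZCallingConfig, IZSet, call_izs, generate_control_regions
from .oct4_regression import paired_window_signal, paired_scatter_table, regress_paired
from .signal_stats import iz_timecourse
from .simulate import (SimConfig, make_feature_sets, plant_blacklist_artifacts,
                       simulate_calling_tracks, simulate_edu_timecourse,
                       simulate_oct4_pair)
from .track_io import bpm_normalize, write_bedgraph

log = logging.getLogger("repliczone")


@dataclass
class RunConfig:
    out_dir: str = "repliczone_run"
    seed: int = 7
    sim: SimConfig = field(default_factory=SimConfig)
    calling: IZCallingConfig = field(default_factory=IZCallingConfig)
    timecourse_times: tuple = (2, 4, 6, 8)
    reference_time_h: float = 2.0
    isolation_distance: int = 100_000
    oct4_half_width: int = 5000

    def __post_init__(self):
        # one seed drives every stage unless the sub-configs override it
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.calling, dict):
            self.calling = IZCallingConfig(**self.calling)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def snapshot(self) -> dict:
        # json round-trip turns tuples into lists so the snapshot is YAML-safe;
        # out_dir is a run location, not scientific config, and is excluded so
        # identical-seed runs to different directories are byte-identical
        d = json.loads(json.dumps(dataclasses.asdict(self)))
        d.pop("out_dir", None)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written as manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    calling = dataclasses.replace(config.calling, rng_seed=config.seed)
    with open(out / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump(config.snapshot(), fh, sort_keys=True)

    log.info("stage 1: simulate calling tracks")
    raw_tracks, truth = simulate_calling_tracks(sim, normalize=False)
    raw_tracks["early"], blacklist = plant_blacklist_artifacts(
        raw_tracks["early"], n=sim.blacklist_n, width=sim.blacklist_width,
        amplitude=sim.blacklist_amplitude, seed=config.seed)
    tracks = {k: bpm_normalize(t) for k, t in raw_tracks.items()}
    truth.to_json(out / "truth.json")
    truth.domains.write_bed(out / "domains.bed")
    blacklist.write_bed(out / "blacklist.bed")
    for key, tr in tracks.items():
        write_bedgraph(tr, out / f"edu_calling_{key}.bpm.bedgraph")
    with open(out / "genome.tsv", "w") as fh:
        for c in truth.genome.chrom_names:
            fh.write(f"{c}\t{truth.genome.chrom_lengths[c]}\n")

    log.info("stage 2: call IZs")
    iz_early, prov_e = call_izs(tracks["early"], truth.domains, blacklist,
                                calling, classes=("early",))
    iz_ml, prov_ml = call_izs(tracks["midlate"], truth.domains, blacklist,
                              calling, classes=("mid", "late"))
    izs = IZSet.union([iz_early, iz_ml])
    izs.write_bed(out / "izs.bed")
    with open(out / "iz_provenance.json", "w") as fh:
        json.dump({"early_track": prov_e, "midlate_track": prov_ml}, fh, indent=1)

    log.info("stage 3: control regions")
    controls = generate_control_regions(truth.genome, izs, calling)
    controls.write_tsv(out / "controls.tsv")

    log.info("stage 4: time course, profiles and fork speed")
    timecourse, _ = simulate_edu_timecourse(sim, times=config.timecourse_times)
    values, medians = iz_timecourse(timecourse, izs)
    medians.to_csv(out / "iz_timecourse_medians.tsv", sep="\t", index=False)
    isolated = select_isolated_izs(izs, config.isolation_distance)
    series = fork_speed(timecourse, isolated.of_class("early"),
                        reference_time=config.reference_time_h)
    series.to_frame().to_csv(out / "fork_speed.tsv", sep="\t", index=False)

    log.info("stage 5: paired-condition regression")
    on, off, truth_oct4 = simulate_oct4_pair(sim)
    paired = paired_window_signal(on, off, izs, config.oct4_half_width)
    fits = regress_paired(paired)
    pd.DataFrame([r.to_row() for r in fits.values()]).to_csv(
        out / "residual_regression.tsv", sep="\t", index=False)
    paired_scatter_table(paired).to_csv(out / "paired_scatter.tsv", sep="\t",
                                        index=False)

    log.info("stage 6: features and manifest")
    features = make_feature_sets(truth, seed=config.seed)
    features.write_tsv(out / "features.tsv")
    outputs = sorted(p.name for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config": config.snapshot(),
        "n_izs": {c: int((izs.df["rt_class"] == c).sum())
                  for c in ("early", "mid", "late")},
        "n_isolated_early": int(len(isolated.of_class("early"))),
        "fork_speed_kb_h": {str(t): s for t, s in series.speed_kb_per_h.items()},
        "regression_slopes": {c: fits[c].slope for c in fits},
        "checksums": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
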