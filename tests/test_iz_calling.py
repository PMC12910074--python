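import numpy as np
import pandas as pd
import pytest

from repliczone.core import Genome, IntervalSet
from repliczone.iz_calling import (IZCallingConfig, IZSet, apply_exclusion_zone,
                                   bin_and_extract, call_broad_regions, call_izs,
                                   class_threshold, filter_blacklist,
                                   generate_control_regions, refine_center,
                                   refine_to_izs)
from repliczone.rt_domains import RTDomainMap
from repliczone.simulate import (SimConfig, callable_origins, evaluate_recovery,
                                 simulate_calling_tracks)
from repliczone.track_io import bpm_normalize

from conftest import make_track


def domain_map(genome, rows, resolution=1000):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return RTDomainMap(IntervalSet(df, genome=genome), resolution)


def intervals(rows):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestBinAndExtract:
    def test_single_domain_bin_count(self, genome):
        track = make_track(genome, fill=1.0)
        dom = domain_map(genome, [("chrA", 0, 10_000, "early")])
        out = bin_and_extract(track, dom, "early")
        assert len(out) == 1 and len(out[0][1]) == 10

    def test_midpoint_rule_at_half_bin_boundary(self, genome):
        track = make_track(genome, fill=1.0)
        # domain ends at 10.5 kb: bin 10 (midpoint 10.5 kb) is excluded
        dom = domain_map(genome, [("chrA", 0, 10_500, "early")])
        assert len(bin_and_extract(track, dom, "early")[0][1]) == 10
        # domain ending at 10.6 kb includes bin 10's midpoint
        dom = domain_map(genome, [("chrA", 0, 10_600, "early")])
        assert len(bin_and_extract(track, dom, "early")[0][1]) == 11

    def test_matches_bruteforce_membership(self, genome):
        rng = np.random.default_rng(0)
        track = make_track(genome, fill=1.0)
        rows = [("chrA", 0, 23_000, "early"), ("chrA", 30_000, 41_000, "early"),
                ("chrB", 7_000, 20_000, "early")]
        dom = domain_map(genome, rows)
        got = {(c, int(p)) for c, pos, _ in bin_and_extract(track, dom, "early")
               for p in pos}
        want = set()
        for chrom in genome.chrom_names:
            for i in range(genome.n_bins(chrom, 1000)):
                mid = i * 1000 + 500
                if any(c == chrom and s <= mid < e for c, s, e, _ in rows):
                    want.add((chrom, i * 1000))
        assert got == want

    def test_blacklist_masking_excludes_bins(self, genome):
        track = make_track(genome, fill=1.0)
        dom = domain_map(genome, [("chrA", 0, 10_000, "early")])
        bl = intervals([("chrA", 3_000, 5_000)])
        out = bin_and_extract(track, dom, "early", blacklist=bl)
        positions = sorted(int(p) for _, pos, _ in out for p in pos)
        assert positions == [0, 1000, 2000, 5000, 6000, 7000, 8000, 9000]


class TestClassThreshold:
    def test_constant_bins(self):
        bins = [("chrA", np.arange(5) * 1000, np.full(5, 3.0))]
        assert class_threshold(bins, 0.5, k=3) == pytest.approx(1.5)

    def test_topk_mean_arithmetic(self):
        bins = [("chrA", np.arange(3) * 1000, np.array([10.0, 8.0, 6.0]))]
        assert class_threshold(bins, 0.5, k=2) == pytest.approx(4.5)

    def test_fewer_than_k_falls_back_to_max(self):
        bins = [("chrA", np.arange(2) * 1000, np.array([4.0, 8.0]))]
        with pytest.warns(UserWarning):
            assert class_threshold(bins, 0.25, k=10) == pytest.approx(2.0)


class TestBroadRegions:
    def test_runs_without_gap_merge(self):
        sig = np.array([0, 5, 5, 0, 5.0])
        bins = [("chrA", np.arange(5) * 1000, sig)]
        regions = call_broad_regions(bins, 3.0, merge_gap=0)
        assert [(r.start, r.end) for r in regions.df.itertuples()] == \
            [(1000, 3000), (4000, 5000)]

    def test_gap_merging(self):
        sig = np.array([0, 5, 5, 0, 5.0])
        bins = [("chrA", np.arange(5) * 1000, sig)]
        regions = call_broad_regions(bins, 3.0, merge_gap=1000)
        assert [(r.start, r.end) for r in regions.df.itertuples()] == [(1000, 5000)]

    def test_all_subthreshold_empty(self):
        bins = [("chrA", np.arange(5) * 1000, np.ones(5))]
        assert len(call_broad_regions(bins, 3.0, merge_gap=2000)) == 0

    def test_matches_run_length_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            sig = rng.uniform(0, 2, 40)
            gap_bins = int(rng.integers(0, 4))
            got = call_broad_regions([("chrA", np.arange(40) * 1000, sig)],
                                     1.0, merge_gap=gap_bins * 1000)
            got_pairs = [(r.start // 1000, r.end // 1000)
                         for r in got.df.itertuples()]
            # oracle: explicit scan
            runs, cur = [], None
            for i, v in enumerate(sig):
                if v >= 1.0:
                    if cur is None:
                        cur = [i, i + 1]
                    elif i - cur[1] <= gap_bins:
                        cur[1] = i + 1
                    else:
                        runs.append(tuple(cur))
                        cur = [i, i + 1]
            if cur:
                runs.append(tuple(cur))
            assert got_pairs == runs


class TestRefineToIZs:
    def test_median_keeps_top_half(self, genome):
        track = make_track(genome, data={"chrA": [1, 2, 3, 4.0]})
        izs = refine_to_izs(track, intervals([("chrA", 0, 4000)]), min_width=2)
        assert [(r.start, r.end) for r in izs.df.itertuples()] == [(2000, 4000)]

    def test_constant_region_fully_retained(self, genome):
        track = make_track(genome, data={"chrA": [2, 2, 2, 2.0]})
        izs = refine_to_izs(track, intervals([("chrA", 0, 4000)]), min_width=2)
        assert [(r.start, r.end) for r in izs.df.itertuples()] == [(0, 4000)]

    def test_min_width_drops_single_bin_runs(self, genome):
        track = make_track(genome, data={"chrA": [5, 1, 5.0]})
        izs = refine_to_izs(track, intervals([("chrA", 0, 3000)]), min_width=2)
        assert len(izs) == 0


class TestFilterBlacklist:
    def test_containment_discarded_abutment_kept(self):
        izs = intervals([("chrA", 1000, 3000), ("chrA", 5000, 7000)])
        bl = intervals([("chrA", 0, 4000), ("chrA", 7000, 9000)])
        kept, n = filter_blacklist(izs, bl)
        assert n == 1
        assert [(r.start, r.end) for r in kept.df.itertuples()] == [(5000, 7000)]

    def test_matches_bruteforce_overlap(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            izs_rows = [("chrA", int(s), int(s) + int(rng.integers(1, 5000)))
                        for s in rng.integers(0, 90_000, 8)]
            bl_rows = [("chrA", int(s), int(s) + int(rng.integers(1, 8000)))
                       for s in rng.integers(0, 90_000, 4)]
            kept, _ = filter_blacklist(intervals(izs_rows), intervals(bl_rows))
            got = {(r.start, r.end) for r in kept.df.itertuples()}
            want = {(s, e) for c, s, e in izs_rows
                    if not any(s < be and bs < e for _, bs, be in bl_rows)}
            assert got == want


class TestRefineCenter:
    def test_symmetric_signal_gives_midpoint(self, genome):
        track = make_track(genome, data={"chrA": [0, 1, 5, 1, 0.0]})
        assert refine_center(track, "chrA", 0, 5000) == 2000

    def test_centroid_arithmetic(self, genome):
        # all mass in bin 2 (midpoint 2.5 kb) -> snapped to 1 kb grid
        track = make_track(genome, data={"chrA": [0, 0, 10.0]})
        center = refine_center(track, "chrA", 0, 3000, resolution=1000)
        assert center == 2000  # round(2.5) -> 2 under banker's rounding

    def test_zero_signal_gives_geometric_midpoint(self, genome):
        track = make_track(genome)
        assert refine_center(track, "chrA", 10_000, 14_000) == 12_000


def izset(genome, rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "center",
                                     "rt_class", "score"])
    return IZSet(df, genome)


class TestExclusionZone:
    def big_genome(self):
        return Genome.from_dict({"chr1": 5_000_000})

    def test_mid_iz_distance_rule(self):
        g = self.big_genome()
        dom = domain_map(g, [("chr1", 0, 1_000_000, "early"),
                             ("chr1", 1_000_000, 5_000_000, "mid")])
        near = izset(g, [("chr1", 1_390_000, 1_410_000, 1_400_000, "mid", 1.0)])
        far = izset(g, [("chr1", 1_590_000, 1_610_000, 1_600_000, "mid", 1.0)])
        kept_near, _ = apply_exclusion_zone(near, dom, 500_000)
        kept_far, _ = apply_exclusion_zone(far, dom, 500_000)
        assert len(kept_near) == 0 and len(kept_far) == 1

    def test_late_iz_excluded_by_either_class(self):
        g = self.big_genome()
        dom = domain_map(g, [("chr1", 0, 500_000, "early"),
                             ("chr1", 1_500_000, 2_000_000, "mid"),
                             ("chr1", 2_000_000, 5_000_000, "late")])
        # 450 kb from mid, > 500 kb from early -> still discarded
        iz = izset(g, [("chr1", 2_440_000, 2_460_000, 2_450_000, "late", 1.0)])
        kept, _ = apply_exclusion_zone(iz, dom, 500_000)
        assert len(kept) == 0

    def test_early_untouched(self):
        g = self.big_genome()
        dom = domain_map(g, [("chr1", 0, 5_000_000, "early")])
        iz = izset(g, [("chr1", 0, 20_000, 10_000, "early", 1.0)])
        kept, _ = apply_exclusion_zone(iz, dom, 500_000)
        assert len(kept) == 1

    def test_matches_bruteforce_distance_oracle(self):
        rng = np.random.default_rng(3)
        g = self.big_genome()
        for _ in range(30):
            # random non-overlapping domain layout
            edges = np.sort(rng.choice(np.arange(1, 50) * 100_000, 6, replace=False))
            edges = [0, *edges, 5_000_000]
            labels = rng.choice(["early", "mid", "late"], len(edges) - 1)
            dom = domain_map(g, [("chr1", s, e, l) for s, e, l in
                                 zip(edges[:-1], edges[1:], labels)])
            centers = rng.integers(10_000, 4_990_000, 12)
            rows, expected = [], []
            excluded_by = {"mid": ("early",), "late": ("early", "mid")}
            for c in centers:
                cls = str(rng.choice(["mid", "late"]))
                if dom.class_of_position("chr1", int(c)) != cls:
                    continue
                rows.append(("chr1", int(c) - 1000, int(c) + 1000, int(c), cls, 1.0))
                dmin = np.inf
                for s, e, l in zip(edges[:-1], edges[1:], labels):
                    if l in excluded_by[cls]:
                        d = 0 if s <= c < e else min(abs(s - c), abs(c - (e - 1)))
                        dmin = min(dmin, d)
                expected.append(dmin >= 500_000)
            if not rows:
                continue
            kept, _ = apply_exclusion_zone(izset(g, rows), dom, 500_000)
            kept_centers = set(kept.df["center"])
            for (_, _, _, c, _, _), keep in zip(rows, expected):
                assert (c in kept_centers) == keep


class TestCallIZs:
    def test_zero_signal_track_clean_exit(self, genome, empty_blacklist):
        track = make_track(genome, fill=1.0)  # flat -> constant, no peaks above
        track.data["chrA"][0] = 1.0
        track = bpm_normalize(track)
        dom = domain_map(genome, [("chrA", 0, 100_000, "early"),
                                  ("chrB", 0, 50_500, "late")])
        with pytest.warns(UserWarning):
            izs, prov = call_izs(track, dom, empty_blacklist,
                                 IZCallingConfig(), classes=("mid",))
        assert len(izs) == 0

    def test_threshold_monotonicity(self, empty_blacklist):
        # raising the early fraction never increases the early IZ count
        cfg = SimConfig(seed=5)
        tracks, truth = simulate_calling_tracks(cfg)
        counts = []
        for frac in (0.3, 0.5, 0.8):
            call_cfg = IZCallingConfig()
            call_cfg.class_fractions = dict(call_cfg.class_fractions,
                                            early=frac)
            izs, _ = call_izs(tracks["early"], truth.domains, empty_blacklist,
                              call_cfg, classes=("early",))
            counts.append(len(izs))
        assert counts[0] >= counts[1] >= counts[2]

    def test_determinism(self, empty_blacklist):
        cfg = SimConfig(seed=5)
        tracks, truth = simulate_calling_tracks(cfg)
        out = []
        for _ in range(2):
            izs, _ = call_izs(tracks["early"], truth.domains, empty_blacklist,
                              IZCallingConfig(rng_seed=5), classes=("early",))
            out.append(izs.df)
        pd.testing.assert_frame_equal(out[0], out[1])

    def test_recovery_and_full_output_invariants(self, empty_blacklist):
        """End-to-end recovery at the default study conditions (seed 7) plus
        an independent re-check of every emitted IZ against the calling rules."""
        cfg = SimConfig(seed=7)
        tracks, truth = simulate_calling_tracks(cfg)
        call_cfg = IZCallingConfig(rng_seed=7)
        early, _ = call_izs(tracks["early"], truth.domains, empty_blacklist,
                            call_cfg, classes=("early",))
        midlate, _ = call_izs(tracks["midlate"], truth.domains, empty_blacklist,
                              call_cfg, classes=("mid", "late"))
        izs = IZSet.union([early, midlate])
        stats = evaluate_recovery(izs, callable_origins(truth), tolerance=20_000)
        for cls in ("early", "mid", "late"):
            assert stats[cls]["recall"] >= 0.9
            assert stats[cls]["precision"] >= 0.9
        # brute-force re-check: class consistency and exclusion rule
        excluded_by = {"early": (), "mid": ("early",), "late": ("early", "mid")}
        for row in izs.df.itertuples(index=False):
            assert truth.domains.class_of_position(row.chrom, int(row.center)) \
                == row.rt_class
            for cls in excluded_by[row.rt_class]:
                for d in truth.domains.of_class(cls).for_chrom(row.chrom) \
                        .itertuples(index=False):
                    assert not (d.start - 500_000 <= row.center < d.end + 500_000)

    def test_planted_mid_iz_near_early_domain_excluded(self, empty_blacklist):
        # a strong mid peak 300 kb from an early domain must be absent from
        # the final calls but present among pre-exclusion candidates
        g = Genome.from_dict({"chr1": 4_000_000})
        dom = domain_map(g, [("chr1", 0, 1_000_000, "early"),
                             ("chr1", 1_000_000, 4_000_000, "mid")])
        track = make_track(g, fill=0.0)
        rng = np.random.default_rng(0)
        track.data["chr1"][:] = rng.poisson(0.5, len(track.data["chr1"]))
        for center, amp in ((1_300_000, 400), (2_500_000, 400)):
            b = center // 1000
            track.data["chr1"][b - 3: b + 4] += amp
        track = bpm_normalize(track)
        izs, prov = call_izs(track, dom, empty_blacklist,
                             IZCallingConfig(), classes=("mid",))
        centers = izs.df["center"].to_numpy()
        assert (np.abs(centers - 2_500_000) <= 20_000).any()
        assert not (np.abs(centers - 1_300_000) <= 20_000).any()
        assert prov["per_class"]["mid"]["n_exclusion_discarded"] >= 1


class TestControlRegions:
    def cfg(self, **kw):
        base = dict(control_candidates=20_000, control_n=500, rng_seed=1)
        base.update(kw)
        return IZCallingConfig(**base)

    def test_no_izs_returns_first_n_shuffled(self, genome):
        controls = generate_control_regions(genome, IZSet.empty(genome),
                                            self.cfg())
        assert len(controls) == 500

    def test_fixed_seed_reproducible(self, genome):
        izs = izset(genome, [("chrA", 40_000, 44_000, 42_000, "early", 1.0)])
        a = generate_control_regions(genome, izs, self.cfg(control_flank=5000))
        b = generate_control_regions(genome, izs, self.cfg(control_flank=5000))
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_exclusion_respected_and_matches_bruteforce(self, genome):
        izs = izset(genome, [("chrA", 40_000, 44_000, 42_000, "early", 1.0),
                             ("chrB", 10_000, 12_000, 11_000, "late", 1.0)])
        controls = generate_control_regions(genome, izs,
                                            self.cfg(control_flank=20_000))
        for row in controls.df.itertuples(index=False):
            for iz in izs.df.itertuples(index=False):
                if iz.chrom == row.chrom:
                    assert abs(row.pos - iz.center) > 20_000

    def test_fully_covered_genome_errors(self, genome):
        izs = izset(genome, [("chrA", 48_000, 52_000, 50_000, "early", 1.0),
                             ("chrB", 24_000, 28_000, 25_000, "early", 1.0)])
        with pytest.raises(ValueError, match="control"):
            generate_control_regions(genome, izs, self.cfg(control_flank=60_000))
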