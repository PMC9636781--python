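import numpy as np
import pandas as pd
import pytest

import methmotif as mm
from methmotif.errors import EmptyInputError, MethMotifError

from conftest import make_records


def anchors_of(*entries):
    return mm.meth_io.anchors_from_tuples(list(entries))


class TestSplitChannels:
    def test_gcmt_hcg_is_intrinsic(self):
        g = mm.Genome({"c": "ACGT"})
        recs = make_records([("c", 2, "+", 1, 1, "CGT")])
        res = mm.split_channels(recs, g, mm.ChannelSpec("GCMT"))
        assert len(res.intrinsic) == 1 and len(res.induced) == 0

    def test_gcmt_gcg_excluded(self):
        g = mm.Genome({"c": "AGCGT"})
        recs = make_records([("c", 3, "+", 1, 1, "CGT")])
        res = mm.split_channels(recs, g, mm.ChannelSpec("GCMT"))
        assert len(res.excluded) == 1
        assert len(res.intrinsic) == len(res.induced) == 0

    def test_gcmt_gch_is_induced(self):
        g = mm.Genome({"c": "AGCAT"})
        recs = make_records([("c", 3, "+", 1, 1, "CAT")])
        res = mm.split_channels(recs, g, mm.ChannelSpec("GCMT"))
        assert len(res.induced) == 1

    def test_ccmt_ccg_splits_both_cs(self):
        # CCG: first C -> induced (CC target), second C -> intrinsic (CG)
        g = mm.Genome({"c": "ACCGT"})
        recs = make_records(
            [("c", 2, "+", 1, 1, "CCG"), ("c", 3, "+", 1, 1, "CGT")]
        )
        res = mm.split_channels(recs, g, mm.ChannelSpec("CCMT"))
        assert list(res.induced["pos"]) == [2]
        assert list(res.intrinsic["pos"]) == [3]

    def test_unknown_mode_errors(self):
        g = mm.Genome({"c": "ACGT"})
        with pytest.raises(MethMotifError):
            mm.split_channels(make_records([]), g, mm.ChannelSpec("XXMT"))

    @pytest.mark.parametrize("mode", ["CCMT", "GCMT"])
    def test_partition_property(self, planted_gc_data, mode):
        """Every record lands in exactly one class; channels are disjoint."""
        genome, records, _ = planted_gc_data
        res = mm.split_channels(records, genome, mm.ChannelSpec(mode))
        parts = [res.intrinsic, res.induced, res.excluded, res.other]
        assert sum(map(len, parts)) == len(records)
        keys = [set(map(tuple, p[["contig", "pos", "strand"]].to_numpy())) for p in parts]
        assert not (keys[0] & keys[1])
        recovered = keys[0] | keys[1] | keys[2] | keys[3]
        assert len(recovered) == len(records)

    def test_gcmt_excludes_exactly_gcg_sites(self, random_genome):
        seq = random_genome["contig1"][:5_000]
        g = mm.Genome({"contig1": seq})
        table = mm.cytosine_table(g)
        recs = table.assign(meth=1, unmeth=1)[mm.meth_io.REPORT_COLUMNS]
        res = mm.split_channels(recs, g, mm.ChannelSpec("GCMT"))
        n_gcg, _ = mm.count_motif_targets(g, "GCG", 1)
        assert len(res.excluded) == n_gcg


class TestBinLevels:
    def test_single_site(self):
        track = mm.bin_levels(make_records([("c", 3, "+", 8, 2, "CNN")]), bin_size=10)
        assert len(track) == 1 and track.iloc[0]["level"] == pytest.approx(0.8)
        assert (track.iloc[0]["start"], track.iloc[0]["end"]) == (0, 10)

    def test_coverage_weighted_not_mean_of_levels(self):
        recs = make_records(
            [("c", 1, "+", 1, 0, "CNN"), ("c", 2, "+", 0, 9, "CNN")]
        )
        track = mm.bin_levels(recs, bin_size=10)
        assert track.iloc[0]["level"] == pytest.approx(0.1)  # 1/10, not (1+0)/2

    def test_conserves_counts(self, planted_gc_data):
        _, records, _ = planted_gc_data
        track = mm.bin_levels(records, bin_size=100)
        assert track["depth"].sum() == (records["meth"] + records["unmeth"]).sum()
        meth_total = (track["level"] * track["depth"]).sum()
        assert meth_total == pytest.approx(records["meth"].sum())

    def test_constant_level_within_binomial_bound(self):
        genome = mm.simulate_genome(mm.GenomeSpec(length=10_000, seed=40))
        table = mm.cytosine_table(genome)
        rng = np.random.default_rng(41)
        depth = rng.poisson(30, len(table))
        meth = rng.binomial(depth, 0.5)
        recs = table.assign(meth=meth, unmeth=depth - meth)[mm.meth_io.REPORT_COLUMNS]
        track = mm.bin_levels(recs, bin_size=100)
        se = np.sqrt(0.25 / track["depth"])
        assert ((track["level"] - 0.5).abs() <= 3 * se + 1e-9).mean() > 0.98


class TestAggregateProfile:
    def test_single_anchor_single_site(self):
        recs = make_records([("c", 108, "+", 1, 0, "CNN")])
        prof = mm.aggregate_profile(recs, anchors_of(("c", 100, "+")), flank=10)
        assert list(prof.table["offset"]) == [7]
        assert prof.table.iloc[0]["mean_level"] == 1.0

    def test_minus_anchor_flips_offset(self):
        recs = make_records([("c", 108, "+", 1, 0, "CNN")])
        prof = mm.aggregate_profile(recs, anchors_of(("c", 100, "-")), flank=10)
        assert list(prof.table["offset"]) == [-7]

    def test_uniform_levels_give_flat_profile(self):
        genome = mm.simulate_genome(mm.GenomeSpec(length=20_000, seed=50))
        table = mm.cytosine_table(genome)
        recs = table.assign(meth=1, unmeth=1)[mm.meth_io.REPORT_COLUMNS]
        anchors = anchors_of(*[("contig1", 2_000 * k, "+") for k in range(1, 9)])
        prof = mm.aggregate_profile(recs, anchors, flank=500)
        assert prof.table["mean_level"].std() == pytest.approx(0.0)

    def test_empty_anchor_set_errors(self):
        with pytest.raises(EmptyInputError):
            mm.aggregate_profile(
                make_records([("c", 1, "+", 1, 0, "CNN")]),
                mm.meth_io.anchors_from_tuples([]),
                flank=10,
            )

    def test_anchor_order_invariance(self, planted_gc_data):
        _, records, _ = planted_gc_data
        a1 = anchors_of(("contig1", 10_000, "+"), ("contig1", 50_000, "-"))
        a2 = anchors_of(("contig1", 50_000, "-"), ("contig1", 10_000, "+"))
        p1 = mm.aggregate_profile(records, a1, flank=200)
        p2 = mm.aggregate_profile(records, a2, flank=200)
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_translation_invariance(self):
        recs = make_records(
            [("c", 95, "+", 3, 1, "CNN"), ("c", 110, "+", 1, 3, "CNN")]
        )
        shifted = recs.assign(pos=recs["pos"] + 1_000)
        p1 = mm.aggregate_profile(recs, anchors_of(("c", 100, "+")), flank=50)
        p2 = mm.aggregate_profile(shifted, anchors_of(("c", 1_100, "+")), flank=50)
        pd.testing.assert_frame_equal(p1.table, p2.table)


class TestPeriodicity:
    @staticmethod
    def cosine_profile(period, flank=1000):
        offs = np.arange(-flank, flank + 1)
        table = pd.DataFrame(
            {
                "offset": offs,
                "mean_level": 0.5 + 0.3 * np.cos(2 * np.pi * offs / period),
                "n_sites": 10,
            }
        )
        return mm.AggregationProfile(flank=flank, table=table)

    def test_pure_cosine_recovered_exactly(self):
        res = mm.estimate_periodicity(self.cosine_profile(165), 120, 220)
        assert res.period == 165 and res.confident

    def test_white_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(60)
        flank = 1000
        offs = np.arange(-flank, flank + 1)
        prof = mm.AggregationProfile(
            flank=flank,
            table=pd.DataFrame(
                {"offset": offs, "mean_level": rng.random(len(offs)), "n_sites": 5}
            ),
        )
        res = mm.estimate_periodicity(prof, 120, 220)
        assert not res.confident

    def test_range_wider_than_profile_errors(self):
        with pytest.raises(MethMotifError):
            mm.estimate_periodicity(self.cosine_profile(165, flank=100), 120, 220)


class TestAccessibleRegions:
    @staticmethod
    def track_of(levels, bin_size=10, depth=20):
        return pd.DataFrame(
            {
                "contig": "c",
                "start": np.arange(len(levels)) * bin_size,
                "end": np.arange(1, len(levels) + 1) * bin_size,
                "level": levels,
                "depth": depth,
            }
        )

    def test_all_below_threshold_empty(self):
        track = self.track_of([0.1] * 50)
        assert len(mm.call_accessible_regions(track, 0.5, 100)) == 0

    def test_single_run(self):
        track = self.track_of([0.05] * 10 + [0.9] * 20 + [0.05] * 10)
        regions = mm.call_accessible_regions(track, 0.5, 100)
        assert len(regions) == 1
        row = regions.iloc[0]
        assert (row["start"], row["end"]) == (100, 300)
        assert row["mean_level"] == pytest.approx(0.9)

    def test_merge_across_small_gap(self):
        levels = [0.9] * 10 + [0.1] + [0.9] * 10
        regions = mm.call_accessible_regions(self.track_of(levels), 0.5, 100, merge_gap=10)
        assert len(regions) == 1 and regions.iloc[0]["end"] - regions.iloc[0]["start"] == 210

    def test_planted_ndr_recovery(self):
        """>=45 of 50 planted NDRs recovered, <=2 false regions."""
        genome = mm.simulate_genome(mm.GenomeSpec(length=320_000, seed=42))
        anchors = mm.meth_io.anchors_from_tuples(
            [("contig1", 5_000 + 6_000 * k, "+" if k % 2 == 0 else "-") for k in range(50)]
        )
        chrom = mm.ChromatinSpec(anchors=anchors, protection=0.95)
        records, _, _ = mm.simulate_nome(
            genome,
            mm.MTaseSpec("CC", efficiency=0.9),
            chrom,
            coverage=mm.CoverageSpec(mean_depth=20, seed=7),
        )
        split = mm.split_channels(records, genome, mm.ChannelSpec("CCMT"))
        track = mm.bin_levels(split.induced, bin_size=25)
        regions = mm.call_accessible_regions(track, 0.4, min_len=100, merge_gap=50)
        ndrs = [
            (a.pos - 250, a.pos - 100) if a.strand == "+" else (a.pos + 100, a.pos + 250)
            for a in anchors.itertuples(index=False)
        ]
        hit = sum(
            any(r.start < hi and r.end > lo for r in regions.itertuples(index=False))
            for lo, hi in ndrs
        )
        false = sum(
            not any(r.start < hi + 60 and r.end > lo - 60 for lo, hi in ndrs)
            for r in regions.itertuples(index=False)
        )
        assert hit >= 45
        assert false <= 2


class TestCompareTracks:
    def test_track_vs_itself(self):
        track = TestAccessibleRegions.track_of(np.linspace(0.1, 0.9, 30))
        _, summary = mm.compare_tracks(track, track)
        assert summary.pearson == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(70)
        n = 2_000
        a = TestAccessibleRegions.track_of(rng.random(n))
        b = TestAccessibleRegions.track_of(rng.random(n))
        _, summary = mm.compare_tracks(a, b)
        assert abs(summary.pearson) < 3 / np.sqrt(n)

    def test_no_shared_bins_errors(self):
        a = TestAccessibleRegions.track_of([0.5] * 5)
        b = TestAccessibleRegions.track_of([0.5] * 5)
        b["contig"] = "other"
        with pytest.raises(EmptyInputError):
            mm.compare_tracks(a, b)

    def test_two_channels_share_accessibility_landscape(self):
        """GC- and CC-probe tracks driven by one chromatin correlate strongly."""
        genome = mm.simulate_genome(mm.GenomeSpec(length=200_000, seed=80))
        anchors = mm.meth_io.anchors_from_tuples(
            [("contig1", 2_000 + 4_000 * k, "+") for k in range(49)]
        )
        # block-scale landscape: alternating 2-kb open/closed domains, so
        # bins are homogeneous and the two probes sample the same signal
        chrom = mm.ChromatinSpec(
            anchors=anchors, ndr=(-1000, 1000), extent=1000, protection=0.95
        )
        tracks = []
        for motif, seed in (("CC", 81), ("GC", 82)):
            records, _, _ = mm.simulate_nome(
                genome,
                mm.MTaseSpec(motif, efficiency=0.9),
                chrom,
                coverage=mm.CoverageSpec(mean_depth=30, seed=seed),
            )
            mode = "CCMT" if motif == "CC" else "GCMT"
            split = mm.split_channels(records, genome, mm.ChannelSpec(mode))
            tracks.append(mm.bin_levels(split.induced, bin_size=100))
        _, summary = mm.compare_tracks(tracks[0], tracks[1])
        assert summary.pearson >= 0.8
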