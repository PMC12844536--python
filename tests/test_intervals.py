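"""Interval model: overlap/nearest queries against brute-force oracles,
activity classification, random-region sampling, coordinate lifting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from strainatac import (
    OffsetMap,
    classify_activity,
    lift_coordinates,
    nearest_tss,
    overlap_query,
    sample_random_regions,
)
from strainatac.intervals import GenomicInterval, ValidationError

from conftest import random_intervals


class TestOverlapQuery:
    def test_single_bp_overlap_reported(self):
        q = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200], "id": ["q"]})
        s = pd.DataFrame({"chrom": ["chr1"], "start": [199], "end": [300], "id": ["s"]})
        out = overlap_query(q, s)
        assert list(out.itertuples(index=False)) == [("q", "s")]

    def test_adjacency_excluded_half_open(self):
        q = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200], "id": ["q"]})
        s = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [300], "id": ["s"]})
        assert len(overlap_query(q, s)) == 0

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(42)
        q = random_intervals(rng, 500)
        s = random_intervals(rng, 500)
        got = set(map(tuple, overlap_query(q, s).to_numpy()))
        expected = set()
        for qi in q.itertuples():
            for si in s.itertuples():
                if qi.chrom == si.chrom and max(qi.start, si.start) < min(qi.end, si.end):
                    expected.add((qi.id, si.id))
        assert got == expected

    def test_malformed_interval_rejected(self):
        q = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [100], "id": ["q"]})
        s = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "id": ["s"]})
        with pytest.raises(ValidationError):
            overlap_query(q, s)


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("", 0, 10)
        iv = GenomicInterval("chr1", 10, 20)
        assert iv.width == 10 and iv.center == 15


class TestClassifyActivity:
    def test_within_and_beyond_flank(self):
        peak = pd.DataFrame(
            {"chrom": ["chr1"], "start": [1000], "end": [1300], "id": ["p"]}
        )
        near = pd.DataFrame({"chrom": ["chr1"], "start": [1500], "end": [1900]})
        far = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [5400]})
        assert classify_activity(peak, near, 1000).iloc[0] == "Active"
        assert classify_activity(peak, far, 1000).iloc[0] == "NonActive"

    def test_monotone_in_flank(self):
        rng = np.random.default_rng(0)
        peaks = random_intervals(rng, 100)
        marks = random_intervals(rng, 30)
        act_small = classify_activity(peaks, marks, 200) == "Active"
        act_big = classify_activity(peaks, marks, 2000) == "Active"
        assert (act_big | ~act_small).all()  # small-flank Active subset of big

    def test_generator_flanked_peaks_exactly_recovered(self, sim):
        peaks = sim.peaks.copy()
        peaks["id"] = peaks["feature_id"]
        act = classify_activity(peaks, sim.h3k27ac, 1000)
        truth = [sim.truth["peaks"][f]["activity"] for f in peaks["feature_id"]]
        assert list(act) == truth

    def test_negative_flank_rejected(self):
        peak = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10], "id": ["p"]}
        )
        with pytest.raises(ValidationError):
            classify_activity(peak, peak, -1)


class TestNearestTSS:
    def make_tss(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "tss_pos", "strand", "expressed"]
        )

    def test_strand_aware_sign(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [4900, 4900], "end": [5100, 5100]}
        )
        tss = self.make_tss(
            [("gA", "chr1", 5500, "+", True), ("gB", "chr2", 0, "+", True)]
        )
        out = nearest_tss(peaks.iloc[[0]], tss)
        assert out["distance"].iloc[0] == -500
        assert out["feature"].iloc[0] == "promoter"
        tss_minus = self.make_tss([("gA", "chr1", 4000, "-", True)])
        out = nearest_tss(peaks.iloc[[0]], tss_minus)
        assert out["distance"].iloc[0] == -1000  # center 5000, minus strand

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(7)
        peaks = random_intervals(rng, 300)
        tss = pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in range(120)],
                "chrom": rng.choice(["chr1", "chr2", "chr3"], size=120),
                "tss_pos": rng.integers(0, 10_000, size=120),
                "strand": rng.choice(["+", "-"], size=120),
                "expressed": True,
            }
        )
        got = nearest_tss(peaks, tss)
        for i, p in enumerate(peaks.itertuples()):
            center = (p.start + p.end) // 2
            cand = tss[tss["chrom"] == p.chrom]
            if len(cand) == 0:
                assert got["gene_id"].iloc[i] is None
                continue
            best = min(
                cand.itertuples(),
                key=lambda t: (abs(center - t.tss_pos), t.gene_id),
            )
            assert got["gene_id"].iloc[i] == best.gene_id

    def test_absent_chrom_gives_none(self):
        peaks = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [10]})
        tss = self.make_tss([("gA", "chr1", 100, "+", True)])
        out = nearest_tss(peaks, tss)
        assert out["gene_id"].iloc[0] is None and np.isnan(out["distance"].iloc[0])


class TestRandomRegions:
    sizes = {"chr1": 100_000, "chr2": 50_000}

    def test_seed_determinism(self):
        t = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
        a = sample_random_regions(t, 3, self.sizes, rng_seed=5)
        b = sample_random_regions(t, 3, self.sizes, rng_seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_width_multiset_conserved(self):
        rng = np.random.default_rng(3)
        t = random_intervals(rng, 100, chroms=("chr1", "chr2"), max_pos=40_000)
        out = sample_random_regions(t, 10, self.sizes, rng_seed=1)
        got = sorted((out["end"] - out["start"]).tolist())
        expected = sorted((t["end"] - t["start"]).tolist() * 10)
        assert got == expected

    def test_start_distribution_uniform(self):
        t = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        out = sample_random_regions(t, 10_000, self.sizes, rng_seed=11)
        for chrom, grp in out.groupby("chrom"):
            span = self.sizes[chrom] - 100 + 1
            bins = np.histogram(grp["start"], bins=10, range=(0, span))[0]
            assert chisquare(bins).pvalue > 0.01

    def test_oversized_template_rejected(self):
        t = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200_000]})
        with pytest.raises(ValidationError):
            sample_random_regions(t, 1, self.sizes, rng_seed=0)


class TestLiftCoordinates:
    def test_identity_map(self):
        omap = OffsetMap.identity({"chr1": 1000})
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        out = lift_coordinates(iv, omap)
        assert out["start"].iloc[0] == 100 and out["end"].iloc[0] == 200
        assert out["mappable"].iloc[0]

    def test_constant_delta(self):
        omap = OffsetMap(pd.DataFrame(
            [{"chrom": "chr1", "src_start": 0, "src_end": 1000, "delta": 7}]
        ))
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        out = lift_coordinates(iv, omap)
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (107, 207)

    def test_boundary_spanning_flagged_unmappable(self):
        omap = OffsetMap(pd.DataFrame(
            [
                {"chrom": "chr1", "src_start": 0, "src_end": 500, "delta": 0},
                {"chrom": "chr1", "src_start": 500, "src_end": 1000, "delta": 10},
            ]
        ))
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [450], "end": [550]})
        out = lift_coordinates(iv, omap)
        assert not out["mappable"].iloc[0]
        assert out["start"].iloc[0] == 450  # untouched

    def test_round_trip_through_inverse(self):
        rng = np.random.default_rng(9)
        # random monotone block map on one chromosome
        edges = np.sort(rng.choice(np.arange(100, 9_900), 9, replace=False))
        blocks = []
        delta = 0
        prev = 0
        for e in list(edges) + [10_000]:
            delta += int(rng.integers(0, 50))  # nondecreasing keeps monotone
            blocks.append(
                {"chrom": "chr1", "src_start": prev, "src_end": e, "delta": delta}
            )
            prev = e
        omap = OffsetMap(pd.DataFrame(blocks))
        iv = random_intervals(rng, 200, chroms=("chr1",), max_pos=9_500)
        fwd = lift_coordinates(iv, omap)
        back = lift_coordinates(fwd[fwd["mappable"]], omap.inverse())
        orig = iv.loc[back.index]
        assert (back["start"].to_numpy() == orig["start"].to_numpy()).all()
        assert (back["end"].to_numpy() == orig["end"].to_numpy()).all()

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValidationError):
            OffsetMap(pd.DataFrame(
                [
                    {"chrom": "chr1", "src_start": 0, "src_end": 600, "delta": 0},
                    {"chrom": "chr1", "src_start": 500, "src_end": 900, "delta": 5},
                ]
            ))
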