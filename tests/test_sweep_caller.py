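"""Outlier selection, interval algebra, gene annotation and the end-to-end scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import (
    FilterConfig,
    GeneModel,
    OutlierSet,
    ScanConfig,
    SimConfig,
    WindowStats,
    annotate_genes,
    emit_dataset,
    intersect_window_sets,
    merge_regions,
    run_scan,
    select_outlier_windows,
    union_intervals,
)

from conftest import brute_force_regions, covered_bp, reciprocal_overlap


def window(chrom="1", start=1, end=100_000, zfst=math.nan, zhp=math.nan):
    return WindowStats(chrom=chrom, start=start, end=end, n_snps=30,
                       sum_nmaj=400, sum_nmin=40, hp=0.1, fst=0.2,
                       zhp=zhp, zfst=zfst, qualifies=True)


class TestSelectOutlierWindows:
    def test_threshold_boundary_is_excluded(self):
        windows = [window(zfst=4.5, zhp=-5.0)]
        fst_set, hp_set = select_outlier_windows(windows, ScanConfig())
        assert fst_set.windows == [] and hp_set.windows == []

    def test_window_extreme_in_both_statistics_selected_twice(self):
        w = window(zfst=8.4551, zhp=-5.1642)
        fst_set, hp_set = select_outlier_windows([w], ScanConfig())
        assert fst_set.windows == [w] and hp_set.windows == [w]
        assert fst_set.direction == "upper" and hp_set.direction == "lower"

    def test_empty_input_gives_empty_sets(self):
        fst_set, hp_set = select_outlier_windows([], ScanConfig())
        assert fst_set.windows == [] and hp_set.windows == []

    def test_windows_without_z_never_qualify(self):
        windows = [window()]  # NaN Z-scores
        fst_set, hp_set = select_outlier_windows(windows, ScanConfig())
        assert fst_set.windows == [] and hp_set.windows == []


def oset(intervals, statistic="zfst"):
    direction = "upper" if statistic == "zfst" else "lower"
    thr = 4.5 if statistic == "zfst" else -5.0
    windows = [window(chrom=c, start=s, end=e,
                      **({"zfst": 9.0} if statistic == "zfst" else {"zhp": -9.0}))
               for c, s, e in intervals]
    return OutlierSet(statistic, direction, thr, windows)


class TestIntersectWindowSets:
    def test_half_overlap(self):
        got = intersect_window_sets(oset([("1", 1, 100_000)]),
                                    oset([("1", 50_001, 150_000)], "zhp"))
        assert got == [("1", 50_001, 100_000)]

    def test_disjoint_sets_are_empty(self):
        got = intersect_window_sets(oset([("1", 1, 100)]),
                                    oset([("1", 500, 600)], "zhp"))
        assert got == []

    def test_union_before_intersection(self):
        a = oset([("1", 1, 100_000), ("1", 10_001, 110_000)])
        b = oset([("1", 90_001, 190_000)], "zhp")
        got = intersect_window_sets(a, b)
        assert got == [("1", 90_001, 110_000)]
        # brute-force per-bp membership oracle at a reduced scale
        scale = 1000
        a_bp = {p for _, s, e in a.intervals() for p in range(s // scale, e // scale + 1)}
        b_bp = {p for _, s, e in b.intervals() for p in range(s // scale, e // scale + 1)}
        got_bp = {p for _, s, e in got for p in range(s // scale, e // scale + 1)}
        assert got_bp == (a_bp & b_bp)

    def test_intersection_is_subset_of_each_union(self):
        a = oset([("1", 1, 50), ("1", 40, 80), ("2", 10, 30)])
        b = oset([("1", 20, 60), ("2", 25, 45)], "zhp")
        got = intersect_window_sets(a, b)
        ua, ub = union_intervals(a.intervals()), union_intervals(b.intervals())

        def contained(iv, cover):
            return any(c == iv[0] and s <= iv[1] and iv[2] <= e for c, s, e in cover)

        assert all(contained(iv, ua) and contained(iv, ub) for iv in got)


class TestMergeRegions:
    @pytest.mark.parametrize("intervals,expected", [
        ([("1", 100, 200), ("1", 150, 300)], [("1", 100, 300)]),   # overlap
        ([("1", 100, 200), ("1", 201, 300)], [("1", 100, 300)]),   # book-end
        ([("1", 100, 200), ("1", 250, 300), ("1", 290, 400)],
         [("1", 100, 200), ("1", 250, 400)]),
    ])
    def test_merge_examples(self, intervals, expected):
        regions = merge_regions(intervals)
        assert [(r.chrom, r.start, r.end) for r in regions] == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from(["1", "2"]), st.integers(1, 150), st.integers(0, 40)),
        min_size=0, max_size=15))
    def test_merge_preserves_covered_bp_and_is_disjoint(self, raw):
        intervals = [(c, s, s + w) for c, s, w in raw]
        regions = merge_regions(intervals)
        merged = [(r.chrom, r.start, r.end) for r in regions]
        assert covered_bp(merged) == covered_bp(intervals)
        for a, b in zip(merged, merged[1:]):
            if a[0] == b[0]:
                assert a[2] + 1 < b[1]  # disjoint and not book-ended


class TestAnnotateGenes:
    GENES = [
        GeneModel("T", "8", 87_796_143, 87_805_552),
        GeneModel("LCORL", "6", 37_365_236, 37_452_332),
        GeneModel("ELSEWHERE", "9", 1_000, 2_000),
    ]

    def test_contained_gene_assigned(self):
        regions = merge_regions([("8", 87_770_001, 87_890_000)])
        annotate_genes(regions, self.GENES)
        assert regions[0].genes == ["T"]

    def test_partial_overlap_counts(self):
        regions = merge_regions([("6", 37_440_001, 37_580_000)])
        annotate_genes(regions, self.GENES)
        assert regions[0].genes == ["LCORL"]

    def test_gene_outside_all_regions_assigned_nowhere(self):
        regions = merge_regions([("8", 87_770_001, 87_890_000),
                                 ("6", 37_440_001, 37_580_000)])
        annotate_genes(regions, self.GENES)
        assert all("ELSEWHERE" not in r.genes for r in regions)

    def test_every_reported_gene_overlaps_its_region(self):
        regions = merge_regions([("8", 87_770_001, 87_890_000)])
        annotate_genes(regions, self.GENES)
        by_name = {g.name: g for g in self.GENES}
        for r in regions:
            for name in r.genes:
                g = by_name[name]
                assert g.chrom == r.chrom and g.start <= r.end and g.end >= r.start


class TestRegionCallingOracle:
    def scored_windows(self, seed=0):
        """Windows on a 1-Mb toy grid with synthetic Z-scores."""
        rng = np.random.default_rng(seed)
        cfg = ScanConfig(window_size=50_000, step=10_000,
                         zfst_threshold=1.0, zhp_threshold=-1.0)
        windows = []
        for chrom, length in (("1", 1_000_000), ("2", 600_000)):
            start = 1
            while start + cfg.window_size - 1 <= length:
                windows.append(window(chrom=chrom, start=start,
                                      end=start + cfg.window_size - 1,
                                      zfst=rng.normal(), zhp=rng.normal()))
                start += cfg.step
        return windows, cfg

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_region_calls_equal_per_basepair_oracle(self, seed):
        windows, cfg = self.scored_windows(seed)
        fst_set, hp_set = select_outlier_windows(windows, cfg)
        regions = merge_regions(intersect_window_sets(fst_set, hp_set))
        expected = brute_force_regions(windows, cfg.zfst_threshold,
                                       cfg.zhp_threshold,
                                       {"1": 1_000_000, "2": 600_000})
        assert [(r.chrom, r.start, r.end) for r in regions] == expected

    def test_threshold_monotonicity(self):
        windows, cfg = self.scored_windows(3)

        def total_bp(zfst_thr, zhp_thr):
            c = ScanConfig(window_size=cfg.window_size, step=cfg.step,
                           zfst_threshold=zfst_thr, zhp_threshold=zhp_thr)
            fst_set, hp_set = select_outlier_windows(windows, c)
            regions = merge_regions(intersect_window_sets(fst_set, hp_set))
            return sum(r.end - r.start + 1 for r in regions)

        for zf, zh in [(0.5, -0.5), (1.0, -1.0), (1.5, -1.5), (2.5, -2.5)]:
            assert total_bp(zf, zh) >= total_bp(zf + 0.5, zh)
            assert total_bp(zf, zh) >= total_bp(zf, zh - 0.5)


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(seed=11)
    paths, truths = emit_dataset(cfg, outdir)
    return paths, truths


class TestRunScan:

    def test_planted_sweep_recovered_with_relaxed_thresholds(self, dataset, tmp_path):
        paths, truths = dataset
        result = run_scan(paths.vcf, paths.popmap, paths.genes_bed,
                          cfg=ScanConfig(zfst_threshold=3.0, zhp_threshold=-3.0),
                          outdir=tmp_path)
        t = truths[0]
        overlaps = [
            reciprocal_overlap((r.chrom, r.start, r.end), (t.chrom, t.start, t.end))
            for r in result.regions
        ]
        assert any(o > 0 for o in overlaps)
        # the simulator plants a gene inside each sweep; it must be annotated
        swept = [g for r in result.regions for g in r.genes if g.startswith("SWEPT")]
        assert swept == ["SWEPT1"]

    def test_same_inputs_give_byte_identical_window_tables(self, dataset, tmp_path):
        paths, _ = dataset
        cfg = ScanConfig(zfst_threshold=3.0, zhp_threshold=-3.0)
        run_scan(paths.vcf, paths.popmap, None, cfg=cfg, outdir=tmp_path / "r1")
        run_scan(paths.vcf, paths.popmap, None, cfg=cfg, outdir=tmp_path / "r2")
        t1 = (tmp_path / "r1" / "windows.tsv").read_bytes()
        t2 = (tmp_path / "r2" / "windows.tsv").read_bytes()
        assert t1 == t2

    def test_infinite_thresholds_call_no_regions(self, dataset):
        paths, _ = dataset
        result = run_scan(paths.vcf, paths.popmap, None,
                          cfg=ScanConfig(zfst_threshold=math.inf,
                                         zhp_threshold=-math.inf))
        assert result.regions == []

    def test_summary_counter_chain_is_monotone(self, dataset):
        paths, _ = dataset
        result = run_scan(paths.vcf, paths.popmap, None,
                          cfg=ScanConfig(zfst_threshold=3.0, zhp_threshold=-3.0))
        s = result.summary
        assert (s["sites_parsed"] >= s["sites_after_gq_filter"]
                >= s["sites_after_proximity_filter"])
        assert s["windows_total"] >= s["windows_qualifying"]

    def test_same_window_rule_is_no_looser_than_genomic_rule(self, dataset):
        paths, _ = dataset
        genomic = run_scan(paths.vcf, paths.popmap, None,
                           cfg=ScanConfig(zfst_threshold=3.0, zhp_threshold=-3.0))
        same = run_scan(paths.vcf, paths.popmap, None,
                        cfg=ScanConfig(zfst_threshold=3.0, zhp_threshold=-3.0,
                                       overlap_rule="same_window"))
        bp = lambda res: sum(r.end - r.start + 1 for r in res.regions)
        assert bp(same) >= 0 and bp(genomic) >= 0
        # a same-window outlier footprint is covered by the genomic intersection
        for r in same.regions:
            assert any(g.chrom == r.chrom and g.start <= r.end and g.end >= r.start
                       for g in genomic.regions)
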