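"""Weir-Cockerham theta, densities, region means, ANOVA/Tukey contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from svdiverge.io_formats import GenomeRegion, RegionType, Window, WindowTrack
from svdiverge.popgen_stats import (
    SnpCounts,
    anova_tukey,
    mean_fst,
    region_mean_snp,
    region_mean_track,
    select_regions,
    snp_density,
    wc_fst,
)
from svdiverge.sv_classify import Category, SVClassification


def _snp(n1, n2, p1, p2, h1=0.0, h2=0.0):
    return SnpCounts("chr1", 1, n1, n2, p1, p2, h1, h2)


class TestWcFst:
    def test_fixed_difference_theta_is_one(self):
        assert wc_fst(_snp(50, 50, 0.0, 1.0)).theta == 1.0

    def test_monomorphic_theta_undefined(self):
        comp = wc_fst(_snp(50, 50, 0.0, 0.0))
        assert comp.a == comp.b == comp.c == 0.0
        assert math.isnan(comp.theta)

    def test_hand_evaluated_example(self):
        # n1=n2=10, p1=0.2, p2=0.8, h1=h2=0.3:
        # n_bar=10, n_c=10, p_bar=0.5, s2=0.18, h_bar=0.3
        # a = 0.18 - (0.25-0.09-0.075)/9 = 1.535/9
        # b = (10/9)(0.25-0.09-0.1425)   = 0.175/9
        # c = 0.15                        = 1.35/9
        comp = wc_fst(_snp(10, 10, 0.2, 0.8, 0.3, 0.3))
        assert comp.a == pytest.approx(1.535 / 9, abs=1e-12)
        assert comp.b == pytest.approx(0.175 / 9, abs=1e-12)
        assert comp.c == pytest.approx(0.15, abs=1e-12)
        assert comp.theta == pytest.approx(1.535 / 3.06, abs=1e-12)

    def test_population_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 100)), int(rng.integers(2, 100))
            p1, p2 = rng.uniform(0, 1, 2)
            h1, h2 = rng.uniform(0, 0.5, 2)
            t1 = wc_fst(_snp(n1, n2, p1, p2, h1, h2)).theta
            t2 = wc_fst(_snp(n2, n1, p2, p1, h2, h1)).theta
            if math.isnan(t1):
                assert math.isnan(t2)
            else:
                assert t1 == pytest.approx(t2, abs=1e-12)

    def test_theta_monotone_in_frequency_difference(self):
        thetas = [
            wc_fst(_snp(50, 50, 0.5 - d, 0.5 + d)).theta
            for d in np.linspace(0.05, 0.5, 10)
        ]
        assert all(b > a for a, b in zip(thetas, thetas[1:]))

    def test_zero_sample_population_rejected(self):
        with pytest.raises(ValueError):
            SnpCounts("chr1", 1, 0, 10, 0.0, 0.5, 0.0, 0.0)


class TestSnpDensity:
    def _region(self, start, end, rid="r1", rtype=RegionType.SYNTENIC):
        return GenomeRegion(rid, "A", "chr1", start, end, rtype)

    def test_two_snps_in_two_kb(self):
        frame = snp_density([self._region(0, 2000)], {"chr1": np.array([10, 1999])})
        assert frame.iloc[0]["n_snps"] == 2
        assert frame.iloc[0]["snps_per_kb"] == pytest.approx(1.0)

    def test_half_open_boundary_excludes_end(self):
        frame = snp_density([self._region(0, 2000)], {"chr1": np.array([2000])})
        assert frame.iloc[0]["n_snps"] == 0

    def test_counts_match_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.integers(0, 100_000, size=1000))
        regions = []
        for i in range(20):
            start = int(rng.integers(0, 95_000))
            regions.append(self._region(start, start + int(rng.integers(100, 5000)), f"r{i}"))
        frame = snp_density(regions, {"chr1": pos})
        for reg, (_, row) in zip(regions, frame.iterrows()):
            expected = sum(1 for p in pos if reg.start <= p < reg.end)
            assert row["n_snps"] == expected


class TestRegionMeans:
    def test_region_exactly_one_window(self):
        track = WindowTrack([Window("chr1", 0, 1000, 0.05)])
        reg = GenomeRegion("r1", "A", "chr1", 0, 1000, RegionType.SYNTENIC)
        frame = region_mean_track(track, [reg])
        assert frame.iloc[0]["mean_value"] == pytest.approx(0.05)

    def test_overlap_weighted_mean(self):
        track = WindowTrack(
            [Window("chr1", 0, 1000, 0.1), Window("chr1", 1000, 2000, 0.4)]
        )
        reg = GenomeRegion("r1", "A", "chr1", 500, 2000, RegionType.SYNTENIC)
        frame = region_mean_track(track, [reg])
        assert frame.iloc[0]["mean_value"] == pytest.approx((500 * 0.1 + 1000 * 0.4) / 1500)

    def test_whole_window_mode(self):
        track = WindowTrack(
            [Window("chr1", 0, 1000, 0.1), Window("chr1", 1000, 2000, 0.4)]
        )
        reg = GenomeRegion("r1", "A", "chr1", 500, 2000, RegionType.SYNTENIC)
        frame = region_mean_track(track, [reg], overlap_weighted=False)
        assert frame.iloc[0]["mean_value"] == pytest.approx(0.25)

    def test_window_split_invariance(self):
        whole = WindowTrack([Window("chr1", 0, 2000, 0.3)])
        split = WindowTrack([Window("chr1", 0, 700, 0.3), Window("chr1", 700, 2000, 0.3)])
        reg = GenomeRegion("r1", "A", "chr1", 100, 1900, RegionType.GENE)
        m1 = region_mean_track(whole, [reg]).iloc[0]["mean_value"]
        m2 = region_mean_track(split, [reg]).iloc[0]["mean_value"]
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_no_overlap_gives_nan(self):
        track = WindowTrack([Window("chr1", 0, 1000, 0.05)])
        reg = GenomeRegion("r1", "A", "chr2", 0, 1000, RegionType.SYNTENIC)
        assert math.isnan(region_mean_track(track, [reg]).iloc[0]["mean_value"])

    def test_snp_mean_excludes_undefined(self):
        snp_frame = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "pos": [10, 20, 30, 5000],
                "theta": [0.1, math.nan, 0.3, 0.9],
            }
        )
        reg = GenomeRegion("r1", "A", "chr1", 0, 100, RegionType.SYNTENIC)
        frame = region_mean_snp([reg], snp_frame)
        assert frame.iloc[0]["n_snps"] == 2
        assert frame.iloc[0]["mean_value"] == pytest.approx(0.2)

    def test_all_undefined_gives_nan(self):
        snp_frame = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [10], "theta": [math.nan]}
        )
        reg = GenomeRegion("r1", "A", "chr1", 0, 100, RegionType.SYNTENIC)
        assert math.isnan(region_mean_snp([reg], snp_frame).iloc[0]["mean_value"])


class TestSelectRegions:
    def _sv_region(self, rid, length, rtype=RegionType.INVERSION):
        return GenomeRegion(rid, "A", "chr1", 0, length, rtype)

    def _classified(self, rid, cat, sub=""):
        return SVClassification(rid, 0.0, 1.0, cat, sub_label=sub)

    def test_length_boundary(self):
        regs = [self._sv_region("a", 1999), self._sv_region("b", 2000)]
        cls = [self._classified(r.region_id, Category.SD) for r in regs]
        kept = select_regions(regs, cls)
        assert [r.region_id for r in kept] == ["b"]

    def test_polymorphic_sv_dropped_when_fixed_required(self):
        regs = [self._sv_region("a", 5000)]
        cls = [self._classified("a", Category.SSP)]
        assert select_regions(regs, cls) == []
        assert select_regions(regs, cls, require_fixed=False) == regs

    def test_genes_filtered_by_length_only(self):
        regs = [
            GenomeRegion("g1", "A", "chr1", 0, 1500, RegionType.GENE),
            GenomeRegion("g2", "A", "chr1", 0, 2500, RegionType.GENE),
        ]
        assert [r.region_id for r in select_regions(regs, [])] == ["g2"]

    def test_mixed_set_matches_brute_force(self):
        rng = np.random.default_rng(12)
        regs, cls = [], []
        cats = list(Category)
        for i in range(100):
            length = int(rng.integers(500, 6000))
            rtype = (
                RegionType.INVERSION if rng.random() < 0.5 else RegionType.GENE
            )
            rid = f"r{i}"
            regs.append(GenomeRegion(rid, "A", "chr1", 0, length, rtype))
            if rtype is RegionType.INVERSION:
                cls.append(self._classified(rid, cats[rng.integers(0, len(cats))]))
        kept = {r.region_id for r in select_regions(regs, cls)}
        sd_ids = {c.sv_id for c in cls if c.category is Category.SD}
        expected = set()
        for r in regs:
            if r.length < 2000:
                continue
            if r.region_type is RegionType.INVERSION and r.region_id not in sd_ids:
                continue
            expected.add(r.region_id)
        assert kept == expected


# Worked example: plasma etch-rate data, four RF power levels, five wafers
# each (Montgomery, Design and Analysis of Experiments; see docs/methods.md).
ETCH_RATE = {
    "160": [575, 542, 530, 539, 570],
    "180": [565, 593, 590, 579, 610],
    "200": [600, 651, 610, 637, 629],
    "220": [725, 700, 715, 685, 710],
}


class TestAnovaTukey:
    def test_identical_constant_groups_flagged_degenerate(self):
        result = anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        assert result.degenerate
        assert (result.pairwise["diff"] == 0).all()

    def test_etch_rate_worked_example(self):
        result = anova_tukey(ETCH_RATE)
        assert result.f_statistic == pytest.approx(66.797, abs=2e-3)
        # all six pairwise power-level differences are significant at 0.05
        assert (result.pairwise["p_adj"] <= 0.05).all()
        row = result.pairwise.set_index(["group_1", "group_2"]).loc[("160", "180")]
        assert abs(row["diff"]) == pytest.approx(36.2, abs=1e-9)
        assert row["p_adj"] == pytest.approx(0.0294, abs=2e-4)
        # simultaneous CI half-width = q_crit(4, 16) * sqrt(MSE/5)
        assert row["ci_high"] - row["diff"] == pytest.approx(33.0544, abs=2e-3)

    def test_matches_statsmodels_on_unbalanced_data(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(6)
        groups = {
            "g1": rng.normal(0.0, 1.0, 12),
            "g2": rng.normal(0.5, 1.0, 20),
            "g3": rng.normal(0.2, 1.0, 7),
        }
        result = anova_tukey(groups)
        vals = np.concatenate(list(groups.values()))
        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        ref = statsmodels.pairwise_tukeyhsd(vals, labels, alpha=0.05)
        for i, (_, mine) in enumerate(result.pairwise.iterrows()):
            # statsmodels reports group2 - group1
            assert -mine["diff"] == pytest.approx(ref.meandiffs[i], abs=1e-9)
            assert mine["p_adj"] == pytest.approx(ref.pvalues[i], abs=1e-6)
            assert -mine["ci_high"] == pytest.approx(ref.confint[i][0], abs=1e-6)

    def test_small_group_excluded_with_notice(self):
        result = anova_tukey({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "tiny": [5.0]})
        assert result.excluded_groups == ["tiny"]
        assert set(result.group_stats["group"]) == {"a", "b"}

    def test_reference_contrast_lookup(self):
        rng = np.random.default_rng(10)
        groups = {
            "SYNTENIC": rng.normal(0, 1, 50),
            "GENE": rng.normal(3, 1, 50),
            "TRANSLOCATION": rng.normal(0, 1, 50),
        }
        result = anova_tukey(groups)
        flags = result.significant_vs_reference("SYNTENIC")
        assert flags["GENE"] is True
        assert flags["TRANSLOCATION"] is False


class TestMeanFst:
    def test_weighted_form_is_ratio_of_sums(self):
        frame = pd.DataFrame(
            {"a": [0.1, 0.2], "b": [0.05, 0.0], "c": [0.05, 0.0],
             "theta": [0.5, 1.0]}
        )
        assert mean_fst(frame) == pytest.approx(0.3 / 0.4)
        assert mean_fst(frame, weighted=False) == pytest.approx(0.75)
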