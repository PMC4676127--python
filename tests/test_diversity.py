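"""Diversity battery: filters, rates, windows, ROH and repeat classes."""

import numpy as np
import pandas as pd
import pytest

from bkit.diversity import (
    MaskSet,
    classify_het_hom,
    classify_tandem_repeats,
    detect_roh,
    filter_by_depth,
    filter_by_mask,
    heterozygosity_rate,
    heterozygosity_rates,
    retention_percent,
    snv_rate,
    window_density,
)
from bkit.io import VariantTable


def make_table(positions, scaffolds=None, gt=None, depth=None, n_samples=3):
    n = len(positions)
    scaffolds = scaffolds if scaffolds is not None else ["s1"] * n
    gt = gt if gt is not None else np.zeros((n, n_samples, 2), dtype=np.int8)
    depth = depth if depth is not None else np.full((n, n_samples), 10)
    return VariantTable(
        samples=[f"i{k}" for k in range(n_samples)],
        scaffold=np.array(scaffolds, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["C"] * n, dtype=object),
        gt=gt, depth=depth)


class TestDepthFilter:
    def test_boundaries_inclusive(self):
        t = make_table([10], depth=np.array([[5, 30, 12]]))
        kept, _ = filter_by_depth(t)
        assert kept.n_sites == 1

    def test_below_minimum_removed(self):
        t = make_table([10], depth=np.array([[4, 20, 20]]))
        kept, log = filter_by_depth(t)
        assert kept.n_sites == 0 and log["kept_sites"] == 0

    def test_random_sites_match_per_site_check(self, rng):
        depth = rng.integers(1, 41, size=(100, 3))
        t = make_table(list(range(1, 101)), depth=depth)
        kept, _ = filter_by_depth(t, 5, 30)
        expected = [i + 1 for i in range(100)
                    if all(5 <= d <= 30 for d in depth[i])]
        assert list(kept.pos) == expected

    def test_widening_bounds_is_monotone(self, rng):
        depth = rng.integers(1, 41, size=(60, 3))
        t = make_table(list(range(1, 61)), depth=depth)
        n_narrow = filter_by_depth(t, 10, 20)[0].n_sites
        n_wide = filter_by_depth(t, 5, 30)[0].n_sites
        assert n_wide >= n_narrow


class TestMaskFilter:
    def test_printed_counts_give_53_percent(self):
        """The repeat filter's published retention: post/pre-filter counts."""
        assert retention_percent(3_438_824, 1_820_419) == 53.0

    def test_empty_mask_keeps_everything(self):
        t = make_table([1, 2, 3])
        kept, removed, pct = filter_by_mask(t, MaskSet())
        assert kept.n_sites == 3 and removed.n_sites == 0 and pct == 100.0

    def test_toy_membership(self):
        # mask [10, 14) 0-based covers 1-based positions 11..14
        t = make_table(list(range(8, 18)))
        mask = MaskSet.from_bed({"s1": [(10, 14)]})
        kept, removed, _ = filter_by_mask(t, mask)
        assert sorted(removed.pos) == [11, 12, 13, 14]
        assert kept.n_sites == 6

    def test_idempotent(self, rng):
        pos = sorted(rng.choice(np.arange(1, 1000), 50, replace=False))
        t = make_table(pos)
        mask = MaskSet.from_bed({"s1": [(100, 300), (500, 600)]})
        once, _, _ = filter_by_mask(t, mask)
        twice, _, _ = filter_by_mask(once, mask)
        assert twice.equals(once)

    def test_unknown_scaffold_in_mask_ignored(self):
        t = make_table([5])
        mask = MaskSet.from_bed({"sX": [(0, 100)]})
        kept, _, _ = filter_by_mask(t, mask)
        assert kept.n_sites == 1


class TestRates:
    def test_zero_sites_zero_rate(self):
        t = make_table([])
        assert (snv_rate(t, 1_000_000) == 0).all()

    def test_direct_division(self):
        gt = np.zeros((100, 1, 2), dtype=np.int8)
        gt[:, 0, 1] = 1  # every site het in the single individual
        t = make_table(list(range(1, 101)), gt=gt, n_samples=1)
        assert snv_rate(t, 1_000_000).iloc[0] == pytest.approx(1e-4)

    def test_per_individual_rates_match_genotype_scan(self, const_cohort):
        table = const_cohort.variants
        rates = snv_rate(table, 1_000_000)
        for k, name in enumerate(table.samples):
            manual = sum(
                1 for i in range(table.n_sites)
                if (table.gt[i, k] >= 0).all() and (table.gt[i, k] > 0).any())
            assert rates[name] == pytest.approx(manual / 1_000_000)

    def test_heterozygosity_scale_matches_printed_percent(self):
        assert heterozygosity_rate(190, 1_000_000) == pytest.approx(0.019)
        assert heterozygosity_rate(0, 10_000) == 0.0
        with pytest.raises(ValueError):
            heterozygosity_rate(5, 0)

    def test_heterozygosity_equals_genotype_tally(self, const_cohort):
        table = const_cohort.variants
        rates = heterozygosity_rates(table, 1_000_000)
        het = table.is_het().sum(axis=0)
        for k, name in enumerate(table.samples):
            assert rates[name] == pytest.approx(100.0 * het[k] / 1_000_000)


class TestWindows:
    def test_short_scaffold_excluded(self):
        wins, summary = window_density(np.array([]), np.array([]),
                                       {"s1": 49_999}, window=50_000)
        assert len(wins) == 0 and summary["excluded_scaffolds"] == 1

    def test_three_full_windows(self):
        wins, _ = window_density(np.array([]), np.array([]),
                                 {"s1": 150_000}, window=50_000)
        assert len(wins) == 3
        assert wins["end"].max() == 150_000

    def test_counts_match_brute_force_binning(self, const_cohort):
        table = const_cohort.variants
        wins, _ = window_density(table.scaffold, table.pos,
                                 {"scaf1": 1_000_000}, window=50_000)
        for row in wins.itertuples():
            manual = int(((table.pos - 1 >= row.start)
                          & (table.pos - 1 < row.end)).sum())
            assert row.snv_count == manual
        in_windows = int((table.pos - 1 < wins["end"].max()).sum())
        assert wins["snv_count"].sum() == in_windows

    def test_threshold_is_strict(self):
        # 41 SNVs -> heterozygous; 40 -> homozygous
        pos41 = np.arange(1, 42)
        pos40 = np.arange(100_001, 100_041)
        pos = np.concatenate([pos41, pos40])
        wins, summary = classify_het_hom(np.array(["s1"] * len(pos)), pos,
                                         {"s1": 200_000})
        assert list(wins["label"]) == ["heterozygous", "homozygous"]
        assert summary["percent_homozygous"] == 50.0

    def test_no_snvs_fully_homozygous(self):
        wins, summary = classify_het_hom(np.array([]), np.array([]),
                                         {"s1": 500_000})
        assert summary["percent_homozygous"] == 100.0

    def test_higher_theta_lowers_homozygous_fraction(self):
        """More diversity -> fewer windows under the 40-SNV threshold."""
        from bkit.syndata import DemographyScenario, simulate_two_pop_cohort
        pct = {}
        for theta_scale, mu in [("low", 2e-9), ("high", 2e-8)]:
            vals = []
            for seed in range(5):
                scen = DemographyScenario(
                    model_id="CONST", ancestral_size=10_000, epoch_params={},
                    mutation_rate=mu, sequence_length=2_000_000,
                    sample_sizes=(4, 4))
                cohort = simulate_two_pop_cohort(scen, seed=seed)
                table = cohort.variants
                het = table.is_het()[:, 0]
                _, summary = classify_het_hom(
                    table.scaffold[het], table.pos[het], {"scaf1": 2_000_000})
                vals.append(summary["percent_homozygous"])
            pct[theta_scale] = np.mean(vals)
        assert pct["high"] < pct["low"]


class TestROH:
    def test_all_heterozygous_no_segments(self):
        pos = np.arange(1, 10_000, 100)
        segs, med = detect_roh(np.array(["s1"] * len(pos)), pos,
                               np.ones(len(pos), dtype=bool))
        assert segs == [] and np.isnan(med)

    def test_planted_tract_recovered(self, rng):
        left = np.sort(rng.choice(np.arange(1, 100_000), 400, replace=False))
        tract = np.arange(100_000, 300_000, 1000)
        right = np.sort(rng.choice(np.arange(300_001, 400_000), 400,
                                   replace=False))
        pos = np.concatenate([left, tract, right])
        het = np.concatenate([rng.random(400) < 0.5,
                              np.zeros(len(tract), dtype=bool),
                              rng.random(400) < 0.5])
        segs, _ = detect_roh(np.array(["s1"] * len(pos)), pos, het)
        overlap = sum(max(0, min(s.end, 300_000) - max(s.start, 100_000))
                      for s in segs)
        assert overlap >= 0.9 * 200_000
        assert len([s for s in segs
                    if s.end > 100_000 and s.start < 300_000]) == 1

    def test_minimum_length_enforced(self):
        # homozygous stretch of 9.9 kb: dense SNVs, no hets -> still rejected
        pos = np.arange(1, 9_901, 100)
        segs, _ = detect_roh(np.array(["s1"] * len(pos)), pos,
                             np.zeros(len(pos), dtype=bool))
        assert segs == []

    def test_unsorted_input_raises(self):
        with pytest.raises(ValueError):
            detect_roh(np.array(["s1", "s1"]), np.array([100, 50]),
                       np.array([False, False]))


class TestTandemRepeats:
    def test_published_class_rules(self):
        recs = pd.DataFrame([
            dict(monomer=4, array_length=80, copy_number=20.0,
                 gc_percent=50.0, entropy=1.5, perfect=True),
            dict(monomer=6, array_length=500, copy_number=80.9,
                 gc_percent=50.0, entropy=1.8, perfect=False),
        ])
        out = classify_tandem_repeats(recs)
        assert bool(out.loc[0, "is_microsatellite"])
        assert not bool(out.loc[0, "is_complex"])
        assert bool(out.loc[1, "is_complex"])

    def test_random_records_match_rule_evaluation(self, rng):
        n = 200
        recs = pd.DataFrame({
            "monomer": rng.integers(1, 200, n),
            "array_length": rng.integers(10, 20_000, n),
            "copy_number": rng.uniform(2, 100, n),
            "gc_percent": rng.uniform(0, 100, n),
            "entropy": rng.uniform(1.0, 2.0, n),
            "perfect": rng.random(n) < 0.5,
            "cn_variation_bp": rng.uniform(0, 10, n),
        })
        out = classify_tandem_repeats(recs)
        for i in range(n):
            r = recs.iloc[i]
            assert out.loc[i, "is_microsatellite"] == (r.monomer < 5)
            expect_complex = (r.monomer > 4 and 20 <= r.gc_percent <= 80
                              and r.array_length > 100 and r.entropy > 1.76
                              and r.cn_variation_bp > 4 and not r.perfect)
            assert bool(out.loc[i, "is_complex"]) == expect_complex
            assert bool(out.loc[i, "is_large"]) == (r.array_length >= 1000)

    def test_missing_field_flagged_unclassifiable(self):
        recs = pd.DataFrame([dict(monomer=4, array_length=np.nan,
                                  copy_number=10.0, gc_percent=50.0,
                                  entropy=1.5, perfect=True)])
        out = classify_tandem_repeats(recs)
        assert bool(out.loc[0, "unclassifiable"])
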