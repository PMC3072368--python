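import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from qfa import (apply_exclusions, assign_region, classify_interactions,
                 estimate_gis, fdr_adjust, fit_comparison_regression,
                 gis_table, normalize_fitness, region_table,
                 strip_revertant_repeats, summarize_interactions)
from qfa.gis import NormalizationError


def bh_stepup(p):
    """Hand-coded Benjamini-Hochberg step-up, the independent oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def fitness_frame(values, orf="YAA001W", **extra):
    base = {"orf": orf, "gene": orf, "query": "q", "temperature": 27.0,
            "library": "SGAv2", "replicate": 1}
    base.update(extra)
    return pd.DataFrame([{**base, "replicate": i + 1, "fitness": v}
                         for i, v in enumerate(values)])


class TestNormalize:
    def test_constant_screen_maps_to_ones(self):
        out = normalize_fitness(fitness_frame([2.0, 2.0, 2.0]))
        assert out["fitness"].tolist() == [1.0, 1.0, 1.0]

    def test_mean_one_screen_unchanged(self):
        out = normalize_fitness(fitness_frame([0.0, 2.0]))
        assert out["fitness"].tolist() == [0.0, 2.0]

    def test_defining_property_and_idempotence(self, rng):
        table = fitness_frame(rng.uniform(0, 50, 40))
        once = normalize_fitness(table)
        assert once["fitness"].mean() == pytest.approx(1.0, abs=1e-12)
        twice = normalize_fitness(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_degenerate_screen_raises(self):
        with pytest.raises(NormalizationError):
            normalize_fitness(fitness_frame([0.0, 0.0]))


class TestEstimateGis:
    def test_identical_groups_are_null_with_p_one(self):
        mu, g2, se, p = estimate_gis([1.0] * 8, [1.0] * 8)
        assert (mu, g2, se, p) == (1.0, 0.0, 0.0, 1.0)

    def test_mean_difference_is_the_interaction(self, rng):
        c = 1.0 + rng.normal(0, 1e-6, 8)
        q = 0.5 + rng.normal(0, 1e-6, 8)
        _, g2, _, p = estimate_gis(c, q)
        assert g2 == pytest.approx(-0.5, abs=1e-5)
        assert p < 1e-10

    def test_worked_example_matches_pooled_t(self):
        c = [0.9, 1.1, 1.0, 1.0]
        q = [1.4, 1.6, 1.5, 1.5]
        mu, g2, se, p = estimate_gis(c, q)
        assert mu == pytest.approx(1.0)
        assert g2 == pytest.approx(0.5)
        t_oracle = stats.ttest_ind(q, c, equal_var=True)
        assert p == pytest.approx(t_oracle.pvalue, abs=1e-12)

    def test_single_replicate_gives_undefined_p(self):
        _, g2, se, p = estimate_gis([1.0], [0.25, 0.5])
        assert np.isnan(p) and np.isnan(se)
        assert g2 == pytest.approx(-0.625)

    def test_matches_independent_t_test_on_random_sets(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(2, 12, 2)
            c = rng.normal(1.0, 0.2, n1)
            q = rng.normal(0.8, 0.3, n2)
            mu, g2, se, p = estimate_gis(c, q)
            assert g2 == pytest.approx(q.mean() - c.mean(), abs=1e-10)
            oracle = stats.ttest_ind(q, c, equal_var=True)
            assert p == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_table_agrees_with_scalar_path(self, rng):
        frames_c, frames_q = [], []
        for i in range(30):
            orf = f"YGI{i:03d}W"
            frames_c.append(fitness_frame(rng.normal(1, 0.1, 8), orf=orf))
            frames_q.append(fitness_frame(rng.normal(0.9, 0.15, 8), orf=orf))
        control, query = pd.concat(frames_c), pd.concat(frames_q)
        table = gis_table(control, query).set_index("orf")
        for i in range(30):
            orf = f"YGI{i:03d}W"
            mu, g2, se, p = estimate_gis(
                control.loc[control["orf"] == orf, "fitness"],
                query.loc[query["orf"] == orf, "fitness"])
            assert table.at[orf, "gis"] == pytest.approx(g2, abs=1e-12)
            assert table.at[orf, "p"] == pytest.approx(p, abs=1e-12)


class TestFdr:
    def test_single_p_is_its_own_q(self):
        assert fdr_adjust([0.03]).tolist() == [0.03]

    def test_hand_computed_stepup(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_nan_sentinels_pass_through(self):
        q = fdr_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[[0, 2]]).any()

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_oracle_and_is_monotone(self, p):
        q = fdr_adjust(p)
        assert np.allclose(q, bh_stepup(p), atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestClassification:
    @pytest.mark.parametrize("gis,q,expected,strong", [
        (+0.6, 0.01, "suppressor", True),
        (-0.3, 0.01, "enhancer", False),
        (+0.9, 0.20, "none", True),
        (-0.5, 0.049, "enhancer", True),
    ])
    def test_call_rules(self, gis, q, expected, strong):
        rec = pd.DataFrame([{"gis": gis, "q": q}])
        out = classify_interactions(rec)
        assert out.loc[0, "classification"] == expected
        assert bool(out.loc[0, "strong"]) is strong

    def test_summary_counts(self):
        rec = pd.DataFrame({
            "gis": [0.7, -0.2, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0],
            "q": [0.01, 0.01, 0.5, 0.9, 0.9, 0.9, 0.9, 0.9],
        })
        summary = summarize_interactions(classify_interactions(rec), n_assayed=8)
        assert (summary.pct_suppressors_any, summary.pct_suppressors_strong,
                summary.pct_enhancers_any, summary.pct_enhancers_strong) == \
            (12.5, 12.5, 12.5, 0.0)

    def test_no_significant_records_gives_zeros(self):
        rec = classify_interactions(pd.DataFrame({"gis": [0.2], "q": [0.8]}))
        summary = summarize_interactions(rec, n_assayed=10)
        assert summary.pct_suppressors_any == 0.0
        assert summary.pct_enhancers_any == 0.0

    def test_zero_denominator_raises(self):
        rec = classify_interactions(pd.DataFrame({"gis": [], "q": []}))
        with pytest.raises(ValueError):
            summarize_interactions(rec, n_assayed=0)


class TestRevertantFilter:
    def _screen(self, reps=8, orf="YRV001W"):
        return fitness_frame(np.linspace(10, 20, reps), orf=orf,
                             library="SGAv2")

    def _check(self, modeled, orf="YRV001W"):
        # K chosen so modelled day-6 density equals `modeled` exactly
        rows = []
        for i, m in enumerate(modeled):
            rows.append({"orf": orf, "gene": orf, "library": "SGAv2",
                         "replicate": i + 1, "g0": 43.0, "r": 20.0,
                         "K": max(m, 43.0)})
        return pd.DataFrame(rows)

    def test_few_high_replicates_are_stripped(self):
        screen = self._screen()
        check = self._check([30000, 30000, 100, 100, 100, 100, 100, 100])
        out, report = strip_revertant_repeats(screen, check)
        assert len(out) == 6 and len(report) == 2

    def test_many_high_replicates_mean_real_suppression(self):
        screen = self._screen()
        check = self._check([30000] * 5 + [100] * 3)
        out, report = strip_revertant_repeats(screen, check)
        assert len(out) == 8 and report.empty

    def test_threshold_is_strict(self):
        screen = self._screen()
        check = self._check([25000] + [100] * 7)
        out, report = strip_revertant_repeats(screen, check)
        assert len(out) == 8 and report.empty

    def test_unmatched_replicates_are_retained(self):
        screen = self._screen()
        check = self._check([30000] * 8, orf="YOTHERW")
        out, report = strip_revertant_repeats(screen, check)
        assert len(out) == 8 and report.empty


class TestExclusions:
    def _screen(self):
        frames = [fitness_frame([1.0, 2.0], orf=f"YEX{i:03d}W")
                  for i in range(10)]
        return pd.concat(frames, ignore_index=True)

    def test_listed_orfs_removed_and_counted(self):
        out, report = apply_exclusions(self._screen(),
                                       exclude_orfs={"YEX000W", "YEX001W"})
        assert out["orf"].nunique() == 8
        assert report["reason"].tolist() == ["listed", "listed"]

    def test_marker_linkage_boundary(self):
        coords = pd.DataFrame({
            "orf": ["YEX000W", "YEX001W", "YEX002W"],
            "chrom": ["chrV", "chrV", "chrII"],
            "midpoint_kb": [110.0, 140.1, 110.0],
        })
        markers = pd.DataFrame({"chrom": ["chrV"], "position_kb": [120.0]})
        out, report = apply_exclusions(self._screen(), gene_coordinates=coords,
                                       marker_loci=markers)
        gone = set(report["orf"])
        assert gone == {"YEX000W"}          # 10 kb from the marker: excluded
        assert "YEX001W" not in gone        # 20.1 kb away: outside the radius
        assert "YEX002W" not in gone        # same midpoint, other chromosome

    def test_orf_without_coordinates_is_retained(self):
        coords = pd.DataFrame({"orf": ["YEX000W"], "chrom": ["chrV"],
                               "midpoint_kb": [110.0]})
        markers = pd.DataFrame({"chrom": ["chrV"], "position_kb": [112.0]})
        out, report = apply_exclusions(self._screen(), gene_coordinates=coords,
                                       marker_loci=markers)
        assert set(report["orf"]) == {"YEX000W"}
        assert out["orf"].nunique() == 9


class TestRegression:
    def test_exact_half_slope_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept = fit_comparison_regression(x, 0.5 * x)
        assert (slope, intercept) == (pytest.approx(0.5), pytest.approx(0.0, abs=1e-12))

    def test_identity_when_screens_equal(self, rng):
        x = rng.uniform(0, 2, 50)
        slope, intercept = fit_comparison_regression(x, x)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            fit_comparison_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRegions:
    def test_published_region_anchors(self):
        # suppress A (cdc13-1-like) & enhance B -> region 1 (NMD genes)
        assert assign_region(+0.8, -0.8, True, True) == 1
        # suppress both -> top right, region 3
        assert assign_region(+0.8, +0.8, True, True) == 3
        # enhance both -> region 7 (telomerase-like)
        assert assign_region(-0.8, -0.8, True, True) == 7
        # enhance A, suppress B -> region 9
        assert assign_region(-0.8, +0.8, True, True) == 9
        assert assign_region(0.0, 0.0, False, False) is None

    def test_significant_but_weak_lands_in_centre(self):
        assert assign_region(0.3, 0.1, True, False) == 5

    @given(ga=st.floats(-2, 2), gb=st.floats(-2, 2),
           sa=st.booleans(), sb=st.booleans())
    def test_partition_is_total_and_unique(self, ga, gb, sa, sb):
        region = assign_region(ga, gb, sa, sb)
        assert region is None or region in range(1, 10)

    def test_region_table_covers_shared_orfs(self, rng):
        rec = pd.DataFrame({
            "orf": [f"YRG{i:03d}W" for i in range(6)],
            "gene": [f"G{i}" for i in range(6)],
            "gis": [0.8, -0.8, 0.1, 0.6, -0.6, 0.0],
            "q": [0.01, 0.01, 0.01, 0.3, 0.01, 0.9],
        })
        table = region_table(rec, rec)
        assert len(table) == 6
        assert set(table["region"]) <= set(range(0, 10))
        # a gene suppressing both screens sits in region 3
        assert table.set_index("orf").at["YRG000W", "region"] == 3
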