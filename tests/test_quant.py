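"""Downstream quantification: percent input, ddCt chromatin metric,
growth fitting, proximity/metaprofile, antimorph classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import meclip as m
from meclip.errors import ConfigError, InputError
from meclip.quant import (
    CATEGORY_A_ONLY,
    CATEGORY_B_ONLY,
    CATEGORY_NS,
    CATEGORY_OPPOSITE,
    CATEGORY_SAME,
)


class TestPercentInput:
    def test_equal_cts_return_the_input_fraction(self):
        r = m.percent_input(m.QPCRMeasurement("t", 24.0, 24.0, 0.05))
        assert r.fraction == pytest.approx(0.05)
        assert not r.saturated

    def test_delta_ct_log2_twenty_saturates_at_one(self):
        r = m.percent_input(
            m.QPCRMeasurement("t", 24.0, 24.0 - math.log2(20), 0.05))
        assert r.fraction == pytest.approx(1.0)

    def test_three_cycle_difference_with_one_percent_input(self):
        r = m.percent_input(m.QPCRMeasurement("t", 27.0, 24.0, 0.01))
        assert r.fraction == pytest.approx(0.08)

    def test_recovery_above_one_is_flagged(self):
        r = m.percent_input(m.QPCRMeasurement("t", 30.0, 24.0, 0.05))
        assert r.saturated

    def test_non_finite_ct_rejected(self):
        with pytest.raises(InputError):
            m.QPCRMeasurement("t", float("nan"), 24.0, 0.05)
        with pytest.raises(InputError):
            m.QPCRMeasurement("t", 24.0, 24.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d1=st.floats(-5, 5), d2=st.floats(0.01, 4.9),
           f=st.floats(0.01, 1.0))
    def test_increasing_in_delta_ct_and_linear_in_fraction(self, d1, d2, f):
        base = m.percent_input(m.QPCRMeasurement("t", 20 + d1, 20.0, f))
        more = m.percent_input(m.QPCRMeasurement("t", 20 + d1 + d2, 20.0, f))
        assert more.fraction > base.fraction
        half = m.percent_input(m.QPCRMeasurement("t", 20 + d1, 20.0, f / 2))
        assert half.fraction == pytest.approx(base.fraction / 2)

    def test_synthetic_measurement_inverts_exactly(self):
        meas = m.synth_rip_measurement("HOTAIR", recovery=0.266)
        assert m.percent_input(meas).fraction == pytest.approx(0.266)


class TestRegionProfile:
    def test_reference_region_maps_to_one_and_ratios_scale(self):
        prof = m.region_profile({"r723_808": 0.30, "r1819_1923": 0.15},
                                "r1819_1923")
        assert prof["r1819_1923"] == pytest.approx(1.0)
        assert prof["r723_808"] == pytest.approx(2.0)

    def test_uniform_recoveries_flatten_to_one(self):
        prof = m.region_profile({f"r{i}": 0.2 for i in range(5)}, "r0")
        assert all(v == pytest.approx(1.0) for v in prof.values())

    def test_zero_reference_recovery_rejected(self):
        with pytest.raises(InputError):
            m.region_profile({"a": 0.0, "b": 0.1}, "a")


class TestChromatinAssociation:
    def test_baseline_is_exactly_one(self):
        conds = m.synth_chromatin_conditions({"wt": 1.0, "mut": 0.23}, "wt")
        result = m.chromatin_association(conds, "wt")
        assert result["wt"] == 1.0

    def test_two_extra_cycles_of_enrichment_is_fourfold(self):
        base = m.CtQuartet(22.0, 22.0, 22.0, 22.0)
        up = m.CtQuartet(20.0, 22.0, 22.0, 22.0)  # 2 cycles earlier on chromatin
        result = m.chromatin_association({"base": base, "up": up}, "base")
        assert result["up"] == pytest.approx(4.0)

    def test_encoded_fold_difference_is_recovered(self):
        # build Cts encoding a 4.3-fold WT-over-mutant difference, then
        # recover it through the ddCt chain
        conds = m.synth_chromatin_conditions({"wt": 1.0, "a783u": 1 / 4.3}, "wt")
        result = m.chromatin_association(conds, "a783u")
        assert result["wt"] == pytest.approx(4.3)

    def test_missing_baseline_rejected(self):
        with pytest.raises(InputError):
            m.chromatin_association({"a": m.CtQuartet(1, 1, 1, 1)}, "b")


class TestDoublingTime:
    def test_exact_doubling_every_24_hours(self):
        g = m.GrowthCurve((0.0, 24.0, 48.0), (5.0, 10.0, 20.0))
        fit = m.doubling_time(g)
        assert fit.growing
        assert abs(fit.doubling_time - 24.0) / 24.0 < 1e-9

    @pytest.mark.parametrize("T", [5.0, 26.5, 50.0, 100.0])
    def test_noiseless_exponential_recovered_exactly(self, T):
        g = m.synth_growth_curve(doubling_h=T, noise=0.0)
        fit = m.doubling_time(g)
        assert abs(fit.doubling_time - T) / T < 1e-9

    def test_constant_confluence_flagged_non_growing(self):
        g = m.GrowthCurve((0.0, 2.0, 4.0), (10.0, 10.0, 10.0))
        fit = m.doubling_time(g)
        assert not fit.growing
        assert math.isnan(fit.doubling_time)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            m.GrowthCurve((0.0, 2.0), (5.0, 6.0))

    def test_unsorted_time_rejected(self):
        with pytest.raises(InputError):
            m.GrowthCurve((0.0, 4.0, 2.0), (5.0, 6.0, 7.0))

    def test_one_percent_noise_keeps_median_error_under_five_percent(self):
        T = 26.5
        errors = []
        for seed in range(100):
            g = m.synth_growth_curve(doubling_h=T, noise=0.01, seed=seed)
            fit = m.doubling_time(g)
            errors.append(abs(fit.doubling_time - T) / T)
        assert np.median(errors) < 0.05


class TestPeakProximity:
    def test_edge_distance_within_window_is_proximal(self):
        peaks = m.PeakSet([("chr1", 5790, 5810, 1.0)])
        result = m.peak_proximity([("chr1", 5000)], peaks, window=1000)
        assert result.n_proximal == 1
        assert result.distances[0] == 790

    def test_beyond_window_is_not_proximal(self):
        peaks = m.PeakSet([("chr1", 6500, 6520, 1.0)])
        result = m.peak_proximity([("chr1", 5000)], peaks, window=1000)
        assert result.n_proximal == 0

    def test_window_boundary_inclusive(self):
        peaks = m.PeakSet([("chr1", 6000, 6020, 1.0)])
        result = m.peak_proximity([("chr1", 5000)], peaks, window=1000)
        assert result.n_proximal == 1

    def test_site_inside_peak_has_distance_zero(self):
        peaks = m.PeakSet([("chr1", 100, 200, 1.0)])
        assert m.peak_proximity([("chr1", 150)], peaks, 0).n_proximal == 1

    def test_planted_fraction_recovered(self):
        sites, peaks = m.synth_sites_and_peaks(100, 4, window=1000, seed=5)
        result = m.peak_proximity(sites, peaks, window=1000)
        assert result.n_proximal == 4
        assert result.fraction == pytest.approx(0.04)

    def test_widening_window_never_loses_sites(self):
        sites, peaks = m.synth_sites_and_peaks(50, 20, window=1000, seed=9)
        counts = [m.peak_proximity(sites, peaks, w).n_proximal
                  for w in (0, 100, 500, 1000, 5000)]
        assert counts == sorted(counts)
        assert all(0 <= c <= 50 for c in counts)

    def test_negative_window_rejected(self):
        with pytest.raises(ConfigError):
            m.peak_proximity([], m.PeakSet([]), -1)


class TestMetaprofile:
    def test_uniform_signal_gives_flat_profile(self):
        track = {"chr1": np.ones(10_000)}
        prof = m.metaprofile([("chr1", 5000), ("chr1", 3000)], track,
                             halfwidth=1000, bins=20)
        values = prof["mean_signal"].dropna()
        assert values.max() - values.min() < 1e-9

    def test_central_depletion_minimizes_at_offset_zero(self):
        track = {"chr1": np.ones(20_000)}
        sites = [("chr1", p) for p in (5000, 9000, 15000)]
        for _, p in sites:
            track["chr1"][p - 50 : p + 51] = 0.0
        prof = m.metaprofile(sites, track, halfwidth=1000, bins=41)
        center = prof.iloc[(prof.offset_start + prof.offset_end).abs().idxmin()]
        assert center.mean_signal == prof.mean_signal.min()

    def test_single_peak_registers_only_in_its_bin(self):
        peaks = m.PeakSet([("chr1", 5230, 5240, 1.0)])
        track = m.peaks_to_track(peaks, {"chr1": 10_000})
        prof = m.metaprofile([("chr1", 5000)], track, halfwidth=1000, bins=20)
        nonzero = prof[prof.mean_signal > 0]
        assert len(nonzero) == 1
        row = nonzero.iloc[0]
        assert row.offset_start <= 230 <= row.offset_end

    def test_no_sites_is_an_error(self):
        with pytest.raises(InputError):
            m.metaprofile([], {"chr1": np.ones(10)}, 5, 2)

    def test_sites_near_edges_contribute_valid_offsets_only(self):
        track = {"chr1": np.ones(100)}
        prof = m.metaprofile([("chr1", 10)], track, halfwidth=50, bins=10)
        # only offsets -10..+50 fall inside the sequence
        assert prof.n_obs.sum() == 61


def toy_table():
    """Six genes covering every category, classified by hand."""
    return pd.DataFrame({
        "gene": ["opp", "same", "aonly", "bonly", "ns", "opp2"],
        "log2fc_a": [-1.0, 1.2, 0.8, 0.05, 0.01, 2.0],
        "padj_a": [0.01, 0.02, 0.05, 0.50, 0.90, 0.001],
        "log2fc_b": [1.0, 0.9, 0.1, -1.5, -0.02, -1.0],
        "padj_b": [0.01, 0.03, 0.70, 0.01, 0.80, 0.04],
    })


class TestAntimorphClassify:
    def test_toy_table_counts_match_hand_enumeration(self):
        result = m.antimorph_classify(toy_table())
        assert result.counts[CATEGORY_OPPOSITE] == 2
        assert result.counts[CATEGORY_SAME] == 1
        assert result.counts[CATEGORY_A_ONLY] == 1
        assert result.counts[CATEGORY_B_ONLY] == 1
        assert result.counts[CATEGORY_NS] == 1
        assert result.categories["opp"] == CATEGORY_OPPOSITE
        assert result.categories["bonly"] == CATEGORY_B_ONLY

    def test_down_with_wildtype_up_with_mutant_is_antimorph(self):
        # the SEMA5A pattern: repressed by the wild type, induced by the mutant
        df = pd.DataFrame({
            "gene": ["SEMA5A-like"],
            "log2fc_a": [-1.0], "padj_a": [0.01],
            "log2fc_b": [1.0], "padj_b": [0.01],
        })
        result = m.antimorph_classify(df)
        assert result.categories["SEMA5A-like"] == CATEGORY_OPPOSITE

    def test_significant_in_a_only(self):
        df = pd.DataFrame({
            "gene": ["g"], "log2fc_a": [1.0], "padj_a": [0.01],
            "log2fc_b": [1.0], "padj_b": [0.5],
        })
        assert m.antimorph_classify(df).categories["g"] == CATEGORY_A_ONLY

    def test_categories_partition_significant_genes(self):
        df = m.synth_foldchange_table(n_null=200, seed=3)
        result = m.antimorph_classify(df)
        sig_any = ((df.padj_a < 0.1) | (df.padj_b < 0.1)).sum()
        n_categorized = sum(result.counts[c] for c in
                            (CATEGORY_SAME, CATEGORY_OPPOSITE,
                             CATEGORY_A_ONLY, CATEGORY_B_ONLY))
        assert n_categorized == sig_any
        assert sum(result.counts.values()) == len(df)

    def test_swapping_contrasts_swaps_only_the_one_sided_counts(self):
        df = m.synth_foldchange_table(n_null=200, seed=4)
        swapped = df.rename(columns={
            "log2fc_a": "log2fc_b", "log2fc_b": "log2fc_a",
            "padj_a": "padj_b", "padj_b": "padj_a"})
        r1 = m.antimorph_classify(df)
        r2 = m.antimorph_classify(swapped)
        assert r1.counts[CATEGORY_OPPOSITE] == r2.counts[CATEGORY_OPPOSITE]
        assert r1.counts[CATEGORY_SAME] == r2.counts[CATEGORY_SAME]
        assert r1.counts[CATEGORY_A_ONLY] == r2.counts[CATEGORY_B_ONLY]
        assert r1.counts[CATEGORY_B_ONLY] == r2.counts[CATEGORY_A_ONLY]

    def test_correlation_filter_excludes_small_fold_changes(self):
        thr = math.log2(1.15)
        df = pd.DataFrame({
            "gene": ["big1", "big2", "big3", "small"],
            "log2fc_a": [1.0, -2.0, 1.5, thr * 0.5],
            "padj_a": [0.01] * 4,
            "log2fc_b": [-1.0, 1.8, -0.9, 3.0],
            "padj_b": [0.01] * 4,
        })
        result = m.antimorph_classify(df)
        assert result.correlation.n == 3

    def test_planted_category_counts_recovered(self):
        df = m.synth_foldchange_table(n_opposite=46, n_same=18, n_a_only=91,
                                      n_b_only=694, n_null=500, seed=11)
        result = m.antimorph_classify(df)
        assert result.counts[CATEGORY_OPPOSITE] == 46
        assert result.counts[CATEGORY_SAME] == 18
        assert result.counts[CATEGORY_A_ONLY] == 91
        assert result.counts[CATEGORY_B_ONLY] == 694
        assert result.correlation.r_linear < -0.3

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigError):
            m.antimorph_classify(toy_table(), alpha=1.5)

    def test_duplicate_genes_rejected(self):
        df = toy_table()
        df.loc[1, "gene"] = "opp"
        with pytest.raises(InputError):
            m.antimorph_classify(df)
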