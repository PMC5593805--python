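"""Reference hyperbolas, binned statistics and the two report pipelines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligeff.synthetic import BindingGenConfig, PriceGenConfig, generate_binding_dataset, generate_price_catalog
from ligeff.trends import (
    TrendConfig,
    binned_means,
    fit_hyperbola_coefficient,
    linear_trend,
    reference_hyperbola,
    run_binding_analysis,
    run_economy_analysis,
    weight_to_molar_price,
)

from ._oracles import grid_search_hyperbola_c


class TestReferenceHyperbola:
    def test_printed_coefficient(self):
        assert reference_hyperbola(8, [100, 200, 400]).tolist() == pytest.approx(
            [0.08, 0.04, 0.02]
        )
        assert reference_hyperbola(8, [8]).tolist() == [1.0]
        assert reference_hyperbola(1, [1, 2, 4]).tolist() == [1, 0.5, 0.25]

    def test_nonpositive_x_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 1"):
            reference_hyperbola(8, [10, -1, 5])


class TestFitHyperbola:
    def test_noise_free_recovery(self):
        model = fit_hyperbola_coefficient([100, 200, 400], [0.08, 0.04, 0.02])
        assert model.c == pytest.approx(8.0)
        assert model.fitted

    def test_zero_data_gives_zero(self):
        assert fit_hyperbola_coefficient([10, 20], [0, 0]).c == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_hyperbola_coefficient([], [])

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        xs = rng.uniform(50, 500, size=30)
        ys = 5.0 / xs + rng.normal(0, 0.002, size=30)
        c = fit_hyperbola_coefficient(xs, ys).c
        assert abs(c - grid_search_hyperbola_c(xs, ys)) <= 1e-3

    def test_recovers_generator_coefficient(self):
        df = generate_binding_dataset(BindingGenConfig(seed=1))
        c = fit_hyperbola_coefficient(df["mw"], df["p_mol"] / df["mw"]).c
        assert c == pytest.approx(8.0, rel=0.05)


class TestBinnedMeans:
    def test_two_point_bin(self):
        df = pd.DataFrame({"mw": [150.0, 160.0], "v": [2.0, 4.0]})
        b = binned_means(df, "v", "mw", bin_width=100, lo=100, hi=200)
        assert b.counts.tolist() == [2]
        assert b.means.tolist() == [3.0]

    def test_single_record_sd_flagged(self):
        df = pd.DataFrame({"mw": [150.0], "v": [5.0]})
        b = binned_means(df, "v", "mw", bin_width=100, lo=100, hi=200)
        assert b.means[0] == 5.0 and np.isnan(b.sds[0])

    def test_empty_bins_kept_and_out_of_range_counted(self):
        df = pd.DataFrame({"mw": [50.0, 250.0, 1500.0], "v": [1.0, 2.0, 3.0]})
        b = binned_means(df, "v", "mw", bin_width=100, lo=100, hi=400)
        assert b.counts.tolist() == [0, 1, 0]
        assert np.isnan(b.means[0]) and np.isnan(b.means[2])
        assert (b.n_below, b.n_above) == (1, 1)

    def test_constant_tier_monte_carlo(self):
        """Every bin mean sits within 3 sd/sqrt(count) of the tier price."""
        cat = generate_price_catalog(
            PriceGenConfig(n_compounds=10_000, tiers=((2.0, 1.0),), seed=11)
        )
        b = binned_means(cat, "price_per_g", "mw", 50, 0, 1000)
        occ = b.counts > 5
        margin = 3 * b.sds[occ] / np.sqrt(b.counts[occ])
        assert np.all(np.abs(b.means[occ] - 2.0) <= margin)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            binned_means(pd.DataFrame({"mw": [1.0], "v": [1.0]}), "v", "mw", 0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, derandomize=True)
    def test_weighted_mean_conservation(self, seed):
        """Count-weighted bin means reconstruct the global in-range mean."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 200)
        df = pd.DataFrame(
            {"mw": rng.uniform(0, 1000, n), "v": rng.normal(0, 10, n)}
        )
        b = binned_means(df, "v", "mw", 50, 0, 1000)
        assert b.weighted_mean() == pytest.approx(df["v"].mean(), rel=1e-9, abs=1e-9)


class TestLinearTrend:
    def test_exact_line(self):
        t = linear_trend([1, 2, 3], [2, 4, 6])
        assert (t.slope, t.intercept, t.r_squared) == pytest.approx((2.0, 0.0, 1.0))

    def test_constant_ys_flagged(self):
        t = linear_trend([1, 2, 3], [5, 5, 5])
        assert t.slope == 0.0 and t.r_squared == 0.0

    def test_degenerate_xs_rejected(self):
        with pytest.raises(ValueError):
            linear_trend([2, 2, 2], [1, 2, 3])

    def test_recovers_tier_price_as_molar_slope(self):
        cat = generate_price_catalog(
            PriceGenConfig(n_compounds=10_000, tiers=((2.0, 1.0),), seed=5)
        )
        t = linear_trend(cat["mw"], cat["price_per_mol"])
        assert t.slope == pytest.approx(2.0, rel=0.05)
        # raw points carry the multiplicative price noise; only the
        # binned-mean fit is expected to be near-perfectly linear
        assert t.r_squared > 0.9


class TestWeightToMolarPrice:
    def test_examples(self):
        assert weight_to_molar_price(2.0, 150.0) == pytest.approx(300.0)
        assert weight_to_molar_price(0.0, 321.0) == 0.0
        assert weight_to_molar_price(1.0, 250.0) == 250.0

    def test_negative_price_rejected(self):
        with pytest.raises(ValueError):
            weight_to_molar_price(-1.0, 100.0)


class TestBindingAnalysis:
    def test_all_panels_and_coefficient(self, binding_df):
        report = run_binding_analysis(binding_df)
        assert set(report.tables) == {"fig2a", "fig2b", "fig2c", "fig2d"}
        assert report.summary["fitted_c_bei"] == pytest.approx(8.0, rel=0.05)
        assert report.summary["mw_vs_hac"]["r_squared"] >= 0.95
        assert len(report.summary["class_mean_bei_residual"]) == 14

    def test_noise_free_bei_equals_reference(self):
        df = generate_binding_dataset(
            BindingGenConfig(dg_sd=0.0, class_offset_sd=0.0, seed=3)
        )
        report = run_binding_analysis(df)
        panel = report.tables["fig2a"]
        assert panel["bei"].to_numpy() == pytest.approx(
            panel["ref_bei"].to_numpy(), rel=1e-12
        )

    def test_noise_free_le_monotone_in_hac(self):
        df = generate_binding_dataset(
            BindingGenConfig(dg_sd=0.0, class_offset_sd=0.0, seed=3)
        )
        panel = run_binding_analysis(df).tables["fig2c"].sort_values("hac")
        assert np.all(np.diff(panel["le"].to_numpy()) <= 1e-12)

    def test_invalid_rows_excluded_with_count(self, binding_df):
        df = binding_df.copy()
        df.loc[df.index[0], "mw"] = np.nan
        report = run_binding_analysis(df)
        assert report.summary["n_excluded"] == {"mw": 1}
        assert report.summary["n_used"] == len(df) - 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_binding_analysis(pd.DataFrame({"p_mol": [], "mw": [], "hac": []}))


class TestEconomyAnalysis:
    def test_constant_tier_structure(self, catalog_df):
        report = run_economy_analysis(catalog_df, TrendConfig(mw_range=(0, 1000)))
        gram = report.summary["binned_gram_price"]
        molar = report.summary["binned_molar_price"]
        assert abs(gram["t_value"]) < 2
        assert molar["slope"] == pytest.approx(2.0, rel=0.05)
        assert molar["r_squared"] > 0.99

    def test_single_br_family_on_exact_hyperbola(self):
        cat = generate_price_catalog(
            PriceGenConfig(n_compounds=500, br_mixture={1: 1.0}, seed=2)
        )
        report = run_economy_analysis(cat)
        panel = report.tables["fig3f"]
        assert panel["br_per_ac"].to_numpy() == pytest.approx(
            1.0 / panel["ac"].to_numpy()
        )

    def test_brc_values_are_integers(self, catalog_df):
        report = run_economy_analysis(catalog_df)
        brc = report.tables["fig3g"]["brc"].to_numpy()
        assert np.all(brc == brc.astype(int))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_economy_analysis(pd.DataFrame({"mw": [], "price_per_g": []}))
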