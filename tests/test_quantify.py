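"""Coordinate normalisation, quadrants, subsampling, summaries, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import divtrace as dt
from divtrace import quantify

from conftest import cells_from_counts, simple_cohort

BOUNDS = {"x_min": -900.0, "x_max": 1100.0, "y_min": -700.0, "y_max": 800.0}
CANAL = (100.0, 50.0)


class TestNormalizeCoordinates:
    def test_central_canal_maps_to_origin(self):
        out = dt.normalize_coordinates([CANAL], BOUNDS, CANAL, "right")
        assert out["x_norm"].iloc[0] == 0.0
        assert out["y_norm"].iloc[0] == 0.0

    def test_ipsilateral_border_mid_height_maps_to_one_zero(self):
        out = dt.normalize_coordinates([(1100.0, 50.0)], BOUNDS, CANAL,
                                       "right")
        assert out["x_norm"].iloc[0] == pytest.approx(1.0)
        assert out["y_norm"].iloc[0] == pytest.approx(0.0)

    def test_contralateral_and_ventral_borders_map_to_minus_one(self):
        out = dt.normalize_coordinates([(-900.0, -700.0)], BOUNDS, CANAL,
                                       "right")
        assert out["x_norm"].iloc[0] == pytest.approx(-1.0)
        assert out["y_norm"].iloc[0] == pytest.approx(-1.0)

    def test_dorsal_point_on_injection_side_is_positive_positive(self):
        for side, x in (("right", 400.0), ("left", -400.0)):
            out = dt.normalize_coordinates([(x, 300.0)], BOUNDS, CANAL, side)
            assert out["x_norm"].iloc[0] > 0
            assert out["y_norm"].iloc[0] > 0

    def test_left_injection_mirrors_x(self):
        right = dt.normalize_coordinates([(400.0, 0.0)], BOUNDS, CANAL,
                                         "right")
        left = dt.normalize_coordinates([(400.0, 0.0)], BOUNDS, CANAL, "left")
        assert left["x_norm"].iloc[0] == pytest.approx(
            -right["x_norm"].iloc[0])

    def test_out_of_bounds_flagged(self):
        out = dt.normalize_coordinates([(2000.0, 0.0), (0.0, 0.0)],
                                       BOUNDS, CANAL, "right")
        assert out["out_of_bounds"].tolist() == [True, False]

    def test_bounds_must_enclose_canal(self):
        with pytest.raises(dt.ConfigError):
            dt.normalize_coordinates([(0.0, 0.0)], BOUNDS, (1200.0, 0.0),
                                     "right")


class TestAssignQuadrant:
    @pytest.mark.parametrize("x, y, expected", [
        (0.3, 0.5, "DI"), (-0.2, -0.7, "VC"), (0.0, 0.0, "DI"),
        (-0.1, 0.9, "DC"), (0.4, -0.3, "VI"), (0.0, -0.5, "VI"),
    ])
    def test_sign_convention_with_ties_to_dorsal_ipsilateral(self, x, y,
                                                             expected):
        assert dt.assign_quadrant(x, y) == expected

    def test_nonfinite_flagged(self):
        out = dt.assign_quadrant(np.array([0.1, np.nan]),
                                 np.array([0.2, 0.3]))
        assert out[0] == "DI"
        assert out[1] is pd.NA
        with pytest.raises(ValueError):
            dt.assign_quadrant(np.nan, 0.0)

    def test_quadrant_counts_conserve_total(self, simulated_cells):
        _, cells = simulated_cells
        quads = dt.assign_quadrant(cells["x_norm"].to_numpy(),
                                   cells["y_norm"].to_numpy())
        counts = pd.Series(quads).value_counts()
        assert counts.sum() == len(cells)
        assert set(counts.index) <= {"DI", "DC", "VI", "VC"}


class TestSubsampleSections:
    def test_one_in_three_keeps_congruent_sections(self):
        cells = simple_cohort(90, "both", seed=1).assign(
            section_index=np.arange(90) % 9, labels="eGFP")
        kept = dt.subsample_sections(cells, "lumbar", k=3, offset=0)
        assert set(kept["section_index"]) == {0, 3, 6}

    def test_k_one_is_identity(self, simulated_cells):
        _, cells = simulated_cells
        assert dt.subsample_sections(cells, "lumbar", k=1) is cells

    def test_other_regions_pass_through(self):
        cells = pd.concat([
            simple_cohort(30, "both", region="lumbar", seed=2),
            simple_cohort(30, "both", region="thoracic", seed=3)],
            ignore_index=True)
        kept = dt.subsample_sections(cells, "lumbar", k=3, offset=1)
        assert (kept["region"] == "thoracic").sum() == 30

    def test_offsets_partition_the_table(self, simulated_cells):
        _, cells = simulated_cells
        parts = [dt.subsample_sections(cells, "lumbar", 3, o)
                 for o in range(3)]
        ids = [set(p.index) for p in parts]
        assert ids[0] | ids[1] | ids[2] == set(cells.index)
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])

    def test_retained_count_is_binomial_third(self):
        n = 30_000
        rng = np.random.default_rng(4)
        cells = simple_cohort(n, "both", seed=4).assign(
            section_index=rng.integers(0, 90, n))
        kept = dt.subsample_sections(cells, "lumbar", k=3, offset=0)
        assert abs(len(kept) - n / 3) <= 3 * np.sqrt(n * (1 / 3) * (2 / 3))

    def test_invalid_k_offset(self):
        cells = simple_cohort(3, "both")
        with pytest.raises(dt.ConfigError):
            dt.subsample_sections(cells, "lumbar", k=0)
        with pytest.raises(dt.ConfigError):
            dt.subsample_sections(cells, "lumbar", k=3, offset=3)


class TestDivergenceSummary:
    @pytest.mark.parametrize("n_double, n_total, printed", [
        (206, 4341, "4.7"),    # lumbar antagonist, pooled
        (74, 1913, "3.9"),     # ventral-ipsilateral synergist
        (134, 2651, "5.1"),    # dorsal-ipsilateral antagonist
        (5, 142, "3.5"),       # dorsal-contralateral antagonist
        (88, 399, "22.1"),     # thoracic dorsal-ipsilateral pooled
    ])
    def test_reproduces_printed_pooled_percentages(self, n_double, n_total,
                                                   printed):
        n_singles = n_total - n_double
        cells = cells_from_counts(n_singles // 2, n_singles - n_singles // 2,
                                  n_double)
        summary = dt.divergence_summary(cells)
        row = summary.iloc[0]
        assert row["n_double"] == n_double
        assert row["n_total"] == n_total
        assert dt.format_percent(row["rate_pooled"]) == printed

    def test_no_doubles_is_zero_percent(self):
        summary = dt.divergence_summary(cells_from_counts(50, 50, 0))
        assert summary["rate_pooled"].iloc[0] == 0.0
        assert dt.format_percent(summary["rate_pooled"].iloc[0]) == "0.0"

    def test_counts_identity(self, simulated_cells):
        _, cells = simulated_cells
        s = dt.divergence_summary(cells)
        assert (s["n_single_A"] + s["n_single_B"] + s["n_double"]
                == s["n_total"]).all()

    def test_colour_swap_and_row_order_invariance(self, simulated_cells):
        _, cells = simulated_cells
        base = dt.divergence_summary(cells)
        swapped = dt.divergence_summary(
            cells, colours=("mCherry", "eGFP"))
        assert swapped["rate_pooled"].equals(base["rate_pooled"])
        assert swapped["n_double"].equals(base["n_double"])
        shuffled = dt.divergence_summary(
            cells.sample(frac=1.0, random_state=9))
        pd.testing.assert_frame_equal(
            shuffled.sort_values("region").reset_index(drop=True), base)

    def test_double_counts_are_exactly_the_double_labelled_divergents(
            self, simulated_cells):
        _, cells = simulated_cells
        premotor = cells[~cells["is_motoneuron"]]
        counted = set(premotor.loc[
            premotor["labels"] == "eGFP+mCherry", "neuron_id"])
        truth = set(premotor.loc[
            (premotor["connectivity"] == "both")
            & premotor["labels"].str.contains("eGFP")
            & premotor["labels"].str.contains("mCherry"), "neuron_id"])
        assert counted == truth

    def test_motoneurons_excluded_from_denominators(self):
        cells = cells_from_counts(40, 40, 20)
        mn = cells.head(10).copy()
        mn["is_motoneuron"] = True
        summary = dt.divergence_summary(
            pd.concat([cells, mn], ignore_index=True))
        assert summary["n_total"].iloc[0] == 100

    def test_empty_group_absent_not_zero(self):
        cells = cells_from_counts(10, 10, 2, region="lumbar")
        summary = dt.divergence_summary(cells)
        assert summary["region"].tolist() == ["lumbar"]

    def test_default_sampling_thins_lumbar_only(self):
        rng = np.random.default_rng(10)
        cells = cells_from_counts(300, 300, 30)
        cells["section_index"] = rng.integers(0, 90, len(cells))
        full = dt.divergence_summary(cells, sampling={})
        sampled = dt.divergence_summary(cells)  # default lumbar 1-in-3
        assert sampled["n_total"].iloc[0] < full["n_total"].iloc[0]

    def test_per_animal_mean_and_sd(self):
        # two animals with rates 0.1 and 0.3 -> mean 0.2, pooled differs
        a = cells_from_counts(45, 45, 10)        # animal rate 0.10
        b = cells_from_counts(14, 14, 12)        # animal rate 0.30
        b["animal_id"] = 2
        summary = dt.divergence_summary(pd.concat([a, b], ignore_index=True))
        row = summary.iloc[0]
        assert row["rate_mean"] == pytest.approx(0.2)
        assert row["rate_sd"] == pytest.approx(np.std([0.1, 0.3], ddof=1))
        assert row["n_animals"] == 2
        assert row["rate_pooled"] == pytest.approx(22 / 140)


class TestPercentRendering:
    @pytest.mark.parametrize("rate, expected", [
        (0.04745450357, "4.7"), (0.0005, "0.1"), (0.0004999, "0.0"),
        (0.045, "4.5"), (-0.0005, "-0.1"), (1.0, "100.0"),
    ])
    def test_half_away_from_zero(self, rate, expected):
        assert dt.format_percent(rate) == expected

    def test_matches_decimal_oracle_on_random_fractions(self):
        from decimal import Decimal, ROUND_HALF_UP

        rng = np.random.default_rng(11)
        for n_double in rng.integers(0, 500, size=50):
            rate = int(n_double) / 500
            oracle = Decimal(repr(100 * rate)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP)
            assert dt.format_percent(rate) == str(oracle)


class TestMeanPooledDiagnostic:
    def test_homogeneous_animals_not_flagged(self):
        parts = [cells_from_counts(120, 120, 10, seed=s) for s in range(4)]
        for i, p in enumerate(parts):
            p["animal_id"] = i + 1
        summary = dt.divergence_summary(pd.concat(parts, ignore_index=True))
        diag = dt.mean_pooled_discrepancy(summary)
        assert not diag["flagged"].any()

    def test_size_rate_correlation_is_flagged(self):
        big = cells_from_counts(980, 980, 40)          # 2% of 2000
        small = cells_from_counts(25, 25, 50)          # 50% of 100
        small["animal_id"] = 2
        summary = dt.divergence_summary(
            pd.concat([big, small], ignore_index=True))
        diag = dt.mean_pooled_discrepancy(summary)
        assert diag["flagged"].all()
        assert diag["discrepancy"].iloc[0] > 0


class TestSomaAreaStats:
    def test_identical_groups_show_no_effect(self):
        g = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]}
        res = dt.soma_area_stats(g)
        assert res.kruskal_p == pytest.approx(1.0, abs=1e-9)
        assert (res.dunn["p_adj"] == 1.0).all()

    def test_two_identical_samples_mann_whitney_p_one(self):
        res = dt.soma_area_stats({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert res.mannwhitney_p == pytest.approx(1.0)

    def test_tiny_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = dt.soma_area_stats(
                {"a": [1.0, 2, 3], "b": [5.0], "c": [7.0, 8, 9]})
        assert set(res.group_stats["group"]) == {"a", "c"}

    def test_dunn_z_squares_to_kruskal_h_for_two_groups(self):
        """For exactly two groups, Dunn's z² equals the (tie-corrected)
        Kruskal–Wallis H — an exact algebraic identity used as the
        independent check of the hand-computed Dunn statistic."""
        rng = np.random.default_rng(12)
        g = {"a": rng.lognormal(5.8, 0.3, 40),
             "b": np.round(rng.lognormal(6.6, 0.3, 25), 0)}  # induce ties
        h, _ = stats.kruskal(g["a"], g["b"])
        z = quantify.dunn_test(g)["z"].iloc[0]
        assert z ** 2 == pytest.approx(h, rel=1e-10)

    def test_separated_lognormal_groups_detected(self):
        rng = np.random.default_rng(13)
        res = dt.soma_area_stats({
            "cervical": rng.lognormal(6.61, 0.29, 38),
            "thoracic": rng.lognormal(5.81, 0.39, 135),
            "lumbar": rng.lognormal(5.71, 0.35, 61)})
        assert res.kruskal_p < 1e-4
        pairs = res.dunn.set_index(["group1", "group2"])
        assert pairs.loc[("cervical", "thoracic"), "p_adj"] < 1e-4
        assert pairs.loc[("cervical", "lumbar"), "p_adj"] < 1e-4
        assert "Kruskal" in res.summary()


class TestSpatialDensity:
    def test_point_mass_lands_in_one_bin(self):
        cells = cells_from_counts(1, 0, 0)
        cells["x_norm"] = 0.5
        prof = dt.spatial_density(cells, axis="x", bins=40)
        hot = prof[prof["density"] > 0]
        assert len(hot) == 1
        assert hot["bin_left"].iloc[0] <= 0.5 <= hot["bin_right"].iloc[0]

    def test_unit_normalization_integrates_to_one(self, simulated_cells):
        _, cells = simulated_cells
        for axis in ("x", "y"):
            prof = dt.spatial_density(cells, axis=axis, bins=25)
            width = prof["bin_right"] - prof["bin_left"]
            assert (prof["density"] * width).sum() == pytest.approx(
                1.0, abs=1e-9)

    def test_uniform_cells_give_flat_profile(self):
        n, bins = 50_000, 20
        cells = cells_from_counts(n, 0, 0, seed=14)  # x ~ U(-1, 1)
        prof = dt.spatial_density(cells, axis="x", bins=bins)
        counts = prof["density"] * (2 / bins) * n
        p = 1 / bins
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 4 * se)

    def test_count_normalization_weights_by_group_share(self):
        cells = pd.concat([
            cells_from_counts(300, 0, 0, region="lumbar"),
            cells_from_counts(100, 0, 0, region="thoracic")],
            ignore_index=True)
        prof = dt.spatial_density(cells, axis="x", by="region",
                                  normalization="count")
        width = prof["bin_right"] - prof["bin_left"]
        share = (prof["density"] * width).groupby(prof["region"]).sum()
        assert share["lumbar"] == pytest.approx(0.75)
        assert share["thoracic"] == pytest.approx(0.25)

    def test_empty_selection_gives_empty_profile(self):
        prof = dt.spatial_density(cells_from_counts(0, 0, 0), axis="x")
        assert prof.empty
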