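"""NDVI vegetation classes and tree-loss anomaly summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fireregimes import make_grid
from fireregimes.degradation import (
    anomaly_ratio,
    classify_vegetation,
    ndvi_statistics,
    smooth_ndvi,
    summarize_degradation,
    tree_loss_fraction,
)
from fireregimes.synthetic import generate_environment, generate_fire_archive


class TestSmoothNdvi:
    def test_constant_unchanged(self):
        s = np.full(20, 0.7)
        np.testing.assert_allclose(smooth_ndvi(s, 5), s)

    def test_spike_removed(self):
        out = smooth_ndvi(np.array([0.0, 0.0, 9.0, 0.0, 0.0]), 5)
        assert out[2] == 0.0

    def test_window_one_is_identity(self):
        s = np.array([0.1, 0.9, 0.3])
        np.testing.assert_array_equal(smooth_ndvi(s, 1), s)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_ndvi(np.zeros(5), 4)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            smooth_ndvi(np.full(5, np.nan), 5)


class TestClassifyVegetation:
    def _classify(self, mean, acv, mcv):
        prof = classify_vegetation(np.array([mean]), np.array([acv]),
                                   np.array([mcv]), normalise=False)
        return prof.veg_class[0]

    @pytest.mark.parametrize("mean, acv, mcv, expected", [
        (0.85, 0.05, 0.02, "forest"),    # high stable canopy
        (0.50, 0.12, 0.20, "grassy"),    # open seasonal canopy
        (0.03, 0.12, 0.20, "other"),     # below the 6% vegetation floor
        (0.85, 0.20, 0.20, "other"),     # high but unstable
        (0.50, 0.12, 0.02, "other"),     # open but aseasonal
    ])
    def test_threshold_rules(self, mean, acv, mcv, expected):
        assert self._classify(mean, acv, mcv) == expected

    @given(st.floats(0, 1), st.floats(0, 0.5), st.floats(0, 0.5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_exhaustive_and_exclusive(self, mean, acv, mcv):
        assert self._classify(mean, acv, mcv) in {"forest", "grassy", "other"}

    def test_normalisation_by_domain_maximum(self):
        prof = classify_vegetation(np.array([0.9, 0.45]), np.array([0.02, 0.2]),
                                   np.array([0.01, 0.2]), normalise=True)
        assert prof.mean_norm[0] == pytest.approx(1.0)
        assert prof.veg_class[0] == "forest"
        assert prof.veg_class[1] == "grassy"


class TestTreeLossFraction:
    def test_total_loss(self):
        assert tree_loss_fraction(np.array([0.5]), np.array([0.5])) == 1.0

    def test_no_loss(self):
        assert tree_loss_fraction(np.array([0.0]), np.array([0.5])) == 0.0

    def test_weighted_example(self):
        f = tree_loss_fraction(np.array([0.1, 0.0]), np.array([0.5, 0.5]))
        assert f == pytest.approx(0.1)

    def test_zero_baseline_is_missing(self):
        assert np.isnan(tree_loss_fraction(np.array([0.0]), np.array([0.0])))

    def test_split_recombination_invariance(self):
        rng = np.random.default_rng(0)
        cover = rng.uniform(0.1, 0.9, 50)
        loss = cover * rng.uniform(0, 0.5, 50)
        whole = tree_loss_fraction(loss, cover)
        left = np.arange(50) < 20
        combined = (loss[left].sum() + loss[~left].sum()) / (cover[left].sum() + cover[~left].sum())
        assert whole == pytest.approx(combined, abs=1e-12)


class TestAnomalyRatio:
    @pytest.mark.parametrize("subset, baseline, expected", [
        (0.10, 0.05, 2.0), (0.05, 0.05, 1.0)])
    def test_examples(self, subset, baseline, expected):
        assert anomaly_ratio(subset, baseline) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            anomaly_ratio(0.1, 0.0)


class TestSummarizeDegradation:
    def _uniform_inputs(self, n=40):
        labels = np.tile([1, 2], n // 2)
        region = np.array(["focal", "continental"] * (n // 2), dtype=object)
        veg = np.array(["forest", "grassy"] * (n // 2), dtype=object)
        cover = np.full(n, 0.5)
        loss = np.full(n, 0.05)
        pop = np.full(n, 30.0)
        return labels, region, veg, cover, loss, pop

    def test_uniform_fields_unit_ratios(self):
        summary = summarize_degradation(*self._uniform_inputs())
        present = summary.dropna(subset=["tree_loss_anomaly"])
        np.testing.assert_allclose(present.tree_loss_anomaly, 1.0)
        np.testing.assert_allclose(present.population_ratio, 1.0)

    def test_all_tropics_baseline_exactly_one(self):
        labels, region, veg, cover, loss, pop = self._uniform_inputs()
        loss = loss * np.linspace(0.2, 1.8, len(loss))
        summary = summarize_degradation(labels, region, veg, cover, loss, pop)
        base = summary[(summary.regime == "all") & (summary.region == "all")
                       & (summary.veg_class == "all")]
        assert base.tree_loss_anomaly.iloc[0] == 1.0

    def test_all_class_row_is_cover_weighted_combination(self):
        labels, region, veg, cover, loss, pop = self._uniform_inputs()
        rng = np.random.default_rng(1)
        cover = rng.uniform(0.2, 0.8, len(cover))
        loss = cover * rng.uniform(0, 0.3, len(loss))
        summary = summarize_degradation(labels, region, veg, cover, loss, pop)
        sel = summary[(summary.regime == 1) & (summary.region == "focal")]
        allrow = sel[sel.veg_class == "all"].iloc[0]
        m = (labels == 1) & (region == "focal")
        assert allrow.tree_loss_fraction == pytest.approx(
            loss[m].sum() / cover[m].sum())

    def test_empty_strata_present_as_missing(self):
        labels, region, veg, cover, loss, pop = self._uniform_inputs()
        summary = summarize_degradation(labels, region, veg, cover, loss, pop)
        row = summary[(summary.regime == 1) & (summary.region == "other")
                      & (summary.veg_class == "all")]
        assert len(row) == 1 and row.n_cells.iloc[0] == 0


class TestEnvironmentRecovery:
    def test_null_anomaly_recovered_near_one(self):
        grid = make_grid(23, 23)   # ~500 cells
        _, truth = generate_fire_archive(grid, years=3, seed=9)
        env = generate_environment(grid, truth, n_years=3)
        frac = {}
        for cls in ("forest", "grassy"):
            m = truth.veg_class == cls
            frac[cls] = tree_loss_fraction(env.tree_loss[m], env.tree_cover[m])
        base = tree_loss_fraction(env.tree_loss, env.tree_cover)
        for cls in frac:
            assert anomaly_ratio(frac[cls], base) == pytest.approx(1.0, abs=0.1)

    def test_forest_ndvi_meets_thresholds_by_construction(self):
        grid = make_grid(15, 15)
        _, truth = generate_fire_archive(grid, years=5, seed=2)
        env = generate_environment(grid, truth, n_years=5)
        stats = ndvi_statistics(env.ndvi)
        norm_mean = stats["ndvi_mean"] / stats["ndvi_mean"].max()
        forest = truth.veg_class == "forest"
        assert (norm_mean[forest] > 0.80).all()
        assert (stats.loc[forest, "ndvi_annual_cv"] < 0.08).all()

    def test_planted_classes_recovered_from_ndvi(self):
        grid = make_grid(15, 15)
        _, truth = generate_fire_archive(grid, years=5, seed=2)
        env = generate_environment(grid, truth, n_years=5)
        stats = ndvi_statistics(env.ndvi)
        prof = classify_vegetation(stats["ndvi_mean"].to_numpy(),
                                   stats["ndvi_annual_cv"].to_numpy(),
                                   stats["ndvi_monthly_cv"].to_numpy())
        agreement = (prof.veg_class == truth.veg_class).mean()
        assert agreement >= 0.95
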