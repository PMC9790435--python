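"""Synthetic-tropics generator: determinism, planted truth, invariants."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from fireregimes import make_grid
from fireregimes.characteristics import (CHARACTERISTIC_COLUMNS,
                                         characteristics_table,
                                         normalise_characteristics)
from fireregimes.grid import GridSpec, block_regions
from fireregimes.synthetic import (EVENT_FLOOR_KM2, RegimeArchetype,
                                   default_archetypes, generate_environment,
                                   generate_fire_archive)


def _clim(total, months):
    c = np.zeros(12)
    c[list(months)] = total / len(months)
    return c


class TestGridSpec:
    def test_block_regions_contiguous(self):
        labels = block_regions(10, 10, (0.2, 0.4, 0.4))
        changes = sum(labels[i] != labels[i + 1] for i in range(99))
        assert changes == 2   # exactly two boundaries: contiguous blocks

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 5, 1.0, np.array([], dtype=object))
        with pytest.raises(ValueError):
            GridSpec(1, 2, 1.0, np.array(["focal", "mars"], dtype=object))


class TestGenerateFireArchive:
    def test_bit_identical_regeneration(self):
        grid = make_grid(8, 8)
        s1, t1 = generate_fire_archive(grid, years=4, seed=17)
        s2, t2 = generate_fire_archive(grid, years=4, seed=17)
        np.testing.assert_array_equal(s1.burned_area, s2.burned_area)
        np.testing.assert_array_equal(s1.fire_count, s2.fire_count)
        np.testing.assert_array_equal(t1.regime_label, t2.regime_label)

    def test_different_seed_differs(self):
        grid = make_grid(8, 8)
        s1, _ = generate_fire_archive(grid, years=4, seed=17)
        s2, _ = generate_fire_archive(grid, years=4, seed=18)
        assert not np.array_equal(s1.burned_area, s2.burned_area)

    def test_nlsf_cells_have_zero_series(self):
        grid = make_grid(10, 10)
        series, truth = generate_fire_archive(grid, years=4, seed=1,
                                              nlsf_fraction=0.5)
        nlsf = truth.regime_label == 0
        assert nlsf.any()
        assert series.burned_area[nlsf].sum() == 0.0

    def test_zero_climatology_archetype_is_nlsf_equivalent(self):
        grid = make_grid(5, 5)
        arch = RegimeArchetype(1, np.zeros(12))
        series, truth = generate_fire_archive(grid, [arch], years=3, seed=0,
                                              nlsf_fraction=0.0)
        assert series.burned_area.sum() == 0.0
        assert (truth.regime_label == 1).all()   # label planted even without fire

    def test_noise_free_climatology_identity(self):
        grid = make_grid(6, 6)
        archs = [RegimeArchetype(1, _clim(6.0, [0, 1, 2]), mean_fire_size=1.0),
                 RegimeArchetype(2, _clim(9.0, [6, 7, 8]), mean_fire_size=1.5)]
        series, truth = generate_fire_archive(grid, archs, years=4, seed=0,
                                              nlsf_fraction=0.0, noise=False)
        clim = series.burned_area.mean(axis=1)
        for label, arch in zip((1, 2), archs):
            cells = truth.regime_label == label
            expected = np.broadcast_to(arch.climatology, (cells.sum(), 12))
            np.testing.assert_allclose(clim[cells], expected, atol=1e-12)

    def test_realized_interannual_cv_near_target(self):
        # 200 cells, 2 archetypes, CV target 0.3
        grid = make_grid(10, 20)
        archs = [RegimeArchetype(1, _clim(20.0, [1, 2, 3]), cv_year=0.3,
                                 mean_fire_size=1.0, fire_size_cv=0.2),
                 RegimeArchetype(2, _clim(60.0, [6, 7, 8]), cv_year=0.3,
                                 mean_fire_size=2.0, fire_size_cv=0.2)]
        # idiosyncratic mode: each cell draws its own year multipliers, so
        # averaging per-cell CV estimates over ~100 cells per regime pins
        # the realized value
        series, truth = generate_fire_archive(grid, archs, years=14, seed=1,
                                              nlsf_fraction=0.0,
                                              shared_interannual=False)
        annual = series.burned_area.sum(axis=2)
        for label in (1, 2):
            cells = annual[truth.regime_label == label]
            cvs = cells.std(axis=1, ddof=1) / cells.mean(axis=1)
            assert cvs.mean() == pytest.approx(0.3, abs=0.1)

    def test_all_events_at_or_above_floor(self):
        grid = make_grid(8, 8)
        series, _ = generate_fire_archive(grid, years=4, seed=3)
        assert (series.events["size_km2"] >= EVENT_FLOOR_KM2).all()

    def test_burned_area_never_exceeds_cell_area(self):
        grid = make_grid(8, 8, cell_area=40.0)
        series, _ = generate_fire_archive(grid, years=4, seed=3)
        assert series.burned_area.max() <= 40.0 + 1e-9

    def test_regional_archetype_weights_respected(self):
        grid = make_grid(10, 10)
        archs = default_archetypes()
        weights = {"focal": np.array([1.0, 1.0, 1.0, 1.0, 0.0])}
        _, truth = generate_fire_archive(grid, archs, years=3, seed=5,
                                         region_weights=weights)
        focal = grid.region_mask("focal")
        assert 5 not in set(truth.regime_label[focal])
        assert 5 in set(truth.regime_label[~focal])

    @pytest.mark.parametrize("kwargs", [
        {"years": 2}, {"nlsf_fraction": 1.0}, {"archetypes": []}])
    def test_invalid_inputs_rejected(self, kwargs):
        grid = make_grid(3, 3)
        with pytest.raises(ValueError):
            generate_fire_archive(grid, seed=0, **{"years": 3, **kwargs})

    def test_planted_separation_silhouette(self):
        # default archetypes satisfy the design conditions (year CVs <= 0.3,
        # >= 3x total burned-area spacing), so planted regimes separate
        # cleanly in normalised characteristic space
        grid = make_grid(15, 15)
        series, truth = generate_fire_archive(grid, years=14, seed=1)
        chars = characteristics_table(series)
        nlsf = chars["is_nlsf"].to_numpy()
        normed, _ = normalise_characteristics(chars, domain=~nlsf)
        sil = silhouette_score(normed.loc[~nlsf, CHARACTERISTIC_COLUMNS],
                               truth.regime_label[~nlsf])
        assert sil > 0.5


class TestGenerateEnvironment:
    def test_deterministic(self):
        grid = make_grid(6, 6)
        _, truth = generate_fire_archive(grid, years=3, seed=4)
        e1 = generate_environment(grid, truth, n_years=3)
        e2 = generate_environment(grid, truth, n_years=3)
        np.testing.assert_array_equal(e1.ndvi, e2.ndvi)
        np.testing.assert_array_equal(e1.tree_loss, e2.tree_loss)

    def test_precipitation_consistent_with_fire_generator(self):
        # both generators derive precipitation from the same seed path,
        # so the planted fire-rainfall coupling refers to the same field
        from fireregimes.synthetic import generate_precipitation
        grid = make_grid(6, 6)
        _, truth = generate_fire_archive(grid, years=3, seed=4)
        env = generate_environment(grid, truth, n_years=3)
        direct = generate_precipitation(grid, truth.regime_label,
                                        truth.archetypes, 24 + 36, seed=4)
        np.testing.assert_array_equal(env.precip, direct)

    def test_mismatched_truth_rejected(self):
        grid = make_grid(6, 6)
        _, truth = generate_fire_archive(grid, years=3, seed=4)
        with pytest.raises(ValueError):
            generate_environment(make_grid(3, 3), truth)

    def test_climate_summary_columns(self):
        grid = make_grid(6, 6)
        _, truth = generate_fire_archive(grid, years=3, seed=4)
        env = generate_environment(grid, truth, n_years=3)
        assert list(env.climate.columns) == ["temp_mean", "temp_cv",
                                             "precip_annual", "precip_cv"]
        assert (env.climate["precip_annual"] > 0).all()
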