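"""Distance metrics against the all-pairs oracle; extent and change rules."""

import numpy as np
import pandas as pd
import pytest

from fragmatrix.grids import (MATRIX, NODATA, SUITABLE, BinaryHabitatMap,
                              FootprintRaster)
from fragmatrix.landscape_metrics import (CENTER_TO_BOUNDARY, MetricsConfig,
                                          UndefinedMetricError,
                                          assemble_features,
                                          fragmentation_degree, hfp_change,
                                          hfp_extent, isolation_degree,
                                          proportion_suitable)

from conftest import brute_force_mean_distance, random_binary_map


class TestDistanceOracle:
    @pytest.mark.parametrize("seed", range(40))
    def test_equals_brute_force_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(3, 13))
        m = random_binary_map(rng, size, p_suitable=float(rng.uniform(0.2, 0.8)))
        assert fragmentation_degree(m) == pytest.approx(
            brute_force_mean_distance(m.suitable, m.matrix), rel=1e-9)
        assert isolation_degree(m) == pytest.approx(
            brute_force_mean_distance(m.matrix, m.suitable), rel=1e-9)

    def test_center_block_fixture(self, center_block_map):
        # 3x3 suitable core: 8 border pixels at distance 1, centre at 2
        assert fragmentation_degree(center_block_map) == pytest.approx(10 / 9)
        assert isolation_degree(center_block_map) == pytest.approx(
            brute_force_mean_distance(center_block_map.matrix,
                                      center_block_map.suitable))

    def test_single_suitable_pixel(self):
        grid = np.full((3, 3), MATRIX, dtype=np.uint8)
        grid[1, 1] = SUITABLE
        assert fragmentation_degree(BinaryHabitatMap(grid)) == pytest.approx(1.0)

    def test_checkerboard_isolation_is_one(self):
        grid = np.indices((6, 6)).sum(axis=0) % 2
        m = BinaryHabitatMap(grid.astype(np.uint8))
        assert isolation_degree(m) == pytest.approx(1.0)

    def test_pixel_size_scale_equivariance(self, center_block_map):
        doubled = BinaryHabitatMap(center_block_map.grid, pixel_size=2.0)
        assert fragmentation_degree(doubled) == pytest.approx(
            2 * fragmentation_degree(center_block_map))

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        m = random_binary_map(rng, 9)
        mirrored = BinaryHabitatMap(m.grid[:, ::-1].copy())
        assert isolation_degree(m) == pytest.approx(isolation_degree(mirrored))
        assert fragmentation_degree(m) == pytest.approx(
            fragmentation_degree(mirrored))

    def test_center_to_boundary_convention(self):
        grid = np.full((3, 3), MATRIX, dtype=np.uint8)
        grid[1, 1] = SUITABLE
        cfg = MetricsConfig(distance_convention=CENTER_TO_BOUNDARY)
        assert fragmentation_degree(BinaryHabitatMap(grid), cfg) == \
            pytest.approx(0.5)

    def test_range_boundary_as_edge(self):
        grid = np.full((5, 5), SUITABLE, dtype=np.uint8)
        grid[0, :] = NODATA
        m = BinaryHabitatMap(grid)
        with pytest.raises(UndefinedMetricError):
            fragmentation_degree(m)  # no matrix, boundary not edge
        cfg = MetricsConfig(treat_range_boundary_as_edge=True)
        assert fragmentation_degree(m, cfg) == pytest.approx(
            brute_force_mean_distance(m.suitable, ~m.in_range))

    def test_undefined_when_region_empty(self):
        all_suitable = BinaryHabitatMap(
            np.full((4, 4), SUITABLE, dtype=np.uint8))
        with pytest.raises(UndefinedMetricError):
            isolation_degree(all_suitable)
        all_matrix = BinaryHabitatMap(np.full((4, 4), MATRIX, dtype=np.uint8))
        with pytest.raises(UndefinedMetricError):
            fragmentation_degree(all_matrix)


class TestFootprintMetrics:
    def test_zero_footprint_zero_extent(self, center_block_map, uniform_footprint):
        assert hfp_extent(center_block_map, uniform_footprint(0), "MATRIX") == 0.0

    def test_threshold_is_inclusive(self, center_block_map, uniform_footprint):
        # a footprint of exactly 3 counts as high pressure ("3 or above")
        assert hfp_extent(center_block_map, uniform_footprint(3), "MATRIX") == 1.0

    def test_counting(self, center_block_map):
        grid = np.zeros((5, 5), dtype=np.int16)
        matrix_idx = np.argwhere(center_block_map.matrix)
        for r, c in matrix_idx[:4]:
            grid[r, c] = 5
        hfp = FootprintRaster(grid)
        assert hfp_extent(center_block_map, hfp, "MATRIX") == pytest.approx(4 / 16)

    def test_extent_non_increasing_in_threshold(self, center_block_map):
        rng = np.random.default_rng(0)
        hfp = FootprintRaster(rng.integers(0, 51, (5, 5)).astype(np.int16))
        extents = [hfp_extent(center_block_map, hfp, "MATRIX",
                              MetricsConfig(hfp_threshold=t))
                   for t in range(0, 51, 5)]
        assert all(a >= b for a, b in zip(extents, extents[1:]))

    def test_change_zero_when_epochs_identical(self, center_block_map,
                                               uniform_footprint):
        hfp = uniform_footprint(7)
        assert hfp_change(center_block_map, hfp, hfp, "MATRIX") == 0.0

    def test_all_decreases_discarded(self, center_block_map):
        h2000 = FootprintRaster(np.full((5, 5), 10, dtype=np.int16), epoch=2000)
        h2013 = FootprintRaster(np.full((5, 5), 1, dtype=np.int16), epoch=2013)
        assert hfp_change(center_block_map, h2000, h2013, "MATRIX") == 0.0

    def test_single_cell_crossing_threshold(self):
        grid = np.full((2, 5), MATRIX, dtype=np.uint8)
        m = BinaryHabitatMap(grid)
        g2000 = np.full((2, 5), 2, dtype=np.int16)
        g2013 = g2000.copy()
        g2013[0, 0] = 5
        change = hfp_change(m, FootprintRaster(g2000),
                            FootprintRaster(g2013, epoch=2013), "MATRIX")
        assert change == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_change_never_negative(self, seed):
        rng = np.random.default_rng(seed)
        m = random_binary_map(rng, 8)
        a = FootprintRaster(rng.integers(0, 51, (8, 8)).astype(np.int16))
        b = FootprintRaster(rng.integers(0, 51, (8, 8)).astype(np.int16),
                            epoch=2013)
        assert hfp_change(m, a, b, "MATRIX") >= 0.0
        assert hfp_change(m, a, b, "SUITABLE") >= 0.0


class TestProportionSuitable:
    def test_extremes_and_counting(self):
        assert proportion_suitable(BinaryHabitatMap(
            np.full((4, 4), SUITABLE, dtype=np.uint8))) == 1.0
        assert proportion_suitable(BinaryHabitatMap(
            np.full((4, 4), MATRIX, dtype=np.uint8))) == 0.0
        grid = np.full((5, 5), MATRIX, dtype=np.uint8)
        grid[:3, :3] = SUITABLE
        assert proportion_suitable(BinaryHabitatMap(grid)) == pytest.approx(0.36)

    def test_nodata_not_counted(self):
        grid = np.full((4, 4), SUITABLE, dtype=np.uint8)
        grid[0, :] = NODATA
        grid[1, :2] = MATRIX
        assert proportion_suitable(BinaryHabitatMap(grid)) == pytest.approx(10 / 12)


class TestAssembleFeatures:
    def _metrics(self):
        return pd.DataFrame({
            "species_id": ["a", "b", "c"],
            "frag_mean_edge_distance": [1.0, 2.0, 3.0],
            "isolation_mean_distance": [0.5, 0.6, 0.7],
        })

    def _traits(self):
        return pd.DataFrame({
            "species_id": ["a", "b", "c"],
            "body_mass": [10.0, 20.0, 30.0],
            "gestation_length": [30.0, np.nan, 90.0],
        })

    def test_identity_join(self):
        out = assemble_features(self._metrics(),
                                self._traits().fillna(60.0))
        assert len(out) == 3
        assert list(out["frag_mean_edge_distance"]) == [1.0, 2.0, 3.0]

    def test_missing_trait_drops_species(self, caplog):
        out = assemble_features(self._metrics(), self._traits())
        assert list(out["species_id"]) == ["a", "c"]

    def test_species_without_metrics_dropped(self):
        out = assemble_features(self._metrics().iloc[:2], self._traits().fillna(0))
        assert list(out["species_id"]) == ["a", "b"]
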