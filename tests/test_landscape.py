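"""Raster ingestion, patch labeling and edge-to-edge distances."""

import numpy as np
import pytest

from fragcap.landscape import (
    DistanceMatrix,
    HabitatGrid,
    filter_patches,
    label_patches,
    min_edge_distances,
    patch_table,
    read_habitat_grid,
    write_ascii_grid,
    write_distance_csv,
)

from conftest import brute_force_min_distances, flood_fill_label, random_grid


class TestReadHabitatGrid:
    def test_ascii_grid_round_trip(self, tmp_path):
        grid = HabitatGrid(
            cells=np.array([[1, 1, 0], [0, 0, 0], [0, 1, 1]]),
            cell_size_km=2.0,
            origin=(10.0, 20.0),
        )
        path = tmp_path / "map.asc"
        write_ascii_grid(grid, path)
        back = read_habitat_grid(path)
        assert back.habitat_cells == 4
        assert back.cell_size_km == 2.0
        assert back.origin == (10.0, 20.0)
        np.testing.assert_array_equal(back.cells, grid.cells)

    def test_all_zero_grid_is_legal(self):
        grid = read_habitat_grid(np.zeros((4, 4)))
        assert grid.habitat_cells == 0

    def test_tiff_round_trip_matches_source(self, tmp_path):
        import tifffile

        rng = np.random.default_rng(42)
        data = (rng.random((20, 30)) < 0.4).astype(np.uint8)
        path = tmp_path / "map.tif"
        tifffile.imwrite(path, data)
        grid = read_habitat_grid(path, cell_size_km=1.0)
        np.testing.assert_array_equal(grid.cells, data)

    def test_tiff_requires_explicit_cell_size(self, tmp_path):
        import tifffile

        path = tmp_path / "map.tif"
        tifffile.imwrite(path, np.ones((2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="cell_size_km"):
            read_habitat_grid(path)

    def test_habitat_values_select_coding(self):
        grid = read_habitat_grid(np.array([[2, 1], [0, 2]]), habitat_values={2})
        assert grid.habitat_cells == 2

    @pytest.mark.parametrize(
        "bad", [np.empty((0, 3)), np.zeros((2, 2, 2))], ids=["empty", "multiband"]
    )
    def test_invalid_rasters_rejected(self, bad):
        with pytest.raises(ValueError):
            read_habitat_grid(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_habitat_grid(tmp_path / "nope.asc")

    def test_nonpositive_cell_size_rejected(self):
        with pytest.raises(ValueError):
            HabitatGrid(cells=np.ones((2, 2)), cell_size_km=0.0)


class TestLabelPatches:
    def test_two_patch_example(self, small_grid):
        patches = label_patches(small_grid, connectivity=4)
        assert patches.n_patches == 2
        np.testing.assert_allclose(patches.areas_km2, [2.0, 2.0])

    @pytest.mark.parametrize("connectivity,expected_n", [(4, 2), (8, 1)])
    def test_diagonal_adjacency(self, connectivity, expected_n):
        grid = HabitatGrid(cells=np.array([[1, 0], [0, 1]]))
        patches = label_patches(grid, connectivity=connectivity)
        assert patches.n_patches == expected_n
        if expected_n == 1:
            assert patches.areas_km2[0] == 2.0

    def test_bad_connectivity(self, small_grid):
        with pytest.raises(ValueError):
            label_patches(small_grid, connectivity=6)

    def test_empty_grid_yields_zero_patches(self):
        patches = label_patches(HabitatGrid(cells=np.zeros((3, 3))))
        assert patches.n_patches == 0
        assert patches.total_area_km2 == 0.0

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(5))
    def test_partition_matches_flood_fill_oracle(self, seed, connectivity):
        grid = random_grid(seed, shape=(50, 50), p=0.4)
        patches = label_patches(grid, connectivity=connectivity)
        expected = flood_fill_label(grid.cells.astype(bool), connectivity)
        got = [
            frozenset(map(tuple, patches.patch_cells(int(pid)))) for pid in patches.patch_ids
        ]
        assert set(got) == set(expected)

    def test_areas_sum_to_habitat_area(self):
        grid = random_grid(3, shape=(40, 40), p=0.35, cell_size_km=0.5)
        patches = label_patches(grid)
        assert patches.total_area_km2 == pytest.approx(grid.habitat_area_km2, abs=0)

    def test_ids_ordered_by_decreasing_area_with_row_major_ties(self):
        # two 2-cell patches: the one whose first cell scans earlier gets id 1
        grid = HabitatGrid(cells=np.array([[0, 0, 1], [1, 0, 1], [1, 0, 0]]))
        patches = label_patches(grid, connectivity=4)
        assert patches.labels[0, 2] == 1  # first cell (0,2) beats (1,0)
        assert patches.labels[1, 0] == 2

    def test_single_cell_patch_is_its_own_boundary(self):
        grid = HabitatGrid(cells=np.array([[0, 0], [1, 0]]))
        patches = label_patches(grid)
        np.testing.assert_array_equal(patches.boundary_cells[0], [[1, 0]])

    def test_labeling_idempotent(self):
        grid = random_grid(11, shape=(30, 30))
        patches = label_patches(grid, connectivity=8)
        again = label_patches(HabitatGrid(cells=patches.to_mask()), connectivity=8)
        np.testing.assert_array_equal(again.labels, patches.labels)

    def test_filter_patches_drops_small_and_renumbers(self):
        grid = HabitatGrid(cells=np.array([[1, 1, 0, 1], [1, 1, 0, 0]]))
        patches = label_patches(grid, connectivity=4)
        kept = filter_patches(patches, min_area_km2=2.0)
        assert kept.n_patches == 1
        np.testing.assert_allclose(kept.areas_km2, [4.0])
        assert kept.labels.max() == 1


class TestMinEdgeDistances:
    def test_axis_aligned_separation(self):
        grid = HabitatGrid(cells=np.array([[1, 0, 0, 1]]))
        patches = label_patches(grid, connectivity=4)
        d = min_edge_distances(patches)
        assert d.values[0, 1] == pytest.approx(3.0)

    def test_diagonal_neighbors_distance(self):
        grid = HabitatGrid(cells=np.array([[1, 0], [0, 1]]))
        patches = label_patches(grid, connectivity=4)
        d = min_edge_distances(patches)
        assert d.values[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_cell_size_scales_distances(self):
        grid = HabitatGrid(cells=np.array([[1, 0, 1]]), cell_size_km=2.5)
        d = min_edge_distances(label_patches(grid, connectivity=4))
        assert d.values[0, 1] == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        grid = random_grid(seed + 100, shape=(40, 40), p=0.3)
        patches = label_patches(grid, connectivity=8)
        d = min_edge_distances(patches)
        expected = brute_force_min_distances(patches)
        np.testing.assert_allclose(d.values, expected, atol=1e-12)

    def test_distance_bounded_by_centroid_distance_for_convex_patches(self):
        # the centroid bound holds for convex patches (for concave
        # interlocking shapes centroids can sit closer than any edge pair);
        # single-cell patches make it exact, rectangles keep a margin
        rng = np.random.default_rng(7)
        cells = np.zeros((30, 30), dtype=np.uint8)
        anchors = rng.choice(100, size=12, replace=False)  # stride-3 lattice
        cells[3 * (anchors // 10), 3 * (anchors % 10)] = 1
        patches = label_patches(HabitatGrid(cells=cells), connectivity=8)
        d = min_edge_distances(patches).values
        cents = patches.centroids_km()
        cd = np.sqrt(((cents[:, None] - cents[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d, cd, atol=1e-9)  # exact for 1-cell patches

        cells = np.zeros((10, 12), dtype=np.uint8)
        cells[1:4, 1:5] = 1  # two separated rectangles
        cells[6:9, 7:11] = 1
        patches = label_patches(HabitatGrid(cells=cells), connectivity=8)
        d = min_edge_distances(patches).values
        cents = patches.centroids_km()
        assert d[0, 1] <= np.hypot(*(cents[0] - cents[1])) + 1e-9

    def test_bridging_two_patches_never_increases_distance_to_third(self):
        # three patches in a row; bridging the outer pair leaves the middle
        # patch no farther from the merged entity than it was from either part
        grid = HabitatGrid(
            cells=np.array([[1, 0, 1, 0, 1], [0, 0, 0, 0, 0], [0, 0, 0, 0, 0]])
        )
        patches = label_patches(grid, connectivity=4)
        d_before = min_edge_distances(patches).values
        bridged = grid.cells.copy()
        bridged[1, 0:3] = 1  # bridge patches at (0,0) and (0,2) from below
        merged = label_patches(HabitatGrid(cells=bridged), connectivity=4)
        assert merged.n_patches == 2
        d_after = min_edge_distances(merged).values
        assert d_after[0, 1] <= min(d_before[0, 1], d_before[1, 2]) + 1e-12

    def test_empty_patchset_rejected(self):
        patches = label_patches(HabitatGrid(cells=np.zeros((2, 2))))
        with pytest.raises(ValueError):
            min_edge_distances(patches)

    def test_distance_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(values=np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            DistanceMatrix(values=np.array([[1.0]]))  # nonzero diagonal


class TestExports:
    def test_patch_table_columns_and_centroids(self):
        grid = HabitatGrid(cells=np.array([[1, 1], [0, 0]]))
        tab = patch_table(label_patches(grid, connectivity=4))
        assert list(tab.columns) == [
            "patch_id", "area_km2", "n_cells", "centroid_x_km", "centroid_y_km",
        ]
        assert tab.loc[0, "n_cells"] == 2
        assert tab.loc[0, "centroid_x_km"] == pytest.approx(1.0)  # between the two cells
        assert tab.loc[0, "centroid_y_km"] == pytest.approx(1.5)  # top row, y up

    def test_distance_csv_round_trip(self, tmp_path):
        import pandas as pd

        grid = HabitatGrid(cells=np.array([[1, 0, 1]]))
        patches = label_patches(grid, connectivity=4)
        d = min_edge_distances(patches)
        path = tmp_path / "d.csv"
        write_distance_csv(d, patches, path)
        back = pd.read_csv(path, index_col="patch_id")
        np.testing.assert_allclose(back.values, d.values)
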