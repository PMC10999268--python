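import math

import numpy as np
import pytest

from biomeshift import (
    SENTINEL,
    GridGeometry,
    ScenarioSpec,
    biome_centroid,
    build_area_vector,
    centroid_step,
    centroid_track,
    label_patches,
    make_scenario,
    non_adjacent_fraction,
    overlap_proportion,
)
from biomeshift.errors import BiomeAbsentError, DegenerateCentroidError

from conftest import make_grid, random_scheme_grid
from oracle_utils import flood_fill_patches


class TestOverlap:
    def test_identical_grids_give_one(self, geom_small, scheme, areas_small):
        grid = random_scheme_grid(np.random.default_rng(0), geom_small, scheme)
        out = overlap_proportion(grid, grid, areas_small)
        assert set(out) == set(grid.present_codes())
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_half_overlap_toy(self, geom_half_row):
        areas = build_area_vector(geom_half_row)
        prev = make_grid(geom_half_row, [[1, 1, 2, 2]])
        curr = make_grid(geom_half_row, [[2, 1, 1, 2]], label="2020-2040")
        out = overlap_proportion(curr, prev, areas)
        assert out[1] == pytest.approx(0.5)
        assert out[2] == pytest.approx(0.5)

    def test_new_biome_scores_zero(self, geom_half_row):
        areas = build_area_vector(geom_half_row)
        prev = make_grid(geom_half_row, [[1, 1, 1, 1]])
        curr = make_grid(geom_half_row, [[1, 1, 1, 9]], label="2020-2040")
        assert overlap_proportion(curr, prev, areas)[9] == 0.0

    def test_absent_biomes_omitted(self, geom_half_row):
        areas = build_area_vector(geom_half_row)
        prev = make_grid(geom_half_row, [[1, 1, 2, 2]])
        curr = make_grid(geom_half_row, [[1, 1, 1, 1]], label="2020-2040")
        assert 2 not in overlap_proportion(curr, prev, areas)


class TestNonAdjacent:
    def test_unchanged_grid_is_zero(self, geom_small, scheme, areas_small):
        grid = random_scheme_grid(np.random.default_rng(1), geom_small, scheme)
        out = non_adjacent_fraction(grid, grid, areas_small)
        assert all(v == 0.0 for v in out.values())

    def test_isolated_appearance_counts_area_share(self, geom_small, areas_small):
        prev_codes = np.zeros(geom_small.shape, dtype=np.int16)
        prev_codes[0, 0] = 3
        curr_codes = np.zeros(geom_small.shape, dtype=np.int16)
        curr_codes[0, 0] = 3
        curr_codes[5, 10] = 3  # far from row 0
        prev = make_grid(geom_small, prev_codes)
        curr = make_grid(geom_small, curr_codes, label="2020-2040")
        w = areas_small.as_grid()
        expected = w[5, 10] / (w[0, 0] + w[5, 10])
        out = non_adjacent_fraction(curr, prev, areas_small, wrap=False)
        assert out[3] == pytest.approx(expected)

    def test_diagonal_neighbour_depends_on_connectivity(self, geom_small,
                                                        areas_small):
        prev_codes = np.zeros(geom_small.shape, dtype=np.int16)
        prev_codes[4, 4] = 3
        curr_codes = np.zeros(geom_small.shape, dtype=np.int16)
        curr_codes[5, 5] = 3  # touches (4,4) only diagonally
        prev = make_grid(geom_small, prev_codes)
        curr = make_grid(geom_small, curr_codes, label="2020-2040")
        out8 = non_adjacent_fraction(curr, prev, areas_small, connectivity=8)
        out4 = non_adjacent_fraction(curr, prev, areas_small, connectivity=4)
        assert out8[3] == 0.0
        assert out4[3] == pytest.approx(1.0)

    def test_wrap_connects_across_meridian(self, geom_small, areas_small):
        prev_codes = np.zeros(geom_small.shape, dtype=np.int16)
        prev_codes[4, 0] = 3
        curr_codes = np.zeros(geom_small.shape, dtype=np.int16)
        curr_codes[4, geom_small.n_lon - 1] = 3
        prev = make_grid(geom_small, prev_codes)
        curr = make_grid(geom_small, curr_codes, label="2020-2040")
        assert non_adjacent_fraction(curr, prev, areas_small, wrap=True)[3] == 0.0
        assert non_adjacent_fraction(curr, prev, areas_small, wrap=False)[3] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_by_one_minus_overlap(self, geom_small, scheme, areas_small,
                                          seed):
        rng = np.random.default_rng(seed)
        prev = random_scheme_grid(rng, geom_small, scheme)
        curr = random_scheme_grid(rng, geom_small, scheme, label="2020-2040")
        overlap = overlap_proportion(curr, prev, areas_small)
        for conn in (4, 8):
            nonadj = non_adjacent_fraction(curr, prev, areas_small,
                                           connectivity=conn)
            for code, far in nonadj.items():
                assert far <= 1.0 - overlap[code] + 1e-12


class TestPatches:
    def test_uniform_grid_single_patch(self, geom_small, grid_factory):
        grid = grid_factory(geom_small, np.full(geom_small.shape, 4, dtype=int))
        assert label_patches(grid).counts == {4: 1}

    def test_two_separated_blocks(self, geom_small, grid_factory):
        codes = np.zeros(geom_small.shape, dtype=int)
        codes[1:3, 2:4] = 7
        codes[6:8, 10:12] = 7
        grid = grid_factory(geom_small, codes)
        labeling = label_patches(grid)
        assert labeling.counts[7] == 2
        cells = labeling.patch_cells(7)
        assert sorted(len(c) for c in cells) == [4, 4]

    def test_block_across_antimeridian(self, geom_small, grid_factory):
        codes = np.zeros(geom_small.shape, dtype=int)
        codes[4:6, 0] = 9
        codes[4:6, geom_small.n_lon - 1] = 9
        grid = grid_factory(geom_small, codes)
        assert label_patches(grid, wrap=True).counts[9] == 1
        assert label_patches(grid, wrap=False).counts[9] == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("wrap", [True, False])
    def test_agrees_with_flood_fill_oracle(self, connectivity, wrap):
        rng = np.random.default_rng(connectivity * 10 + wrap)
        geom = GridGeometry(n_lat=20, n_lon=20, lat_step=4, lon_step=18,
                            origin=(38.0, -171.0))
        for _ in range(25):
            codes = rng.choice([SENTINEL, 1, 2, 3], size=(20, 20))
            grid = make_grid(geom, codes)
            labeling = label_patches(grid, connectivity, wrap)
            for code in grid.present_codes():
                expected = flood_fill_patches(grid.codes == code, connectivity,
                                              wrap)
                assert labeling.counts[code] == expected

    def test_patches_partition_and_are_mutually_separated(self, geom_small,
                                                          grid_factory):
        rng = np.random.default_rng(42)
        codes = rng.choice([SENTINEL, 1, 2], size=geom_small.shape)
        grid = grid_factory(geom_small, codes)
        labeling = label_patches(grid, connectivity=4, wrap=False)
        for code in grid.present_codes():
            cells = labeling.patch_cells(code)
            union = set().union(*cells)
            assert union == {tuple(c) for c in np.argwhere(grid.codes == code)}
            assert sum(len(c) for c in cells) == len(union)  # disjoint
            for a_idx in range(len(cells)):
                for b_idx in range(a_idx + 1, len(cells)):
                    for (i, j) in cells[a_idx]:
                        for (k, l) in cells[b_idx]:
                            assert abs(i - k) + abs(j - l) > 1


class TestCentroid:
    def test_single_cell(self):
        geom = GridGeometry(n_lat=2, n_lon=4, lat_step=10, lon_step=10,
                            origin=(10.0, 20.0))
        codes = np.zeros((2, 4), dtype=int)
        codes[0, 0] = 5
        grid = make_grid(geom, codes)
        lat, lon = biome_centroid(grid, 5, build_area_vector(geom))
        assert lat == pytest.approx(10.0, abs=1e-9)
        assert lon == pytest.approx(20.0, abs=1e-9)

    def test_symmetric_pair_on_equator(self):
        geom = GridGeometry(n_lat=1, n_lon=36, lat_step=1, lon_step=10,
                            origin=(0.0, -175.0))
        codes = np.full((1, 36), SENTINEL, dtype=int)
        j_west = 16  # lon -15
        j_east = 19  # lon +15
        codes[0, j_west] = codes[0, j_east] = 4
        grid = make_grid(geom, codes)
        lat, lon = biome_centroid(grid, 4, build_area_vector(geom))
        assert lat == pytest.approx(0.0, abs=1e-9)
        assert lon == pytest.approx(0.0, abs=1e-9)

    def test_three_cells_on_parallel_match_vector_mean(self):
        geom = GridGeometry(n_lat=1, n_lon=36, lat_step=1, lon_step=10,
                            origin=(30.0, -175.0))
        codes = np.full((1, 36), SENTINEL, dtype=int)
        cols = [0, 5, 11]
        for j in cols:
            codes[0, j] = 2
        grid = make_grid(geom, codes)
        areas = build_area_vector(geom)
        lat, lon = biome_centroid(grid, 2, areas)
        # independent 3-D mean (equal weights on one parallel)
        lons = np.radians(geom.lon_centers[cols])
        phi = math.radians(30.0)
        x = np.mean(np.cos(phi) * np.cos(lons))
        y = np.mean(np.cos(phi) * np.sin(lons))
        z = math.sin(phi)
        norm = math.sqrt(x * x + y * y + z * z)
        assert lat == pytest.approx(math.degrees(math.asin(z / norm)), abs=1e-9)
        assert lon == pytest.approx(math.degrees(math.atan2(y, x)), abs=1e-9)

    def test_absent_biome_raises(self, geom_small, grid_factory, areas_small):
        grid = grid_factory(geom_small, np.zeros(geom_small.shape, dtype=int))
        with pytest.raises(BiomeAbsentError):
            biome_centroid(grid, 17, areas_small)

    def test_antipodal_balance_is_degenerate(self):
        geom = GridGeometry(n_lat=1, n_lon=2, lat_step=1, lon_step=180,
                            origin=(0.0, 0.0))
        grid = make_grid(geom, [[3, 3]])
        with pytest.raises(DegenerateCentroidError):
            biome_centroid(grid, 3, build_area_vector(geom))

    def test_full_grid_matches_independent_summation(self, geom_small,
                                                     grid_factory, areas_small):
        codes = np.full(geom_small.shape, SENTINEL, dtype=int)
        codes[:4, :7] = 1  # asymmetric block so the mean vector is non-zero
        grid = grid_factory(geom_small, codes)
        lat, lon = biome_centroid(grid, 1, areas_small)
        sel = grid.terrestrial
        w = np.where(sel, areas_small.as_grid(), 0.0)
        lats = np.radians(np.broadcast_to(
            geom_small.lat_centers[:, None], geom_small.shape))
        lons = np.radians(np.broadcast_to(
            geom_small.lon_centers[None, :], geom_small.shape))
        x = (w * np.cos(lats) * np.cos(lons)).sum() / w.sum()
        y = (w * np.cos(lats) * np.sin(lons)).sum() / w.sum()
        z = (w * np.sin(lats)).sum() / w.sum()
        norm = math.sqrt(x * x + y * y + z * z)
        assert lat == pytest.approx(math.degrees(math.asin(z / norm)), abs=1e-9)


class TestGeodesy:
    def test_due_east_on_equator(self):
        dist, bearing = centroid_step((0.0, 0.0), (0.0, 10.0))
        assert bearing == pytest.approx(90.0)

    def test_one_degree_distance(self):
        dist, _ = centroid_step((0.0, 0.0), (0.0, 1.0))
        assert dist == pytest.approx(2 * math.pi * 6371.0 / 360.0, rel=1e-9)
        assert dist == pytest.approx(111.19, abs=0.01)

    def test_identical_points(self):
        assert centroid_step((12.0, 34.0), (12.0, 34.0)) == (0.0, 0.0)

    @pytest.mark.parametrize("target,expected", [
        ((10.0, 0.0), 0.0), ((-10.0, 0.0), 180.0), ((0.0, -10.0), 270.0),
    ])
    def test_cardinal_bearings(self, target, expected):
        _, bearing = centroid_step((0.0, 0.0), target)
        assert bearing == pytest.approx(expected, abs=1e-9)

    def test_bearing_always_in_range(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = (rng.uniform(-89, 89), rng.uniform(-180, 180))
            b = (rng.uniform(-89, 89), rng.uniform(-180, 180))
            dist, bearing = centroid_step(a, b)
            assert dist >= 0.0
            assert 0.0 <= bearing < 360.0


class TestCentroidTrack:
    def drift_series(self):
        # partial longitude coverage so zonal bands have a finite centroid
        geom = GridGeometry(n_lat=180, n_lon=10, lat_step=1.0, lon_step=12.0,
                            origin=(89.5, -54.0))
        spec = ScenarioSpec(geometry=geom, zonal_layout=(25, 10, 21, 11, 26),
                            n_slices=5, drift_deg_per_slice=2.0, seed=0)
        return make_scenario(spec), build_area_vector(geom)

    def test_pure_drift_is_meridional_by_hemisphere(self):
        grids, areas = self.drift_series()
        north = centroid_track(grids, 10, areas)  # northern mid-lat band
        south = centroid_track(grids, 11, areas)  # southern mid-lat band
        for rec in north[1:]:
            assert min(rec.step_bearing_deg, 360 - rec.step_bearing_deg) < 5.0
        for rec in south[1:]:
            assert abs(rec.step_bearing_deg - 180.0) < 5.0

    def test_drift_distance_within_ten_percent(self):
        grids, areas = self.drift_series()
        per_degree = 2 * math.pi * 6371.0 / 360.0
        expected = 2.0 * per_degree
        for rec in centroid_track(grids, 10, areas)[1:]:
            assert rec.step_distance_km == pytest.approx(expected, rel=0.10)

    def test_absent_slice_records_gap(self, geom_half_row):
        areas = build_area_vector(geom_half_row)
        g0 = make_grid(geom_half_row, [[3, 3, 1, 1]], label="2000-2020")
        g1 = make_grid(geom_half_row, [[1, 1, 1, 1]], label="2020-2040")
        g2 = make_grid(geom_half_row, [[3, 1, 1, 1]], label="2040-2060")
        track = centroid_track([g0, g1, g2], 3, areas)
        assert math.isnan(track[1].lat)
        assert not math.isnan(track[2].lat)
        assert math.isnan(track[2].step_distance_km)  # step after a gap

    def test_tiny_step_flagged_low_confidence(self, geom_half_row):
        areas = build_area_vector(geom_half_row)
        g0 = make_grid(geom_half_row, [[3, 3, 1, 1]], label="2000-2020")
        g1 = make_grid(geom_half_row, [[3, 3, 1, 1]], label="2020-2040")
        track = centroid_track([g0, g1], 3, areas)
        assert track[1].step_distance_km == 0.0
        assert track[1].low_confidence_bearing
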