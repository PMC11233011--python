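from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from rapoport import gridding
from rapoport.gridding import (
    EARTH_RADIUS_KM,
    AlbersParams,
    EnvLayerSet,
    Grid,
    PresenceAbsenceMatrix,
    inverse_project,
    project_lonlat,
)

ALBERS = AlbersParams(
    std_parallel_1=17.0, std_parallel_2=45.0, central_meridian=-100.0,
    latitude_of_origin=30.0, false_easting=1000.0, false_northing=2000.0,
)


class TestAlbersProjection:
    def test_central_meridian_maps_to_false_easting(self):
        x, y = project_lonlat(np.array([-100.0]), np.array([35.0]), ALBERS)
        assert x[0] == pytest.approx(1000.0, abs=1e-9)

    def test_equal_area_against_spherical_excess(self):
        """A 1°×1° quadrilateral at 25°N projects to a polygon whose area
        matches R²·Δλ·(sinφ2−sinφ1) within 0.5%."""
        lons = np.linspace(-101.0, -100.0, 50)
        lats = np.linspace(25.0, 26.0, 50)
        ring_lon = np.concatenate(
            [lons, np.full(50, lons[-1]), lons[::-1], np.full(50, lons[0])]
        )
        ring_lat = np.concatenate(
            [np.full(50, lats[0]), lats, np.full(50, lats[-1]), lats[::-1]]
        )
        x, y = project_lonlat(ring_lon, ring_lat, ALBERS)
        from shapely.geometry import Polygon

        projected_area = Polygon(zip(x, y)).area
        spherical = (
            EARTH_RADIUS_KM**2
            * np.radians(1.0)
            * (np.sin(np.radians(26.0)) - np.sin(np.radians(25.0)))
        )
        assert projected_area == pytest.approx(spherical, rel=5e-3)

    def test_forward_inverse_roundtrip(self):
        rng = np.random.default_rng(1)
        lon = rng.uniform(-120, -80, 200)
        lat = rng.uniform(5, 60, 200)
        x, y = project_lonlat(lon, lat, ALBERS)
        lon2, lat2 = inverse_project(x, y, ALBERS)
        np.testing.assert_allclose(lon2, lon, atol=1e-9)
        np.testing.assert_allclose(lat2, lat, atol=1e-9)

    def test_degenerate_parallels_rejected(self):
        bad = AlbersParams(30.0, -30.0, -100.0)
        with pytest.raises(gridding.ProjectionDomainError):
            project_lonlat(np.array([-100.0]), np.array([10.0]), bad)

    def test_pole_rejected(self):
        with pytest.raises(gridding.ProjectionDomainError):
            project_lonlat(np.array([-100.0]), np.array([90.0]), ALBERS)


def rp(species, geom):
    return SimpleNamespace(species=species, geometry=geom)


class TestRasterize:
    def test_square_overlapping_four_cells(self):
        grid = Grid((0, 0), 50.0, 3, 3)
        pam = gridding.rasterize_ranges([rp("A", box(20, 20, 80, 80))], grid)
        assert pam.column("A").sum() == 4

    def test_polygon_inside_one_cell(self):
        grid = Grid((0, 0), 50.0, 3, 3)
        pam = gridding.rasterize_ranges([rp("A", box(10, 10, 40, 40))], grid)
        assert pam.column("A").sum() == 1

    def test_edge_contact_does_not_count(self):
        grid = Grid((0, 0), 50.0, 3, 3)
        # polygon exactly filling cell (0,0): touches neighbours along edges
        pam = gridding.rasterize_ranges([rp("A", box(0, 0, 50, 50))], grid)
        assert pam.column("A").sum() == 1

    def test_empty_range_list_rejected(self):
        grid = Grid((0, 0), 50.0, 3, 3)
        with pytest.raises(ValueError):
            gridding.rasterize_ranges([], grid)

    def test_rasterize_of_cell_union_reproduces_pam_row(self, small_world):
        """Rasterizing the rectangle union of a simulated species' cells
        reproduces its PAM row exactly."""
        cfg, (tree, grid, env, pam, occ, truth) = small_world
        from shapely.ops import unary_union

        for sp in pam.species[:4]:
            cells = np.flatnonzero(pam.column(sp))
            union = unary_union([grid.cell_box(i) for i in cells])
            re_pam = gridding.rasterize_ranges([rp(sp, union)], grid)
            np.testing.assert_array_equal(re_pam.column(sp), pam.column(sp))


class TestSpeciesSummaries:
    def make_pam(self):
        grid = Grid((0, 0), 50.0, 3, 2)  # y centers 25, 75, 125
        m = np.zeros((6, 2), dtype=bool)
        m[[0, 1, 2], 0] = True  # A: 3 cells (rows 0,0,1)
        m[5, 1] = True  # B: single cell, row 2
        return PresenceAbsenceMatrix(grid, ["A", "B"], m)

    def test_range_size_in_km2(self):
        pam = self.make_pam()
        sizes = gridding.species_range_size(pam)
        assert sizes["A"] == pytest.approx(7500.0)
        assert sizes["B"] == pytest.approx(2500.0)

    def test_range_size_conservation(self):
        pam = self.make_pam()
        assert gridding.species_range_size(pam).sum() == \
            pytest.approx(pam.matrix.sum() * 2500.0)

    def test_midpoint_mean_of_cell_latitudes(self):
        pam = self.make_pam()
        mid = gridding.species_midpoint(pam)
        # A occupies two cells at y=25 and one at y=75 (L-shape)
        assert mid["A"] == pytest.approx((25 + 25 + 75) / 3)
        assert mid["B"] == pytest.approx(125.0)

    def test_unknown_species_keyerror(self):
        pam = self.make_pam()
        with pytest.raises(KeyError):
            pam.column("Z")

    def test_env_means_within_range(self):
        pam = self.make_pam()
        layer = np.array([[10.0, 20.0], [30.0, np.nan], [5.0, 7.0]])
        env = EnvLayerSet(pam.grid, {"t": layer})
        means = gridding.summarize_env_cross_species(pam, env)
        assert means.loc["A", "t"] == pytest.approx((10 + 20 + 30) / 3)
        assert means.loc["B", "t"] == pytest.approx(7.0)

    def test_env_mean_skips_masked_cells(self):
        grid = Grid((0, 0), 50.0, 1, 2)
        m = np.ones((2, 1), dtype=bool)
        pam = PresenceAbsenceMatrix(grid, ["A"], m)
        env = EnvLayerSet(grid, {"t": np.array([[np.nan, 42.0]])})
        assert gridding.summarize_env_cross_species(pam, env).loc["A", "t"] \
            == pytest.approx(42.0)

    def test_constant_layer_gives_constant_means(self):
        pam = self.make_pam()
        env = EnvLayerSet(pam.grid, {"t": np.full((3, 2), 3.5)})
        means = gridding.summarize_env_cross_species(pam, env)
        assert (means["t"] == 3.5).all()


class TestAssemblageTable:
    def make(self, log_sizes, matrix):
        grid = Grid((0, 0), 50.0, 1, matrix.shape[0])
        pam = PresenceAbsenceMatrix(
            grid, [f"s{i}" for i in range(matrix.shape[1])], matrix
        )
        st = pd.DataFrame(
            {"log_range_size": log_sizes},
            index=[f"s{i}" for i in range(matrix.shape[1])],
        )
        return gridding.assemblage_median_log_range(pam, st)

    def test_odd_count_median(self):
        out = self.make([1.0, 2.0, 3.0], np.ones((1, 3), dtype=bool))
        assert out["median_log_range"].iloc[0] == pytest.approx(2.0)

    def test_even_count_median_mean_of_central_pair(self):
        out = self.make([1.0, 2.0, 3.0, 10.0], np.ones((1, 4), dtype=bool))
        assert out["median_log_range"].iloc[0] == pytest.approx(2.5)

    def test_single_species_cell(self):
        m = np.array([[True], [False]])
        out = self.make([1.7], m)
        assert len(out) == 1
        assert out["median_log_range"].iloc[0] == pytest.approx(1.7)

    def test_unoccupied_sites_excluded(self):
        m = np.array([[True, True], [False, False], [True, False]])
        out = self.make([1.0, 2.0], m)
        assert set(out.index) == {0, 2}

    def test_median_bounded_and_permutation_invariant(self, small_world):
        cfg, (tree, grid, env, pam, occ, truth) = small_world
        st = gridding.build_species_table(pam)
        a = gridding.assemblage_median_log_range(pam, st)
        lo, hi = st["log_range_size"].min(), st["log_range_size"].max()
        assert (a["median_log_range"] >= lo - 1e-12).all()
        assert (a["median_log_range"] <= hi + 1e-12).all()
        perm = list(reversed(pam.species))
        pam2 = PresenceAbsenceMatrix(
            grid, perm, pam.matrix[:, [pam.species.index(s) for s in perm]]
        )
        b = gridding.assemblage_median_log_range(pam2, st)
        np.testing.assert_allclose(
            a["median_log_range"], b["median_log_range"]
        )


class TestResample:
    def test_constant_layer(self):
        fine = Grid((0, 0), 10.0, 10, 10)
        coarse = Grid((0, 0), 50.0, 2, 2)
        out = gridding.resample_env_to_grid(np.full((10, 10), 2.0), fine, coarse)
        np.testing.assert_allclose(out, 2.0)

    def test_block_mean(self):
        fine = Grid((0, 0), 25.0, 2, 2)
        coarse = Grid((0, 0), 50.0, 1, 1)
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = gridding.resample_env_to_grid(vals, fine, coarse)
        assert out[0, 0] == pytest.approx(2.5)

    def test_linear_gradient_recovered_at_cell_centers(self):
        fine = Grid((0, 0), 5.0, 40, 40)
        coarse = Grid((0, 0), 50.0, 4, 4)
        fx, fy = fine.cell_centroids()
        vals = (0.3 * fx).reshape(40, 40)
        out = gridding.resample_env_to_grid(vals, fine, coarse)
        cx = coarse.x_centers()
        for j in range(4):
            assert abs(out[0, j] - 0.3 * cx[j]) <= 0.3 * 5.0 / 2
    def test_no_overlap_rejected(self):
        fine = Grid((10000, 10000), 10.0, 4, 4)
        coarse = Grid((0, 0), 50.0, 2, 2)
        with pytest.raises(ValueError):
            gridding.resample_env_to_grid(np.ones((4, 4)), fine, coarse)


class TestVelocity:
    def test_closed_form_uniform_gradient(self):
        # gradient 0.01 °C/km along x, ΔT = 1 °C over 21000 yr
        grid = Grid((0, 0), 50.0, 5, 5)
        xs, _ = grid.cell_centroids()
        now = (0.01 * xs).reshape(5, 5)
        past = now - 1.0
        v = gridding.climate_change_velocity(now, past, 21000.0, 50.0)
        np.testing.assert_allclose(v, (1 / 21000) / 0.01, rtol=1e-12)

    def test_no_change_gives_zero(self):
        grid = Grid((0, 0), 50.0, 4, 4)
        xs, _ = grid.cell_centroids()
        now = (0.01 * xs).reshape(4, 4)
        v = gridding.climate_change_velocity(now, now, 21000.0, 50.0)
        np.testing.assert_allclose(v, 0.0)

    def test_flat_field_masked_never_negative(self):
        now = np.full((4, 4), 10.0)
        past = now - 1.0
        v = gridding.climate_change_velocity(now, past, 21000.0, 50.0)
        assert np.isnan(v).all()

    def test_misaligned_layers_rejected(self):
        with pytest.raises(ValueError):
            gridding.climate_change_velocity(
                np.ones((3, 3)), np.ones((4, 4)), 21000.0, 50.0
            )


class TestAsciiGridIO:
    def test_roundtrip_with_nodata(self, tmp_path):
        grid = Grid((100.0, 200.0), 50.0, 3, 4)
        vals = np.arange(12, dtype=float).reshape(3, 4)
        vals[1, 2] = np.nan
        path = tmp_path / "layer.asc"
        gridding.write_ascii_grid(path, vals, grid)
        back, grid2 = gridding.read_ascii_grid(path)
        np.testing.assert_allclose(back, vals)
        assert grid2.origin == grid.origin
        assert grid2.cell_size == grid.cell_size
        assert (grid2.n_rows, grid2.n_cols) == (3, 4)

    def test_header_is_standard_esri(self, tmp_path):
        grid = Grid((0, 0), 50.0, 2, 2)
        path = tmp_path / "g.asc"
        gridding.write_ascii_grid(path, np.ones((2, 2)), grid)
        head = path.read_text().splitlines()[:6]
        keys = [line.split()[0].lower() for line in head]
        assert keys == ["ncols", "nrows", "xllcorner", "yllcorner",
                        "cellsize", "nodata_value"]
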