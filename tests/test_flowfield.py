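"""Grid data model, I/O round trips, regridding, mirroring, bulk hydraulics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eelpass.flowfield import (DepthField, GridFormatError, GridSpec,
                               VelocityField, hydraulic_summary,
                               mirror_spanwise, read_grid, regrid_linear,
                               temporal_average, write_grid)


def make_field(speed, cell=5e-4, **meta):
    arr = np.asarray(speed, dtype=float)
    return VelocityField(grid=GridSpec(*arr.shape, cell), speed=arr, meta=meta)


class TestGridSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(n_streamwise=1, n_spanwise=3),
        dict(n_streamwise=3, n_spanwise=0),
        dict(n_streamwise=3, n_spanwise=3, cell_size=0.0),
    ])
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)

    def test_centroids_at_cell_centres(self):
        g = GridSpec(2, 2, 1.0)
        x, z = g.centroids()
        assert x[0, 0] == 0.5 and x[1, 0] == 1.5 and z[0, 1] == 1.5


class TestGridIO:
    def test_round_trip_identity(self, tmp_path):
        f = make_field(np.full((3, 3), 0.30), angle_deg=11.0, q_m2s=3.33e-3)
        f.speed[1, 1] = np.nan
        path = tmp_path / "f.grid"
        write_grid(f, path)
        g = read_grid(path)
        assert g.grid == f.grid
        assert g.sample_height == f.sample_height
        np.testing.assert_array_equal(np.isnan(g.speed), np.isnan(f.speed))
        np.testing.assert_array_equal(g.speed[~np.isnan(g.speed)],
                                      f.speed[~np.isnan(f.speed)])
        assert g.meta["angle_deg"] == 11.0
        # text representation is a fixed point of write . read
        write_grid(g, tmp_path / "g.grid")
        assert (tmp_path / "g.grid").read_text() == path.read_text()

    def test_nodata_mask_count_preserved(self, tmp_path):
        f = make_field(np.full((4, 3), 0.2))
        f.speed[2, 1] = np.nan
        write_grid(f, tmp_path / "f.grid")
        assert read_grid(tmp_path / "f.grid").nodata.sum() == 1

    def test_missing_row_is_parse_error(self, tmp_path):
        f = make_field(np.full((4, 3), 0.2))
        path = tmp_path / "f.grid"
        write_grid(f, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(GridFormatError, match="rows"):
            read_grid(path)

    def test_ragged_row_error_names_line(self, tmp_path):
        f = make_field(np.full((3, 3), 0.2))
        path = tmp_path / "f.grid"
        write_grid(f, path)
        lines = path.read_text().splitlines()
        lines[-1] = "0.2 0.2"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(GridFormatError, match="line"):
            read_grid(path)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            make_field([[0.1, -0.2], [0.1, 0.1]])


class TestRegrid:
    def test_affine_field_reproduced_exactly(self):
        # speed = a + b x + c z is reproduced at every interior node
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, size=(40, 2))
        # corners guarantee the hull covers the grid
        pts = np.vstack([pts, [[0, 0], [0, 1], [1, 0], [1, 1]]])
        speed = 0.1 + 0.2 * pts[:, 0] + 0.05 * pts[:, 1]
        target = GridSpec(8, 8, 0.1)
        f = regrid_linear(np.column_stack([pts, speed]), target)
        x, z = target.centroids()
        inside = ~np.isnan(f.speed)
        assert inside.sum() > 30
        np.testing.assert_allclose(f.speed[inside],
                                   (0.1 + 0.2 * x + 0.05 * z)[inside],
                                   atol=1e-12)

    def test_unit_square_centre_is_half(self):
        # four corners with speeds 0,0,1,1: barycentric interpolation gives
        # speed = x, so the centre node (0.5, 0.5) reads 0.5
        pts = np.array([[0, 0, 0.0], [0, 1, 0.0], [1, 0, 1.0], [1, 1, 1.0]])
        target = GridSpec(3, 3, 1.0 / 3.0)  # centre centroid at (0.5, 0.5)
        f = regrid_linear(pts, target)
        assert f.speed[1, 1] == pytest.approx(0.5)
        x, _ = target.centroids()
        np.testing.assert_allclose(f.speed, x, atol=1e-12)

    def test_sample_on_grid_node_is_exact(self):
        pts = np.array([[0, 0, 0.0], [0, 1, 0.0], [1, 0, 1.0], [1, 1, 1.0],
                        [0.5, 0.5, 0.5]])
        f = regrid_linear(pts, GridSpec(3, 3, 1.0 / 3.0))
        assert f.speed[1, 1] == pytest.approx(0.5)

    def test_outside_hull_is_nodata(self):
        pts = np.array([[0, 0, 0.1], [0, 1, 0.1], [1, 0, 0.1]])
        f = regrid_linear(pts, GridSpec(4, 4, 0.5))  # extends to 2.0
        assert f.nodata.any()

    def test_collinear_points_error(self):
        pts = np.array([[0, 0, 0.1], [0.5, 0.5, 0.1], [1, 1, 0.1]])
        with pytest.raises(ValueError):
            regrid_linear(pts, GridSpec(3, 3, 0.5))


class TestTemporalAverage:
    def test_mean_and_window_selection(self):
        f1 = make_field(np.full((3, 2), 0.2))
        f2 = make_field(np.full((3, 2), 0.4))
        avg = temporal_average([f1, f2], times=[8.5, 9.5], window=(8, 10))
        np.testing.assert_allclose(avg.speed, 0.3)
        # snapshot outside the window is excluded
        avg2 = temporal_average([f1, f2, make_field(np.full((3, 2), 9.9))],
                                times=[8.5, 9.5, 12.0], window=(8, 10))
        np.testing.assert_allclose(avg2.speed, 0.3)

    def test_duplicate_invariance(self):
        f1 = make_field(np.full((3, 2), 0.2))
        f2 = make_field(np.full((3, 2), 0.4))
        once = temporal_average([f1, f2], [8.1, 8.2], (8, 10))
        twice = temporal_average([f1, f2, f1, f2], [8.1, 8.2, 8.3, 8.4], (8, 10))
        np.testing.assert_allclose(once.speed, twice.speed)

    def test_any_nodata_propagates(self):
        f1 = make_field(np.full((3, 2), 0.2))
        f2 = make_field(np.full((3, 2), 0.4))
        f2.speed[1, 1] = np.nan
        avg = temporal_average([f1, f2], [8.0, 9.0], (8, 10))
        assert np.isnan(avg.speed[1, 1]) and not np.isnan(avg.speed[0, 0])

    def test_empty_window_and_grid_mismatch(self):
        f1 = make_field(np.full((3, 2), 0.2))
        with pytest.raises(ValueError):
            temporal_average([f1], [5.0], (8, 10))
        with pytest.raises(ValueError):
            temporal_average([f1, make_field(np.full((4, 2), 0.2))],
                             [8, 9], (8, 10))


class TestMirror:
    def test_doubles_width_and_is_symmetric(self):
        rng = np.random.default_rng(3)
        f = make_field(rng.uniform(0.1, 0.5, size=(6, 4)))
        m = mirror_spanwise(f)
        assert m.grid.n_spanwise == 8
        for j in range(8):
            np.testing.assert_array_equal(m.speed[:, j], m.speed[:, 7 - j])

    def test_left_half_reconstructs(self):
        f = make_field(np.arange(8, dtype=float).reshape(4, 2) / 10)
        m = mirror_spanwise(f)
        np.testing.assert_array_equal(m.speed[:, :2], f.speed)
        m2 = mirror_spanwise(VelocityField(grid=f.grid, speed=m.speed[:, :2]))
        np.testing.assert_array_equal(m2.speed, m.speed)

    def test_single_column(self):
        f = make_field(np.full((3, 1), 0.2))
        m = mirror_spanwise(f)
        np.testing.assert_array_equal(m.speed[:, 0], m.speed[:, 1])


class TestHydraulicSummary:
    def test_validated_case_reynolds(self):
        # published bulk values: U = 0.299 m/s, h = 5.58 mm, nu = 9.6e-7
        f = make_field(np.full((5, 5), 0.299))
        d = DepthField(grid=f.grid, depth=np.full((5, 5), 5.58e-3))
        s = hydraulic_summary(f, d, nu=9.6e-7, stud_diameter=1.48e-2)
        assert round(s.re_depth, -1) == 1740
        assert s.unit_discharge == pytest.approx(0.299 * 5.58e-3)

    @pytest.mark.parametrize("u,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_speeds(self, u, expected):
        f = make_field(np.full((3, 3), u))
        d = DepthField(grid=f.grid, depth=np.ones((3, 3)))
        s = hydraulic_summary(f, d, nu=1.0, stud_diameter=1.0)
        assert s.re_depth == expected and s.re_stud == expected

    @settings(max_examples=25, derandomize=True)
    @given(c=st.floats(0.1, 10.0))
    def test_homogeneous_in_speed(self, c):
        f = make_field(np.full((3, 3), 0.2))
        fc = make_field(np.full((3, 3), 0.2 * c))
        d = DepthField(grid=f.grid, depth=np.full((3, 3), 0.005))
        s1 = hydraulic_summary(f, d, nu=1e-6, stud_diameter=0.01)
        s2 = hydraulic_summary(fc, d, nu=1e-6, stud_diameter=0.01)
        assert s2.re_depth == pytest.approx(c * s1.re_depth)
        assert s2.unit_discharge == pytest.approx(c * s1.unit_discharge)

    def test_all_nodata_errors(self):
        f = make_field(np.full((3, 3), np.nan))
        d = DepthField(grid=f.grid, depth=np.ones((3, 3)))
        with pytest.raises(ValueError):
            hydraulic_summary(f, d, nu=1e-6, stud_diameter=0.01)
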