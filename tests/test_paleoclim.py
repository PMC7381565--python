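"""Anomaly, spatial gradient and change-velocity grids against analytic fields."""

import numpy as np
import pytest

from divpart import (
    ClimateGrid,
    anomaly,
    change_velocity,
    derive_historical,
    gen_paleo_grids,
    multi_model_mean,
    read_ascii_grid,
    spatial_gradient,
    write_ascii_grid,
)
from divpart.paleoclim import RegistrationError


def _grid(values, cellsize=1.0, **kw):
    return ClimateGrid(np.asarray(values, float), cellsize=cellsize, origin=(0.0, 0.0), **kw)


@pytest.fixture()
def planar_pair():
    return gen_paleo_grids(8, 6, 1.0, {"kind": "planar", "a": 0.003, "b": 0.004, "c": 10.0,
                                       "lgm_offset": -4.0})


class TestMultiModelMean:
    def test_identical_grids_identity(self, planar_pair):
        g, _ = planar_pair
        np.testing.assert_allclose(multi_model_mean([g, g]).values, g.values)

    def test_cellwise_mean(self):
        out = multi_model_mean([_grid(np.full((3, 3), 3.0)), _grid(np.full((3, 3), 5.0))])
        np.testing.assert_allclose(out.values, 4.0)

    def test_nodata_propagates(self):
        a = np.full((3, 3), 3.0)
        a[1, 1] = -9999.0
        out = multi_model_mean([_grid(a), _grid(np.full((3, 3), 5.0))])
        assert out.values[1, 1] == out.nodata
        assert out.values[0, 0] == 4.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(RegistrationError):
            multi_model_mean([_grid(np.zeros((3, 3)) + 1), _grid(np.ones((4, 3)))])


class TestAnomaly:
    def test_constant_offset(self, planar_pair):
        cur, lgm = planar_pair
        np.testing.assert_allclose(anomaly(cur, lgm).values, 4.0)

    def test_identical_grids_zero(self, planar_pair):
        cur, _ = planar_pair
        np.testing.assert_allclose(anomaly(cur, cur).values, 0.0)

    def test_antisymmetry(self, planar_pair):
        cur, lgm = planar_pair
        np.testing.assert_allclose(
            anomaly(cur, lgm).values, -anomaly(lgm, cur).values
        )


class TestSpatialGradient:
    def test_constant_grid_zero_interior(self):
        g = spatial_gradient(_grid(np.full((5, 5), 7.0)))
        np.testing.assert_allclose(g.values[1:-1, 1:-1], 0.0)

    def test_planar_field_analytic_magnitude(self, planar_pair):
        cur, _ = planar_pair
        g = spatial_gradient(cur)
        interior = g.values[1:-1, 1:-1]
        np.testing.assert_allclose(interior, 0.005, rtol=1e-10)

    def test_one_dimensional_plane(self):
        cur, _ = gen_paleo_grids(6, 6, 2.0, {"kind": "planar", "a": -0.01, "b": 0.0, "c": 0.0})
        g = spatial_gradient(cur)
        np.testing.assert_allclose(g.values[1:-1, 1:-1], 0.01, rtol=1e-10)

    def test_edges_are_nodata(self, planar_pair):
        g = spatial_gradient(planar_pair[0])
        assert (g.values[0, :] == g.nodata).all()
        assert (g.values[:, -1] == g.nodata).all()

    def test_nodata_neighbor_propagates(self):
        v = np.full((5, 5), 1.0)
        v[2, 1] = -9999.0
        g = spatial_gradient(_grid(v))
        assert g.values[2, 2] == g.nodata  # west neighbor missing

    def test_degree_grid_uses_cos_latitude(self):
        # east-west plane on a degree grid at ~60N: dx shrinks by cos(lat) ~ 0.5
        v = np.tile(np.arange(5, dtype=float), (5, 1))  # +1 unit per cell east
        g = _grid(v, cellsize=1.0, cell_units="deg")
        g = ClimateGrid(v, cellsize=1.0, origin=(0.0, 57.5), cell_units="deg")
        grad = spatial_gradient(g)
        row = 2  # center latitude 60N
        lat = g.row_center_y(row)
        expect = 1.0 / (111.32 * np.cos(np.radians(lat)))
        np.testing.assert_allclose(grad.values[row, 1:-1], expect, rtol=1e-10)


class TestChangeVelocity:
    def test_hand_value(self):
        an = _grid(np.full((3, 3), 4.2))
        gr = _grid(np.full((3, 3), 0.0021))
        v = change_velocity(an, gr)
        np.testing.assert_allclose(v.values, 2000.0, rtol=1e-12)

    def test_zero_anomaly_zero_velocity(self):
        v = change_velocity(_grid(np.zeros((3, 3))), _grid(np.full((3, 3), 0.5)))
        np.testing.assert_allclose(v.values, 0.0)

    def test_flat_gradient_floor(self):
        v = change_velocity(_grid(np.full((3, 3), 2.0)), _grid(np.zeros((3, 3))), floor=0.01)
        np.testing.assert_allclose(v.values, 200.0)

    def test_velocity_scales_with_anomaly(self):
        gr = _grid(np.full((3, 3), 0.01))
        v1 = change_velocity(_grid(np.full((3, 3), 1.0)), gr)
        v2 = change_velocity(_grid(np.full((3, 3), 2.0)), gr)
        np.testing.assert_allclose(v2.values, 2 * v1.values)

    def test_bad_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            change_velocity(_grid(np.zeros((3, 3))), _grid(np.zeros((3, 3))), floor=0.0)


class TestGenPaleoGrids:
    def test_planar_identical_pair_zero_anomaly(self):
        cur, lgm = gen_paleo_grids(5, 5, 1.0, {"kind": "planar", "lgm_offset": 0.0})
        np.testing.assert_allclose(anomaly(cur, lgm).values, 0.0)

    def test_noisy_planar_deterministic(self):
        a = gen_paleo_grids(6, 7, 1.0, {"kind": "noisy-planar"}, seed=7)
        b = gen_paleo_grids(6, 7, 1.0, {"kind": "noisy-planar"}, seed=7)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="stencil"):
            gen_paleo_grids(2, 5, 1.0)


class TestDeriveHistorical:
    def _grids(self):
        cur_t, lgm_t = gen_paleo_grids(10, 10, 1.0, {"a": 0.003, "b": 0.004, "lgm_offset": -4.2})
        cur_p, lgm_p = gen_paleo_grids(
            10, 10, 1.0, {"a": 0.1, "b": 0.2, "c": 800.0, "lgm_offset": -50.0, "variable": "MAP"}
        )
        return cur_t, lgm_t, cur_p, lgm_p

    def test_planar_chain_closed_form(self):
        hv = derive_historical(*self._grids(), sites=[("A", 5.2, 5.7)])[0]
        assert hv.TA == pytest.approx(4.2, abs=1e-12)
        assert hv.PA == pytest.approx(50.0, abs=1e-12)
        # velocity = anomaly / planar gradient magnitude, logged base 10
        assert hv.raw_TCV == pytest.approx(4.2 / 0.005, rel=1e-10)
        assert hv.TCV == pytest.approx(np.log10(4.2 / 0.005), rel=1e-10)
        assert hv.raw_PCV == pytest.approx(50.0 / np.hypot(0.1, 0.2), rel=1e-10)

    def test_log_identity_and_2000km_value(self):
        assert np.log10(2000.0) == pytest.approx(3.3010, abs=1e-4)
        assert np.log10(1.0) == 0.0

    def test_site_outside_extent_named(self):
        with pytest.raises(LookupError, match="far_site"):
            derive_historical(*self._grids(), sites=[("far_site", 99.0, 5.0)])

    def test_edge_site_nodata_velocity(self):
        # edge cells have no gradient stencil -> velocity nodata there
        with pytest.raises(ValueError, match="edge"):
            derive_historical(*self._grids(), sites=[("edge", 0.2, 5.0)])

    def test_translation_consistency(self):
        grids = self._grids()
        hv1 = derive_historical(*grids, sites=[("A", 5.2, 5.7)])[0]
        shifted = [g.like(g.values, origin=(100.0, 200.0)) for g in grids]
        hv2 = derive_historical(*shifted, sites=[("A", 105.2, 205.7)])[0]
        assert hv1.TA == pytest.approx(hv2.TA)
        assert hv1.raw_TCV == pytest.approx(hv2.raw_TCV)

    def test_nonpositive_velocity_needs_offset(self):
        cur_t, lgm_t = gen_paleo_grids(5, 5, 1.0, {"lgm_offset": 0.0})  # zero anomaly
        cur_p, lgm_p = gen_paleo_grids(5, 5, 1.0, {"lgm_offset": -50.0, "variable": "MAP"})
        with pytest.raises(ValueError, match="offset"):
            derive_historical(cur_t, lgm_t, cur_p, lgm_p, sites=[("A", 2.5, 2.5)])
        hv = derive_historical(
            cur_t, lgm_t, cur_p, lgm_p, sites=[("A", 2.5, 2.5)], log_offset=1.0
        )[0]
        assert hv.TCV == pytest.approx(0.0)  # log10(0 + 1)


class TestAsciiGridIO:
    def test_round_trip(self, tmp_path, planar_pair):
        cur, _ = planar_pair
        path = tmp_path / "t.asc"
        write_ascii_grid(cur, path)
        back = read_ascii_grid(path)
        np.testing.assert_array_equal(back.values, cur.values)
        assert back.cellsize == cur.cellsize
        assert back.origin == cur.origin
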