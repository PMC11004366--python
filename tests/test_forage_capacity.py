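"""Biomass partitioning, yield conversion, carrying capacity, aggregation."""

import numpy as np
import pytest
import xarray as xr

from grazecap import (
    CapacityParams,
    aggregate_windows,
    npp_to_yield,
    partition_fraction,
    yield_to_capacity,
)
from grazecap.forage_capacity import G_M2_TO_KG_HM2, default_utilization
from grazecap.grids import make_raster, make_series, monthly_index


@pytest.mark.parametrize(
    "mat,expected",
    [
        (0.0, 0.171),  # intercept of the partition function
        (10.0, 0.300),
        (-20.0, 0.0),  # clamped: linear form goes negative below -13.26 degC
        (100.0, 1.0),  # clamped above
    ],
)
def test_partition_fraction_values(mat, expected):
    assert partition_fraction(mat) == pytest.approx(expected, abs=1e-12)


def test_partition_fraction_vectorized():
    out = partition_fraction(np.array([0.0, 10.0]))
    np.testing.assert_allclose(out, [0.171, 0.300])


class TestYield:
    def _series(self, value, n=1):
        time = monthly_index(2000, 2000)[:n]
        return make_series(np.full((n, 1, 1), float(value)), time)

    def test_known_arithmetic(self):
        """NPP 47 gC/m2 at 0 degC -> 17.1 g/m2 = 171 kg/hm2."""
        yld = npp_to_yield(self._series(47.0), self._series(0.0))
        assert yld.values[0, 0, 0] == pytest.approx(17.1)
        assert yld.values[0, 0, 0] * G_M2_TO_KG_HM2 == pytest.approx(171.0)

    def test_zero_npp_zero_yield(self):
        assert npp_to_yield(self._series(0.0), self._series(12.0)).values.sum() == 0.0

    def test_unit_view_identity(self, rng):
        time = monthly_index(2001, 2001)
        npp = make_series(rng.uniform(0, 80, (12, 4, 4)), time)
        mat = make_series(rng.uniform(-10, 25, (12, 4, 4)), time)
        yld = npp_to_yield(npp, mat)
        np.testing.assert_array_equal(yld.values * 10.0, yld.values * G_M2_TO_KG_HM2)


class TestCapacity:
    def _grid(self, agb_kg, type_code=1, shape=(3, 3)):
        agb = make_raster(np.full(shape, float(agb_kg)))
        types = xr.DataArray(np.full(shape, type_code, dtype=np.int32), dims=("y", "x"))
        return agb, types

    def test_known_arithmetic(self):
        """1000 kg/hm2 at Gi=0.5, L=1.8, D=365 -> ~0.761 SU/hm2."""
        agb, types = self._grid(1000.0)
        params = CapacityParams(utilization={1: 0.5})
        grid = yield_to_capacity(agb, types, params, days=365.0)
        assert grid.cc.values[0, 0] == pytest.approx(500.0 / 657.0)

    def test_zero_biomass_zero_capacity(self):
        agb, types = self._grid(0.0)
        grid = yield_to_capacity(agb, types, CapacityParams(utilization={1: 0.5}), days=365.0)
        np.testing.assert_array_equal(grid.cc.values, 0.0)

    def test_linear_in_utilization(self):
        agb, types = self._grid(800.0)
        lo = yield_to_capacity(agb, types, CapacityParams(utilization={1: 0.3}), days=100.0)
        hi = yield_to_capacity(agb, types, CapacityParams(utilization={1: 0.6}), days=100.0)
        np.testing.assert_allclose(hi.cc.values, 2.0 * lo.cc.values)

    def test_missing_utilization_rate_rejected(self):
        agb, types = self._grid(500.0, type_code=3)
        with pytest.raises(KeyError, match="type"):
            yield_to_capacity(agb, types, CapacityParams(utilization={1: 0.5}), days=365.0)

    def test_non_grassland_masked(self):
        agb = make_raster(np.full((2, 2), 100.0))
        types = xr.DataArray(np.array([[0, 1], [1, -1]], dtype=np.int32), dims=("y", "x"))
        grid = yield_to_capacity(agb, types, CapacityParams(utilization={1: 0.5}), days=30.0)
        assert np.isnan(grid.cc.values[0, 0]) and np.isnan(grid.cc.values[1, 1])
        assert np.isfinite(grid.cc.values[0, 1])

    def test_chain_linearity_against_scalar_recompute(self, rng):
        """CC is linear in NPP: spot-check 100 random pixels end to end."""
        time = monthly_index(2002, 2002)
        npp_vals = rng.uniform(0, 60, (12, 10, 10))
        mat_vals = rng.uniform(-5, 25, (12, 10, 10))
        npp = make_series(npp_vals, time)
        mat = make_series(mat_vals, time)
        types = xr.DataArray(rng.integers(1, 6, (10, 10)).astype(np.int32), dims=("y", "x"))
        params = CapacityParams(utilization=default_utilization())
        yld = npp_to_yield(npp, mat)
        grid = aggregate_windows(yld, types, params, "year")[0]
        for _ in range(100):
            iy, ix = rng.integers(0, 10, 2)
            fanpp = np.clip(0.171 + 0.0129 * mat_vals[:, iy, ix], 0, 1)
            agb_kg = (npp_vals[:, iy, ix] * fanpp / 0.47).sum() * 10.0
            gi = default_utilization()[int(types.values[iy, ix])]
            expect = agb_kg * gi / (1.8 * 365.0)
            assert grid.cc.values[iy, ix] == pytest.approx(expect, rel=1e-12)


class TestAggregation:
    @pytest.fixture()
    def monthly_yield(self, rng):
        time = monthly_index(2000, 2001)
        vals = rng.uniform(0, 30, (24, 6, 6))
        types = xr.DataArray(np.ones((6, 6), dtype=np.int32), dims=("y", "x"))
        return make_series(vals, time), types

    def test_annual_window_sums_months(self, monthly_yield):
        yld, types = monthly_yield
        params = CapacityParams(utilization={1: 0.5})
        years = aggregate_windows(yld, types, params, "year")
        assert [g.window for g in years] == ["2000", "2001"]
        np.testing.assert_allclose(
            years[0].agb_g_m2.values, yld.values[:12].sum(axis=0), rtol=1e-12
        )
        # bookkeeping identity: CC equals summed yield through the formula
        np.testing.assert_allclose(
            years[0].cc.values,
            years[0].agb_g_m2.values * 10.0 * 0.5 / (1.8 * 365.0),
            rtol=1e-12,
        )

    def test_season_windows_complete(self, monthly_yield):
        yld, types = monthly_yield
        params = CapacityParams(utilization={1: 0.5})
        seasons = aggregate_windows(yld, types, params, "season")
        assert len(seasons) == 10  # 5 windows x 2 years
        growing = [g for g in seasons if "growing_season" in g.window]
        assert all(g.days == params.season_days for g in growing)

    def test_type_partition_conserves_total(self, rng):
        time = monthly_index(2003, 2003)
        vals = rng.uniform(0, 20, (12, 8, 8))
        types = xr.DataArray(rng.integers(1, 6, (8, 8)).astype(np.int32), dims=("y", "x"))
        yld = make_series(vals, time)
        params = CapacityParams(utilization=default_utilization())
        grid = aggregate_windows(yld, types, params, "year")[0]
        summary = grid.type_summary(types, pixel_area_hm2=100.0)
        total_from_types = summary["total_yield_t"].sum()
        scene_total = np.nansum(grid.agb_g_m2.values) * 100.0 / 100.0
        assert total_from_types == pytest.approx(scene_total, rel=1e-12)

    def test_incomplete_window_rejected(self, monthly_yield):
        yld, types = monthly_yield
        short = yld.isel(time=slice(0, 18))
        with pytest.raises(ValueError, match="incomplete"):
            aggregate_windows(short, types, CapacityParams(utilization={1: 0.5}), "year")

    def test_invalid_scheme_rejected(self, monthly_yield):
        yld, types = monthly_yield
        with pytest.raises(ValueError, match="scheme"):
            aggregate_windows(yld, types, CapacityParams(utilization={1: 0.5}), "decade")


def test_capacity_params_validation():
    with pytest.raises(ValueError, match="utilization"):
        CapacityParams(utilization={1: 1.5})
    with pytest.raises(ValueError, match="intake"):
        CapacityParams(utilization={1: 0.5}, intake=0.0)
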