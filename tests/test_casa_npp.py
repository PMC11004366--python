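"""CASA light-use-efficiency model: FPAR ramp, stress terms, NPP product."""

import numpy as np
import pytest

from grazecap import CasaParams, compute_apar, compute_epsilon, compute_fpar, compute_npp
from grazecap.casa_npp import precipitation_et_ratio, thornthwaite_pet
from grazecap.grids import make_series, monthly_index


def _flat_series(values, n_months=12, shape=(2, 2)):
    time = monthly_index(2000, 2000)[:n_months]
    arr = np.broadcast_to(np.asarray(values, dtype=float).reshape(-1, 1, 1), (n_months, *shape))
    return make_series(arr.copy(), time)


@pytest.fixture()
def ramp_inputs():
    """NDVI stack spanning a known envelope on a single-type grid."""
    ndvi = _flat_series(np.linspace(0.0, 1.0, 12))
    solar = _flat_series(np.full(12, 100.0))
    return ndvi, solar


class TestFpar:
    def test_linear_ramp_midpoint(self):
        # envelope [0, 1] with an exact midpoint month
        ndvi = _flat_series(np.concatenate([np.linspace(0.0, 1.0, 11), [1.0]]))
        params = CasaParams(fpar_min=0.001, fpar_max=0.95, ndvi_percentile_lo=0, ndvi_percentile_hi=100)
        fpar = compute_fpar(ndvi, params)
        mid = 0.5 * (0.001 + 0.95)
        idx = int(np.flatnonzero(ndvi.values[:, 0, 0] == 0.5)[0])
        assert fpar.values[idx, 0, 0] == pytest.approx(mid, abs=1e-12)
        assert mid == pytest.approx(0.4755)

    def test_ramp_floor_and_ceiling(self, ramp_inputs):
        ndvi, _ = ramp_inputs
        params = CasaParams(ndvi_percentile_lo=20, ndvi_percentile_hi=80)
        fpar = compute_fpar(ndvi, params)
        assert fpar.values.min() == pytest.approx(params.fpar_min)
        assert fpar.values.max() == pytest.approx(params.fpar_max)

    def test_bounded_in_unit_interval(self, default_scene):
        fpar = compute_fpar(default_scene.ndvi_true, CasaParams(), default_scene.grassland_types)
        vals = fpar.values[np.isfinite(fpar.values)]
        assert vals.min() >= 0.0 and vals.max() <= 1.1


class TestApar:
    def test_half_of_solar_times_fpar(self, ramp_inputs):
        ndvi, solar = ramp_inputs
        params = CasaParams()
        apar = compute_apar(ndvi, solar, params)
        fpar = compute_fpar(ndvi, params)
        np.testing.assert_allclose(apar.values, 0.5 * 100.0 * fpar.values)

    def test_zero_solar_gives_zero_apar(self, ramp_inputs):
        ndvi, _ = ramp_inputs
        solar = _flat_series(np.zeros(12))
        apar = compute_apar(ndvi, solar, CasaParams())
        np.testing.assert_array_equal(apar.values, 0.0)

    def test_negative_solar_rejected(self, ramp_inputs):
        ndvi, _ = ramp_inputs
        solar = _flat_series(np.full(12, -1.0))
        with pytest.raises(ValueError, match="negative solar"):
            compute_apar(ndvi, solar, CasaParams())


class TestEpsilon:
    def test_te1_polynomial_at_20C(self):
        """Topt = 20 degC maximizes the quadratic temperature term at 1.0."""
        # constant 20 degC, NDVI peaking in July -> Topt = 20
        temp = _flat_series(np.full(12, 20.0))
        ndvi = _flat_series(np.concatenate([np.linspace(0.1, 0.6, 7), np.linspace(0.55, 0.1, 5)]))
        precip = _flat_series(np.full(12, 50.0))
        solar = _flat_series(np.full(12, 100.0))
        eps, factors = compute_epsilon(
            temp, precip, solar, CasaParams(), ndvi, return_factors=True
        )
        np.testing.assert_allclose(factors["te1"].values, 0.8 + 0.4 - 0.2)

    def test_water_stress_floor_when_fully_dry(self):
        temp = _flat_series(np.full(12, 15.0))
        ndvi = _flat_series(np.linspace(0.1, 0.5, 12))
        precip = _flat_series(np.zeros(12))
        solar = _flat_series(np.full(12, 100.0))
        params = CasaParams(water_stress_floor=0.5)
        _, factors = compute_epsilon(temp, precip, solar, params, ndvi, return_factors=True)
        np.testing.assert_allclose(factors["we"].values, 0.5)

    def test_epsilon_maximum_without_any_stress(self):
        """At Topt with saturated moisture, eps = Te1 * Te2max * eps_max."""
        temp = _flat_series(np.full(12, 20.0))
        ndvi = _flat_series(np.linspace(0.1, 0.5, 12))
        precip = _flat_series(np.full(12, 1e4))  # P >> PET -> E/Ep = 1
        solar = _flat_series(np.full(12, 100.0))
        params = CasaParams()
        eps, factors = compute_epsilon(temp, precip, solar, params, ndvi, return_factors=True)
        te2_max = 1.1814 / ((1 + np.exp(-2.0)) * (1 + np.exp(-3.0)))
        expected = 1.0 * te2_max * 1.0 * params.epsilon_max_default
        np.testing.assert_allclose(eps.values, expected, rtol=1e-12)
        np.testing.assert_allclose(factors["we"].values, 1.0)

    def test_factors_bounded(self, default_scene):
        eps, factors = compute_epsilon(
            default_scene.temperature,
            default_scene.precipitation,
            default_scene.solar_radiation,
            CasaParams(),
            default_scene.ndvi_true,
            default_scene.grassland_types,
            return_factors=True,
        )
        for name in ("te1", "te2", "we"):
            vals = factors[name].values
            vals = vals[np.isfinite(vals)]
            assert vals.min() >= 0.0 and vals.max() <= 1.1, name
        evals = eps.values[np.isfinite(eps.values)]
        assert evals.min() >= 0.0
        assert evals.max() <= CasaParams().epsilon_max_default + 1e-12

    def test_et_ratio_closure_bounded_and_wet_limit(self):
        temp = _flat_series(np.linspace(-5, 25, 12))
        precip = _flat_series(np.full(12, 1e5))
        solar = _flat_series(np.full(12, 100.0))
        ratio = precipitation_et_ratio(temp, precip, solar)
        pet = thornthwaite_pet(temp)
        assert (pet.values >= 0).all()
        warm = pet.values > 0
        np.testing.assert_allclose(ratio.values[warm], 1.0)
        assert ratio.values.min() >= 0.0


class TestNpp:
    def test_product_of_apar_and_epsilon(self):
        apar = _flat_series(np.full(12, 100.0))
        eps = _flat_series(np.full(12, 0.5))
        npp = compute_npp(apar, eps)
        np.testing.assert_allclose(npp.values, 50.0)

    @pytest.mark.parametrize("which", ["apar", "eps"])
    def test_zero_factor_annihilates(self, which):
        apar = _flat_series(np.zeros(12) if which == "apar" else np.full(12, 80.0))
        eps = _flat_series(np.zeros(12) if which == "eps" else np.full(12, 0.4))
        np.testing.assert_array_equal(compute_npp(apar, eps).values, 0.0)

    def test_monotone_in_each_factor(self, rng):
        apar = _flat_series(rng.uniform(10, 200, 12))
        eps = _flat_series(rng.uniform(0.05, 0.5, 12))
        base = compute_npp(apar, eps)
        more = compute_npp(apar + 1.0, eps)
        assert (more.values > base.values).all()
        more_eps = compute_npp(apar, eps + 0.01)
        assert (more_eps.values > base.values).all()

    def test_nonnegative_on_scene(self, default_scene):
        """Full-stack NPP is non-negative and annual means are logged."""
        from grazecap.ndvi_fusion import harmonize_series

        params = CasaParams()
        ndvi = harmonize_series(default_scene.ndvi_a, default_scene.ndvi_b)
        apar = compute_apar(ndvi, default_scene.solar_radiation, params, default_scene.grassland_types)
        eps = compute_epsilon(
            default_scene.temperature,
            default_scene.precipitation,
            default_scene.solar_radiation,
            params,
            ndvi,
            default_scene.grassland_types,
        )
        npp = compute_npp(apar, eps)
        vals = npp.values[np.isfinite(npp.values)]
        assert (vals >= 0).all()
        annual = float(np.nanmean(npp.values)) * 12
        # soft plausibility: arid-steppe annual NPP magnitude
        print(f"scene mean annual NPP = {annual:.1f} gC/m2/yr")
        assert 20.0 < annual < 1000.0
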