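"""Structural properties of the NPP algorithm skeletons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nppeval.algorithms import (
    AlgorithmParams,
    OceanColourInputs,
    compute_npp,
    npp_abpm,
    npp_cafe,
    npp_cbpm,
    npp_vgpm,
    popt_vgpm,
)
from nppeval.errors import ConfigurationError, ValidationError
from nppeval.synthetic import make_ocean_colour_scene

SST_GRID = np.linspace(-2.0, 35.0, 371)

# temperature at which the Eppley exponential equals exactly 1
SST_POPT_ONE = (np.log10(1 / 1.54) + 0.07) / 0.0275


def _inputs(**overrides) -> OceanColourInputs:
    base = dict(
        chl=np.array([0.3]),
        sst=np.array([15.0]),
        par=np.array([40.0]),
        day_length=np.array([12.0]),
        zeu=np.array([50.0]),
        bbp443=np.array([2e-3]),
        aph443=np.array([0.02]),
        kd490=np.array([0.08]),
        mld=np.array([30.0]),
    )
    base.update(overrides)
    return OceanColourInputs(**base)


class TestPopt:
    def test_eppley_constant_temperature_ratio(self):
        """Exponential structure: popt(T+10)/popt(T) is the same for all T."""
        ratios = popt_vgpm(SST_GRID + 10.0, "eppley") / popt_vgpm(SST_GRID, "eppley")
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    @pytest.mark.parametrize("variant", ["eppley", "behrenfeld"])
    def test_non_negative_over_ocean_temperatures(self, variant):
        assert np.all(popt_vgpm(SST_GRID, variant) >= 0)

    def test_eppley_strictly_increasing_behrenfeld_interior_maximum(self):
        """Grid-scan oracle over SST in [-2, 35]."""
        epp = popt_vgpm(SST_GRID, "eppley")
        assert np.all(np.diff(epp) > 0)
        beh = popt_vgpm(SST_GRID, "behrenfeld")
        imax = int(np.argmax(beh))
        assert 0 < imax < SST_GRID.size - 1
        assert beh[imax] > beh[0] and beh[imax] > beh[-1]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            popt_vgpm(np.array([10.0]), "bogus")


class TestVGPM:
    def test_zero_chlorophyll_zero_npp(self):
        assert npp_vgpm(_inputs(chl=np.array([0.0])), AlgorithmParams()) == 0.0

    @given(alpha=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=25)
    def test_exact_linearity_in_chlorophyll(self, alpha):
        params = AlgorithmParams()
        base = npp_vgpm(_inputs(), params)
        scaled = npp_vgpm(_inputs(chl=np.array([0.3 * alpha])), params)
        np.testing.assert_allclose(scaled, alpha * base, rtol=1e-12)

    def test_direct_product_value(self):
        """Chl=1, P_opt=1, DL=12, f(PAR)=1, Zeu=50 multiplies out to 600."""
        params = AlgorithmParams(fpar=lambda par: np.ones_like(np.asarray(par, float)))
        out = npp_vgpm(
            _inputs(chl=np.array([1.0]), sst=np.array([SST_POPT_ONE])), params
        )
        np.testing.assert_allclose(out, 600.0, rtol=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            _inputs(chl=np.array([-1.0]))


class TestCbPM:
    def test_zero_growth_zero_npp(self):
        params = AlgorithmParams(growth_rate=lambda chl, cph, ig, mu_max: np.zeros_like(np.asarray(cph, float)))
        assert npp_cbpm(_inputs(), params, "behrenfeld") == 0.0

    def test_zero_carbon_zero_npp(self):
        # backscatter at the conversion offset: carbon clamps to zero
        assert npp_cbpm(_inputs(bbp443=np.array([3.5e-4])), AlgorithmParams(), "behrenfeld") == 0.0

    def test_backscatter_below_offset_clamps_not_raises(self):
        out = npp_cbpm(_inputs(bbp443=np.array([1e-4])), AlgorithmParams(), "behrenfeld")
        assert out == 0.0

    def test_depth_resolved_matches_surface_product_for_constant_profile(self):
        """With depth-constant carbon and growth, the depth integral must
        reproduce the surface product (with f(PAR)=1) to <=0.1%."""
        const_mu = lambda chl, cph, ig, mu_max: np.broadcast_to(
            0.7, np.broadcast(np.asarray(cph), np.asarray(ig)).shape
        ).copy()
        params = AlgorithmParams(
            growth_rate=const_mu,
            fpar=lambda par: np.ones_like(np.asarray(par, float)),
        )
        inp = _inputs()
        surface = npp_cbpm(inp, params, "behrenfeld")
        integral = npp_cbpm(inp, params, "westberry")
        np.testing.assert_allclose(integral, surface, rtol=1e-3)

    def test_growth_capped_at_mu_max(self):
        from nppeval.algorithms import default_growth_rate

        mu = default_growth_rate(
            chl=np.array([50.0]), cphyto=np.array([1.0]), ig=np.array([5.0]), mu_max=2.0
        )
        assert np.all(mu <= 2.0)


class TestAbPM:
    def test_zero_absorption_zero_npp(self):
        assert npp_abpm(_inputs(aph443=np.array([0.0])), AlgorithmParams()) == 0.0

    def test_zero_par_zero_npp(self):
        assert npp_abpm(_inputs(par=np.array([0.0])), AlgorithmParams()) == 0.0

    def test_identity_product_stub_contract(self):
        params = AlgorithmParams(abpm_inner=lambda a, k, z, p: a * k * z * p)
        inp = _inputs()
        out = npp_abpm(inp, params)
        np.testing.assert_allclose(out, inp.aph443 * inp.kd490 * inp.zeu * inp.par)

    def test_missing_inner_function_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            npp_abpm(_inputs(), AlgorithmParams(abpm_inner=None))


class TestCAFE:
    def test_saturating_limit_and_upper_bound(self):
        params = AlgorithmParams(q_par=100.0, phi_mu_max=0.35, e_k=10.0)
        # E_k/PAR -> infinity: tanh -> 1
        tiny_par = npp_cafe(_inputs(par=np.array([1e-9])), params)
        np.testing.assert_allclose(tiny_par, 100.0 * 0.35, rtol=1e-6)
        for par in (1.0, 10.0, 40.0, 60.0):
            out = npp_cafe(_inputs(par=np.array([par])), params)
            assert out <= 100.0 * 0.35 + 1e-12

    def test_zero_par_handled_as_saturating_limit(self):
        params = AlgorithmParams(q_par=100.0, phi_mu_max=0.5, e_k=10.0)
        out = npp_cafe(_inputs(par=np.array([0.0])), params)
        np.testing.assert_allclose(out, 50.0)

    def test_small_ratio_linear_expansion(self):
        """tanh(x) ~ x within 1% for x <= 0.1."""
        params = AlgorithmParams(q_par=1.0, phi_mu_max=1.0, e_k=1.0)
        for par in (10.0, 20.0, 100.0):
            x = 1.0 / par
            out = float(npp_cafe(_inputs(par=np.array([par])), params)[0])
            assert abs(out - x) / x < 0.01

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValidationError):
            AlgorithmParams(phi_mu_max=1.5)


class TestWarmingDivergence:
    def test_eppley_trend_exceeds_behrenfeld_above_polynomial_optimum(self):
        """On a warming scene with fixed chlorophyll, the exponential
        temperature function keeps raising NPP while the polynomial one
        declines past its optimum."""
        beh = popt_vgpm(SST_GRID, "behrenfeld")
        t_opt = SST_GRID[int(np.argmax(beh))]
        years = np.arange(20)
        sst = t_opt + 1.0 + 0.05 * years  # warming above the optimum
        params_e = AlgorithmParams(popt_variant="eppley")
        params_b = AlgorithmParams(popt_variant="behrenfeld")
        npp_e, npp_b = [], []
        for T in sst:
            inp = _inputs(sst=np.array([T]))
            npp_e.append(float(npp_vgpm(inp, params_e)[0]))
            npp_b.append(float(npp_vgpm(inp, params_b)[0]))
        trend_e = np.polyfit(years, npp_e, 1)[0]
        trend_b = np.polyfit(years, npp_b, 1)[0]
        assert trend_e > 0 > trend_b
        assert trend_e >= trend_b


def test_all_algorithms_non_negative_on_generated_scene(small_grid):
    scene = make_ocean_colour_scene(small_grid, seed=2)
    for name in (
        "eppley-vgpm",
        "behrenfeld-vgpm",
        "behrenfeld-cbpm",
        "westberry-cbpm",
        "lee-abpm",
        "silsbe-cafe",
    ):
        npp = compute_npp(scene, name)
        vals = npp[small_grid.ocean_mask]
        assert np.all(vals[np.isfinite(vals)] >= 0), name
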