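"""Tissue-transport verification: retention-factor arithmetic, the Patlak
exchange against a 50-digit oracle, heat-kernel spreading, conservation,
and the coupled-simulation properties."""

import math
from dataclasses import replace

import mpmath
import numpy as np
import pytest

from braintx.bbbd import AgentTransvascular, SonicationProtocol
from braintx.flow import solve_interstitial_flow
from braintx.phantom import Region, uniform_box_phantom
from braintx.scenarios import ModelBundle
from braintx.transport import (ConcentrationState, NegativeConcentrationError,
                               SpeciesTissueParams, StabilityError,
                               TissueTransport, apparent_coefficients, omega,
                               patlak_flux, simulate)


@pytest.fixture(scope="module")
def free_params():
    return SpeciesTissueParams.free_doxorubicin()


class TestOmega:
    def test_tumour_and_normal_arithmetic(self, free_params):
        # 0.35*4 + 0.55*1*4 + 0.10*0.3 and 0.20*4 + 0.65*4 + 0.15*0.3
        assert omega(free_params, "tumour") == pytest.approx(3.63, rel=1e-12)
        assert omega(free_params, "normal") == pytest.approx(3.445, rel=1e-12)

    def test_no_retention_limit(self):
        p = SpeciesTissueParams(
            name="inert", d_ecs_m2_s={"tumour": 1e-10, "normal": 1e-10},
            sigma={"tumour": 0.0, "normal": 0.0},
            p_ics_ecs=1.0, p_cm_ecs=1.0, k_ecs=0.0, k_ics=0.0)
        assert omega(p, "tumour") == pytest.approx(1.0, rel=1e-12)
        assert omega(p, "normal") == pytest.approx(1.0, rel=1e-12)

    def test_omega_at_least_one_for_defaults(self, free_params):
        lipo = SpeciesTissueParams.liposome()
        for p in (free_params, lipo):
            for r in ("tumour", "normal"):
                assert omega(p, r) >= 1.0


class TestApparentCoefficients:
    def test_tumour_values(self, free_params, coarse_phantom, coarse_flow):
        app = apparent_coefficients(free_params, coarse_flow, Region.TUMOUR)
        assert app.d_star_m2_s == pytest.approx(0.35 / 3.63 * 3.4e-10, rel=1e-12)
        assert app.k_rel_star_per_s == pytest.approx(1e-4 / 3.63, rel=1e-12)
        # voxel oracle: ((0.35+0.55)*5.8e-4 + F_b)/omega
        m = coarse_phantom.mask(Region.TUMOUR)
        fb = coarse_flow.f_b[m]
        np.testing.assert_allclose(
            app.k_e_star_per_s[m], (0.9 * 5.8e-4 + fb) / 3.63, rtol=1e-12)

    def test_k_e_star_magnitude_matches_reported_filtration(self, free_params,
                                                            coarse_flow):
        """At F_b = 3.61e-5 1/s the apparent elimination is ~1.54e-4 1/s."""
        k = (0.9 * 5.8e-4 + 3.61e-5) / omega(free_params, "tumour")
        assert k == pytest.approx(1.54e-4, rel=0.01)

    def test_no_elimination_no_filtration_gives_zero(self, coarse_flow):
        p = replace(SpeciesTissueParams.free_doxorubicin(), k_e_per_s=0.0)
        app = apparent_coefficients(p, coarse_flow, Region.TUMOUR)
        m = coarse_flow.phantom.mask(Region.TUMOUR)
        fb = coarse_flow.f_b[m]
        np.testing.assert_allclose(app.k_e_star_per_s[m] * omega(p, "tumour"),
                                   fb, rtol=1e-12)


class TestPatlakFlux:
    def test_zero_filtration_reduces_to_permeability_surface(self):
        ex = patlak_flux(0.0, 2e-6, 0.15, 2e4, 1e-3, 2e-4)
        assert ex.pe == 0.0
        assert ex.ex == pytest.approx(2e-6 * 2e4 * (1e-3 - 2e-4), rel=1e-12)

    def test_intact_barrier_blocks_everything(self):
        ex = patlak_flux(3.6e-5, 0.0, 0.15, 2e4, 1e-3, 0.0)
        assert ex.ex == 0.0

    def test_matches_50_digit_oracle(self, rng):
        """Random parameter tuples vs mpmath at 50 significant digits,
        Péclet numbers spanning 1e-12 .. 700."""
        mpmath.mp.dps = 50

        def oracle(f_b, p, sigma, sv, c_ivs, c_ecs):
            # mpf from a Python float is exact (binary), so the oracle sees
            # the same inputs as the implementation
            f_b, p, sigma, sv, c_ivs, c_ecs = (
                mpmath.mpf(float(v)) for v in (f_b, p, sigma, sv, c_ivs, c_ecs))
            pe = f_b * (1 - sigma) / (p * sv)
            return float(f_b * (1 - sigma) * c_ivs
                         + p * sv * (c_ivs - c_ecs) * pe / mpmath.expm1(pe))

        for _ in range(200):
            pe_target = 10.0 ** rng.uniform(-12, math.log10(700))
            if rng.random() < 0.3:
                pe_target = -pe_target
            sigma = rng.uniform(0.0, 0.99)
            sv = 10.0 ** rng.uniform(3, 5)
            p = 10.0 ** rng.uniform(-9, -5)
            f_b = pe_target * p * sv / (1.0 - sigma)
            c_ivs, c_ecs = rng.uniform(0, 1e-2, size=2)
            got = patlak_flux(f_b, p, sigma, sv, c_ivs, c_ecs)
            want = oracle(f_b, p, sigma, sv, c_ivs, c_ecs)
            assert got.ex == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_finite_at_extreme_peclet(self):
        # Pe > 700: diffusive factor underflows to zero, convection remains
        sv, p = 2e4, 1e-9
        f_b = 800.0 * p * sv
        ex = patlak_flux(f_b, p, 0.0, sv, 1e-3, 0.0)
        assert np.isfinite(ex.ex)
        assert ex.ex == pytest.approx(f_b * 1e-3, rel=1e-12)

    def test_sigma_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            patlak_flux(1e-5, 1e-6, 1.5, 2e4, 1e-3, 0.0)


def _quiescent_model(box, hydraulics, dt=10.0, d_t=3.4e-10, **kw):
    """Transport stepper on a uniform box with no vasculature and no flow:
    pure diffusion/advection test harness."""
    params = replace(hydraulics,
                     tumour=replace(hydraulics.tumour, k_b_m_pa_s=0.0),
                     normal=replace(hydraulics.normal, k_b_m_pa_s=0.0))
    flow = solve_interstitial_flow(box, params)
    free = replace(SpeciesTissueParams.free_doxorubicin(),
                   d_ecs_m2_s={"tumour": d_t, "normal": 1.6e-10},
                   k_e_per_s=0.0, k_rel_per_s=0.0)
    lipo = replace(SpeciesTissueParams.liposome(), k_rel_per_s=1e-30)
    dox = AgentTransvascular.doxorubicin().with_ps(0.0)
    # seal the vessel wall entirely: closed-system harness
    lip = replace(AgentTransvascular.liposome().with_ps(0.0),
                  p0_m_s={"tumour": 0.0, "normal": 0.0})
    model = TissueTransport(box, flow, free, lipo, dox, lip,
                            SonicationProtocol(), dt_s=dt, **kw)
    return model


class TestAdvanceTissue:
    def test_gaussian_spreads_with_heat_kernel_variance(self, hydraulics):
        """Zero velocity, zero exchange: after 100 steps the free-drug
        variance grows by 2 D* t per axis to within 2%."""
        h = 1e-3
        box = uniform_box_phantom((41, 41, 41), h, Region.TUMOUR)
        model = _quiescent_model(box, hydraulics, dt=10.0)
        x = (np.arange(43) - 21.0) * h
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        s0 = 3.0e-3
        c0 = np.exp(-(xx**2 + yy**2 + zz**2) / (2 * s0**2))
        c0[~box.interior_mask] = 0.0
        state = ConcentrationState(0.0, np.zeros_like(c0), c0.copy())

        def var_x(c):
            return float(np.sum(c * xx**2) / np.sum(c))

        v0 = var_x(state.c_f_ecs)
        for _ in range(100):
            state, _ = model.step(state, 0.0, 0.0)
        growth = var_x(state.c_f_ecs) - v0
        d_star = 0.35 / 3.63 * 3.4e-10
        assert growth == pytest.approx(2 * d_star * 1000.0, rel=0.02)

    def test_closed_system_conserves_mass(self, hydraulics):
        """Conservative liposome transport with no exchange or reactions:
        total mass constant to 1e-6 relative over 1000 steps."""
        box = uniform_box_phantom((16, 16, 16), 2e-3, Region.TUMOUR)
        model = _quiescent_model(box, hydraulics, dt=10.0)
        rng = np.random.default_rng(7)
        c0 = np.zeros(box.grid_shape)
        c0[box.interior_mask] = rng.uniform(0, 1e-3,
                                            box.interior_mask.sum())
        state = ConcentrationState(0.0, c0.copy(), np.zeros_like(c0))
        m0 = float(c0.sum())
        for _ in range(1000):
            state, _ = model.step(state, 0.0, 0.0)
        assert float(state.c_l_ecs.sum()) == pytest.approx(m0, rel=1e-6)

    def test_uniform_field_unchanged_without_sources(self, hydraulics):
        """Gradient-form advection of a uniform field is exactly zero; with
        no exchange/reaction the free-drug field is invariant."""
        box = uniform_box_phantom((12, 12, 12), 2e-3, Region.TUMOUR)
        model = _quiescent_model(box, hydraulics)
        c0 = np.zeros(box.grid_shape)
        c0[box.interior_mask] = 5e-4
        state = ConcentrationState(0.0, np.zeros_like(c0), c0.copy())
        for _ in range(50):
            state, _ = model.step(state, 0.0, 0.0)
        np.testing.assert_allclose(state.c_f_ecs[box.interior_mask], 5e-4,
                                   rtol=1e-12)

    def test_implicit_diffusion_matches_explicit(self, hydraulics):
        box = uniform_box_phantom((14, 14, 14), 1e-3, Region.TUMOUR)
        x = (np.arange(16) - 8.0) * 1e-3
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        c0 = np.exp(-(xx**2 + yy**2 + zz**2) / (2 * 2e-3**2))
        c0[~box.interior_mask] = 0.0
        results = []
        for implicit in (False, True):
            model = _quiescent_model(box, hydraulics, dt=10.0,
                                     implicit_diffusion=implicit)
            state = ConcentrationState(0.0, np.zeros_like(c0), c0.copy())
            for _ in range(20):
                state, _ = model.step(state, 0.0, 0.0)
            results.append(state.c_f_ecs)
        # both are consistent discretisations; at this dt they agree closely
        scale = results[0].max()
        assert np.max(np.abs(results[0] - results[1])) / scale < 1e-3

    def test_stability_violation_reported(self, hydraulics):
        box = uniform_box_phantom((10, 10, 10), 1e-4, Region.TUMOUR)
        with pytest.raises(StabilityError):
            _quiescent_model(box, hydraulics, dt=100.0, d_t=3.4e-8)

    def test_negative_concentration_detected(self, hydraulics):
        box = uniform_box_phantom((8, 8, 8), 2e-3, Region.TUMOUR)
        model = _quiescent_model(box, hydraulics)
        c0 = np.zeros(box.grid_shape)
        c0[box.interior_mask] = -1.0
        state = ConcentrationState(0.0, np.zeros_like(c0), c0)
        with pytest.raises(NegativeConcentrationError):
            model.step(state, 0.0, 0.0)


class TestCoupledSimulation:
    def test_liposome_only_free_flux_identically_zero(self, coarse_phantom,
                                                      coarse_flow, bundle):
        """Without sonication the BBB is closed to free doxorubicin: its
        transvascular flux stays exactly zero for the whole treatment."""
        res = simulate(coarse_phantom, coarse_flow, "liposome",
                       SonicationProtocol(), bundle.regimen, bundle.free,
                       bundle.lipo, bundle.dox_agent, bundle.lipo_agent,
                       t_end_s=1800.0, dt_s=10.0, output_interval_s=60.0)
        assert np.all(res.flux_free_tumour == 0.0)
        assert np.all(res.c_f_ecs_tumour[1:] > 0)   # release still feeds ECS

    def test_bbbd_timing_insensitive_liposome_accumulation(
            self, coarse_phantom, coarse_flow, bundle):
        """Burst sonication decays within seconds for liposomes, so moving
        its onset leaves the liposome ECS course essentially unchanged."""
        out = []
        for delay in (0.0, 1800.0):
            res = simulate(coarse_phantom, coarse_flow, "liposome_bbbd",
                           SonicationProtocol.burst_at(delay), bundle.regimen,
                           bundle.free, bundle.lipo, bundle.dox_agent,
                           bundle.lipo_agent, t_end_s=3600.0, dt_s=10.0,
                           output_interval_s=300.0)
            out.append(res.c_l_ecs_tumour[-1])
        assert out[1] == pytest.approx(out[0], rel=1e-3)

    def test_time_step_independence(self, coarse_phantom, coarse_flow, bundle):
        """Halving dt from 10 to 5 s moves 2 h region means by < 1%."""
        vals = []
        for dt in (10.0, 5.0):
            res = simulate(coarse_phantom, coarse_flow, "liposome_bbbd",
                           SonicationProtocol.burst_at(0.0), bundle.regimen,
                           bundle.free, bundle.lipo, bundle.dox_agent,
                           bundle.lipo_agent, t_end_s=7200.0, dt_s=dt,
                           output_interval_s=7200.0)
            vals.append((res.c_f_ecs_tumour[-1], res.c_l_ecs_tumour[-1]))
        assert vals[1][0] == pytest.approx(vals[0][0], rel=0.01)
        assert vals[1][1] == pytest.approx(vals[0][1], rel=0.01)

    def test_concentrations_nonnegative_and_finite(self, coarse_phantom,
                                                   coarse_flow, bundle):
        res = simulate(coarse_phantom, coarse_flow, "direct_bbbd",
                       SonicationProtocol.burst_at(0.0), bundle.regimen,
                       bundle.free, bundle.lipo, bundle.dox_agent,
                       bundle.lipo_agent, t_end_s=1800.0, dt_s=10.0,
                       output_interval_s=300.0)
        for arr in (res.c_f_ecs_tumour, res.c_f_ecs_normal, res.c_f_ivs):
            assert np.all(np.isfinite(arr)) and np.all(arr >= 0)

    def test_normal_tissue_orders_of_magnitude_below_tumour(
            self, coarse_phantom, coarse_flow, bundle):
        """Drug reaches normal tissue only through the tumour interface, so
        its ECS concentration stays orders of magnitude lower."""
        res = simulate(coarse_phantom, coarse_flow, "liposome_bbbd",
                       SonicationProtocol.burst_at(0.0), bundle.regimen,
                       bundle.free, bundle.lipo, bundle.dox_agent,
                       bundle.lipo_agent, t_end_s=7200.0, dt_s=10.0,
                       output_interval_s=3600.0)
        ratio = res.c_f_ecs_normal[-1] / res.c_f_ecs_tumour[-1]
        assert 0.0 < ratio < 1e-2
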