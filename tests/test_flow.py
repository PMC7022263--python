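"""Flow-solver verification: Starling arithmetic oracles, a 1D analytic
slab, the method of manufactured solutions for convergence order, and the
discrete conservation identities."""

import math

import numpy as np
import pytest

from braintx.flow import (FlowSolverError, HydraulicParams, RegionHydraulics,
                          divergence, flow_summary, region_mean_starling,
                          solve_interstitial_flow, starling_flux)
from braintx.phantom import PhantomSpec, Region, build_phantom, uniform_box_phantom


def no_vasculature(params: HydraulicParams) -> HydraulicParams:
    from dataclasses import replace
    return replace(params,
                   tumour=replace(params.tumour, k_b_m_pa_s=0.0),
                   normal=replace(params.normal, k_b_m_pa_s=0.0))


class TestStarlingFlux:
    def test_equilibrium_pressure_gives_zero(self, hydraulics):
        # p_i = p_b - sigma_T (pi_b - pi_i) = 2714 Pa in the tumour
        p_eq = 4600.0 - 0.82 * (3400.0 - 1100.0)
        assert p_eq == pytest.approx(2714.0)
        assert starling_flux(p_eq, Region.TUMOUR, hydraulics) == \
            pytest.approx(0.0, abs=1e-18)

    def test_arithmetic_oracle_tumour(self, hydraulics):
        # K_b S/V (p_b - p_i - sigma_T dpi) at the reported tumour mean IFP
        expected = 1.1e-12 * 2.0e4 * (4600.0 - 1071.79 - 0.82 * 2300.0)
        assert expected == pytest.approx(3.61e-5, rel=1e-2)
        assert starling_flux(1071.79, Region.TUMOUR, hydraulics) == \
            pytest.approx(expected, rel=1e-12)

    def test_arithmetic_oracle_normal(self, hydraulics):
        expected = 1.4e-13 * 7.0e3 * (4600.0 - 876.03 - 0.91 * 2660.0)
        assert expected == pytest.approx(1.28e-6, rel=1e-2)
        assert starling_flux(876.03, Region.NORMAL, hydraulics) == \
            pytest.approx(expected, rel=1e-12)

    def test_reabsorption_possible(self, hydraulics):
        assert starling_flux(4000.0, Region.TUMOUR, hydraulics) < 0

    @pytest.mark.parametrize("region", [Region.VENTRICLE, Region.EXTERIOR])
    def test_avascular_regions_rejected(self, region, hydraulics):
        with pytest.raises(ValueError):
            starling_flux(1000.0, region, hydraulics)


class TestSlabAnalytic:
    def test_linear_profile_and_constant_velocity(self, hydraulics):
        """1D slab with no vasculature: pressure interpolates linearly
        between the surface and far boundary values; velocity is uniform."""
        params = no_vasculature(hydraulics)
        box = uniform_box_phantom((40, 3, 3), 1e-3, Region.NORMAL)
        field = solve_interstitial_flow(box, params)
        p = field.p_pa[1:-1, 2, 2]
        # both x-ends are EXTERIOR -> same Dirichlet value; the profile is flat
        np.testing.assert_allclose(p, params.p_surface_pa, rtol=1e-8)
        assert np.max(np.abs(field.cell_speed()[box.interior_mask])) < 1e-15

    def test_imposed_end_pressures_give_linear_profile(self, hydraulics):
        """Drive one end with the ventricle pressure by placing VENTRICLE
        voxels there; interior profile must be linear with constant flux."""
        from braintx.phantom import VoxelPhantom
        # full-span in y/z so the side walls are zero-flux (truly 1D)
        labels = np.full((42, 5, 5), int(Region.EXTERIOR), dtype=np.int8)
        labels[1:-1, :, :] = int(Region.NORMAL)
        labels[1, :, :] = int(Region.VENTRICLE)
        box = VoxelPhantom(spacing=1e-3, labels=labels)
        params = no_vasculature(hydraulics)
        field = solve_interstitial_flow(box, params)
        p = field.p_pa[2:-1, 2, 2]
        # analytic: linear from p_ventricle (face at x0) to p_surface
        n = len(p)
        x = np.arange(n) + 0.5
        expected = params.p_ventricle_pa + (
            params.p_surface_pa - params.p_ventricle_pa) * x / n
        np.testing.assert_allclose(p, expected, rtol=1e-7)
        vx = field.face_velocity[0][3:-2, 2, 2]
        assert np.ptp(vx) < 1e-8 * abs(vx.mean())


class TestManufacturedSolution:
    @staticmethod
    def _solve_mms(n: int, hydraulics):
        """p = p_surface + A sin(pi x/L) sin(pi y/L) sin(pi z/L) on a cube
        with homogeneous-in-p Dirichlet faces; the matching source is
        f = 3 (kappa/mu) A (pi/L)^2 sin sin sin."""
        params = no_vasculature(hydraulics)
        h = 0.04 / n
        box = uniform_box_phantom((n, n, n), h, Region.NORMAL)
        L = n * h
        A = 100.0
        k = params.normal.kappa_m2 / params.mu_kg_m_s
        coords = (np.arange(n) + 0.5) * h
        s = np.sin(np.pi * coords / L)
        sss = s[:, None, None] * s[None, :, None] * s[None, None, :]
        exact = params.p_surface_pa + A * sss
        src = np.zeros(box.grid_shape)
        src[1:-1, 1:-1, 1:-1] = 3.0 * k * A * (np.pi / L) ** 2 * sss
        field = solve_interstitial_flow(box, params, extra_source=src)
        err = field.p_pa[1:-1, 1:-1, 1:-1] - exact
        return float(np.sqrt(np.mean(err**2)))

    def test_second_order_convergence(self, hydraulics):
        e1 = self._solve_mms(12, hydraulics)
        e2 = self._solve_mms(24, hydraulics)
        order = math.log2(e1 / e2)
        assert 1.7 < order < 2.3


class TestPhantomFlow:
    def test_global_mass_balance(self, coarse_phantom, coarse_flow):
        """Total Starling filtration equals the net outflow through the
        brain surface and ventricle boundaries."""
        ph, field = coarse_phantom, coarse_flow
        h = ph.spacing
        total_source = float(np.sum(field.f_b)) * h**3
        outflow = 0.0
        interior = ph.interior_mask
        for ax, fv in enumerate(field.face_velocity):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            mid = [slice(None)] * 3
            mid[ax] = slice(1, -1)
            v = fv[tuple(mid)]
            boundary_hi = interior[lo] & ~interior[hi]   # outward = +v
            boundary_lo = interior[hi] & ~interior[lo]   # outward = -v
            outflow += float(np.sum(v[boundary_hi]) - np.sum(v[boundary_lo])) * h**2
        assert outflow == pytest.approx(total_source, rel=1e-6)

    def test_divergence_equals_starling_source(self, coarse_phantom, coarse_flow):
        div = divergence(coarse_flow)
        m = coarse_phantom.interior_mask
        scale = np.max(np.abs(coarse_flow.f_b[m]))
        assert np.max(np.abs(div[m] - coarse_flow.f_b[m])) / scale < 1e-6

    def test_tumour_pressure_exceeds_normal(self, coarse_phantom, coarse_flow):
        s = flow_summary(coarse_flow, coarse_phantom)
        assert s["tumour"]["mean_ifp_pa"] > s["normal"]["mean_ifp_pa"]

    def test_grid_refinement_changes_region_means_below_5pct(
            self, coarse_phantom, coarse_flow, phantom_2mm, flow_2mm):
        s4 = flow_summary(coarse_flow, coarse_phantom)
        s2 = flow_summary(flow_2mm, phantom_2mm)
        for reg in ("tumour", "normal"):
            assert s4[reg]["mean_ifp_pa"] == pytest.approx(
                s2[reg]["mean_ifp_pa"], rel=0.05)
            assert s4[reg]["mean_ifv_m_s"] == pytest.approx(
                s2[reg]["mean_ifv_m_s"], rel=0.05)

    def test_region_mean_starling_positive_by_default(self, coarse_phantom,
                                                      coarse_flow):
        fb = region_mean_starling(coarse_flow, coarse_phantom)
        assert fb["tumour"] > fb["normal"] > 0

    def test_uniform_pressure_means_zero_speed(self, hydraulics):
        """With no vasculature and a single boundary value the solution is
        constant, so the summary speed is exactly the degenerate case."""
        box = uniform_box_phantom((8, 8, 8), 2e-3, Region.NORMAL)
        field = solve_interstitial_flow(box, no_vasculature(hydraulics))
        speeds = field.cell_speed()[box.interior_mask]
        assert np.max(speeds) < 1e-15

    def test_empty_region_summary_rejected(self, hydraulics):
        box = uniform_box_phantom((6, 6, 6), 2e-3, Region.NORMAL)
        field = solve_interstitial_flow(box, no_vasculature(hydraulics))
        with pytest.raises(ValueError):
            flow_summary(field, box)

    def test_no_tissue_raises(self, hydraulics):
        box = uniform_box_phantom((4, 4, 4), 2e-3, Region.VENTRICLE)
        with pytest.raises(FlowSolverError):
            solve_interstitial_flow(box, hydraulics)
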