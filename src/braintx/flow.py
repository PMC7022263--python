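"""Steady interstitial fluid flow with a Starling transvascular source.

The interstitial fluid in tumour and normal tissue is treated as flow through
a porous medium. At the observed interstitial velocities (~1e-7 m/s) the
inertial and shear terms of the momentum equation are negligible by many
orders of magnitude, so the model reduces to Darcy's law

    v = -(kappa/mu) grad(p_i)

combined with mass conservation  div(v) = F_b,  where the Starling source

    F_b = K_b (S/V) [p_b - p_i - sigma_T (pi_b - pi_i)]

is the fluid filtration rate from the microvasculature. F_b is affine in
p_i, so the whole problem is one symmetric positive-definite linear system:
it is assembled once on the voxel grid (7-point stencil, harmonic-mean face
conductances so flux is continuous across the tumour/normal interface) and
solved by preconditioned conjugate gradients. Dirichlet gauge pressures are
imposed on brain-surface and ventricle faces (face-centred, half-cell
conductance). Fluid density ``rho`` is carried in the parameter set for
completeness but does not enter the reduced (inertia-free) equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from . import params as _p
from .phantom import Region, VoxelPhantom

_TISSUE_REGIONS = (Region.NORMAL, Region.TUMOUR)


class FlowSolverError(RuntimeError):
    """Raised when the flow system is singular or the solver fails."""


@dataclass(frozen=True)
class RegionHydraulics:
    """Per-region hydraulic properties (SI units)."""

    kappa_m2: float          # Darcian permeability of the tissue
    k_b_m_pa_s: float        # hydraulic conductivity of the vessel wall
    sv_per_m: float          # vascular surface area density S/V
    sigma_t: float           # osmotic reflection coefficient for proteins
    pi_i_pa: float           # interstitial osmotic pressure

    def __post_init__(self) -> None:
        if min(self.kappa_m2, self.k_b_m_pa_s, self.sv_per_m) < 0:
            raise ValueError("hydraulic parameters must be nonnegative")
        if not 0.0 <= self.sigma_t <= 1.0:
            raise ValueError("sigma_t must lie in [0, 1]")


@dataclass(frozen=True)
class HydraulicParams:
    """Hydraulic parameter set: per-region properties plus globals."""

    tumour: RegionHydraulics
    normal: RegionHydraulics
    p_b_pa: float = _p.TISSUE["p_b_pa"]
    pi_b_pa: float = _p.TISSUE["pi_b_pa"]
    rho_kg_m3: float = _p.TISSUE["rho_kg_m3"]
    mu_kg_m_s: float = _p.TISSUE["mu_kg_m_s"]
    p_surface_pa: float = _p.BOUNDARY["p_surface_pa"]
    p_ventricle_pa: float = _p.BOUNDARY["p_ventricle_pa"]

    def __post_init__(self) -> None:
        if self.mu_kg_m_s <= 0 or self.rho_kg_m3 <= 0:
            raise ValueError("mu and rho must be positive")

    @classmethod
    def default(cls) -> "HydraulicParams":
        t = _p.TISSUE

        def region(r: str) -> RegionHydraulics:
            return RegionHydraulics(
                kappa_m2=t["kappa_m2"][r], k_b_m_pa_s=t["k_b_m_pa_s"][r],
                sv_per_m=t["sv_per_m"][r], sigma_t=t["sigma_t"][r],
                pi_i_pa=t["pi_i_pa"][r])

        return cls(tumour=region("tumour"), normal=region("normal"))

    def region(self, region: Region) -> RegionHydraulics:
        if region == Region.TUMOUR:
            return self.tumour
        if region == Region.NORMAL:
            return self.normal
        raise ValueError(f"region {region!r} has no vasculature")


def starling_flux(p_i_pa: float | np.ndarray, region: Region,
                  params: HydraulicParams) -> float | np.ndarray:
    """Starling filtration rate F_b (1/s) at interstitial pressure ``p_i``.

    Negative values mean fluid reabsorption into the vasculature. Only
    NORMAL and TUMOUR carry vasculature; other regions raise ValueError.
    """
    r = params.region(region)
    return r.k_b_m_pa_s * r.sv_per_m * (
        params.p_b_pa - p_i_pa - r.sigma_t * (params.pi_b_pa - r.pi_i_pa))


@dataclass
class FlowField:
    """Steady flow solution on a phantom.

    ``p_pa`` holds the interstitial pressure on the full grid (boundary
    values in VENTRICLE/EXTERIOR voxels adjacent to tissue, NaN elsewhere).
    ``face_velocity`` holds the Darcy velocity normal to each voxel face,
    one staggered array per axis with shape grid+1 along that axis; positive
    values point toward increasing index. ``f_b`` is the Starling source per
    voxel (1/s, zero outside tissue).
    """

    phantom: VoxelPhantom
    p_pa: np.ndarray
    face_velocity: tuple[np.ndarray, np.ndarray, np.ndarray]
    f_b: np.ndarray
    residual: float = 0.0
    _cell_v: np.ndarray | None = field(default=None, repr=False)

    def cell_velocity(self) -> np.ndarray:
        """Voxel-centred velocity (m/s), shape grid+(3,): face averages."""
        if self._cell_v is None:
            v = np.zeros(self.phantom.grid_shape + (3,))
            for ax, fv in enumerate(self.face_velocity):
                lo = [slice(None)] * 3
                hi = [slice(None)] * 3
                lo[ax] = slice(0, -1)
                hi[ax] = slice(1, None)
                v[..., ax] = 0.5 * (fv[tuple(lo)] + fv[tuple(hi)])
            v[~self.phantom.interior_mask] = 0.0
            self._cell_v = v
        return self._cell_v

    def cell_speed(self) -> np.ndarray:
        """Voxel-centred speed |v| (m/s)."""
        return np.linalg.norm(self.cell_velocity(), axis=-1)


def _mobility_field(phantom: VoxelPhantom, params: HydraulicParams) -> np.ndarray:
    """kappa/mu per voxel (zero outside tissue)."""
    k = np.zeros(phantom.grid_shape)
    for reg in _TISSUE_REGIONS:
        k[phantom.mask(reg)] = params.region(reg).kappa_m2 / params.mu_kg_m_s
    return k


def solve_interstitial_flow(phantom: VoxelPhantom, params: HydraulicParams,
                            extra_source: np.ndarray | None = None,
                            rtol: float = 1e-10,
                            maxiter: int = 20000) -> FlowField:
    """Solve the steady Darcy-Starling problem on the phantom.

    Solves ``-div((kappa/mu) grad p) = F_b(p) + extra_source`` over
    NORMAL/TUMOUR voxels with Dirichlet pressure ``p_surface`` on
    brain-surface faces and ``p_ventricle`` on ventricle faces. Because the
    Starling source is affine in p the system is linear and assembled once.

    ``extra_source`` (1/s per voxel) supports manufactured-solution
    verification. The returned field satisfies the discrete divergence
    identity div(v) = F_b + extra_source to the linear-solver tolerance.
    """
    h = phantom.spacing
    interior = phantom.interior_mask
    n_unk = int(np.count_nonzero(interior))
    if n_unk == 0:
        raise FlowSolverError("phantom has no tissue voxels")

    index = -np.ones(phantom.grid_shape, dtype=np.int64)
    index[interior] = np.arange(n_unk)
    mob = _mobility_field(phantom, params)
    labels = phantom.labels

    # Starling affine split F_b = a - L p
    lcoef = np.zeros(phantom.grid_shape)
    acoef = np.zeros(phantom.grid_shape)
    for reg in _TISSUE_REGIONS:
        r = params.region(reg)
        m = phantom.mask(reg)
        L = r.k_b_m_pa_s * r.sv_per_m
        lcoef[m] = L
        acoef[m] = L * (params.p_b_pa - r.sigma_t * (params.pi_b_pa - r.pi_i_pa))
    if extra_source is not None:
        acoef = acoef + np.where(interior, extra_source, 0.0)

    diag = lcoef[interior].copy()
    rhs = acoef[interior].copy()
    rows, cols, vals = [], [], []

    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        a, b = interior[lo], interior[hi]

        # interior-interior faces: harmonic-mean mobility, coefficient k/h^2
        both = a & b
        ka, kb = mob[lo][both], mob[hi][both]
        kface = np.where(ka + kb > 0, 2.0 * ka * kb / np.maximum(ka + kb, 1e-300), 0.0)
        c = kface / h**2
        ia, ib = index[lo][both], index[hi][both]
        np.add.at(diag, ia, c)
        np.add.at(diag, ib, c)
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-c, -c])

        # Dirichlet faces: interior voxel next to EXTERIOR or VENTRICLE.
        for side_sel, nb_sel in ((lo, hi), (hi, lo)):
            me = interior[side_sel]
            nb_lab = labels[nb_sel]
            for outside, pval in ((int(Region.EXTERIOR), params.p_surface_pa),
                                  (int(Region.VENTRICLE), params.p_ventricle_pa)):
                sel = me & (nb_lab == outside)
                if not np.any(sel):
                    continue
                idx = index[side_sel][sel]
                c = 2.0 * mob[side_sel][sel] / h**2   # face-centred Dirichlet
                np.add.at(diag, idx, c)
                np.add.at(rhs, idx, c * pval)

    if not np.any(rhs != 0) and not np.any(diag > 0):
        raise FlowSolverError("singular system: no Dirichlet faces or sources")

    eye = np.arange(n_unk)
    rows = np.concatenate([*rows, eye]) if rows else eye
    cols = np.concatenate([*cols, eye]) if cols else eye
    vals = np.concatenate([*vals, diag]) if vals else diag
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n_unk, n_unk))

    if np.min(diag) <= 0:
        raise FlowSolverError("system not positive definite "
                              "(a tissue voxel has no coupling)")

    M = sparse.diags(1.0 / diag)
    p_vec, info = cg(A, rhs, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(A @ p_vec - rhs) / np.linalg.norm(rhs))
    if info != 0 or not np.isfinite(res):
        raise FlowSolverError(f"CG did not converge (info={info}, "
                              f"relative residual {res:.3e})")

    p = np.full(phantom.grid_shape, np.nan)
    p[interior] = p_vec

    # fill Dirichlet values into adjacent boundary voxels for plotting/IO
    for outside, pval in ((Region.EXTERIOR, params.p_surface_pa),
                          (Region.VENTRICLE, params.p_ventricle_pa)):
        p[phantom.mask(outside)] = pval

    f_b = np.where(interior, acoef - lcoef * p_fill(p, interior), 0.0)
    if extra_source is not None:
        f_b -= np.where(interior, extra_source, 0.0)

    face_v = _face_velocities(phantom, params, mob, p)
    return FlowField(phantom=phantom, p_pa=p, face_velocity=face_v, f_b=f_b,
                     residual=res)


def p_fill(p: np.ndarray, interior: np.ndarray) -> np.ndarray:
    """Pressure with non-tissue voxels zeroed (for vectorised arithmetic)."""
    return np.where(interior, p, 0.0)


def _face_velocities(phantom: VoxelPhantom, params: HydraulicParams,
                     mob: np.ndarray, p: np.ndarray):
    """Darcy velocity on voxel faces; zero on faces with no fluid path."""
    h = phantom.spacing
    interior = phantom.interior_mask
    labels = phantom.labels
    out: list[np.ndarray] = []
    for ax in range(3):
        shape = list(phantom.grid_shape)
        shape[ax] += 1
        fv = np.zeros(shape)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        mid = [slice(None)] * 3
        mid[ax] = slice(1, -1)
        mid = tuple(mid)

        a, b = interior[lo], interior[hi]
        both = a & b
        ka, kb = mob[lo], mob[hi]
        kface = np.where((ka + kb) > 0, 2.0 * ka * kb / np.maximum(ka + kb, 1e-300), 0.0)
        pz = p_fill(p, interior)
        inner = np.where(both, -kface * (pz[hi] - pz[lo]) / h, 0.0)

        # Dirichlet faces: one-sided gradient over half a cell. Positive
        # velocity points toward increasing index along the axis.
        for outside, pval in ((int(Region.EXTERIOR), params.p_surface_pa),
                              (int(Region.VENTRICLE), params.p_ventricle_pa)):
            sel = a & (labels[hi] == outside)      # boundary on the high side
            inner = np.where(sel, -2.0 * mob[lo] * (pval - pz[lo]) / h, inner)
            sel = b & (labels[lo] == outside)      # boundary on the low side
            inner = np.where(sel, -2.0 * mob[hi] * (pz[hi] - pval) / h, inner)

        fv[mid] = inner
        out.append(fv)
    return tuple(out)


def divergence(field: FlowField) -> np.ndarray:
    """Discrete divergence of the face velocities (1/s per voxel)."""
    h = field.phantom.spacing
    div = np.zeros(field.phantom.grid_shape)
    for ax, fv in enumerate(field.face_velocity):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        div += (fv[tuple(hi)] - fv[tuple(lo)]) / h
    div[~field.phantom.interior_mask] = 0.0
    return div


def flow_summary(field: FlowField, phantom: VoxelPhantom) -> dict[str, dict[str, float]]:
    """Volume-weighted mean IFP (Pa) and mean speed (m/s) per tissue region.

    Voxels are uniform, so the volume-weighted mean reduces to the
    arithmetic mean over each region's voxels.
    """
    speed = field.cell_speed()
    out: dict[str, dict[str, float]] = {}
    for reg in _TISSUE_REGIONS:
        m = phantom.mask(reg)
        if not np.any(m):
            raise ValueError(f"region {reg.name} is empty")
        out[reg.name.lower()] = {
            "mean_ifp_pa": float(np.mean(field.p_pa[m])),
            "mean_ifv_m_s": float(np.mean(speed[m])),
        }
    return out


def region_mean_starling(field: FlowField, phantom: VoxelPhantom) -> dict[str, float]:
    """Region-mean Starling source F_b (1/s) over tumour and normal tissue."""
    return {reg.name.lower(): float(np.mean(field.f_b[phantom.mask(reg)]))
            for reg in _TISSUE_REGIONS}
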