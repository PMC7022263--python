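"""Convection-diffusion-reaction transport of drug in tissue extracellular space.

Two species are tracked on the voxel phantom, each only where there is
tissue (NORMAL and TUMOUR voxels):

* liposome-encapsulated drug ``C_L,ECS`` — confined to the ECS (PEGylated
  carriers neither cross cell membranes nor bind), transported by the full
  interstitial velocity in conservative form:

      dC_L/dt = D_L lap(C_L) - div(v C_L) - k_rel C_L + Ex(C_L,IVS, C_L)

* free drug ``C_F,ECS`` — in fast partition/binding equilibrium with the
  intracellular space and cell membrane, which folds into the retention
  factor  omega = v_ECS (1+K_ECS) + v_ICS P_ICS-ECS (1+K_ICS)
  + (1 - v_ECS - v_ICS) P_CM-ECS  and yields apparent coefficients
  D* = (v_ECS/omega) D_ECS, v* = (v_ECS/omega) v,
  k_e* = [(v_ECS + v_ICS) k_e + F_b]/omega, k_rel* = k_rel/omega:

      dC_F/dt = D* lap(C_F) - v*.grad(C_F) - k_e* C_F
                + (v_ECS/omega) Ex(C_F,IVS, C_F) + k_rel* C_L

  The free-drug advection is deliberately non-conservative (v*.grad form)
  while the liposome advection is conservative — the two governing forms
  differ in the source model and both are kept as written.

Transvascular exchange follows the Patlak form

    Ex = F_b (1 - sigma) C_IVS + P (S/V) (C_IVS - C_ECS) Pe/(e^Pe - 1),
    Pe = F_b (1 - sigma) / (P S/V),

with the convention that an intact barrier (P = 0) blocks *all* solute
flux, convective included: without it the convective term alone would leak
free drug through the closed BBB. Exchange acts only in vascularised
regions, and the sonication enhancement only in the tumour.

Numerics: operator splitting (advection, diffusion, reaction/exchange) with
first-order upwind advection and an explicit 7-point diffusion stencil at a
fixed 10 s step; at >= 1 mm spacing the explicit stability margins exceed
100x for the default coefficients. An implicit (backward-Euler, CG)
diffusion option exists for stiff configurations. Wall permeabilities are
applied as exact interval averages over each step (see
:func:`braintx.bbbd.permeability_average`). Drug flux is zero through the
brain surface and ventricle wall; face coefficients use harmonic means so
diffusive flux is continuous across the tumour/normal interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import cg as _cg

from . import params as _p
from .bbbd import AgentTransvascular, SonicationProtocol, permeability_average
from .flow import FlowField, HydraulicParams
from .phantom import Region, VoxelPhantom
from .plasma import (DoseRegimen, direct_plasma_concentration,
                     free_plasma_step, liposome_plasma_concentration)

_REGIONS = ("tumour", "normal")

log = logging.getLogger("braintx.transport")


class StabilityError(RuntimeError):
    """An explicit step would violate a stability bound."""


class NegativeConcentrationError(RuntimeError):
    """A concentration went negative beyond numerical-noise tolerance."""


# ---------------------------------------------------------------------------
# Parameters and apparent coefficients
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SpeciesTissueParams:
    """Tissue-transport parameters of one species (per-region dicts).

    ``confined_to_ecs`` marks the liposome case: no partitioning into cells,
    so the retention factor omega is not applied and the raw coefficients
    govern the ECS balance.
    """

    name: str
    d_ecs_m2_s: dict[str, float]
    sigma: dict[str, float]
    k_e_per_s: float = 0.0
    k_rel_per_s: float = 0.0
    v_ecs: dict[str, float] = field(default_factory=lambda: dict(_p.TISSUE["v_ecs"]))
    v_ics: dict[str, float] = field(default_factory=lambda: dict(_p.TISSUE["v_ics"]))
    p_ics_ecs: float = 1.0
    p_cm_ecs: float = 1.0
    k_ecs: float = 0.0
    k_ics: float = 0.0
    confined_to_ecs: bool = False

    def __post_init__(self) -> None:
        for r in _REGIONS:
            if self.v_ecs[r] + self.v_ics[r] > 1.0 + 1e-12:
                raise ValueError("volume fractions exceed 1")
            if not 0.0 <= self.sigma[r] <= 1.0:
                raise ValueError("sigma must lie in [0, 1]")
        if min(self.k_e_per_s, self.k_rel_per_s, self.p_ics_ecs,
               self.p_cm_ecs, self.k_ecs, self.k_ics) < 0:
            raise ValueError("rates, partitions and binding constants "
                             "must be nonnegative")

    @classmethod
    def free_doxorubicin(cls, k_rel_per_s: float | None = None) -> "SpeciesTissueParams":
        d = _p.DOXORUBICIN
        return cls(name="free_doxorubicin",
                   d_ecs_m2_s=dict(d["d_ecs_m2_s"]), sigma=dict(d["sigma"]),
                   k_e_per_s=d["k_e_per_s"],
                   k_rel_per_s=(_p.LIPOSOME["k_rel_per_s"]
                                if k_rel_per_s is None else k_rel_per_s),
                   p_ics_ecs=d["p_ics_ecs"], p_cm_ecs=d["p_cm_ecs"],
                   k_ecs=d["k_ecs"], k_ics=d["k_ics"])

    @classmethod
    def liposome(cls, k_rel_per_s: float | None = None) -> "SpeciesTissueParams":
        lp = _p.LIPOSOME
        return cls(name="liposome",
                   d_ecs_m2_s=dict(lp["d_ecs_m2_s"]), sigma=dict(lp["sigma"]),
                   k_e_per_s=lp["k_e_per_s"],
                   k_rel_per_s=(lp["k_rel_per_s"]
                                if k_rel_per_s is None else k_rel_per_s),
                   confined_to_ecs=True)


def omega(params: SpeciesTissueParams, region: Region | str) -> float:
    """Retention factor converting ECS dynamics to whole-tissue conservation."""
    r = region.name.lower() if isinstance(region, Region) else region
    ve, vi = params.v_ecs[r], params.v_ics[r]
    return (ve * (1.0 + params.k_ecs)
            + vi * params.p_ics_ecs * (1.0 + params.k_ics)
            + (1.0 - ve - vi) * params.p_cm_ecs)


@dataclass(frozen=True)
class ApparentCoefficients:
    """Per-region apparent transport coefficients for the free drug."""

    omega: float
    d_star_m2_s: float
    v_star_factor: float            # multiply interstitial v by this
    k_e_star_per_s: np.ndarray      # per-voxel (F_b enters), zero off-region
    k_rel_star_per_s: float


def apparent_coefficients(params: SpeciesTissueParams, flow: FlowField,
                          region: Region) -> ApparentCoefficients:
    """Apparent (retention-corrected) coefficients of a species in a region."""
    r = region.name.lower()
    w = omega(params, r)
    if w == 0:
        raise ZeroDivisionError("omega is zero")
    mask = flow.phantom.mask(region)
    k_e_star = np.zeros(flow.phantom.grid_shape)
    k_e_star[mask] = ((params.v_ecs[r] + params.v_ics[r]) * params.k_e_per_s
                      + flow.f_b[mask]) / w
    return ApparentCoefficients(
        omega=w, d_star_m2_s=params.v_ecs[r] / w * params.d_ecs_m2_s[r],
        v_star_factor=params.v_ecs[r] / w, k_e_star_per_s=k_e_star,
        k_rel_star_per_s=params.k_rel_per_s / w)


# ---------------------------------------------------------------------------
# Patlak transvascular exchange
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ExchangeTerm:
    """Péclet number and transvascular source (mg/mL/s)."""

    pe: np.ndarray | float
    ex: np.ndarray | float


def _patlak_factor(pe: np.ndarray) -> np.ndarray:
    """Pe/(e^Pe - 1), numerically stable for Pe in (-inf, +inf)."""
    pe = np.asarray(pe, dtype=float)
    out = np.empty_like(pe)
    small = np.abs(pe) < 1e-6
    out[small] = 1.0 - pe[small] / 2.0 + pe[small]**2 / 12.0
    huge = pe > 700.0
    out[huge] = 0.0
    mid = ~(small | huge)
    out[mid] = pe[mid] / np.expm1(pe[mid])
    return out


def patlak_flux(f_b: np.ndarray | float, p_m_s: np.ndarray | float,
                sigma: np.ndarray | float, sv_per_m: np.ndarray | float,
                c_ivs: float, c_ecs: np.ndarray | float) -> ExchangeTerm:
    """Transvascular exchange Ex (mg/mL/s) and Péclet number.

    Vectorised over voxels. Where P = 0 the barrier is intact and the total
    flux — convective term included — is zero.
    """
    f_b, p, sv = (np.asarray(a, dtype=float) for a in (f_b, p_m_s, sv_per_m))
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0) or np.any(sigma > 1):
        raise ValueError("sigma must lie in [0, 1]")
    if np.any(p < 0) or np.any(sv < 0):
        raise ValueError("P and S/V must be nonnegative")
    c_ecs = np.asarray(c_ecs, dtype=float)

    conv, psv, c_ecs = np.broadcast_arrays(f_b * (1.0 - sigma), p * sv, c_ecs)
    open_wall = psv > 0.0
    pe = np.zeros(psv.shape)
    np.divide(conv, psv, out=pe, where=open_wall)
    ex = np.where(open_wall,
                  conv * c_ivs + psv * (c_ivs - c_ecs) * _patlak_factor(pe),
                  0.0)
    if ex.ndim == 0:
        return ExchangeTerm(pe=float(pe), ex=float(ex))
    return ExchangeTerm(pe=pe, ex=ex)


# ---------------------------------------------------------------------------
# Concentration state
# ---------------------------------------------------------------------------
@dataclass
class ConcentrationState:
    """ECS concentration fields (mg/mL) for both species at time ``t_s``.

    Intracellular, membrane and bound pools are equilibrium diagnostics
    derived from ``c_f_ecs`` via the partition/binding constants, not state.
    """

    t_s: float
    c_l_ecs: np.ndarray
    c_f_ecs: np.ndarray

    def copy(self) -> "ConcentrationState":
        return ConcentrationState(self.t_s, self.c_l_ecs.copy(),
                                  self.c_f_ecs.copy())


# ---------------------------------------------------------------------------
# The discrete stepper
# ---------------------------------------------------------------------------
def _region_field(phantom: VoxelPhantom, values: dict[str, float]) -> np.ndarray:
    out = np.zeros(phantom.grid_shape)
    out[phantom.mask(Region.TUMOUR)] = values["tumour"]
    out[phantom.mask(Region.NORMAL)] = values["normal"]
    return out


class TissueTransport:
    """Pre-assembled discrete operators for one phantom/flow configuration."""

    def __init__(self, phantom: VoxelPhantom, flow: FlowField,
                 free: SpeciesTissueParams, lipo: SpeciesTissueParams | None,
                 dox_agent: AgentTransvascular,
                 lipo_agent: AgentTransvascular | None,
                 protocol: SonicationProtocol,
                 dt_s: float = 10.0,
                 implicit_diffusion: bool = False) -> None:
        if dt_s <= 0:
            raise ValueError("dt must be positive")
        self.phantom = phantom
        self.flow = flow
        self.free = free
        self.lipo = lipo
        self.dox_agent = dox_agent
        self.lipo_agent = lipo_agent
        self.protocol = protocol
        self.dt = float(dt_s)
        self.implicit_diffusion = implicit_diffusion
        h = phantom.spacing
        self.h = h
        self.interior = phantom.interior_mask

        # retention-corrected coefficients for the free drug
        self.app = {reg: apparent_coefficients(free, flow, reg)
                    for reg in (Region.TUMOUR, Region.NORMAL)}
        self.k_e_star = (self.app[Region.TUMOUR].k_e_star_per_s
                         + self.app[Region.NORMAL].k_e_star_per_s)
        self.k_rel_star = _region_field(phantom, {
            "tumour": self.app[Region.TUMOUR].k_rel_star_per_s,
            "normal": self.app[Region.NORMAL].k_rel_star_per_s})
        self.v_ecs_over_omega = _region_field(phantom, {
            "tumour": self.app[Region.TUMOUR].v_star_factor,
            "normal": self.app[Region.NORMAL].v_star_factor})

        d_star_free = {r: self.app[Region[r.upper()]].d_star_m2_s for r in _REGIONS}
        self.g_free = self._face_conductances(d_star_free)
        if lipo is not None:
            self.g_lipo = self._face_conductances(lipo.d_ecs_m2_s)

        # advective velocities: raw faces for the conservative liposome form,
        # retention-scaled cell-centred components for the free-drug form
        self.face_v = self._masked_face_velocities()
        self.cell_v_star = (flow.cell_velocity()
                            * self.v_ecs_over_omega[..., None])

        # exchange fields
        self.sv = _region_field(phantom, {r: _p.TISSUE["sv_per_m"][r]
                                          for r in _REGIONS})
        self.sigma_free = _region_field(phantom, free.sigma)
        self.sigma_lipo = (_region_field(phantom, lipo.sigma)
                           if lipo is not None else None)
        self.f_b = flow.f_b

        self._check_stability()

    # -- assembly helpers ---------------------------------------------------
    def _face_conductances(self, d_by_region: dict[str, float]) -> list[np.ndarray]:
        """Harmonic-mean D/h² on interior-interior faces (zero elsewhere)."""
        dfield = _region_field(self.phantom, d_by_region)
        out = []
        for ax in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            both = self.interior[lo] & self.interior[hi]
            da, db = dfield[lo], dfield[hi]
            g = np.where(both & (da + db > 0),
                         2.0 * da * db / np.maximum(da + db, 1e-300), 0.0)
            out.append(g / self.h**2)
        return out

    def _masked_face_velocities(self) -> list[np.ndarray]:
        """Face velocities with zero drug flux through boundary faces."""
        out = []
        for ax, fv in enumerate(self.flow.face_velocity):
            mid = [slice(None)] * 3
            mid[ax] = slice(1, -1)
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            both = self.interior[tuple(lo)] & self.interior[tuple(hi)]
            v = np.zeros_like(fv)
            v[tuple(mid)] = np.where(both, fv[tuple(mid)], 0.0)
            out.append(v)
        return out

    def _check_stability(self) -> None:
        dt, h = self.dt, self.h
        diff_rate = sum(float(np.max(g)) for g in self.g_free) * 2.0
        if self.lipo is not None:
            diff_rate = max(diff_rate,
                            sum(float(np.max(g)) for g in self.g_lipo) * 2.0)
        if dt * diff_rate > 1.0 and not self.implicit_diffusion:
            raise StabilityError(
                f"explicit diffusion unstable: dt*rate = {dt * diff_rate:.3g} > 1 "
                f"(dt = {dt:g} s, spacing = {h:g} m); reduce dt or enable "
                "implicit diffusion")
        cfl = max(float(np.max(np.abs(v))) for v in self.face_v) * dt / h
        if cfl > 1.0:
            raise StabilityError(f"advective CFL = {cfl:.3g} > 1")
        react = float(np.max(np.abs(self.k_e_star))) + float(np.max(self.k_rel_star))
        if self.lipo is not None:
            react = max(react, self.lipo.k_rel_per_s)
        if dt * react > 1.0:
            raise StabilityError(f"reaction rate dt*k = {dt * react:.3g} > 1")

    # -- split sub-steps ----------------------------------------------------
    def _advect_conservative(self, c: np.ndarray) -> np.ndarray:
        """div(v C) update with first-order upwind face values."""
        dc = np.zeros_like(c)
        for ax, v in enumerate(self.face_v):
            mid = [slice(None)] * 3
            mid[ax] = slice(1, -1)
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            vm = v[tuple(mid)]
            flux = np.where(vm > 0, vm * c[lo], vm * c[hi])
            dc[lo] -= flux / self.h
            dc[hi] += flux / self.h
        return c + self.dt * dc

    def _advect_gradient(self, c: np.ndarray) -> np.ndarray:
        """Non-conservative v*.grad(C) update, upwind one-sided differences."""
        dc = np.zeros_like(c)
        interior = self.interior
        for ax in range(3):
            u = self.cell_v_star[..., ax]
            back = (c - np.roll(c, 1, axis=ax)) / self.h
            fwd = (np.roll(c, -1, axis=ax) - c) / self.h
            # one-sided difference is valid only toward interior neighbours;
            # at zero-flux boundaries the gradient is taken as zero
            nb_lo = np.roll(interior, 1, axis=ax)
            nb_hi = np.roll(interior, -1, axis=ax)
            back = np.where(nb_lo, back, 0.0)
            fwd = np.where(nb_hi, fwd, 0.0)
            dc -= u * np.where(u > 0, back, fwd)
        return c + self.dt * np.where(interior, dc, 0.0)

    def _diffuse(self, c: np.ndarray, g: list[np.ndarray]) -> np.ndarray:
        if self.implicit_diffusion:
            return self._diffuse_implicit(c, g)
        dc = np.zeros_like(c)
        for ax, gax in enumerate(g):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            d = gax * (c[hi] - c[lo])
            dc[lo] += d
            dc[hi] -= d
        return c + self.dt * dc

    def _diffuse_implicit(self, c: np.ndarray, g: list[np.ndarray],
                          rtol: float = 1e-10) -> np.ndarray:
        """Backward-Euler diffusion via matrix-free CG on the full grid."""

        def apply_op(x_flat: np.ndarray) -> np.ndarray:
            x = x_flat.reshape(c.shape)
            dc = np.zeros_like(x)
            for ax, gax in enumerate(g):
                lo = [slice(None)] * 3
                hi = [slice(None)] * 3
                lo[ax] = slice(0, -1)
                hi[ax] = slice(1, None)
                lo, hi = tuple(lo), tuple(hi)
                d = gax * (x[hi] - x[lo])
                dc[lo] += d
                dc[hi] -= d
            return (x - self.dt * dc).ravel()

        from scipy.sparse.linalg import LinearOperator
        n = c.size
        op = LinearOperator((n, n), matvec=apply_op, dtype=np.float64)
        sol, info = _cg(op, c.ravel(), rtol=rtol, atol=0.0, maxiter=500)
        if info != 0:
            raise StabilityError("implicit diffusion CG did not converge")
        return sol.reshape(c.shape)

    def permeabilities(self, t0: float, t1: float) -> dict[str, dict[str, float]]:
        """Interval-averaged wall permeability per species and region."""
        out: dict[str, dict[str, float]] = {"free": {}, "lipo": {}}
        for r, reg in (("tumour", Region.TUMOUR), ("normal", Region.NORMAL)):
            out["free"][r] = permeability_average(t0, t1, self.protocol,
                                                  self.dox_agent, reg)
            if self.lipo_agent is not None:
                out["lipo"][r] = permeability_average(t0, t1, self.protocol,
                                                      self.lipo_agent, reg)
        return out

    # -- one full operator-split step --------------------------------------
    def step(self, state: ConcentrationState, c_l_ivs: float, c_f_ivs: float
             ) -> tuple[ConcentrationState, dict[str, dict[str, float]]]:
        """Advance both species by one dt; return new state and region-mean
        raw exchange terms {species: {region: <Ex> mg/mL/s}} for the plasma
        balance and flux diagnostics."""
        t0, dt = state.t_s, self.dt
        perm = self.permeabilities(t0, t0 + dt)
        c_f = state.c_f_ecs
        c_l = state.c_l_ecs

        # (a) advection
        c_f = self._advect_gradient(c_f)
        if self.lipo is not None:
            c_l = self._advect_conservative(c_l)
        # (b) diffusion
        c_f = self._diffuse(c_f, self.g_free)
        if self.lipo is not None:
            c_l = self._diffuse(c_l, self.g_lipo)
        # (c) reactions and transvascular exchange
        means: dict[str, dict[str, float]] = {"free": {}, "lipo": {}}
        p_free = _region_field(self.phantom, perm["free"])
        ex_f = patlak_flux(self.f_b, p_free, self.sigma_free, self.sv,
                           c_f_ivs, c_f).ex
        for r, reg in (("tumour", Region.TUMOUR), ("normal", Region.NORMAL)):
            m = self.phantom.mask(reg)
            means["free"][r] = float(np.mean(np.asarray(ex_f)[m])) if m.any() else 0.0
        rhs_f = -self.k_e_star * c_f + self.v_ecs_over_omega * np.asarray(ex_f)
        if self.lipo is not None:
            p_lipo = _region_field(self.phantom, perm["lipo"])
            ex_l = patlak_flux(self.f_b, p_lipo, self.sigma_lipo, self.sv,
                               c_l_ivs, c_l).ex
            for r, reg in (("tumour", Region.TUMOUR), ("normal", Region.NORMAL)):
                m = self.phantom.mask(reg)
                means["lipo"][r] = (float(np.mean(np.asarray(ex_l)[m]))
                                    if m.any() else 0.0)
            rhs_f = rhs_f + self.k_rel_star * c_l
            c_l = c_l + dt * np.where(self.interior,
                                      -self.lipo.k_rel_per_s * c_l
                                      + np.asarray(ex_l), 0.0)
        c_f = c_f + dt * np.where(self.interior, rhs_f, 0.0)

        c_f = self._clip(c_f)
        c_l = self._clip(c_l) if self.lipo is not None else c_l
        return ConcentrationState(t0 + dt, c_l, c_f), means

    def _clip(self, c: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(c)):
            raise NegativeConcentrationError("non-finite concentration")
        tol = 1e-14 + 1e-10 * float(np.max(c, initial=0.0))
        if float(np.min(c)) < -tol:
            raise NegativeConcentrationError(
                f"concentration {np.min(c):.3e} below -{tol:.1e}")
        return np.maximum(c, 0.0)


def advance_tissue(model: TissueTransport, state: ConcentrationState,
                   c_l_ivs: float, c_f_ivs: float) -> ConcentrationState:
    """One operator-split transport step (see :meth:`TissueTransport.step`)."""
    return model.step(state, c_l_ivs, c_f_ivs)[0]


# ---------------------------------------------------------------------------
# Full simulation driver
# ---------------------------------------------------------------------------
MODES = ("direct_bbbd", "liposome", "liposome_bbbd")


@dataclass
class SimulationResult:
    """Sampled compartment timelines plus the final fields."""

    mode: str
    times_s: np.ndarray
    c_l_ivs: np.ndarray
    c_f_ivs: np.ndarray
    c_l_ecs_tumour: np.ndarray
    c_f_ecs_tumour: np.ndarray
    c_l_ecs_normal: np.ndarray
    c_f_ecs_normal: np.ndarray
    flux_free_tumour: np.ndarray    # region-mean Ex of free drug (mg/mL/s)
    flux_lipo_tumour: np.ndarray
    final_state: ConcentrationState | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.times_s,
            "C_L_IVS": self.c_l_ivs, "C_F_IVS": self.c_f_ivs,
            "C_L_ECS_tumour": self.c_l_ecs_tumour,
            "C_F_ECS_tumour": self.c_f_ecs_tumour,
            "C_L_ECS_normal": self.c_l_ecs_normal,
            "C_F_ECS_normal": self.c_f_ecs_normal,
            "Ex_free_tumour": self.flux_free_tumour,
            "Ex_lipo_tumour": self.flux_lipo_tumour,
        })


def simulate(phantom: VoxelPhantom, flow: FlowField, mode: str,
             protocol: SonicationProtocol, regimen: DoseRegimen,
             free: SpeciesTissueParams, lipo: SpeciesTissueParams,
             dox_agent: AgentTransvascular, lipo_agent: AgentTransvascular,
             t_end_s: float = 86400.0, dt_s: float = 10.0,
             output_interval_s: float = 60.0,
             implicit_diffusion: bool = False,
             keep_final_state: bool = True) -> SimulationResult:
    """Run one delivery scenario on the phantom.

    The steady flow field is taken as given (solved once); plasma and
    tissue are stepped together at ``dt_s`` from zero initial drug
    everywhere, and volume-averaged compartment concentrations are recorded
    every ``output_interval_s``. Modes:

    * ``direct_bbbd`` — bolus free doxorubicin, closed-form plasma decay,
      sonication-enhanced free-drug permeability;
    * ``liposome`` — liposomal delivery, intact BBB (free drug cannot cross);
    * ``liposome_bbbd`` — liposomal delivery plus sonication.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    n_steps = round(t_end_s / dt_s)
    if abs(n_steps * dt_s - t_end_s) > 1e-9 * max(t_end_s, 1.0):
        raise ValueError("t_end must be a multiple of dt")
    every = max(1, round(output_interval_s / dt_s))

    liposomal = mode in ("liposome", "liposome_bbbd")
    if mode == "liposome":
        # intact barrier for the free drug: no enhancement anywhere
        dox_agent = dox_agent.with_ps(0.0)
        lipo_agent = lipo_agent.with_ps(0.0)

    model = TissueTransport(
        phantom, flow, free, lipo if liposomal else None, dox_agent,
        lipo_agent if liposomal else None, protocol, dt_s=dt_s,
        implicit_diffusion=implicit_diffusion)

    masks = {r: phantom.mask(Region[r.upper()]) for r in _REGIONS}
    vols = {r: phantom.region_volume(Region[r.upper()]) for r in _REGIONS}
    state = ConcentrationState(0.0, np.zeros(phantom.grid_shape),
                               np.zeros(phantom.grid_shape))
    c_f_ivs = (float(direct_plasma_concentration(0.0, regimen)[1])
               if mode == "direct_bbbd" else 0.0)

    rec: dict[str, list[float]] = {k: [] for k in (
        "t", "c_l_ivs", "c_f_ivs", "clt", "cft", "cln", "cfn", "exf", "exl")}

    def record(t: float, c_l_ivs_t: float, c_f_ivs_t: float,
               means: dict[str, dict[str, float]]) -> None:
        rec["t"].append(t)
        rec["c_l_ivs"].append(c_l_ivs_t)
        rec["c_f_ivs"].append(c_f_ivs_t)
        rec["clt"].append(float(np.mean(state.c_l_ecs[masks["tumour"]])))
        rec["cft"].append(float(np.mean(state.c_f_ecs[masks["tumour"]])))
        rec["cln"].append(float(np.mean(state.c_l_ecs[masks["normal"]])))
        rec["cfn"].append(float(np.mean(state.c_f_ecs[masks["normal"]])))
        rec["exf"].append(means["free"].get("tumour", 0.0))
        rec["exl"].append(means["lipo"].get("tumour", 0.0))

    c_l_ivs = float(liposome_plasma_concentration(0.0, regimen)) if liposomal else 0.0
    record(0.0, c_l_ivs, c_f_ivs, {"free": {}, "lipo": {}})

    h3 = phantom.voxel_volume
    for n in range(n_steps):
        t = n * dt_s
        if n % 100 == 0 and n > 0:
            log.info("t = %.0f s (%d/%d): tissue free-drug mass %.3e mg, "
                     "max C_F %.3e mg/mL", t, n, n_steps,
                     float(state.c_f_ecs.sum()) * h3 * 1e6,
                     float(state.c_f_ecs.max()))
        c_l_ivs = (float(liposome_plasma_concentration(t, regimen))
                   if liposomal else 0.0)
        if mode == "direct_bbbd":
            c_f_ivs = float(direct_plasma_concentration(t, regimen)[1])
        state, means = model.step(state, c_l_ivs, c_f_ivs)
        if liposomal:
            c_f_ivs = free_plasma_step(
                c_f_ivs, t, dt_s, regimen,
                exchange_mg_ml_s=means["free"], region_volumes_m3=vols)
        if (n + 1) % every == 0 or n == n_steps - 1:
            t1 = (n + 1) * dt_s
            c_l_now = (float(liposome_plasma_concentration(t1, regimen))
                       if liposomal else 0.0)
            c_f_now = (float(direct_plasma_concentration(t1, regimen)[1])
                       if mode == "direct_bbbd" else c_f_ivs)
            record(t1, c_l_now, c_f_now, means)

    return SimulationResult(
        mode=mode, times_s=np.array(rec["t"]),
        c_l_ivs=np.array(rec["c_l_ivs"]), c_f_ivs=np.array(rec["c_f_ivs"]),
        c_l_ecs_tumour=np.array(rec["clt"]), c_f_ecs_tumour=np.array(rec["cft"]),
        c_l_ecs_normal=np.array(rec["cln"]), c_f_ecs_normal=np.array(rec["cfn"]),
        flux_free_tumour=np.array(rec["exf"]),
        flux_lipo_tumour=np.array(rec["exl"]),
        final_state=state if keep_final_state else None)
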