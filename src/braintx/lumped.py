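"""Lumped (well-mixed) two-compartment reduction of the tissue model.

Treats tumour and normal tissue as spatially uniform compartments driven by
their region-mean Starling filtration rate from the steady flow solve. The
intra-tissue diffusion and advection terms drop out (they redistribute drug
within a region but barely move its volume average on the treatment time
scale), leaving per region r the ODEs

    dC_L,r/dt = -k_rel C_L,r + Ex(C_L,IVS, C_L,r)
    dC_F,r/dt = -k_e*_r C_F,r + (v_ECS/omega)_r Ex(C_F,IVS, C_F,r)
                + k_rel*_r C_L,r

coupled to the same plasma balance as the full model. This reduction is
orders of magnitude faster and is the workhorse for 24 h scenario sweeps;
its known blind spot is normal tissue, which in the full model receives
drug from the tumour by interstitial transport but here stays at zero
whenever its own vasculature is closed to the agent.
"""

from __future__ import annotations

import numpy as np

from . import params as _p
from .bbbd import AgentTransvascular, SonicationProtocol, permeability_average
from .flow import FlowField, region_mean_starling
from .phantom import Region, VoxelPhantom
from .plasma import (DoseRegimen, direct_plasma_concentration,
                     free_plasma_step, liposome_plasma_concentration)
from .transport import MODES, SimulationResult, SpeciesTissueParams, omega, patlak_flux

_REGIONS = ("tumour", "normal")


def simulate_lumped(phantom: VoxelPhantom, flow: FlowField, mode: str,
                    protocol: SonicationProtocol, regimen: DoseRegimen,
                    free: SpeciesTissueParams, lipo: SpeciesTissueParams,
                    dox_agent: AgentTransvascular,
                    lipo_agent: AgentTransvascular,
                    t_end_s: float = 86400.0, dt_s: float = 10.0,
                    output_interval_s: float = 60.0) -> SimulationResult:
    """Run a delivery scenario on the two-compartment reduction.

    Mirrors :func:`braintx.transport.simulate` (same modes, same plasma
    coupling, same interval-averaged permeabilities) with region-mean
    states instead of fields.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    n_steps = round(t_end_s / dt_s)
    every = max(1, round(output_interval_s / dt_s))
    liposomal = mode in ("liposome", "liposome_bbbd")
    if mode == "liposome":
        dox_agent = dox_agent.with_ps(0.0)
        lipo_agent = lipo_agent.with_ps(0.0)

    f_b = region_mean_starling(flow, phantom)
    vols = {r: phantom.region_volume(Region[r.upper()]) for r in _REGIONS}
    sv = {r: _p.TISSUE["sv_per_m"][r] for r in _REGIONS}
    w = {r: omega(free, r) for r in _REGIONS}
    k_e_star = {r: ((free.v_ecs[r] + free.v_ics[r]) * free.k_e_per_s
                    + f_b[r]) / w[r] for r in _REGIONS}
    k_rel_star = {r: free.k_rel_per_s / w[r] for r in _REGIONS}
    vfac = {r: free.v_ecs[r] / w[r] for r in _REGIONS}
    reg_enum = {"tumour": Region.TUMOUR, "normal": Region.NORMAL}

    c_l = {r: 0.0 for r in _REGIONS}
    c_f = {r: 0.0 for r in _REGIONS}
    c_f_ivs = (float(direct_plasma_concentration(0.0, regimen)[1])
               if mode == "direct_bbbd" else 0.0)
    c_l_ivs = float(liposome_plasma_concentration(0.0, regimen)) if liposomal else 0.0

    rec = {k: [] for k in ("t", "c_l_ivs", "c_f_ivs", "clt", "cft", "cln",
                           "cfn", "exf", "exl")}

    def record(t, cliv, cfiv, exf, exl):
        rec["t"].append(t)
        rec["c_l_ivs"].append(cliv)
        rec["c_f_ivs"].append(cfiv)
        rec["clt"].append(c_l["tumour"])
        rec["cft"].append(c_f["tumour"])
        rec["cln"].append(c_l["normal"])
        rec["cfn"].append(c_f["normal"])
        rec["exf"].append(exf)
        rec["exl"].append(exl)

    record(0.0, c_l_ivs, c_f_ivs, 0.0, 0.0)

    for n in range(n_steps):
        t = n * dt_s
        c_l_ivs = (float(liposome_plasma_concentration(t, regimen))
                   if liposomal else 0.0)
        if mode == "direct_bbbd":
            c_f_ivs = float(direct_plasma_concentration(t, regimen)[1])

        ex_f, ex_l = {}, {}
        for r in _REGIONS:
            p_f = permeability_average(t, t + dt_s, protocol, dox_agent,
                                       reg_enum[r])
            ex_f[r] = float(patlak_flux(f_b[r], p_f, free.sigma[r], sv[r],
                                        c_f_ivs, c_f[r]).ex)
            if liposomal:
                p_l = permeability_average(t, t + dt_s, protocol, lipo_agent,
                                           reg_enum[r])
                ex_l[r] = float(patlak_flux(f_b[r], p_l, lipo.sigma[r], sv[r],
                                            c_l_ivs, c_l[r]).ex)

        for r in _REGIONS:
            rhs_f = (-k_e_star[r] * c_f[r] + vfac[r] * ex_f[r])
            if liposomal:
                rhs_f += k_rel_star[r] * c_l[r]
                c_l[r] = max(c_l[r] + dt_s * (-lipo.k_rel_per_s * c_l[r]
                                              + ex_l[r]), 0.0)
            c_f[r] = max(c_f[r] + dt_s * rhs_f, 0.0)

        if liposomal:
            c_f_ivs = free_plasma_step(c_f_ivs, t, dt_s, regimen,
                                       exchange_mg_ml_s=ex_f,
                                       region_volumes_m3=vols)
        if (n + 1) % every == 0 or n == n_steps - 1:
            t1 = (n + 1) * dt_s
            cliv = (float(liposome_plasma_concentration(t1, regimen))
                    if liposomal else 0.0)
            cfiv = (float(direct_plasma_concentration(t1, regimen)[1])
                    if mode == "direct_bbbd" else c_f_ivs)
            record(t1, cliv, cfiv, ex_f["tumour"],
                   ex_l.get("tumour", 0.0) if liposomal else 0.0)

    return SimulationResult(
        mode=mode, times_s=np.array(rec["t"]),
        c_l_ivs=np.array(rec["c_l_ivs"]), c_f_ivs=np.array(rec["c_f_ivs"]),
        c_l_ecs_tumour=np.array(rec["clt"]), c_f_ecs_tumour=np.array(rec["cft"]),
        c_l_ecs_normal=np.array(rec["cln"]), c_f_ecs_normal=np.array(rec["cfn"]),
        flux_free_tumour=np.array(rec["exf"]),
        flux_lipo_tumour=np.array(rec["exl"]), final_state=None)
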