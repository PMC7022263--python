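"""TOML configuration layer over the model defaults.

The configuration mirrors the parameter tables as nested groups with
unit-suffixed keys. An empty file reproduces the baseline parameter set
exactly; overrides are merged key-by-key, every overridden key is logged,
and unknown keys or out-of-range values are rejected rather than silently
ignored. A single ``liposome.k_rel_per_s`` value feeds both the plasma
release source and the tissue release terms (single source of truth).
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

from . import params as _p
from .bbbd import AgentTransvascular, SonicationProtocol
from .flow import HydraulicParams, RegionHydraulics
from .phantom import PhantomSpec
from .plasma import DoseRegimen
from .scenarios import ModelBundle, Scenario
from .transport import SpeciesTissueParams

log = logging.getLogger("braintx.config")


class ConfigError(ValueError):
    """Unknown key or invalid value in a configuration file."""


def default_config_dict() -> dict[str, Any]:
    """The full baseline configuration as a nested dictionary."""
    d, lp, t = _p.DOXORUBICIN, _p.LIPOSOME, _p.TISSUE
    return {
        "drug": {
            "mw_da": d["mw_da"],
            "d_h_nm": d["d_h_nm"],
            "mw_mode": "kDa",            # unit of MW in the Ps correlation
            "ps_override_m_s": -1.0,     # <0 means "use the correlation"
            "p_ics_ecs": d["p_ics_ecs"], "p_cm_ecs": d["p_cm_ecs"],
            "k_ivs": d["k_ivs"], "k_ecs": d["k_ecs"], "k_ics": d["k_ics"],
            "d_ecs_tumour_m2_s": d["d_ecs_m2_s"]["tumour"],
            "d_ecs_normal_m2_s": d["d_ecs_m2_s"]["normal"],
            "sigma_tumour": d["sigma"]["tumour"],
            "sigma_normal": d["sigma"]["normal"],
            "k_e_per_s": d["k_e_per_s"], "k_c_per_s": d["k_c_per_s"],
            "v_d_m3": d["v_d_m3"],
        },
        "liposome": {
            "d_h_nm": lp["d_h_nm"],
            "enhancement_factor": lp["enhancement_factor"],
            "d_ecs_tumour_m2_s": lp["d_ecs_m2_s"]["tumour"],
            "d_ecs_normal_m2_s": lp["d_ecs_m2_s"]["normal"],
            "p0_tumour_m_s": lp["p0_m_s"]["tumour"],
            "p0_normal_m_s": lp["p0_m_s"]["normal"],
            "sigma_tumour": lp["sigma"]["tumour"],
            "sigma_normal": lp["sigma"]["normal"],
            "k_c_per_s": lp["k_c_per_s"], "k_rel_per_s": lp["k_rel_per_s"],
            "v_d_m3": lp["v_d_m3"],
        },
        "tissue": {
            "v_ecs_tumour": t["v_ecs"]["tumour"], "v_ecs_normal": t["v_ecs"]["normal"],
            "v_ics_tumour": t["v_ics"]["tumour"], "v_ics_normal": t["v_ics"]["normal"],
            "rho_kg_m3": t["rho_kg_m3"], "mu_kg_m_s": t["mu_kg_m_s"],
            "pi_b_pa": t["pi_b_pa"],
            "pi_i_tumour_pa": t["pi_i_pa"]["tumour"],
            "pi_i_normal_pa": t["pi_i_pa"]["normal"],
            "p_b_pa": t["p_b_pa"],
            "sv_tumour_per_m": t["sv_per_m"]["tumour"],
            "sv_normal_per_m": t["sv_per_m"]["normal"],
            "sigma_t_tumour": t["sigma_t"]["tumour"],
            "sigma_t_normal": t["sigma_t"]["normal"],
            "k_b_tumour_m_pa_s": t["k_b_m_pa_s"]["tumour"],
            "k_b_normal_m_pa_s": t["k_b_m_pa_s"]["normal"],
            "kappa_tumour_m2": t["kappa_m2"]["tumour"],
            "kappa_normal_m2": t["kappa_m2"]["normal"],
        },
        "boundary": {
            "p_surface_pa": _p.BOUNDARY["p_surface_pa"],
            "p_ventricle_pa": _p.BOUNDARY["p_ventricle_pa"],
        },
        "regimen": {
            "dose_per_area_mg_m2": _p.REGIMEN["dose_per_area_mg_m2"],
            "body_surface_area_m2": _p.REGIMEN["body_surface_area_m2"],
        },
        "phantom": {
            "voxel_spacing_m": 2.0e-3,
            "tumour_offset_fraction": _p.GEOMETRY["tumour_offset_fraction"],
        },
        "sonication": {
            "delay_s": 0.0,
            "duration_s": 0.0,
        },
        "scenario": {
            "mode": "liposome_bbbd",
            "t_end_s": 86400.0,
            "dt_s": 10.0,
            "output_interval_s": 60.0,
        },
    }


_POSITIVE = {  # keys that must be strictly positive
    "mw_da", "d_h_nm", "v_d_m3", "rho_kg_m3", "mu_kg_m_s",
    "voxel_spacing_m", "t_end_s", "dt_s", "output_interval_s",
    "body_surface_area_m2", "k_rel_per_s",
}
_NONNEGATIVE_PREFIXES = ("d_ecs", "k_e", "k_c", "k_b", "kappa", "sv_", "p0_",
                         "k_ivs", "k_ecs", "k_ics", "p_ics", "p_cm", "pi_",
                         "p_b", "p_surface", "p_ventricle", "delay", "duration",
                         "dose_per_area", "v_ecs", "v_ics", "enhancement")
_UNIT_INTERVAL_PREFIXES = ("sigma",)


def _validate_leaf(path: str, key: str, value: Any) -> None:
    if isinstance(value, bool) or isinstance(value, str):
        return
    if not isinstance(value, (int, float)):
        raise ConfigError(f"{path}: value must be a number, got {value!r}")
    if key in _POSITIVE and value <= 0:
        raise ConfigError(f"{path} = {value}: must be positive")
    if key.startswith(_UNIT_INTERVAL_PREFIXES) and not 0.0 <= value <= 1.0:
        raise ConfigError(f"{path} = {value}: must lie in [0, 1]")
    if (key.startswith(_NONNEGATIVE_PREFIXES) and key not in _POSITIVE
            and value < 0):
        raise ConfigError(f"{path} = {value}: must be nonnegative")


def _merge(base: dict, override: dict, prefix: str = "") -> list[str]:
    changed = []
    for key, value in override.items():
        path = f"{prefix}{key}"
        if key not in base:
            raise ConfigError(f"unknown configuration key {path!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{path}: expected a table")
            changed += _merge(base[key], value, prefix=path + ".")
        else:
            _validate_leaf(path, key, value)
            if value != base[key]:
                changed.append(f"{path} = {value!r} (default {base[key]!r})")
            base[key] = value
    return changed


@dataclass
class ModelConfig:
    """Validated configuration: raw dict plus typed builders."""

    data: dict[str, Any]
    overridden: list[str] = field(default_factory=list)

    @classmethod
    def defaults(cls) -> "ModelConfig":
        return cls(data=default_config_dict())

    # -- typed views --------------------------------------------------------
    def phantom_spec(self) -> PhantomSpec:
        ph = self.data["phantom"]
        return PhantomSpec.default(
            voxel_spacing=ph["voxel_spacing_m"],
            tumour_offset_fraction=ph["tumour_offset_fraction"])

    def hydraulics(self) -> HydraulicParams:
        t, b = self.data["tissue"], self.data["boundary"]

        def region(r: str) -> RegionHydraulics:
            return RegionHydraulics(
                kappa_m2=t[f"kappa_{r}_m2"], k_b_m_pa_s=t[f"k_b_{r}_m_pa_s"],
                sv_per_m=t[f"sv_{r}_per_m"], sigma_t=t[f"sigma_t_{r}"],
                pi_i_pa=t[f"pi_i_{r}_pa"])

        return HydraulicParams(
            tumour=region("tumour"), normal=region("normal"),
            p_b_pa=t["p_b_pa"], pi_b_pa=t["pi_b_pa"],
            rho_kg_m3=t["rho_kg_m3"], mu_kg_m_s=t["mu_kg_m_s"],
            p_surface_pa=b["p_surface_pa"], p_ventricle_pa=b["p_ventricle_pa"])

    def bundle(self) -> ModelBundle:
        d, lp, t = self.data["drug"], self.data["liposome"], self.data["tissue"]
        v_ecs = {"tumour": t["v_ecs_tumour"], "normal": t["v_ecs_normal"]}
        v_ics = {"tumour": t["v_ics_tumour"], "normal": t["v_ics_normal"]}
        free = SpeciesTissueParams(
            name="free_doxorubicin",
            d_ecs_m2_s={"tumour": d["d_ecs_tumour_m2_s"],
                        "normal": d["d_ecs_normal_m2_s"]},
            sigma={"tumour": d["sigma_tumour"], "normal": d["sigma_normal"]},
            k_e_per_s=d["k_e_per_s"], k_rel_per_s=lp["k_rel_per_s"],
            v_ecs=v_ecs, v_ics=v_ics,
            p_ics_ecs=d["p_ics_ecs"], p_cm_ecs=d["p_cm_ecs"],
            k_ecs=d["k_ecs"], k_ics=d["k_ics"])
        lipo = SpeciesTissueParams(
            name="liposome",
            d_ecs_m2_s={"tumour": lp["d_ecs_tumour_m2_s"],
                        "normal": lp["d_ecs_normal_m2_s"]},
            sigma={"tumour": lp["sigma_tumour"], "normal": lp["sigma_normal"]},
            k_e_per_s=0.0, k_rel_per_s=lp["k_rel_per_s"],
            v_ecs=v_ecs, v_ics=v_ics, confined_to_ecs=True)
        regimen = DoseRegimen(
            dose_per_area_mg_m2=self.data["regimen"]["dose_per_area_mg_m2"],
            body_surface_area_m2=self.data["regimen"]["body_surface_area_m2"],
            v_f_d_m3=d["v_d_m3"], v_l_d_m3=lp["v_d_m3"],
            k_f_c_per_s=d["k_c_per_s"], k_l_c_per_s=lp["k_c_per_s"],
            k_rel_per_s=lp["k_rel_per_s"], k_ivs=d["k_ivs"])
        dox_agent = AgentTransvascular.doxorubicin(
            d_h_nm=d["d_h_nm"],
            ps_override_m_s=(d["ps_override_m_s"]
                             if d["ps_override_m_s"] >= 0 else None),
            mw_mode=d["mw_mode"])
        dox_agent = replace(dox_agent,
                            sigma={"tumour": d["sigma_tumour"],
                                   "normal": d["sigma_normal"]})
        lipo_agent = AgentTransvascular(
            name="liposome",
            p0_m_s={"tumour": lp["p0_tumour_m_s"], "normal": lp["p0_normal_m_s"]},
            ps_m_s=(lp["enhancement_factor"] - 1.0) * lp["p0_tumour_m_s"],
            sigma={"tumour": lp["sigma_tumour"], "normal": lp["sigma_normal"]},
            d_h_nm=lp["d_h_nm"])
        return ModelBundle(hydraulics=self.hydraulics(), regimen=regimen,
                           free=free, lipo=lipo, dox_agent=dox_agent,
                           lipo_agent=lipo_agent)

    def scenario(self) -> Scenario:
        sc, so = self.data["scenario"], self.data["sonication"]
        return Scenario(
            mode=sc["mode"], k_rel_per_s=self.data["liposome"]["k_rel_per_s"],
            protocol=SonicationProtocol(delay_s=so["delay_s"],
                                        duration_s=so["duration_s"]),
            t_end_s=sc["t_end_s"], dt_s=sc["dt_s"],
            output_interval_s=sc["output_interval_s"])


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a TOML config merged over the defaults; fully validated."""
    base = default_config_dict()
    changed: list[str] = []
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        changed = _merge(base, user)
        for line in changed:
            log.info("config override: %s", line)
    cfg = ModelConfig(data=base, overridden=changed)
    cfg.scenario()      # triggers cross-field validation
    cfg.hydraulics()
    return cfg


def non_default_keys(cfg: ModelConfig) -> dict[str, Any]:
    """Flat {dotted key: value} map of every key differing from defaults."""
    out: dict[str, Any] = {}

    def walk(base: dict, cur: dict, prefix: str = "") -> None:
        for k, v in cur.items():
            if isinstance(v, dict):
                walk(base[k], v, prefix=f"{prefix}{k}.")
            elif base[k] != v:
                out[f"{prefix}{k}"] = v

    walk(default_config_dict(), cfg.data)
    return out
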