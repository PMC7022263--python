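"""Baseline physical parameters for the brain-tumour drug-delivery model.

All values are the literature baselines for a human glioma and for free vs
liposome-encapsulated doxorubicin: transport properties of the two agents,
hydraulic properties of tumour and normal tissue, boundary pressures, and the
dosing regimen (50 mg/m² bolus to a 70 kg patient). Everything is SI except
concentrations, which are carried in mg/mL throughout to match the scale on
which exposure (AUC) is reported.

These dictionaries are the single source of truth: the typed parameter
objects in :mod:`braintx.flow`, :mod:`braintx.bbbd`, :mod:`braintx.plasma`
and :mod:`braintx.transport` all build their defaults from here, as does the
TOML config layer.
"""

from __future__ import annotations

import math

# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------
BOLTZMANN_J_PER_K = 1.380649e-23
BODY_TEMPERATURE_K = 310.0

#: Transvascular permeability of Gd-DTPA under 0.6 MPa sonication (m/s),
#: the reference point of the molecular-weight permeability correlation.
P_GD_DTPA_M_S = 2.0e-6

# ---------------------------------------------------------------------------
# Chemotherapeutic agents (free doxorubicin and PEGylated liposome)
# ---------------------------------------------------------------------------
DOXORUBICIN = {
    "mw_da": 543.5,                 # molecular weight (Da)
    "p_ics_ecs": 1.0,               # ICS/ECS partition coefficient
    "p_cm_ecs": 0.3,                # cell-membrane/ECS partition coefficient
    "k_ivs": 3.0,                   # plasma protein-binding constant
    "k_ecs": 3.0,
    "k_ics": 3.0,
    "d_ecs_m2_s": {"tumour": 3.4e-10, "normal": 1.6e-10},
    "p0_m_s": {"tumour": 0.0, "normal": 0.0},   # intact BBB blocks free dox
    "sigma": {"tumour": 0.15, "normal": 0.15},
    "k_e_per_s": 5.8e-4,            # tissue elimination rate
    "k_c_per_s": 2.4e-3,            # plasma clearance rate
    "v_d_m3": 7.7e-3,               # distribution volume
    # Hydrodynamic diameter (nm). Consistent with the Einstein-Stokes
    # prediction for an aqueous diffusivity of order 5e-10 m²/s; gives a
    # barrier-recovery half-life of ~4.6 h for the free drug.
    "d_h_nm": 1.4,
}

LIPOSOME = {
    "d_ecs_m2_s": {"tumour": 9.0e-12, "normal": 5.8e-12},
    "p0_m_s": {"tumour": 3.4e-9, "normal": 0.0},
    "sigma": {"tumour": 0.95, "normal": 1.0},
    "k_e_per_s": 0.0,               # no tissue elimination for liposomes
    "k_c_per_s": 3.9e-6,
    "k_rel_per_s": 1.0e-4,          # drug release rate
    "v_d_m3": 6.4e-3,
    "d_h_nm": 120.0,
    # Sonication raises liposome wall permeability to ~4.25x baseline.
    "enhancement_factor": 4.25,
}

# ---------------------------------------------------------------------------
# Tissue (tumour / normal) and interstitial fluid
# ---------------------------------------------------------------------------
TISSUE = {
    "v_ecs": {"tumour": 0.35, "normal": 0.20},      # ECS volume fraction
    "v_ics": {"tumour": 0.55, "normal": 0.65},      # ICS volume fraction
    "rho_kg_m3": 1.0e3,
    "mu_kg_m_s": 7.8e-4,
    "pi_b_pa": 3.4e3,               # blood osmotic pressure
    "pi_i_pa": {"tumour": 1.1e3, "normal": 7.4e2},
    "p_b_pa": 4.6e3,                # intravascular pressure
    "sv_per_m": {"tumour": 2.0e4, "normal": 7.0e3},  # vascular surface density
    "sigma_t": {"tumour": 0.82, "normal": 0.91},     # protein reflection coeff
    "k_b_m_pa_s": {"tumour": 1.1e-12, "normal": 1.4e-13},
    "kappa_m2": {"tumour": 6.4e-14, "normal": 6.5e-15},
}

BOUNDARY = {
    "p_surface_pa": 658.0,          # gauge pressure on the brain surface
    "p_ventricle_pa": 1447.0,       # gauge pressure at the ventricle wall
}

# ---------------------------------------------------------------------------
# Dosing regimen
# ---------------------------------------------------------------------------
REGIMEN = {
    "dose_per_area_mg_m2": 50.0,
    "body_surface_area_m2": 1.8,    # adopted for a 70 kg patient
}

# ---------------------------------------------------------------------------
# Geometry targets
# ---------------------------------------------------------------------------
GEOMETRY = {
    "tumour_volume_m3": 2.47e-5,
    "normal_volume_m3": 1.39e-3,
    "ventricle_radius_m": 0.015,
    # Tumour centre offset from brain centre, as a fraction of the brain
    # radius; places the tumour superficially (near the brain surface).
    "tumour_offset_fraction": 0.55,
}


def dose_mg(dose_per_area_mg_m2: float = REGIMEN["dose_per_area_mg_m2"],
            body_surface_area_m2: float = REGIMEN["body_surface_area_m2"]) -> float:
    """Total administered dose in mg (50 mg/m² x 1.8 m² = 90 mg by default)."""
    return dose_per_area_mg_m2 * body_surface_area_m2


def sphere_radius_for_volume(volume_m3: float) -> float:
    """Radius of the sphere with the given volume."""
    return (3.0 * volume_m3 / (4.0 * math.pi)) ** (1.0 / 3.0)
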