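# Methods

This note documents the model implemented in `braintx`, the choices made
where the design was genuinely open, and what the synthetic phantom does and
does not establish about real anatomy.

## Geometry: the voxel phantom

The simulator targets a human brain carrying a single glioma next to the
ventricles. Rather than patient imaging, it uses a synthetic phantom of
three nested spheres on a regular isotropic grid: brain (radius 6.99 cm),
a central ventricle cavity (1.5 cm), and a tumour (1.806 cm) whose centre
sits at 0.55 × brain radius from the centre, i.e. superficially. Radii are
derived analytically from the calibration volumes — tumour 2.47 × 10⁻⁵ m³
and surrounding normal tissue 1.39 × 10⁻³ m³ — so the voxelized regions
reproduce them to ≲0.3% at 1–2 mm spacing. The superficial placement
matters: it produces the elevated tumour-interior pressure gradient toward
the nearby brain surface and hence the faster tumour interstitial flow.

Labels are assigned by voxel-centre membership; the tumour must voxelize to
a single connected component strictly inside the brain (checked). Default
spacing is 2 mm (1 mm available, matching typical MR resolution); the
convergence of voxel volumes to the analytic sphere volumes under
refinement is part of the test suite.

What the phantom does *not* emulate: irregular tumour margins, the
elongated high-surface-area shape of real lateral ventricles, gyri/sulci,
and heterogeneous vasculature. Consequences are visible and documented
below (flow speeds land at the low end of the measured range).

## Interstitial fluid flow

Tissue is a porous medium with a distributed Starling source:

    ∇·v = F_b,   v = −(κ/μ)∇p_i,
    F_b = K_b (S/V)[p_b − p_i − σ_T(π_b − π_i)].

At the micron-per-second velocities involved, the inertial and Brinkman
shear terms of the momentum balance are smaller than the Darcy drag by many
orders of magnitude, so the reduced Darcy–Starling elliptic problem is
solved instead of full Navier–Stokes; fluid density ρ is retained in the
parameter set but does not enter the reduced equations. Since F_b is affine
in p_i, the whole problem is a single symmetric positive-definite linear
system: 7-point finite volumes, harmonic-mean face mobility κ/μ (flux
continuity across the tumour/normal interface), face-centred Dirichlet
values (658 Pa brain surface, 1447 Pa ventricle; gauge pressures) imposed
through half-cell conductances. Jacobi-preconditioned conjugate gradients
solve it to a 10⁻¹⁰ relative residual (~2 s for 1.8 × 10⁵ unknowns at
2 mm). Discrete divergence equals the Starling source to solver tolerance,
and total filtration balances boundary outflow to <10⁻⁶ — both tested, along
with second-order convergence on a manufactured solution.

On the default phantom this yields mean IFP 1139 Pa (tumour) / 806 Pa
(normal) and mean speed 0.30 / 0.086 µm/s. The pressures bracket the
reference predictions (1071.79 / 876.03 Pa) within ±8%. The speeds sit
~30% below the reference values (0.43 / 0.13 µm/s), and the normal-tissue
mean falls just below the 0.1–1.0 µm/s experimental window: the compact
spherical ventricle presents far less inflow surface than a real ventricle
system, which starves the normal tissue of through-flow. This is a known
geometry artefact of the phantom, not a parameter choice.

## Barrier-disruption kinetics

Sonication with circulating microbubbles opens the barrier instantly (on
the model's time scale) and the opening recovers exponentially with a rate
that grows quadratically with agent size, k_r = ln2(1 + 0.21 d_H²)/2.34e4
(d_H in nm). Two consequences drive everything downstream: the 120 nm
liposome's enhancement (4.25× its baseline wall permeability) decays with a
7.74 s half-life — effectively a blip — while free doxorubicin
(d_H ≈ 1.4 nm, chosen via Einstein–Stokes from an aqueous diffusivity of
order 5 × 10⁻¹⁰ m²/s) keeps an open wall for hours (half-life ≈ 4.6 h).

The enhancement magnitude for small molecules is tied to the measured
Gd-DTPA permeability (2.0 × 10⁻⁶ m/s) by the correlation
P/P_Gd = 1 − 0.5·log₁₀(MW). Read with MW in daltons this is negative for
every drug heavier than 100 Da, doxorubicin included; the package therefore
defaults to the kilodalton reading (ratio 1.13 for doxorubicin, P_s =
2.26 × 10⁻⁶ m/s), which is near unity at the reference tracer's own mass.
The dalton reading is available but raises an explicit domain error rather
than silently producing a negative permeability; a direct P_s override
exists for users with measured values. Disruption is assumed uniform and
confined to the tumour vasculature; sonication schedules are a delay T_d
plus duration T_s, with "burst" = (T_s = 0, recovery from T_d).

Because the liposome enhancement half-life (7.74 s) is shorter than the
transport step (10 s), permeabilities enter each step as exact closed-form
interval averages rather than point samples; a point sample at the step
start would overweight the burst by ~50%.

## Systemic pharmacokinetics

Bolus dosing at 50 mg/m² over a 1.8 m² body surface (90 mg; the body
surface area is an adopted value for a 70 kg adult, configurable).
Encapsulated drug decays as a single exponential with k_Lc + k_rel (no
transvascular-loss feedback — tissue uptake of liposomes is a negligible
fraction of the plasma pool). Released free drug obeys

    (1 + K_IVS) dC_F/dt = k_rel C_L − Σ_r (V_r/V_Fd)⟨Ex⟩_r − k_Fc C_F,

where the (1 + K_IVS) factor comes from quasi-equilibrium protein binding
and ⟨Ex⟩_r is the volume-averaged transvascular exchange over region r.
The release source is deliberately k_rel·C_L with no distribution-volume
conversion — the governing balance is implemented exactly as stated in its
source, and the literalism is recorded here. The step uses an exponential
integrator (exact linear part, midpoint source), which matches the
zero-exchange two-exponential closed form to ~10⁻⁵ relative at 10 s steps.

A documented consequence of the literal balance: the plasma free-drug peak
falls at ≈1.0 h, whereas the reference solution shows ≈1.5 h. The
discrepancy propagates into every quantity that compares tissue against
plasma levels; see "Known limitations".

## Tissue transport

Both species live on NORMAL∪TUMOUR voxels, zero elsewhere, zero initial
drug. Liposomes are confined to the ECS (PEGylation blocks endocytosis)
and are transported in conservative form with the full Darcy velocity;
free drug is in fast partition/binding equilibrium with cells and membrane,
folded into the retention factor

    ω = υ_ECS(1+K_ECS) + υ_ICS P_ICS-ECS(1+K_ICS) + (1−υ_ECS−υ_ICS) P_CM-ECS

(3.63 tumour, 3.445 normal), and is advanced in non-conservative gradient
form with apparent coefficients D* = (υ_ECS/ω)D, v* = (υ_ECS/ω)v,
k_e* = [(υ_ECS+υ_ICS)k_e + F_b]/ω, k_rel* = k_rel/ω. The asymmetry between
the conservative liposome form and the non-conservative free-drug form is
preserved from the source model on purpose.

Transvascular exchange is the Patlak form with Pe = F_b(1−σ)/(P·S/V) and
the diffusive factor Pe/(e^Pe − 1) (series below |Pe| < 10⁻⁶, zero above
Pe = 700; verified against a 50-digit evaluation to 10⁻¹² relative). One
deliberate deviation from the bare formula: an intact barrier (P = 0)
blocks the *total* flux, convective term included. The convective term
alone (σ_F = 0.15) would leak free drug through a closed BBB, contradicting
the defining property of the system being modelled; the physical narrative
wins over the formula here. Exchange acts only in vascularised regions, and
enhancement only in the tumour.

Numerics: operator splitting (advection → diffusion → reaction/exchange),
first-order upwind advection, explicit 7-point diffusion, explicit
reactions, fixed dt = 10 s. At ≥1 mm spacing the explicit diffusion bound
has >100× margin for the default coefficients (stability is checked at
setup and violations raise an error naming the binding constraint). An
implicit backward-Euler diffusion option (matrix-free CG) exists for stiff
configurations. Drug flux is zero through the brain surface and ventricle
wall; concentrations are clipped at zero only within float-noise tolerance,
anything larger is an error. Halving dt changes 2 h region means by <1%
(tested). The Gaussian-spreading, mass-conservation and uniform-field
invariance checks in the test suite pin the split operators individually.

## Lumped two-compartment reduction

For 24 h scenario sweeps a well-mixed reduction treats tumour and normal
tissue as single compartments driven by their region-mean Starling source
from the flow solve, with the same plasma coupling, exchange law and
interval-averaged permeabilities but no intra-tissue transport. It is
orders of magnitude faster and reproduces the spatial model's orderings for
the release-rate/timing/duration sweeps. Its blind spot: normal tissue
receives drug *only* from the tumour by interstitial transport, so the
reduction keeps it at zero whenever its own vasculature is closed to the
agent; any normal-tissue question needs the spatial model.

## Problem sizes used by tests and drivers

Flow-field and 2 h enhancement computations run at 2 mm / dt = 10 s (the
reference configuration for those quantities); 24 h strategy comparisons
and the normal-tissue covariation check run the spatial model at
4 mm / dt = 60 s; the 24 h sweeps run on the lumped reduction at dt = 10 s.
Region-mean flow summaries move by <5% between 2 mm and 4 mm (tested), so
the coarse 24 h runs are adequate for ordering questions.

## Known limitations

* **Sphere-for-anatomy substitution.** IFP means match the reference within
  ±8%, IFV means are ~30% low and the normal-tissue mean speed
  (0.086 µm/s) lands marginally below the 0.1–1.0 µm/s measured window —
  attributable to the compact spherical ventricle (see above).
* **Plasma-vs-tissue balance.** With the literal plasma balance the
  release-fed tumour ECS level is high relative to plasma. Two downstream
  effects, both reported by the test suite rather than hidden: the 2 h
  sonication enhancement ratio computes to ≈1.48 (reference 2.08, reported
  in-vivo range 1.51–2.65 — just below its floor), and over the full 24 h
  the sonication-opened wall lets the release-fed tissue pool drain back to
  plasma, so the liposome+BBBD arm ends *below* the intact-barrier arm in
  tumour AUC, inverting the reference ranking. The early-time (≲4 h)
  behaviour — sonication multiplies tumour free-drug levels — is robust.
* **No microbubble pharmacokinetics, acoustics, spatial BBBD heterogeneity,
  thermo/pH-sensitive release, endocytosis, or cell-kill model**: all out
  of scope by design.
* The direct-injection arm's transvascular flux reverses sign at ~5 min
  (reference: ~30 min), another face of the plasma-balance literalism.
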