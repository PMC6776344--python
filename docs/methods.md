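# Methods

## System and scope

The package models a 1-D two-compartment cell: a polyelectrolyte solution
(carboxymethylcellulose as a cartilage proxy; fixed charge density
FCD ∈ {−73, −92, −108} mM in the reference experiments, always ≤ 0) for
z < 0, an uncharged semipermeable membrane, and 150 mM NaCl for z > 0. At
t = 0 a trace amount (0.33 mM) of the divalent anionic contrast agent
Gd(DTPA)²⁻ is added to the salt side and diffuses across. Modelling is
strictly 1-D (the experimental holder is a vertical tube imaged along its
axis); hydrodynamic convection is not solved — it is represented either by
truncating the salt domain at a clamped boundary (d_salt, 1–5 mm) or by an
instantaneous-mixing operator on the salt compartment.

## Donnan equilibrium with non-ideal corrections

Each ion's chemical potential is μᵢ = μᵢᶿ + RT ln cᵢ + μᵢᶜᵒʳʳ + zᵢFϕ. The
standard potential cancels from every difference used anywhere in the
package and is deliberately not represented. The non-ideal corrections enter
only as per-region constants; their polyelectrolyte−salt differences
Δμᵢᶜᵒʳʳ (units of RT) are inputs, taken for Na⁺ from independent Monte Carlo
electrolyte simulations, for Cl⁻ inferred from measured equilibrium
concentrations (`infer_delta_mu_cl`), and for Gd(DTPA)²⁻ from equilibrium
concentrations or dynamic profile matching (`infer_delta_mu_gd`,
`fit_delta_mu_gd_dynamic`). Computing Δμ from first principles is out of
scope.

Equating electrochemical potentials across the interface gives
cᵢ,p = cᵢ,s·exp(−Δμᵢ − zᵢψ) with the dimensionless potential ψ = FΔϕ/RT.
Electroneutrality closes the system; the residual
c_Na,p − c_Cl,p + FCD is strictly monotone in ψ, so a bracketed Brent solve
on ψ ∈ [−10, 10] is deterministic and globally convergent (tolerance
1e−14; solved states satisfy electroneutrality to better than 1e−10
relative). The trace contrast agent is excluded from the charge balance —
its charge is 2–3 orders of magnitude below the background — and
`neglected_gd_charge_fraction` reports the size of that neglect.

The small-|FCD| linearizations (potential
ψ ≈ ½(FCD/C − (Δμ_Na − Δμ_Cl)) and the three interfacial concentration
steps) are provided for insight and for the approximate-solution
comparisons; their error is second order in FCD/C (verified by a log–log
slope test). All Δ ("step") quantities are polyelectrolyte minus salt.

## Transport solvers

Both tiers are conservative finite-volume method-of-lines discretizations,
linear in the contrast-agent concentration because the background state is
steady (trace approximation), integrated with an adaptive implicit BDF
scheme (scipy's `solve_ivp`, analytic sparse Jacobian, no randomness).
Negative concentrations abort the run rather than being clipped.

**Resolved-interface tier.** The background Na⁺/Cl⁻/ψ problem is the
nonlinear Poisson–Boltzmann equation on a geometrically graded mesh (default
0.2 nm at z = 0 growing by 15% per cell to 0.1 mm; ~300 nodes for a 13 mm
cell), solved by damped Newton iteration. Boundary conditions: dψ/dz = 0 at
the polyelectrolyte bottom, ψ = 0 (reference) and 150 mM at the salt end.
The chemical-potential step is smoothed with an erf of width 1 nm — wide
enough to remove the singularity, narrow enough (vs the 0.78 nm Debye
length) not to move the macroscopic step; the FCD step uses the same
smoothing. The contrast-agent flux is discretized in Slotboom form
J = −(D/w)·∂(cw)/∂z with w = exp(μᶜᵒʳʳ/RT + zψ) and face resistances
integrated over half-cells, so the stationary state is exactly the
Boltzmann distribution and mass is conserved to solver tolerance. Default
integration tolerance rtol = 1e−6 (the 9-decade spread of cell sizes makes
tighter tolerances counterproductive for multi-day horizons).

**Macroscopic jump tier.** Pure diffusion per region (polyelectrolyte,
membrane, salt; per-region D), with the double layer replaced by the
partition jump c_p(0⁻) = ratio·c(0⁺) folded into the interface
transmissibility T = ab/(ar + b) (a, b the half-cell conductances), which
preserves linearity, conservation and the correct equilibrium. The two
tiers agree within 0.5% pointwise outside the interface cell for t ≥ 1 h
(tested at 0.02%). Salt-end boundary modes: Dirichlet clamp at d_salt
(the convection truncation), zero-flux (closed reservoir), an
interface-Dirichlet mode that prescribes the salt-side interface
concentration directly (used for clean length-scaling studies), and a
stirred mode in which the salt compartment is one well-mixed,
zero-internal-resistance cell evolving by mass balance (exported as a flat
profile over its extent).

The membrane thickness is not independently known; the default is 100 μm
with D = 1.5e−10 m²/s and zero FCD. Only the ratio thickness/D (the
membrane resistance) matters — the two are confounded — so both are
configuration parameters.

## Approximate analytic solution

For semi-infinite domains the field is erf-shaped in each phase with
time-independent interface values; flux matching gives
C_s(0⁺) = C_s,0/(1 + √(D_p/D_s)·ratio). The default uses the exact
exponential partition ratio; the linearized-ratio variant (used for
validity illustrations) degrades with |FCD| — max deviation from the
numerical solver ≈1.3% of C_s,0 at FCD = −50 mM vs ≈11% at −150 mM. The
solution is trusted for t < 0.1·L_p²/D_p (≈7 h for the 10 mm, 4e−10 m²/s
reference column); beyond that a warning is emitted. The
convective/bounded correction re-evaluates the interface value each time
from the supplied well-mixed salt concentration — a reconstruction of the
correction used in practice, not a closed form.

## μMRI reconstruction

Voxel-wise nonlinear least squares of the magnitude inversion-recovery
model |I| = I₀|1 − A·exp(−τ/T₁)| (32 logarithmic delays, 1.7 ms–15 s). The
absolute value folds the cost surface at the null τ = T₁ln A, so fits start
from the observed signal minimum (T₁ ≈ τ_null/ln 2) and fall back to a
log-spaced T₁ grid if the first solution is poor; A is bounded above 2 only
with a warning flag (A < 2 signals imperfect inversion or short repetition
time). Voxels whose recovery null is not sampled are flagged unidentifiable
and excluded from maps rather than reported. Parameter uncertainties follow
the Monte-Carlo recipe: refit synthetic curves equal to the fitted model
plus Gaussian noise at the RMS-residual amplitude (residual-σ variant;
seeded, reproducible). Concentration conversion uses
c = (1/T₁ − 1/T₁ᵖʳᵉ)/R with per-region relaxivities (salt 3.84, the
polyelectrolytes 3.92–3.96 (mM·s)⁻¹); small negative concentrations from
noise are preserved unclipped (clipping would bias spatial averages) with a
warning. "0.2 mm Gaussian smoothing" is interpreted as FWHM
(σ ≈ 85 μm) — the convention is not fixed by the source data — and is
configurable; reflective borders preserve the image sum. A configurable
exclusion band (default ±2 voxels ≈ ±174 μm around z = 0, plus the
membrane span) masks membrane artifacts.

## Parameter estimation

`fit_d_poly` jointly fits (D_p, interface scale) to all polyelectrolyte-side
(z, t) samples in a window, by default 2.5–6 h: late enough that the
membrane's influx lag is small, early enough that the far wall is
unreached. Two interface models: a single free constant (semi-infinite
regime) or a free scale times the measured time-dependent interface value
(`interface_scale_from_series`), which is the mode to use when the salt
side is stirred or a finite reservoir depletes/feeds the interface.
Residuals are weighted by per-point standard errors when present. Standard
errors come from the SVD of the Jacobian at the optimum. Known systematic:
with the default geometry (100 μm membrane, finite reservoir) the erf model
underestimates D_p by ≈3–4%; without a membrane the bias is <0.3%.
`fit_delta_mu_gd_dynamic` wraps the jump solver in a bounded deterministic
scalar minimization of profile misfit, initialized from the algebraic
estimate. `estimate_d_salt` locates the onset of convective flattening as
the smallest z where observed and diffusion-only salt profiles diverge
beyond 5%, clamped to the practical 1–5 mm range.

## Synthetic experiments

`ExperimentConfig` defaults are the reference experimental conditions:
150 mM NaCl, 0.33 mM initial contrast agent (the 0.36 mM as-prepared value
is available), FCD parameter sets as packaged, 10 mm polyelectrolyte +
0.1 mm membrane + ~13 mm salt column (closed, no convection), 87 × 100 μm
voxels, the 32-point τ grid, I₀ = 100, A = 2, Gaussian magnitude noise at
SNR 50 (Rician available; at low SNR it reproduces the signal floor at
recovery nulls). T₁ᵖʳᵉ defaults (3.2 s salt, 2.8 s polyelectrolyte) are
representative dilute-solution values; they cancel in the round trip.
One integer seed drives all noise; regeneration is byte-identical.

The generator emulates the statistical structure of the experiment — erf- or
solver-shaped fields, per-voxel magnitude noise, replicated y columns — but
not scanner physics (RARE readout artifacts, B1 inhomogeneity beyond the
scalar A, registration error) nor real convection patterns. Passing
closed-loop tests therefore validates the analysis chain and its noise
behaviour, not those instrument effects.

## Problem sizes used in validation

Acceptance-level checks run at desk scale by design: the resolved-tier
invariance run uses the full 10 mm + 3 mm geometry to 80 h (~300 graded
cells); analytic-vs-numerical comparisons use a 50 mm "long-domain" cell so
container walls stay out of reach within the validity window; the
closed-loop recovery uses 4 frames × ~130 × 6 voxels per seed, 10 seeds at
SNR 50. Equilibrium-limit tests use sub-mm closed cells where equilibration
is fast; the L² scaling test uses the interface-Dirichlet mode so the
polyelectrolyte length is the only length scale.

## Known limitations

- 1-D geometry only; no holder cross-section effects, no CFD convection.
- The membrane is a resistance layer; pore-scale physics is not modelled.
- Δμ corrections are constants per region (concentration-independent), as
  justified only at trace contrast-agent levels.
- The erf-model D fit inherits a small negative bias from the membrane lag
  (documented above); joint (D, Δμ) inference is deliberately not offered —
  estimation follows the sequential scheme.
- The exact closed forms of the bounded/convective analytic corrections are
  reconstructions; they are validated against the numerical solver, not
  against an external formula.
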