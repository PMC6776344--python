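# donnanflux

Donnan partitioning and 1-D electro-diffusive transport of charged MRI
contrast agents between a salt solution and a fixed-charge polyelectrolyte
solution — a quantitative model of how Gd(DTPA)²⁻ (the dGEMRIC contrast
agent) distributes in and diffuses into cartilage-like media — together with
the μMRI inversion-recovery T1 pipeline that turns image stacks into
concentration profiles and transport parameters.

It is written for biophysicists and MR researchers who study solute
transport in charged gels, cartilage and cartilage models: it predicts
equilibrium partitioning from non-ideal Donnan theory, simulates the full
time course of contrast-agent uptake, and estimates diffusion coefficients
and non-ideality corrections from measured (or synthetic) profile series.

## The model

A polyelectrolyte solution with fixed charge density FCD < 0 (mM of
elementary charge) occupies z < 0; 150 mM NaCl occupies z > 0 behind a
semipermeable membrane. Each mobile ion i carries an excess
chemical-potential correction μᵢᶜᵒʳʳ (units of RT) from electrostatic
correlations and steric crowding. At equilibrium,

    cᵢ,p = cᵢ,s · exp(−Δμᵢᶜᵒʳʳ/RT − zᵢψ),     ψ = FΔϕ/RT,

with ψ the dimensionless Donnan potential fixed by electroneutrality
c_Na,p − c_Cl,p + FCD = 0. Transport follows the Nernst–Planck flux
J = −D(∂c/∂z + c·∂(μᶜᵒʳʳ/RT + zψ)/∂z) with Poisson's equation for ψ; for
the trace-level divalent anion the nanometre double layer collapses to a
time-independent concentration jump c_p(0⁻)/c_s(0⁺) = exp(−Δμᶜᵒʳʳ/RT + 2ψ)
plus flux continuity, and the early/intermediate-time field is the
two-domain erf solution with interface values fixed by flux matching.
Concentration maps come from voxel-wise fits of the magnitude
inversion-recovery model |I| = I₀|1 − A·exp(−τ/T₁)| and the relaxivity
relation c = (1/T₁ − 1/T₁ᵖʳᵉ)/R.

Two solver tiers implement the transport: a resolved-interface
Poisson–Boltzmann/Nernst–Planck solver on a geometrically graded mesh
(sub-nm at the interface) and a macroscopic jump-condition solver for
multi-day runs; they agree to a fraction of a percent.

## Worked example

```bash
donnanflux equilibrium --set fcd-108 --linearized
```

prints (abridged):

```json
{
  "fcd_mM": -108.0,
  "psi": -0.2754931918586741,
  "c_na_poly_mM": 223.01264769099316,
  "c_cl_poly_mM": 115.01264769099318,
  "partition_ratio_gd": 0.7400878499234523,
  "delta_mu_cl_inferred_RT": -0.009899999999999964,
  "psi_linearized": -0.3044
}
```

Reading: at FCD = −108 mM the Donnan potential is ψ = −0.2755 (−7.1 mV),
Na⁺ is enriched to 223 mM and Cl⁻ depleted to 115 mM in the polyelectrolyte,
and the divalent contrast agent partitions at 0.74 — it reaches only 74% of
the adjacent salt-side concentration, which is why T1 maps of healthy
(GAG-rich, high-|FCD|) cartilage show less contrast agent. The linearized
small-|FCD| expression overestimates the potential (−0.3044), illustrating
why the exact solve matters at physiological charge densities.

The same quantities are available in Python:

```python
from donnanflux import get_parameter_set, solve_donnan_equilibrium

p = get_parameter_set("fcd-108")
state = solve_donnan_equilibrium(p.bath, p.na, p.cl, p.gd)
state.partition_ratio_gd   # 0.7400878499234523
```

Simulation, synthetic-experiment generation and stack analysis run through
`donnanflux simulate`, `donnanflux synth` and `donnanflux analyze` (see
`--help`), or through the library functions (`jump_interface_solver`,
`run_full_loop`, `fit_d_poly`, ...).

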