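# tumorperf

Hybrid vascularized-tumor simulator for interstitial fluid flow (IFF)
and drug delivery.

Solid tumors remodel their host vasculature — angiogenic sprouting at
the hypoxic rim, co-option and dilation of host vessels, wall
degeneration and collapse in the interior — and the leaky vessels that
remain raise the interstitial fluid pressure (IFP) toward blood
pressure. The resulting pressure plateau and outward rim flow shape how
a chemotherapeutic (Doxorubicin-like) drug distributes through the
tissue. `tumorperf` models this chain end to end at desk scale:
discrete vessel networks coupled to continuum tissue, for computational
oncology researchers who want a transparent, testable implementation of
every stage.

## Model components

- **Vessel networks on lattices** (`lattice`, `builder`): vessels occupy
  bonds of an FCC lattice (12 neighbors, 60° branching angles; a
  triangular lattice is the 2D desk-scale analogue). Synthetic
  arteriovenous trees grow stochastically from alternating boundary
  roots, are capillarized between arterial and venous terminals,
  remodeled by wall shear stress until the capillary count plateaus, and
  refined by hierarchical up-scaling. Radii obey Murray's law
  r_parent^α = Σ r_child^α (α = 3).
- **Hemodynamics** (`hemodynamics`): Poiseuille conductances
  πr⁴/(8ηl) with the Pries et al. in-vivo apparent viscosity η(d, H)
  (Fåhræus–Lindqvist effect, H = 0.45), Kirchhoff mass balance solved
  sparsely for nodal pressures, wall shear f = r|Δp|/(2l),
  radius-dependent root pressures.
- **Tissue continuum** (`continuum`): volume fractions of tumor, normal
  and necrotic cells plus ECM and interstitial fluid (closure Σφ = 1) on
  a staggered grid (h = 30 µm); Darcy-type cell motion down solid
  pressure gradients; a signed-distance level set for the tumor
  interface (WENO-free PDE redistancing with a subcell interface lock);
  quasi-stationary oxygen with vessel-surface sources; growth factor as
  capped linear kernels around hypoxic tumor cells.
- **Vascular remodeling** (`remodel`): per-hour stochastic rules —
  sprout initiation along the growth-factor gradient, tip migration and
  splitting, wall degeneration, circumferential dilation, collapse of
  degenerate low-shear vessels — with named RNG streams per rule.
- **Interstitial fluid** (`iff`): ∇·(K∇p) + Q(p) = 0 with Starling
  transvascular exchange λ_l (S/V)(p_v − p − σΔπ) deposited from uniform
  vessel-surface samples, lymphatic sinks λ_L S_L (p − p_L) absent
  inside the tumor, Darcy velocity u = −K∇p, per-channel source
  decomposition and diagnostics (vessel pressure decay length,
  extravasation ratio r_Γ).
- **Drug transport** (`drug`): two compartments — extracellular s₁
  (advected by IFF, diffusing, exchanging with vessels/lymphatics) and
  intracellular s₂ with uptake/release velocities k₁₂/k₂₁ = 100;
  bolus (e^{−t/τ}, τ = 1 h) and constant-infusion plasma schedules;
  exposure maps ICmax and ICAUC with region summaries.
- **Analysis** (`analysis`): profiles vs signed distance to the tumor
  edge, distance-to-vessel profiles with exponential penetration fits,
  region statistics, fluid-budget tables.

## Worked example

```python
from tumorperf.params import Parameters
from tumorperf.fixtures import make_fixture
from tumorperf.sampling import sample_surfaces
from tumorperf.iff import (assemble_and_solve_ifp, source_decomposition,
                           extravasation_ratio)
from tumorperf.hemodynamics import solve_nodal_pressures
from tumorperf.drug import compartment_ode_steady_ratio, saturation_time_h
from tumorperf.rng import named_stream

params = Parameters()
net, state = make_fixture("frozen-spherical-tumor", size=32, seed=1,
                          params=params)
samp = sample_surfaces(net, state.grid, named_stream(1, "demo"))
sol = assemble_and_solve_ifp(state, samp, params.iff)
src = source_decomposition(state, samp, sol, params.iff)
r_gamma = extravasation_ratio(state, net, solve_nodal_pressures(net), src)
tum = state.tumor_mask()
print(f"tumor IFP (mean/max): {sol.pressure[tum].mean():.2f} / "
      f"{sol.pressure.max():.2f} kPa")
print(f"far-field IFP:        {sol.pressure[state.theta > 300].mean():.2f} kPa")
print(f"extravasation ratio:  {r_gamma:.2e}")
print(f"steady s2/s1 ratio:   {compartment_ode_steady_ratio(params.drug):.1f}")
print(f"1 mm saturation time: {saturation_time_h(params.drug):.0f} h")
```

prints

```
tumor IFP (mean/max): 2.85 / 4.81 kPa
far-field IFP:        2.33 kPa
extravasation ratio:  5.85e-05
steady s2/s1 ratio:   100.0
1 mm saturation time: 1736 h
```

The frozen-tumor scene (a level-set sphere with degenerate, dilated
central vessels) shows the elevated tumor IFP with its drop toward the
host tissue; the extravasation ratio confirms that only a vanishing
fraction of tumor blood flow is lost to the interstitium (which
justifies leaving plasma loss out of the vascular mass balance); the
two-compartment ratio is the hundredfold intracellular enrichment of a
Doxorubicin-like drug; and the retarded-diffusion estimate shows why
day-long infusions stay far from saturating a tumor a millimetre from
its vessels.

A command-line interface mirrors the library:

```
tumorperf build-network --extent 13x16 --seed 3 -o net.h5
tumorperf fixtures frozen-spherical-tumor --size 24 -o scene.h5
tumorperf ifp scene.h5 -o ifp.h5
tumorperf drug scene.h5 --schedule bolus -o drug.h5
tumorperf analyze scene.h5 drug.h5 -o report/
```

## Layout

```
src/tumorperf/     lattice, hemodynamics, builder, continuum, remodel,
                   iff, drug, analysis, sampling, fixtures, params, io, cli
tests/             unit, property (hypothesis) and acceptance suites
docs/methods.md    model description, parameter provenance, numerics
scripts/           acceptance script
```
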