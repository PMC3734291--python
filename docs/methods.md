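# Methods

`tumorperf` couples a discrete blood-vessel network to continuum tissue
fields. This note records the model equations as implemented, where
each parameter value comes from, the numerical choices, and what the
desk-scale configurations do and do not demonstrate.

## Vessel networks and blood flow

Vessels occupy bonds of a face-centered-cubic lattice; sites are integer
triples (i+j+k even) whose Cartesian positions are derived from the
lattice constant, so all incidence tests are exact integer arithmetic.
Interior sites have 12 neighbors and distinct bond directions meet at
60°. The 2D desk mode uses the triangular lattice, the natural 2D
analogue with 6 neighbors and the same angles; every downstream module
is dimension-agnostic. Segments are straight (the endpoint offset is an
integer multiple of one neighbor offset) and an occupancy table forbids
two segments on one bond.

Blood flow is ideal Poiseuille pipe flow, conductance πr⁴/(8ηl), with
mass conservation at nodes; the resulting sparse linear system for the
nodal pressures is solved directly at desk scale and by
ILU-preconditioned GMRES above ~2·10⁴ nodes. The apparent viscosity is
the plasma viscosity (1.2·10⁻⁶ kPa·s) times the Pries et al. in-vivo
relative viscosity η_rel(d, H); hematocrit is fixed network-wide at the
human average H = 0.45. Note that the *in-vivo* law attains its
minimum near d ≈ 50 µm and rises steeply toward capillary diameters
(the in-vitro law's minimum near 7–10 µm does not apply); the tests
assert this in-vivo shape. Wall shear stress is r|Δp|/(2l).

Root boundary pressures as a function of vessel radius are logistic
fits to the measured microvascular pressure–radius relation: arterial
3.8 → 12 kPa rising with radius, venous 2.1 → 0.4 kPa falling, arterial
above venous everywhere. The physiological wall thickness used to
anchor permeabilities is the power-law fit w(r) = 0.181 r^1.07 µm
(≈0.8 µm capillaries, ≈12 µm for 50 µm arterioles). Both are smooth
calibrations to literature trends, exposed in `hemodynamics` and
swappable.

Extravasated plasma is *not* subtracted from the vascular mass balance:
the computed extravasation ratio r_Γ (see below) is of order 10⁻⁴–10⁻⁵,
so the coupling would not change the flow solution measurably.

## Network construction

Arterial/venous roots alternate along boundary sites. Trees grow by
appending structural elements — single bonds or Y-shaped triples — at
uniformly chosen leaves onto free bonds until no legal attachment
remains. Capillaries (r = 4 µm) temporarily bridge neighboring
arterial and venous terminals (straight, at most two bonds); terminal
radii are 5 µm (arterial) and 7 µm (venous) and higher-level radii
follow Murray's law with α = 3 (literature range 2.7–3.0). Shear-stress
remodeling then stochastically removes or extends terminal branches;
because the printed sources leave the shear→probability map open, we
use rank-based probabilities p_attach ∝ rank(f), p_remove ∝ 1−rank(f),
bounded away from 0 and 1 — it preserves the "high shear grows"
ordering without inventing constants. The stage ends when the moving
average of the capillary count changes by <1–2% over a configurable
window (default 50 sweeps; the smaller desk configs use 16–20).
Up-scaling subdivides the lattice (each segment then spans two bonds),
resets the spacing so the extent doubles, treats previous terminals as
new growth fronts, and repeats growth + remodeling. Dangling terminals
without capillaries are pruned at the end, so the final network is
fully perfused.

## Tissue continuum

State per grid cell: tumor φ_T, normal φ_N, necrotic φ_D cell
fractions, fixed ECM fraction (0.2), interstitial fluid as the closure
remainder. All cells share one velocity v = −(μE)∇p_solid with
p_solid = (φ − φ₀)₊ in modulus units, φ₀ = 0.4, and the combined
mobility·modulus 2000 µm²/h chosen so rim speeds are a few µm/h,
matching millimetre-per-month growth. Because v derives from φ itself
the transport is a degenerate porous-medium diffusion; the stable step
h²/(2·ndim·μE·φ_max) is enforced alongside the advective CFL.

Tumor and normal cells are immiscible: the interface is a signed
distance θ (negative inside), advected with v (second-order ENO
gradients, Heun) and periodically redistanced by the Godunov
Hamiltonian iteration with the Russo–Smereka subcell fix. The
redistanced field satisfies |∇θ| ∈ [0.95, 1.05] in smooth bands; near
the distance function's skeleton (e.g. a sphere's center) central
differences legitimately undershoot, which the audits exclude. The
tumor/normal split of the advected viable fraction is re-derived each
step as φ_v·(1−H(θ)) / φ_v·H(θ) with a smoothed Heaviside of width h —
this keeps the closure exact across the moving front.

Net phase kinetics: proliferation min(r_p, r_a + k(φ_h − φ))·H(c −
c_prol) with k = sensitivity·r_p (sensitivity 10), apoptosis at
constant rate r_a, necrosis transfer at r_n·H(c_necro − c). At the
homeostatic fraction (0.6 tumor, 0.4 normal) proliferation and
apoptosis cancel; the net rate is linear in φ around it; necrotic loss
transfers mass while apoptotic loss leaves no debris. Rates: division
once per day for both phases, normal apoptosis 1/(240 h), tumor
apoptosis 0, necrosis 1/(48 h).

Oxygen is quasi-stationary, normalized to 1 in perfused vessels:
∇²c − (α/D)c + (γ/D)S_perf(1 − c) = 0, zero-flux boundaries.
Only quotients with the diffusivity matter: α_T/D = 10⁻⁴ µm⁻² fixes the
100 µm tumor penetration depth, α_N = α_T/5, necrotic consumption 0,
and the wall-exchange coefficient 3·10⁻³ µm⁻¹ keeps normal tissue above
c ≈ 0.4 on the desk scenes. Thresholds: proliferation arrest below
c = 0.3, necrosis below 0.03; growth-factor production uses the
proliferation-arrest threshold. Growth factor is the capped
superposition g = min(1, Σ max(0, 1 − d/R_g)) over hypoxic tumor cells,
R_g = 200 µm, evaluated by FFT convolution.

## Vascular remodeling

Rules fire once per 1 h network step, in a fixed order (flow solve →
sprout initiation → migration → wall degeneration → dilation → collapse
→ continuum sub-steps), each with its own named RNG stream derived from
the master seed so trajectories replay bitwise. Stochastic rates are
converted to per-step probabilities p = rate·Δt, validated ≤ 1.

- Sprouting: rate 0.1/h per vessel site with g > 0, at least 20 µm from
  a branch point, and tumor residence below 100 h; the new bond follows
  the maximal growth-factor gradient among free edges (ties uniform).
  Initiation from sprouts emulates tip splitting.
- Migration: tips extend along their own direction at 5 µm/h (one
  10 µm bond every 2 h in expectation); fusion that creates a
  conducting path, or age beyond 100 h, removes the sprout tag.
  Sprouts are exempt from dilation, degeneration and collapse.
- Degeneration: tumor vessels lose wall at 0.05 µm/h to zero.
- Dilation: co-opted tumor vessels with g > 0 and residence beyond the
  24 h circumferential switch grow at 0.4 µm/h up to r_max = 25 µm.
- Collapse: vessels with exhausted walls and shear below
  f_coll = 5·10⁻⁴ kPa are removed with probability Δt/t_surv,
  t_surv = 20 h (the unstable-vessel survival time); orphaned branches
  are detected by the subsequent flow solve and marked unperfused.

## Interstitial fluid

Stationary Darcy flow: ∇·(K∇p) + Q(p) = 0. The conductivity
interpolates normal (6.4) → tumor (187.5 µm²/(kPa·s), the
dense-vs-loose interstitium contrast of the classic
poroelastic-transport literature) across the interface with the same
smoothed Heaviside, blending to a necrotic value (2× tumor — debris is
looser than intact tumor; a documented assumption). Vessel exchange is
Starling flux λ_l(w, r)·(p_v − p − σ(π_v − π_i)) deposited from uniform
random samples of the cylindrical vessel surfaces; per-sample areas sum
exactly to 2πrl. The deposition kernel is cloud-in-cell (an exact
partition of unity; a quartic radius-2h kernel is available) and the
same kernel interpolates fields back to samples, so global exchange
budgets close to round-off. The wall permeability is anchored so a
physiologically normal wall gives λ_l^N = 2.7·10⁻³ and capped at the
leaky-tumor value λ_l^T = 2.1·10⁻² µm/(kPa·s) as w → 0 (resistance
proportional to wall thickness). Lymphatics are a continuous sink
λ_L S_L (p − p_L) with λ_L = 2.7·10⁻³ µm/(kPa·s), S_L = 0.02 µm⁻¹
(a channel grid of 10 µm radius every 100 µm), p_L = −0.5 kPa, ramped
to zero inside the tumor like K. Osmosis: π_v = 2.7, π_i = 1.33 kPa,
σ = 0.91 normal / 0.82 tumor. The vascular volume is not excluded from
the interstitium. Boundaries are zero-flux; lymphatics anchor the
pressure level (a Dirichlet mask is available for slab tests).

Diagnostics: the blood-pressure decay length toward the interstitium
λ = sqrt[(πr⁴/8η)/(λ_l 2πr)] (sealed wall → ∞, standard Poiseuille);
the extravasation ratio r_Γ = ∫_tumor Q_in dV / Σ blood inflow across
the interface.

## Drug transport

On the frozen tumor + IFF state: ∂(φ_f s₁)/∂t = −∇·(u s₁) +
∇·(D_s φ_f ∇s₁) − Γ₁₂ + vascular/lymphatic exchange;
φ_c ∂s₂/∂t = Γ₁₂ with Γ₁₂ = γ(φ_c)(k₁₂s₁ − k₂₁s₂),
γ = φ_c·f_contact·(A_c/V_c) (spherical cells of 5 µm radius, half the
surface wetted). Doxorubicin-like constants: D_s = 16 µm²/s,
k₁₂ = 0.028 µm/s (uptake within minutes), k₂₁ = k₁₂/100 (release over
hours; the hundredfold steady enrichment matches cell-culture ratios).
Diffusive wall permeabilities mirror the hydraulic maturity law with
endpoints 0.2 µm/s (tumor) and 0.2·(λ_l^N/λ_l^T) µm/s (normal), tying
the tumor/normal ratio to the hydraulic one. Vessel exchange adds a
diffusive term λ_diff S (s_B − s₁) on perfused surfaces, convective
extravasation carrying s_B, and fluid uptake removing s₁ (vessel and
lymphatic uptake only where the pressure ordering qualifies); drug
entering lymphatics leaves the system. The plasma concentration s_B is
uniform over the network: e^{−t/τ} (τ = 1 h) for a bolus, a unit
plateau for 24/96 h infusions. Heavier particles (case i) scale D_s and
the wall permeabilities by (m/m₀)^{−1/3} with m/m₀ = 10⁶.

Numerics: operator splitting per sub-step — MUSCL/minmod central-upwind
advection with Heun, explicit face-harmonic diffusion of φ_f s₁, then
*exact* exponential relaxations for the locally linear membrane and
vascular exchange (unconditionally stable and positivity-preserving).
The sub-step bounds the summed per-cell advective + diffusive rates,
which carry a 1/φ_f factor because fluxes are built from s₁ = m/φ_f;
typical sub-steps are a few seconds. Exposure maps: ICmax is the
running maximum and ICAUC the trapezoidal time integral of s₂ over the
96 h observation window.

## Analysis

Fields are binned into shells of θ (default 100 µm width); per-run bin
means are averaged across an ensemble and error bars are the ensemble
standard deviation, never pooled-cell statistics; empty bins are marked
missing. Vessel quantities are sampled along center lines and binned
identically. Distance-to-vessel profiles threshold the vessel volume
fraction at 10⁻³, take a Euclidean distance transform, and fit
A·e^{−d/ℓ} to the positive-distance bin means. Regions for exposure
summaries: viable tumor (tumor cells present, θ < 0), boundary
(|θ| < 100 µm), interior (θ < −100 µm).

## Desk scale vs full scale

The full-scale study conditions are an 8 mm box, 700 h of growth and
15-seed ensembles; the package's defaults encode those (grid 30 µm,
initial tumor radius 0.5 mm, 1 h steps, 96 h drug window, base lattice
25×31×31 with 2 up-scaling steps). Tests and fixtures run reduced
configurations — 2D triangular-lattice networks, 0.6–1 mm boxes, frozen
tumor states built directly (level-set sphere, smoothly carved necrotic
core, degenerate dilated central vessels) instead of grown. These
reproduce *orderings and signs*: elevated tumor IFP with a boundary
drop, rim-peaked outflow, fluid uptake by low-pressure tumor vessels,
early-time exponential drug halos, and higher peripheral retention with
convection disabled (demonstrated under a 20× sparser interstitium
where convection dominates; at base-case conductivity the desk tumor is
smaller than the IFP penetration depth sqrt(K/λ_L S_L) ≈ 340 µm, so rim
velocities are too small for visible washout). Quantities that depend
on full-scale morphology — the 6 kPa IFP plateau, the 2.5 mm 700 h
radius, 20-fold transvascular flow increases — are not asserted at desk
scale. The analytic quantities (compartment ratio 100, millimetre
saturation time ≈ 1.7·10³ h) are scale-free.

## Parameter provenance

Values marked physiological above are transcriptions from the
microvascular and tumor-transport literature (in-vivo viscosity law;
Starling constants, conductivities and reflection coefficients from the
poroelastic tumor-transport canon; Doxorubicin diffusivity and exchange
rates from tissue-penetration measurements and modeling). Quantities
the sources leave open — the shear→probability map, the plateau
criterion, the necrotic conductivity, boundary conditions, Heaviside
width — are documented package choices, each behind a config field.
All parameters live in `tumorperf.params` with units in the field
names; `load_config` validates ranges, per-step probabilities and
closure at load time. Variation cases (i)–(vii) apply multiplicative
deltas to named parameters only.

## Known limitations

No pharmacodynamics (cell kill), no plasma-loss feedback on vascular
flow, no surface tension at the interface, no hematocrit phase
separation at bifurcations, no saturable intracellular binding (late
concentrations are likely overestimates), no lymphatic drug
recirculation. The 2D desk mode shares all code paths with 3D but its
lattice parallelogram only approximately tiles the square grid; fixture
vessels near the domain edge may be partially clipped, which the tests
account for.
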