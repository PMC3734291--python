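"""Model parameters.

Units are micrometre / second / kilopascal throughout, except where a field
name says otherwise (vascular remodeling operates on a 1 h step; rates whose
name ends in ``_per_h`` are per hour).

The defaults describe the base case: a dense solid tumor (melanoma/glioma
phenotype) growing against an arteriovenous host vasculature, with Starling
exchange parameters for interstitial fluid and Doxorubicin-like drug
kinetics.  Values follow the microvascular literature: in-vivo blood
viscosity after Pries et al., interstitial/vascular hydraulic conductivities
after Baxter & Jain, Doxorubicin diffusivity after Lankelma et al. and
cellular exchange rates with an uptake/release ratio of 100 as observed in
cell-culture experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

MMHG_PER_KPA = 7.50062


# --------------------------------------------------------------------------
# tumor growth (vascular remodeling + continuum tissue)
# --------------------------------------------------------------------------

@dataclass
class GrowthParams:
    """Tumor growth, vascular remodeling and tissue continuum parameters."""

    # lattices / grids
    lattice_spacing: float = 10.0        # µm, fine vessel lattice
    builder_spacing: float = 40.0        # µm, coarse construction lattice (inter-capillary distance after 2 subdivisions -> 10 µm)
    grid_h: float = 30.0                 # µm, continuum grid spacing (2-3 cell diameters)
    domain_size: float = 8000.0          # µm, lateral size of the continuum box (full scale)
    initial_tumor_radius: float = 500.0  # µm, radius of the initial tumor sphere

    # time stepping
    dt_vessel_h: float = 1.0             # h, vessel-network update step

    # sprouting
    sprout_rate_per_h: float = 0.1       # 1/h, initiation probability rate per candidate site
    sprout_speed: float = 5.0            # µm/h, tip extension speed
    sprout_max_age_h: float = 100.0      # h, maximal lifetime as sprout
    sprout_min_separation: float = 20.0  # µm, min distance to next branching point (~2 ECs)
    sprout_radius: float = 4.0           # µm, initial sprout vessel radius

    # dilation / degeneration / collapse
    switch_delay_h: float = 24.0         # h, circumferential-growth switch delay
    dilation_rate: float = 0.4           # µm/h, radial growth rate k_r
    max_dilation_radius: float = 25.0    # µm, r_max
    critical_shear_kpa: float = 5e-4     # kPa, collapse shear threshold f_coll (0.5 Pa)
    unstable_survival_h: float = 20.0    # h, mean survival of a collapse-eligible vessel
    wall_degradation_rate: float = 0.05  # µm/h, dw/dt for tumor vessels

    # tissue composition
    ecm_fraction: float = 0.2            # phi_ECM (fixed)
    relaxed_cell_fraction: float = 0.4   # phi_0: no solid pressure below this
    homeostatic_tumor_fraction: float = 0.6
    homeostatic_normal_fraction: float = 0.4
    pressure_sensitivity: float = 10.0   # dimensionless slope of net rate in (phi - phi_h)
    mobility_modulus: float = 2000.0     # µm²/h, product (cell mobility)x(elastic modulus)

    # cell kinetics (per hour)
    prolif_rate_tumor_per_h: float = 1.0 / 24.0
    prolif_rate_normal_per_h: float = 1.0 / 24.0
    apoptosis_rate_tumor_per_h: float = 0.0
    apoptosis_rate_normal_per_h: float = 1.0 / 240.0
    necrosis_rate_tumor_per_h: float = 1.0 / 48.0
    necrosis_rate_normal_per_h: float = 1.0 / 48.0

    # oxygen (normalized: c = 1 in perfused vessels). Only quotients with the
    # diffusion constant matter; cons_* are alpha/D in 1/µm².
    oxygen_prolif_threshold: float = 0.3
    oxygen_necrosis_threshold: float = 0.03
    oxygen_cons_tumor: float = 1e-4      # 1/µm² -> 100 µm penetration depth in tumor
    oxygen_cons_normal: float = 2e-5     # 1/µm²
    oxygen_cons_necrotic: float = 0.0
    oxygen_wall_perm: float = 3e-3       # 1/µm (gamma/D), per vessel-surface area
    gf_radius: float = 200.0             # µm, growth-factor diffusion/cutoff radius R_g

    # network construction
    capillary_radius: float = 4.0        # µm
    arterial_terminal_radius: float = 5.0
    venous_terminal_radius: float = 7.0
    murray_alpha: float = 3.0            # Murray exponent (literature range 2.7-3.0)
    upscaling_steps: int = 2
    plateau_window: int = 50             # remodeling sweeps in the plateau test
    plateau_tol: float = 0.01            # relative capillary-count change

    # hemodynamics
    hematocrit: float = 0.45             # human average, constant network-wide
    plasma_viscosity: float = 1.2e-6     # kPa s  (1.2 mPa s)

    def validate(self) -> None:
        if self.lattice_spacing <= 0 or self.grid_h <= 0:
            raise ValueError("lattice_spacing and grid_h must be positive")
        if not (2.7 <= self.murray_alpha <= 3.0):
            raise ValueError("murray_alpha outside the physiological range [2.7, 3.0]")
        if self.upscaling_steps < 0:
            raise ValueError("upscaling_steps must be >= 0")
        if not 0.0 <= self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in [0, 1)")
        for name in ("sprout_rate_per_h",):
            p = getattr(self, name) * self.dt_vessel_h
            if p > 1.0:
                raise ValueError(
                    f"{name} * dt = {p:.3g} > 1: stochastic per-step probability "
                    "exceeds one; decrease the rate or the step"
                )
        if self.unstable_survival_h > 0 and self.dt_vessel_h / self.unstable_survival_h > 1:
            raise ValueError("collapse probability per step exceeds one")
        fr = (self.ecm_fraction, self.relaxed_cell_fraction,
              self.homeostatic_tumor_fraction, self.homeostatic_normal_fraction)
        if any(not 0 <= f <= 1 for f in fr):
            raise ValueError("volume fractions must lie in [0, 1]")
        if self.ecm_fraction + self.homeostatic_tumor_fraction >= 1.0:
            raise ValueError("ECM + homeostatic tumor fraction leaves no room for fluid")


# --------------------------------------------------------------------------
# interstitial fluid
# --------------------------------------------------------------------------

@dataclass
class IFParams:
    """Starling exchange, lymphatics and porous-medium conductivities.

    Conductivities K are bulk values in µm²/(kPa s); wall permeabilities
    lambda_* in µm/(kPa s); surface densities S_* in 1/µm.
    """

    conductivity_normal: float = 6.4      # K_N, dense normal tissue
    conductivity_tumor: float = 187.5     # K_T (Baxter-Jain 2.5e-7 cm²/mmHg/s)
    conductivity_necrotic: float = 375.0  # loose necrotic debris, 2x tumor
    lymph_pressure: float = -0.5          # kPa, p_L
    lymph_surface_density: float = 0.02   # 1/µm, S_L in normal tissue (channel every 100 µm, r = 10 µm)
    lymph_surface_density_tumor: float = 0.0  # tumors lack functional lymphatics
    lymph_wall_perm: float = 2.7e-3       # µm/(kPa s), lambda_L ~ normal capillary
    reflection_normal: float = 0.91       # sigma, normal tissue
    reflection_tumor: float = 0.82        # sigma, tumor
    oncotic_vessel: float = 2.7           # kPa, pi_v (20 mmHg)
    oncotic_interstitial: float = 1.33    # kPa, pi_i (10 mmHg)
    wall_perm_tumor: float = 2.1e-2       # µm/(kPa s), lambda_l^T cap (leaky)
    wall_perm_normal: float = 2.7e-3      # µm/(kPa s), lambda_l^N at normal wall thickness

    def validate(self) -> None:
        if min(self.conductivity_normal, self.conductivity_tumor,
               self.conductivity_necrotic) <= 0:
            raise ValueError("tissue conductivities must be positive")
        for s in (self.reflection_normal, self.reflection_tumor):
            if not 0.0 <= s <= 1.0:
                raise ValueError("reflection coefficients must lie in [0, 1]")
        if min(self.lymph_wall_perm, self.wall_perm_tumor, self.wall_perm_normal) < 0:
            raise ValueError("wall permeabilities must be non-negative")
        if min(self.lymph_surface_density, self.lymph_surface_density_tumor) < 0:
            raise ValueError("lymphatic surface densities must be non-negative")


# --------------------------------------------------------------------------
# drug
# --------------------------------------------------------------------------

@dataclass
class DrugParams:
    """Two-compartment (interstitial / intracellular) Doxorubicin-like drug.

    ``k12``/``k21`` are interfacial transfer velocities across the cell
    membrane; their ratio (100) sets the steady intracellular enrichment.
    Wall permeabilities mirror the hydraulic law with drug-specific
    endpoints whose tumor/normal ratio equals the hydraulic one.
    """

    diffusivity: float = 16.0            # µm²/s, D_s in interstitium (Doxorubicin)
    k12: float = 0.028                   # µm/s, uptake velocity (cell entry ~ minutes)
    k21: float = 0.00028                 # µm/s, release velocity (~ hours); k12/k21 = 100
    wall_perm_tumor: float = 0.2         # µm/s, diffusive permeability of leaky tumor wall
    wall_perm_normal: float = 0.2 * (2.7e-3 / 2.1e-2)   # ratio tied to hydraulic ratio
    cell_radius: float = 5.0             # µm (V_c = 4/3 pi r³, A_c = 4 pi r²)
    contact_fraction: float = 0.5        # fraction of cell surface wetted by IF
    mol_mass_ratio: float = 1.0          # m/m0 relative to Doxorubicin; case (i) uses 1e6
    bolus_tau_h: float = 1.0             # h, plasma decay time of a bolus

    @property
    def cell_area_per_volume(self) -> float:
        """A_c/V_c = 3/r for a spherical cell, in 1/µm."""
        return 3.0 / self.cell_radius

    def gamma(self, phi_c: float) -> float:
        """Exchange coefficient per tissue volume (1/µm), Eq.-(22)-style.

        gamma = phi_c * f_contact * A_c / V_c : interface area density of the
        wetted cell surface.
        """
        return phi_c * self.contact_fraction * self.cell_area_per_volume

    @property
    def retention_ratio(self) -> float:
        """Steady intracellular/extracellular concentration ratio k12/k21."""
        return self.k12 / self.k21

    def mass_scaled(self, mass_ratio: float) -> "DrugParams":
        """Heavier particle: diffusion-related parameters scale with (m/m0)^(-1/3)."""
        f = mass_ratio ** (-1.0 / 3.0)
        return dataclasses.replace(
            self,
            diffusivity=self.diffusivity * f,
            wall_perm_tumor=self.wall_perm_tumor * f,
            wall_perm_normal=self.wall_perm_normal * f,
            mol_mass_ratio=mass_ratio,
        )

    def validate(self) -> None:
        if min(self.diffusivity, self.k12, self.k21) <= 0:
            raise ValueError("diffusivity and exchange rates must be positive")
        if min(self.wall_perm_tumor, self.wall_perm_normal) < 0:
            raise ValueError("wall permeabilities must be non-negative")
        if not 0 < self.contact_fraction <= 1:
            raise ValueError("contact_fraction must lie in (0, 1]")


# --------------------------------------------------------------------------
# umbrella
# --------------------------------------------------------------------------

@dataclass
class Parameters:
    growth: GrowthParams = field(default_factory=GrowthParams)
    iff: IFParams = field(default_factory=IFParams)
    drug: DrugParams = field(default_factory=DrugParams)
    seed: int = 0

    def validate(self) -> "Parameters":
        self.growth.validate()
        self.iff.validate()
        self.drug.validate()
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Parameters":
        p = cls(
            growth=GrowthParams(**d.get("growth", {})),
            iff=IFParams(**d.get("iff", {})),
            drug=DrugParams(**d.get("drug", {})),
            seed=int(d.get("seed", 0)),
        )
        return p.validate()


def load_config(path: str) -> Parameters:
    """Load and validate a YAML configuration file."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    try:
        return Parameters.from_dict(raw)
    except TypeError as e:  # unknown key -> name it
        raise ValueError(f"unknown configuration entry: {e}") from e


def save_config(params: Parameters, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(params.to_dict(), f, sort_keys=False)


# --------------------------------------------------------------------------
# variation cases (i)-(vii)
# --------------------------------------------------------------------------

#: case id -> list of (section, field, multiplicative factor) or special keys
CASE_SPECS: dict[str, dict[str, Any]] = {
    "base": {},
    "i": {"mass_ratio": 1e6},
    "ii-a": {"schedule": ("infusion", 24.0)},
    "ii-b": {"schedule": ("infusion", 96.0)},
    "iii": {"convection": False},
    "iv-a": {"scale": [("iff", "wall_perm_tumor", 10.0), ("drug", "wall_perm_tumor", 10.0)]},
    "iv-b": {"scale": [("iff", "wall_perm_tumor", 0.1), ("drug", "wall_perm_tumor", 0.1)]},
    "iv-c": {"scale": [("iff", "wall_perm_tumor", 1e-3), ("drug", "wall_perm_tumor", 1e-3)]},
    "v": {"scale": [("iff", "conductivity_normal", 10.0),
                     ("iff", "conductivity_tumor", 10.0),
                     ("iff", "conductivity_necrotic", 10.0),
                     ("iff", "lymph_wall_perm", 10.0),
                     ("drug", "diffusivity", 10.0)]},
    "vi": {"scale": [("iff", "lymph_wall_perm", 10.0)]},
    "vii-a": {"tumor_lymph_fraction": 0.1},
    "vii-b": {"tumor_lymph_fraction": 1.0},
}


def apply_case(params: Parameters, case: str) -> tuple[Parameters, dict[str, Any]]:
    """Return (modified parameters, run options) for a named variation case.

    Run options carry the non-parameter switches: injection ``schedule``,
    ``convection`` on/off.
    """
    if case not in CASE_SPECS:
        raise KeyError(f"unknown case {case!r}; known: {sorted(CASE_SPECS)}")
    spec = CASE_SPECS[case]
    p = Parameters.from_dict(params.to_dict())
    opts: dict[str, Any] = {"schedule": ("bolus", None), "convection": True}
    for section, name, factor in spec.get("scale", []):
        obj = getattr(p, section)
        setattr(obj, name, getattr(obj, name) * factor)
    if "mass_ratio" in spec:
        p.drug = p.drug.mass_scaled(spec["mass_ratio"])
    if "tumor_lymph_fraction" in spec:
        p.iff.lymph_surface_density_tumor = (
            spec["tumor_lymph_fraction"] * p.iff.lymph_surface_density)
    if "schedule" in spec:
        opts["schedule"] = spec["schedule"]
    if "convection" in spec:
        opts["convection"] = spec["convection"]
    return p.validate(), opts
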