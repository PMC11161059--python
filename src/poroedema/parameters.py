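"""Model parameter registry with units and defaults.

Physical reasoning behind the defaults is documented in docs/methods.md.
Permeabilities are stated in mm^3 s kg^-1 (the conventional unit in the
multi-compartment brain perfusion literature) and converted to SI
(m^3 s kg^-1) at assembly time; pressures are Pa internally.  The
mmHg<->Pa constant is configurable so that the rounded literature values
(12000 Pa = 90 mmHg) can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Pa per mmHg.
MMHG = 133.322
#: mm^3 s kg^-1 -> m^3 s kg^-1
PERM_TO_SI = 1e-9
#: mm -> m
MM = 1e-3


def mmhg_to_pa(x: float, mmhg: float = MMHG) -> float:
    return x * mmhg


def pa_to_mmhg(x, mmhg: float = MMHG):
    return x / mmhg


@dataclass
class PerfusionParameters:
    """Coefficients of the steady three-compartment Darcy system.

    K_a, K_c, K_v: compartment permeabilities, mm^3 s kg^-1.
    omega_ac, omega_cv: inter-compartment transfer coefficients, 1/(Pa s).
    p_a_cortex, p_v_cortex: cortical boundary pressures, Pa.
    Arterioles and venules are penetrating vessels, modelled on the
    idealized geometry as transversely isotropic with principal direction
    radial (perpendicular to the pial surface); ``anisotropy_ratio`` is
    K_transverse / K_axial.  ``anisotropic=False`` gives the isotropic
    variant used by the algebraic oracles.
    """

    K_a: float = 1.234
    K_c: float = 4.28e-3
    K_v: float = 2.468
    omega_ac: float = 1.326e-6
    omega_cv: float = 4.641e-6
    p_a_cortex: float = 12000.0
    p_v_cortex: float = 2000.0
    anisotropic: bool = True
    anisotropy_ratio: float = 0.01

    def validate(self):
        for name in ("K_a", "K_c", "K_v", "omega_ac", "omega_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.anisotropy_ratio <= 1):
            raise ValueError("anisotropy_ratio must be in (0, 1]")


@dataclass
class OedemaParameters:
    """Coefficients of the transient four-compartment poroelastic model.

    c_w, c_b: storage factors of interstitial fluid and blood, 1/Pa.
    K_w: interstitial permeability, mm^3 s kg^-1.
    L_p: capillary-wall hydraulic permeability, m/(s Pa) — the
        blood-brain-barrier damage severity dial.
    sigma: reflection coefficient (Donnan-corrected), dimensionless.
    Pi_c: plasma osmotic pressure, Pa.
    n_b: blood volume fraction; R_c: mean capillary radius, m.
    G, nu: shear modulus (Pa) and Poisson ratio of the tissue skeleton.
    p_w_boundary: CSF pressure pinning the interstitial compartment at the
        cortical and ventricle surfaces, Pa (10 mmHg baseline ICP).
    """

    c_w: float = 3.08e-4
    c_b: float = 1.59e-3
    K_w: float = 3.6e-3
    L_p: float = 3.0e-11
    sigma: float = 0.65
    Pi_c: float = 2445.0
    n_b: float = 0.03
    R_c: float = 5e-6
    G: float = 592.7
    nu: float = 0.35
    p_w_boundary: float = 10.0 * MMHG
    clamp_starling: bool = False
    perfusion: PerfusionParameters = field(default_factory=PerfusionParameters)

    @property
    def lam(self) -> float:
        """First Lame parameter from (G, nu)."""
        return 2.0 * self.G * self.nu / (1.0 - 2.0 * self.nu)

    @property
    def starling_coefficient(self) -> float:
        """2 n_b L_p / R_c, 1/(Pa s)."""
        return 2.0 * self.n_b * self.L_p / self.R_c

    def validate(self):
        if not (0 <= self.sigma <= 1):
            raise ValueError("sigma must be in [0, 1]")
        if not (0 < self.nu < 0.5):
            raise ValueError("nu must be in (0, 0.5)")
        for name in ("c_w", "c_b", "K_w", "G", "n_b", "R_c", "Pi_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.L_p < 0:
            raise ValueError("L_p must be non-negative")
        self.perfusion.validate()


@dataclass
class NumericalControls:
    """Solver and contact settings (all config keys)."""

    core_threshold: float = 0.7      # perfusion-reduction fraction defining the core
    penalty_factor: float = 10.0     # eps_N = penalty_factor * G / h  (Pa/mm)
    g_tol_factor: float = 0.01       # g_tol = g_tol_factor * slit thickness (mm)
    max_augmentations: int = 120
    max_contact_inner: int = 30
    contact_u_rtol: float = 1e-6     # inner fixed-point tolerance on u
    linear_rtol: float = 1e-8


@dataclass
class Schedule:
    """Time stepping and ABP protocol for an oedema run."""

    dt: float = 125.0
    t_end: float = 1000.0
    abp_mmhg: tuple = (90.0,)
    venous_offset_mmhg: float = 75.0

    def validate(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.t_end / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_end must be a multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


def parameters_to_dict(p) -> dict:
    return asdict(p)
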