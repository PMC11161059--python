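"""Transient four-compartment poroelastic oedema model.

Fluid phase (backward Euler, fully implicit, linear in the pressures):

    c_w dp_w/dt = div(K_w grad p_w) + S_cw
    c_b dp_a/dt = div(K_a grad p_a) - w_ac (p_a - p_c)
    c_b dp_c/dt = div(K_c grad p_c) + w_ac (p_a - p_c) - w_cv (p_c - p_v) - S_cw
    c_b dp_v/dt = div(K_v grad p_v) + w_cv (p_c - p_v)

with the Starling-type capillary leakage, active only in the oedema core
(the blood-brain barrier is intact elsewhere):

    S_cw = (2 n_b L_p / R_c) [ (p_c - p_w) - sigma Pi_c ]

Solid phase (quasi-static, time-scale separation: deformation equilibrates
instantly relative to fluid accumulation):

    G lap(u) + (G + lambda) grad(div u) = grad(p_w)

solved each step after the pressures, in the undeformed configuration
(small-strain kinematics; "large deformation" enters only through the
ventricle-wall self-contact handled by :mod:`poroedema.contact`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem
from .geometry import Domain, midplane_nodes
from .parameters import (
    OedemaParameters,
    NumericalControls,
    Schedule,
    MM,
    MMHG,
    PERM_TO_SI,
)
from .perfusion import PressureFields, permeability_tensor, solve_steady_perfusion
from .postprocess import SimulationResult, compute_icp, compute_mls, probe_displacement


@dataclass
class MechanicalState:
    """Quasi-static tissue response at one time level.

    u: nodal displacement (N, 2), mm.
    eps / stress: per-cell small strain and effective stress in Voigt order
    (xx, yy, xy); stress in Pa.
    """

    u: np.ndarray
    eps: np.ndarray
    stress: np.ndarray
    dilatation: np.ndarray
    contact: dict = field(default_factory=dict)


def default_pressure_bcs(params: OedemaParameters, abp_pa: float, pv_pa: float) -> dict:
    """Dirichlet data per field as {field: [(facet-tag prefix, value Pa), ...]}.

    Blood boundary data matches restored perfusion (no occlusion); the
    interstitial compartment is pinned at CSF pressure on both the cortical
    and ventricle surfaces.  Everything else is natural (zero flux).
    """
    pwb = params.p_w_boundary
    return {
        "p_w": [("cortical", pwb), ("ventricle", pwb)],
        "p_a": [("cortical", abp_pa)],
        "p_c": [],
        "p_v": [("cortical", pv_pa)],
    }


def starling_source(
    domain: Domain,
    fields: PressureFields,
    params: OedemaParameters,
    core: np.ndarray,
) -> np.ndarray:
    """Per-cell leakage rate S_cw (1/s), evaluated at cell midpoints; zero
    outside the core.  Negative values (reabsorption) are permitted unless
    ``params.clamp_starling``."""
    pc = fields.p_c[domain.cells].mean(axis=1)
    pw = fields.p_w[domain.cells].mean(axis=1)
    s = params.starling_coefficient * ((pc - pw) - params.sigma * params.Pi_c)
    s = np.where(core, s, 0.0)
    if params.clamp_starling:
        s = np.maximum(s, 0.0)
    return s


class PressureStepper:
    """Backward-Euler integrator of the coupled four-field system.

    The system matrix is constant in time, so its LU factorisation is
    reused across steps.  Field stacking order: (p_w, p_a, p_c, p_v).
    """

    def __init__(
        self,
        domain: Domain,
        params: OedemaParameters,
        core: np.ndarray,
        dt: float,
        bcs: dict | None = None,
    ):
        if dt <= 0:
            raise ValueError("dt must be positive")
        params.validate()
        self.domain = domain
        self.params = params
        self.core = np.asarray(core, dtype=bool)
        self.dt = float(dt)
        pf = params.perfusion
        if bcs is None:
            bcs = default_pressure_bcs(params, pf.p_a_cortex, pf.p_v_cortex)
        self.bcs = bcs

        nodes_m = domain.nodes * MM
        cells = domain.cells
        n = self.n = len(nodes_m)
        M = _fem.mass(nodes_m, cells)
        Mcore = _fem.mass(nodes_m, cells, cell_mask=self.core)
        Sw = _fem.stiffness(nodes_m, cells, params.K_w * PERM_TO_SI)
        Sa = _fem.stiffness(nodes_m, cells, permeability_tensor(domain, pf.K_a, pf))
        Sc = _fem.stiffness(nodes_m, cells, pf.K_c * PERM_TO_SI)
        Sv = _fem.stiffness(nodes_m, cells, permeability_tensor(domain, pf.K_v, pf))
        wac, wcv = pf.omega_ac, pf.omega_cv
        al = params.starling_coefficient
        cw, cb = params.c_w, params.c_b
        dt = self.dt
        Z = sp.csr_matrix((n, n))

        #           p_w                          p_a            p_c                                          p_v
        A = sp.bmat(
            [
                [cw / dt * M + Sw + al * Mcore, Z, -al * Mcore, Z],
                [Z, cb / dt * M + Sa + wac * M, -wac * M, Z],
                [-al * Mcore, -wac * M, cb / dt * M + Sc + (wac + wcv) * M + al * Mcore, -wcv * M],
                [Z, Z, -wcv * M, cb / dt * M + Sv + wcv * M],
            ],
            format="csr",
        )
        self.A = A
        self.M, self.Mcore = M, Mcore
        osm = al * params.sigma * params.Pi_c * (Mcore @ np.ones(n))
        self.const_rhs = np.concatenate([-osm, np.zeros(n), +osm, np.zeros(n)])

        # Dirichlet dofs
        dofs, vals = [], []
        for k, fld in enumerate(("p_w", "p_a", "p_c", "p_v")):
            for prefix, value in self.bcs.get(fld, []):
                ids = domain.facet_nodes(domain.facets_where(prefix))
                dofs.append(k * n + ids)
                vals.append(np.full(len(ids), float(value)))
        self.bc_dofs = np.concatenate(dofs) if dofs else np.array([], dtype=np.int64)
        self.bc_vals = np.concatenate(vals) if vals else np.array([])

        A_bc, _ = _fem.apply_dirichlet(A, np.zeros(4 * n), self.bc_dofs, self.bc_vals)
        self._lu = spla.splu(A_bc.tocsc())

    def step(self, fields: PressureFields) -> PressureFields:
        n = self.n
        p = self.params
        xold = np.concatenate([fields.p_w, fields.p_a, fields.p_c, fields.p_v])
        stor = np.concatenate(
            [
                p.c_w / self.dt * (self.M @ fields.p_w),
                p.c_b / self.dt * (self.M @ fields.p_a),
                p.c_b / self.dt * (self.M @ fields.p_c),
                p.c_b / self.dt * (self.M @ fields.p_v),
            ]
        )
        b = stor + self.const_rhs
        _, b_bc = _fem.apply_dirichlet(self.A, b, self.bc_dofs, self.bc_vals)
        x = self._lu.solve(b_bc)
        if not np.all(np.isfinite(x)):
            raise RuntimeError("pressure step diverged (non-finite solution)")
        new = PressureFields(
            p_w=x[:n], p_a=x[n : 2 * n], p_c=x[2 * n : 3 * n], p_v=x[3 * n :],
            time=fields.time + self.dt,
        )
        new.info["balance"] = self._balance(xold, x)
        return new

    def _balance(self, xold, xnew) -> dict:
        """Discrete interstitial fluid audit over the step.

        storage change = conservative boundary flux + Starling source.
        Fluxes are recovered from the unconstrained residual (boundary
        integration of the discrete form), so the identity is exact up to
        linear-solver precision; the audit guards the assembly.
        """
        n = self.n
        r = self.A @ xnew - (
            np.concatenate(
                [
                    self.params.c_w / self.dt * (self.M @ xold[:n]),
                    self.params.c_b / self.dt * (self.M @ xold[n : 2 * n]),
                    self.params.c_b / self.dt * (self.M @ xold[2 * n : 3 * n]),
                    self.params.c_b / self.dt * (self.M @ xold[3 * n :]),
                ]
            )
            + self.const_rhs
        )
        pw_new, pw_old = xnew[:n], xold[:n]
        storage = self.params.c_w / self.dt * float(
            np.ones(n) @ (self.M @ (pw_new - pw_old))
        )
        boundary_flux = float(r[:n].sum())  # nonzero only at Dirichlet rows
        al = self.params.starling_coefficient
        source = float(
            np.ones(n) @ (al * (self.Mcore @ (xnew[2 * n : 3 * n] - pw_new)))
            - al * self.params.sigma * self.params.Pi_c * np.ones(n) @ (self.Mcore @ np.ones(n))
        )
        return {"storage": storage, "boundary_flux": boundary_flux, "source": source}


class ElasticitySolver:
    """Quasi-static plane-strain elasticity with pressure-gradient load.

    Fixed (u = 0) on the cortical surface; the ventricle surface is
    traction-free in the effective stress except for contact tractions,
    which enter through ``extra_K`` / ``extra_f`` supplied by the contact
    loop.  Works in SI internally; displacements are returned in mm.
    """

    def __init__(self, domain: Domain, params: OedemaParameters):
        params.validate()
        self.domain = domain
        self.params = params
        self.nodes_m = domain.nodes * MM
        self.K0 = _fem.elasticity_stiffness(self.nodes_m, domain.cells, params.G, params.lam)
        cort = domain.facet_nodes(domain.cortical_facets())
        self.fixed_dofs = np.concatenate([2 * cort, 2 * cort + 1])
        self._lu0 = None

    def load_vector(self, p_w: np.ndarray) -> np.ndarray:
        return _fem.pressure_gradient_load(self.nodes_m, self.domain.cells, p_w)

    def bc_rhs(self, f: np.ndarray) -> np.ndarray:
        """Right-hand side with homogeneous Dirichlet rows zeroed."""
        b = f.copy()
        b[self.fixed_dofs] = 0.0
        return b

    def _ensure_lu(self):
        if self._lu0 is None:
            A_bc, _ = _fem.apply_dirichlet(
                self.K0, np.zeros(self.K0.shape[0]), self.fixed_dofs, 0.0
            )
            self._lu0 = spla.splu(A_bc.tocsc())
        return self._lu0

    def solve_flat(self, b_bc: np.ndarray, U: np.ndarray | None = None, c=None) -> np.ndarray:
        """Solve (K_bc + U diag(c) U^T) x = b_bc via the Woodbury identity.

        b_bc must already have Dirichlet rows zeroed (see :meth:`bc_rhs`);
        U columns must vanish on fixed dofs (contact dofs never do not).
        Returns x in SI (metres), flat.
        """
        lu = self._ensure_lu()
        x0 = lu.solve(b_bc)
        if U is None or U.shape[1] == 0:
            return x0
        Z = lu.solve(U)
        S = np.diag(1.0 / np.asarray(c)) + U.T @ Z
        x = x0 - Z @ np.linalg.solve(S, U.T @ x0)
        return x

    def solve_u(self, p_w: np.ndarray, extra_K=None, extra_f=None) -> np.ndarray:
        """Nodal displacement (N, 2) in mm."""
        f = self.load_vector(p_w)
        if extra_f is not None:
            f = f + extra_f
        if extra_K is None:
            if self._lu0 is None:
                A_bc, _ = _fem.apply_dirichlet(
                    self.K0, np.zeros_like(f), self.fixed_dofs, 0.0
                )
                self._lu0 = spla.splu(A_bc.tocsc())
            _, b_bc = _fem.apply_dirichlet(self.K0, f, self.fixed_dofs, 0.0)
            x = self._lu0.solve(b_bc)
        else:
            A = self.K0 + extra_K
            A_bc, b_bc = _fem.apply_dirichlet(A, f, self.fixed_dofs, 0.0)
            x = spla.spsolve(A_bc.tocsc(), b_bc)
        if not np.all(np.isfinite(x)):
            raise RuntimeError("displacement solve diverged (non-finite solution)")
        return x.reshape(-1, 2) / MM  # m -> mm

    def mechanical_state(self, u_mm: np.ndarray, contact_info=None) -> MechanicalState:
        u_flat = (u_mm * MM).reshape(-1)
        eps, sig = _fem.cell_strain_stress(
            self.nodes_m, self.domain.cells, u_flat, self.params.G, self.params.lam
        )
        return MechanicalState(
            u=u_mm,
            eps=eps,
            stress=sig,
            dilatation=eps[:, 0] + eps[:, 1],
            contact=contact_info or {},
        )


def solve_displacement(
    domain: Domain,
    p_w: np.ndarray,
    params: OedemaParameters,
    contact_state=None,
    controls: NumericalControls | None = None,
) -> MechanicalState:
    """One-shot displacement solve (contact loop if a contact state is given)."""
    solver = ElasticitySolver(domain, params)
    if contact_state is None:
        u = solver.solve_u(p_w)
        return solver.mechanical_state(u)
    from .contact import solve_contact_equilibrium

    return solve_contact_equilibrium(solver, p_w, contact_state, controls or NumericalControls())


def run_oedema_simulation(
    domain: Domain,
    params: OedemaParameters,
    core: np.ndarray,
    schedule: Schedule,
    abp_mmhg: float,
    contact: bool = True,
    probes=None,
    controls: NumericalControls | None = None,
    record_fields: bool = False,
    midplane_tol: float | None = None,
) -> SimulationResult:
    """Full transient run at one arterial blood pressure.

    The cortical arteriole Dirichlet value is ABP; the venule value tracks
    ABP - 75 mmHg (fixed arteriovenous offset).  Initial blood pressures
    come from the healthy steady perfusion solve at that ABP; the
    interstitial pressure starts at the CSF baseline (10 mmHg).
    """
    schedule.validate()
    controls = controls or NumericalControls()
    pf = params.perfusion
    abp_pa = abp_mmhg * MMHG
    pv_pa = (abp_mmhg - schedule.venous_offset_mmhg) * MMHG

    import dataclasses

    pf_run = dataclasses.replace(pf, p_a_cortex=abp_pa, p_v_cortex=pv_pa)
    params_run = dataclasses.replace(params, perfusion=pf_run)

    steady = solve_steady_perfusion(domain, pf_run)
    fields = PressureFields(
        p_a=steady.p_a, p_c=steady.p_c, p_v=steady.p_v,
        p_w=np.full(len(domain.nodes), params.p_w_boundary), time=0.0,
    )

    stepper = PressureStepper(domain, params_run, core, schedule.dt)
    solver = ElasticitySolver(domain, params_run)
    state_c = None
    if contact and domain.contact_pairs:
        from .contact import ContactState

        state_c = ContactState.from_domain(domain, params_run, controls)

    h = float(np.sqrt(np.median(domain.cell_volumes()) * 2.0))
    mp = midplane_nodes(domain, midplane_tol if midplane_tol is not None else h / 10.0)

    result = SimulationResult(
        abp_mmhg=abp_mmhg,
        core_volume_ml=float(
            domain.cell_volumes()[core].sum() / 1000.0
        ),
        params_echo={"L_p": params.L_p, "G": params.G, "nu": params.nu,
                     "sigma": params.sigma, "dt": schedule.dt, "t_end": schedule.t_end},
    )
    probes = probes or {}

    def record(fields, mech):
        icp = compute_icp(fields.p_w)
        mls = compute_mls(mech.u, mp)
        row = {
            "t": fields.time,
            "icp_mmhg": icp,
            "mls_mm": mls,
            "abp_mmhg": abp_mmhg,
        }
        for name, pt in probes.items():
            ux, uy = probe_displacement(domain, mech.u, [pt])[0]
            row[f"probe_{name}_ux"] = ux
            row[f"probe_{name}_uy"] = uy
        if state_c is not None:
            row.update(
                contact_active=mech.contact.get("n_active", 0),
                max_penetration_mm=mech.contact.get("max_penetration", float("nan")),
                max_multiplier_pa=mech.contact.get("max_multiplier", 0.0),
            )
        result.rows.append(row)
        if record_fields:
            result.snapshots.append((fields.copy(), mech))

    mech0 = solver.mechanical_state(np.zeros_like(domain.nodes))
    record(fields, mech0)

    for k in range(schedule.n_steps):
        try:
            fields = stepper.step(fields)
            if state_c is not None:
                from .contact import solve_contact_equilibrium

                mech = solve_contact_equilibrium(solver, fields.p_w, state_c, controls)
            else:
                u = solver.solve_u(fields.p_w)
                mech = solver.mechanical_state(u)
        except Exception as err:
            raise RuntimeError(
                f"oedema simulation failed at step {k + 1} "
                f"(t = {(k + 1) * schedule.dt} s): {err}"
            ) from err
        record(fields, mech)

    result.finalize()
    return result
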