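"""Steady three-compartment Darcy perfusion and oedema-core extraction.

Governing system (pressures p_a, p_c, p_v in arteriole, capillary, venule
networks):

    div(K_a grad p_a) = -w_ac (p_a - p_c)
    div(K_c grad p_c) =  w_ac (p_a - p_c) - w_cv (p_c - p_v)
    div(K_v grad p_v) =  w_cv (p_c - p_v)

Boundary conditions: p_a Dirichlet (ABP) on non-occluded cortical facets,
zero normal flux on occluded facets and on the ventricle; p_c zero flux
everywhere; p_v Dirichlet on the whole cortical surface, zero flux on the
ventricle.  Occluding an arterial territory removes its arteriole Dirichlet
data, which starves the capillary bed beneath it; the tissue-feeding flux
w_cv (p_c - p_v) is the perfusion measure used for the ischaemic-core
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem
from .geometry import Domain
from .parameters import PerfusionParameters, MM, PERM_TO_SI


@dataclass
class PressureFields:
    """Nodal pressures (Pa) of all fluid compartments at one time level."""

    p_a: np.ndarray
    p_c: np.ndarray
    p_v: np.ndarray
    p_w: np.ndarray | None = None
    time: float = 0.0
    info: dict = field(default_factory=dict)

    def copy(self) -> "PressureFields":
        return PressureFields(
            self.p_a.copy(), self.p_c.copy(), self.p_v.copy(),
            None if self.p_w is None else self.p_w.copy(), self.time, dict(self.info),
        )


def permeability_tensor(domain: Domain, K_scalar: float, params: PerfusionParameters):
    """Per-cell 2x2 permeability tensor in SI units.

    Penetrating-vessel compartments are transversely isotropic with the
    axial direction radial from the domain centroid (perpendicular to the
    pial surface of the idealized brain).
    """
    K = K_scalar * PERM_TO_SI
    if not params.anisotropic:
        return K
    cent = domain.nodes[domain.cells].mean(axis=1) - domain.nodes.mean(axis=0)
    r = np.linalg.norm(cent, axis=1)
    r = np.where(r < 1e-12, 1.0, r)
    rhat = cent / r[:, None]
    eye = np.eye(2)[None, :, :]
    rr = np.einsum("ci,cj->cij", rhat, rhat)
    return K * (rr + params.anisotropy_ratio * (eye - rr))


def _dirichlet_nodes(domain: Domain, facet_ids) -> np.ndarray:
    return domain.facet_nodes(facet_ids)


def solve_steady_perfusion(
    domain: Domain,
    params: PerfusionParameters,
    occluded: np.ndarray | None = None,
    pin_blood: bool = False,
) -> PressureFields:
    """Solve the steady three-compartment system.

    occluded: boolean facet mask (from :func:`geometry.occlude_territories`);
        arteriole Dirichlet data is dropped on masked facets.
    pin_blood: oracle/test variant — clamp p_a and p_v to their cortical
        boundary values over the *whole* domain and solve only the capillary
        balance.  Its exact discrete solution is the 0-D algebraic
        compartment balance, which anchors the solver tests.
    """
    params.validate()
    nodes_m = domain.nodes * MM
    cells = domain.cells
    n = len(nodes_m)

    Ka = permeability_tensor(domain, params.K_a, params)
    Kv = permeability_tensor(domain, params.K_v, params)
    Kc = params.K_c * PERM_TO_SI  # capillary bed is isotropic

    Sa = _fem.stiffness(nodes_m, cells, Ka)
    Sc = _fem.stiffness(nodes_m, cells, Kc)
    Sv = _fem.stiffness(nodes_m, cells, Kv)
    M = _fem.mass(nodes_m, cells)
    wac, wcv = params.omega_ac, params.omega_cv

    cort = domain.cortical_facets()
    if occluded is not None:
        occ_ids = np.flatnonzero(occluded)
        open_cort = np.setdiff1d(cort, occ_ids)
    else:
        open_cort = cort

    zero = sp.csr_matrix((n, n))
    A = sp.bmat(
        [
            [Sa + wac * M, -wac * M, zero],
            [-wac * M, Sc + (wac + wcv) * M, -wcv * M],
            [zero, -wcv * M, Sv + wcv * M],
        ],
        format="csr",
    )
    b = np.zeros(3 * n)

    if pin_blood:
        a_nodes = np.arange(n)
        v_nodes = np.arange(n)
    else:
        if len(open_cort) == 0:
            raise ValueError(
                "entire cortical boundary is occluded: the arteriole pressure has "
                "no Dirichlet data and the system is singular"
            )
        a_nodes = _dirichlet_nodes(domain, open_cort)
        v_nodes = _dirichlet_nodes(domain, cort)

    dofs = np.concatenate([a_nodes, 2 * n + v_nodes])
    vals = np.concatenate(
        [np.full(len(a_nodes), params.p_a_cortex), np.full(len(v_nodes), params.p_v_cortex)]
    )
    A_bc, b_bc = _fem.apply_dirichlet(A, b, dofs, vals)
    x = spla.spsolve(A_bc.tocsc(), b_bc)
    res = np.linalg.norm(A_bc @ x - b_bc) / max(np.linalg.norm(b_bc), 1.0)
    if not np.all(np.isfinite(x)) or res > 1e-6:
        raise RuntimeError(f"steady perfusion solve did not converge (residual {res:.2e})")

    fields = PressureFields(p_a=x[:n], p_c=x[n : 2 * n], p_v=x[2 * n :])
    # conservative boundary fluxes from the unconstrained residual
    r = A @ x - b
    fields.info.update(
        residual=res,
        arteriole_influx=float(r[:n].sum()),
        venule_influx=float(r[2 * n :].sum()),
        capillary_influx=float(r[n : 2 * n].sum()),
    )
    return fields


def perfusion_rate(fields: PressureFields, params: PerfusionParameters) -> np.ndarray:
    """Tissue-feeding capillary->venule transfer w_cv (p_c - p_v), 1/s, nodal."""
    return params.omega_cv * (fields.p_c - fields.p_v)


def core_volume_ml(domain: Domain, mask: np.ndarray, thickness_mm: float = 1.0) -> float:
    """Mask volume in ml; 2D domains assume unit (1 mm) out-of-plane depth."""
    vols = domain.cell_volumes()
    v = float(vols[mask].sum())
    if domain.dim == 2:
        v *= thickness_mm
    return v / 1000.0  # mm^3 -> ml


def extract_oedema_core(
    domain: Domain,
    healthy: PressureFields,
    occluded: PressureFields,
    params: PerfusionParameters,
    threshold: float = 0.7,
):
    """Cells whose perfusion dropped by >= threshold (cell-midpoint rule).

    Returns (cell mask, volume in ml).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    rate_h = perfusion_rate(healthy, params)[domain.cells].mean(axis=1)
    rate_o = perfusion_rate(occluded, params)[domain.cells].mean(axis=1)
    if np.any(rate_h <= 0):
        raise ValueError(
            "healthy perfusion rate is non-positive on some cells; "
            "relative reduction is ill-defined"
        )
    reduction = (rate_h - rate_o) / rate_h
    mask = reduction >= threshold
    return mask, core_volume_ml(domain, mask)
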