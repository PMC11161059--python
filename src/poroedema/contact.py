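"""Ventricle-wall self-contact by an augmented-Lagrangian scheme.

Node-to-surface discretisation: each node of a slave wall is projected
onto the closest facet of the opposing (master) wall in the deformed
configuration.  A positive gap g denotes penetration.  Non-penetration is
enforced by a normal traction t_N = <lambda_N + eps_N g> (Macaulay
bracket), with the multiplier updated between outer iterations,

    lambda_N <- < lambda_N + eps_N g >,

until the residual penetration falls below g_tol.  The contact is
frictionless and normal-only; tie-break when a node projects onto a facet
edge is the smaller facet index (deterministic runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import Domain
from .parameters import OedemaParameters, NumericalControls, MM
from . import _fem


def macaulay(x):
    """Macaulay bracket <x> = max(x, 0); elementwise on arrays."""
    return np.maximum(x, 0.0)


@dataclass
class ContactPair:
    slave_nodes: np.ndarray      # node ids on the slave wall
    master_facets: np.ndarray    # (m, 2) node ids of master wall facets
    master_outward: np.ndarray   # (m, 2) reference outward normals (into cavity)
    slave_weight_m: np.ndarray   # lumped boundary measure per slave node (m)
    master_node_ids: np.ndarray = None   # unique master wall nodes
    master_local: np.ndarray = None      # (m, 2) facet nodes as indices into master_node_ids


@dataclass
class ContactState:
    """Gaps, multipliers and pairing of all candidate wall pairs."""

    pairs: list
    eps_n: float                 # penalty, Pa/m
    g_tol: float                 # convergence tolerance on penetration, m
    lam: list = field(default_factory=list)       # multiplier per slave node, Pa
    gap: list = field(default_factory=list)       # current signed gap, m (+ = penetration)
    projection: list = field(default_factory=list)
    u_warm: np.ndarray | None = None              # warm-start displacement, mm

    @classmethod
    def from_domain(
        cls,
        domain: Domain,
        params: OedemaParameters,
        controls: NumericalControls,
        slit_thickness_mm: float | None = None,
    ) -> "ContactState":
        if slit_thickness_mm is None:
            spec = domain.metadata.get("spec", {})
            slit_thickness_mm = spec.get("ventricle_thickness", 3.0)
        h_mm = float(np.sqrt(np.median(domain.cell_volumes()) * 2.0))
        eps_n_pa_mm = controls.penalty_factor * params.G / h_mm
        pairs = []
        for slave_tag, master_tag in domain.contact_pairs:
            sf = domain.facets_where(slave_tag)
            mf = domain.facets_where(master_tag)
            if len(sf) == 0 or len(mf) == 0:
                continue
            slave_nodes = domain.facet_nodes(sf)
            mfacets = domain.facets[mf]
            outward = _reference_outward_normals(domain, mf)
            w = _fem.boundary_lumped_length(domain.nodes * MM, domain.facets[sf] , slave_nodes)
            mnodes = np.unique(mfacets.ravel())
            lookup = {n: i for i, n in enumerate(mnodes)}
            mlocal = np.vectorize(lookup.get)(mfacets)
            pairs.append(ContactPair(slave_nodes, mfacets, outward, w, mnodes, mlocal))
        st = cls(
            pairs=pairs,
            eps_n=eps_n_pa_mm / MM,                       # Pa/mm -> Pa/m
            g_tol=controls.g_tol_factor * slit_thickness_mm * MM,
        )
        st.lam = [np.zeros(len(p.slave_nodes)) for p in pairs]
        st.gap = [np.full(len(p.slave_nodes), -np.inf) for p in pairs]
        st.projection = [None] * len(pairs)
        return st

    def reset_multipliers(self):
        self.lam = [np.zeros_like(l) for l in self.lam]

    def diagnostics(self) -> dict:
        gaps = np.concatenate([g for g in self.gap]) if self.gap else np.array([-np.inf])
        lams = np.concatenate([l for l in self.lam]) if self.lam else np.array([0.0])
        return {
            "n_active": int((lams > 0).sum()),
            "max_penetration": float(max(gaps.max(), -np.inf)) / MM,  # mm
            "max_multiplier": float(lams.max()),
        }


def _reference_outward_normals(domain: Domain, facet_ids) -> np.ndarray:
    """Outward (tissue -> cavity) unit normals of boundary facets.

    Orientation is fixed by pointing away from the adjacent cell centroid.
    """
    # facet -> adjacent cell lookup
    edge_map = {}
    for ci, cell in enumerate(domain.cells):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edge_map.setdefault(tuple(sorted((cell[a], cell[b]))), []).append(ci)
    normals = np.empty((len(facet_ids), 2))
    for k, fi in enumerate(facet_ids):
        a, b = domain.facets[fi]
        cells_adj = edge_map[tuple(sorted((a, b)))]
        ccent = domain.nodes[domain.cells[cells_adj[0]]].mean(axis=0)
        t = domain.nodes[b] - domain.nodes[a]
        n = np.array([-t[1], t[0]])
        n /= np.linalg.norm(n)
        fmid = 0.5 * (domain.nodes[a] + domain.nodes[b])
        if n @ (fmid - ccent) < 0:
            n = -n
        normals[k] = n
    return normals


def detect_penetration(domain: Domain, u_mm: np.ndarray, state: ContactState) -> ContactState:
    """Closest-point projection of slave nodes on deformed master walls.

    Updates ``state.gap`` and ``state.projection``; gap > 0 is penetration.
    Each projection record is (master_facet_local_idx, weight_b, normal),
    with the deformed facet normal re-oriented by the reference outward
    direction.
    """
    x = domain.nodes + u_mm
    for ip, pair in enumerate(state.pairs):
        xs = x[pair.slave_nodes]                    # (s, 2)
        a = x[pair.master_facets[:, 0]]             # (m, 2)
        b = x[pair.master_facets[:, 1]]
        ab = b - a
        denom = np.einsum("md,md->m", ab, ab)
        # projection parameter for every (slave, master) pair
        t = np.clip(
            np.einsum("smd,md->sm", xs[:, None, :] - a[None, :, :], ab) / denom[None, :],
            0.0,
            1.0,
        )
        q = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d2 = np.einsum("smd,smd->sm", xs[:, None, :] - q, xs[:, None, :] - q)
        best = np.argmin(d2, axis=1)  # ties resolve to smallest index
        # deformed master facet normals, oriented by the reference outward
        # direction, then averaged to the wall nodes so the normal field is
        # continuous across facet junctions (prevents gap jumps when a
        # projection slides from one facet to the next)
        tvec = ab / np.sqrt(denom)[:, None]
        nvec = np.stack([-tvec[:, 1], tvec[:, 0]], axis=1)
        flip = np.einsum("md,md->m", nvec, pair.master_outward) < 0
        nvec[flip] = -nvec[flip]
        nodal = np.zeros((len(pair.master_node_ids), 2))
        np.add.at(nodal, pair.master_local[:, 0], nvec)
        np.add.at(nodal, pair.master_local[:, 1], nvec)
        nodal /= np.maximum(np.linalg.norm(nodal, axis=1, keepdims=True), 1e-30)
        tb = t[np.arange(len(xs)), best]
        nb = (1 - tb)[:, None] * nodal[pair.master_local[best, 0]] + tb[:, None] * nodal[
            pair.master_local[best, 1]
        ]
        nb /= np.maximum(np.linalg.norm(nb, axis=1, keepdims=True), 1e-30)
        qb = q[np.arange(len(xs)), best]
        gap_mm = -np.einsum("sd,sd->s", xs - qb, nb)   # + = penetration
        state.gap[ip] = gap_mm * MM
        state.projection[ip] = (best, t[np.arange(len(xs)), best], nb)
    return state


@dataclass
class _FrozenPairing:
    """Constraint linearisation captured at one detection.

    Gap model per constraint: g(u) = g0 + d^T u (u flat, SI).  Columns of
    D touch 6 dofs: d_slave = -n, d_masterA = (1-t) n, d_masterB = t n.
    """

    dofs: np.ndarray   # (m, 6)
    dvec: np.ndarray   # (m, 6)
    g0: np.ndarray     # (m,)
    w: np.ndarray      # (m,) slave lumped measure, m
    lam: np.ndarray    # (m,) multipliers, Pa

    def gaps(self, u_flat: np.ndarray) -> np.ndarray:
        return self.g0 + np.einsum("mk,mk->m", self.dvec, u_flat[self.dofs])


def _capture(state: ContactState, u_flat_m: np.ndarray) -> _FrozenPairing:
    dofs, dvec, g0, wgt, lam = [], [], [], [], []
    for ip, pair in enumerate(state.pairs):
        best, tpar, nvec = state.projection[ip]
        for k in range(len(pair.slave_nodes)):
            s = pair.slave_nodes[k]
            ma, mb = pair.master_facets[best[k]]
            nk = nvec[k]
            dk = np.concatenate([-nk, (1 - tpar[k]) * nk, tpar[k] * nk])
            dd = np.array([2 * s, 2 * s + 1, 2 * ma, 2 * ma + 1, 2 * mb, 2 * mb + 1])
            dofs.append(dd)
            dvec.append(dk)
            g0.append(state.gap[ip][k] - dk @ u_flat_m[dd])
            wgt.append(pair.slave_weight_m[k])
            lam.append(state.lam[ip][k])
    return _FrozenPairing(
        np.asarray(dofs), np.asarray(dvec), np.asarray(g0), np.asarray(wgt), np.asarray(lam)
    )


def _solve_frozen(solver, f0_bc_rhs, fro: _FrozenPairing, eps_n: float, u_flat: np.ndarray,
                  max_newton: int = 10):
    """Semismooth Newton on the active set with frozen pairing.

    The frozen problem is piecewise linear; each iteration solves the
    elasticity system plus a low-rank penalty term via the Woodbury
    identity against the prefactored stiffness.  Returns (u_flat, active).
    """
    n_dof = len(f0_bc_rhs)
    act_prev = None
    for _ in range(max_newton):
        g_lin = fro.gaps(u_flat)
        act = (fro.lam + eps_n * g_lin) > 0.0
        if act_prev is not None and np.array_equal(act, act_prev):
            break
        idx = np.flatnonzero(act)
        if len(idx) == 0:
            u_flat = solver.solve_flat(f0_bc_rhs)
            act_prev = act
            continue
        # force constant term and low-rank columns
        f = f0_bc_rhs.copy()
        tcoef = fro.w[idx] * (fro.lam[idx] + eps_n * fro.g0[idx])
        np.add.at(
            f,
            fro.dofs[idx].ravel(),
            -(tcoef[:, None] * fro.dvec[idx]).ravel(),
        )
        U = np.zeros((n_dof, len(idx)))
        for j, k in enumerate(idx):
            U[fro.dofs[k], j] += fro.dvec[k]
        c = eps_n * fro.w[idx]
        u_flat = solver.solve_flat(f, U=U, c=c)
        act_prev = act
    return u_flat, act_prev if act_prev is not None else np.zeros(len(fro.g0), bool)


def solve_contact_equilibrium(solver, p_w, state: ContactState, controls: NumericalControls):
    """Augmented-Lagrangian (Uzawa) outer loop.

    Each augmentation: refresh the closest-point pairing in the deformed
    configuration, solve the frozen piecewise-linear penalty problem
    exactly by active-set iteration, re-detect the true gaps, then update
    the multipliers lambda_N <- <lambda_N + eps_N g>.  Converged when the
    re-detected penetration is below g_tol.  The displacement is
    warm-started from the previous converged state of the same
    ContactState (time stepping loads the contact smoothly), which keeps
    the pairing refresh a small correction.  Raises on the augmentation
    cap or on divergence (the usual cause being a too-large penalty).
    """
    domain = solver.domain
    fresh_solve = state.u_warm is None
    u_mm = solver.solve_u(p_w) if fresh_solve else state.u_warm
    detect_penetration(domain, u_mm, state)
    if fresh_solve and all((g < state.g_tol).all() for g in state.gap) and all(
        (l == 0).all() for l in state.lam
    ):
        state.u_warm = u_mm
        mech = solver.mechanical_state(u_mm, contact_info=state.diagnostics())
        mech.contact.update(G=solver.params.G, lam=solver.params.lam, converged=True,
                            augmentations=0)
        return mech

    u_scale = max(np.abs(u_mm).max(), np.abs(solver.solve_u(p_w)).max(), 1e-12)
    f0 = solver.bc_rhs(solver.load_vector(p_w))

    best_pen = np.inf
    # damping of the pairing iterate suppresses tangential re-pairing limit
    # cycles of the frictionless walls
    relax = 0.5
    for aug in range(controls.max_augmentations):
        u_flat = (u_mm * MM).reshape(-1)
        fro = _capture(state, u_flat)
        u_new_flat, _ = _solve_frozen(solver, f0, fro, state.eps_n, u_flat,
                                      max_newton=controls.max_contact_inner)
        u_new = u_new_flat.reshape(-1, 2) / MM
        if not np.all(np.isfinite(u_new)) or np.abs(u_new).max() > 100 * u_scale:
            raise RuntimeError(
                "contact solve diverged; reduce the penalty coefficient eps_N"
            )
        # convergence is judged on the exact equilibrium iterate
        detect_penetration(domain, u_new, state)
        max_pen = max(g.max() for g in state.gap)
        best_pen = min(best_pen, max_pen)
        if max_pen <= state.g_tol:
            state.u_warm = u_new
            mech = solver.mechanical_state(u_new, contact_info=state.diagnostics())
            mech.contact.update(G=solver.params.G, lam=solver.params.lam,
                                converged=True, augmentations=aug + 1)
            return mech
        # relaxed iterate drives the next pairing and the multiplier update
        u_mm = u_mm + relax * (u_new - u_mm)
        detect_penetration(domain, u_mm, state)
        for ip in range(len(state.pairs)):
            state.lam[ip] = macaulay(state.lam[ip] + state.eps_n * state.gap[ip])
    raise RuntimeError(
        f"contact augmentation cap ({controls.max_augmentations}) reached with "
        f"residual penetration {best_pen / MM:.4g} mm > g_tol {state.g_tol / MM:.4g} mm"
    )
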