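"""Piecewise-linear (P1) finite-element assembly on simplicial meshes.

Internal numerical layer shared by the perfusion and oedema solvers.
All assembly is done in SI units: callers pass node coordinates in metres.
Triangles only for the PDE solves (the simulator's governing equations are
dimension-agnostic and are exercised in plane strain); tetrahedra are
supported by the mesh I/O layer but not by the assembly routines.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def cross2(a, b):
    """z-component of the cross product of stacked 2D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def cell_volumes(nodes: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Signed area of each triangle (positive for CCW orientation)."""
    p0, p1, p2 = (nodes[cells[:, i]] for i in range(3))
    return 0.5 * cross2(p1 - p0, p2 - p0)


def gradients(nodes: np.ndarray, cells: np.ndarray):
    """Constant P1 basis gradients per cell.

    Returns (grads, areas) with grads of shape (ncells, 3, 2):
    grads[c, i] = grad of the barycentric basis of local node i on cell c.
    """
    p0, p1, p2 = (nodes[cells[:, i]] for i in range(3))
    areas = 0.5 * cross2(p1 - p0, p2 - p0)
    if np.any(areas <= 0):
        raise ValueError("mesh contains non-positively oriented or degenerate cells")
    # edge vectors opposite each node, rotated by 90 degrees
    def rot(v):
        return np.stack([-v[:, 1], v[:, 0]], axis=1)

    g = np.empty((len(cells), 3, 2))
    g[:, 0] = rot(p2 - p1)
    g[:, 1] = rot(p0 - p2)
    g[:, 2] = rot(p1 - p0)
    g /= (2.0 * areas)[:, None, None]
    return g, areas


def stiffness(nodes, cells, coeff) -> sp.csr_matrix:
    """Assemble ∫ coeff ∇u·∇v.

    coeff: scalar, per-cell scalar array (nc,), or per-cell 2x2 tensor (nc,2,2).
    """
    g, areas = gradients(nodes, cells)
    coeff = np.asarray(coeff, dtype=float)
    if coeff.ndim == 0:
        local = (float(coeff) * areas)[:, None, None] * np.einsum("cid,cjd->cij", g, g)
    elif coeff.ndim == 1:
        local = (coeff * areas)[:, None, None] * np.einsum("cid,cjd->cij", g, g)
    else:
        kg = np.einsum("cde,cje->cjd", coeff, g)
        local = areas[:, None, None] * np.einsum("cid,cjd->cij", g, kg)
    return _scatter(local, cells, nodes.shape[0])


def mass(nodes, cells, coeff=1.0, cell_mask=None, lumped=False) -> sp.csr_matrix:
    """Assemble ∫ coeff u v, optionally restricted to masked cells."""
    _, areas = gradients(nodes, cells)
    w = np.asarray(coeff, dtype=float) * areas
    if cell_mask is not None:
        w = np.where(cell_mask, w, 0.0)
    n = nodes.shape[0]
    if lumped:
        local = np.zeros((len(cells), 3, 3))
        local[:, [0, 1, 2], [0, 1, 2]] = w[:, None] / 3.0
    else:
        base = (np.ones((3, 3)) + np.eye(3)) / 12.0
        local = w[:, None, None] * base
    return _scatter(local, cells, n)


def _scatter(local, cells, n) -> sp.csr_matrix:
    rows = np.repeat(cells, 3, axis=1).ravel()
    cols = np.tile(cells, (1, 3)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def load_vector(nodes, cells, values, cell_mask=None) -> np.ndarray:
    """Assemble ∫ f v for a per-cell constant source f (values shape (nc,))."""
    _, areas = gradients(nodes, cells)
    w = np.asarray(values, dtype=float) * areas
    if cell_mask is not None:
        w = np.where(cell_mask, w, 0.0)
    b = np.zeros(nodes.shape[0])
    np.add.at(b, cells.ravel(), np.repeat(w / 3.0, 3))
    return b


def elasticity_stiffness(nodes, cells, G: float, lam: float) -> sp.csr_matrix:
    """Plane-strain linear elasticity stiffness, dof order (u0x,u0y,u1x,...).

    Constitutive law: sigma = 2 G eps(u) + lam tr(eps) I.
    """
    g, areas = gradients(nodes, cells)
    nc = len(cells)
    # B matrix per cell: strain (exx, eyy, 2exy) = B @ u_local (6,)
    B = np.zeros((nc, 3, 6))
    B[:, 0, 0::2] = g[:, :, 0]
    B[:, 1, 1::2] = g[:, :, 1]
    B[:, 2, 0::2] = g[:, :, 1]
    B[:, 2, 1::2] = g[:, :, 0]
    D = np.array(
        [
            [lam + 2 * G, lam, 0.0],
            [lam, lam + 2 * G, 0.0],
            [0.0, 0.0, G],
        ]
    )
    local = areas[:, None, None] * np.einsum("cki,kl,clj->cij", B, D, B)
    dofs = np.empty((nc, 6), dtype=np.int64)
    dofs[:, 0::2] = 2 * cells
    dofs[:, 1::2] = 2 * cells + 1
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    n = 2 * nodes.shape[0]
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def pressure_gradient_load(nodes, cells, p: np.ndarray) -> np.ndarray:
    """RHS of the equilibrium weak form for div(sigma) = grad(p):

    ∫ sigma:eps(v) = -∫ grad(p)·v  for all v.
    Returns the vector -∫ grad(p)·v with grad(p) the per-cell P1 gradient.
    """
    g, areas = gradients(nodes, cells)
    gp = np.einsum("cid,ci->cd", g, p[cells])  # per-cell grad p
    b = np.zeros(2 * nodes.shape[0])
    w = -(areas / 3.0)[:, None] * gp  # same weight on each of the 3 nodes
    for i in range(3):
        np.add.at(b, 2 * cells[:, i], w[:, 0])
        np.add.at(b, 2 * cells[:, i] + 1, w[:, 1])
    return b


def cell_strain_stress(nodes, cells, u: np.ndarray, G: float, lam: float):
    """Per-cell small strain and effective stress from nodal displacements.

    u flat (2N,). Returns (eps, sig) with shape (nc, 3) in Voigt order
    (xx, yy, xy) — note xy is the tensor component, not the engineering one.
    """
    g, _ = gradients(nodes, cells)
    ux = u[0::2][cells]
    uy = u[1::2][cells]
    exx = np.einsum("ci,ci->c", g[:, :, 0], ux)
    eyy = np.einsum("ci,ci->c", g[:, :, 1], uy)
    exy = 0.5 * (np.einsum("ci,ci->c", g[:, :, 1], ux) + np.einsum("ci,ci->c", g[:, :, 0], uy))
    eps = np.stack([exx, eyy, exy], axis=1)
    tr = exx + eyy
    sig = np.stack([2 * G * exx + lam * tr, 2 * G * eyy + lam * tr, 2 * G * exy], axis=1)
    return eps, sig


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, dofs: np.ndarray, values: np.ndarray):
    """Row-eliminate Dirichlet dofs (symmetrically inexpensive variant).

    Returns (A_bc, b_bc); A is not modified in place.
    """
    dofs = np.asarray(dofs, dtype=np.int64)
    values = np.broadcast_to(np.asarray(values, dtype=float), dofs.shape)
    n = A.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[dofs] = True
    x0 = np.zeros(n)
    x0[dofs] = values
    b_bc = b - A @ x0
    b_bc[dofs] = values
    keep = sp.diags((~mask).astype(float))
    A_bc = keep @ A @ keep + sp.diags(mask.astype(float))
    return A_bc.tocsr(), b_bc


def boundary_lumped_length(nodes, facets, node_ids=None) -> np.ndarray:
    """Lumped boundary measure per node (half of each adjacent facet length)."""
    w = np.zeros(nodes.shape[0])
    seg = np.linalg.norm(nodes[facets[:, 1]] - nodes[facets[:, 0]], axis=1)
    np.add.at(w, facets[:, 0], 0.5 * seg)
    np.add.at(w, facets[:, 1], 0.5 * seg)
    if node_ids is not None:
        return w[node_ids]
    return w
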