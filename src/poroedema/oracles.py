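"""Independent reference solutions used to validate the numerical kernels.

These deliberately share no assembly code with the solvers: the
compartment balance is plain arithmetic, the slab solution is a Fourier
series, the radial swelling problem is integrated as a two-point boundary
value ODE, and the bar-stop contact problem is a closed form.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_bvp


def compartment_balance(p_a: float, p_v: float, omega_ac: float, omega_cv: float) -> float:
    """Zero-dimensional steady capillary pressure.

    With the arteriole and venule pressures held fixed, the capillary
    compartment balances inflow against outflow:
    p_c = (w_ac p_a + w_cv p_v) / (w_ac + w_cv).
    """
    s = omega_ac + omega_cv
    if s <= 0:
        raise ValueError("omega_ac + omega_cv must be positive")
    return (omega_ac * p_a + omega_cv * p_v) / s


def slab_diffusion(x, t, D: float, p0: float, p1: float, L: float, n_terms: int = 200):
    """Transient 1D diffusion in a slab after a boundary step.

    Initial condition p = p0 everywhere; at t = 0 the boundary at x = 0
    jumps to p1 while x = L stays at p0.  Diffusivity D (for the
    interstitial compartment D = K_w / c_w).  Fourier-series solution:

        p(x,t) = p1 + (p0-p1) x/L
                 + sum_n 2 (p0-p1)/(n pi) sin(n pi x / L) exp(-D (n pi/L)^2 t)
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    x = np.asarray(x, dtype=float)
    steady = p1 + (p0 - p1) * x / L
    n = np.arange(1, n_terms + 1)
    modes = np.sin(np.outer(x, n) * np.pi / L) * (2.0 * (p0 - p1) / (np.pi * n))
    decay = np.exp(-D * (n * np.pi / L) ** 2 * t)
    return steady + modes @ decay


def slab_diffusion_fd(x_eval, t_end: float, D: float, p0: float, p1: float, L: float,
                      nx: int = 400):
    """Finite-difference cross-check of :func:`slab_diffusion` (oracle of the
    oracle): implicit Euler on a fine grid with many small steps."""
    x = np.linspace(0, L, nx + 1)
    p = np.full(nx + 1, float(p0))
    p[0] = p1
    dt = 0.1 * (L / nx) ** 2 / D
    nsteps = max(int(np.ceil(t_end / dt)), 1)
    dt = t_end / nsteps
    r = D * dt / (x[1] - x[0]) ** 2
    # tridiagonal implicit Euler
    from scipy.sparse import diags
    from scipy.sparse.linalg import splu

    n_in = nx - 1
    A = diags(
        [np.full(n_in - 1, -r), np.full(n_in, 1 + 2 * r), np.full(n_in - 1, -r)],
        offsets=[-1, 0, 1],
    ).tocsc()
    lu = splu(A)
    for _ in range(nsteps):
        b = p[1:-1].copy()
        b[0] += r * p1
        b[-1] += r * p0
        p[1:-1] = lu.solve(b)
    return np.interp(x_eval, x, p)


def radial_elastic_response(r_eval, p_w_of_r, G: float, lam: float,
                            r_inner: float, r_outer: float, dp_w=None):
    """Plane-strain radial swelling of an annulus under a pressure load.

    Equilibrium div(sigma_eff) = grad(p_w) reduces in the axisymmetric case
    to (lam + 2G) (u'' + u'/r - u/r^2) = p_w'(r), with the outer rim fixed
    (u(r_outer) = 0) and the inner rim free of effective traction
    (sigma_rr = (lam+2G) u' + lam u/r = 0 at r_inner).  Integrated with a
    collocation two-point boundary-value solver.
    """
    if r_inner >= r_outer:
        raise ValueError("r_inner must be < r_outer")
    m = lam + 2.0 * G
    if dp_w is None:
        eps = 1e-6 * (r_outer - r_inner)

        def dp_w(r):
            return (p_w_of_r(r + eps) - p_w_of_r(r - eps)) / (2 * eps)

    def rhs(r, y):
        u, up = y
        return np.vstack([up, dp_w(r) / m - up / r + u / r**2])

    def bc(ya, yb):
        sig_in = m * ya[1] + lam * ya[0] / r_inner
        return np.array([sig_in, yb[0]])

    r0 = np.linspace(r_inner, r_outer, 200)
    sol = solve_bvp(rhs, bc, r0, np.zeros((2, r0.size)), tol=1e-10, max_nodes=20000)
    if not sol.success:
        raise RuntimeError(f"radial BVP solve failed: {sol.message}")
    return sol.sol(np.asarray(r_eval, dtype=float))[0]


def bar_stop_closure(E: float, A: float, L: float, P: float, gap: float):
    """Closed-form 1D bar pushed against a rigid stop.

    A bar clamped at x=0 with axial stiffness EA/L carries an end load P
    towards a stop a distance ``gap`` beyond the tip.  If the free tip
    displacement PL/EA stays below the gap there is no contact; otherwise
    the tip is arrested at the gap and the stop carries the excess load.
    Returns (tip displacement, contact reaction).
    """
    u_free = P * L / (E * A)
    if u_free <= gap:
        return u_free, 0.0
    return gap, P - E * A * gap / L
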