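"""Ventricle self-contact: detection, Macaulay algebra, augmented Lagrangian."""

import numpy as np
import pytest

from poroedema.contact import (
    ContactState,
    detect_penetration,
    macaulay,
    solve_contact_equilibrium,
)
from poroedema.oracles import bar_stop_closure
from poroedema.parameters import NumericalControls, OedemaParameters, Schedule
from poroedema.oedema import ElasticitySolver, run_oedema_simulation


class TestMacaulay:
    @pytest.mark.parametrize("x,expected", [(3.0, 3.0), (-2.0, 0.0), (0.0, 0.0)])
    def test_scalar_values(self, x, expected):
        assert macaulay(x) == expected

    def test_elementwise_on_arrays(self):
        x = np.array([-1.0, 0.0, 2.5])
        assert np.array_equal(macaulay(x), [0.0, 0.0, 2.5])


def _brute_force_gaps(domain, u, pair):
    """All-pairs nearest-facet reference for the spatial-indexed detection."""
    x = domain.nodes + u
    gaps = []
    for s in pair.slave_nodes:
        best = np.inf
        best_gap = None
        for f, n0 in zip(pair.master_facets, pair.master_outward):
            a, b = x[f[0]], x[f[1]]
            ab = b - a
            t = np.clip((x[s] - a) @ ab / (ab @ ab), 0.0, 1.0)
            q = a + t * ab
            d = np.linalg.norm(x[s] - q)
            if d < best:
                best = d
                tv = ab / np.linalg.norm(ab)
                n = np.array([-tv[1], tv[0]])
                if n @ n0 < 0:
                    n = -n
                best_gap = -(x[s] - q) @ n
        gaps.append(best_gap)
    return np.array(gaps)


class TestDetection:
    def test_open_slit_has_negative_gaps(self, brain, params):
        state = ContactState.from_domain(brain, params, NumericalControls())
        detect_penetration(brain, np.zeros_like(brain.nodes), state)
        for g in state.gap:
            assert g.max() <= -3.0e-3 + 1e-9  # slit thickness 3 mm, SI gaps
        assert state.diagnostics()["n_active"] == 0

    def test_rigid_wall_translation_matches_brute_force(self, brain, params):
        """Push the right lateral wall 3.5 mm towards the medial wall."""
        state = ContactState.from_domain(brain, params, NumericalControls())
        pair = state.pairs[0]
        u = np.zeros_like(brain.nodes)
        u[pair.slave_nodes, 0] = -3.5
        detect_penetration(brain, u, state)
        ref = _brute_force_gaps(brain, u, pair)
        assert np.abs(state.gap[0] / 1e-3 - ref).max() < 1e-9
        assert state.gap[0].max() == pytest.approx(0.5e-3, abs=0.2e-3)

    def test_tangential_slide_leaves_gaps_unchanged(self, brain, params):
        state = ContactState.from_domain(brain, params, NumericalControls())
        pair = state.pairs[0]
        detect_penetration(brain, np.zeros_like(brain.nodes), state)
        base = state.gap[0].copy()
        u = np.zeros_like(brain.nodes)
        u[pair.slave_nodes, 1] = 0.4  # slide along the wall
        detect_penetration(brain, u, state)
        interior = np.abs(brain.nodes[pair.slave_nodes, 1] - (-20.0)) < 25.0
        assert np.abs(state.gap[0] - base)[interior].max() < 1e-6


class TestBarStopClosure:
    """1D bar pushed through a gap onto a rigid stop, solved with the same
    augmented-Lagrangian update as the 2D solver and compared with the
    closed form."""

    def _solve_bar(self, E, A, L, P, gap, n_el=20, eps_n=None, n_aug=100):
        # tip dof displacement of a clamped bar under end load P with a
        # stop at distance `gap`; stiffness matrix assembled directly
        k = E * A / (L / n_el)
        n = n_el + 1
        K = np.zeros((n, n))
        for e in range(n_el):
            K[e : e + 2, e : e + 2] += k * np.array([[1, -1], [-1, 1]])
        K = K[1:, 1:]  # clamp node 0
        f = np.zeros(n_el)
        f[-1] = P
        eps_n = eps_n or 10 * k
        lam = 0.0
        for _ in range(n_aug):
            Kc = K.copy()
            fc = f.copy()
            u = np.linalg.solve(Kc, fc)
            g = u[-1] - gap  # penetration of the stop
            t = macaulay(lam + eps_n * g)
            if t > 0:
                Kc[-1, -1] += eps_n
                fc[-1] -= lam + eps_n * (-gap)
                u = np.linalg.solve(Kc, fc)
                g = u[-1] - gap
            new_lam = macaulay(lam + eps_n * g)
            if abs(new_lam - lam) < 1e-12 * max(abs(new_lam), 1.0) and g <= 1e-14:
                lam = new_lam
                break
            lam = new_lam
        return u[-1], lam

    def test_matches_closed_form_in_contact(self):
        E, A, L, P, gap = 1000.0, 1e-4, 1.0, 0.5, 2e-3
        u_ref, r_ref = bar_stop_closure(E, A, L, P, gap)
        u, lam = self._solve_bar(E, A, L, P, gap)
        assert abs(u - u_ref) / u_ref < 0.005
        assert abs(lam - r_ref) / r_ref < 0.005

    def test_no_contact_below_closure(self):
        E, A, L, P, gap = 1000.0, 1e-4, 1.0, 1e-4, 2e-3  # free tip: 1 mm < 2 mm gap
        u_ref, r_ref = bar_stop_closure(E, A, L, P, gap)
        assert r_ref == 0.0
        u, lam = self._solve_bar(E, A, L, P, gap)
        assert u == pytest.approx(u_ref, rel=1e-12)
        assert lam == 0.0


class TestBrainContact:
    def test_loading_below_closure_equals_contact_free_solve(self, brain, params):
        pw = np.full(len(brain.nodes), params.p_w_boundary)
        pw += 30.0 * np.exp(-((brain.nodes[:, 0] - 40) ** 2
                              + (brain.nodes[:, 1] + 20) ** 2) / 400.0)
        solver = ElasticitySolver(brain, params)
        u_free = solver.solve_u(pw)
        state = ContactState.from_domain(brain, params, NumericalControls())
        mech = solve_contact_equilibrium(solver, pw, state, NumericalControls())
        assert state.diagnostics()["n_active"] == 0
        assert np.abs(mech.u - u_free).max() < 1e-12

    def test_converged_state_satisfies_complementarity(self, reference_run):
        """At every recorded step: penetration <= g_tol and multipliers >= 0."""
        tab = reference_run.table
        g_tol_mm = 0.01 * 3.0  # 1% of slit thickness
        pen = tab["max_penetration_mm"].to_numpy()
        assert np.nanmax(pen) <= g_tol_mm + 1e-12
        assert (tab["max_multiplier_pa"].to_numpy() >= 0).all()
        # contact engages during the run (the slit actually collapses)
        assert tab["contact_active"].iloc[-1] > 0

    def test_penalty_path_independence(self, brain, params, hemispheric_core):
        """Halving eps_N changes the converged displacement by < 1%."""
        sch = Schedule(dt=250.0, t_end=500.0)
        c1 = NumericalControls()
        c2 = NumericalControls(penalty_factor=c1.penalty_factor / 2)
        r1 = run_oedema_simulation(brain, params, hemispheric_core, sch, 90.0,
                                   controls=c1)
        r2 = run_oedema_simulation(brain, params, hemispheric_core, sch, 90.0,
                                   controls=c2)
        assert abs(r1.mls[-1] - r2.mls[-1]) / abs(r1.mls[-1]) < 0.01
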