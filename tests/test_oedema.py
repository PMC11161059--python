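"""Transient oedema model: Starling source, stepping, displacement solve."""

import dataclasses

import numpy as np
import pytest

from poroedema.geometry import build_annulus, build_slab, midplane_nodes
from poroedema.oracles import radial_elastic_response, slab_diffusion
from poroedema.parameters import MMHG, OedemaParameters, PerfusionParameters, Schedule
from poroedema.perfusion import PressureFields
from poroedema.oedema import (
    ElasticitySolver,
    PressureStepper,
    run_oedema_simulation,
    starling_source,
)

STARLING_COEFF = 3.6e-7  # 2 * 0.03 * 3.0e-11 / 5e-6, 1/(Pa s)


class TestStarlingSource:
    def _fields(self, brain, pc, pw):
        n = len(brain.nodes)
        return PressureFields(
            p_a=np.full(n, 12000.0), p_c=np.full(n, pc),
            p_v=np.full(n, 2000.0), p_w=np.full(n, pw),
        )

    def test_table_value_arithmetic(self, brain, params):
        """Coefficient and magnitude recomputed from the defaults."""
        assert np.isclose(params.starling_coefficient, STARLING_COEFF)
        core = np.ones(len(brain.cells), bool)
        f = self._fields(brain, 4222.2222, 1333.22)
        s = starling_source(brain, f, params, core)
        expected = STARLING_COEFF * ((4222.2222 - 1333.22) - 0.65 * 2445.0)
        assert np.allclose(s, expected)
        assert np.isclose(expected, 4.679e-4, rtol=1e-3)

    def test_equilibrium_gives_exact_zero(self, brain, params):
        pw = 4222.2222 - params.sigma * params.Pi_c
        f = self._fields(brain, 4222.2222, pw)
        s = starling_source(brain, f, params, np.ones(len(brain.cells), bool))
        assert np.all(s == 0.0)

    def test_zero_outside_core(self, brain, params):
        f = self._fields(brain, 9000.0, 1000.0)
        s = starling_source(brain, f, params, np.zeros(len(brain.cells), bool))
        assert np.all(s == 0.0)

    def test_clamp_suppresses_reabsorption(self, brain, params):
        p = dataclasses.replace(params, clamp_starling=True)
        f = self._fields(brain, 1000.0, 5000.0)  # strongly negative driving term
        s = starling_source(brain, f, p, np.ones(len(brain.cells), bool))
        assert np.all(s == 0.0)


class TestPressureStepping:
    def test_zero_leakage_preserves_steady_state(self, brain, hemispheric_core):
        """With L_p = 0 the healthy steady state is a fixed point of the
        implicit stepper for arbitrarily many steps."""
        p0 = OedemaParameters(L_p=0.0)
        r = run_oedema_simulation(brain, p0, hemispheric_core, Schedule(), 90.0)
        assert np.allclose(r.icp, 10.0, atol=1e-9)
        assert np.abs(r.mls).max() < 1e-9

    def test_interstitial_balance_closes_each_step(self, brain, params, hemispheric_core):
        stepper = PressureStepper(brain, params, hemispheric_core, 125.0)
        n = len(brain.nodes)
        f = PressureFields(
            p_a=np.full(n, 12000.0), p_c=np.full(n, 4222.22),
            p_v=np.full(n, 2000.0), p_w=np.full(n, params.p_w_boundary),
        )
        for _ in range(4):
            f = stepper.step(f)
            b = f.info["balance"]
            closure = abs(b["storage"] - b["boundary_flux"] - b["source"])
            assert closure <= 0.005 * max(abs(b["storage"]), 1e-30)

    def test_single_compartment_slab_matches_series(self):
        """Diffusion-only reduction against the Fourier-series oracle."""
        L = 50.0
        slab = build_slab(L, 10.0, 1.0, tag_lo="cortical:lo", tag_hi="ventricle:hi")
        pf = PerfusionParameters(omega_ac=0.0, omega_cv=0.0)
        par = OedemaParameters(L_p=0.0, perfusion=pf)
        p_hot, p_cold = 2666.44, 1333.22
        bcs = {
            "p_w": [("cortical:lo", p_hot), ("ventricle:hi", p_cold)],
            "p_a": [("cortical", 12000.0)], "p_c": [], "p_v": [("cortical", 2000.0)],
        }
        D = par.K_w * 1e-9 / par.c_w
        t_end = 0.1 * (L * 1e-3) ** 2 / D
        nsteps = 160
        stepper = PressureStepper(slab, par, np.zeros(len(slab.cells), bool),
                                  t_end / nsteps, bcs=bcs)
        n = len(slab.nodes)
        f = PressureFields(p_a=np.full(n, 12000.0), p_c=np.full(n, 4222.22),
                           p_v=np.full(n, 2000.0), p_w=np.full(n, p_cold))
        for _ in range(nsteps):
            f = stepper.step(f)
        ref = slab_diffusion(slab.nodes[:, 0] * 1e-3, f.time, D, p_cold, p_hot, L * 1e-3)
        l2 = np.sqrt(np.mean((f.p_w - ref) ** 2) / np.mean((ref - p_cold) ** 2))
        assert l2 < 0.01

    def test_invalid_dt_rejected(self, brain, params, hemispheric_core):
        with pytest.raises(ValueError, match="dt"):
            PressureStepper(brain, params, hemispheric_core, 0.0)


class TestDisplacement:
    def test_uniform_pressure_gives_zero_displacement(self, brain, params):
        """Gauge invariance: only pressure gradients load the tissue."""
        s = ElasticitySolver(brain, params)
        u = s.solve_u(np.full(len(brain.nodes), 2666.0))
        assert np.abs(u).max() < 1e-10

    def test_annulus_matches_radial_bvp_oracle(self, params):
        d = build_annulus(20.0, 80.0, 1.0)
        r = np.hypot(d.nodes[:, 0], d.nodes[:, 1]) * 1e-3
        ri, ro = 0.02, 0.08
        grad = -2000.0 / (ro - ri)
        pw = 2000.0 * (ro - r) / (ro - ri)
        u = ElasticitySolver(d, params).solve_u(pw)
        ur = (u * d.nodes).sum(axis=1) / np.hypot(d.nodes[:, 0], d.nodes[:, 1])
        uref = radial_elastic_response(
            r, None, params.G, params.lam, ri, ro, dp_w=lambda rr: grad + 0 * rr
        ) * 1e3
        assert np.abs(ur - uref).max() / np.abs(uref).max() < 0.01

    def test_symmetric_load_gives_antisymmetric_displacement(self, brain, params):
        """Mirror-symmetric p_w: u_x is odd in x, so the midplane stays put."""
        pw = np.full(len(brain.nodes), 1333.22)
        pw += 800.0 * np.exp(-((np.abs(brain.nodes[:, 0]) - 30) ** 2
                               + brain.nodes[:, 1] ** 2) / 400.0)
        s = ElasticitySolver(brain, params)
        u = s.solve_u(pw)
        mp = midplane_nodes(brain, 0.2)
        assert np.abs(u[mp, 0]).max() < 1e-9 * max(np.abs(u).max(), 1.0)


class TestTransientRun:
    def test_schedule_records_eight_post_initial_states(self, reference_run):
        assert len(reference_run.rows) == 9  # initial + 8 steps of 125 s to 1000 s
        assert reference_run.times[0] == 0.0
        assert reference_run.times[-1] == 1000.0
        assert np.allclose(np.diff(reference_run.times), 125.0)

    def test_icp_monotonically_rises_towards_equilibrium(self, reference_run):
        assert np.all(np.diff(reference_run.icp) > -1e-9)
        assert reference_run.icp[0] == pytest.approx(10.0)

    def test_venule_boundary_tracks_abp_offset(self, brain, params, hemispheric_core):
        """The cortical venule pressure is exactly ABP - 75 mmHg."""
        abp = 97.5
        stepperless = run_oedema_simulation(
            brain, params, hemispheric_core,
            Schedule(dt=125.0, t_end=125.0), abp, contact=False, record_fields=True,
        )
        fields, _ = stepperless.snapshots[-1]
        vc = brain.facet_nodes(brain.facets_where("cortical"))
        assert np.allclose(fields.p_v[vc], (abp - 75.0) * MMHG)
        assert np.allclose(fields.p_a[vc], abp * MMHG)

    def test_pressure_response_linear_in_abp_increment(self, brain, params, hemispheric_core):
        """Doubling (ABP - 90) doubles interior pressure perturbations."""
        sch = Schedule()
        base = run_oedema_simulation(brain, params, hemispheric_core, sch, 90.0,
                                     contact=False)
        mid = run_oedema_simulation(brain, params, hemispheric_core, sch, 97.5,
                                    contact=False)
        high = run_oedema_simulation(brain, params, hemispheric_core, sch, 105.0,
                                     contact=False)
        d1 = mid.icp[-1] - base.icp[-1]
        d2 = high.icp[-1] - base.icp[-1]
        assert abs(d2 / d1 - 2.0) < 0.01
        m1 = mid.mls[-1] - base.mls[-1]
        m2 = high.mls[-1] - base.mls[-1]
        assert abs(m2 / m1 - 2.0) < 0.01

    def test_halving_dt_changes_final_icp_below_two_percent(
        self, brain, params, hemispheric_core, reference_run
    ):
        fine = run_oedema_simulation(brain, params, hemispheric_core,
                                     Schedule(dt=62.5), 90.0)
        rel = abs(fine.icp[-1] - reference_run.icp[-1]) / reference_run.icp[-1]
        assert rel < 0.02

    def test_larger_lp_gives_larger_interstitial_pressure(self, lp_sweep_runs):
        icp = {m: r.icp[-1] for m, r in lp_sweep_runs.items()}
        assert icp[1.0] < icp[2.0] < icp[5.0] <= icp[8.0] + 1e-9

    def test_empty_core_stays_at_baseline(self, brain, params):
        core = np.zeros(len(brain.cells), bool)
        r = run_oedema_simulation(brain, params, core, Schedule(), 90.0)
        assert np.allclose(r.icp, 10.0, atol=1e-9)
        assert np.abs(r.mls).max() < 1e-9
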