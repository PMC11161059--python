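"""Shared fixtures: domains, steady solves and reference transient runs.

Heavy objects are session-scoped so the oedema-type and L_p sweeps are
computed once and reused by both the unit tests and the acceptance tests.
"""

import dataclasses

import numpy as np
import pytest

from poroedema.geometry import (
    IdealizedBrainSpec,
    build_idealized_brain,
    occlude_territories,
)
from poroedema.parameters import OedemaParameters, PerfusionParameters, Schedule
from poroedema.perfusion import solve_steady_perfusion, extract_oedema_core
from poroedema.oedema import run_oedema_simulation


@pytest.fixture(scope="session")
def brain():
    """Default 2D bihemispheric brain (h = 2 mm)."""
    return build_idealized_brain(IdealizedBrainSpec())


@pytest.fixture(scope="session")
def coarse_brain():
    return build_idealized_brain(IdealizedBrainSpec(h=3.0))


@pytest.fixture(scope="session")
def params():
    return OedemaParameters()


@pytest.fixture(scope="session")
def healthy(brain, params):
    return solve_steady_perfusion(brain, params.perfusion)


def _core(brain, healthy, pf, territories, threshold=0.7):
    occ = occlude_territories(brain, territories)
    occluded = solve_steady_perfusion(brain, pf, occluded=occ)
    return extract_oedema_core(brain, healthy, occluded, pf, threshold=threshold)


@pytest.fixture(scope="session")
def hemispheric_core(brain, healthy, params):
    mask, vol = _core(brain, healthy, params.perfusion, ["right_hemispheric"])
    return mask


@pytest.fixture(scope="session")
def reference_run(brain, params, hemispheric_core):
    """Hemispheric oedema at baseline ABP 90 mmHg with contact."""
    return run_oedema_simulation(
        brain, params, hemispheric_core, Schedule(), 90.0, contact=True
    )


@pytest.fixture(scope="session")
def reference_run_nocontact(brain, params, hemispheric_core):
    return run_oedema_simulation(
        brain, params, hemispheric_core, Schedule(), 90.0, contact=False
    )


@pytest.fixture(scope="session")
def type_runs(brain, params, healthy):
    """One transient run per occluded territory (oedema-type comparison)."""
    out = {}
    for terr in ("right_hemispheric", "right_MCA", "right_ACA", "right_PCA"):
        mask, vol = _core(brain, healthy, params.perfusion, [terr])
        r = run_oedema_simulation(brain, params, mask, Schedule(), 90.0, contact=True)
        out[terr] = (r, vol)
    return out


@pytest.fixture(scope="session")
def lp_sweep_runs(brain, params, hemispheric_core):
    out = {}
    for mult in (1.0, 2.0, 5.0, 8.0):
        p = dataclasses.replace(params, L_p=params.L_p * mult)
        out[mult] = run_oedema_simulation(
            brain, p, hemispheric_core, Schedule(), 90.0, contact=True
        )
    return out
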