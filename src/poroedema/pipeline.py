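"""Pipeline orchestration: geometry -> perfusion -> core -> oedema -> fits.

Experiment presets mirror the study designs the simulator exists for:

single        one transient oedema run per scheduled ABP value.
abp_sweep     vary ABP, pool (ABP, ICP) samples over time steps, fit the
              confidence ellipse and the pooled zero-intercept ICP-MLS slope.
lp_sweep      blood-brain-barrier severity: L_p x {1, 2, 5, 8} at the
              baseline ABP; compare ICP-MLS slopes.
oedema_types  occlude hemispheric / MCA-like / ACA-like / PCA-like
              territories; compare core volumes and ICP-MLS slopes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .geometry import build_idealized_brain, occlude_territories
from .io import load_domain
from .oedema import run_oedema_simulation
from .perfusion import solve_steady_perfusion, extract_oedema_core
from .postprocess import fit_icp_mls_slope, fit_confidence_ellipse

log = logging.getLogger("poroedema")

LP_MULTIPLIERS = (1.0, 2.0, 5.0, 8.0)
OEDEMA_TYPES = ("right_hemispheric", "right_MCA", "right_ACA", "right_PCA")


def _prepare(config: RunConfig):
    if config.geometry_path:
        domain = load_domain(config.geometry_path)
    else:
        domain = build_idealized_brain(config.geometry)
    return domain


def _core(domain, config: RunConfig, territories):
    pf = config.params.perfusion
    healthy = solve_steady_perfusion(domain, pf)
    occ = occlude_territories(domain, territories)
    occluded = solve_steady_perfusion(domain, pf, occluded=occ)
    mask, vol = extract_oedema_core(domain, healthy, occluded, pf,
                                    threshold=config.core_threshold)
    return mask, vol


def _slope_of(result):
    return fit_icp_mls_slope(result.icp[1:], result.mls[1:],
                             baseline_mmhg=result.icp[0])


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the configured preset; write CSV/JSON artifacts; return report."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"preset": config.preset, "config": config.echo()}

    stage = "geometry"
    try:
        domain = _prepare(config)
        report["geometry"] = {
            "n_nodes": int(len(domain.nodes)),
            "n_cells": int(len(domain.cells)),
            "territories": domain.territories(),
        }

        if not config.occlusion and config.preset != "oedema_types":
            report["core_volume_ml"] = 0.0
            report["note"] = "empty occlusion list: no oedema core, oedema runs skipped"
            _dump(report, outdir / "report.json")
            return report

        stage = "perfusion"
        if config.preset != "oedema_types":
            core, vol = _core(domain, config, config.occlusion)
            report["core_volume_ml"] = vol

        stage = f"oedema ({config.preset})"
        if config.preset == "single":
            runs = []
            for abp in config.schedule.abp_mmhg:
                r = run_oedema_simulation(domain, config.params, core, config.schedule,
                                          abp, contact=config.contact,
                                          controls=config.controls)
                r.to_csv(outdir / f"series_abp{abp:g}.csv")
                slope, r2 = _slope_of(r)
                runs.append({**r.summary(), "slope_mm_per_mmhg": slope, "r2": r2})
            report["runs"] = runs

        elif config.preset == "abp_sweep":
            icp_all, mls_all, pts = [], [], []
            runs = []
            for abp in config.schedule.abp_mmhg:
                r = run_oedema_simulation(domain, config.params, core, config.schedule,
                                          abp, contact=config.contact,
                                          controls=config.controls)
                r.to_csv(outdir / f"series_abp{abp:g}.csv")
                icp_all += list(r.icp[1:])
                mls_all += list(r.mls[1:])
                pts += [(abp, icp) for icp in r.icp[1:]]
                runs.append(r.summary())
            slope, r2 = fit_icp_mls_slope(icp_all, mls_all)
            ell = fit_confidence_ellipse(pts, level=0.75)
            report["runs"] = runs
            report["icp_mls_slope_mm_per_mmhg"] = slope
            report["icp_mls_r2"] = r2
            report["mls_stats_mm"] = {
                "mean": float(np.mean(mls_all)),
                "min": float(np.min(mls_all)),
                "max": float(np.max(mls_all)),
            }
            report["abp_icp_ellipse"] = {
                "center": list(ell["center"]),
                "semi_axes": list(ell["semi_axes"]),
                "rotation_deg": ell["rotation_deg"],
                "line_slope": ell["line_slope"],
                "line_intercept": ell["line_intercept"],
                "degenerate": ell["degenerate"],
            }

        elif config.preset == "lp_sweep":
            abp = config.schedule.abp_mmhg[0]
            sweeps = []
            for m in LP_MULTIPLIERS:
                params_m = dataclasses.replace(config.params,
                                               L_p=config.params.L_p * m)
                r = run_oedema_simulation(domain, params_m, core, config.schedule,
                                          abp, contact=config.contact,
                                          controls=config.controls)
                r.to_csv(outdir / f"series_lp{m:g}x.csv")
                slope, r2 = _slope_of(r)
                sweeps.append({"lp_multiplier": m, "slope_mm_per_mmhg": slope,
                               "r2": r2, **r.summary()})
            report["lp_sweep"] = sweeps

        elif config.preset == "oedema_types":
            abp = config.schedule.abp_mmhg[0]
            cases = []
            for terr in OEDEMA_TYPES:
                core, vol = _core(domain, config, [terr])
                r = run_oedema_simulation(domain, config.params, core, config.schedule,
                                          abp, contact=config.contact,
                                          controls=config.controls)
                r.to_csv(outdir / f"series_{terr}.csv")
                slope, r2 = _slope_of(r)
                cases.append({"territory": terr, "core_volume_ml": vol,
                              "slope_mm_per_mmhg": slope, "r2": r2,
                              **r.summary()})
            report["oedema_types"] = cases

    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    _dump(report, outdir / "report.json")
    _dump(config.echo(), outdir / "config_echo.json")
    return report


def _dump(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.generic):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
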