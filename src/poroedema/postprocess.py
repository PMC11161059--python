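"""Scalar reductions of simulation fields and the ICP-MLS / ABP-ICP fits.

ICP is defined as the maximum interstitial pressure over the domain
(reported in mmHg); MLS as the signed maximum right-to-left displacement
on the midplane x = 0 (positive = shift towards the left hemisphere, the
clinical convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import chi2

from ._fem import cross2
from .parameters import MMHG


@dataclass
class SimulationResult:
    """Time series and metadata of one transient oedema run."""

    abp_mmhg: float = float("nan")
    core_volume_ml: float = 0.0
    params_echo: dict = field(default_factory=dict)
    rows: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    table: pd.DataFrame | None = None

    def finalize(self):
        self.table = pd.DataFrame(self.rows)
        icp = self.table["icp_mmhg"].to_numpy()
        pwb_mmhg = self.params_echo.get("p_w_boundary_mmhg", 10.0)
        if np.any(icp < pwb_mmhg - 1e-6):
            raise ValueError("ICP fell below the CSF baseline; inconsistent series")
        return self

    @property
    def times(self):
        return self.table["t"].to_numpy()

    @property
    def icp(self):
        return self.table["icp_mmhg"].to_numpy()

    @property
    def mls(self):
        return self.table["mls_mm"].to_numpy()

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "abp_mmhg": self.abp_mmhg,
            "core_volume_ml": self.core_volume_ml,
            "final_icp_mmhg": float(self.icp[-1]),
            "final_mls_mm": float(self.mls[-1]),
            "n_records": len(self.rows),
        }


def compute_icp(p_w: np.ndarray, mmhg: float = MMHG) -> float:
    """Maximum interstitial pressure over the domain, in mmHg."""
    return float(np.max(p_w)) / mmhg


def compute_mls(u_mm: np.ndarray, midplane_ids: np.ndarray, mode: str = "signed") -> float:
    """Midline shift from the displacement field, in mm.

    mode="signed": maximum of the right-to-left (-x) displacement component
    over the midplane nodes (positive = shift towards the left).
    mode="magnitude": maximum displacement magnitude (the looser reading of
    "maximum displacement on the centreline").
    """
    if len(midplane_ids) == 0:
        raise ValueError("empty midplane node set")
    if mode == "signed":
        return float(np.max(-u_mm[midplane_ids, 0]))
    if mode == "magnitude":
        return float(np.max(np.linalg.norm(u_mm[midplane_ids], axis=1)))
    raise ValueError(f"unknown MLS mode {mode!r}")


def probe_displacement(domain, u_mm: np.ndarray, points) -> list:
    """P1-interpolated displacement (mm) at given points (mm).

    Raises if a point lies outside the domain.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cent = domain.nodes[domain.cells].mean(axis=1)
    tree = cKDTree(cent)
    out = []
    k = min(32, len(cent))
    for ip, p in enumerate(pts):
        _, cand = tree.query(p, k=k)
        cand = np.atleast_1d(cand)
        hit = None
        for c in cand:
            tri = domain.cells[c]
            T = np.column_stack(
                [domain.nodes[tri[1]] - domain.nodes[tri[0]], domain.nodes[tri[2]] - domain.nodes[tri[0]]]
            )
            try:
                lam12 = np.linalg.solve(T, p - domain.nodes[tri[0]])
            except np.linalg.LinAlgError:
                continue
            lam = np.array([1.0 - lam12.sum(), lam12[0], lam12[1]])
            if np.all(lam >= -1e-9):
                hit = (tri, lam)
                break
        if hit is None:
            raise ValueError(f"probe point {ip} at {p.tolist()} lies outside the domain")
        tri, lam = hit
        out.append(tuple(lam @ u_mm[tri]))
    return out


def _von_mises_plane_strain(stress_voigt: np.ndarray, lam: float, G: float) -> np.ndarray:
    """Von Mises of the effective stress, with the plane-strain out-of-plane
    component s_zz = lam * tr(eps) recovered from the in-plane stresses."""
    sxx, syy, sxy = stress_voigt[:, 0], stress_voigt[:, 1], stress_voigt[:, 2]
    # tr(eps) = (sxx + syy) / (2 (G + lam));  s_zz = lam tr(eps)
    tr_eps = (sxx + syy) / (2.0 * (G + lam))
    szz = lam * tr_eps
    sm = (sxx + syy + szz) / 3.0
    dxx, dyy, dzz = sxx - sm, syy - sm, szz - sm
    return np.sqrt(1.5 * (dxx**2 + dyy**2 + dzz**2 + 2 * sxy**2))


def compute_stress_summaries(domain, state, band_mm: float = 5.0) -> dict:
    """Stress maxima split into periventricular band vs bulk parenchyma.

    band_mm: distance from the ventricle surface defining "periventricular".
    "Intraparenchymal" means bulk tissue farther than band_mm from *any*
    pial or ventricular surface: the rigidly fixed pial boundary (and its
    re-entrant fissure corners) produces boundary-layer concentrations
    that are artefacts of the fixation, not parenchymal stress.  Reports
    von Mises maxima and in-plane principal-stress extrema (tension
    positive, compression negative).
    """
    vent_nodes = domain.facet_nodes(domain.ventricle_facets())
    if len(vent_nodes) == 0:
        raise ValueError("domain has no ventricle surface")
    cort_nodes = domain.facet_nodes(domain.cortical_facets())
    cent = domain.nodes[domain.cells].mean(axis=1)
    d = cKDTree(domain.nodes[vent_nodes]).query(cent)[0]
    d_cort = cKDTree(domain.nodes[cort_nodes]).query(cent)[0]
    band = d <= band_mm
    if not np.any(band):
        raise ValueError(f"periventricular band of {band_mm} mm contains no cells")

    from .parameters import OedemaParameters  # default moduli for recovery

    G = state.contact.get("G") if state.contact else None
    lam = state.contact.get("lam") if state.contact else None
    if G is None or lam is None:
        p = OedemaParameters()
        G, lam = p.G, p.lam
    vm = _von_mises_plane_strain(state.stress, lam, G)
    sxx, syy, sxy = state.stress[:, 0], state.stress[:, 1], state.stress[:, 2]
    mean = 0.5 * (sxx + syy)
    rad = np.sqrt((0.5 * (sxx - syy)) ** 2 + sxy**2)
    p1, p2 = mean + rad, mean - rad

    def block(mask):
        return {
            "max_von_mises_pa": float(vm[mask].max()) if mask.any() else 0.0,
            "max_tension_pa": float(p1[mask].max()) if mask.any() else 0.0,
            "max_compression_pa": float(p2[mask].min()) if mask.any() else 0.0,
        }

    return {
        "periventricular": block(band),
        "intraparenchymal": block((~band) & (d_cort > band_mm)),
        "near_pial": block((~band) & (d_cort <= band_mm)),
        "band_mm": band_mm,
    }


def compute_volume_change(domain, u_mm: np.ndarray) -> dict:
    """Per-cell relative volume change, percent.

    Exact geometric measure from the deformed cell areas plus the
    small-strain surrogate 100 * tr(eps).  Inverted cells are flagged.
    """
    x = domain.nodes + u_mm
    c = domain.cells
    a_def = 0.5 * cross2(x[c[:, 1]] - x[c[:, 0]], x[c[:, 2]] - x[c[:, 0]])
    a_ref = 0.5 * cross2(
        domain.nodes[c[:, 1]] - domain.nodes[c[:, 0]],
        domain.nodes[c[:, 2]] - domain.nodes[c[:, 0]],
    )
    dv = (a_def - a_ref) / a_ref * 100.0
    from ._fem import gradients

    g, _ = gradients(domain.nodes, domain.cells)
    tr_eps = np.einsum("ci,ci->c", g[:, :, 0], u_mm[c][:, :, 0]) + np.einsum(
        "ci,ci->c", g[:, :, 1], u_mm[c][:, :, 1]
    )
    return {
        "dv_percent": dv,
        "dv_small_strain_percent": 100.0 * tr_eps,
        "inverted_cells": np.flatnonzero(a_def <= 0),
        "total_percent": float((a_def.sum() - a_ref.sum()) / a_ref.sum() * 100.0),
    }


def fit_icp_mls_slope(icp_mmhg, mls_mm, baseline_mmhg: float = 10.0):
    """Zero-intercept least-squares slope of MLS vs (ICP - baseline).

    The intercept is pinned because MLS vanishes without a pressure rise.
    Returns (slope mm/mmHg, R^2 of the constrained fit).
    """
    x = np.asarray(icp_mmhg, dtype=float) - baseline_mmhg
    y = np.asarray(mls_mm, dtype=float)
    keep = x > 1e-9
    if not np.any(keep):
        raise ValueError("all ICP samples are at baseline; slope undefined")
    x, y = x[keep], y[keep]
    slope = float(x @ y / (x @ x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return slope, r2


def fit_confidence_ellipse(points, level: float = 0.75) -> dict:
    """Gaussian confidence ellipse and OLS line for (x, y) scatter.

    The ellipse is the level-set of the fitted bivariate normal enclosing
    ``level`` probability mass: semi-axes sqrt(chi2_2^-1(level) * eigvals)
    along the covariance eigenvectors.  Collinear clouds are flagged
    degenerate and only the line is returned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    x, y = pts[:, 0], pts[:, 1]
    vx = x - x.mean()
    slope = float(vx @ (y - y.mean()) / (vx @ vx)) if vx @ vx > 0 else float("nan")
    intercept = float(y.mean() - slope * x.mean()) if np.isfinite(slope) else float("nan")
    degenerate = evals[0] <= 1e-12 * max(evals[1], 1e-300)
    q = chi2.ppf(level, df=2)
    out = {
        "center": mean,
        "semi_axes": np.sqrt(np.maximum(q * evals, 0.0)),
        "rotation_deg": float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1]))),
        "eigvecs": evecs,
        "level": level,
        "degenerate": bool(degenerate),
        "line_slope": slope,
        "line_intercept": intercept,
    }
    return out
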