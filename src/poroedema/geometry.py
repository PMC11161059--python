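"""Simulation domains: synthetic idealized brains, tagging and queries.

The idealized brain is a 2D (plane-strain) bihemispheric disc with two thin
vertical slit cavities standing in for the lateral ventricles and angular
cortical sectors standing in for the ACA/MCA/PCA perfusion territories.  The
slits are the self-contact candidates: under oedematous swelling their
opposing walls approach and collapse.  It is a surrogate geometry, not an
anatomical model — every governing equation of the simulator is
dimension-agnostic, and the 2D domain exposes the full pipeline at desk
scale.

Coordinate convention: the interhemispheric midplane is x = 0; +x is the
right hemisphere; +y is anterior.  A positive midline shift is displacement
from right (+x) to left (-x), matching the clinical sign convention.
Lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from ._fem import cross2

#: Canonical cortical territory names for the bihemispheric brain.
TERRITORIES = (
    "right_ACA",
    "right_MCA",
    "right_PCA",
    "left_ACA",
    "left_MCA",
    "left_PCA",
)

#: Aliases expanding to unions of elementary territories.
TERRITORY_ALIASES = {
    "right_hemispheric": ("right_ACA", "right_MCA", "right_PCA"),
    "left_hemispheric": ("left_ACA", "left_MCA", "left_PCA"),
}

#: Default angular sectors per hemisphere, degrees from the +y (anterior)
#: axis: anterior ACA-like 60 deg, lateral MCA-like 90 deg, posterior
#: PCA-like 30 deg.  Sized so occluded-core volumes order MCA > ACA > PCA.
DEFAULT_SECTORS = (("ACA", 0.0, 60.0), ("MCA", 60.0, 150.0), ("PCA", 150.0, 180.0))


class MeshingError(ValueError):
    """Raised when a geometry spec cannot be meshed as requested."""


@dataclass
class IdealizedBrainSpec:
    """Parameters of the synthetic bihemispheric brain.

    All lengths in mm.  ``ventricle_offset`` is the distance from the
    midplane to the slit centreline; the slit spans
    ``ventricle_center_y +/- ventricle_half_length`` in y with wall
    separation ``ventricle_thickness``.  The default slit is offset
    posteriorly (negative y), emulating the posterior extension of the
    lateral ventricles (body + occipital horn) relative to the
    interhemispheric midline.

    ``fissure_width`` > 0 cuts an interhemispheric-fissure notch along the
    midline from the anterior pole down to ``fissure_anterior_y`` and from
    the posterior pole up to ``fissure_posterior_y``.  The notch surfaces
    are pial (cortical, hence fixed in the mechanics), which anchors the
    midline at the poles the way the longitudinal fissure does in vivo;
    only the central corridor between the fissures — the latitudes of the
    ventricles — can shift.  Set fissure_width = 0 for a plain disc.
    """

    dimension: int = 2
    radius: float = 80.0
    ventricle_offset: float = 10.0
    ventricle_half_length: float = 30.0
    ventricle_center_y: float = -20.0
    ventricle_thickness: float = 3.0
    fissure_width: float = 3.0
    fissure_anterior_y: float = 25.0
    fissure_posterior_y: float = -40.0
    sectors: tuple = DEFAULT_SECTORS
    h: float = 2.0
    seed: int = 0

    def validate(self):
        if self.dimension != 2:
            raise NotImplementedError(
                "only the 2D plane-strain idealized brain is generated; "
                "3D domains can be imported via load_domain"
            )
        t = self.ventricle_thickness
        if not (0 < t < self.radius / 4):
            raise MeshingError("slit thickness must lie in (0, radius/4)")
        if t < self.h:
            raise MeshingError(
                f"slit under-resolved: thickness {t} mm < mesh size h={self.h} mm; "
                "the slit gap must be resolved by the wall node spacing "
                "(and its length by at least 3 elements)"
            )
        if 2 * self.ventricle_half_length < 3 * self.h:
            raise MeshingError("slit under-resolved along its length (needs >= 3 elements)")
        if self.ventricle_offset - t / 2 <= 0:
            raise MeshingError("slit crosses the midplane")
        if self.ventricle_offset + t / 2 >= self.radius:
            raise MeshingError("slit reaches the cortical surface")
        corner = np.hypot(
            self.ventricle_offset + t / 2,
            max(abs(self.ventricle_center_y - self.ventricle_half_length),
                abs(self.ventricle_center_y + self.ventricle_half_length)),
        )
        if corner >= self.radius - 3 * self.h:
            raise MeshingError("slit end too close to the cortical surface")
        if self.fissure_width > 0:
            if self.fissure_width / 2 >= self.ventricle_offset - t / 2:
                raise MeshingError("fissure overlaps the ventricle slits")
            if not (self.fissure_posterior_y < self.ventricle_center_y < self.fissure_anterior_y):
                raise MeshingError("fissures must leave a free midline corridor at ventricle level")
        angles = sorted((lo, hi) for _, lo, hi in self.sectors)
        cover = 0.0
        for lo, hi in angles:
            if lo < cover - 1e-9:
                raise MeshingError("territory sectors overlap")
            cover = hi
        if abs(angles[0][0]) > 1e-9 or abs(cover - 180.0) > 1e-9:
            raise MeshingError("territory sectors must cover the hemispheric arc [0, 180] deg")


@dataclass
class Domain:
    """A conforming simplicial mesh with boundary and cell tags.

    nodes: (N, dim) coordinates in mm.
    cells: (M, dim+1) simplices, CCW in 2D.
    facets: (F, dim) exterior facets.
    facet_tags: (F,) string tag per exterior facet.  Cortical facets carry
        ``cortical:<territory>``, ventricle facets ``ventricle:<side>:<wall>``.
    cell_tags: named boolean masks over cells (e.g. the oedema core).
    contact_pairs: (slave_wall_tag, master_wall_tag) tuples of opposing
        ventricle walls considered for self-contact.
    """

    nodes: np.ndarray
    cells: np.ndarray
    facets: np.ndarray
    facet_tags: np.ndarray
    cell_tags: dict = field(default_factory=dict)
    contact_pairs: list = field(default_factory=list)
    length_unit: str = "mm"
    metadata: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    # -- tag queries ---------------------------------------------------
    def facets_where(self, prefix: str) -> np.ndarray:
        """Indices of exterior facets whose tag starts with ``prefix``."""
        return np.array(
            [i for i, t in enumerate(self.facet_tags) if t.startswith(prefix)], dtype=np.int64
        )

    def cortical_facets(self) -> np.ndarray:
        return self.facets_where("cortical")

    def ventricle_facets(self) -> np.ndarray:
        return self.facets_where("ventricle")

    def facet_nodes(self, facet_ids) -> np.ndarray:
        return np.unique(self.facets[facet_ids].ravel())

    def boundary_measure(self, facet_ids) -> float:
        f = self.facets[facet_ids]
        return float(np.linalg.norm(self.nodes[f[:, 1]] - self.nodes[f[:, 0]], axis=1).sum())

    def territories(self) -> list:
        names = set()
        for t in self.facet_tags:
            if t.startswith("cortical:"):
                names.add(t.split(":", 1)[1])
        return sorted(names)

    def cell_volumes(self) -> np.ndarray:
        """Cell measures in mm^dim (areas for triangles)."""
        if self.cells.shape[1] == 3:
            p0, p1, p2 = (self.nodes[self.cells[:, i]] for i in range(3))
            return 0.5 * np.abs(cross2(p1 - p0, p2 - p0))
        p0, p1, p2, p3 = (self.nodes[self.cells[:, i]] for i in range(4))
        return np.abs(np.einsum("ij,ij->i", np.cross(p1 - p0, p2 - p0), p3 - p0)) / 6.0

    def check_invariants(self):
        """Exhaustive tag-partition and conformity checks; raises on failure."""
        ref = boundary_facets(self.cells)
        ours = {tuple(sorted(f)) for f in self.facets}
        theirs = {tuple(sorted(f)) for f in ref}
        if ours != theirs:
            raise ValueError("facet list does not match the exterior boundary of the cells")
        if len(self.facet_tags) != len(self.facets):
            raise ValueError("every exterior facet must carry exactly one tag")
        if self.cells.shape[1] == 3:
            areas = self.cell_volumes()
            if np.any(areas <= 0):
                raise ValueError("degenerate cells present")
        for name, mask in self.cell_tags.items():
            if len(mask) != len(self.cells):
                raise ValueError(f"cell tag {name!r} has wrong length")


# ---------------------------------------------------------------------------
# mesh construction helpers
# ---------------------------------------------------------------------------

def boundary_facets(cells: np.ndarray) -> np.ndarray:
    """Exterior facets of a simplicial mesh (edges of triangles, faces of tets)."""
    nv = cells.shape[1]
    if nv == 3:
        combos = [(0, 1), (1, 2), (2, 0)]
    else:
        combos = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    faces = np.concatenate([cells[:, c] for c in combos], axis=0)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def _half_brain_points(spec: IdealizedBrainSpec):
    """Point cloud for the right half (x >= 0) of the brain disc."""
    R, h = spec.radius, spec.h
    xw0 = spec.ventricle_offset - spec.ventricle_thickness / 2.0
    xw1 = spec.ventricle_offset + spec.ventricle_thickness / 2.0
    y0 = spec.ventricle_center_y - spec.ventricle_half_length
    y1 = spec.ventricle_center_y + spec.ventricle_half_length

    fw = spec.fissure_width / 2.0
    ya, yp = spec.fissure_anterior_y, spec.fissure_posterior_y

    xs = np.arange(0.0, R + h, h)
    xs = xs[np.abs(xs - xw0) > 0.45 * h]
    xs = xs[np.abs(xs - xw1) > 0.45 * h]
    extra_x = [xw0, xw1]
    if fw > 0:
        xs = xs[(np.abs(xs - fw) > 0.45 * h) | (xs == 0.0)]
        extra_x.append(fw)
    xs = np.unique(np.concatenate([xs, extra_x]))

    ys = np.arange(0.0, R + h, h)
    ys = np.unique(np.concatenate([-ys[::-1], ys]))
    extra_y = [y0, y1]
    for yf in ([ya, yp] if fw > 0 else []):
        extra_y.append(yf)
    for yv_ in extra_y:
        ys = ys[np.abs(ys - yv_) > 0.45 * h]
    ys = np.unique(np.concatenate([ys, extra_y]))

    X, Y = np.meshgrid(xs, ys)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    r = np.hypot(pts[:, 0], pts[:, 1])
    pts = pts[r <= R - 0.55 * h]
    # drop interior-of-slit points (walls themselves are kept)
    inside = (
        (pts[:, 0] > xw0 + 1e-9)
        & (pts[:, 0] < xw1 - 1e-9)
        & (pts[:, 1] > y0 + 1e-9)
        & (pts[:, 1] < y1 - 1e-9)
    )
    if fw > 0:
        inside |= (pts[:, 0] < fw - 1e-9) & (pts[:, 1] > ya + 1e-9)
        inside |= (pts[:, 0] < fw - 1e-9) & (pts[:, 1] < yp - 1e-9)
    pts = pts[~inside]

    # slit wall and end-cap points, taken from the shared grid coordinates
    # so features never create near-duplicate nodes
    tol = 1e-9
    ywall = ys[(ys >= y0 - tol) & (ys <= y1 + tol)]
    wall = np.concatenate(
        [
            np.stack([np.full_like(ywall, xw0), ywall], axis=1),
            np.stack([np.full_like(ywall, xw1), ywall], axis=1),
        ]
    )
    xcap = xs[(xs > xw0 + tol) & (xs < xw1 - tol)]
    caps = np.concatenate(
        [
            np.stack([xcap, np.full_like(xcap, y0)], axis=1),
            np.stack([xcap, np.full_like(xcap, y1)], axis=1),
        ]
    ) if len(xcap) else np.empty((0, 2))

    # cortical arc of the right hemisphere: theta in [0, 180] deg from +y
    narc = max(int(np.ceil(np.pi * R / h)), 8)
    th = np.linspace(0.0, np.pi, narc + 1)
    arc = np.stack([R * np.sin(th), R * np.cos(th)], axis=1)
    arc[np.abs(arc[:, 0]) < 1e-12, 0] = 0.0

    fiss = np.empty((0, 2))
    if fw > 0:
        # remove arc points swallowed by the fissure mouths, add the
        # fissure walls, end caps and wall/arc corner points
        mouth = (arc[:, 0] < fw - 1e-9) & ((arc[:, 1] > ya) | (arc[:, 1] < yp))
        arc = arc[~mouth]
        y_top = np.sqrt(R**2 - fw**2)
        parts = []
        for ylo, yhi in ((ya, y_top), (-y_top, yp)):
            yy = ys[(ys >= ylo + 0.45 * h) & (ys <= yhi - 0.45 * h)]
            yy = np.unique(np.concatenate([yy, [ylo, yhi]]))
            parts.append(np.stack([np.full_like(yy, fw), yy], axis=1))
        xc = xs[(xs > 1e-9) & (xs < fw - 1e-9)]
        xc = np.concatenate([[0.0], xc])
        parts.append(np.stack([xc, np.full_like(xc, ya)], axis=1))
        parts.append(np.stack([xc, np.full_like(xc, yp)], axis=1))
        fiss = np.concatenate(parts)

    pts = np.concatenate([pts, wall, caps, arc, fiss])
    # deduplicate
    _, keep = np.unique(np.round(pts / (1e-6 * h)).astype(np.int64), axis=0, return_index=True)
    return pts[np.sort(keep)]


def _smooth_interior(pts, cells, rounds=2, lam=0.6):
    """Laplacian smoothing of interior nodes (boundary/feature nodes fixed).

    Improves the quality of the Delaunay triangles between feature lines;
    strongly anisotropic Darcy operators are sensitive to slivers.
    """
    from scipy.sparse import coo_matrix

    n = len(pts)
    bnd = np.unique(boundary_facets(cells).ravel())
    fixed = np.zeros(n, dtype=bool)
    fixed[bnd] = True
    e = np.concatenate([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    A = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    A = ((A + A.T) > 0).astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    for _ in range(rounds):
        avg = A @ pts / deg[:, None]
        pts = np.where(fixed[:, None], pts, pts + lam * (avg - pts))
    return pts


def _mesh_half(spec: IdealizedBrainSpec):
    pts = _half_brain_points(spec)
    tri = Delaunay(pts)
    # pre-filter to find the true boundary, smooth, then re-triangulate
    cells0 = _filter_cells(spec, pts, tri.simplices)
    used0 = np.unique(cells0)
    sub = -np.ones(len(pts), dtype=np.int64)
    sub[used0] = np.arange(len(used0))
    pts = _smooth_interior(pts[used0], sub[cells0])
    cells = _filter_cells(spec, pts, tri.simplices)
    used = np.unique(cells)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return pts[used], remap[cells]


def _filter_cells(spec: IdealizedBrainSpec, pts, cells):
    """Drop cavity/degenerate triangles and enforce CCW orientation."""
    cells = cells.copy()
    cent = pts[cells].mean(axis=1)
    xw0 = spec.ventricle_offset - spec.ventricle_thickness / 2.0
    xw1 = spec.ventricle_offset + spec.ventricle_thickness / 2.0
    in_slit = (
        (cent[:, 0] > xw0)
        & (cent[:, 0] < xw1)
        & (cent[:, 1] > spec.ventricle_center_y - spec.ventricle_half_length)
        & (cent[:, 1] < spec.ventricle_center_y + spec.ventricle_half_length)
    )
    if spec.fissure_width > 0:
        fw = spec.fissure_width / 2.0
        in_slit |= (cent[:, 0] < fw) & (cent[:, 1] > spec.fissure_anterior_y)
        in_slit |= (cent[:, 0] < fw) & (cent[:, 1] < spec.fissure_posterior_y)
    keep = ~in_slit
    p0, p1, p2 = pts[cells[:, 0]], pts[cells[:, 1]], pts[cells[:, 2]]
    areas = 0.5 * cross2(p1 - p0, p2 - p0)
    flip = areas < 0
    cells[flip] = cells[flip][:, [0, 2, 1]]
    keep &= np.abs(areas) > 1e-6 * spec.h**2
    return cells[keep]


def _mirror(nodes, cells):
    """Mirror a half mesh (x >= 0) through x = 0, merging midplane nodes."""
    n = len(nodes)
    on_mid = np.abs(nodes[:, 0]) < 1e-9
    idx_map = np.empty(n, dtype=np.int64)
    new_nodes = [nodes]
    nxt = n
    for i in range(n):
        if on_mid[i]:
            idx_map[i] = i
        else:
            idx_map[i] = nxt
            nxt += 1
    mirrored = nodes[~on_mid] * np.array([-1.0, 1.0])
    new_nodes.append(mirrored)
    allnodes = np.concatenate(new_nodes)
    mcells = idx_map[cells][:, [0, 2, 1]]  # flip orientation
    return allnodes, np.concatenate([cells, mcells])


def _classify_facets(spec: IdealizedBrainSpec, nodes, facets):
    R = spec.radius
    xw0 = spec.ventricle_offset - spec.ventricle_thickness / 2.0
    xw1 = spec.ventricle_offset + spec.ventricle_thickness / 2.0
    y0 = spec.ventricle_center_y - spec.ventricle_half_length
    y1 = spec.ventricle_center_y + spec.ventricle_half_length
    tol = 1e-6 * max(R, 1.0)

    tags = np.empty(len(facets), dtype=object)
    r = np.hypot(nodes[:, 0], nodes[:, 1])
    sector_of = _sector_lookup(spec)
    for i, (a, b) in enumerate(facets):
        if r[a] > R - 1e-6 and r[b] > R - 1e-6:
            cx, cy = nodes[[a, b]].mean(axis=0)
            tags[i] = "cortical:" + sector_of(cx, cy)
            continue
        cx, cy = nodes[[a, b]].mean(axis=0)
        ax = abs(cx)
        side = "right" if cx > 0 else "left"
        fw = spec.fissure_width / 2.0
        if abs(ax - xw0) < tol and y0 - tol <= cy <= y1 + tol:
            tags[i] = f"ventricle:{side}:medial"
        elif abs(ax - xw1) < tol and y0 - tol <= cy <= y1 + tol:
            tags[i] = f"ventricle:{side}:lateral"
        elif xw0 - tol <= ax <= xw1 + tol and (abs(cy - y0) < tol or abs(cy - y1) < tol):
            tags[i] = f"ventricle:{side}:end"
        elif spec.fissure_width > 0 and ax <= fw + tol and (
            cy >= spec.fissure_anterior_y - tol or cy <= spec.fissure_posterior_y + tol
        ):
            # medial (fissure) pial surface: ACA territory anteriorly,
            # PCA territory posteriorly, as in the vascular atlas
            terr = "ACA" if cy > 0 else "PCA"
            tags[i] = f"cortical:{side}_{terr}"
        else:
            tags[i] = "other"
    return tags


def _sector_lookup(spec: IdealizedBrainSpec):
    sectors = spec.sectors

    def lookup(cx, cy):
        side = "right" if cx > 0 else "left"
        ang = np.degrees(np.arctan2(abs(cx), cy))  # 0 at +y, 180 at -y
        for name, lo, hi in sectors:
            if lo - 1e-9 <= ang <= hi + 1e-9:
                return f"{side}_{name}"
        return f"{side}_{sectors[-1][0]}"

    return lookup


def build_idealized_brain(spec: IdealizedBrainSpec | None = None, **kw) -> Domain:
    """Generate the tagged 2D bihemispheric brain domain.

    The right half (x >= 0) is meshed and mirrored through the midplane, so
    the node set is exactly symmetric under x -> -x and the midplane column
    of nodes lies exactly on x = 0.
    """
    if spec is None:
        spec = IdealizedBrainSpec(**kw)
    spec.validate()
    half_nodes, half_cells = _mesh_half(spec)
    nodes, cells = _mirror(half_nodes, half_cells)
    facets = boundary_facets(cells)
    tags = _classify_facets(spec, nodes, facets)
    dom = Domain(
        nodes=nodes,
        cells=cells,
        facets=facets,
        facet_tags=tags,
        contact_pairs=[
            ("ventricle:right:lateral", "ventricle:right:medial"),
            ("ventricle:left:lateral", "ventricle:left:medial"),
        ],
        metadata={"spec": spec.__dict__ | {"sectors": [list(s) for s in spec.sectors]},
                  "kind": "idealized_brain"},
    )
    n_vent = len(dom.ventricle_facets())
    if n_vent < 6:
        raise MeshingError("ventricle slits were not resolved by the mesh")
    dom.check_invariants()
    return dom


def build_annulus(r_inner: float, r_outer: float, h: float) -> Domain:
    """Structured annulus; outer rim tagged cortical, inner rim ventricle."""
    if r_inner >= r_outer:
        raise MeshingError("r_inner must be < r_outer")
    nr = max(int(np.ceil((r_outer - r_inner) / h)), 2)
    nt = max(int(np.ceil(2 * np.pi * r_outer / h)), 12)
    rs = np.linspace(r_inner, r_outer, nr + 1)
    th = np.linspace(0, 2 * np.pi, nt, endpoint=False)
    nodes = np.stack(
        [np.outer(rs, np.cos(th)).ravel(), np.outer(rs, np.sin(th)).ravel()], axis=1
    )
    cells = []
    for i in range(nr):
        for j in range(nt):
            a = i * nt + j
            b = i * nt + (j + 1) % nt
            c = (i + 1) * nt + j
            d = (i + 1) * nt + (j + 1) % nt
            cells.append([a, b, d])
            cells.append([a, d, c])
    cells = np.asarray(cells, dtype=np.int64)
    p0, p1, p2 = (nodes[cells[:, i]] for i in range(3))
    flip = 0.5 * cross2(p1 - p0, p2 - p0) < 0
    cells[flip] = cells[flip][:, [0, 2, 1]]
    facets = boundary_facets(cells)
    r = np.hypot(nodes[:, 0], nodes[:, 1])
    tags = np.empty(len(facets), dtype=object)
    rm = r[facets].mean(axis=1)
    tags[:] = "other"
    tags[rm > (r_inner + r_outer) / 2] = "cortical:outer"
    tags[rm <= (r_inner + r_outer) / 2] = "ventricle:inner"
    return Domain(nodes, cells, facets, tags, metadata={"kind": "annulus"})


def build_slab(length: float, width: float, h: float,
               tag_lo: str = "end:lo", tag_hi: str = "end:hi") -> Domain:
    """Structured rectangle [0, L] x [0, W]; x=0 and x=L facets tagged."""
    nx = max(int(np.ceil(length / h)), 2)
    ny = max(int(np.ceil(width / h)), 1)
    xs = np.linspace(0, length, nx + 1)
    ys = np.linspace(0, width, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)
    cells = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = (i + 1) * (ny + 1) + j
            cells.append([a, b, b + 1])
            cells.append([a, b + 1, a + 1])
    cells = np.asarray(cells, dtype=np.int64)
    facets = boundary_facets(cells)
    cent = nodes[facets].mean(axis=1)
    tags = np.empty(len(facets), dtype=object)
    tags[:] = "wall:side"
    tags[np.abs(cent[:, 0]) < 1e-9] = tag_lo
    tags[np.abs(cent[:, 0] - length) < 1e-9] = tag_hi
    return Domain(nodes, cells, facets, tags, metadata={"kind": "slab"})


def build_ball_3d(radius: float, h: float) -> Domain:
    """Coarse unstructured tetrahedral ball (used to exercise 3D mesh I/O)."""
    n = max(int(np.ceil(2 * radius / h)), 3)
    g = np.linspace(-radius, radius, n + 1)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    pts = pts[np.linalg.norm(pts, axis=1) <= radius - 0.4 * h]
    # Fibonacci sphere surface points
    m = max(int(4 * np.pi * radius**2 / h**2), 32)
    k = np.arange(m) + 0.5
    phi = np.arccos(1 - 2 * k / m)
    theta = np.pi * (1 + 5**0.5) * k
    surf = radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    pts = np.concatenate([pts, surf])
    tet = Delaunay(pts)
    cells = tet.simplices
    cent = pts[cells].mean(axis=1)
    cells = cells[np.linalg.norm(cent, axis=1) < radius]
    used = np.unique(cells)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes, cells = pts[used], remap[cells]
    facets = boundary_facets(cells)
    tags = np.empty(len(facets), dtype=object)
    tags[:] = "cortical:surface"
    return Domain(nodes, cells, facets, tags, metadata={"kind": "ball3d"})


# ---------------------------------------------------------------------------
# queries used by the solvers
# ---------------------------------------------------------------------------

def midplane_nodes(domain: Domain, tol: float) -> np.ndarray:
    """Node indices lying on the midplane x = 0 within ``tol`` (mm)."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    ids = np.flatnonzero(np.abs(domain.nodes[:, 0]) <= tol)
    if len(ids) == 0:
        raise ValueError(
            "no nodes found on the midplane x=0; increase tol or align the mesh to x=0"
        )
    return ids


def resolve_territories(names) -> list:
    out = []
    for n in names:
        if n in TERRITORY_ALIASES:
            out.extend(TERRITORY_ALIASES[n])
        else:
            out.append(n)
    return out


def occlude_territories(domain: Domain, names) -> np.ndarray:
    """Boolean facet mask covering the named territories' cortical facets."""
    names = resolve_territories(names)
    known = set(domain.territories())
    for n in names:
        if n not in known:
            raise ValueError(f"unknown territory {n!r}; known: {sorted(known)}")
    mask = np.zeros(len(domain.facets), dtype=bool)
    for i, t in enumerate(domain.facet_tags):
        if t.startswith("cortical:") and t.split(":", 1)[1] in names:
            mask[i] = True
    return mask
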