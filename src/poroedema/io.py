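"""Domain and field I/O: Gmsh MSH 4.1 ASCII and XDMF + HDF5.

Boundary tags are stored as physical groups (MSH) or labelled HDF5
datasets (XDMF).  Cell masks and contact-pair metadata, which have no
natural MSH representation, travel in a JSON sidecar ``<path>.tags.json``
next to MSH files; the XDMF/HDF5 container holds everything in one pair
of files.  Round trips preserve coordinates, connectivity and tags
exactly (coordinates are written in full double precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import Domain, boundary_facets

_REQUIRED_PREFIXES = ("cortical", "ventricle")


def save_domain(domain: Domain, path, fmt: str | None = None):
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "msh":
        _write_msh41(domain, path)
    elif fmt == "xdmf":
        _write_xdmf(domain, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r} (use 'msh' or 'xdmf')")


def load_domain(path, fmt: str | None = None, require_tags=_REQUIRED_PREFIXES) -> Domain:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "msh":
        dom = _read_msh41(path)
    elif fmt == "xdmf":
        dom = _read_xdmf(path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r} (use 'msh' or 'xdmf')")
    for prefix in require_tags:
        if not any(t.startswith(prefix) for t in dom.facet_tags):
            raise ValueError(
                f"mesh at {path} is missing boundary tag group {prefix!r}; "
                "tag the surface or pass require_tags=() for generic meshes"
            )
    dom.check_invariants()
    return dom


def _infer_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf == ".msh":
        return "msh"
    if suf == ".xdmf":
        return "xdmf"
    raise ValueError(f"cannot infer mesh format from suffix {suf!r}")


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 ASCII
# ---------------------------------------------------------------------------

def _write_msh41(domain: Domain, path: Path):
    dim = domain.dim
    facet_groups = {}
    for i, t in enumerate(domain.facet_tags):
        facet_groups.setdefault(t, []).append(i)
    names = sorted(facet_groups)
    # physical/entity tag per facet group; one bulk entity for the cells
    bulk_tag = len(names) + 1

    lines = []
    lines.append("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
    lines.append("$PhysicalNames\n")
    lines.append(f"{len(names) + 1}\n")
    for k, name in enumerate(names, start=1):
        lines.append(f'{dim - 1} {k} "{name}"\n')
    lines.append(f'{dim} {bulk_tag} "bulk"\n')
    lines.append("$EndPhysicalNames\n")

    lo = domain.nodes.min(axis=0)
    hi = domain.nodes.max(axis=0)
    lo3 = np.zeros(3)
    hi3 = np.zeros(3)
    lo3[:dim], hi3[:dim] = lo, hi
    box = " ".join(f"{v:.17g}" for v in (*lo3, *hi3))
    lines.append("$Entities\n")
    if dim == 2:
        lines.append(f"0 {len(names)} 1 0\n")
        for k in range(1, len(names) + 1):
            lines.append(f"{k} {box} 1 {k} 0\n")
        lines.append(f"{bulk_tag} {box} 1 {bulk_tag} 0\n")
    else:
        lines.append(f"0 0 {len(names)} 1\n")
        for k in range(1, len(names) + 1):
            lines.append(f"{k} {box} 1 {k} 0\n")
        lines.append(f"{bulk_tag} {box} 1 {bulk_tag} 0\n")
    lines.append("$EndEntities\n")

    n = len(domain.nodes)
    lines.append("$Nodes\n")
    lines.append(f"1 {n} 1 {n}\n")
    lines.append(f"{dim} {bulk_tag} 0 {n}\n")
    for i in range(1, n + 1):
        lines.append(f"{i}\n")
    for p in domain.nodes:
        p3 = np.zeros(3)
        p3[:dim] = p
        lines.append(" ".join(f"{v:.17g}" for v in p3) + "\n")
    lines.append("$EndNodes\n")

    facet_type = 1 if dim == 2 else 2   # line / triangle
    cell_type = 2 if dim == 2 else 4    # triangle / tet
    n_blocks = len(names) + 1
    n_elem = len(domain.facets) + len(domain.cells)
    lines.append("$Elements\n")
    lines.append(f"{n_blocks} {n_elem} 1 {n_elem}\n")
    tag = 1
    for k, name in enumerate(names, start=1):
        ids = facet_groups[name]
        lines.append(f"{dim - 1} {k} {facet_type} {len(ids)}\n")
        for fi in ids:
            conn = " ".join(str(v + 1) for v in domain.facets[fi])
            lines.append(f"{tag} {conn}\n")
            tag += 1
    lines.append(f"{dim} {bulk_tag} {cell_type} {len(domain.cells)}\n")
    for c in domain.cells:
        conn = " ".join(str(v + 1) for v in c)
        lines.append(f"{tag} {conn}\n")
        tag += 1
    lines.append("$EndElements\n")

    path.write_text("".join(lines))
    sidecar = {
        "cell_tags": {k: np.flatnonzero(v).tolist() for k, v in domain.cell_tags.items()},
        "contact_pairs": [list(p) for p in domain.contact_pairs],
        "length_unit": domain.length_unit,
        "metadata": _jsonable(domain.metadata),
    }
    Path(str(path) + ".tags.json").write_text(json.dumps(sidecar))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _read_msh41(path: Path) -> Domain:
    text = path.read_text().splitlines()
    sections = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            while j < len(text) and text[j].strip() != f"$End{name}":
                j += 1
            sections[name] = text[i + 1 : j]
            i = j + 1
        else:
            i += 1
    if "MeshFormat" not in sections or not sections["MeshFormat"][0].startswith("4.1"):
        raise ValueError(f"{path}: not an MSH 4.1 ASCII file")

    phys = {}
    if "PhysicalNames" in sections:
        for line in sections["PhysicalNames"][1:]:
            parts = line.split(None, 2)
            if len(parts) == 3:
                phys[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')

    body = sections["Nodes"]
    n_blocks, n_nodes = int(body[0].split()[0]), int(body[0].split()[1])
    coords = np.empty((n_nodes, 3))
    tags_order = np.empty(n_nodes, dtype=np.int64)
    row = 1
    seen = 0
    for _ in range(n_blocks):
        bn = int(body[row].split()[3])
        row += 1
        ids = [int(body[row + k]) for k in range(bn)]
        row += bn
        for k in range(bn):
            coords[seen + k] = [float(v) for v in body[row + k].split()]
            tags_order[seen + k] = ids[k]
        row += bn
        seen += bn
    order = np.argsort(tags_order)
    coords = coords[order]
    remap = {t: i for i, t in enumerate(np.sort(tags_order))}

    body = sections["Elements"]
    n_blocks = int(body[0].split()[0])
    row = 1
    facets, facet_tags, cells = [], [], []
    max_dim = 0
    for _ in range(n_blocks):
        edim, etag, etype, ne = (int(v) for v in body[row].split())
        row += 1
        max_dim = max(max_dim, edim)
        name = phys.get((edim, etag), "other")
        for k in range(ne):
            parts = [int(v) for v in body[row + k].split()]
            conn = [remap[v] for v in parts[1:]]
            if etype == 1 and edim == 1:          # boundary line of a 2D mesh
                facets.append(conn)
                facet_tags.append(name)
            elif etype == 2 and edim == 2:
                if name == "bulk":                # triangle cell of a 2D mesh
                    cells.append(conn)
                else:                             # boundary triangle of a 3D mesh
                    facets.append(conn)
                    facet_tags.append(name)
            elif etype == 4 and edim == 3:        # tetrahedron
                cells.append(conn)
            else:
                raise ValueError(f"{path}: unsupported element type {etype} (dim {edim})")
        row += ne
    dim = 3 if max_dim == 3 else 2
    nodes = coords[:, :dim]
    cells = np.asarray(cells, dtype=np.int64)
    facets = np.asarray(facets, dtype=np.int64)
    facet_tags = np.asarray(facet_tags, dtype=object)

    dom = Domain(nodes=nodes, cells=cells, facets=facets, facet_tags=facet_tags)
    side = Path(str(path) + ".tags.json")
    if side.exists():
        meta = json.loads(side.read_text())
        nc = len(cells)
        dom.cell_tags = {
            k: np.isin(np.arange(nc), np.asarray(v, dtype=np.int64))
            for k, v in meta.get("cell_tags", {}).items()
        }
        dom.contact_pairs = [tuple(p) for p in meta.get("contact_pairs", [])]
        dom.length_unit = meta.get("length_unit", "mm")
        dom.metadata = meta.get("metadata", {})
    return dom


# ---------------------------------------------------------------------------
# XDMF + HDF5
# ---------------------------------------------------------------------------

def _write_xdmf(domain: Domain, path: Path):
    import h5py

    h5path = path.with_suffix(".h5")
    with h5py.File(h5path, "w") as f:
        f.create_dataset("nodes", data=domain.nodes)
        f.create_dataset("cells", data=domain.cells)
        f.create_dataset("facets", data=domain.facets)
        st = h5py.string_dtype()
        f.create_dataset("facet_tags", data=np.asarray(domain.facet_tags, dtype=st))
        g = f.create_group("cell_tags")
        for k, v in domain.cell_tags.items():
            g.create_dataset(k, data=np.asarray(v, dtype=bool))
        f.attrs["contact_pairs"] = json.dumps([list(p) for p in domain.contact_pairs])
        f.attrs["length_unit"] = domain.length_unit
        f.attrs["metadata"] = json.dumps(_jsonable(domain.metadata))

    topo = "Triangle" if domain.cells.shape[1] == 3 else "Tetrahedron"
    geom = "XY" if domain.dim == 2 else "XYZ"
    xml = f"""<?xml version="1.0"?>
<Xdmf Version="3.0">
  <Domain>
    <Grid Name="mesh" GridType="Uniform">
      <Topology TopologyType="{topo}" NumberOfElements="{len(domain.cells)}">
        <DataItem Dimensions="{len(domain.cells)} {domain.cells.shape[1]}" Format="HDF">{h5path.name}:/cells</DataItem>
      </Topology>
      <Geometry GeometryType="{geom}">
        <DataItem Dimensions="{len(domain.nodes)} {domain.dim}" Format="HDF">{h5path.name}:/nodes</DataItem>
      </Geometry>
    </Grid>
  </Domain>
</Xdmf>
"""
    path.write_text(xml)


def _read_xdmf(path: Path) -> Domain:
    import h5py

    h5path = path.with_suffix(".h5")
    if not h5path.exists():
        raise FileNotFoundError(f"{path}: companion HDF5 file {h5path} not found")
    with h5py.File(h5path, "r") as f:
        nodes = f["nodes"][()]
        cells = f["cells"][()].astype(np.int64)
        facets = f["facets"][()].astype(np.int64)
        facet_tags = np.asarray([t.decode() if isinstance(t, bytes) else t
                                 for t in f["facet_tags"][()]], dtype=object)
        cell_tags = {k: f["cell_tags"][k][()].astype(bool) for k in f["cell_tags"]}
        pairs = [tuple(p) for p in json.loads(f.attrs.get("contact_pairs", "[]"))]
        unit = f.attrs.get("length_unit", "mm")
        meta = json.loads(f.attrs.get("metadata", "{}"))
    return Domain(nodes=nodes, cells=cells, facets=facets, facet_tags=facet_tags,
                  cell_tags=cell_tags, contact_pairs=pairs, length_unit=unit,
                  metadata=meta)


def write_field_xdmf(domain: Domain, fields: dict, path):
    """Export nodal or cell scalar/vector fields for visualisation."""
    import h5py

    path = Path(path)
    h5path = path.with_suffix(".h5")
    with h5py.File(h5path, "w") as f:
        f.create_dataset("nodes", data=domain.nodes)
        f.create_dataset("cells", data=domain.cells)
        for k, v in fields.items():
            f.create_dataset(f"fields/{k}", data=np.asarray(v))
    topo = "Triangle" if domain.cells.shape[1] == 3 else "Tetrahedron"
    geom = "XY" if domain.dim == 2 else "XYZ"
    attrs = []
    for k, v in fields.items():
        v = np.asarray(v)
        center = "Node" if v.shape[0] == len(domain.nodes) else "Cell"
        atype = "Vector" if v.ndim == 2 else "Scalar"
        dims = " ".join(str(s) for s in v.shape)
        attrs.append(
            f'      <Attribute Name="{k}" AttributeType="{atype}" Center="{center}">\n'
            f'        <DataItem Dimensions="{dims}" Format="HDF">{h5path.name}:/fields/{k}</DataItem>\n'
            f"      </Attribute>"
        )
    xml = f"""<?xml version="1.0"?>
<Xdmf Version="3.0">
  <Domain>
    <Grid Name="mesh" GridType="Uniform">
      <Topology TopologyType="{topo}" NumberOfElements="{len(domain.cells)}">
        <DataItem Dimensions="{len(domain.cells)} {domain.cells.shape[1]}" Format="HDF">{h5path.name}:/cells</DataItem>
      </Topology>
      <Geometry GeometryType="{geom}">
        <DataItem Dimensions="{len(domain.nodes)} {domain.dim}" Format="HDF">{h5path.name}:/nodes</DataItem>
      </Geometry>
{chr(10).join(attrs)}
    </Grid>
  </Domain>
</Xdmf>
"""
    path.write_text(xml)
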