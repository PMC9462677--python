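"""File formats: legacy-ASCII VTK, raw+JSON grids, CSV clouds/markers,
JSON transforms and an Abaqus input-deck subset.

The VTK writers/readers cover exactly the two legacy datasets the
pipeline exchanges — STRUCTURED_POINTS for density grids and
UNSTRUCTURED_GRID for tet meshes/solutions — in ASCII, so every artifact
stays inspectable text.  Coordinates round-trip to 1e-12 (printed with
17 significant digits); connectivity and labels round-trip exactly.
All files carry the model-frame tag in their comment/header line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import MarkerCluster, RigidTransform
from .materials import DensityGrid
from .mesh import TetMesh
from .registration import SurfaceField

__all__ = [
    "write_grid_vtk", "read_grid_vtk", "write_grid_raw", "read_grid_raw",
    "write_mesh_vtk", "read_mesh_vtk", "write_solution_vtk",
    "write_cloud_csv", "read_cloud_csv", "write_cloud_ply", "read_cloud_ply",
    "write_markers_csv", "read_markers_csv",
    "write_transform_json", "read_transform_json",
    "write_abaqus_inp", "write_report",
]

_G = "%.17g"
FRAME_TAG = "frame=model"


class ParseError(ValueError):
    pass


def _fmt_row(vals) -> str:
    return " ".join(_G % v for v in vals)


# ---------------------------------------------------------------- density grid

def write_grid_vtk(grid: DensityGrid, path) -> None:
    nx, ny, nz = grid.dims
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"spinefe grid kind={grid.value_kind} {FRAME_TAG}\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {_fmt_row(grid.origin)}\n")
        f.write(f"SPACING {_fmt_row(grid.spacing)}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("SCALARS values double 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, grid.values.ravel(order="F")[:, None], fmt=_G)


def read_grid_vtk(path) -> DensityGrid:
    lines = Path(path).read_text().splitlines()
    kind = "HU"
    if len(lines) > 1 and "kind=" in lines[1]:
        kind = lines[1].split("kind=")[1].split()[0]
    dims = origin = spacing = None
    data_start = None
    for i, ln in enumerate(lines):
        t = ln.split()
        if not t:
            continue
        if t[0] == "DIMENSIONS":
            dims = tuple(int(v) for v in t[1:4])
        elif t[0] == "ORIGIN":
            origin = [float(v) for v in t[1:4]]
        elif t[0] == "SPACING":
            spacing = [float(v) for v in t[1:4]]
        elif t[0] == "LOOKUP_TABLE":
            data_start = i + 1
            break
    if dims is None or origin is None or spacing is None or data_start is None:
        raise ParseError(f"{path}: not a structured-points VTK file")
    n = dims[0] * dims[1] * dims[2]
    vals = np.array(" ".join(lines[data_start:]).split(), dtype=float)
    if vals.size != n:
        raise ParseError(f"{path}: expected {n} scalars, found {vals.size}")
    values = vals.reshape(dims, order="F")
    return DensityGrid(origin=origin, spacing=spacing, values=values, value_kind=kind)


def write_grid_raw(grid: DensityGrid, header_path) -> None:
    """Raw little-endian float64 array + JSON header sidecar."""
    header_path = Path(header_path)
    raw_path = header_path.with_suffix(".raw")
    header = {
        "origin": grid.origin.tolist(),
        "spacing": grid.spacing.tolist(),
        "dims": list(grid.dims),
        "value_kind": grid.value_kind,
        "dtype": "<f8",
        "order": "C",
        "data": raw_path.name,
        "frame": "model",
    }
    header_path.write_text(json.dumps(header, indent=2))
    grid.values.astype("<f8").tofile(raw_path)


def read_grid_raw(header_path) -> DensityGrid:
    header_path = Path(header_path)
    h = json.loads(header_path.read_text())
    raw = np.fromfile(header_path.parent / h["data"], dtype=h["dtype"])
    values = raw.reshape(h["dims"], order=h.get("order", "C"))
    return DensityGrid(origin=h["origin"], spacing=h["spacing"], values=values,
                       value_kind=h["value_kind"])


# ----------------------------------------------------------------------- mesh

_VTK_TET4, _VTK_TET10 = 10, 24


def write_mesh_vtk(mesh: TetMesh, path, point_vectors: dict | None = None,
                   cell_scalars: dict | None = None) -> None:
    """Unstructured-grid VTK with materials, element sets and optional data.

    Element sets are stored as a ``region_id`` cell array; the set names
    (in region-id order) live in the comment line.
    """
    set_names = sorted(mesh.element_sets)
    region = np.full(mesh.n_elements, -1, dtype=int)
    for rid, name in enumerate(set_names):
        region[np.asarray(mesh.element_sets[name])] = rid
    order = mesh.order
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"spinefe mesh sets={','.join(set_names)} {FRAME_TAG}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt=_G)
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (order + 1)}\n")
        cells = np.hstack([np.full((mesh.n_elements, 1), order), mesh.elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        ct = _VTK_TET10 if order == 10 else _VTK_TET4
        np.savetxt(f, np.full(mesh.n_elements, ct)[:, None], fmt="%d")
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        f.write("SCALARS region_id int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, region[:, None], fmt="%d")
        if mesh.E is not None:
            f.write("SCALARS E double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, mesh.E[:, None], fmt=_G)
            f.write("SCALARS nu double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, mesh.nu[:, None], fmt=_G)
        for name, arr in (cell_scalars or {}).items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, np.asarray(arr)[:, None], fmt=_G)
        if point_vectors:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_vectors.items():
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, np.asarray(arr), fmt=_G)


def read_mesh_vtk(path):
    """Read a mesh written by :func:`write_mesh_vtk`.

    Returns ``(mesh, point_vectors)`` where point_vectors maps names to
    (N, 3) arrays (e.g. a stored displacement field).
    """
    tok_lines = Path(path).read_text().splitlines()
    set_names = []
    if len(tok_lines) > 1 and "sets=" in tok_lines[1]:
        names = tok_lines[1].split("sets=")[1].split()[0]
        set_names = [s for s in names.split(",") if s]
    # tokenize from the DATASET line on; section keywords drive the parse
    toks = " ".join(tok_lines[2:]).split()
    i = 0

    def expect(word):
        nonlocal i
        while i < len(toks) and toks[i] != word:
            i += 1
        if i >= len(toks):
            raise ParseError(f"{path}: missing {word} section")
        i += 1

    expect("POINTS")
    n_pts = int(toks[i]); i += 2  # skip dtype
    nodes = np.array(toks[i:i + 3 * n_pts], dtype=float).reshape(-1, 3)
    i += 3 * n_pts
    expect("CELLS")
    n_cells = int(toks[i]); total = int(toks[i + 1]); i += 2
    raw = np.array(toks[i:i + total], dtype=np.int64)
    i += total
    per = total // n_cells - 1
    cells = raw.reshape(n_cells, per + 1)[:, 1:]
    expect("CELL_TYPES")
    i += 1 + n_cells

    region = None
    e = nu = None
    point_vectors: dict[str, np.ndarray] = {}
    while i < len(toks):
        if toks[i] == "SCALARS":
            name = toks[i + 1]
            i += 3  # SCALARS, name, dtype
            if i < len(toks) and toks[i].isdigit():
                i += 1  # optional numComponents
            if i < len(toks) and toks[i] == "LOOKUP_TABLE":
                i += 2
            vals = np.array(toks[i:i + n_cells], dtype=float)
            i += n_cells
            if name == "region_id":
                region = vals.astype(int)
            elif name == "E":
                e = vals
            elif name == "nu":
                nu = vals
        elif toks[i] == "VECTORS":
            name = toks[i + 1]
            i += 3
            point_vectors[name] = np.array(toks[i:i + 3 * n_pts], dtype=float).reshape(-1, 3)
            i += 3 * n_pts
        else:
            i += 1

    sets = {}
    if region is not None and set_names:
        for rid, name in enumerate(set_names):
            sets[name] = np.where(region == rid)[0]
    mesh = TetMesh(nodes, cells, sets, e, nu)
    return mesh, point_vectors


def write_solution_vtk(solution, path) -> None:
    """Mesh + nodal displacement vectors + centroid strain components."""
    comp = ["exx", "eyy", "ezz", "gxy", "gyz", "gzx"]
    write_mesh_vtk(
        solution.mesh, path,
        point_vectors={"displacement": solution.u},
        cell_scalars={f"strain_{c}": solution.strain[:, k] for k, c in enumerate(comp)},
    )


# ---------------------------------------------------------------------- cloud

def write_cloud_csv(fld: SurfaceField, path) -> None:
    with open(path, "w") as f:
        f.write(f"# spinefe cloud roi={fld.roi_label} {FRAME_TAG}\n")
        f.write("point_id,x,y,z,ux,uy,uz\n")
        for k in range(fld.points.shape[0]):
            f.write("%d,%s\n" % (k, ",".join(
                _G % v for v in (*fld.points[k], *fld.displacements[k]))))


def read_cloud_csv(path) -> SurfaceField:
    roi = "custom"
    first = Path(path).read_text().splitlines()
    if first and first[0].startswith("#") and "roi=" in first[0]:
        roi = first[0].split("roi=")[1].split()[0]
    try:
        df = pd.read_csv(path, comment="#")
        arr = df[["x", "y", "z", "ux", "uy", "uz"]].to_numpy(dtype=float)
    except (ValueError, KeyError) as exc:
        raise ParseError(f"{path}: malformed cloud CSV ({exc})") from exc
    if not np.all(np.isfinite(arr)):
        bad = int(np.where(~np.isfinite(arr).all(axis=1))[0][0])
        raise ParseError(f"{path}: non-numeric value in data row {bad}")
    return SurfaceField(points=arr[:, :3], displacements=arr[:, 3:], roi_label=roi)


def write_cloud_ply(fld: SurfaceField, path) -> None:
    """ASCII PLY of the point positions (displacements go in the CSV)."""
    import trimesh

    cloud = trimesh.PointCloud(fld.points)
    Path(path).write_bytes(cloud.export(file_type="ply", encoding="ascii"))


def read_cloud_ply(path) -> np.ndarray:
    import trimesh

    return np.asarray(trimesh.load(path).vertices, dtype=float)


# --------------------------------------------------------------------- markers

def write_markers_csv(cluster: MarkerCluster, path) -> None:
    """Frames 0 (reference) and 1 (deformed) of a tracked marker cluster."""
    with open(path, "w") as f:
        f.write("frame,marker_id,x,y,z\n")
        for frame, pts in ((0, cluster.reference), (1, cluster.deformed)):
            for mid, p in zip(cluster.ids, pts):
                f.write("%d,%s,%s\n" % (frame, mid, ",".join(_G % v for v in p)))


def read_markers_csv(path, frame: int = 1) -> MarkerCluster:
    try:
        df = pd.read_csv(path)
        ref = df[df["frame"] == 0].sort_values("marker_id")
        dfm = df[df["frame"] == frame].sort_values("marker_id")
        r = ref[["x", "y", "z"]].to_numpy(dtype=float)
        d = dfm[["x", "y", "z"]].to_numpy(dtype=float)
    except (ValueError, KeyError) as exc:
        raise ParseError(f"{path}: malformed marker CSV ({exc})") from exc
    if r.shape[0] == 0 or r.shape != d.shape:
        raise ParseError(f"{path}: frames 0 and {frame} differ in marker count")
    return MarkerCluster(ids=ref["marker_id"].to_numpy(), reference=r, deformed=d)


# ------------------------------------------------------------------ transforms

def write_transform_json(t: RigidTransform, path) -> None:
    Path(path).write_text(json.dumps(
        {"matrix": t.matrix().tolist(), "about": t.about.tolist(), "frame": "model"},
        indent=2))


def read_transform_json(path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    t = RigidTransform.from_matrix(np.array(d["matrix"]))
    if "about" in d:
        t = t.about_point(np.array(d["about"], dtype=float))
    return t


# --------------------------------------------------------------------- exports

def write_abaqus_inp(mesh: TetMesh, path, fixed_nodes=None) -> None:
    """Abaqus input-deck subset: nodes, C3D4/C3D10 elements, sets, *BOUNDARY."""
    etype = "C3D10" if mesh.order == 10 else "C3D4"
    with open(path, "w") as f:
        f.write("*HEADING\nspinefe mesh export\n*NODE\n")
        for k, p in enumerate(mesh.nodes, start=1):
            f.write("%d, %s\n" % (k, ", ".join(_G % v for v in p)))
        for name in sorted(mesh.element_sets):
            ids = np.asarray(mesh.element_sets[name])
            f.write(f"*ELEMENT, TYPE={etype}, ELSET={name}\n")
            for eid in ids:
                conn = ", ".join(str(int(v) + 1) for v in mesh.elements[eid])
                f.write("%d, %s\n" % (int(eid) + 1, conn))
        if fixed_nodes is not None and len(fixed_nodes):
            f.write("*NSET, NSET=FIXED\n")
            ids = [str(int(n) + 1) for n in fixed_nodes]
            for k in range(0, len(ids), 8):
                f.write(", ".join(ids[k:k + 8]) + "\n")
            f.write("*BOUNDARY\nFIXED, 1, 3, 0.\n")


def write_report(report, base_path) -> None:
    """Validation report as a metric table CSV + full JSON + pointwise CSVs."""
    base = Path(base_path)
    report.to_frame().to_csv(base.with_suffix(".csv"))
    base.with_suffix(".json").write_text(report.to_json())
    for roi, df in report.pointwise.items():
        df.to_csv(base.parent / f"{base.stem}_{roi}_pointwise.csv", index=False)
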