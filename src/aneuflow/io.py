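"""Readers and writers for trees (YAML + CSV), fields (ASCII VTU) and tables.

Geometry files carry their unit in a header field (default mm); physics
is computed in SI after conversion.  The VTU support covers the ASCII
``UnstructuredGrid`` subset this package emits: tetrahedra (volume),
triangles (wall), a ``velocity`` point array, optional ``wss`` and
``region`` cell arrays and a ``TimeValue`` field-data entry.
"""

from __future__ import annotations

import glob as globmod
import json
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
import yaml

from .hemodynamics import FieldSeries, RegionSet
from .vessel_model import CrossSection, VesselTree

__all__ = [
    "read_tree",
    "write_tree",
    "read_field_series",
    "write_field_series",
    "read_regions",
    "write_regions",
    "read_stl_surface",
    "splits_to_frame",
]

#: cell-region integer labels used in VTU files
REGION_LABELS = {"other": 0, "sac_volume": 1, "parent_volume": 2,
                 "sac_surface": 3, "parent_surface": 4}

_VTK_TETRA, _VTK_TRIANGLE = 10, 5


# ---------------------------------------------------------------------------
# vessel trees
# ---------------------------------------------------------------------------

def write_tree(tree: VesselTree, path: str | Path) -> None:
    """Write a tree as YAML; section boundaries go to sidecar x,y,z CSVs."""
    path = Path(path)
    sec_dir = path.with_suffix("") .parent / (path.stem + "_sections")
    doc: dict = {"units": "mm", "nodes": {}, "segments": []}
    for node, data in tree.graph.nodes(data=True):
        doc["nodes"][node] = {"kind": data["kind"]}
    wrote_sections = False
    for u, v, data in tree.graph.edges(data=True):
        seg: dict = {"parent": u, "child": v, "length": float(data["length"])}
        if data.get("radius") is not None:
            seg["radius"] = float(data["radius"])
        sec: CrossSection | None = data.get("section")
        if sec is not None:
            sec_dir.mkdir(parents=True, exist_ok=True)
            wrote_sections = True
            csv_name = f"{u}__{v}.csv"
            np.savetxt(sec_dir / csv_name, sec.boundary, delimiter=",",
                       header="x,y,z", comments="", fmt="%.17g")
            seg["section"] = {
                "anchor": [float(x) for x in sec.anchor],
                "normal": [float(x) for x in sec.normal],
                "boundary_csv": f"{sec_dir.name}/{csv_name}",
            }
        doc["segments"].append(seg)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_tree(path: str | Path) -> VesselTree:
    """Read a tree written by :func:`write_tree` (schema errors name the field)."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    for key in ("nodes", "segments"):
        if key not in doc:
            raise ValueError(f"{path}: missing top-level key {key!r}")
    tree = VesselTree()
    for node, data in doc["nodes"].items():
        kind = (data or {}).get("kind")
        if kind not in ("inlet", "junction", "outlet"):
            raise ValueError(f"{path}: node {node!r} has invalid kind {kind!r}")
        tree.add_node(node, kind=kind)
    for i, seg in enumerate(doc["segments"]):
        for key in ("parent", "child", "length"):
            if key not in seg:
                raise ValueError(f"{path}: segment #{i} missing {key!r}")
        section = None
        if "section" in seg:
            s = seg["section"]
            boundary = np.loadtxt(path.parent / s["boundary_csv"], delimiter=",", skiprows=1)
            section = CrossSection(anchor=np.array(s["anchor"], float),
                                   normal=np.array(s["normal"], float),
                                   boundary=boundary)
        if "radius" not in seg and section is None:
            raise ValueError(
                f"{path}: segment {seg['parent']}->{seg['child']} has neither radius nor section"
            )
        tree.add_segment(seg["parent"], seg["child"], length=seg["length"],
                         radius=seg.get("radius"), section=section)
    return tree


def read_stl_surface(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Vertices and faces of an STL surface (via trimesh)."""
    import trimesh

    mesh = trimesh.load_mesh(str(path))
    return np.asarray(mesh.vertices, float), np.asarray(mesh.faces, int)


# ---------------------------------------------------------------------------
# field series (ASCII VTU, one file per time step)
# ---------------------------------------------------------------------------

def _fmt(arr: np.ndarray) -> str:
    return " ".join(f"{x:.17g}" for x in np.asarray(arr).ravel())


def _data_array(name: str | None, arr: np.ndarray, vtk_type: str, ncomp: int) -> ET.Element:
    el = ET.Element("DataArray", {"type": vtk_type, "format": "ascii",
                                  "NumberOfComponents": str(ncomp)})
    if name:
        el.set("Name", name)
    el.text = _fmt(arr)
    return el


def write_field_series(
    series: FieldSeries,
    regions: RegionSet,
    out_dir: str | Path,
    basename: str = "step",
) -> list[Path]:
    """One ASCII ``.vtu`` file per time step plus a ``regions.yaml`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_tets, n_tris = len(series.tets), len(series.surface_tris)
    region = np.zeros(n_tets + n_tris, dtype=int)
    region[np.asarray(regions.sac_cells)] = REGION_LABELS["sac_volume"]
    region[np.asarray(regions.parent_cells)] = REGION_LABELS["parent_volume"]
    region[n_tets + np.asarray(regions.sac_surface)] = REGION_LABELS["sac_surface"]
    region[n_tets + np.asarray(regions.parent_surface)] = REGION_LABELS["parent_surface"]

    connectivity = np.concatenate([series.tets.ravel(), series.surface_tris.ravel()])
    offsets = np.concatenate([4 * np.arange(1, n_tets + 1),
                              4 * n_tets + 3 * np.arange(1, n_tris + 1)])
    types = np.concatenate([np.full(n_tets, _VTK_TETRA), np.full(n_tris, _VTK_TRIANGLE)])

    paths = []
    for it, t in enumerate(series.times):
        root = ET.Element("VTKFile", {"type": "UnstructuredGrid", "version": "0.1",
                                      "byte_order": "LittleEndian"})
        ug = ET.SubElement(root, "UnstructuredGrid")
        fd = ET.SubElement(ug, "FieldData")
        for name, val in (("TimeValue", t), ("Density", series.rho), ("Viscosity", series.mu)):
            da = ET.Element("DataArray", {"type": "Float64", "Name": name,
                                          "NumberOfTuples": "1", "format": "ascii"})
            da.text = f"{val:.17g}"
            fd.append(da)
        piece = ET.SubElement(ug, "Piece", {"NumberOfPoints": str(len(series.points)),
                                            "NumberOfCells": str(n_tets + n_tris)})
        pts = ET.SubElement(piece, "Points")
        pts.append(_data_array(None, series.points, "Float64", 3))
        cells = ET.SubElement(piece, "Cells")
        cells.append(_data_array("connectivity", connectivity, "Int64", 1))
        cells.append(_data_array("offsets", offsets, "Int64", 1))
        cells.append(_data_array("types", types, "UInt8", 1))
        pdata = ET.SubElement(piece, "PointData")
        pdata.append(_data_array("velocity", series.velocity[it], "Float64", 3))
        cdata = ET.SubElement(piece, "CellData")
        cdata.append(_data_array("region", region, "Int64", 1))
        if series.wss is not None:
            wss_full = np.zeros((n_tets + n_tris, 3))
            wss_full[n_tets:] = series.wss[it]
            cdata.append(_data_array("wss", wss_full, "Float64", 3))
        p = out_dir / f"{basename}_{it:04d}.vtu"
        ET.ElementTree(root).write(p, xml_declaration=True, encoding="unicode")
        paths.append(p)
    write_regions(regions, out_dir / "regions.yaml")
    return paths


def _read_array(piece: ET.Element, xpath: str, name: str | None = None) -> np.ndarray | None:
    for da in piece.findall(xpath):
        if name is None or da.get("Name") == name:
            return np.fromstring(da.text, sep=" ")
    return None


def read_field_series(pattern: str) -> tuple[FieldSeries, RegionSet]:
    """Assemble a :class:`FieldSeries` from a glob of ASCII VTU steps.

    Files are ordered by their ``TimeValue``; all steps must share the
    same topology.
    """
    files = sorted(globmod.glob(str(pattern)))
    if len(files) < 2:
        raise ValueError(f"pattern {pattern!r} matched {len(files)} files; need >= 2 time steps")
    steps = []
    for f in files:
        root = ET.parse(f).getroot()
        piece = root.find(".//Piece")
        if piece is None:
            raise ValueError(f"{f}: no <Piece> element")
        time_el = None
        meta = {"TimeValue": None, "Density": 1055.0, "Viscosity": 0.004}
        for da in root.findall(".//FieldData/DataArray"):
            if da.get("Name") in meta:
                meta[da.get("Name")] = float(da.text.strip())
        if meta["TimeValue"] is None:
            raise ValueError(f"{f}: missing TimeValue field data")
        points = _read_array(piece, "Points/DataArray").reshape(-1, 3)
        conn = _read_array(piece, "Cells/DataArray", "connectivity").astype(int)
        offsets = _read_array(piece, "Cells/DataArray", "offsets").astype(int)
        types = _read_array(piece, "Cells/DataArray", "types").astype(int)
        velocity = _read_array(piece, "PointData/DataArray", "velocity")
        if velocity is None:
            raise ValueError(f"{f}: missing 'velocity' point array")
        velocity = velocity.reshape(-1, 3)
        region = _read_array(piece, "CellData/DataArray", "region")
        wss = _read_array(piece, "CellData/DataArray", "wss")
        steps.append((meta, points, conn, offsets, types, velocity, region, wss))

    steps.sort(key=lambda s: s[0]["TimeValue"])
    meta0, points0, conn0, off0, types0 = steps[0][:5]
    for f, s in zip(files, steps):
        if s[1].shape != points0.shape or not np.array_equal(s[2], conn0):
            raise ValueError("topology differs between time steps")

    starts = np.concatenate([[0], off0[:-1]])
    tets = np.array([conn0[a:b] for a, b, t in zip(starts, off0, types0) if t == _VTK_TETRA])
    tris = np.array([conn0[a:b] for a, b, t in zip(starts, off0, types0) if t == _VTK_TRIANGLE])
    tet_idx = np.where(types0 == _VTK_TETRA)[0]
    tri_idx = np.where(types0 == _VTK_TRIANGLE)[0]

    times = np.array([s[0]["TimeValue"] for s in steps])
    velocity = np.stack([s[5] for s in steps])
    wss = None
    if steps[0][7] is not None:
        wss = np.stack([s[7].reshape(-1, 3)[tri_idx] for s in steps])

    # outward wall normals from triangle winding
    p = points0[tris]
    normals = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-300)

    series = FieldSeries(points=points0, tets=tets, surface_tris=tris,
                         surface_normals=normals, times=times, velocity=velocity,
                         wss=wss, rho=meta0["Density"], mu=meta0["Viscosity"])

    region = steps[0][6]
    if region is not None:
        region = region.astype(int)
        vol_r = region[tet_idx]
        surf_r = region[tri_idx]
        regions = RegionSet(
            sac_cells=np.where(vol_r == REGION_LABELS["sac_volume"])[0],
            parent_cells=np.where(vol_r == REGION_LABELS["parent_volume"])[0],
            sac_surface=np.where(surf_r == REGION_LABELS["sac_surface"])[0],
            parent_surface=np.where(surf_r == REGION_LABELS["parent_surface"])[0],
        )
    else:
        regions = RegionSet(sac_cells=np.arange(len(tets)), parent_cells=[],
                            sac_surface=np.arange(len(tris)), parent_surface=[])
    return series, regions


def write_regions(regions: RegionSet, path: str | Path) -> None:
    doc = {"labels": REGION_LABELS}
    if regions.ostium_point is not None:
        doc["ostium"] = {"point": [float(x) for x in regions.ostium_point],
                         "normal": [float(x) for x in regions.ostium_normal]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_regions(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def splits_to_frame(splits: dict[str, "SplitResult"], model: str = "1") -> pd.DataFrame:
    """Long-form CSV-ready frame: vessel_model, outlet, method, fraction."""
    rows = []
    for method, result in splits.items():
        for outlet, frac in result.fractions.items():
            rows.append({"vessel_model": model, "outlet": outlet,
                         "method": method, "fraction": frac})
    return pd.DataFrame(rows, columns=["vessel_model", "outlet", "method", "fraction"])
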