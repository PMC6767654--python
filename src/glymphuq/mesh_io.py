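"""Labeled-mesh I/O: XDMF+HDF5, ASCII VTU, and Gmsh MSH 4.1 (ASCII).

Cell labels travel as the integer cell field ``subdomain`` (gray=1,
white=2), boundary-facet labels as ``boundary`` (SAS=1, ventricle=2).
The VTU writer stores tetrahedra and boundary triangles in one mixed
unstructured grid with both arrays (each valid on its own cell type and
zero on the other); the XDMF file holds a volume grid and a boundary grid
referencing one HDF5 file; the MSH writer emits four physical groups.

A ``label_map`` may translate foreign integer tags into the canonical
roles, e.g. ``{"gray": 3, "white": 4, "SAS": 1, "ventricle": 2}``.
"""

from __future__ import annotations

import pathlib
import xml.etree.ElementTree as ET

import numpy as np

from . import fem
from .geometry import GRAY, WHITE, SAS, VENTRICLE, LabeledMesh

_CANONICAL = {"gray": GRAY, "white": WHITE, "SAS": SAS, "ventricle": VENTRICLE}


def _apply_label_map(cell_label, facet_label, label_map):
    if not label_map:
        return cell_label, facet_label
    out_c = np.full_like(cell_label, -1)
    out_f = np.full_like(facet_label, -1)
    for role, tag in label_map.items():
        if role in ("gray", "white"):
            out_c[cell_label == tag] = _CANONICAL[role]
        elif role in ("SAS", "ventricle"):
            out_f[facet_label == tag] = _CANONICAL[role]
        else:
            raise ValueError(f"unknown role {role!r} in label_map")
    if np.any(out_c < 0):
        bad = np.unique(cell_label[out_c < 0])
        raise ValueError(f"unknown cell tags {bad.tolist()} not covered by label_map")
    if np.any(out_f < 0):
        bad = np.unique(facet_label[out_f < 0])
        raise ValueError(f"unknown facet tags {bad.tolist()} not covered by label_map")
    return out_c, out_f


def save_labeled_mesh(mesh: LabeledMesh, path, file_format: str | None = None) -> None:
    path = pathlib.Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt == "xdmf":
        _write_xdmf(mesh, path)
    elif fmt == "vtu":
        _write_vtu(mesh, path)
    elif fmt == "msh":
        _write_msh(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")


def load_labeled_mesh(path, file_format: str | None = None,
                      label_map: dict | None = None) -> LabeledMesh:
    """Read a labeled mesh, validate its invariants and return it.

    Facets missing from the file are recovered from the cells; a boundary
    facet that then carries no label is an error (named in the message).
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt == "xdmf":
        data = _read_xdmf(path)
    elif fmt == "vtu":
        data = _read_vtu(path)
    elif fmt == "msh":
        data = _read_msh(path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    vertices, cells, cell_label, facets, facet_label = data
    cell_label, facet_label = _apply_label_map(cell_label, facet_label, label_map)
    mesh = LabeledMesh(vertices, cells, cell_label, facets, facet_label,
                       metadata={"source": str(path), "format": fmt})
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# XDMF + HDF5
# ---------------------------------------------------------------------------

def _write_xdmf(mesh: LabeledMesh, path: pathlib.Path) -> None:
    import h5py

    h5path = path.with_suffix(".h5")
    with h5py.File(h5path, "w") as f:
        f["vertices"] = mesh.vertices
        f["cells"] = mesh.cells
        f["subdomain"] = mesh.cell_label
        f["facets"] = mesh.facets
        f["boundary"] = mesh.facet_label

    def data_item(parent, name, arr, dtype):
        d = ET.SubElement(parent, "DataItem", Dimensions=" ".join(map(str, arr.shape)),
                          NumberType=dtype, Format="HDF")
        d.text = f"{h5path.name}:/{name}"

    root = ET.Element("Xdmf", Version="3.0")
    dom = ET.SubElement(root, "Domain")
    vol = ET.SubElement(dom, "Grid", Name="volume", GridType="Uniform")
    topo = ET.SubElement(vol, "Topology", TopologyType="Tetrahedron",
                         NumberOfElements=str(mesh.n_cells))
    data_item(topo, "cells", mesh.cells, "Int")
    geo = ET.SubElement(vol, "Geometry", GeometryType="XYZ")
    data_item(geo, "vertices", mesh.vertices, "Float")
    att = ET.SubElement(vol, "Attribute", Name="subdomain", Center="Cell")
    data_item(att, "subdomain", mesh.cell_label, "Int")

    bnd = ET.SubElement(dom, "Grid", Name="boundary", GridType="Uniform")
    topo = ET.SubElement(bnd, "Topology", TopologyType="Triangle",
                         NumberOfElements=str(len(mesh.facets)))
    data_item(topo, "facets", mesh.facets, "Int")
    geo = ET.SubElement(bnd, "Geometry", GeometryType="XYZ")
    data_item(geo, "vertices", mesh.vertices, "Float")
    att = ET.SubElement(bnd, "Attribute", Name="boundary", Center="Cell")
    data_item(att, "boundary", mesh.facet_label, "Int")

    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True)


def _read_xdmf(path: pathlib.Path):
    import h5py

    tree = ET.parse(path)
    refs = {}
    for grid in tree.getroot().iter("Grid"):
        name = grid.get("Name")
        for el in grid.iter("DataItem"):
            fname, dset = el.text.strip().split(":")
            refs.setdefault(name, {})[dset.lstrip("/")] = fname
    volrefs = refs.get("volume", {})
    with h5py.File(path.parent / next(iter(volrefs.values())), "r") as f:
        vertices = f["vertices"][()]
        cells = f["cells"][()]
        cell_label = f["subdomain"][()]
        facets = f["facets"][()] if "facets" in f else None
        facet_label = f["boundary"][()] if "boundary" in f else None
    if facets is None:
        facets, facet_label = _recover_facets(cells, None, None)
    return vertices, cells, cell_label, facets, facet_label


# ---------------------------------------------------------------------------
# VTU (ASCII XML)
# ---------------------------------------------------------------------------

def _write_vtu(mesh: LabeledMesh, path: pathlib.Path) -> None:
    nv = mesh.n_vertices
    conn = np.concatenate([mesh.cells.ravel(), mesh.facets.ravel()])
    offsets = np.concatenate([4 * np.arange(1, mesh.n_cells + 1),
                              4 * mesh.n_cells + 3 * np.arange(1, len(mesh.facets) + 1)])
    types = np.concatenate([np.full(mesh.n_cells, 10), np.full(len(mesh.facets), 5)])
    subdomain = np.concatenate([mesh.cell_label, np.zeros(len(mesh.facets), dtype=int)])
    boundary = np.concatenate([np.zeros(mesh.n_cells, dtype=int), mesh.facet_label])

    def fmt(arr):
        return "\n".join(" ".join(f"{x:.17g}" for x in np.atleast_1d(row))
                         for row in np.asarray(arr))

    ncells = mesh.n_cells + len(mesh.facets)
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        f.write(f'<UnstructuredGrid><Piece NumberOfPoints="{nv}" NumberOfCells="{ncells}">\n')
        f.write('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        f.write(fmt(mesh.vertices))
        f.write('\n</DataArray></Points>\n<Cells>\n')
        for name, arr, typ in (("connectivity", conn, "Int64"),
                               ("offsets", offsets, "Int64"),
                               ("types", types, "UInt8")):
            f.write(f'<DataArray type="{typ}" Name="{name}" format="ascii">\n')
            f.write(" ".join(map(str, arr)))
            f.write("\n</DataArray>\n")
        f.write('</Cells>\n<CellData>\n')
        for name, arr in (("subdomain", subdomain), ("boundary", boundary)):
            f.write(f'<DataArray type="Int64" Name="{name}" format="ascii">\n')
            f.write(" ".join(map(str, arr)))
            f.write("\n</DataArray>\n")
        f.write('</CellData>\n</Piece></UnstructuredGrid></VTKFile>\n')


def _read_vtu(path: pathlib.Path):
    tree = ET.parse(path)
    piece = tree.getroot().find("UnstructuredGrid").find("Piece")
    arrays = {}
    for da in piece.iter("DataArray"):
        key = da.get("Name") or "points"
        arrays[key] = np.array(da.text.split(), dtype=float)
    vertices = arrays["points"].reshape(-1, 3)
    conn = arrays["connectivity"].astype(int)
    offsets = arrays["offsets"].astype(int)
    types = arrays["types"].astype(int)
    starts = np.concatenate([[0], offsets[:-1]])
    tets, tris, sub, bnd = [], [], [], []
    subdomain = arrays.get("subdomain")
    boundary = arrays.get("boundary")
    for idx, (s, e, t) in enumerate(zip(starts, offsets, types)):
        if t == 10:
            tets.append(conn[s:e])
            sub.append(int(subdomain[idx]) if subdomain is not None else GRAY)
        elif t == 5:
            tris.append(conn[s:e])
            bnd.append(int(boundary[idx]) if boundary is not None else 0)
        else:
            raise ValueError(f"unsupported VTK cell type {t}")
    cells = np.array(tets, dtype=int)
    facets = np.array(tris, dtype=int).reshape(-1, 3)
    facets, facet_label = _recover_facets(cells, facets, np.array(bnd, dtype=int))
    return vertices, cells, np.array(sub, dtype=int), facets, facet_label


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 (ASCII), single node block, one entity per physical group
# ---------------------------------------------------------------------------

def _write_msh(mesh: LabeledMesh, path: pathlib.Path) -> None:
    groups = [
        (2, SAS, mesh.facets[mesh.facet_label == SAS], 2),       # (dim, tag, conn, type=triangle)
        (2, VENTRICLE, mesh.facets[mesh.facet_label == VENTRICLE], 2),
        (3, GRAY, mesh.cells[mesh.cell_label == GRAY], 4),       # type 4 = tetrahedron
        (3, WHITE, mesh.cells[mesh.cell_label == WHITE], 4),
    ]
    groups = [g for g in groups if len(g[2])]
    with open(path, "w") as f:
        f.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        f.write("$Entities\n")
        nsurf = sum(1 for g in groups if g[0] == 2)
        nvol = sum(1 for g in groups if g[0] == 3)
        f.write(f"0 0 {nsurf} {nvol}\n")
        lo, hi = mesh.bounding_box()
        box = " ".join(f"{x:.17g}" for x in (*lo, *hi))
        for dim, tag, _, _ in groups:
            if dim == 2:
                f.write(f"{tag} {box} 1 {tag} 0\n")
        for dim, tag, _, _ in groups:
            if dim == 3:
                f.write(f"{tag} {box} 1 {tag} 0\n")
        f.write("$EndEntities\n")
        nv = mesh.n_vertices
        first_vol = next(g for g in groups if g[0] == 3)
        f.write(f"$Nodes\n1 {nv} 1 {nv}\n3 {first_vol[1]} 0 {nv}\n")
        f.write("\n".join(str(i + 1) for i in range(nv)))
        f.write("\n")
        f.write("\n".join(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in mesh.vertices))
        f.write("\n$EndNodes\n")
        nelem = sum(len(g[2]) for g in groups)
        f.write(f"$Elements\n{len(groups)} {nelem} 1 {nelem}\n")
        eid = 1
        for dim, tag, conn, etype in groups:
            f.write(f"{dim} {tag} {etype} {len(conn)}\n")
            for row in conn:
                f.write(f"{eid} " + " ".join(str(v + 1) for v in row) + "\n")
                eid += 1
        f.write("$EndElements\n")


def _read_msh(path: pathlib.Path):
    with open(path) as f:
        lines = [ln.strip() for ln in f]
    def section(name):
        i = lines.index(f"${name}")
        j = lines.index(f"$End{name}")
        return lines[i + 1:j]

    nodes = section("Nodes")
    nblocks, ntotal = int(nodes[0].split()[0]), int(nodes[0].split()[1])
    vertices = np.empty((ntotal, 3))
    tag_of = {}
    i = 1
    for _ in range(nblocks):
        _, _, _, nn = (int(x) for x in nodes[i].split())
        ids = [int(nodes[i + 1 + k]) for k in range(nn)]
        for k, nid in enumerate(ids):
            tag_of[nid] = len(tag_of)
            vertices[tag_of[nid]] = [float(x) for x in nodes[i + 1 + nn + k].split()]
        i += 1 + 2 * nn
    vertices = vertices[:len(tag_of)]

    elems = section("Elements")
    nblocks = int(elems[0].split()[0])
    cells, cell_label, facets, facet_label = [], [], [], []
    i = 1
    for _ in range(nblocks):
        dim, tag, etype, ne = (int(x) for x in elems[i].split())
        for k in range(ne):
            parts = [int(x) for x in elems[i + 1 + k].split()]
            conn = [tag_of[t] for t in parts[1:]]
            if etype == 4:
                cells.append(conn)
                cell_label.append(tag)
            elif etype == 2:
                facets.append(conn)
                facet_label.append(tag)
            else:
                raise ValueError(f"unsupported MSH element type {etype}")
        i += 1 + ne
    cells = np.array(cells, dtype=int)
    facets, facet_label = _recover_facets(cells, np.array(facets, dtype=int).reshape(-1, 3),
                                          np.array(facet_label, dtype=int))
    return vertices, cells, np.array(cell_label, dtype=int), facets, facet_label


# ---------------------------------------------------------------------------
# nodal field dumps (inspection output)
# ---------------------------------------------------------------------------

def save_nodal_fields(mesh: LabeledMesh, fields: dict, path) -> None:
    """Write named nodal fields (scalar (nv,) or vector (nv, 3)) for inspection.

    XDMF: one grid with the mesh topology and one attribute per field, data
    in a sibling HDF5 file.  VTU: ASCII point data.  A time series can be
    dumped by naming the fields, e.g. ``{"c_3h": ..., "c_24h": ...}``.
    """
    path = pathlib.Path(path)
    fmt = path.suffix.lstrip(".").lower()
    fields = {k: np.asarray(v, dtype=float) for k, v in fields.items()}
    for name, arr in fields.items():
        if arr.shape[0] != mesh.n_vertices:
            raise ValueError(f"field {name!r} is not nodal (shape {arr.shape})")
    if fmt == "xdmf":
        import h5py

        h5path = path.with_suffix(".h5")
        with h5py.File(h5path, "w") as f:
            f["vertices"] = mesh.vertices
            f["cells"] = mesh.cells
            for name, arr in fields.items():
                f[f"fields/{name}"] = arr
        root = ET.Element("Xdmf", Version="3.0")
        grid = ET.SubElement(ET.SubElement(root, "Domain"), "Grid",
                             Name="fields", GridType="Uniform")
        topo = ET.SubElement(grid, "Topology", TopologyType="Tetrahedron",
                             NumberOfElements=str(mesh.n_cells))
        ET.SubElement(topo, "DataItem", Dimensions=f"{mesh.n_cells} 4",
                      NumberType="Int", Format="HDF").text = f"{h5path.name}:/cells"
        geo = ET.SubElement(grid, "Geometry", GeometryType="XYZ")
        ET.SubElement(geo, "DataItem", Dimensions=f"{mesh.n_vertices} 3",
                      NumberType="Float", Format="HDF").text = f"{h5path.name}:/vertices"
        for name, arr in fields.items():
            kind = "Vector" if arr.ndim == 2 else "Scalar"
            att = ET.SubElement(grid, "Attribute", Name=name, Center="Node",
                                AttributeType=kind)
            ET.SubElement(att, "DataItem",
                          Dimensions=" ".join(map(str, arr.shape)),
                          NumberType="Float", Format="HDF").text = \
                f"{h5path.name}:/fields/{name}"
        ET.indent(root)
        ET.ElementTree(root).write(path, xml_declaration=True)
    elif fmt == "vtu":
        with open(path, "w") as f:
            f.write('<?xml version="1.0"?>\n'
                    '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
                    f'<UnstructuredGrid><Piece NumberOfPoints="{mesh.n_vertices}" '
                    f'NumberOfCells="{mesh.n_cells}">\n'
                    '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
            f.write("\n".join(" ".join(f"{x:.17g}" for x in p) for p in mesh.vertices))
            f.write('\n</DataArray></Points>\n<Cells>\n')
            f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n'
                    + " ".join(map(str, mesh.cells.ravel()))
                    + '\n</DataArray>\n')
            f.write('<DataArray type="Int64" Name="offsets" format="ascii">\n'
                    + " ".join(map(str, 4 * np.arange(1, mesh.n_cells + 1)))
                    + '\n</DataArray>\n')
            f.write('<DataArray type="UInt8" Name="types" format="ascii">\n'
                    + " ".join(["10"] * mesh.n_cells) + '\n</DataArray>\n</Cells>\n')
            f.write('<PointData>\n')
            for name, arr in fields.items():
                ncomp = arr.shape[1] if arr.ndim == 2 else 1
                f.write(f'<DataArray type="Float64" Name="{name}" '
                        f'NumberOfComponents="{ncomp}" format="ascii">\n')
                f.write("\n".join(" ".join(f"{x:.17g}" for x in np.atleast_1d(row))
                                  for row in arr))
                f.write('\n</DataArray>\n')
            f.write('</PointData>\n</Piece></UnstructuredGrid></VTKFile>\n')
    else:
        raise ValueError(f"unsupported field-dump format {fmt!r}")


# ---------------------------------------------------------------------------

def _recover_facets(cells, facets, facet_label):
    """Match stored facet labels onto the actual mesh boundary.

    Raises if a boundary facet carries no label (naming the facet).
    """
    actual, _, _ = fem.boundary_facets(cells)
    if facets is None or len(facets) == 0:
        raise ValueError(
            f"boundary facet without a label: {tuple(actual[0])} (no facet data in file)")
    keys = {tuple(f): lab for f, lab in zip(np.sort(facets, axis=1), facet_label)}
    labels = np.empty(len(actual), dtype=int)
    for i, f in enumerate(actual):
        lab = keys.get(tuple(f))
        if lab is None or lab == 0:
            raise ValueError(f"boundary facet without a label: vertices {tuple(f)}")
        labels[i] = lab
    return actual, labels
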