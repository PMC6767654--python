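"""Labeled tetrahedral geometry: synthetic brain-like domain and subregions.

The computational domain is the brain parenchyma: a gray-matter shell
around a white-matter core with an interior ventricular cavity.  The
synthetic stand-in is a pair of concentric ellipsoids (outer surface =
SAS interface, shell = gray matter) with a central spherical cavity whose
surface is the ventricular interface.  Coordinates are metres, with z = 0
at the level of the lateral ventricles (cavity center), z ~ -0.1 at the
foramen magnum and z ~ +0.1 at the precentral sulcus.

Meshes are built by Kuhn (Freudenthal) subdivision of a regular grid into
six tetrahedra per cube, keeping cells whose centroid lies inside the
domain.  This is deterministic given the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem

GRAY = 1
WHITE = 2
SAS = 1
VENTRICLE = 2

#: largest admissible axis-aligned bounding box of a brain-scale domain (m)
MAX_EXTENT = (0.16, 0.21, 0.17)

# Kuhn subdivision of the unit cube (vertex k has coords = bits of k in
# x,y,z order) into 6 tets sharing the main diagonal 0-7.  All six have
# positive volume 1/6 and the subdivision is conforming across cubes.
_KUHN_TETS = np.array([
    [0, 1, 3, 7],
    [0, 3, 2, 7],
    [0, 2, 6, 7],
    [0, 6, 4, 7],
    [0, 4, 5, 7],
    [0, 5, 1, 7],
])


@dataclass
class LabeledMesh:
    """Conforming tetrahedral mesh with compartment and boundary labels.

    vertices : (nv, 3) float, metres
    cells : (nc, 4) int
    cell_label : (nc,) int, GRAY (1) or WHITE (2)
    facets : (nf, 3) int, boundary facets
    facet_label : (nf,) int, SAS (1) or VENTRICLE (2)
    metadata : free-form provenance (generator parameters etc.)
    """

    vertices: np.ndarray
    cells: np.ndarray
    cell_label: np.ndarray
    facets: np.ndarray
    facet_label: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        self.cell_label = np.ascontiguousarray(self.cell_label, dtype=np.int64)
        self.facets = np.ascontiguousarray(self.facets, dtype=np.int64)
        self.facet_label = np.ascontiguousarray(self.facet_label, dtype=np.int64)
        self._cell_volumes = None
        self._boundary = None

    # -- derived quantities -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_volumes(self) -> np.ndarray:
        if self._cell_volumes is None:
            self._cell_volumes = fem.tet_volumes(self.vertices, self.cells)
        return self._cell_volumes

    @property
    def cell_centroids(self) -> np.ndarray:
        return self.vertices[self.cells].mean(axis=1)

    def total_volume(self) -> float:
        return float(self.cell_volumes.sum())

    def compartment_cells(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.cell_label == label)

    def facet_vertices(self, label: int) -> np.ndarray:
        """Sorted unique vertex indices of the facets carrying ``label``."""
        return np.unique(self.facets[self.facet_label == label])

    def bounding_box(self):
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        if self.cell_volumes.min(initial=np.inf) <= 0:
            raise ValueError("mesh contains a degenerate (zero-volume) cell")
        labels = set(np.unique(self.cell_label))
        if not labels <= {GRAY, WHITE}:
            raise ValueError(f"unknown cell labels {labels - {GRAY, WHITE}}")
        if GRAY not in labels or WHITE not in labels:
            raise ValueError("gray and white compartments must both be non-empty")
        facets, _, _ = fem.boundary_facets(self.cells)  # raises if non-conforming
        ours = {tuple(f) for f in np.sort(self.facets, axis=1)}
        actual = {tuple(f) for f in facets}
        missing = actual - ours
        if missing:
            raise ValueError(
                f"{len(missing)} boundary facet(s) without a label, e.g. {sorted(missing)[0]}")
        extra = ours - actual
        if extra:
            raise ValueError(f"{len(extra)} labeled facet(s) are not on the boundary")
        flabels = set(np.unique(self.facet_label))
        if not flabels <= {SAS, VENTRICLE}:
            raise ValueError(f"unknown facet labels {flabels - {SAS, VENTRICLE}}")


@dataclass
class RegionMask:
    """A subregion: a set of cell (or vertex) indices with its volume in m^3."""

    kind: str  # 'cell-set' or 'vertex-set'
    members: np.ndarray
    volume: float

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=np.int64)
        if self.kind == "cell-set" and self.volume <= 0:
            raise ValueError("region volume must be positive")


# ---------------------------------------------------------------------------
# mesh generators
# ---------------------------------------------------------------------------

def _structured_tets(origin, spacing, shape):
    """Vertices and Kuhn tets of a regular (nx, ny, nz)-cube grid."""
    nx, ny, nz = shape
    xs = origin[0] + spacing * np.arange(nx + 1)
    ys = origin[1] + spacing * np.arange(ny + 1)
    zs = origin[2] + spacing * np.arange(nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack([vid(i + (b & 1), j + ((b >> 1) & 1), k + ((b >> 2) & 1))
                        for b in range(8)], axis=1)
    cells = corners[:, _KUHN_TETS].reshape(-1, 4)
    return vertices, cells


def _compress(vertices, cells):
    used, inverse = np.unique(cells.ravel(), return_inverse=True)
    return vertices[used], inverse.reshape(cells.shape)


def build_box_mesh(lengths=(1.0, 1.0, 1.0), divisions=(4, 4, 4), origin=(0.0, 0.0, 0.0)):
    """Structured box mesh (testing / verification helper).

    The whole boundary is labeled SAS; cells are split gray/white by the
    x-midplane so the compartment invariant holds.
    """
    lengths = np.asarray(lengths, dtype=float)
    divisions = np.asarray(divisions, dtype=int)
    spacing = lengths / divisions
    if not np.allclose(spacing, spacing[0]):
        # anisotropic spacing: stretch an isotropic grid
        vertices, cells = _structured_tets((0, 0, 0), 1.0, divisions)
        vertices = vertices * spacing[None, :] + np.asarray(origin)[None, :]
    else:
        vertices, cells = _structured_tets(origin, spacing[0], divisions)
    centroids = vertices[cells].mean(axis=1)
    label = np.where(centroids[:, 0] < origin[0] + lengths[0] / 2, GRAY, WHITE)
    facets, _, _ = fem.boundary_facets(cells)
    mesh = LabeledMesh(vertices, cells, label, facets,
                       np.full(len(facets), SAS),
                       metadata={"generator": "box", "lengths": lengths.tolist()})
    return mesh


def build_synthetic_brain(outer_semi_axes=(0.07, 0.09, 0.08),
                          gray_thickness=0.02,
                          ventricle_radius=0.02,
                          target_edge_length=0.01) -> LabeledMesh:
    """Synthetic two-compartment brain-like domain.

    Concentric-ellipsoid construction: cells with centroid inside the outer
    ellipsoid but outside a central sphere of ``ventricle_radius`` are kept;
    cells outside the inner ellipsoid (semi-axes reduced by
    ``gray_thickness``) are gray, the rest white.  The outer staircase
    surface is labeled SAS, the cavity surface ventricle.  z = 0 passes
    through the cavity center.
    """
    a = np.asarray(outer_semi_axes, dtype=float)
    h = float(target_edge_length)
    if gray_thickness >= a.min():
        raise ValueError("infeasible geometry: gray_thickness >= min(outer_semi_axes)")
    if ventricle_radius >= a.min() - gray_thickness:
        raise ValueError("infeasible geometry: ventricular cavity reaches the gray shell")
    if np.any(2 * a > np.asarray(MAX_EXTENT)):
        raise ValueError(f"domain exceeds the admissible bounding box {MAX_EXTENT}")
    if ventricle_radius > 0 and h > ventricle_radius:
        raise ValueError("mesher failure: edge length too coarse to resolve the cavity")

    n = np.ceil(a / h).astype(int)
    origin = -n * h
    vertices, cells = _structured_tets(origin, h, 2 * n)
    centroids = vertices[cells].mean(axis=1)

    rho = np.linalg.norm(centroids / a[None, :], axis=1)  # ellipsoidal coordinate
    rad = np.linalg.norm(centroids, axis=1)
    keep = (rho < 1.0) & (rad > ventricle_radius)
    cells = cells[keep]
    if len(cells) == 0:
        raise ValueError("mesher failure: no cells at the requested resolution")
    vertices, cells = _compress(vertices, cells)

    centroids = vertices[cells].mean(axis=1)
    inner = a - gray_thickness
    rho_inner = np.linalg.norm(centroids / inner[None, :], axis=1)
    label = np.where(rho_inner > 1.0, GRAY, WHITE)

    facets, _, _ = fem.boundary_facets(cells)
    fc = vertices[facets].mean(axis=1)
    threshold = 0.5 * (ventricle_radius + a.min())
    flabel = np.where(np.linalg.norm(fc, axis=1) < threshold, VENTRICLE, SAS)
    if ventricle_radius > 0 and not np.any(flabel == VENTRICLE):
        raise ValueError("mesher failure: ventricular cavity unresolved at this edge length")

    mesh = LabeledMesh(vertices, cells, label, facets, flabel, metadata={
        "generator": "synthetic_brain",
        "outer_semi_axes": a.tolist(),
        "gray_thickness": float(gray_thickness),
        "ventricle_radius": float(ventricle_radius),
        "target_edge_length": h,
    })
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# subregions
# ---------------------------------------------------------------------------

def define_spherical_subregion(mesh: LabeledMesh, center, radius: float,
                               restrict_to: str = "any") -> RegionMask:
    """Cell-set of all cells with centroid inside the sphere (and label)."""
    center = np.asarray(center, dtype=float)
    inside = np.linalg.norm(mesh.cell_centroids - center[None, :], axis=1) < radius
    if restrict_to == "gray":
        inside &= mesh.cell_label == GRAY
    elif restrict_to == "white":
        inside &= mesh.cell_label == WHITE
    elif restrict_to != "any":
        raise ValueError(f"unknown compartment {restrict_to!r}")
    members = np.flatnonzero(inside)
    if len(members) == 0:
        raise ValueError("empty subregion: sphere does not intersect the requested compartment")
    volume = float(mesh.cell_volumes[members].sum())
    return RegionMask("cell-set", members, volume)


def default_subregions(mesh: LabeledMesh, radius: float = 0.004):
    """Default gray/white regions of interest (S_g, S_w) at the z = 0 level.

    S_g sits 3 mm beneath the SAS surface along +y; S_w mid-way through the
    white core along +y.  Requires generator metadata on the mesh.  On
    meshes coarser than the nominal 4 mm radius the radius is floored at
    the edge length so the region always contains at least one cell.
    """
    md = mesh.metadata
    if md.get("generator") != "synthetic_brain":
        raise ValueError("default subregions are defined for the synthetic geometry only")
    a = np.asarray(md["outer_semi_axes"])
    t = md["gray_thickness"]
    rv = md["ventricle_radius"]
    radius = max(radius, md["target_edge_length"])
    s_g = define_spherical_subregion(mesh, (0.0, a[1] - 0.003, 0.0), radius, "gray")
    s_w = define_spherical_subregion(mesh, (0.0, 0.5 * (rv + a[1] - t), 0.0), radius, "white")
    return s_g, s_w


def region_volume(mesh: LabeledMesh, mask: RegionMask) -> float:
    """Volume of a cell-set region (sum of member cell volumes)."""
    if mask.kind != "cell-set":
        raise ValueError("region_volume requires a cell-set mask")
    if len(mask.members) == 0:
        raise ValueError("empty mask")
    return float(mesh.cell_volumes[mask.members].sum())


def compartment_mask(mesh: LabeledMesh, label: int) -> RegionMask:
    """Whole gray- or white-matter compartment as a RegionMask."""
    members = mesh.compartment_cells(label)
    return RegionMask("cell-set", members, float(mesh.cell_volumes[members].sum()))
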