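"""Low-level P1 finite-element primitives on tetrahedral meshes.

Everything here is plain numpy/scipy: signed tet volumes, shape-function
gradients, the (lumped) mass matrix, the stiffness matrix for a cellwise
diffusivity, and the convection operator for the divergence form
``div(v c)`` with nodal (P1) velocity.  All integrals over a tetrahedron
of products of P1 basis functions are evaluated with the exact formula

    int_K phi_i phi_j dx = V_K (1 + delta_ij) / 20.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

# local faces of a tet, face f is opposite local vertex f
_TET_FACES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


def tet_volumes(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Unsigned volumes of the tetrahedra, (ncells,)."""
    p = vertices[cells]
    e = p[:, 1:] - p[:, :1]
    det = np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2]))
    return np.abs(det) / 6.0


def shape_gradients(vertices: np.ndarray, cells: np.ndarray):
    """Gradients of the four P1 shape functions per cell.

    Returns ``(grads, volumes)`` with ``grads`` of shape (ncells, 4, 3);
    gradients are constant on each tet.
    """
    p = vertices[cells]  # (nc, 4, 3)
    e = p[:, 1:] - p[:, :1]  # edge matrix, row i = p_{i+1} - p_0
    det = np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2]))
    vol = np.abs(det) / 6.0
    # nodal values satisfy f_i - f_0 = E g for the cell gradient g, so
    # grad(phi_i) is the (i-1)-th column of inv(E) for i = 1..3
    g = np.linalg.inv(e).transpose(0, 2, 1)
    g0 = -g.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g], axis=1)
    return grads, vol


def lumped_mass(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Diagonal of the lumped mass matrix (row-sum lumping), (nvertices,).

    Entry i equals ``int_D phi_i dx``; the diagonal sums to the mesh volume.
    """
    vol = tet_volumes(vertices, cells)
    diag = np.zeros(len(vertices))
    np.add.at(diag, cells, (vol / 4.0)[:, None] * np.ones((1, 4)))
    return diag


def stiffness_matrix(vertices: np.ndarray, cells: np.ndarray,
                     diffusivity_cell: np.ndarray) -> sp.csr_matrix:
    """Assemble ``A_ij = int_D D grad(phi_j) . grad(phi_i) dx``.

    ``diffusivity_cell`` is a scalar per cell (nodal fields are averaged
    onto cells by the caller).  The result is symmetric positive
    semi-definite.
    """
    grads, vol = shape_gradients(vertices, cells)
    coef = np.asarray(diffusivity_cell, dtype=float) * vol
    local = np.einsum("kid,kjd->kij", grads, grads) * coef[:, None, None]
    rows = np.repeat(cells, 4, axis=1).reshape(-1)
    colsm = np.tile(cells, (1, 4)).reshape(-1)
    n = len(vertices)
    A = sp.coo_matrix((local.reshape(-1), (rows, colsm)), shape=(n, n))
    return A.tocsr()


def convection_matrix(vertices: np.ndarray, cells: np.ndarray,
                      v_nodal: np.ndarray) -> sp.csr_matrix:
    """Volume part of the weak divergence-form convection operator.

    Weak form of ``div(v c)`` tested against phi_i, after integration by
    parts: ``-int_D (v . grad phi_i) c dx`` plus a boundary term handled
    separately (see :func:`boundary_convection_matrix`).  With P1 velocity
    the element integral is exact:

        C^K_ij = -grad(phi_i) . [ (V/20) (sum_k v_k + v_j) ].
    """
    grads, vol = shape_gradients(vertices, cells)
    v = np.asarray(v_nodal, dtype=float)[cells]  # (nc, 4, 3)
    s = (v.sum(axis=1, keepdims=True) + v) * (vol / 20.0)[:, None, None]
    local = -np.einsum("kid,kjd->kij", grads, s)
    rows = np.repeat(cells, 4, axis=1).reshape(-1)
    colsm = np.tile(cells, (1, 4)).reshape(-1)
    n = len(vertices)
    C = sp.coo_matrix((local.reshape(-1), (rows, colsm)), shape=(n, n))
    return C.tocsr()


def boundary_facets(cells: np.ndarray):
    """Facets of the mesh boundary.

    Returns ``(facets, owner_cell, opposite_local)``: each boundary facet
    as a vertex triple (orientation arbitrary), the cell owning it, and the
    local index of the cell vertex opposite to it.  Raises ``ValueError``
    if any interior facet is shared by more than two cells
    (non-conforming mesh).
    """
    nc = len(cells)
    faces = cells[:, _TET_FACES]  # (nc, 4, 3)
    flat = np.sort(faces.reshape(-1, 3), axis=1)
    order = np.lexsort(flat.T[::-1])
    sorted_faces = flat[order]
    owner = np.repeat(np.arange(nc), 4)[order]
    local = np.tile(np.arange(4), nc)[order]
    # group identical facets
    new = np.ones(len(sorted_faces), dtype=bool)
    new[1:] = np.any(sorted_faces[1:] != sorted_faces[:-1], axis=1)
    group = np.cumsum(new) - 1
    counts = np.bincount(group)
    if counts.max(initial=0) > 2:
        raise ValueError("non-conforming mesh: a facet is shared by more than two cells")
    single = counts[group] == 1
    return sorted_faces[single], owner[single], local[single]


def facet_areas_normals(vertices: np.ndarray, cells: np.ndarray,
                        facets: np.ndarray, owner: np.ndarray):
    """Areas and outward unit normals of boundary facets."""
    p = vertices[facets]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = 0.5 * np.linalg.norm(n, axis=1)
    unit = n / np.linalg.norm(n, axis=1)[:, None]
    # orient outward: away from the owning cell's centroid
    cent_cell = vertices[cells[owner]].mean(axis=1)
    cent_face = p.mean(axis=1)
    flip = np.einsum("ij,ij->i", unit, cent_face - cent_cell) < 0
    unit[flip] *= -1.0
    return area, unit


def boundary_convection_matrix(vertices: np.ndarray, facets: np.ndarray,
                               areas: np.ndarray, normals: np.ndarray,
                               v_nodal: np.ndarray, nv: int) -> sp.csr_matrix:
    """Boundary term ``int (v.n) phi_i phi_j ds`` over the given facets.

    ``v.n`` is evaluated at the facet centroid (exact for facetwise-constant
    normal flux); the phi_i phi_j surface integral uses the exact triangle
    rule A (1 + delta_ij)/12.
    """
    if len(facets) == 0:
        return sp.csr_matrix((nv, nv))
    vc = np.asarray(v_nodal)[facets].mean(axis=1)  # centroid velocity
    vn = np.einsum("ij,ij->i", vc, normals) * areas
    base = (np.ones((3, 3)) + np.eye(3)) / 12.0
    local = vn[:, None, None] * base
    rows = np.repeat(facets, 3, axis=1).reshape(-1)
    colsm = np.tile(facets, (1, 3)).reshape(-1)
    B = sp.coo_matrix((local.reshape(-1), (rows, colsm)), shape=(nv, nv))
    return B.tocsr()


def facet_area_total(vertices: np.ndarray, facets: np.ndarray) -> float:
    p = vertices[facets]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return float(0.5 * np.linalg.norm(n, axis=1).sum())
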