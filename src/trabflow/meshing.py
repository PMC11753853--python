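"""Structured boundary-tagged meshes for the gap-channel geometry.

The domain is a union of axis-aligned boxes (channel plus groove), so the
mesh is generated as a tensor-product grid whose grid lines are snapped to
the crack edges, with cells outside the fluid region dropped.  Cells are
quadrilaterals (planar 2D) or hexahedra (full 3D); every boundary facet
carries exactly one of the tags

``inlet`` (x = 0), ``outlet`` (x = L), ``top_wall`` (z = H),
``bottom_wall`` (z = 0 outside the crack), ``crack_wall`` (groove faces)
and, in 3D, ``side_walls`` (y = 0 and y = W).

Node coordinates are stored in meters; the μm → m conversion happens here
and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import UM_TO_M, GapGeometry, GeometryError, build_geometry

__all__ = ["TaggedMesh", "generate_mesh", "write_vtk"]

TAG_NAMES = ("inlet", "outlet", "top_wall", "bottom_wall", "crack_wall", "side_walls")

# Local faces in tensor-corner ordering (x fastest, then y, then z).
# 2D: corner i = ix + 2*iz ; 3D: i = ix + 2*iy + 4*iz.
_FACES_2D = {0: ([0, 2], (-1.0, 0.0)), 1: ([1, 3], (1.0, 0.0)),
             2: ([0, 1], (0.0, -1.0)), 3: ([2, 3], (0.0, 1.0))}
_FACES_3D = {
    0: ([0, 2, 4, 6], (-1.0, 0.0, 0.0)),
    1: ([1, 3, 5, 7], (1.0, 0.0, 0.0)),
    2: ([0, 1, 4, 5], (0.0, -1.0, 0.0)),
    3: ([2, 3, 6, 7], (0.0, 1.0, 0.0)),
    4: ([0, 1, 2, 3], (0.0, 0.0, -1.0)),
    5: ([4, 5, 6, 7], (0.0, 0.0, 1.0)),
}


@dataclass
class TaggedMesh:
    """Conforming quad/hex mesh with a complete boundary-tag partition."""

    dim: int
    nodes: np.ndarray          # (Nv, dim) vertex coordinates, meters
    cells: np.ndarray          # (Nc, 2**dim) vertex ids, tensor-corner order
    cell_sizes: np.ndarray     # (Nc, dim) edge lengths hx(, hy), hz, meters
    facet_cell: np.ndarray     # (Nf,) owning cell of each boundary facet
    facet_face: np.ndarray     # (Nf,) local face id
    facet_tag: np.ndarray      # (Nf,) index into TAG_NAMES
    characteristic_size_um: float
    geometry: GapGeometry
    tag_names: tuple[str, ...] = field(default=TAG_NAMES)

    # -- derived facet geometry ------------------------------------------
    def facet_vertices(self) -> np.ndarray:
        """(Nf, 2**(dim-1)) vertex ids of each boundary facet."""
        faces = _FACES_2D if self.dim == 2 else _FACES_3D
        loc = np.array([faces[f][0] for f in self.facet_face])
        return self.cells[self.facet_cell[:, None], loc]

    def facet_centroids(self) -> np.ndarray:
        return self.nodes[self.facet_vertices()].mean(axis=1)

    def facet_normals(self) -> np.ndarray:
        faces = _FACES_2D if self.dim == 2 else _FACES_3D
        return np.array([faces[f][1] for f in self.facet_face])

    def facet_measures(self) -> np.ndarray:
        """Length (2D) or area (3D) of each boundary facet."""
        sizes = self.cell_sizes[self.facet_cell]
        axis = self.facet_face // 2
        m = np.ones(len(self.facet_cell))
        for d in range(self.dim):
            m = m * np.where(axis == d, 1.0, sizes[:, d])
        return m

    def facets_with_tag(self, tag: str) -> np.ndarray:
        if tag not in self.tag_names:
            raise KeyError(f"unknown boundary tag {tag!r}; have {self.tag_names}")
        return np.flatnonzero(self.facet_tag == self.tag_names.index(tag))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _axis_coords(segments: list[tuple[float, float, float]]) -> np.ndarray:
    """Uniform subdivision of each (a, b, h) segment, merged into one axis."""
    pts = []
    for a, b, h in segments:
        n = max(1, int(round((b - a) / h)))
        pts.append(np.linspace(a, b, n + 1))
    coords = np.unique(np.concatenate(pts))
    # collapse near-duplicate grid lines from floating merges
    keep = np.concatenate([[True], np.diff(coords) > 1e-9 * max(abs(coords).max(), 1.0)])
    return coords[keep]


def generate_mesh(
    geom: GapGeometry,
    target_size_um: float,
    refine_crack_factor: float = 0.25,
    *,
    target_size_y_um: float | None = None,
    target_size_z_um: float | None = None,
) -> TaggedMesh:
    """Generate a boundary-tagged tensor-product mesh for ``geom``.

    ``target_size_um`` is the nominal element edge length; cells in the
    crack x-band and inside the groove are refined to
    ``refine_crack_factor * target_size_um``.  The optional per-axis target
    overrides allow anisotropic cells (useful to keep 3D width-sweep meshes
    affordable while retaining resolution across the gap height).
    """
    geom = build_geometry(geom)
    if not target_size_um > 0:
        raise GeometryError(f"target_size_um must be positive, got {target_size_um}")
    if not 0 < refine_crack_factor <= 1:
        raise GeometryError("refine_crack_factor must be in (0, 1]")

    L, W, H = geom.length_um, geom.width_um, geom.height_um
    h = float(target_size_um)
    hy = float(target_size_y_um) if target_size_y_um else h
    hz = float(target_size_z_um) if target_size_z_um else h
    hr = h * refine_crack_factor
    hzr = hz * refine_crack_factor
    crack = geom.effective_crack

    if crack is None:
        xs = _axis_coords([(0.0, L, h)])
        zs = _axis_coords([(0.0, H, hz)])
    else:
        xl, xr = geom.crack_x_interval_um
        xs = _axis_coords([(0.0, xl, h), (xl, xr, hr), (xr, L, h)])
        zs = _axis_coords([(-crack.depth_um, 0.0, hzr), (0.0, H, hz)])
    axes = [xs, zs]
    if geom.dim == 3:
        if crack is not None and crack.span == "centered":
            yl = (W - crack.span_y_um) / 2.0
            ys = _axis_coords([(0.0, yl, hy), (yl, W - yl, hy), (W - yl, W, hy)])
        else:
            ys = _axis_coords([(0.0, W, hy)])
        axes = [xs, ys, zs]

    centers = [0.5 * (a[:-1] + a[1:]) for a in axes]
    shape = tuple(len(c) for c in centers)

    # activity mask over the structured cell grid
    xl_xr = geom.crack_x_interval_um
    if geom.dim == 2:
        xc, zc = np.meshgrid(centers[0], centers[1], indexing="ij")
        yc = None
    else:
        xc, yc, zc = np.meshgrid(centers[0], centers[1], centers[2], indexing="ij")
    active = zc > 0.0
    if crack is not None:
        in_crack = (xc > xl_xr[0]) & (xc < xl_xr[1]) & (zc < 0.0)
        if geom.dim == 3 and crack.span == "centered":
            yl = (W - crack.span_y_um) / 2.0
            in_crack &= (yc > yl) & (yc < W - yl)
        active |= in_crack
    if not active.any():
        raise GeometryError("degenerate geometry: no active cells")

    # vertex grid (structured), compressed to vertices used by active cells
    nv_shape = tuple(len(a) for a in axes)
    cell_idx = np.argwhere(active)  # (Nc, dim) structured cell indices
    # corners in tensor order: x fastest, then y, then z
    corner_offsets = np.array(
        [[(i >> d) & 1 for d in range(geom.dim)] for i in range(2 ** geom.dim)]
    )
    vert_multi = cell_idx[:, None, :] + corner_offsets[None, :, :]  # (Nc, 2**dim, dim)
    flat = np.ravel_multi_index(vert_multi.reshape(-1, geom.dim).T, nv_shape)
    used, inv = np.unique(flat, return_inverse=True)
    cells = inv.reshape(len(cell_idx), 2 ** geom.dim)
    unravel = np.unravel_index(used, nv_shape)
    nodes_um = np.stack([axes[d][unravel[d]] for d in range(geom.dim)], axis=1)
    nodes = nodes_um * UM_TO_M
    sizes_um = np.stack(
        [np.diff(axes[d])[cell_idx[:, d]] for d in range(geom.dim)], axis=1
    )
    cell_sizes = sizes_um * UM_TO_M

    # boundary facets: faces whose structured neighbor is inactive/outside
    lin_active = np.full(shape, -1, dtype=np.int64)
    lin_active[tuple(cell_idx.T)] = np.arange(len(cell_idx))
    f_cell, f_face = [], []
    n_faces = 2 * geom.dim
    for face in range(n_faces):
        d, side = face // 2, face % 2
        nb = cell_idx.copy()
        nb[:, d] += 1 if side else -1
        inside = (nb[:, d] >= 0) & (nb[:, d] < shape[d])
        has_nb = np.zeros(len(cell_idx), dtype=bool)
        has_nb[inside] = lin_active[tuple(nb[inside].T)] >= 0
        bnd = np.flatnonzero(~has_nb)
        f_cell.append(bnd)
        f_face.append(np.full(len(bnd), face))
    facet_cell = np.concatenate(f_cell)
    # map structured face axis (x, y, z) to local face ids used by _FACES_*
    if geom.dim == 2:
        # axes order here is (x, z): structured faces 0..3 == local 0..3
        facet_face = np.concatenate(f_face)
    else:
        facet_face = np.concatenate(f_face)

    mesh = TaggedMesh(
        dim=geom.dim,
        nodes=nodes,
        cells=cells,
        cell_sizes=cell_sizes,
        facet_cell=facet_cell,
        facet_face=facet_face.astype(np.int64),
        facet_tag=np.zeros(len(facet_cell), dtype=np.int64),
        characteristic_size_um=h,
        geometry=geom,
    )
    mesh.facet_tag = _tag_facets(mesh)
    return mesh


def _tag_facets(mesh: TaggedMesh) -> np.ndarray:
    g = mesh.geometry
    cen = mesh.facet_centroids() / UM_TO_M  # back to μm for comparisons
    tol = 1e-6 * max(g.length_um, g.height_um)
    x = cen[:, 0]
    z = cen[:, -1]
    tags = np.full(len(cen), -1, dtype=np.int64)
    tags[np.abs(x) < tol] = TAG_NAMES.index("inlet")
    tags[np.abs(x - g.length_um) < tol] = TAG_NAMES.index("outlet")
    if mesh.dim == 3:
        # y = 0 / y = W planes stay side_walls even where the groove meets
        # them (a full-width groove's end faces continue the side walls)
        untagged = tags < 0
        y = cen[:, 1]
        on_side = (np.abs(y) < tol) | (np.abs(y - g.width_um) < tol)
        tags[untagged & on_side] = TAG_NAMES.index("side_walls")
    untagged = tags < 0
    tags[untagged & (np.abs(z - g.height_um) < tol)] = TAG_NAMES.index("top_wall")
    untagged = tags < 0
    tags[untagged & (z < -tol)] = TAG_NAMES.index("crack_wall")
    untagged = tags < 0
    tags[untagged & (np.abs(z) < tol)] = TAG_NAMES.index("bottom_wall")
    if (tags < 0).any():
        bad = cen[tags < 0][:5]
        raise GeometryError(f"untagged boundary facets at (μm): {bad}")
    return tags


def write_vtk(
    path: str,
    mesh: TaggedMesh,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh (and optional nodal fields) as legacy ASCII VTK.

    Coordinates are in meters.  2D meshes are embedded in the z = 0 plane
    of the VTK file (the model's z axis maps to the file's y axis there).
    """
    nodes = mesh.nodes
    if mesh.dim == 2:
        xyz = np.column_stack([nodes, np.zeros(len(nodes))])
        # VTK_QUAD needs counter-clockwise corner order
        conn = mesh.cells[:, [0, 1, 3, 2]]
        cell_type = 9
    else:
        # VTK_HEXAHEDRON ordering: bottom CCW then top CCW
        xyz = nodes
        conn = mesh.cells[:, [0, 1, 3, 2, 4, 5, 7, 6]]
        cell_type = 12
    npts, ncell, k = len(xyz), len(conn), conn.shape[1]
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ntrabflow mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {npts} double\n")
        np.savetxt(f, xyz, fmt="%.9e")
        f.write(f"CELLS {ncell} {ncell * (k + 1)}\n")
        np.savetxt(f, np.column_stack([np.full(ncell, k), conn]), fmt="%d")
        f.write(f"CELL_TYPES {ncell}\n")
        np.savetxt(f, np.full(ncell, cell_type), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {npts}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.9e")
                else:
                    vec = arr
                    if vec.shape[1] == 2:
                        vec = np.column_stack([vec, np.zeros(len(vec))])
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, vec, fmt="%.9e")
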