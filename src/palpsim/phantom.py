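"""Synthetic abdomen phantom: voxel meshing, surface smoothing, liver-edge ROI.

The phantom is a rectangular block of lumped abdominal tissue ("flesh")
with an embedded ellipsoidal liver and a row of cylindrical rib bars,
meshed voxel-by-voxel into hexahedral elements.  It is a parametric
stand-in for a CT-segmented abdomen: geometry is explicit and every
classification is a closed-form predicate on voxel centres, which makes
the mesh easy to verify independently.

Coordinate convention: x–y is the palpation (skin) plane, z is depth with
the palpated surface at z = block_dims[2] and the fixed base at z = 0.
Lengths in mm, indices 0-based.  Element node ordering follows the VTK
hexahedron convention (nodes 0–3 on the lower z face, counter-clockwise,
then 4–7 above them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np

__all__ = [
    "Part",
    "PhantomConfig",
    "HexMesh",
    "PhantomConfigError",
    "SmoothingError",
    "build_phantom",
    "mesh_from_mask",
    "smooth_surface",
    "select_roi",
    "write_mesh",
    "read_mesh",
]


class Part(IntEnum):
    FLESH = 0
    RIB = 1
    LIVER = 2


class PhantomConfigError(ValueError):
    """Invalid phantom geometry."""


class SmoothingError(RuntimeError):
    """Surface smoothing inverted an element."""


# VTK hexahedron faces (local node indices of each quad).
_HEX_FACES = np.array(
    [
        [0, 3, 2, 1],  # -z
        [4, 5, 6, 7],  # +z
        [0, 1, 5, 4],  # -y
        [1, 2, 6, 5],  # +x
        [2, 3, 7, 6],  # +y
        [3, 0, 4, 7],  # -x
    ]
)

# Natural (xi, eta, zeta) coordinates of the 8 nodes.
_HEX_XI = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the default synthetic abdomen phantom (all lengths mm)."""

    block_dims: tuple[float, float, float] = (96.0, 72.0, 60.0)
    voxel_size: float = 6.0
    liver_center: tuple[float, float, float] = (48.0, 30.0, 42.0)
    liver_semiaxes: tuple[float, float, float] = (30.0, 16.0, 11.0)
    rib_count: int = 3
    rib_spacing: float = 12.0
    rib_radius: float = 4.0
    rib_first_y: float = 46.0
    rib_depth_z: float = 52.0
    smoothing_iterations: int = 2
    roi_band_mm: float = 12.0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise PhantomConfigError("voxel size must be positive")
        if self.roi_band_mm < 0:
            raise PhantomConfigError("ROI band width must be >= 0")
        c, a, d = np.array(self.liver_center), np.array(self.liver_semiaxes), np.array(self.block_dims)
        if np.any(c - a < 0) or np.any(c + a > d):
            raise PhantomConfigError("liver ellipsoid must lie fully inside the block")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(round(d / self.voxel_size)) for d in self.block_dims)


@dataclass
class HexMesh:
    """Hexahedral mesh with per-element part labels and a liver-edge ROI tag.

    node_coords: (N, 3) float mm; elements: (E, 8) int (VTK ordering);
    part_label: (E,) int (Part enum values); boundary_facets: (B, 4) int
    quads owned by exactly one element; fixed_node_set: (F,) int node ids
    with zero prescribed displacement.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    part_label: np.ndarray
    boundary_facets: np.ndarray
    fixed_node_set: np.ndarray
    roi_elements: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.node_coords[self.elements].mean(axis=1)

    def centroid_jacobians(self) -> np.ndarray:
        """det of the isoparametric Jacobian at each element centroid (mm^3/8)."""
        coords = self.node_coords[self.elements]  # (E, 8, 3)
        dn = _HEX_XI / 8.0  # dN_a/dxi at xi=0: (8, 3)
        jac = np.einsum("eai,aj->eij", coords, dn)
        return np.linalg.det(jac)

    def element_volumes(self) -> np.ndarray:
        """One-point-quadrature element volumes 8 * det J(0)."""
        return 8.0 * self.centroid_jacobians()

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def copy(self) -> "HexMesh":
        return HexMesh(
            node_coords=self.node_coords.copy(),
            elements=self.elements.copy(),
            part_label=self.part_label.copy(),
            boundary_facets=self.boundary_facets.copy(),
            fixed_node_set=self.fixed_node_set.copy(),
            roi_elements=self.roi_elements.copy(),
        )

    def validate(self) -> None:
        if self.n_elements == 0:
            raise PhantomConfigError("mesh has no elements")
        if self.elements.min() < 0 or self.elements.max() >= self.n_nodes:
            raise ValueError("element node index out of range")
        if np.any(self.centroid_jacobians() <= 0):
            raise ValueError("degenerate element (non-positive centroid Jacobian)")


def compute_boundary_facets(elements: np.ndarray, with_owners: bool = False):
    """Quad faces owned by exactly one element (recomputable oracle).

    With ``with_owners`` also returns the owning element id and the local
    face index of each boundary facet.
    """
    e = np.asarray(elements)
    faces = e[:, _HEX_FACES]  # (E, 6, 4)
    flat = faces.reshape(-1, 4)
    keys = np.sort(flat, axis=1)
    _, first, counts = np.unique(keys, axis=0, return_index=True, return_counts=True)
    sel = first[counts == 1]
    sel.sort()
    if not with_owners:
        return flat[sel]
    owners = sel // 6
    local = sel % 6
    return flat[sel], owners, local


def mesh_from_mask(mask: np.ndarray, voxel_size: float, origin=(0.0, 0.0, 0.0)) -> HexMesh:
    """Build a hexahedral mesh from a voxel occupancy/label mask.

    ``mask`` is an (nx, ny, nz) integer array; voxels with value < 0 are
    empty, values >= 0 become the element part label.  Nodes sit on the
    voxel lattice; only nodes referenced by an element are kept.  Nodes on
    the z = origin_z plane form the fixed set.
    """
    mask = np.asarray(mask)
    nx, ny, nz = mask.shape
    occupied = np.argwhere(mask >= 0)
    if len(occupied) == 0:
        raise PhantomConfigError("mask selects zero elements")

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = occupied.T
    elems_full = np.stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ],
        axis=1,
    )
    used, inv = np.unique(elems_full, return_inverse=True)
    elements = inv.reshape(elems_full.shape).astype(np.int64)
    gi = used // ((ny + 1) * (nz + 1))
    gj = (used // (nz + 1)) % (ny + 1)
    gk = used % (nz + 1)
    coords = np.stack([gi, gj, gk], axis=1).astype(float) * voxel_size + np.asarray(origin, float)
    labels = mask[i, j, k].astype(np.int64)
    boundary = compute_boundary_facets(elements)
    fixed = np.flatnonzero(np.isclose(coords[:, 2], origin[2]))
    mesh = HexMesh(
        node_coords=coords,
        elements=elements,
        part_label=labels,
        boundary_facets=boundary,
        fixed_node_set=fixed,
    )
    mesh.validate()
    return mesh


def _classify_voxels(config: PhantomConfig) -> np.ndarray:
    """Part label per voxel centre: liver ellipsoid, then rib bars, else flesh."""
    nx, ny, nz = config.grid_shape
    h = config.voxel_size
    cx = (np.arange(nx) + 0.5) * h
    cy = (np.arange(ny) + 0.5) * h
    cz = (np.arange(nz) + 0.5) * h
    x, y, z = np.meshgrid(cx, cy, cz, indexing="ij")
    lc, ls = np.asarray(config.liver_center), np.asarray(config.liver_semiaxes)
    liver = ((x - lc[0]) / ls[0]) ** 2 + ((y - lc[1]) / ls[1]) ** 2 + ((z - lc[2]) / ls[2]) ** 2 <= 1.0
    rib = np.zeros_like(liver)
    for b in range(config.rib_count):
        yb = config.rib_first_y + b * config.rib_spacing
        rib |= (y - yb) ** 2 + (z - config.rib_depth_z) ** 2 <= config.rib_radius**2
    labels = np.full((nx, ny, nz), int(Part.FLESH), dtype=np.int64)
    labels[rib] = int(Part.RIB)
    labels[liver] = int(Part.LIVER)
    return labels


def build_phantom(config: PhantomConfig | None = None) -> HexMesh:
    """Generate the voxel phantom mesh from a geometry config.

    Every voxel of the block becomes one hexahedral element; the element
    part is decided by its centre (inside the liver ellipsoid -> LIVER,
    inside a rib bar -> RIB, otherwise FLESH).  Bottom-face nodes are
    fixed.
    """
    config = config or PhantomConfig()
    labels = _classify_voxels(config)
    mesh = mesh_from_mask(labels, config.voxel_size)
    return mesh


# ---------------------------------------------------------------------------
# Surface smoothing
# ---------------------------------------------------------------------------


def _boundary_adjacency(mesh: HexMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge list of the boundary-facet graph (unique undirected edges)."""
    f = mesh.boundary_facets
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 3]], f[:, [3, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    nodes = np.unique(f)
    return nodes, edges[:, 0], edges[:, 1]


def smooth_surface(mesh: HexMesh, iterations: int) -> HexMesh:
    """Taubin lambda/mu smoothing of boundary nodes only.

    Each iteration applies an inflating-compensated pair of Laplacian
    steps (lambda = 0.5, mu = -0.53) over the boundary-edge graph, which
    removes voxel staircase jaggedness while approximately conserving
    volume.  Interior nodes are untouched.  Aborts if any element
    Jacobian becomes non-positive.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0:
        return out
    bnodes, ea, eb = _boundary_adjacency(mesh)
    deg = np.zeros(mesh.n_nodes)
    np.add.at(deg, ea, 1.0)
    np.add.at(deg, eb, 1.0)
    is_boundary = np.zeros(mesh.n_nodes, dtype=bool)
    is_boundary[bnodes] = True
    coords = out.node_coords

    def lap(c):
        acc = np.zeros_like(c)
        np.add.at(acc, ea, c[eb])
        np.add.at(acc, eb, c[ea])
        d = np.where(deg > 0, deg, 1.0)[:, None]
        delta = acc / d - c
        delta[~is_boundary] = 0.0
        return delta

    for it in range(iterations):
        coords = coords + 0.5 * lap(coords)
        coords = coords - 0.53 * lap(coords)
        out.node_coords = coords
        jac = out.centroid_jacobians()
        if np.any(jac <= 0):
            bad = int(np.argmin(jac))
            raise SmoothingError(
                f"smoothing iteration {it} inverted element {bad} (det J = {jac[bad]:.3e})"
            )
    return out


# ---------------------------------------------------------------------------
# Liver-edge region of interest
# ---------------------------------------------------------------------------


def liver_surface_facets(mesh: HexMesh) -> tuple[np.ndarray, np.ndarray]:
    """(owner element ids, facet centroids) of the liver part's surface.

    A liver surface facet is a face of a LIVER element not shared with
    another LIVER element (i.e. facing flesh, rib or the mesh exterior).
    """
    liver_ids = np.flatnonzero(mesh.part_label == int(Part.LIVER))
    if len(liver_ids) == 0:
        raise ValueError("mesh has no LIVER elements")
    sub = mesh.elements[liver_ids]
    faces = sub[:, _HEX_FACES].reshape(-1, 4)
    keys = np.sort(faces, axis=1)
    _, first, inv, counts = np.unique(
        keys, axis=0, return_index=True, return_inverse=True, return_counts=True
    )
    surf = counts[inv] == 1  # per flattened face
    owners = np.repeat(liver_ids, 6)[surf]
    centroids = mesh.node_coords[faces[surf]].mean(axis=1)
    return owners, centroids


def liver_edge_points(mesh: HexMesh, n_bins: int = 64) -> np.ndarray:
    """Sample points on the liver's anterior-inferior edge curve.

    The palpable liver edge is the rim where the anterior (top-facing)
    liver surface folds under: in plan view it is the outline of the
    liver on its inferior (-y) side.  We bin liver surface facet
    centroids by plan-view angle about the liver centroid, keep the
    inferior half, and take the outermost centroid per bin.
    """
    _, cents = liver_surface_facets(mesh)
    liver_ids = np.flatnonzero(mesh.part_label == int(Part.LIVER))
    center = mesh.element_centroids()[liver_ids].mean(axis=0)
    rel = cents[:, :2] - center[:2]
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    r = np.hypot(rel[:, 0], rel[:, 1])
    inferior = np.sin(theta) <= 0.0  # y below liver centre
    idx = np.flatnonzero(inferior)
    if len(idx) == 0:
        raise ValueError("liver surface has no inferior-side facets")
    bins = np.clip(((theta[idx] + np.pi) / np.pi * n_bins).astype(int), 0, n_bins - 1)
    pts = []
    for b in range(n_bins):
        sel = idx[bins == b]
        if len(sel):
            pts.append(cents[sel[np.argmax(r[sel])]])
    return np.array(pts)


def select_roi(mesh: HexMesh, band_mm: float) -> np.ndarray:
    """Liver elements whose surface facet centroid lies within ``band_mm``
    of the anterior-inferior liver edge curve.

    Returns a sorted, deterministic element-id array.  A non-positive band
    or an empty result is an error (the surrogate output dimension would
    be undefined).
    """
    if band_mm <= 0:
        raise ValueError("ROI band width must be positive")
    owners, cents = liver_surface_facets(mesh)
    edge = liver_edge_points(mesh)
    d = np.linalg.norm(cents[:, None, :] - edge[None, :, :], axis=-1).min(axis=1)
    ids = np.unique(owners[d <= band_mm])
    if len(ids) == 0:
        raise ValueError(f"ROI band of {band_mm} mm selects no liver elements")
    return ids


def tag_roi(mesh: HexMesh, band_mm: float | None = None) -> HexMesh:
    """Return a copy of the mesh with roi_elements filled in."""
    band = PhantomConfig().roi_band_mm if band_mm is None else band_mm
    out = mesh.copy()
    out.roi_elements = select_roi(mesh, band)
    return out


# ---------------------------------------------------------------------------
# Legacy-VTK unstructured-grid I/O (ASCII)
# ---------------------------------------------------------------------------


def write_mesh(mesh: HexMesh, path, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid.

    Cell fields ``part_label`` and ``roi_flag`` are always written; a
    point field ``fixed_flag`` preserves the fixed node set.  Extra cell
    fields (e.g. stress components) can be passed via ``cell_data``.
    """
    path = Path(path)
    n, e = mesh.n_nodes, mesh.n_elements
    roi_flag = np.zeros(e, dtype=int)
    roi_flag[mesh.roi_elements] = 1
    fixed_flag = np.zeros(n, dtype=int)
    fixed_flag[mesh.fixed_node_set] = 1
    fields: dict[str, np.ndarray] = {"part_label": mesh.part_label, "roi_flag": roi_flag}
    if cell_data:
        fields.update(cell_data)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\npalpsim phantom\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, mesh.node_coords, fmt="%.10g")
        fh.write(f"CELLS {e} {e * 9}\n")
        cells = np.column_stack([np.full(e, 8), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {e}\n")
        np.savetxt(fh, np.full(e, 12), fmt="%d")
        fh.write(f"CELL_DATA {e}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            if np.issubdtype(arr.dtype, np.integer):
                fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr, fmt="%d")
            else:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr, fmt="%.10g")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS fixed_flag int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, fixed_flag, fmt="%d")


def read_mesh(path) -> tuple[HexMesh, dict[str, np.ndarray]]:
    """Read a mesh written by :func:`write_mesh`.

    Returns the mesh and any extra cell fields beyond part/roi labels.
    """
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_nodes = n_cells = 0
    coords = cells = None
    cell_fields: dict[str, np.ndarray] = {}
    point_fields: dict[str, np.ndarray] = {}

    def read_block(start: int, count: int, per_line: int) -> tuple[np.ndarray, int]:
        vals: list[float] = []
        j = start
        while len(vals) < count * per_line:
            vals.extend(float(t) for t in lines[j].split())
            j += 1
        return np.array(vals).reshape(count, per_line), j

    mode = None
    n_data = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n_nodes = int(parts[1])
            coords, i = read_block(i + 1, n_nodes, 3)
            continue
        if key == "CELLS":
            n_cells = int(parts[1])
            raw, i = read_block(i + 1, n_cells, 9)
            cells = raw[:, 1:].astype(np.int64)
            continue
        if key == "CELL_TYPES":
            _, i = read_block(i + 1, int(parts[1]), 1)
            continue
        if key == "CELL_DATA":
            mode, n_data = "cell", int(parts[1])
            i += 1
            continue
        if key == "POINT_DATA":
            mode, n_data = "point", int(parts[1])
            i += 1
            continue
        if key == "SCALARS":
            name, dtype = parts[1], parts[2]
            arr, i = read_block(i + 2, n_data, 1)  # skip LOOKUP_TABLE line
            arr = arr[:, 0]
            if dtype == "int":
                arr = arr.astype(np.int64)
            (cell_fields if mode == "cell" else point_fields)[name] = arr
            continue
        i += 1
    if coords is None or cells is None:
        raise ValueError(f"{path}: not a legacy VTK unstructured grid")
    part = cell_fields.pop("part_label").astype(np.int64)
    roi_flag = cell_fields.pop("roi_flag", np.zeros(n_cells, dtype=np.int64))
    fixed_flag = point_fields.get("fixed_flag", np.zeros(n_nodes, dtype=np.int64))
    mesh = HexMesh(
        node_coords=coords,
        elements=cells,
        part_label=part,
        boundary_facets=compute_boundary_facets(cells),
        fixed_node_set=np.flatnonzero(fixed_flag),
        roi_elements=np.flatnonzero(roi_flag),
    )
    return mesh, cell_fields
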