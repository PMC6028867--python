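"""First-order hexahedral meshes of the polymer unit cell.

The polymer block occupies ``0 <= x <= w``, ``0 <= y <= l`` and
``s(x, y) <= z <= D`` where ``s`` is the depth of the conical imprint left by
the titanium feature (z is depth into the polymer, z = 0 at the nominal
interface plane, z = D at the fixed bottom).  Meshing is a structured grid
with a terrain-following vertical mapping: each node column is squeezed
between the local imprint surface and the bottom, so the top node sheet lies
*exactly* on the imprint geometry (body-fitted) and all Jacobians stay
positive by construction.

Node numbering of the 8-node hex follows the VTK convention: nodes 0-3 on the
ζ=-1 face counterclockwise (when looking along +ζ), nodes 4-7 above them.
Element activity flags implement element-death fracture: deactivated elements
contribute neither stiffness nor volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surface import ConeFeature, GeometryError, UnitCell

__all__ = [
    "HexMesh",
    "NodeSets",
    "MeshingError",
    "build_unit_cell_mesh",
    "build_fixture_mesh",
    "mesh_volume",
    "element_volumes",
    "export_vtk",
    "export_msh",
]


class MeshingError(GeometryError):
    """Mesh generation produced invalid (e.g. inverted) elements."""


# reference-element Gauss points (2x2x2) and trilinear shape gradients
_GP = np.array([[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)],
               dtype=float) / np.sqrt(3.0)
_CORNERS = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape-function gradients dN/dξ at points ``xi`` (g, 3) -> (g, 8, 3)."""
    xi = np.atleast_2d(xi)
    g = xi.shape[0]
    out = np.empty((g, 8, 3))
    for n in range(8):
        cx, cy, cz = _CORNERS[n]
        out[:, n, 0] = cx * (1 + cy * xi[:, 1]) * (1 + cz * xi[:, 2]) / 8.0
        out[:, n, 1] = cy * (1 + cx * xi[:, 0]) * (1 + cz * xi[:, 2]) / 8.0
        out[:, n, 2] = cz * (1 + cx * xi[:, 0]) * (1 + cy * xi[:, 1]) / 8.0
    return out


_DN_GP = shape_gradients(_GP)  # (8 gp, 8 nodes, 3)


@dataclass
class HexMesh:
    """First-order hexahedral mesh with per-element activity flags.

    Attributes
    ----------
    nodes : (N, 3) float array, µm
    elems : (E, 8) int array, VTK hex connectivity
    active : (E,) bool array; all true at construction
    """

    nodes: np.ndarray
    elems: np.ndarray
    active: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elems = np.ascontiguousarray(self.elems, dtype=np.int64)
        if self.elems.ndim != 2 or self.elems.shape[1] != 8:
            raise ValueError("elems must be (E, 8)")
        if self.elems.min(initial=0) < 0 or self.elems.max(initial=-1) >= len(self.nodes):
            raise ValueError("connectivity index out of range")
        if self.active is None:
            self.active = np.ones(len(self.elems), dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool).copy()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    def element_coords(self, which: np.ndarray | None = None) -> np.ndarray:
        """Corner coordinates (E, 8, 3) of the selected (default all) elements."""
        e = self.elems if which is None else self.elems[which]
        return self.nodes[e]

    def attached_nodes(self, active_only: bool = True) -> np.ndarray:
        """Sorted indices of nodes belonging to at least one (active) element."""
        e = self.elems[self.active] if active_only else self.elems
        return np.unique(e)

    def copy(self) -> "HexMesh":
        other = HexMesh(self.nodes.copy(), self.elems.copy(), self.active.copy())
        # geometry-derived caches remain valid (activity flags are not cached)
        for attr in ("_volume_cache", "_fem_geom_cache", "_fem_ke_cache"):
            if hasattr(self, attr):
                setattr(other, attr, getattr(self, attr))
        return other


@dataclass
class NodeSets:
    """Named boundary node-index sets of the unit-cell (or fixture) mesh."""

    bottom: np.ndarray
    side_x_min: np.ndarray
    side_x_max: np.ndarray
    side_y_min: np.ndarray
    side_y_max: np.ndarray
    imprint_surface: np.ndarray


def _jacobians(coords: np.ndarray) -> np.ndarray:
    """det J at the 8 Gauss points for element corner blocks (E, 8, 3)."""
    J = np.einsum("gna,enb->egab", _DN_GP, coords)
    return np.linalg.det(J)


def element_volumes(mesh: HexMesh) -> np.ndarray:
    """Per-element volume (µm³) by 8-point Gauss integration of det J.

    Cached on the mesh: element geometry never changes after construction
    (fracture only flips activity flags).
    """
    cached = getattr(mesh, "_volume_cache", None)
    if cached is None:
        cached = _jacobians(mesh.element_coords()).sum(axis=1)  # unit weights
        mesh._volume_cache = cached
    return cached


def mesh_volume(mesh: HexMesh, active_only: bool = True) -> float:
    """Total (active) mesh volume in µm³."""
    vols = element_volumes(mesh)
    if active_only:
        vols = vols[mesh.active]
    return float(vols.sum())


def _structured_connectivity(nx: int, ny: int, nz: int) -> np.ndarray:
    def nid(i, j, k):
        return (k * (ny + 1) + j) * (nx + 1) + i

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    conn = np.stack([
        nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
        nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
        nid(i, j + 1, k + 1),
    ], axis=1)
    return conn


def _structured_sets(nx: int, ny: int, nz: int) -> NodeSets:
    I, J, K = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1),
                          indexing="ij")
    nid = (K * (ny + 1) + J) * (nx + 1) + I

    return NodeSets(
        bottom=np.sort(nid[:, :, nz].ravel()),
        side_x_min=np.sort(nid[0, :, :].ravel()),
        side_x_max=np.sort(nid[nx, :, :].ravel()),
        side_y_min=np.sort(nid[:, 0, :].ravel()),
        side_y_max=np.sort(nid[:, ny, :].ravel()),
        imprint_surface=np.sort(nid[:, :, 0].ravel()),
    )


def build_unit_cell_mesh(cone: ConeFeature, cell: UnitCell,
                         target_elem_size_um: float) -> tuple[HexMesh, NodeSets]:
    """Body-fitted structured hex mesh of the polymer block with a conical pit.

    The number of divisions per axis is the cell dimension over the target
    element size (rounded, at least 2 in-plane / enough in depth).  Node
    columns are mapped between the local imprint depth ``s(x, y)`` and the
    substrate bottom, so the top node sheet coincides with the imprint
    surface.
    """
    if target_elem_size_um <= 0:
        raise ValueError("target_elem_size_um must be > 0")
    if cone.base_radius_um > 0 and target_elem_size_um >= cone.base_radius_um:
        raise ValueError("target element size must be smaller than the cone base radius")
    from .surface import _check_cone_fits  # shared validation
    _check_cone_fits(cone, cell)
    if cone.height_um >= cell.substrate_depth_um:
        raise GeometryError(
            f"cone height {cone.height_um} µm must be smaller than the substrate "
            f"depth {cell.substrate_depth_um} µm")

    w, l, D = cell.width_um, cell.length_um, cell.substrate_depth_um
    nx = max(2, round(w / target_elem_size_um))
    ny = max(2, round(l / target_elem_size_um))

    x = np.linspace(0.0, w, nx + 1)
    y = np.linspace(0.0, l, ny + 1)
    cx, cy = cone.apex_in(cell)
    r = np.hypot(x[:, None] - cx, y[None, :] - cy)
    if cone.base_radius_um > 0:
        s = np.maximum(0.0, cone.height_um * (1.0 - r / cone.base_radius_um))
    else:
        s = np.zeros_like(r)

    # the body-fitted (terrain-following) transition is confined to a band
    # just below the feature, meshed at the target size; below it the layer
    # height grows geometrically (ratio 1.5).  Changing the substrate depth
    # therefore leaves the near-interface mesh bit-identical and adds only a
    # few coarse layers, which carry smooth far-field shear only.
    band = target_elem_size_um * np.ceil(
        (cone.height_um + 2 * target_elem_size_um) / target_elem_size_um)
    if band >= D:
        band = D
        n_band = max(2, round(D / target_elem_size_um))
        below = np.empty(0)
    else:
        n_band = max(2, round(band / target_elem_size_um))
        below = _graded_layers(D - band, target_elem_size_um, ratio=1.5)
    nz = n_band + len(below)

    z_col = np.empty((nx + 1, ny + 1, nz + 1))
    frac = np.arange(n_band + 1) / n_band
    z_col[:, :, :n_band + 1] = (s[:, :, None]
                                + (band - s[:, :, None]) * frac[None, None, :])
    if len(below):
        z_col[:, :, n_band + 1:] = band + np.cumsum(below)[None, None, :]

    # nodes ordered k-major to match _structured_connectivity's nid()
    X = np.broadcast_to(x[:, None, None], (nx + 1, ny + 1, nz + 1))
    Y = np.broadcast_to(y[None, :, None], (nx + 1, ny + 1, nz + 1))
    nodes = np.stack([X, Y, z_col], axis=-1).transpose(2, 1, 0, 3).reshape(-1, 3)

    mesh = HexMesh(nodes, _structured_connectivity(nx, ny, nz))
    detJ = _jacobians(mesh.element_coords())
    bad = int(np.count_nonzero(detJ.min(axis=1) <= 0))
    if bad:
        raise MeshingError(f"{bad} elements have non-positive Jacobians after "
                           f"imprint projection; reduce the element size")
    return mesh, _structured_sets(nx, ny, nz)


def _graded_layers(thickness: float, first: float, ratio: float = 1.5
                   ) -> np.ndarray:
    """Layer heights growing geometrically from ``first``; the remainder is
    absorbed by the deepest layer so the shallow layers are identical for
    every substrate depth (only the far field coarsens)."""
    heights: list[float] = []
    while sum(heights) < thickness:
        heights.append((heights[-1] * ratio) if heights else first)
    rest = thickness - sum(heights[:-1])
    if len(heights) > 1 and rest < 0.5 * heights[-2]:
        heights.pop()
        heights[-1] += rest
    else:
        heights[-1] = rest
    return np.array(heights)


_FIXTURES = ("single_element", "block", "cantilever")


def build_fixture_mesh(kind: str, dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       divisions: tuple[int, int, int] = (1, 1, 1),
                       ) -> tuple[HexMesh, NodeSets]:
    """Canonical box meshes for patch, uniaxial, and bending verification.

    ``single_element`` ignores ``divisions`` (one hex).  ``cantilever``
    defaults to a 10 x 1 x 1 beam with 40 x 4 x 4 divisions unless overridden.
    """
    if kind not in _FIXTURES:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {_FIXTURES}")
    if kind == "single_element":
        divisions = (1, 1, 1)
    elif kind == "cantilever" and divisions == (1, 1, 1):
        dims = (10.0, 1.0, 1.0)
        divisions = (40, 4, 4)
    nx, ny, nz = divisions
    w, l, D = dims
    x = np.linspace(0.0, w, nx + 1)
    y = np.linspace(0.0, l, ny + 1)
    z = np.linspace(0.0, D, nz + 1)
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    mesh = HexMesh(nodes, _structured_connectivity(nx, ny, nz))
    return mesh, _structured_sets(nx, ny, nz)


# ---------------------------------------------------------------------------
# Plain-text mesh export
# ---------------------------------------------------------------------------

def export_vtk(mesh: HexMesh, path, cell_data: dict[str, np.ndarray] | None = None,
               point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh as a VTK legacy ASCII unstructured grid (coordinates µm).

    Element activity is always exported as the cell scalar ``active``.
    """
    cd = {"active": mesh.active.astype(float)}
    if cell_data:
        cd.update({k: np.asarray(v, dtype=float) for k, v in cell_data.items()})
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("torquecell mesh (units: um)\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.10g")
        fh.write(f"CELLS {mesh.n_elems} {mesh.n_elems * 9}\n")
        np.savetxt(fh, np.hstack([np.full((mesh.n_elems, 1), 8), mesh.elems]), fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_elems}\n")
        fh.write("\n".join(["12"] * mesh.n_elems) + "\n")
        fh.write(f"CELL_DATA {mesh.n_elems}\n")
        for name, vals in cd.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, vals, fmt="%.10g")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, vals in point_data.items():
                vals = np.asarray(vals, dtype=float)
                if vals.ndim == 2 and vals.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, vals, fmt="%.10g")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, vals, fmt="%.10g")


def export_msh(mesh: HexMesh, path) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII format (coordinates µm)."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {x:.10g} {y:.10g} {z:.10g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_elems}\n")
        for e, conn in enumerate(mesh.elems, start=1):
            tag = int(mesh.active[e - 1])
            nodes = " ".join(str(n + 1) for n in conn)
            fh.write(f"{e} 5 2 {tag} 0 {nodes}\n")
        fh.write("$EndElements\n")
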