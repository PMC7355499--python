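"""Catheter geometry, surface meshes and geodesic distance fields.

The mapping catheter modelled here is a PentaRay-style device: 20 electrodes
spaced along five branches, grouped into an inner and an outer loop of five
bipolar pairs each.  Bipolar pairs carry odd indices — 1, 3, 5, 7, 9 on the
inner loop and 11, 13, 15, 17, 19 on the outer loop — and pair ``k + 10``
lies on the same branch as pair ``k``.

Distances along the cardiac surface are approximated by shortest paths on
the triangle-mesh edge graph (Dijkstra).  In planar mode (no mesh) the
geodesic distance degenerates to the Euclidean distance, which keeps
closed-form oracles available for the localization solver.

All coordinates are 3-D and in millimetres.  Vertex ids are 0-based in
memory and 1-based in files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "Electrode",
    "BipolarPair",
    "CatheterLayout",
    "SurfaceMesh",
    "GeodesicField",
    "InvalidGeometryError",
    "MeshFormatError",
    "build_pentaray_layout",
    "pair_channels",
    "load_surface_mesh",
    "geodesic_field",
    "snap_to_surface",
    "layout_from_json",
    "layout_to_json",
]

INNER_PAIR_INDICES = (1, 3, 5, 7, 9)
OUTER_PAIR_INDICES = (11, 13, 15, 17, 19)
N_BRANCHES = 5
PAIRS_PER_LOOP = 5  # D in the multinomial model


class InvalidGeometryError(ValueError):
    """Raised for impossible catheter geometry (e.g. inverted loop radii)."""


class MeshFormatError(ValueError):
    """Raised when a surface mesh file cannot be read or fails validation."""


@dataclass(frozen=True)
class Electrode:
    """A single catheter electrode."""

    electrode_id: int  # 1..20
    branch: int  # 1..5
    loop: str  # "inner" | "outer"
    position: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass(frozen=True)
class BipolarPair:
    """Two adjacent electrodes whose signal difference forms one channel."""

    pair_index: int  # odd; inner 1..9, outer 11..19
    loop: str
    member_electrodes: tuple[int, int]
    midpoint: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "midpoint", np.asarray(self.midpoint, dtype=float))


@dataclass(frozen=True)
class CatheterLayout:
    """Full 20-electrode, 10-pair catheter layout."""

    electrodes: tuple[Electrode, ...]
    pairs: tuple[BipolarPair, ...]
    center: np.ndarray
    orientation: float  # rotation about the surface normal, radians
    inner_radius: float
    outer_radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if len(self.electrodes) != 4 * N_BRANCHES:
            raise InvalidGeometryError(f"expected 20 electrodes, got {len(self.electrodes)}")
        if len(self.pairs) != 2 * PAIRS_PER_LOOP:
            raise InvalidGeometryError(f"expected 10 pairs, got {len(self.pairs)}")

    @property
    def pair_midpoints(self) -> np.ndarray:
        """(10, 3) midpoints in ascending pair_index order."""
        ordered = sorted(self.pairs, key=lambda p: p.pair_index)
        return np.stack([p.midpoint for p in ordered])

    @property
    def pair_indices(self) -> np.ndarray:
        return np.array(sorted(p.pair_index for p in self.pairs))

    def midpoint_of(self, pair_index: int) -> np.ndarray:
        for p in self.pairs:
            if p.pair_index == pair_index:
                return p.midpoint
        raise KeyError(f"no bipolar pair with index {pair_index}")


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface with a connected edge graph."""

    vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=int))
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshFormatError("vertices must be an (V, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshFormatError("faces must be an (F, 3) array")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshFormatError(
                f"face index out of range: faces reference vertex {int(f.max())} "
                f"but the mesh has {len(v)} vertices"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edge_graph(self):
        """Sparse symmetric matrix of edge lengths (each edge stored once
        per direction — shared face edges must not double the weight)."""
        f = self.faces
        i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        edges = np.unique(np.sort(np.column_stack([i, j]), axis=1), axis=0)
        i, j = edges[:, 0], edges[:, 1]
        w = np.linalg.norm(self.vertices[i] - self.vertices[j], axis=1)
        n = self.n_vertices
        g = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        )
        return g.tocsr()


@dataclass(frozen=True)
class GeodesicField:
    """Shortest-path distance from a seed vertex to every mesh vertex."""

    seed: int
    distance_per_vertex: np.ndarray  # (V,) mm; +inf for unreachable vertices


def build_pentaray_layout(
    center=(0.0, 0.0, 0.0),
    orientation: float = 0.0,
    inner_radius: float = 5.0,
    outer_radius: float = 15.0,
    electrode_gap: float = 2.0,
) -> CatheterLayout:
    """Construct the 20-electrode, 5-branch, two-loop catheter layout.

    Branches radiate from ``center`` at 72° spacing starting at angle
    ``orientation``; each branch holds an inner bipolar pair centred at
    ``inner_radius`` and an outer pair centred at ``outer_radius``, with
    ``electrode_gap`` mm between the two electrodes of a pair.  The layout
    lies in the z = 0 plane through ``center`` (surface snapping, when a
    mesh is used, happens downstream).
    """
    if inner_radius <= 0 or outer_radius <= 0:
        raise InvalidGeometryError("loop radii must be positive")
    if inner_radius >= outer_radius:
        raise InvalidGeometryError(
            f"inner radius ({inner_radius} mm) must be smaller than outer radius ({outer_radius} mm)"
        )
    if electrode_gap <= 0 or electrode_gap >= 2 * inner_radius:
        raise InvalidGeometryError("electrode gap must be positive and smaller than the inner loop diameter")

    center = np.asarray(center, dtype=float)
    half = electrode_gap / 2.0
    electrodes: list[Electrode] = []
    pairs: list[BipolarPair] = []
    for b in range(N_BRANCHES):
        theta = orientation + 2.0 * np.pi * b / N_BRANCHES
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        # electrode ids 4b+1..4b+4, ordered proximal to distal along the branch
        radii = [inner_radius - half, inner_radius + half, outer_radius - half, outer_radius + half]
        loops = ["inner", "inner", "outer", "outer"]
        ids = [4 * b + k for k in (1, 2, 3, 4)]
        for eid, r, lp in zip(ids, radii, loops):
            electrodes.append(Electrode(eid, b + 1, lp, center + r * u))
        pairs.append(
            BipolarPair(2 * b + 1, "inner", (ids[0], ids[1]), center + inner_radius * u)
        )
        pairs.append(
            BipolarPair(2 * b + 11, "outer", (ids[2], ids[3]), center + outer_radius * u)
        )
    return CatheterLayout(
        electrodes=tuple(electrodes),
        pairs=tuple(pairs),
        center=center,
        orientation=float(orientation),
        inner_radius=float(inner_radius),
        outer_radius=float(outer_radius),
    )


def pair_channels(layout: CatheterLayout, loop: str | None = None) -> list[BipolarPair]:
    """The 10 bipolar channels in ascending pair-index order.

    With ``loop`` set to ``"inner"`` or ``"outer"`` only that loop's five
    channels are returned.
    """
    chans = sorted(layout.pairs, key=lambda p: p.pair_index)
    if loop is not None:
        if loop not in ("inner", "outer"):
            raise ValueError(f"unknown loop {loop!r}")
        chans = [c for c in chans if c.loop == loop]
    return chans


def load_surface_mesh(path) -> SurfaceMesh:
    """Read an OFF or ascii-PLY triangle mesh and validate its connectivity."""
    path = Path(path)
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # trimesh raises a zoo of exception types
        raise MeshFormatError(f"cannot read mesh {path}: {exc}") from exc
    if not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangular faces")
    mesh = SurfaceMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=int))
    n_comp, _ = connected_components(mesh.edge_graph(), directed=False)
    if n_comp != 1:
        raise MeshFormatError(f"{path}: edge graph has {n_comp} connected components, expected 1")
    return mesh


def geodesic_field(mesh: SurfaceMesh, seed_vertex: int) -> GeodesicField:
    """Dijkstra shortest-path distances along mesh edges from ``seed_vertex``.

    Edge-graph geodesics overestimate true polyhedral geodesics by a
    discretization factor bounded by the mesh's triangle quality; at the
    noise level of activation-time data this bias is immaterial and the
    computation is exactly reproducible.
    """
    if not (0 <= seed_vertex < mesh.n_vertices):
        raise IndexError(f"seed vertex {seed_vertex} out of range for mesh with {mesh.n_vertices} vertices")
    dist = dijkstra(mesh.edge_graph(), directed=False, indices=seed_vertex)
    if np.isinf(dist).any():
        warnings.warn("mesh has vertices unreachable from the seed; their distance is +inf", stacklevel=2)
    return GeodesicField(seed=int(seed_vertex), distance_per_vertex=dist)


def snap_to_surface(layout: CatheterLayout, mesh: SurfaceMesh) -> dict[int, int]:
    """Map each bipolar-pair midpoint to its nearest mesh vertex.

    Ties are broken toward the smallest vertex id (``argmin`` order).
    """
    out: dict[int, int] = {}
    for p in sorted(layout.pairs, key=lambda q: q.pair_index):
        d = np.linalg.norm(mesh.vertices - p.midpoint, axis=1)
        out[p.pair_index] = int(np.argmin(d))
    return out


def layout_to_json(layout: CatheterLayout, path) -> None:
    """Write a layout description as JSON (1-based ids, mm, radians)."""
    doc = {
        "center": list(map(float, layout.center)),
        "orientation_rad": layout.orientation,
        "inner_radius_mm": layout.inner_radius,
        "outer_radius_mm": layout.outer_radius,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def layout_from_json(path) -> CatheterLayout:
    doc = json.loads(Path(path).read_text())
    return build_pentaray_layout(
        center=doc["center"],
        orientation=doc["orientation_rad"],
        inner_radius=doc["inner_radius_mm"],
        outer_radius=doc["outer_radius_mm"],
    )
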