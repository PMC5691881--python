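"""Robust 3D geometric primitives for vertebral morphometry.

Conventions used throughout the package: coordinates are millimetres in a
right-handed frame, directions are unit 3-vectors, and angles are degrees at
the API surface (radians internally).  Points and directions are plain numpy
arrays of shape ``(3,)``; a *rim* is an ordered closed polyline stored as an
``(n, 3)`` array whose last vertex implicitly connects back to the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REGION_WALL",
    "REGION_UPPER",
    "REGION_LOWER",
    "Plane",
    "TriMesh",
    "unit",
    "volume_centroid",
    "fit_plane_tls",
    "point_plane_distance",
    "rotation_matrix",
    "rotate_direction",
    "rotate_point",
    "rotate_plane",
    "rotate_about_axis",
    "plane_rim_intersections",
    "extract_endplate",
]

#: Per-vertex region labels carried by labeled vertebral-body meshes.
REGION_WALL = 0
REGION_UPPER = 1
REGION_LOWER = 2

# Consistent tie-break for vertices lying exactly on a cutting plane: the
# signed distance is shifted by this amount so each geometric crossing of a
# rim yields exactly one intersection point.
_ON_PLANE_PERTURBATION = 1e-12


def unit(v, name: str = "vector") -> np.ndarray:
    """Return ``v`` normalized to unit length, raising on (near-)zero input."""
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError(f"cannot normalize near-zero {name} (norm={n:g})")
    return v / n


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``n . p = offset`` with unit normal ``n`` (mm)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = unit(self.normal, "plane normal")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    @classmethod
    def from_point_normal(cls, point, normal) -> "Plane":
        n = unit(normal, "plane normal")
        return cls(n, float(n @ np.asarray(point, dtype=float)))

    def signed_distance(self, points):
        """Signed distance of one point or an ``(n, 3)`` array of points."""
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def distance(self, points):
        return np.abs(self.signed_distance(points))


@dataclass
class TriMesh:
    """Triangle mesh with optional per-vertex region labels.

    ``region`` uses the integer labels ``REGION_WALL`` (0),
    ``REGION_UPPER`` (1) and ``REGION_LOWER`` (2).
    """

    vertices: np.ndarray
    faces: np.ndarray
    region: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of vertex indices")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertices contain non-finite coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("faces index out-of-range vertices")
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=np.int64)
            if self.region.shape != (len(self.vertices),):
                raise ValueError("region labels must be one integer per vertex")

    def open_edge_count(self) -> int:
        """Number of undirected edges not shared by exactly two faces."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.count_nonzero(counts != 2))

    @property
    def is_watertight(self) -> bool:
        return self.open_edge_count() == 0

    @property
    def is_winding_consistent(self) -> bool:
        directed = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        uniq = np.unique(directed, axis=0)
        return len(uniq) == len(directed)

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        lens = np.linalg.norm(n, axis=1)
        lens[lens == 0] = 1.0
        return n / lens[:, None]

    def transformed(self, rotation=None, translation=None, scale=None) -> "TriMesh":
        """Rigidly (plus optional uniform scale) transformed copy."""
        v = self.vertices
        if scale is not None:
            v = v * float(scale)
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        region = None if self.region is None else self.region.copy()
        return TriMesh(v, self.faces.copy(), region)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


def volume_centroid(mesh: TriMesh) -> np.ndarray:
    """Centroid of the solid enclosed by a watertight mesh (uniform density).

    Uses the signed-tetrahedron decomposition against the origin; the result
    is independent of the chosen apex for a closed, consistently oriented
    surface.
    """
    open_edges = mesh.open_edge_count()
    if open_edges:
        raise ValueError(
            f"mesh is not watertight: {open_edges} open edges; "
            "cannot compute a solid centroid"
        )
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1], tri[:, 2])
    vols = np.einsum("ij,ij->i", tri[:, 0], cross) / 6.0
    total = vols.sum()
    if abs(total) < 1e-12:
        raise ValueError("mesh encloses (near-)zero volume")
    centroids = tri.sum(axis=1) / 4.0
    return (vols[:, None] * centroids).sum(axis=0) / total


def fit_plane_tls(points) -> Plane:
    """Total-least-squares plane: minimizes summed squared perpendicular
    distances, via the SVD of the centered point cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    center = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - center, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1e-9):
        raise ValueError("degenerate point set: points are (near-)collinear")
    normal = vt[2]
    # deterministic orientation: largest-magnitude component positive
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    return Plane(normal, float(normal @ center))


def point_plane_distance(point, plane: Plane) -> float:
    """Non-negative perpendicular distance from a point to a plane (mm)."""
    return float(abs(plane.signed_distance(np.asarray(point, dtype=float))))


def rotation_matrix(axis_dir, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis, angle in degrees."""
    k = unit(axis_dir, "rotation axis")
    theta = np.deg2rad(float(angle_deg))
    K = np.array(
        [[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]]
    )
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def rotate_direction(d, axis_dir, angle_deg: float) -> np.ndarray:
    return rotation_matrix(axis_dir, angle_deg) @ np.asarray(d, dtype=float)


def rotate_point(p, axis_point, axis_dir, angle_deg: float) -> np.ndarray:
    axis_point = np.asarray(axis_point, dtype=float)
    R = rotation_matrix(axis_dir, angle_deg)
    return axis_point + R @ (np.asarray(p, dtype=float) - axis_point)


def rotate_plane(plane: Plane, axis_point, axis_dir, angle_deg: float) -> Plane:
    """Rigid rotation of a plane about an axis through ``axis_point``."""
    R = rotation_matrix(axis_dir, angle_deg)
    normal = R @ plane.normal
    on_plane = plane.offset * plane.normal
    moved = rotate_point(on_plane, axis_point, axis_dir, angle_deg)
    return Plane(normal, float(normal @ moved))


def rotate_about_axis(obj, axis_point, axis_dir, angle_deg: float):
    """Rotate a direction (3-vector) or a :class:`Plane` about an axis."""
    if isinstance(obj, Plane):
        return rotate_plane(obj, axis_point, axis_dir, angle_deg)
    arr = np.asarray(obj, dtype=float)
    if arr.shape == (3,):
        return rotate_direction(arr, axis_dir, angle_deg)
    raise TypeError("rotate_about_axis accepts a direction 3-vector or a Plane")


def plane_rim_intersections(plane: Plane, rim) -> np.ndarray:
    """All crossings of a closed rim polyline with a plane.

    Crossing points are linearly interpolated along each crossing segment and
    returned in rim-traversal order.  Vertices lying exactly on the plane are
    resolved by a consistent positive perturbation of the signed distance so
    that each geometric crossing yields exactly one point.  A rim entirely on
    one side yields an empty ``(0, 3)`` array.
    """
    rim = np.asarray(rim, dtype=float)
    if rim.ndim != 2 or rim.shape[1] != 3 or len(rim) < 3:
        raise ValueError("rim must be an (n>=3, 3) closed polyline")
    d = plane.signed_distance(rim) + _ON_PLANE_PERTURBATION
    d_next = np.roll(d, -1)
    crossing = d * d_next < 0
    if not crossing.any():
        return np.empty((0, 3))
    t = d[crossing] / (d[crossing] - d_next[crossing])
    seg_start = rim[crossing]
    seg_end = np.roll(rim, -1, axis=0)[crossing]
    return seg_start + t[:, None] * (seg_end - seg_start)


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Ordered boundary loops (vertex-index lists) of an oriented face set."""
    directed = {(int(a), int(b)) for f in faces for a, b in
                ((f[0], f[1]), (f[1], f[2]), (f[2], f[0]))}
    succ: dict[int, int] = {}
    for a, b in directed:
        if (b, a) not in directed:
            if a in succ:
                raise ValueError("non-manifold endplate boundary")
            succ[a] = b
    loops: list[list[int]] = []
    remaining = dict(succ)
    while remaining:
        start, nxt = next(iter(remaining.items()))
        loop = [start]
        del remaining[start]
        while nxt != start:
            loop.append(nxt)
            follow = remaining.pop(nxt, None)
            if follow is None:
                raise ValueError("open endplate boundary chain")
            nxt = follow
        loops.append(loop)
    return loops


def _largest_face_component(faces: np.ndarray, face_ids: np.ndarray) -> np.ndarray:
    """Indices (into ``face_ids``) of the largest edge-connected component."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    sel = faces[face_ids]
    edges = np.sort(sel[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    keys = edges[:, 0] * (faces.max() + 1) + edges[:, 1]
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    face_of_edge = np.repeat(np.arange(len(sel)), 3)[order]
    rows, cols = [], []
    i = 0
    while i < len(sorted_keys):
        j = i
        while j + 1 < len(sorted_keys) and sorted_keys[j + 1] == sorted_keys[i]:
            j += 1
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                rows.append(face_of_edge[a])
                cols.append(face_of_edge[b])
        i = j + 1
    n = len(sel)
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp == 1:
        return face_ids
    best = np.argmax(np.bincount(labels))
    return face_ids[labels == best]


def extract_endplate(
    mesh: TriMesh,
    which: str,
    axis=None,
    normal_threshold_deg: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Endplate vertex set and boundary rim of a vertebral-body mesh.

    Labeled meshes are authoritative: the tagged region is returned directly.
    For unlabeled meshes a normal-based fallback selects faces whose outward
    normal lies within ``normal_threshold_deg`` of ``+axis`` (upper endplate)
    or ``-axis`` (lower), keeping the largest connected component.

    Returns ``(vertex_indices, rim)`` where ``rim`` is the ordered ``(k, 3)``
    boundary polyline of the endplate region.
    """
    if which not in ("upper", "lower"):
        raise ValueError("which must be 'upper' or 'lower'")
    target = REGION_UPPER if which == "upper" else REGION_LOWER

    if mesh.region is not None:
        vert_mask = mesh.region == target
        face_mask = vert_mask[mesh.faces].all(axis=1)
        face_ids = np.flatnonzero(face_mask)
    else:
        if axis is None:
            raise ValueError("unlabeled mesh requires an axis for endplate extraction")
        direction = unit(axis) if which == "upper" else -unit(axis)
        cos_thresh = np.cos(np.deg2rad(float(normal_threshold_deg)))
        cosang = mesh.face_normals() @ direction
        face_ids = np.flatnonzero(cosang > cos_thresh)
        if len(face_ids):
            face_ids = _largest_face_component(mesh.faces, face_ids)

    if len(face_ids) == 0:
        raise ValueError(f"empty {which} endplate region")
    region_faces = mesh.faces[face_ids]
    loops = _boundary_loops(region_faces)
    if len(loops) != 1:
        raise ValueError(
            f"{which} endplate region has {len(loops)} boundary loops (expected 1)"
        )
    vertex_ids = np.unique(region_faces)
    rim = mesh.vertices[np.asarray(loops[0], dtype=np.int64)]
    return vertex_ids, rim
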