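"""Reading, orienting, and comparing triangular facial meshes.

All downstream anthropometry assumes a canonical anatomical frame:

* origin at the midpoint of the two (outer) eye-corner landmarks,
* x-axis along the inter-ocular direction,
* y-axis vertical with the chin at negative y,
* z-axis anterior (out of the face; the nose tip has the largest z).

:func:`orient_face` computes the rigid transform into this frame from five
user-supplied landmarks; :func:`mesh_deviation` measures unsigned
nearest-point distances between two pre-aligned scans (e.g. the same face
captured by two scanning systems).

Meshes are held as :class:`trimesh.Trimesh` objects. STL stores each
triangle independently, so :func:`read_stl` merges duplicate vertices
(within ``MERGE_TOL`` mm) to obtain a connected surface suitable for
section and proximity queries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import LandmarkError, MeshError

__all__ = [
    "MERGE_TOL",
    "LandmarkSet",
    "RigidTransform",
    "DeviationMap",
    "read_stl",
    "write_stl",
    "validate_mesh",
    "read_landmarks",
    "write_landmarks",
    "orient_face",
    "mesh_deviation",
]

#: Vertices closer than this (mm) are considered identical when merging.
MERGE_TOL = 1e-6

LANDMARK_NAMES = ("left_eye", "right_eye", "chin", "nose_tip", "nose_bridge")


@dataclass(frozen=True)
class LandmarkSet:
    """Five anatomical points (mm) marking eye corners, chin, and nasal ridge.

    ``left_eye`` / ``right_eye`` are the outer eye corners, ``chin`` the
    lowest midline chin point, and ``nose_bridge`` → ``nose_tip`` spans the
    nasal ridge.
    """

    left_eye: np.ndarray
    right_eye: np.ndarray
    chin: np.ndarray
    nose_tip: np.ndarray
    nose_bridge: np.ndarray

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise LandmarkError(f"landmark {name!r} has non-finite coordinates")
            object.__setattr__(self, name, p)
        if np.allclose(self.left_eye, self.right_eye):
            raise LandmarkError("left_eye and right_eye coincide")
        # chin must not be collinear with the eye pair
        e = self.right_eye - self.left_eye
        c = self.chin - self.left_eye
        if np.linalg.norm(np.cross(e, c)) < 1e-9 * np.linalg.norm(e) * max(
            np.linalg.norm(c), 1.0
        ):
            raise LandmarkError("chin is collinear with the eye landmarks")

    def as_array(self) -> np.ndarray:
        return np.stack([getattr(self, n) for n in LANDMARK_NAMES])

    def transformed(self, transform: "RigidTransform") -> "LandmarkSet":
        pts = transform.apply(self.as_array())
        return LandmarkSet(*pts)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation matrix determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=tol) and np.allclose(
            self.translation, 0.0, atol=tol
        )


@dataclass(frozen=True)
class DeviationMap:
    """Unsigned per-vertex distance (mm) from a query mesh to a reference surface."""

    per_vertex_distance: np.ndarray
    mean: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self):
        d = np.asarray(self.per_vertex_distance, dtype=float).reshape(-1)
        if d.size == 0:
            raise MeshError("deviation map is empty")
        if np.any(d < 0):
            raise ValueError("deviation distances must be non-negative")
        object.__setattr__(self, "per_vertex_distance", d)
        object.__setattr__(self, "mean", float(d.mean()))
        object.__setattr__(self, "max", float(d.max()))


def validate_mesh(mesh: trimesh.Trimesh, name: str = "mesh") -> trimesh.Trimesh:
    """Check the mesh invariants: finite coordinates, valid face indices,
    at least one face."""
    if mesh is None or not isinstance(mesh, trimesh.Trimesh):
        raise MeshError(f"{name} is not a triangle mesh")
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces)
    if f.size == 0:
        raise MeshError(f"{name} has no faces")
    if v.size == 0:
        raise MeshError(f"{name} has no vertices")
    if not np.all(np.isfinite(v)):
        raise MeshError(f"{name} contains non-finite vertex coordinates")
    if f.min() < 0 or f.max() >= len(v):
        raise MeshError(f"{name} has face indices outside the vertex range")
    return mesh


def _merge_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = MERGE_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (grid snap) and drop faces that
    collapse to fewer than three distinct vertices."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged_v = vertices[first]
    merged_f = inverse[faces]
    ok = (
        (merged_f[:, 0] != merged_f[:, 1])
        & (merged_f[:, 1] != merged_f[:, 2])
        & (merged_f[:, 0] != merged_f[:, 2])
    )
    return merged_v, merged_f[ok]


def read_stl(path) -> trimesh.Trimesh:
    """Read a binary or ASCII STL file into a merged triangle mesh.

    Duplicate vertices within :data:`MERGE_TOL` mm are merged so that
    triangles share vertices and the surface is queryable.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"STL file not found: {p}")
    try:
        raw = trimesh.load_mesh(str(p), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise MeshError(f"malformed STL file {p}: {exc}") from exc
    if isinstance(raw, trimesh.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise MeshError(f"STL file {p} contains no geometry")
        raw = trimesh.util.concatenate(geoms)
    v = np.asarray(raw.vertices, dtype=float)
    f = np.asarray(raw.faces, dtype=np.int64)
    if f.size == 0 or v.size == 0:
        raise MeshError(f"STL file {p} describes an empty mesh")
    v, f = _merge_vertices(v, f)
    mesh = trimesh.Trimesh(vertices=v, faces=f, process=False)
    return validate_mesh(mesh, name=str(p))


def write_stl(mesh: trimesh.Trimesh, path, ascii: bool = False) -> Path:
    """Write a mesh as binary (default) or ASCII STL."""
    validate_mesh(mesh)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(p), file_type="stl_ascii" if ascii else "stl")
    return p


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark sidecar: JSON mapping each landmark name to [x, y, z] mm."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"landmark file not found: {p}")
    with open(p) as fh:
        data = json.load(fh)
    missing = [n for n in LANDMARK_NAMES if n not in data]
    if missing:
        raise LandmarkError(f"landmark file {p} is missing keys: {missing}")
    return LandmarkSet(*(np.asarray(data[n], dtype=float) for n in LANDMARK_NAMES))


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        json.dump(
            {n: list(map(float, getattr(landmarks, n))) for n in LANDMARK_NAMES},
            fh,
            indent=2,
        )
    return p


def canonical_frame(landmarks: LandmarkSet) -> RigidTransform:
    """Rigid transform taking the landmark coordinates into the canonical
    anatomical frame (see module docstring)."""
    origin = 0.5 * (landmarks.left_eye + landmarks.right_eye)
    ex = landmarks.right_eye - landmarks.left_eye
    nx = np.linalg.norm(ex)
    if nx < 1e-12:
        raise LandmarkError("eye landmarks coincide; cannot define the x-axis")
    ex = ex / nx
    d = landmarks.chin - origin
    d_perp = d - np.dot(d, ex) * ex
    if np.linalg.norm(d_perp) < 1e-9:
        raise LandmarkError("chin is collinear with the eye landmarks")
    ey = -d_perp / np.linalg.norm(d_perp)  # chin sits at negative y
    ez = np.cross(ex, ey)
    # anterior check: the nose tip must have the largest z of all landmarks
    z_coords = landmarks.as_array() @ ez
    if z_coords[LANDMARK_NAMES.index("nose_tip")] < z_coords.max() - 1e-12:
        # flip x and z; keeps the frame right-handed and chin at -y
        ex, ez = -ex, -ez
    R = np.stack([ex, ey, ez])
    return RigidTransform(R, -R @ origin)


def orient_face(
    mesh: trimesh.Trimesh, landmarks: LandmarkSet
) -> tuple[trimesh.Trimesh, RigidTransform]:
    """Rigidly move a facial mesh into the canonical anatomical frame.

    Returns the re-oriented mesh and the transform that was applied (so the
    same transform can be applied to the landmarks or other point data).
    """
    validate_mesh(mesh)
    lo, hi = mesh.bounds
    pts = landmarks.as_array()
    margin = 1e-6 + 0.05 * float(np.max(hi - lo))
    if np.any(pts < lo - margin) or np.any(pts > hi + margin):
        raise LandmarkError("landmarks lie outside the mesh bounding box")
    transform = canonical_frame(landmarks)
    oriented = trimesh.Trimesh(
        vertices=transform.apply(mesh.vertices), faces=mesh.faces.copy(), process=False
    )
    return oriented, transform


def _closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from each point to its paired triangle (Ericson's region test).

    ``points``: (n, 3); ``tri``: (n, 3, 3). Returns (n,) distances.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def settle(mask, value):
        mask = mask & ~done
        closest[mask] = value[mask]
        done[mask] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(np.abs(d1 - d3) > 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(np.abs(d2 - d6) > 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(np.abs(denom_bc) > 0, (d4 - d3) / denom_bc, 0.0)
    settle(
        (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
        b + w_bc[:, None] * (c - b),
    )  # edge BC

    # interior
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    settle(~done, a + v[:, None] * ab + w[:, None] * ac)

    return np.linalg.norm(points - closest, axis=1)


def mesh_deviation(
    query: trimesh.Trimesh, reference: trimesh.Trimesh, k: int = 8
) -> DeviationMap:
    """Unsigned distance from every query vertex to the reference surface.

    Exact nearest-point-on-triangle distances; a KD-tree over triangle
    centroids prunes the candidate set, then the search radius is expanded
    by the largest triangle circumradius so no closer triangle can be
    missed. The meshes are assumed pre-aligned (use :func:`orient_face`).
    """
    validate_mesh(query, "query mesh")
    validate_mesh(reference, "reference mesh")
    pts = np.asarray(query.vertices, dtype=float)
    tris = np.asarray(reference.triangles, dtype=float)
    centroids = tris.mean(axis=1)
    # radius of the farthest triangle vertex from its centroid
    tri_radius = np.linalg.norm(tris - centroids[:, None, :], axis=2).max()
    tree = cKDTree(centroids)
    k_eff = min(k, len(centroids))
    _, idx = tree.query(pts, k=k_eff)
    idx = np.atleast_2d(idx.T).T  # (n, k)
    best = np.full(len(pts), np.inf)
    for j in range(idx.shape[1]):
        d = _closest_point_on_triangles(pts, tris[idx[:, j]])
        best = np.minimum(best, d)
    # guaranteed-correct pass: any triangle whose centroid lies within the
    # current bound + its circumradius could still be closer
    neighbourhoods = tree.query_ball_point(pts, best + tri_radius + 1e-12)
    for i, cand in enumerate(neighbourhoods):
        cand = np.asarray(cand)
        if cand.size == 0:
            continue
        d = _closest_point_on_triangles(
            np.repeat(pts[i][None, :], cand.size, axis=0), tris[cand]
        )
        best[i] = min(best[i], d.min())
    return DeviationMap(best)
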