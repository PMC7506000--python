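"""Triangle-mesh containers, I/O, validation and clearance queries.

Bone segments are rigid triangle meshes in millimetres.  File I/O for
OBJ/PLY/STL goes through :mod:`trimesh`; validation and distance
queries use the vectorised kernels in :mod:`osteorom.geometry` so that
the whole pipeline has a single, testable geometric backend.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import geometry

log = logging.getLogger(__name__)

SUPPORTED_FORMATS = ("obj", "ply", "stl")


class MeshValidationError(ValueError):
    """Raised when a mesh violates the TriangleMesh invariants."""


@dataclass(frozen=True)
class TriangleMesh:
    """An indexed triangle mesh of one rigid bone segment (mm units).

    Invariants (enforced in ``__post_init__``): all face indices valid,
    all coordinates finite, no zero-area faces.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "segment"

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64)).reshape(-1, 3)
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64)).reshape(-1, 3)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if v.shape[0] == 0 or f.shape[0] == 0:
            raise MeshValidationError(f"{self.name}: empty mesh")
        if not np.isfinite(v).all():
            raise MeshValidationError(f"{self.name}: non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= v.shape[0]:
            raise MeshValidationError(f"{self.name}: face references missing vertex")
        if (self.face_areas() <= 0).any():
            raise MeshValidationError(f"{self.name}: degenerate (zero-area) faces")

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def triangles(self) -> np.ndarray:
        """Triangle corner coordinates, shape (n_faces, 3, 3)."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def surface_area(self) -> float:
        return float(self.face_areas().sum())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight


@dataclass(frozen=True)
class SurfacePatch:
    """A subset of a mesh's faces marking one articular surface."""

    parent: TriangleMesh
    face_indices: np.ndarray
    label: str = "patch"

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.face_indices, dtype=np.int64))
        object.__setattr__(self, "face_indices", idx)
        if idx.size == 0:
            raise MeshValidationError(f"patch {self.label}: empty face list")
        if idx.min() < 0 or idx.max() >= self.parent.n_faces:
            raise MeshValidationError(f"patch {self.label}: face index out of range")

    def triangles(self) -> np.ndarray:
        return self.parent.vertices[self.parent.faces[self.face_indices]]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``x -> R @ x + t`` (R right-handed)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-9
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass(frozen=True)
class MeshReport:
    """Defect counts from :func:`validate_mesh` (reporting only)."""

    n_vertices: int
    n_faces: int
    n_nonmanifold_edges: int
    n_boundary_edges: int
    n_degenerate_faces: int
    n_self_intersections: int
    watertight: bool

    @property
    def clean(self) -> bool:
        return (
            self.n_nonmanifold_edges == 0
            and self.n_degenerate_faces == 0
            and self.n_self_intersections == 0
        )


# ---------------------------------------------------------------------------
# I/O


def load_mesh(path: str | Path, fmt: str | None = None, name: str | None = None,
              scale: float = 1.0) -> TriangleMesh:
    """Load an OBJ/PLY/STL mesh file into a validated TriangleMesh.

    ``scale`` applies a uniform isometric scale factor (specimen
    rescaling in a multi-specimen composite is declared per file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {SUPPORTED_FORMATS}")
    try:
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # parse failure from the format layer
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshValidationError(f"{path}: no geometry found")
        tm = trimesh.util.concatenate(geoms)
    verts = np.asarray(tm.vertices, dtype=np.float64) * float(scale)
    mesh = TriangleMesh(verts, np.asarray(tm.faces), name or path.stem)
    log.info("loaded %s: %d vertices, %d faces", path, mesh.n_vertices, mesh.n_faces)
    return mesh


def save_mesh(mesh: TriangleMesh, path: str | Path) -> Path:
    """Write a mesh to OBJ/PLY/STL (format from the file suffix)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    mesh.to_trimesh().export(str(path))
    return path


def load_patch(patch_file: str | Path, mesh: TriangleMesh) -> SurfacePatch:
    """Read a JSON patch definition ``{"mesh":…, "label":…, "faces":[…]}``."""
    data = json.loads(Path(patch_file).read_text())
    if data.get("mesh") not in (None, mesh.name):
        raise MeshValidationError(
            f"patch file targets mesh {data.get('mesh')!r}, got {mesh.name!r}"
        )
    return SurfacePatch(mesh, np.asarray(data["faces"], dtype=np.int64),
                        data.get("label", "patch"))


def save_patch(patch: SurfacePatch, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "mesh": patch.parent.name,
        "label": patch.label,
        "faces": patch.face_indices.tolist(),
    }))
    return path


# ---------------------------------------------------------------------------
# operations


def validate_mesh(mesh: TriangleMesh, check_self_intersections: bool = True) -> MeshReport:
    """Report mesh defects (non-manifold edges, boundary edges,
    degenerate faces, self-intersections).  Repair is out of scope:
    cleaning is assumed to have happened upstream."""
    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    n_nonmanifold = int((counts > 2).sum())
    n_boundary = int((counts == 1).sum())
    n_degenerate = int((mesh.face_areas() <= geometry.TOL).sum())
    n_self = _count_self_intersections(mesh) if check_self_intersections else 0
    return MeshReport(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        n_nonmanifold_edges=n_nonmanifold,
        n_boundary_edges=n_boundary,
        n_degenerate_faces=n_degenerate,
        n_self_intersections=n_self,
        watertight=mesh.is_watertight(),
    )


def _count_self_intersections(mesh: TriangleMesh) -> int:
    """Count non-adjacent face pairs whose triangles strictly overlap."""
    tris = mesh.triangles()
    lo, hi = geometry.tri_aabbs(tris)
    ia, ib = geometry.aabb_overlap_pairs(lo, hi, lo, hi, pad=1e-9)
    keep = ia < ib
    ia, ib = ia[keep], ib[keep]
    # drop pairs sharing a vertex: they touch by construction
    fa, fb = mesh.faces[ia], mesh.faces[ib]
    shared = (fa[:, :, None] == fb[:, None, :]).any(axis=(1, 2))
    ia, ib = ia[~shared], ib[~shared]
    if ia.size == 0:
        return 0
    return int(geometry.tri_tri_overlap_interval(tris[ia], tris[ib]).sum())


def apply_transform(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Rigidly move a mesh; faces are untouched, distances preserved."""
    return TriangleMesh(transform.apply(mesh.vertices), mesh.faces, mesh.name)


def patch_points(patch: SurfacePatch) -> np.ndarray:
    """Unique vertex coordinates referenced by the patch's faces."""
    idx = np.unique(patch.parent.faces[patch.face_indices])
    return patch.parent.vertices[idx]


def signed_clearance(
    moving_patch: SurfacePatch,
    fixed_patch: SurfacePatch,
    pose: RigidTransform | None = None,
    reference_centre: np.ndarray | None = None,
) -> np.ndarray:
    """Signed nearest-surface distance for every moving-patch vertex.

    Each vertex of ``moving_patch`` (after applying ``pose``) is matched
    to its nearest point on the ``fixed_patch`` triangles.  The sign is
    negative when the vertex sits on the interior (bone-material) side
    of the fixed surface: the vector to the nearest point is compared
    with the outward direction, taken as pointing away from
    ``reference_centre`` (the fitted-primitive centre of the fixed
    surface; defaults to the fixed patch's vertex centroid).  The mean
    of the returned values is the joint spacing; negative spacing means
    interpenetrating cartilage space.
    """
    pose = pose or RigidTransform.identity()
    pts = pose.apply(patch_points(moving_patch))
    tris = fixed_patch.triangles()
    if reference_centre is None:
        reference_centre = patch_points(fixed_patch).mean(axis=0)
    reference_centre = np.asarray(reference_centre, dtype=np.float64)

    dist, closest, _ = geometry.closest_points_on_triangles(pts, tris)
    outward = closest - reference_centre
    norms = np.linalg.norm(outward, axis=1, keepdims=True)
    outward = outward / np.where(norms > 0, norms, 1.0)
    to_surface = closest - pts
    sign = np.where(np.einsum("ij,ij->i", to_surface, outward) >= 0, 1.0, -1.0)
    sign = np.where(dist <= geometry.TOL, 1.0, sign)
    return sign * dist


def joint_spacing(
    moving_patch: SurfacePatch,
    fixed_patch: SurfacePatch,
    pose: RigidTransform | None = None,
    reference_centre: np.ndarray | None = None,
) -> float:
    """Mean signed clearance: the average articular distance (mm)."""
    return float(signed_clearance(moving_patch, fixed_patch, pose, reference_centre).mean())
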