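"""Least-squares geometric primitives for articular surfaces.

Joint centres of fossil joints are estimated by fitting primitive
shapes (sphere, ellipsoid, cylinder, plane) to the articular-surface
point clouds of the two bones and superimposing the fitted centres.
Sphere and ellipsoid use a two-stage fit: a linear/constrained
algebraic solve followed by geometric (orthogonal-distance) refinement,
which is the robust choice for partial caps such as an acetabulum.
All fits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .mesh_core import SurfacePatch
from .mesh_core import patch_points as _patch_points


class FitError(ValueError):
    """Raised for degenerate point configurations or non-convergence."""


@dataclass(frozen=True)
class FittedPrimitive:
    """A fitted primitive: ``kind`` in sphere|ellipsoid|cylinder|plane.

    ``centre`` is the geometric centre (sphere/ellipsoid), a point on
    the axis (cylinder), or a point on the plane.  ``radii`` holds 1
    (sphere, cylinder) or 3 (ellipsoid, sorted descending) semi-axes in
    mm; empty for a plane.  ``axes`` rows are the principal axes
    (ellipsoid), the axis direction in row 0 (cylinder), or the normal
    in row 0 (plane).  ``rms_residual`` is the root-mean-square
    orthogonal distance of the points to the fitted surface.
    """

    kind: str
    centre: np.ndarray
    radii: np.ndarray
    axes: np.ndarray
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=np.float64))
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=np.float64))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=np.float64))
        if (self.radii <= 0).any():
            raise FitError(f"{self.kind} fit produced non-positive radii {self.radii}")
        if self.rms_residual < 0:
            raise FitError("negative rms residual")

    @property
    def has_centre(self) -> bool:
        return self.kind != "plane"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "centre": self.centre.tolist(),
            "radii": self.radii.tolist(),
            "axes": self.axes.tolist(),
            "rms_residual": self.rms_residual,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class JointCentre:
    """Joint centre from superimposing two fitted primitive centres.

    The socket-side centre (fixed bone) defines the world-frame pivot;
    the head-side centre is the point of the moving bone pinned to the
    pivot at the reference pose.
    """

    position: np.ndarray
    pinned_point: np.ndarray
    source_a: FittedPrimitive | None
    source_b: FittedPrimitive | None


def _as_points(points) -> np.ndarray:
    if isinstance(points, SurfacePatch):
        points = _patch_points(points)
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if not np.isfinite(pts).all():
        raise FitError("non-finite input points")
    return pts


# ---------------------------------------------------------------------------
# sphere


def fit_sphere(points) -> FittedPrimitive:
    """Two-stage sphere fit: linear algebraic solve, then geometric
    Levenberg–Marquardt refinement of centre and radius."""
    pts = _as_points(points)
    if pts.shape[0] < 4:
        raise FitError("sphere fit needs at least 4 points")
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(pts).max())) < 3:
        raise FitError("sphere fit needs non-coplanar points")

    # algebraic: |p|^2 = 2 c.p + (r^2 - |c|^2)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0, k = sol[:3], sol[3]
    r0 = float(np.sqrt(max(k + c0 @ c0, 1e-300)))

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    res = least_squares(resid, np.r_[c0, r0], method="lm", max_nfev=200)
    c, r = res.x[:3], float(res.x[3])
    if r <= 0:
        raise FitError("sphere fit collapsed to non-positive radius")
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return FittedPrimitive("sphere", c, np.array([r]), np.eye(3), rms, len(pts))


# ---------------------------------------------------------------------------
# ellipsoid


def _algebraic_ellipsoid(pts: np.ndarray) -> np.ndarray:
    """Ellipsoid-specific algebraic fit (Li–Griffiths k=4 constraint).

    Returns the 10 quadric coefficients (a,b,c,f,g,h,p,q,r,d) of
    ax^2+by^2+cz^2+2fyz+2gxz+2hxy+2px+2qy+2rz+d = 0, guaranteed to
    describe an ellipsoid.
    """
    x, y, z = pts.T
    d1 = np.column_stack([x * x, y * y, z * z, 2 * y * z, 2 * x * z, 2 * x * y])
    d2 = np.column_stack([2 * x, 2 * y, 2 * z, np.ones_like(x)])
    s11 = d1.T @ d1
    s12 = d1.T @ d2
    s22 = d2.T @ d2
    try:
        s22_inv = np.linalg.inv(s22)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate point configuration for ellipsoid fit") from exc
    m = s11 - s12 @ s22_inv @ s12.T
    # constraint 4J - I^2 > 0 (ellipsoid-specific for k=4)
    c = np.zeros((6, 6))
    c[:3, :3] = np.array([[-1.0, 1.0, 1.0], [1.0, -1.0, 1.0], [1.0, 1.0, -1.0]])
    c[3:, 3:] = -4.0 * np.eye(3)
    try:
        evals, evecs = np.linalg.eig(np.linalg.inv(c) @ m)
    except np.linalg.LinAlgError as exc:
        raise FitError("ellipsoid eigen-solve failed") from exc
    real = np.isreal(evals) & (evals.real > 0)
    if not real.any():
        raise FitError("no ellipsoid solution for this point configuration")
    v1 = evecs[:, np.argmax(np.where(real, evals.real, -np.inf))].real
    v2 = -s22_inv @ s12.T @ v1
    return np.r_[v1, v2]


def _quadric_to_ellipsoid(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, b, c, f, g, h, p, q, r, d = v
    a3 = np.array([[a, h, g], [h, b, f], [g, f, c]])
    try:
        centre = np.linalg.solve(-a3, np.array([p, q, r]))
    except np.linalg.LinAlgError as exc:
        raise FitError("singular quadric in ellipsoid fit") from exc
    scale = centre @ a3 @ centre + 2 * np.array([p, q, r]) @ centre + d
    evals, evecs = np.linalg.eigh(a3 / -scale)
    if (evals <= 0).any():
        raise FitError("quadric is not an ellipsoid")
    semi = 1.0 / np.sqrt(evals)
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    axes = evecs[:, order].T
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return centre, semi, axes


def _ellipsoid_residuals(pts, centre, semi, axes):
    """Approximate orthogonal distances: scaled algebraic residual."""
    local = (pts - centre) @ axes.T
    w = local / semi
    nw = np.linalg.norm(w, axis=1)
    nw = np.maximum(nw, 1e-12)
    # distance from point to the ellipsoid along the ray to the centre
    return np.linalg.norm(local, axis=1) * (1.0 - 1.0 / nw)


def fit_ellipsoid(points) -> FittedPrimitive:
    """Constrained algebraic ellipsoid fit plus geometric refinement.

    The algebraic stage cannot return a hyperboloid even on partial
    patches; the refinement minimises a first-order geometric distance.
    Semi-axes are sorted descending; ``axes`` rows are the matching
    principal directions (right-handed).
    """
    pts = _as_points(points)
    if pts.shape[0] < 9:
        raise FitError("ellipsoid fit needs at least 9 points")
    try:
        centre0, semi0, axes0 = _quadric_to_ellipsoid(_algebraic_ellipsoid(pts))
    except FitError:
        # (near-)exactly spherical data makes the constrained quadric
        # problem degenerate; seed the geometric stage from a sphere fit
        sphere = fit_sphere(pts)
        centre0 = sphere.centre
        semi0 = np.repeat(sphere.radii[0], 3)
        axes0 = np.eye(3)

    def pack(centre, semi, rotvec):
        return np.r_[centre, np.log(semi), rotvec]

    def unpack(x):
        from scipy.spatial.transform import Rotation

        centre = x[:3]
        semi = np.exp(x[3:6])
        axes = Rotation.from_rotvec(x[6:9]).as_matrix() @ axes0
        return centre, semi, axes

    def resid(x):
        return _ellipsoid_residuals(pts, *unpack(x))

    x0 = pack(centre0, semi0, np.zeros(3))
    res = least_squares(resid, x0, method="lm", max_nfev=400)
    centre, semi, axes = unpack(res.x)
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    axes = axes[order]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return FittedPrimitive("ellipsoid", centre, semi, axes, rms, len(pts))


# ---------------------------------------------------------------------------
# cylinder


def _orthonormal_complement(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def _dir_from_angles(theta: float, phi: float) -> np.ndarray:
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def fit_cylinder(points, max_nfev: int = 400) -> FittedPrimitive:
    """Orthogonal-residual cylinder fit.

    Deterministic initialisation: each of the three principal directions
    of the point cloud is tried as a candidate axis (with an algebraic
    circle fit in the normal plane); the best candidate seeds a
    Levenberg–Marquardt refinement of axis direction, axis point and
    radius.  Raises :class:`FitError` if the refinement does not
    converge within ``max_nfev`` evaluations.
    """
    pts = _as_points(points)
    if pts.shape[0] < 6:
        raise FitError("cylinder fit needs at least 6 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise FitError("cylinder fit needs non-collinear points")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)

    def axis_cost(d):
        u, v = _orthonormal_complement(d)
        xy = np.column_stack([centred @ u, centred @ v])
        # Kasa circle fit in the normal plane
        A = np.column_stack([2.0 * xy, np.ones(len(xy))])
        b = (xy**2).sum(axis=1)
        try:
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        except np.linalg.LinAlgError:
            return np.inf, None
        cx, cy, k = sol
        r2 = k + cx * cx + cy * cy
        if r2 <= 0:
            return np.inf, None
        r = np.sqrt(r2)
        res = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) - r
        return float((res**2).mean()), (cx * u + cy * v + centroid, r)

    best = min(
        (axis_cost(d) + (d,) for d in vt), key=lambda t: t[0]
    )
    if not np.isfinite(best[0]):
        raise FitError("no valid cylinder initialisation")
    (c0, r0), d0 = best[1], best[2]

    theta0 = float(np.arccos(np.clip(d0[2], -1, 1)))
    phi0 = float(np.arctan2(d0[1], d0[0]))
    u0, v0 = _orthonormal_complement(d0)

    def unpack(x):
        d = _dir_from_angles(x[0], x[1])
        c = centroid + x[2] * u0 + x[3] * v0
        return d, c, x[4]

    def resid(x):
        d, c, r = unpack(x)
        rel = pts - c
        perp = rel - np.outer(rel @ d, d)
        return np.linalg.norm(perp, axis=1) - r

    x0 = np.array([theta0, phi0, (c0 - centroid) @ u0, (c0 - centroid) @ v0, r0])
    res = least_squares(resid, x0, method="lm", max_nfev=max_nfev)
    if not res.success:
        raise FitError(f"cylinder fit did not converge: {res.message}")
    d, c, r = unpack(res.x)
    if r <= 0:
        raise FitError("cylinder fit collapsed to non-positive radius")
    if d[np.abs(d).argmax()] < 0:
        d = -d  # canonical sign
    # report the axis point closest to the centroid
    c = c + ((centroid - c) @ d) * d
    u, v = _orthonormal_complement(d)
    axes = np.vstack([d, u, v])
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return FittedPrimitive("cylinder", c, np.array([float(r)]), axes, rms, len(pts))


# ---------------------------------------------------------------------------
# plane


def fit_plane(points, outward_hint: np.ndarray | None = None) -> FittedPrimitive:
    """Total-least-squares plane through a point cloud.

    The normal is the smallest principal direction.  Its sign is chosen
    to point along ``outward_hint`` (e.g. away from the parent mesh
    interior) when given, otherwise canonically (largest component
    positive).
    """
    pts = _as_points(points)
    if pts.shape[0] < 3:
        raise FitError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise FitError("plane fit needs non-collinear points")
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[2]
    if outward_hint is not None:
        if np.linalg.norm(outward_hint) == 0:
            raise FitError("outward_hint must be a non-zero vector")
        if normal @ np.asarray(outward_hint, dtype=np.float64) < 0:
            normal = -normal
    elif normal[np.abs(normal).argmax()] < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    axes = np.vstack([normal, vt[0], np.cross(normal, vt[0])])
    return FittedPrimitive("plane", centroid, np.empty(0), axes, rms, len(pts))


# ---------------------------------------------------------------------------
# joint centres


def make_joint_centre(
    socket_fit: FittedPrimitive, head_fit: FittedPrimitive, rule: str = "socket_pivot"
) -> JointCentre:
    """Superimpose two fitted centres into one joint centre.

    Default rule ``socket_pivot``: the socket-side (fixed bone) centre
    defines the world-frame pivot, and the head-side centre is the
    moving-bone point pinned to it at reference.  ``head_pivot`` swaps
    the roles.  A plane primitive has no centre; if one side is a plane
    the other side's centre is used for both roles, and two planes are
    an error.
    """
    if rule not in ("socket_pivot", "head_pivot"):
        raise ValueError(f"unknown superposition rule {rule!r}")
    a_has, b_has = socket_fit.has_centre, head_fit.has_centre
    if not a_has and not b_has:
        raise FitError("two plane primitives define no joint centre")
    pivot_fit, pinned_fit = (socket_fit, head_fit) if rule == "socket_pivot" else (head_fit, socket_fit)
    pivot = pivot_fit.centre if pivot_fit.has_centre else pinned_fit.centre
    pinned = head_fit.centre if head_fit.has_centre else socket_fit.centre
    return JointCentre(
        position=np.asarray(pivot, dtype=np.float64),
        pinned_point=np.asarray(pinned, dtype=np.float64),
        source_a=socket_fit,
        source_b=head_fit,
    )


def fibular_lar_centre(fibula_distal_patch: SurfacePatch) -> JointCentre:
    """Single-sided joint centre for a crural long-axis-rotation joint:
    the centre of a sphere fitted to the distal fibular surface."""
    fit = fit_sphere(fibula_distal_patch)
    return JointCentre(
        position=fit.centre, pinned_point=fit.centre, source_a=fit, source_b=None
    )


FIT_FUNCTIONS = {
    "sphere": fit_sphere,
    "ellipsoid": fit_ellipsoid,
    "cylinder": fit_cylinder,
    "plane": fit_plane,
}
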