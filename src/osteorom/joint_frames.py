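"""Joint coordinate systems, pose generation and axis recovery.

Rotation convention (XROMM-style): the three rotational degrees of
freedom of the ball-and-socket joint are applied as an intrinsic
FE → ABAD → LAR sequence —

* flexion/extension (FE) about the proximal frame's z axis,
* abduction/adduction (ABAD) about the floating mutual perpendicular
  (the y axis after FE),
* long-axis rotation (LAR) about the distal frame's x axis —

all right-handed, counter-clockwise positive, i.e. the world rotation
is ``P · Rz(fe) · Ry(abad) · Rx(lar) · Pᵀ`` with ``P`` the proximal
axes.  The reference pose is (0°, 0°, 0°), where the proximal and
distal frames coincide.  Epiphyseal-cartilage spacing enters as a pure
translation of the femur along the socket pole axis by a percentage of
femur length, applied after the rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import RigidTransform
from .primitive_fit import JointCentre

ROTATION_ORDER = "FE-ABAD-LAR"

_GIMBAL_COS_TOL = 1e-9


class FrameError(ValueError):
    """Raised for non-orthonormal frames or reference-pose violations."""


def _check_frame(axes: np.ndarray, what: str) -> np.ndarray:
    axes = np.asarray(axes, dtype=np.float64).reshape(3, 3)
    if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
        raise FrameError(f"{what} axes are not orthonormal")
    if not np.isclose(np.linalg.det(axes), 1.0, atol=1e-9):
        raise FrameError(f"{what} axes are not right-handed")
    return axes


@dataclass(frozen=True)
class JointCoordinateSystem:
    """Shared joint centre plus proximal/distal axis frames.

    Axis matrices have the frame axes as *columns* (local → world).
    At reference pose the two frames coincide; FE axis = proximal z,
    LAR axis = distal x, ABAD = the floating mutual perpendicular.
    """

    centre: JointCentre
    proximal_axes: np.ndarray
    distal_axes: np.ndarray
    rotation_order: str = ROTATION_ORDER

    @property
    def fe_axis(self) -> np.ndarray:
        return self.proximal_axes[:, 2]

    @property
    def abad_axis(self) -> np.ndarray:
        return self.proximal_axes[:, 1]  # floating axis at reference

    @property
    def lar_axis(self) -> np.ndarray:
        return self.distal_axes[:, 0]


@dataclass(frozen=True)
class JointPose:
    """One (FE, ABAD, LAR) rotation triple in degrees."""

    fe_deg: float
    abad_deg: float
    lar_deg: float

    def __post_init__(self) -> None:
        triple = (self.fe_deg, self.abad_deg, self.lar_deg)
        if not np.isfinite(triple).all():
            raise ValueError("pose angles must be finite")
        if not (-180 <= self.fe_deg <= 180 and -90 <= self.abad_deg <= 90
                and -180 <= self.lar_deg <= 180):
            raise ValueError(f"pose {triple} outside canonical ranges")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.fe_deg, self.abad_deg, self.lar_deg)


@dataclass(frozen=True)
class CartilageRule:
    """Extra joint spacing standing in for epiphyseal cartilage:
    an outward displacement of ``pct × femur_length`` along the socket
    pole axis (pointing out of the cup)."""

    pct: float = 0.0
    femur_length: float = 0.0
    offset_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        if self.pct < 0:
            raise ValueError("cartilage pct must be >= 0")
        ax = np.asarray(self.offset_axis, dtype=np.float64).reshape(3)
        n = np.linalg.norm(ax)
        if self.pct > 0 and not n > 0:
            raise ValueError("offset_axis must be non-zero")
        object.__setattr__(self, "offset_axis", ax / n if n > 0 else ax)

    @property
    def offset_vector(self) -> np.ndarray:
        return self.pct * self.femur_length * self.offset_axis


def build_jcs(
    centre: JointCentre,
    socket_axes: np.ndarray,
    femur_axes: np.ndarray,
    atol_deg: float = 1e-6,
) -> JointCoordinateSystem:
    """Join two anatomical frames into a joint coordinate system.

    Both frames must be orthonormal and must coincide at the reference
    pose (all joint rotations zero); a mismatch is reported as a
    reference-pose violation rather than silently re-zeroed.
    """
    p = _check_frame(socket_axes, "socket")
    d = _check_frame(femur_axes, "femur")
    rel = p.T @ d
    # atan2 formulation: well-conditioned near the identity (arccos is not)
    skew = 0.5 * (rel - rel.T)
    sin_ang = np.linalg.norm([skew[2, 1], skew[0, 2], skew[1, 0]])
    cos_ang = np.clip((np.trace(rel) - 1) / 2, -1, 1)
    ang = np.degrees(np.arctan2(sin_ang, cos_ang))
    if ang > atol_deg:
        raise FrameError(
            f"reference-pose violation: proximal and distal frames differ by {ang:.3g} deg"
        )
    return JointCoordinateSystem(centre=centre, proximal_axes=p, distal_axes=d)


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def pose_transform(
    jcs: JointCoordinateSystem,
    pose: JointPose,
    cartilage: CartilageRule | None = None,
) -> RigidTransform:
    """Rigid transform taking the femur from its reference placement
    (pinned point at the joint centre, zero rotations, zero offset) to
    the posed placement: intrinsic FE→ABAD→LAR rotation about the joint
    centre, then the cartilage offset translation.  (0,0,0) with zero
    cartilage is the identity."""
    fe, ab, la = np.radians(pose.as_tuple())
    p = jcs.proximal_axes
    r = p @ _rz(fe) @ _ry(ab) @ _rx(la) @ p.T
    c = np.asarray(jcs.centre.position, dtype=np.float64)
    t = c - r @ c
    if cartilage is not None:
        t = t + cartilage.offset_vector
    return RigidTransform(r, t)


def euler_from_transform(
    jcs: JointCoordinateSystem,
    transform: RigidTransform,
    cartilage: CartilageRule | None = None,
    atol: float = 1e-6,
) -> tuple[JointPose, bool]:
    """Invert :func:`pose_transform`: recover (FE, ABAD, LAR) degrees.

    Returns ``(pose, gimbal_locked)``; at |ABAD| = 90° the FE and LAR
    axes align and only their sum/difference is defined, in which case
    the flag is True and LAR is reported as 0.  Raises if the transform
    is not a rotation about the joint centre composed with the declared
    cartilage offset.
    """
    c = np.asarray(jcs.centre.position, dtype=np.float64)
    expected = transform.rotation @ c + transform.translation
    target = c + (cartilage.offset_vector if cartilage is not None else 0.0)
    if not np.allclose(expected, target, atol=max(atol, 1e-9 * (1 + np.abs(c).max()))):
        raise FrameError(
            "transform does not rotate about the joint centre "
            "(translation inconsistent with the cartilage rule)"
        )
    p = jcs.proximal_axes
    r = p.T @ transform.rotation @ p
    sb = -r[2, 0]
    sb = np.clip(sb, -1.0, 1.0)
    gimbal = bool(1.0 - abs(sb) < _GIMBAL_COS_TOL)
    ab = np.arcsin(sb)
    if gimbal:
        fe = np.arctan2(-r[0, 1], r[1, 1])
        la = 0.0
    else:
        fe = np.arctan2(r[1, 0], r[0, 0])
        la = np.arctan2(r[2, 1], r[2, 2])
    pose = JointPose(float(np.degrees(fe)), float(np.degrees(ab)), float(np.degrees(la)))
    return pose, gimbal


# ---------------------------------------------------------------------------
# helical axis


@dataclass(frozen=True)
class HelicalAxis:
    """Finite helical axis of a relative rigid motion."""

    direction: np.ndarray  # unit vector
    point: np.ndarray  # point on the axis (minimum-norm solution)
    angle_deg: float
    translation_mm: float  # advance along the axis


def helical_axis(
    t1: RigidTransform, t2: RigidTransform, min_angle_deg: float = 1.0
) -> HelicalAxis:
    """Finite helical axis of the motion from placement ``t1`` to ``t2``.

    Back-calculates the rotation axis from motion: the relative
    transform ``t2 ∘ t1⁻¹`` is decomposed into a rotation of
    ``angle_deg`` about a spatial line plus ``translation_mm`` of
    advance along it.  Relative rotations below ``min_angle_deg`` are
    rejected as numerically unstable.
    """
    from scipy.spatial.transform import Rotation

    rel = t2.compose(t1.inverse())
    rot = Rotation.from_matrix(rel.rotation)
    rotvec = rot.as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < min_angle_deg:
        raise ValueError(
            f"relative rotation {angle:.3g} deg below stability threshold "
            f"{min_angle_deg} deg"
        )
    n = rotvec / np.linalg.norm(rotvec)
    t = rel.translation
    tau = float(t @ n)
    # (I - R) p = t - tau n ; rank-2 system, minimum-norm solution
    p, *_ = np.linalg.lstsq(np.eye(3) - rel.rotation, t - tau * n, rcond=None)
    return HelicalAxis(direction=n, point=p, angle_deg=angle, translation_mm=tau)


def axis_obliquity(axis_a: np.ndarray, axis_b: np.ndarray) -> float:
    """Angle in [0°, 90°] between two undirected axes (e.g. the ankle
    hinge vs the knee axis)."""
    a = np.asarray(axis_a, dtype=np.float64)
    b = np.asarray(axis_b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("axes must be non-zero vectors")
    return float(np.degrees(np.arccos(np.clip(abs(a @ b) / (na * nb), 0.0, 1.0))))


# ---------------------------------------------------------------------------
# convenience for synthetic scenes


def scene_jcs(scene) -> tuple[JointCoordinateSystem, CartilageRule]:
    """JCS and cartilage rule for a generated joint scene, using the
    ground-truth cup centre as pivot and identity anatomical frames
    (the generator's construction convention)."""
    centre = JointCentre(
        position=scene.socket_truth.centre,
        pinned_point=scene.femur_truth.head_centre,
        source_a=None,
        source_b=None,
    )
    jcs = build_jcs(centre, np.eye(3), np.eye(3))
    rule = CartilageRule(
        pct=scene.cartilage_pct,
        femur_length=scene.femur_truth.femur_length,
        offset_axis=scene.socket_truth.pole_axis,
    )
    return jcs, rule
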