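"""Parametric ground-truth bone meshes for a ball-and-socket hip.

Real osteological ROM studies start from manually segmented CT meshes;
this module generates watertight stand-ins with exactly known geometry
so every downstream stage (primitive fitting, joint rigging, pose
sweeping, ROM metrics) can be validated against analytic truth.

Conventions (world frame = socket frame at reference pose):

* the cup opens along ``+x`` (the socket "pole" axis, out of the cup);
* the supra-acetabular rim lip is centred on the ``-z`` azimuth of the
  opening, so positive abduction (right-handed rotation about ``+y``,
  which carries the femur shaft towards ``-z``) swings the femur
  against the rim;
* the femoral head is centred at the cup centre (the world origin) at
  reference, with the neck exiting along ``+x`` and the shaft bent
  towards ``-z``.

Geometry of the socket: a spherical shell (inner articular radius
``cup_radius``, outer radius ``cup_radius + shell_thickness``).  The
cup proper covers polar angles (measured from +x) from
``theta_open = 180° − depth_fraction·90°`` to the pole at 180°.  The
rim lip continues the same spherical shell past ``theta_open`` by up to
``rim_overhang_deg``, over an azimuthal plateau of width
``rim_arc_deg`` with a cosine taper of ``rim_taper_deg`` on each side —
a localised dorsal shelf, not a full annulus.  The cup-proper vertex
lattice does not depend on the overhang, so socket meshes for
increasing overhang are geometrically nested (the basis of the
rim-monotonicity property).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .mesh_core import SurfacePatch, TriangleMesh

_MIN_LIP_EXTENT_DEG = 0.2  # keeps lip rows distinct where the bump vanishes


@dataclass(frozen=True)
class SocketSpec:
    """Parameters of the synthetic socket (acetabulum) bone, mm/degrees."""

    cup_radius: float = 6.0
    depth_fraction: float = 1.0  # full hemisphere: opening at polar 90 deg
    rim_overhang_deg: float = 25.0
    rim_arc_deg: float = 12.0  # full plateau width of the lip
    rim_taper_deg: float = 3.0
    rim_azimuth_deg: float = 270.0  # lip centred on -z
    shell_thickness: float = 1.5
    mesh_resolution: int = 3
    noise_sigma_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.cup_radius <= 0 or self.shell_thickness <= 0:
            raise ValueError("cup_radius and shell_thickness must be positive")
        if not 0 < self.depth_fraction <= 1:
            raise ValueError("depth_fraction must be in (0, 1]")
        if not 0 <= self.rim_overhang_deg <= 60:
            raise ValueError("rim_overhang_deg must be in [0, 60]")
        if self.mesh_resolution < 1:
            raise ValueError("mesh_resolution must be >= 1")
        if self.rim_overhang_deg > 0 and self.opening_polar_deg - self.rim_overhang_deg <= 5:
            raise ValueError("rim lip would close the cup opening (infeasible spec)")

    @property
    def opening_polar_deg(self) -> float:
        """Polar angle of the cup-proper edge, measured from the +x pole axis."""
        return 180.0 - self.depth_fraction * 90.0


@dataclass(frozen=True)
class FemurSpec:
    """Parameters of the synthetic femur, mm/degrees.

    ``head_radii`` are the ellipsoid semi-axes along (neck axis x, y, z)
    at reference; equal radii give a spherical head.  ``neck_angle_deg``
    is the anatomical neck–shaft angle (the shaft deviates from the
    neck axis by ``180° − neck_angle_deg``, towards −z at reference).
    """

    head_radii: tuple[float, float, float] = (5.4, 5.1, 4.9)
    neck_length: float = 10.0
    neck_angle_deg: float = 130.0
    shaft_length: float = 45.0
    shaft_radius: float = 1.0
    mesh_resolution: int = 3
    noise_sigma_mm: float = 0.0

    def __post_init__(self) -> None:
        if min(self.head_radii) <= 0 or self.neck_length <= 0 or self.shaft_length <= 0:
            raise ValueError("all femur lengths must be positive")
        if self.shaft_radius <= 0:
            raise ValueError("shaft_radius must be positive")
        if not 90 < self.neck_angle_deg < 180:
            raise ValueError("neck_angle_deg must be in (90, 180)")
        if self.neck_length <= max(self.head_radii):
            raise ValueError("neck_length must exceed the head radius")
        if self.shaft_radius >= 0.5 * min(self.head_radii[1:]):
            raise ValueError("shaft_radius too large to blend into the head")

    @property
    def femur_length(self) -> float:
        """Cartilage-percentage base: path length head centre -> shaft end."""
        return self.neck_length + self.shaft_length


@dataclass(frozen=True)
class SocketTruth:
    centre: np.ndarray
    radius: float
    pole_axis: np.ndarray
    opening_polar_deg: float


@dataclass(frozen=True)
class FemurTruth:
    head_centre: np.ndarray
    head_semi_axes: np.ndarray  # along head_axes rows
    head_axes: np.ndarray  # 3x3, rows are the ellipsoid principal axes
    neck_axis: np.ndarray
    shaft_axis: np.ndarray
    femur_length: float


@dataclass(frozen=True)
class JointScene:
    """Both bones in the reference articulation, with ground truth."""

    socket_mesh: TriangleMesh
    socket_patch: SurfacePatch
    socket_truth: SocketTruth
    femur_mesh: TriangleMesh
    femur_patch: SurfacePatch
    femur_truth: FemurTruth
    cartilage_pct: float = 0.0
    cartilage_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))


# ---------------------------------------------------------------------------
# socket


def _rim_extent_deg(spec: SocketSpec, phi_deg: np.ndarray) -> np.ndarray:
    """Local lip extent (degrees past the opening) at azimuth ``phi_deg``."""
    d = np.abs((phi_deg - spec.rim_azimuth_deg + 180.0) % 360.0 - 180.0)
    half = 0.5 * spec.rim_arc_deg
    w = np.where(
        d <= half,
        1.0,
        np.where(
            d <= half + spec.rim_taper_deg,
            0.5 * (1.0 + np.cos(np.pi * (d - half) / max(spec.rim_taper_deg, 1e-9))),
            0.0,
        ),
    )
    return spec.rim_overhang_deg * w


def _sph_dir(theta_deg: np.ndarray, phi_deg: np.ndarray) -> np.ndarray:
    """Unit direction at polar angle theta from +x, azimuth phi (from +y to +z)."""
    th = np.radians(theta_deg)
    ph = np.radians(phi_deg)
    return np.stack(
        [np.cos(th), np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph)], axis=-1
    )


def make_socket(
    spec: SocketSpec, seed: int = 0
) -> tuple[TriangleMesh, SurfacePatch, SocketTruth]:
    """Build the socket bone: a watertight spherical-shell cup with a
    localised overhanging rim lip, plus the acetabular surface patch and
    the exact fit ground truth.

    The generator is deterministic given the spec; the seed only drives
    the optional Gaussian vertex noise (``noise_sigma_mm``).
    """
    res = spec.mesh_resolution
    n_phi = 16 * res
    n_cup = 5 * res  # polar intervals of the cup proper
    n_lip = max(2, res)

    phi = np.arange(n_phi) * 360.0 / n_phi
    theta_open = spec.opening_polar_deg
    extent = np.maximum(_rim_extent_deg(spec, phi), _MIN_LIP_EXTENT_DEG)

    # rows from lip edge to just before the pole; the pole itself is one vertex
    n_rows = n_lip + n_cup  # row n_lip sits exactly at theta_open
    theta = np.empty((n_rows, n_phi))
    for i in range(n_lip):
        theta[i] = theta_open - extent * (1.0 - i / n_lip)
    cup_t = np.arange(n_cup) / n_cup
    theta[n_lip:] = theta_open + (180.0 - theta_open) * cup_t[:, None]

    r_in = spec.cup_radius
    r_out = spec.cup_radius + spec.shell_thickness
    dirs = _sph_dir(theta, phi[None, :])  # (n_rows, n_phi, 3)

    verts: list[np.ndarray] = []
    inner0 = 0
    verts.append((r_in * dirs).reshape(-1, 3))
    inner_pole = n_rows * n_phi
    verts.append(np.array([[-r_in, 0.0, 0.0]]))
    outer0 = inner_pole + 1
    verts.append((r_out * dirs).reshape(-1, 3))
    outer_pole = outer0 + n_rows * n_phi
    verts.append(np.array([[-r_out, 0.0, 0.0]]))
    vertices = np.concatenate(verts, axis=0)

    def ring(base: int, i: int, j: int) -> int:
        return base + i * n_phi + (j % n_phi)

    faces: list[tuple[int, int, int]] = []
    inner_faces: list[int] = []
    # inner surface (articular): wound so normals face the cup interior
    for i in range(n_rows - 1):
        for j in range(n_phi):
            a = ring(inner0, i, j)
            b = ring(inner0, i, j + 1)
            c = ring(inner0, i + 1, j + 1)
            d = ring(inner0, i + 1, j)
            inner_faces += [len(faces), len(faces) + 1]
            faces.append((a, b, c))
            faces.append((a, c, d))
    for j in range(n_phi):
        inner_faces.append(len(faces))
        faces.append((ring(inner0, n_rows - 1, j), ring(inner0, n_rows - 1, j + 1), inner_pole))
    # outer surface, opposite winding
    for i in range(n_rows - 1):
        for j in range(n_phi):
            a = ring(outer0, i, j)
            b = ring(outer0, i, j + 1)
            c = ring(outer0, i + 1, j + 1)
            d = ring(outer0, i + 1, j)
            faces.append((a, c, b))
            faces.append((a, d, c))
    for j in range(n_phi):
        faces.append((ring(outer0, n_rows - 1, j + 1), ring(outer0, n_rows - 1, j), outer_pole))
    # rim edge band joining inner and outer lip-edge rings
    for j in range(n_phi):
        a = ring(inner0, 0, j)
        b = ring(inner0, 0, j + 1)
        c = ring(outer0, 0, j + 1)
        d = ring(outer0, 0, j)
        faces.append((a, b, c))
        faces.append((a, c, d))

    vertices = _apply_noise(vertices, spec.noise_sigma_mm, seed)
    mesh = _oriented(TriangleMesh(vertices, np.asarray(faces), name="socket"))
    patch = SurfacePatch(mesh, np.asarray(inner_faces), label="acetabulum")
    truth = SocketTruth(
        centre=np.zeros(3),
        radius=spec.cup_radius,
        pole_axis=np.array([1.0, 0.0, 0.0]),
        opening_polar_deg=theta_open,
    )
    return mesh, patch, truth


# ---------------------------------------------------------------------------
# femur


def make_femur(
    spec: FemurSpec, seed: int = 0
) -> tuple[TriangleMesh, SurfacePatch, FemurTruth]:
    """Build the femur: an ellipsoidal head lofted into an offset neck
    and a bent cylindrical shaft, as one watertight tube mesh.

    Head vertices lie exactly on the ground-truth ellipsoid; the head
    articular patch is its -x hemisphere (the half facing the cup at
    reference).  ``femur_length = neck_length + shaft_length`` is the
    documented cartilage-percentage base.
    """
    res = spec.mesh_resolution
    n_ring = 6 * res
    a, b, c = spec.head_radii
    r_s = spec.shaft_radius
    dev = np.radians(180.0 - spec.neck_angle_deg)  # shaft deviation from neck axis

    u_cut = 25.0  # head kept down to 25 deg from the +x head pole
    n_back = 3 * res  # rows over the articular (-x) hemisphere
    n_front = max(2, 2 * res)  # rows from the equator down to the neck cut
    u_levels = np.concatenate(
        [np.linspace(180.0, 90.0, n_back + 1), np.linspace(90.0, u_cut, n_front + 1)[1:]]
    )

    rows: list[np.ndarray] = []  # each (n_ring, 3)
    alphas = np.arange(n_ring) * 2.0 * np.pi / n_ring
    ca, sa = np.cos(alphas), np.sin(alphas)
    ey = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])

    def add_row(centre, e1, e2, s1, s2):
        rows.append(centre + s1 * np.outer(ca, e1) + s2 * np.outer(sa, e2))

    for u in u_levels[1:]:  # u=180 is the pole vertex, handled as a fan
        ur = np.radians(u)
        add_row(np.array([a * np.cos(ur), 0.0, 0.0]), ey, ez, b * np.sin(ur), c * np.sin(ur))
    head_last_articular_row = n_back - 1  # row index of the u=90 ring

    # neck: blend the cut ellipse into a circular tube, then run to the bend
    x_cut = a * np.cos(np.radians(u_cut))
    s1_cut, s2_cut = b * np.sin(np.radians(u_cut)), c * np.sin(np.radians(u_cut))
    # blend quickly so the tube narrows to the shaft radius while still
    # inside the head's circumscribed sphere (keeps the effective neck slim)
    x_blend_end = x_cut + min(0.2 * (spec.neck_length - x_cut), 0.16 * max(spec.head_radii))
    n_blend, n_tube = 3, 3
    for x in np.linspace(x_cut, x_blend_end, n_blend + 1)[1:]:
        t = (x - x_cut) / (x_blend_end - x_cut)
        t = t * t * (3 - 2 * t)  # smoothstep
        add_row(np.array([x, 0.0, 0.0]), ey, ez, s1_cut + t * (r_s - s1_cut), s2_cut + t * (r_s - s2_cut))
    for x in np.linspace(x_blend_end, spec.neck_length, n_tube + 1)[1:-1]:
        add_row(np.array([x, 0.0, 0.0]), ey, ez, r_s, r_s)

    # mitre ring at the neck-shaft bend
    bend = np.array([spec.neck_length, 0.0, 0.0])
    d_shaft = np.array([np.cos(dev), 0.0, -np.sin(dev)])
    e_mitre = np.array([np.sin(dev), 0.0, 1.0 + np.cos(dev)])
    e_mitre /= np.linalg.norm(e_mitre)
    add_row(bend, ey, e_mitre, r_s, r_s / np.cos(dev / 2.0))

    # shaft
    e2_shaft = np.array([np.sin(dev), 0.0, np.cos(dev)])
    n_shaft = 3
    for t in np.linspace(0.0, spec.shaft_length, n_shaft + 1)[1:]:
        add_row(bend + t * d_shaft, ey, e2_shaft, r_s, r_s)

    ring_pts = np.asarray(rows)  # (n_rows, n_ring, 3)
    n_rows = ring_pts.shape[0]
    vertices = [ring_pts.reshape(-1, 3)]
    pole = n_rows * n_ring
    vertices.append(np.array([[-a, 0.0, 0.0]]))
    end_centre = pole + 1
    vertices.append((bend + spec.shaft_length * d_shaft)[None, :])
    vertices = np.concatenate(vertices, axis=0)

    faces: list[tuple[int, int, int]] = []
    head_faces: list[int] = []

    def rv(i: int, j: int) -> int:
        return i * n_ring + (j % n_ring)

    for j in range(n_ring):  # head pole fan
        head_faces.append(len(faces))
        faces.append((pole, rv(0, j), rv(0, j + 1)))
    for i in range(n_rows - 1):
        articular = i < head_last_articular_row
        for j in range(n_ring):
            if articular:
                head_faces += [len(faces), len(faces) + 1]
            faces.append((rv(i, j), rv(i + 1, j), rv(i + 1, j + 1)))
            faces.append((rv(i, j), rv(i + 1, j + 1), rv(i, j + 1)))
    for j in range(n_ring):  # distal cap fan
        faces.append((end_centre, rv(n_rows - 1, j + 1), rv(n_rows - 1, j)))

    vertices = _apply_noise(vertices, spec.noise_sigma_mm, seed)
    mesh = _oriented(TriangleMesh(vertices, np.asarray(faces), name="femur"))
    patch = SurfacePatch(mesh, np.asarray(head_faces), label="femoral_head")
    truth = FemurTruth(
        head_centre=np.zeros(3),
        head_semi_axes=np.asarray(spec.head_radii, dtype=np.float64),
        head_axes=np.eye(3),
        neck_axis=np.array([1.0, 0.0, 0.0]),
        shaft_axis=d_shaft,
        femur_length=spec.femur_length,
    )
    return mesh, patch, truth


# ---------------------------------------------------------------------------
# scene


def make_joint_scene(
    socket_spec: SocketSpec,
    femur_spec: FemurSpec,
    cartilage_pct: float = 0.0,
    seed: int = 0,
    allow_tight_fit: bool = False,
) -> JointScene:
    """Articulate a generated socket and femur in the reference pose.

    The femoral head centre coincides with the cup centre, then the
    femur is displaced by ``cartilage_pct × femur_length`` along the
    socket pole axis (out of the cup) — the epiphyseal-cartilage joint
    spacing rule.  All joint rotations are zero at reference.
    """
    if cartilage_pct < 0:
        raise ValueError("cartilage_pct must be >= 0")
    if max(femur_spec.head_radii) >= socket_spec.cup_radius and not allow_tight_fit:
        raise ValueError(
            "femoral head does not fit the cup "
            f"(max semi-axis {max(femur_spec.head_radii)} >= cup radius "
            f"{socket_spec.cup_radius}); pass allow_tight_fit=True to override"
        )
    s_mesh, s_patch, s_truth = make_socket(socket_spec, seed=seed)
    f_mesh, f_patch, f_truth = make_femur(femur_spec, seed=seed)

    offset = cartilage_pct * femur_spec.femur_length * s_truth.pole_axis
    f_mesh = TriangleMesh(f_mesh.vertices + offset, f_mesh.faces, f_mesh.name)
    f_patch = SurfacePatch(f_mesh, f_patch.face_indices, f_patch.label)
    f_truth = replace(f_truth, head_centre=f_truth.head_centre + offset)
    return JointScene(
        socket_mesh=s_mesh,
        socket_patch=s_patch,
        socket_truth=s_truth,
        femur_mesh=f_mesh,
        femur_patch=f_patch,
        femur_truth=f_truth,
        cartilage_pct=cartilage_pct,
        cartilage_offset=offset,
    )


def euparkeria_like_specs() -> tuple[SocketSpec, FemurSpec]:
    """Canned demo: deep cup, 25 deg dorsal rim lip, mildly ellipsoidal
    head.  Qualitative analogue of a well-preserved archosauriform hip
    with a developed supra-acetabular rim; no claim of anatomical
    fidelity."""
    return SocketSpec(), FemurSpec()


def damaged_rim_specs() -> tuple[SocketSpec, FemurSpec]:
    """Canned demo variant: shallower cup with a nearly absent (5 deg)
    rim lip, mimicking a specimen whose supra-acetabular rim is damaged."""
    return replace(SocketSpec(), rim_overhang_deg=5.0, depth_fraction=0.85), FemurSpec()


# ---------------------------------------------------------------------------
# helpers


def _apply_noise(vertices: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    if sigma <= 0:
        return vertices
    rng = np.random.default_rng(seed)
    return vertices + rng.normal(0.0, sigma, size=vertices.shape)


def _oriented(mesh: TriangleMesh) -> TriangleMesh:
    """Flip face winding if the enclosed volume comes out negative."""
    tm = mesh.to_trimesh()
    if tm.is_watertight and tm.volume < 0:
        return TriangleMesh(mesh.vertices, mesh.faces[:, ::-1], mesh.name)
    return mesh
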