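"""Tests for primitive fitting and joint-centre construction."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from osteorom.mesh_core import patch_points
from osteorom.primitive_fit import (
    FitError, fibular_lar_centre, fit_cylinder, fit_ellipsoid, fit_plane,
    fit_sphere, make_joint_centre,
)
from osteorom.synthetic_joints import FemurSpec, make_femur


def _cap_points(rng, centre, radius, polar_max_deg=70.0, n=400, sigma=0.0):
    """Points on a partial spherical cap (articular-surface analogue)."""
    u = rng.uniform(np.cos(np.radians(polar_max_deg)), 1.0, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - u**2)
    pts = centre + radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
    return pts + rng.normal(0, sigma, pts.shape)


# ---------------------------------------------------------------------------
# sphere


def test_sphere_fit_exact(rng):
    pts = _cap_points(rng, np.array([1.0, -2.0, 3.0]), 5.0)
    fit = fit_sphere(pts)
    assert np.allclose(fit.centre, [1, -2, 3], atol=1e-9)
    assert fit.radii[0] == pytest.approx(5.0, abs=1e-9)
    assert fit.rms_residual < 1e-9


def test_sphere_fit_noisy_cap(rng):
    pts = _cap_points(rng, np.array([0.0, 0.0, 0.0]), 5.0, sigma=0.05)
    fit = fit_sphere(pts)
    assert np.linalg.norm(fit.centre) < 0.05
    assert fit.radii[0] == pytest.approx(5.0, rel=0.01)


def test_sphere_fit_matches_independent_nonlinear_oracle(rng):
    """Cross-check against a from-scratch Nelder–Mead formulation."""
    pts = _cap_points(rng, np.array([2.0, 1.0, -1.0]), 4.0, sigma=0.03, n=250)
    fit = fit_sphere(pts)

    def cost(x):
        return np.mean((np.linalg.norm(pts - x[:3], axis=1) - x[3]) ** 2)

    oracle = minimize(cost, np.r_[pts.mean(axis=0), 4.0], method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    assert np.allclose(fit.centre, oracle.x[:3], atol=1e-4)
    assert fit.radii[0] == pytest.approx(oracle.x[3], abs=1e-4)


def test_sphere_fit_rejects_degenerate_inputs(rng):
    with pytest.raises(FitError):
        fit_sphere(np.zeros((3, 3)))
    plane_pts = rng.normal(size=(50, 3)) * np.array([1.0, 1.0, 0.0])
    with pytest.raises(FitError):
        fit_sphere(plane_pts)
    with pytest.raises(FitError):
        fit_sphere(np.full((10, 3), np.nan))


# ---------------------------------------------------------------------------
# ellipsoid


def _ellipsoid_points(rng, centre, semi, axes, n=500, sigma=0.0,
                      polar_max_deg=120.0):
    u = rng.uniform(np.cos(np.radians(polar_max_deg)), 1.0, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - u**2)
    unit = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
    pts = centre + (unit * semi) @ axes
    return pts + rng.normal(0, sigma, pts.shape)


def test_ellipsoid_fit_exact(rng):
    axes = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
    semi = np.array([5.4, 5.1, 4.9])
    pts = _ellipsoid_points(rng, np.array([1.0, 2.0, 3.0]), semi, axes)
    fit = fit_ellipsoid(pts)
    assert np.allclose(fit.centre, [1, 2, 3], atol=1e-6)
    assert np.allclose(fit.radii, semi, rtol=1e-6)


def test_ellipsoid_fit_noisy_partial(rng):
    semi = np.array([5.4, 5.1, 4.9])
    pts = _ellipsoid_points(rng, np.zeros(3), semi, np.eye(3), sigma=0.03)
    fit = fit_ellipsoid(pts)
    assert np.abs(fit.radii / semi - 1).max() < 0.02


def test_ellipsoid_fit_spherical_data_degenerate_fallback(rng):
    """Exactly spherical data break the constrained algebraic stage; the
    sphere-seeded fallback must still return the right ellipsoid."""
    pts = _cap_points(rng, np.array([1.0, 0.0, 0.0]), 6.0, polar_max_deg=90.0)
    fit = fit_ellipsoid(pts)
    assert np.allclose(fit.radii, 6.0, rtol=1e-6)
    assert np.allclose(fit.centre, [1, 0, 0], atol=1e-6)


def test_ellipsoid_recovers_generator_head():
    _, patch, truth = make_femur(FemurSpec(mesh_resolution=2))
    fit = fit_ellipsoid(patch)
    assert np.abs(fit.radii / truth.head_semi_axes - 1).max() < 0.02
    assert np.linalg.norm(fit.centre - truth.head_centre) < 0.02 * truth.head_semi_axes[0]


# ---------------------------------------------------------------------------
# equivariance (applies to all centred fits)


@pytest.mark.parametrize("fitter,maker", [
    (fit_sphere, lambda rng: _cap_points(rng, np.zeros(3), 5.0, sigma=0.02)),
    (fit_ellipsoid, lambda rng: _ellipsoid_points(
        rng, np.zeros(3), np.array([5.4, 5.1, 4.9]), np.eye(3), sigma=0.01)),
])
def test_fit_equivariant_under_rigid_transform(rng, fitter, maker):
    pts = maker(rng)
    base = fitter(pts)
    r = Rotation.from_rotvec([0.4, 0.1, -0.7]).as_matrix()
    t = np.array([10.0, -5.0, 2.0])
    moved = fitter(pts @ r.T + t)
    assert np.allclose(moved.centre, r @ base.centre + t, atol=1e-5)
    assert np.allclose(moved.radii, base.radii, rtol=1e-6)
    assert moved.rms_residual == pytest.approx(base.rms_residual, abs=1e-7)


# ---------------------------------------------------------------------------
# cylinder


def _cylinder_points(rng, axis_point, axis_dir, radius, length, n=400, sigma=0.0):
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    u = np.array([1.0, 0.0, 0.0])
    if abs(u @ axis_dir) > 0.9:
        u = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis_dir, u)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_dir, e1)
    t = rng.uniform(-length / 2, length / 2, n)
    phi = rng.uniform(0, 1.2 * np.pi, n)  # partial arc, articular-like
    pts = (axis_point + np.outer(t, axis_dir)
           + radius * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)))
    return pts + rng.normal(0, sigma, pts.shape)


def test_cylinder_fit_recovers_truth(rng):
    axis_dir = np.array([1.0, 2.0, 0.5])
    fit = fit_cylinder(_cylinder_points(rng, np.array([1.0, 0.0, -2.0]),
                                        axis_dir, 3.0, 12.0, sigma=0.01))
    got = fit.axes[0]
    want = axis_dir / np.linalg.norm(axis_dir)
    assert min(np.linalg.norm(got - want), np.linalg.norm(got + want)) < 0.01
    assert fit.radii[0] == pytest.approx(3.0, rel=0.01)
    # fitted axis point lies on the true axis
    off = fit.centre - np.array([1.0, 0.0, -2.0])
    assert np.linalg.norm(off - (off @ want) * want) < 0.05


def test_cylinder_fit_requires_enough_points():
    with pytest.raises(FitError):
        fit_cylinder(np.zeros((4, 3)))


# ---------------------------------------------------------------------------
# plane


def test_plane_fit_recovers_normal(rng):
    normal = np.array([1.0, -1.0, 2.0]) / np.sqrt(6.0)
    e1 = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
    e2 = np.cross(normal, e1)
    uv = rng.uniform(-3, 3, (200, 2))
    pts = np.array([2.0, 0.0, 1.0]) + np.outer(uv[:, 0], e1) + np.outer(uv[:, 1], e2)
    pts += rng.normal(0, 0.01, pts.shape) * normal
    fit = fit_plane(pts, outward_hint=normal)
    assert np.linalg.norm(fit.axes[0] - normal) < 1e-3
    assert fit.rms_residual < 0.02
    assert not fit.has_centre
    flipped = fit_plane(pts, outward_hint=-normal)
    assert np.linalg.norm(flipped.axes[0] + normal) < 1e-3


def test_plane_fit_rejects_collinear():
    line = np.outer(np.linspace(0, 1, 30), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(FitError):
        fit_plane(line)


# ---------------------------------------------------------------------------
# joint centres


def test_joint_centre_socket_pivot_rule(rng):
    socket = fit_sphere(_cap_points(rng, np.array([0.0, 0.0, 0.0]), 6.0))
    head = fit_sphere(_cap_points(rng, np.array([0.5, 0.0, 0.0]), 5.0))
    jc = make_joint_centre(socket, head)
    assert np.allclose(jc.position, socket.centre)
    assert np.allclose(jc.pinned_point, head.centre)
    swapped = make_joint_centre(socket, head, rule="head_pivot")
    assert np.allclose(swapped.position, head.centre)


def test_joint_centre_with_plane_uses_other_centre(rng):
    sphere = fit_sphere(_cap_points(rng, np.zeros(3), 5.0))
    plane = fit_plane(rng.normal(size=(50, 3)) * np.array([1.0, 1.0, 0.0]))
    jc = make_joint_centre(plane, sphere)
    assert np.allclose(jc.position, sphere.centre)
    with pytest.raises(FitError):
        make_joint_centre(plane, plane)
    with pytest.raises(ValueError):
        make_joint_centre(sphere, sphere, rule="nonsense")


def test_fibular_lar_centre(coarse_femur):
    _, patch, truth = coarse_femur
    jc = fibular_lar_centre(patch)
    # sphere fitted to a partial triaxial cap: centre is biased but close
    assert np.linalg.norm(jc.position - truth.head_centre) < 0.1 * truth.head_semi_axes[0]
    assert np.allclose(jc.position, jc.pinned_point)


def test_fit_serialisation(rng):
    fit = fit_sphere(_cap_points(rng, np.zeros(3), 5.0))
    d = fit.to_dict()
    assert d["kind"] == "sphere" and len(d["centre"]) == 3
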