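"""Low-level vectorised triangle geometry.

Everything here operates on raw ``(n, 3, 3)`` triangle arrays (triangle,
corner, xyz) in float64 and is shared by mesh validation, clearance
queries and the collision detector.  Two independent triangle–triangle
overlap predicates are provided on purpose:

* :func:`tri_tri_overlap_interval` — signed-distance / interval test in
  the style of Möller's 1997 algorithm (used by the accelerated
  collision path);
* :func:`tri_tri_overlap_pierce` — edge-piercing formulation (each edge
  of one triangle tested for a strict crossing through the interior of
  the other), used as the brute-force oracle.

Both treat mere surface contact (separation below ``tol``) as
non-overlapping: only transversal crossings with positive intersection
length count.  Coplanar pairs therefore never "overlap" here — a shared
face patch has no interpenetration volume.
"""

from __future__ import annotations

import numpy as np

#: default geometric tolerance, millimetre scale
TOL = 1e-9


# ---------------------------------------------------------------------------
# bounding boxes


def tri_aabbs(tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-triangle axis-aligned bounding boxes ``(lo, hi)``, each (n, 3)."""
    return tris.min(axis=1), tris.max(axis=1)


def aabb_overlap_pairs(
    lo_a: np.ndarray,
    hi_a: np.ndarray,
    lo_b: np.ndarray,
    hi_b: np.ndarray,
    pad: float = TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices ``(ia, ib)`` of box pairs that overlap (padded by ``pad``)."""
    # (na, nb) broadcast; fine for the mesh sizes this pipeline targets
    ok = np.ones((lo_a.shape[0], lo_b.shape[0]), dtype=bool)
    for k in range(3):
        ok &= lo_a[:, k, None] <= hi_b[None, :, k] + pad
        ok &= lo_b[None, :, k] <= hi_a[:, k, None] + pad
    return np.nonzero(ok)


# ---------------------------------------------------------------------------
# triangle–triangle overlap, interval formulation


def _plane_dists(tris: np.ndarray, n: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Signed distances of each triangle corner to plane (n, d): (k, 3)."""
    return np.einsum("kij,kj->ki", tris, n) + d[:, None]


def tri_tri_overlap_interval(t1: np.ndarray, t2: np.ndarray, tol: float = TOL) -> np.ndarray:
    """Strict overlap test for paired triangles ``t1[i]`` vs ``t2[i]``.

    Returns a boolean array of length k.  Implements the interval
    (signed-distance) formulation: reject when one triangle lies
    entirely on one side of the other's plane, otherwise intersect the
    spans the two triangles cut out of the common plane–plane line.
    """
    t1 = np.asarray(t1, dtype=np.float64).reshape(-1, 3, 3)
    t2 = np.asarray(t2, dtype=np.float64).reshape(-1, 3, 3)
    k = t1.shape[0]
    out = np.zeros(k, dtype=bool)
    if k == 0:
        return out

    n2 = np.cross(t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 0])
    d2 = -np.einsum("kj,kj->k", n2, t2[:, 0])
    dv1 = _plane_dists(t1, n2, d2)

    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    d1 = -np.einsum("kj,kj->k", n1, t1[:, 0])
    dv2 = _plane_dists(t2, n1, d1)

    # scale-aware tolerance per pair
    scale1 = np.abs(dv1).max(axis=1) + np.linalg.norm(n2, axis=1)
    scale2 = np.abs(dv2).max(axis=1) + np.linalg.norm(n1, axis=1)
    eps1 = tol * np.maximum(scale1, 1.0)
    eps2 = tol * np.maximum(scale2, 1.0)

    # strict interpenetration requires each triangle to straddle the
    # other's plane: vertices beyond tolerance on BOTH sides.  Touching
    # configurations (contact within tolerance, shared edges/vertices)
    # have zero penetration volume and do not count.  Coplanar pairs are
    # excluded by the same rule.
    straddle_1 = (dv1 > eps1[:, None]).any(axis=1) & (dv1 < -eps1[:, None]).any(axis=1)
    straddle_2 = (dv2 > eps2[:, None]).any(axis=1) & (dv2 < -eps2[:, None]).any(axis=1)
    cand = straddle_1 & straddle_2
    if not cand.any():
        return out

    idx = np.nonzero(cand)[0]
    s1 = _line_span(t1[idx], dv1[idx], np.cross(n1[idx], n2[idx]))
    s2 = _line_span(t2[idx], dv2[idx], np.cross(n1[idx], n2[idx]))
    valid = ~(np.isnan(s1).any(axis=1) | np.isnan(s2).any(axis=1))
    lo = np.maximum(s1[:, 0], s2[:, 0])
    hi = np.minimum(s1[:, 1], s2[:, 1])
    span_scale = np.maximum(
        np.maximum(np.abs(s1).max(axis=1), np.abs(s2).max(axis=1)), 1.0
    )
    out[idx] = valid & (hi - lo > tol * span_scale)
    return out


def _line_span(tris: np.ndarray, dists: np.ndarray, line_dir: np.ndarray) -> np.ndarray:
    """Span (t_lo, t_hi) a triangle cuts from the plane–plane line.

    ``dists`` are the corners' signed distances to the *other* plane;
    the triangle crosses that plane, so exactly one corner is alone on
    its side.  Projection onto the dominant axis of ``line_dir`` keeps
    the parametrisation shared between both triangles of a pair.
    """
    k = tris.shape[0]
    axis = np.abs(line_dir).argmax(axis=1)
    proj = np.take_along_axis(tris, axis[:, None, None], axis=2)[:, :, 0]  # (k, 3)

    span = np.full((k, 2), np.nan)
    sign = np.sign(dists)
    for lone in range(3):
        o1, o2 = (lone + 1) % 3, (lone + 2) % 3
        sel = (sign[:, lone] != sign[:, o1]) & (sign[:, lone] != sign[:, o2])
        sel &= sign[:, lone] != 0
        if not sel.any():
            continue
        i = np.nonzero(sel)[0]
        for j, other in enumerate((o1, o2)):
            denom = dists[i, lone] - dists[i, other]
            frac = dists[i, lone] / denom
            span[i, j] = proj[i, lone] + (proj[i, other] - proj[i, lone]) * frac
    span.sort(axis=1)
    return span


# ---------------------------------------------------------------------------
# triangle–triangle overlap, edge-piercing formulation (oracle)


def _point_in_triangles(x: np.ndarray, tris: np.ndarray, eps: float) -> np.ndarray:
    """Strict barycentric interior test for points already in-plane."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    v0, v1, v2 = b - a, c - a, x - a
    d00 = np.einsum("kj,kj->k", v0, v0)
    d01 = np.einsum("kj,kj->k", v0, v1)
    d11 = np.einsum("kj,kj->k", v1, v1)
    d20 = np.einsum("kj,kj->k", v2, v0)
    d21 = np.einsum("kj,kj->k", v2, v1)
    denom = d00 * d11 - d01 * d01
    ok = denom > 0
    v = np.where(ok, (d11 * d20 - d01 * d21) / np.where(ok, denom, 1.0), -1.0)
    w = np.where(ok, (d00 * d21 - d01 * d20) / np.where(ok, denom, 1.0), -1.0)
    u = 1.0 - v - w
    return (u > eps) & (v > eps) & (w > eps)


def _segments_pierce_triangles(
    p0: np.ndarray, p1: np.ndarray, tris: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment (p0[i], p1[i]) vs tris[i] plane crossing.

    Returns ``(strict, loose, x)``: strict = crossing point strictly
    interior, loose = crossing point interior or on the boundary, x =
    crossing point (garbage where the segment does not straddle the
    plane, flagged by ``loose`` being False there too).
    """
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    n = np.cross(b - a, c - a)
    d0 = np.einsum("kj,kj->k", p0 - a, n)
    d1 = np.einsum("kj,kj->k", p1 - a, n)
    scale = np.maximum(np.maximum(np.abs(d0), np.abs(d1)), 1.0)
    crosses = (d0 * d1 < 0) & (np.abs(d0) > tol * scale) & (np.abs(d1) > tol * scale)
    k = tris.shape[0]
    strict = np.zeros(k, dtype=bool)
    loose = np.zeros(k, dtype=bool)
    x_out = np.zeros((k, 3))
    if not crosses.any():
        return strict, loose, x_out
    i = np.nonzero(crosses)[0]
    t = d0[i] / (d0[i] - d1[i])
    x = p0[i] + t[:, None] * (p1[i] - p0[i])
    x_out[i] = x
    # barycentric test
    v0 = b[i] - a[i]
    v1 = c[i] - a[i]
    v2 = x - a[i]
    d00 = np.einsum("kj,kj->k", v0, v0)
    d01 = np.einsum("kj,kj->k", v0, v1)
    d11 = np.einsum("kj,kj->k", v1, v1)
    d20 = np.einsum("kj,kj->k", v2, v0)
    d21 = np.einsum("kj,kj->k", v2, v1)
    denom = d00 * d11 - d01 * d01
    ok = denom > 0
    v = np.where(ok, (d11 * d20 - d01 * d21) / np.where(ok, denom, 1.0), -1.0)
    w = np.where(ok, (d00 * d21 - d01 * d20) / np.where(ok, denom, 1.0), -1.0)
    u = 1.0 - v - w
    strict[i] = (u > tol) & (v > tol) & (w > tol)
    loose[i] = (u > -tol) & (v > -tol) & (w > -tol)
    return strict, loose, x_out


def tri_tri_overlap_pierce(t1: np.ndarray, t2: np.ndarray, tol: float = TOL) -> np.ndarray:
    """Independent strict overlap predicate: any edge of one triangle
    strictly pierces the interior of the other.

    Degeneracy rescue: when every edge–plane crossing point of a pair
    lands exactly on the other triangle's boundary (congruent
    tessellations can do this), the crossing *segment* may still run
    through both interiors.  Pairs with two or more boundary-grade
    crossing points and no strict hit are re-examined by testing
    midpoints of crossing-point pairs for strict interiority in both
    triangles.
    """
    t1 = np.asarray(t1, dtype=np.float64).reshape(-1, 3, 3)
    t2 = np.asarray(t2, dtype=np.float64).reshape(-1, 3, 3)
    n_pairs = t1.shape[0]
    hit = np.zeros(n_pairs, dtype=bool)
    loose_masks = []
    points = []
    for e in range(3):
        s_a, l_a, x_a = _segments_pierce_triangles(t1[:, e], t1[:, (e + 1) % 3], t2, tol)
        s_b, l_b, x_b = _segments_pierce_triangles(t2[:, e], t2[:, (e + 1) % 3], t1, tol)
        hit |= s_a | s_b
        loose_masks.extend((l_a, l_b))
        points.extend((x_a, x_b))
    n_loose = np.sum(loose_masks, axis=0)
    rescue = np.nonzero(~hit & (n_loose >= 2))[0]
    for i in rescue:
        xs = [p[i] for m, p in zip(loose_masks, points) if m[i]]
        for j in range(len(xs)):
            for k in range(j + 1, len(xs)):
                mid = 0.5 * (xs[j] + xs[k])[None, :]
                if (_point_in_triangles(mid, t1[i : i + 1], tol)[0]
                        and _point_in_triangles(mid, t2[i : i + 1], tol)[0]):
                    hit[i] = True
                    break
            if hit[i]:
                break
    return hit


# ---------------------------------------------------------------------------
# ray casting / containment


_RAY_DIR = np.array([0.5773502691896258, 0.26726124191242440, 0.7715167498104596])
_RAY_DIR = _RAY_DIR / np.linalg.norm(_RAY_DIR)


def ray_crossings(origin: np.ndarray, tris: np.ndarray, direction: np.ndarray | None = None) -> int:
    """Number of triangles a ray from ``origin`` crosses (Möller–Trumbore)."""
    d = _RAY_DIR if direction is None else np.asarray(direction, dtype=np.float64)
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    p = np.cross(d[None, :], e2)
    det = np.einsum("kj,kj->k", e1, p)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origin[None, :] - v0
    u = np.einsum("kj,kj->k", s, p) * inv
    q = np.cross(s, e1)
    v = np.einsum("kj,j->k", q, d) * inv
    t = np.einsum("kj,kj->k", q, e2) * inv
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > TOL)
    return int(hit.sum())


def point_in_mesh(point: np.ndarray, tris: np.ndarray) -> bool:
    """Ray-parity containment test; assumes a closed triangle soup."""
    return ray_crossings(np.asarray(point, dtype=np.float64), tris) % 2 == 1


# ---------------------------------------------------------------------------
# point–triangle distance


def closest_points_on_triangles(points: np.ndarray, tris: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest point on any of ``tris`` for each query point.

    Returns ``(distances, closest_points, tri_index)``.  Fully
    vectorised over the (points × triangles) product, chunked over
    points to bound memory.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    tris = np.asarray(tris, dtype=np.float64).reshape(-1, 3, 3)
    n_pts = points.shape[0]
    dist = np.empty(n_pts)
    closest = np.empty((n_pts, 3))
    tri_idx = np.empty(n_pts, dtype=np.int64)
    chunk = max(1, int(4e6 // max(tris.shape[0], 1)))
    for s in range(0, n_pts, chunk):
        p = points[s : s + chunk]
        d2, cp = _closest_block(p, tris)
        j = d2.argmin(axis=1)
        i = np.arange(p.shape[0])
        dist[s : s + chunk] = np.sqrt(d2[i, j])
        closest[s : s + chunk] = cp[i, j]
        tri_idx[s : s + chunk] = j
    return dist, closest, tri_idx


def _closest_block(points: np.ndarray, tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared distances and closest points, (np, nt) and (np, nt, 3).

    Candidate-based: the closest point is either the in-triangle plane
    projection or lies on one of the three edges; take the best.
    """
    a = tris[None, :, 0]  # (1, nt, 3)
    b = tris[None, :, 1]
    c = tris[None, :, 2]
    p = points[:, None, :]  # (np, 1, 3)

    best_cp = _closest_on_segment(p, a, b)
    best_d2 = ((p - best_cp) ** 2).sum(-1)
    for s0, s1 in ((b, c), (c, a)):
        cp = _closest_on_segment(p, s0, s1)
        d2 = ((p - cp) ** 2).sum(-1)
        better = d2 < best_d2
        best_d2 = np.where(better, d2, best_d2)
        best_cp = np.where(better[..., None], cp, best_cp)

    # plane projection, kept only when it falls inside the triangle
    n = np.cross(b - a, c - a)
    nn = (n**2).sum(-1)
    nn_safe = np.where(nn > 0, nn, 1.0)
    t = ((p - a) * n).sum(-1) / nn_safe
    proj = p - t[..., None] * n
    v0, v1, v2 = b - a, c - a, proj - a
    d00 = (v0 * v0).sum(-1)
    d01 = (v0 * v1).sum(-1)
    d11 = (v1 * v1).sum(-1)
    d20 = (v2 * v0).sum(-1)
    d21 = (v2 * v1).sum(-1)
    denom = d00 * d11 - d01 * d01
    denom_safe = np.where(np.abs(denom) > 0, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / denom_safe
    w = (d00 * d21 - d01 * d20) / denom_safe
    inside = (v >= 0) & (w >= 0) & (v + w <= 1) & (nn > 0) & (np.abs(denom) > 0)
    d2p = ((p - proj) ** 2).sum(-1)
    better = inside & (d2p < best_d2)
    best_d2 = np.where(better, d2p, best_d2)
    best_cp = np.where(better[..., None], proj, best_cp)
    return best_d2, best_cp


def _closest_on_segment(p: np.ndarray, s0: np.ndarray, s1: np.ndarray) -> np.ndarray:
    d = s1 - s0
    dd = (d * d).sum(-1)
    dd_safe = np.where(dd > 0, dd, 1.0)
    t = np.clip(((p - s0) * d).sum(-1) / dd_safe, 0.0, 1.0)
    return s0 + t[..., None] * d
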