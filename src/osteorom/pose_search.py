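"""Exhaustive 3-DOF pose sampling with interpenetration rejection.

The osteological range of motion is mapped by sampling every (FE,
ABAD, LAR) combination on a regular lattice and testing each posed
femur for mesh interpenetration with the pelvis.  Every cell is tested
explicitly — there are no skipped or default states — and the sweep is
fully deterministic, so any execution order yields the same lattice.

Collision testing is two-phase: a vectorised axis-aligned bounding-box
broad phase prunes triangle pairs, and an exact triangle–triangle
narrow phase decides overlap.  Surface contact (separation below the
geometric tolerance) counts as viable: only true interpenetration
volumes reject a pose.  A brute-force all-pairs detector with an
independently formulated overlap predicate is provided as an oracle.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry
from .joint_frames import CartilageRule, JointCoordinateSystem, JointPose, pose_transform
from .mesh_core import RigidTransform, TriangleMesh

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """The (FE × ABAD × LAR) sampling lattice, degrees.

    Defaults are the full-circle hip grid: FE and LAR from −180° to
    180°, ABAD from −90° to 90°, at 5° increments; both ±180° endpoints
    are sampled as distinct cells (the periodic seam can be merged
    downstream).
    """

    fe_range: tuple[float, float] = (-180.0, 180.0)
    abad_range: tuple[float, float] = (-90.0, 90.0)
    lar_range: tuple[float, float] = (-180.0, 180.0)
    step: float = 5.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        for name, (lo, hi) in (
            ("fe", self.fe_range), ("abad", self.abad_range), ("lar", self.lar_range)
        ):
            if hi < lo:
                raise ValueError(f"{name}_range is not well ordered")
            n = (hi - lo) / self.step
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name}_range span is not divisible by step")

    def _axis(self, rng: tuple[float, float]) -> np.ndarray:
        n = int(round((rng[1] - rng[0]) / self.step)) + 1
        return rng[0] + self.step * np.arange(n)

    @property
    def fe_values(self) -> np.ndarray:
        return self._axis(self.fe_range)

    @property
    def abad_values(self) -> np.ndarray:
        return self._axis(self.abad_range)

    @property
    def lar_values(self) -> np.ndarray:
        return self._axis(self.lar_range)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.fe_values), len(self.abad_values), len(self.lar_values))

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class PoseGrid:
    """Per-cell viability verdicts over a GridSpec lattice.

    ``viable[i, j, k]`` corresponds to (fe_values[i], abad_values[j],
    lar_values[k]); every cell holds an explicit collision verdict.
    """

    spec: GridSpec
    viable: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.viable, dtype=bool)
        object.__setattr__(self, "viable", v)
        if v.shape != self.spec.shape:
            raise ValueError(f"lattice shape {v.shape} != spec shape {self.spec.shape}")

    # -- serialisation -------------------------------------------------------

    def to_csv(self, path: str | Path) -> Path:
        """Long-format CSV: fe,abad,lar,viable — one row per cell."""
        path = Path(path)
        fe, ab, la = np.meshgrid(
            self.spec.fe_values, self.spec.abad_values, self.spec.lar_values,
            indexing="ij",
        )
        buf = io.StringIO()
        buf.write("fe,abad,lar,viable\n")
        flat = np.column_stack(
            [fe.ravel(), ab.ravel(), la.ravel(), self.viable.ravel().astype(int)]
        )
        np.savetxt(buf, flat, fmt=["%.10g", "%.10g", "%.10g", "%d"], delimiter=",")
        path.write_text(buf.getvalue())
        return path

    @classmethod
    def from_csv(cls, path: str | Path, spec: GridSpec, meta: dict | None = None) -> "PoseGrid":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        if data.shape[0] != spec.n_cells:
            raise ValueError("CSV row count does not match the grid spec")
        viable = data[:, 3].astype(bool).reshape(spec.shape)
        return cls(spec, viable, meta or {})

    def to_binary(self, path_prefix: str | Path) -> tuple[Path, Path]:
        """Compact packed-bit lattice plus a JSON header; lossless."""
        prefix = Path(path_prefix)
        bin_path = prefix.with_suffix(".bin")
        hdr_path = prefix.with_suffix(".json")
        bin_path.write_bytes(np.packbits(self.viable.ravel()).tobytes())
        hdr_path.write_text(json.dumps({
            "fe_range": list(self.spec.fe_range),
            "abad_range": list(self.spec.abad_range),
            "lar_range": list(self.spec.lar_range),
            "step": self.spec.step,
            "shape": list(self.spec.shape),
            "meta": self.meta,
        }, indent=2))
        return bin_path, hdr_path

    @classmethod
    def from_binary(cls, path_prefix: str | Path) -> "PoseGrid":
        prefix = Path(path_prefix)
        hdr = json.loads(prefix.with_suffix(".json").read_text())
        spec = GridSpec(
            tuple(hdr["fe_range"]), tuple(hdr["abad_range"]),
            tuple(hdr["lar_range"]), hdr["step"],
        )
        bits = np.frombuffer(prefix.with_suffix(".bin").read_bytes(), dtype=np.uint8)
        viable = np.unpackbits(bits)[: spec.n_cells].astype(bool).reshape(spec.shape)
        return cls(spec, viable, hdr.get("meta", {}))


def viable_count(grid: PoseGrid) -> int:
    """Number of osteologically viable poses (true cells)."""
    return int(grid.viable.sum())


# ---------------------------------------------------------------------------
# collision detection


class _FixedMeshCollider:
    """Precomputed broad-phase data for one static mesh."""

    def __init__(self, fixed: TriangleMesh):
        self.mesh = fixed
        self.tris = fixed.triangles()
        self.lo, self.hi = geometry.tri_aabbs(self.tris)
        self.bounds = (self.lo.min(axis=0), self.hi.max(axis=0))
        self.watertight = fixed.is_watertight()

    def intersects(self, moving_tris: np.ndarray, moving_watertight: bool,
                   predicate=geometry.tri_tri_overlap_interval) -> bool:
        mlo, mhi = geometry.tri_aabbs(moving_tris)
        # whole-mesh reject
        if (mlo.min(axis=0) > self.bounds[1] + geometry.TOL).any() or (
            self.bounds[0] > mhi.max(axis=0) + geometry.TOL
        ).any():
            return False
        ia, ib = geometry.aabb_overlap_pairs(self.lo, self.hi, mlo, mhi)
        if ia.size and predicate(self.tris[ia], moving_tris[ib]).any():
            return True
        # no surface crossing: check full containment via ray parity
        if self.watertight and geometry.point_in_mesh(moving_tris[0, 0], self.tris):
            return True
        if moving_watertight and geometry.point_in_mesh(self.tris[0, 0], moving_tris):
            return True
        return False


def meshes_intersect(
    fixed: TriangleMesh,
    moving: TriangleMesh,
    transform: RigidTransform | None = None,
    method: str = "bvh",
) -> bool:
    """True iff the posed ``moving`` mesh interpenetrates ``fixed``.

    True when any triangle pair strictly overlaps, or when one mesh is
    entirely contained in the other (ray-parity test on a representative
    vertex; skipped with a warning for non-watertight meshes —
    surface-intersection-only mode).  ``method='bvh'`` uses the
    bounding-box broad phase; ``method='brute'`` tests all triangle
    pairs with the independent edge-piercing predicate (the oracle).
    """
    if method not in ("bvh", "brute"):
        raise ValueError(f"unknown collision method {method!r}")
    mtris = (moving.triangles() if transform is None
             else transform.apply(moving.vertices)[moving.faces])

    fixed_watertight = fixed.is_watertight()
    moving_watertight = moving.is_watertight()
    if not fixed_watertight or not moving_watertight:
        log.warning(
            "non-watertight mesh: containment check limited to "
            "surface-intersection-only mode"
        )
    ftris = fixed.triangles()
    if method == "brute":
        n_f, n_m = ftris.shape[0], mtris.shape[0]
        ia = np.repeat(np.arange(n_f), n_m)
        ib = np.tile(np.arange(n_m), n_f)
        if geometry.tri_tri_overlap_pierce(ftris[ia], mtris[ib]).any():
            return True
        if fixed_watertight and geometry.point_in_mesh(mtris[0, 0], ftris):
            return True
        if moving_watertight and geometry.point_in_mesh(ftris[0, 0], mtris):
            return True
        return False
    collider = _FixedMeshCollider(fixed)
    return collider.intersects(mtris, moving_watertight)


# ---------------------------------------------------------------------------
# the sweep


def sweep_grid(
    scene,
    jcs: JointCoordinateSystem,
    cartilage: CartilageRule,
    spec: GridSpec,
    method: str = "bvh",
    log_every: int = 0,
) -> PoseGrid:
    """Test every lattice cell for bone–bone interpenetration.

    The reference pose is tested like any other cell.  The femur is
    posed by rotating its canonical reference placement (pinned point at
    the joint centre, no cartilage offset) with
    :func:`~osteorom.joint_frames.pose_transform`, which appends the
    cartilage offset.

    Because every pose rotates the femur about the fixed joint centre,
    femur triangles whose maximum distance from the pivot (plus the
    cartilage offset) is below the socket's minimum distance from the
    pivot can never collide; they are culled once, exactly, before the
    sweep.  The verdict per cell is unchanged by the culling.
    """
    fixed = scene.socket_mesh
    moving = scene.femur_mesh
    pivot = np.asarray(jcs.centre.position, dtype=np.float64)
    # canonical reference placement: undo the scene's cartilage offset
    canon_verts = moving.vertices - getattr(scene, "cartilage_offset", 0.0)

    collider = _FixedMeshCollider(fixed)
    fixed_min_r = float(
        geometry.closest_points_on_triangles(pivot[None, :], collider.tris)[0][0]
    )
    tri_r = np.linalg.norm(canon_verts[moving.faces] - pivot, axis=2).max(axis=1)
    keep = tri_r + np.linalg.norm(cartilage.offset_vector) >= fixed_min_r - geometry.TOL
    faces = moving.faces[keep]
    moving_watertight = moving.is_watertight()
    log.info(
        "sweep: %d cells, %d fixed tris, %d/%d moving tris after pivot culling",
        spec.n_cells, collider.tris.shape[0], faces.shape[0], moving.faces.shape[0],
    )

    predicate = (geometry.tri_tri_overlap_interval if method == "bvh"
                 else geometry.tri_tri_overlap_pierce)
    fe_vals, ab_vals, la_vals = spec.fe_values, spec.abad_values, spec.lar_values
    viable = np.empty(spec.shape, dtype=bool)
    n_done = 0
    for i, fe in enumerate(fe_vals):
        for j, ab in enumerate(ab_vals):
            for k, la in enumerate(la_vals):
                t = pose_transform(jcs, JointPose(fe, ab, la), cartilage)
                tris = (canon_verts @ t.rotation.T + t.translation)[faces]
                try:
                    hit = collider.intersects(tris, moving_watertight, predicate)
                except Exception as exc:
                    raise RuntimeError(
                        f"collision test failed at cell (fe={fe}, abad={ab}, lar={la})"
                    ) from exc
                viable[i, j, k] = not hit
                n_done += 1
                if log_every and n_done % log_every == 0:
                    log.info("sweep progress: %d/%d cells", n_done, spec.n_cells)
    meta = {
        "method": method,
        "cartilage_pct": cartilage.pct,
        "n_cells": spec.n_cells,
        "n_viable": int(viable.sum()),
    }
    log.info("sweep done: %(n_viable)d/%(n_cells)d viable", meta)
    return PoseGrid(spec, viable, meta)


def sweep_grid_free(spec: GridSpec) -> PoseGrid:
    """Sweep with no opposing bone: every explicitly enumerated cell is
    viable (nothing to collide with)."""
    shape = spec.shape
    viable = np.ones(shape, dtype=bool)
    # explicit enumeration of every cell, honouring the no-skip contract
    count = sum(1 for _ in np.ndindex(*shape))
    assert count == spec.n_cells
    return PoseGrid(spec, viable, {"method": "free", "n_cells": count,
                                   "n_viable": count})
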