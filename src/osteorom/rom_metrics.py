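"""Results-level quantities derived from a viability lattice.

Given a swept :class:`~osteorom.pose_search.PoseGrid`, this module
computes mobility summaries: viable-pose counts, ROM volumes in
degrees³, 2-D cross-sections, connected components of the viable set
(the "locking" analysis), extreme poses under constraints, and joint
spacing across primitive/cartilage configurations.

Two ROM volume definitions are provided.  The naive volume assigns
``step³`` per viable cell.  Because an Euler grid oversamples
orientations near |ABAD| → 90° (lattice cells there cover less solid
angle), a cosine-corrected volume weighting each cell by cos(ABAD) is
also computed and is the default; both are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .joint_frames import CartilageRule, JointPose
from .mesh_core import RigidTransform, signed_clearance
from .pose_search import GridSpec, PoseGrid
from .primitive_fit import fit_ellipsoid, fit_sphere, make_joint_centre

SEAM_POLICIES = ("endpoints-distinct", "seam-merged")


@dataclass(frozen=True)
class RomSummary:
    """Counts, volumes and connectivity of the viable pose set."""

    n_viable: int
    n_cells: int
    volume_naive_deg3: float
    volume_cosine_deg3: float
    n_components: int
    component_sizes: tuple[int, ...]
    seam_policy: str

    def to_dict(self) -> dict:
        return {
            "n_viable": self.n_viable,
            "n_cells": self.n_cells,
            "volume_naive_deg3": self.volume_naive_deg3,
            "volume_cosine_deg3": self.volume_cosine_deg3,
            "n_components": self.n_components,
            "component_sizes": list(self.component_sizes),
            "seam_policy": self.seam_policy,
        }


@dataclass(frozen=True)
class CrossSection:
    """A 2-D slice of the lattice at a fixed axis value."""

    fixed_axis: str  # FE | ABAD | LAR
    fixed_value: float
    row_axis: str
    col_axis: str
    row_values: np.ndarray
    col_values: np.ndarray
    map: np.ndarray  # 2-D boolean

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            self.map.astype(int), index=self.row_values, columns=self.col_values
        )
        df.index.name = f"{self.row_axis}\\{self.col_axis}"
        df.to_csv(path)
        return path

    def to_png(self, path: str | Path) -> Path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.imshow(
            self.map.T, origin="lower", aspect="auto", cmap="Greys", vmin=0, vmax=1,
            extent=(
                self.row_values[0], self.row_values[-1],
                self.col_values[0], self.col_values[-1],
            ),
        )
        ax.set_xlabel(f"{self.row_axis} (deg)")
        ax.set_ylabel(f"{self.col_axis} (deg)")
        ax.set_title(f"{self.fixed_axis} = {self.fixed_value:g} deg")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)


# ---------------------------------------------------------------------------
# volumes


def rom_volume(grid: PoseGrid, method: str = "cosine") -> float:
    """ROM volume in degrees³.

    ``naive``: n_viable × step³ exactly.  ``cosine``: step³ × Σ
    cos(ABAD) over viable cells, compensating the Euler-grid
    oversampling near |ABAD| = 90°.
    """
    step3 = grid.spec.step**3
    if method == "naive":
        return float(grid.viable.sum()) * step3
    if method == "cosine":
        cos_ab = np.cos(np.radians(grid.spec.abad_values))
        return float(step3 * (grid.viable.sum(axis=(0, 2)) @ cos_ab))
    raise ValueError(f"unknown volume method {method!r}")


# ---------------------------------------------------------------------------
# slicing


_AXES = ("FE", "ABAD", "LAR")


def _axis_values(spec: GridSpec, axis: str) -> np.ndarray:
    return {"FE": spec.fe_values, "ABAD": spec.abad_values, "LAR": spec.lar_values}[axis]


def cross_section(grid: PoseGrid, axis: str, value: float) -> CrossSection:
    """The 2-D viability map at a fixed FE, ABAD or LAR lattice value."""
    axis = axis.upper()
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}")
    vals = _axis_values(grid.spec, axis)
    idx = np.nonzero(np.isclose(vals, value, atol=1e-9))[0]
    if idx.size == 0:
        near = vals[np.argsort(np.abs(vals - value))[:2]]
        raise ValueError(
            f"{axis} = {value} is not on the lattice; nearest values: {sorted(near)}"
        )
    dim = _AXES.index(axis)
    sl = [slice(None)] * 3
    sl[dim] = idx[0]
    remaining = [a for a in _AXES if a != axis]
    return CrossSection(
        fixed_axis=axis,
        fixed_value=float(vals[idx[0]]),
        row_axis=remaining[0],
        col_axis=remaining[1],
        row_values=_axis_values(grid.spec, remaining[0]),
        col_values=_axis_values(grid.spec, remaining[1]),
        map=grid.viable[tuple(sl)],
    )


# ---------------------------------------------------------------------------
# connectivity


def label_lattice(mask: np.ndarray, periodic: tuple[bool, ...]) -> np.ndarray:
    """Face-connected component labels of a boolean lattice.

    ``periodic[d]`` identifies the first and last index along axis d
    (e.g. −180° and +180° samples of a full-circle axis).  Labels are
    1-based; 0 is background.  Deterministic.
    """
    if mask.ndim != len(periodic):
        raise ValueError("periodic flags must match lattice dimensionality")
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for d, per in enumerate(periodic):
        if not per or mask.shape[d] < 2:
            continue
        first = np.take(labels, 0, axis=d)
        last = np.take(labels, mask.shape[d] - 1, axis=d)
        both = (first > 0) & (last > 0)
        for a, b in zip(first[both].ravel(), last[both].ravel()):
            union(int(a), int(b))
    # also identify duplicated seam cells themselves (done above: the pair
    # (first, last) at identical remaining coordinates is merged)
    root = np.array([find(i) for i in range(n + 1)])
    compact = np.zeros(n + 1, dtype=labels.dtype)
    compact[np.unique(root[1:])] = np.arange(1, len(np.unique(root[1:])) + 1)
    return compact[root[labels]]


def connected_components(
    grid: PoseGrid, seam_policy: str = "endpoints-distinct"
) -> list[np.ndarray]:
    """Maximal face-connected (6-neighbour) components of the viable set.

    With ``seam-merged``, the FE and LAR axes are periodic (their ±180°
    samples are identified); ABAD is never periodic.  Returns each
    component as an (n, 3) array of cell indices, sorted by size
    descending then by first cell for determinism.
    """
    if seam_policy not in SEAM_POLICIES:
        raise ValueError(f"seam_policy must be one of {SEAM_POLICIES}")
    periodic = (seam_policy == "seam-merged",) * 3
    periodic = (periodic[0], False, periodic[2])  # ABAD never periodic
    labels = label_lattice(grid.viable, periodic)
    comps = []
    for lab in range(1, labels.max() + 1):
        cells = np.argwhere(labels == lab)
        comps.append(cells)
    comps.sort(key=lambda c: (-len(c), tuple(c[0])))
    return comps


def summarize(grid: PoseGrid, seam_policy: str = "endpoints-distinct") -> RomSummary:
    """Bundle counts, both volume definitions and connectivity."""
    comps = connected_components(grid, seam_policy)
    return RomSummary(
        n_viable=int(grid.viable.sum()),
        n_cells=grid.spec.n_cells,
        volume_naive_deg3=rom_volume(grid, "naive"),
        volume_cosine_deg3=rom_volume(grid, "cosine"),
        n_components=len(comps),
        component_sizes=tuple(len(c) for c in comps),
        seam_policy=seam_policy,
    )


@dataclass(frozen=True)
class LockingReport:
    """Per-ABAD-slice connectivity of the (FE, LAR) viability maps.

    ``n_components[j]`` counts face-connected components of the slice at
    ``abad_values[j]`` with LAR periodic; ``full_lar_circuit[j]`` is
    True when some FE row of the slice admits an unbroken 360° LAR
    rotation.  ``min_locked_abad``/``max_locked_abad`` bound the slices
    with ≥ 2 components ("locking"); ``max_free_abad`` is the largest
    ABAD whose slice is a single component with a full LAR circuit.
    """

    abad_values: np.ndarray
    n_components: np.ndarray
    full_lar_circuit: np.ndarray
    min_locked_abad: float | None
    max_locked_abad: float | None
    max_free_abad: float | None


def locking_report(grid: PoseGrid, fe_periodic: bool = False) -> LockingReport:
    """Detect "locking": ABAD slices whose (FE, LAR) viability splits
    into disconnected clusters, and the ABAD range with free LAR.

    LAR is always treated as periodic here (a full circuit closes on
    itself); FE periodicity is optional.
    """
    ab = grid.spec.abad_values
    n_comp = np.zeros(len(ab), dtype=int)
    circuit = np.zeros(len(ab), dtype=bool)
    lar_dup = grid.spec.lar_range == (-180.0, 180.0)
    for j in range(len(ab)):
        sl = grid.viable[:, j, :]
        labels = label_lattice(sl, (fe_periodic, True))
        n_comp[j] = labels.max()
        # a full circuit must cover every distinct LAR value in a row
        rows = sl[:, :-1] if lar_dup else sl
        circuit[j] = bool(rows.all(axis=1).any()) if rows.size else False
    locked = np.nonzero(n_comp >= 2)[0]
    free = np.nonzero((n_comp == 1) & circuit)[0]
    return LockingReport(
        abad_values=ab,
        n_components=n_comp,
        full_lar_circuit=circuit,
        min_locked_abad=float(ab[locked[0]]) if locked.size else None,
        max_locked_abad=float(ab[locked[-1]]) if locked.size else None,
        max_free_abad=float(ab[free[-1]]) if free.size else None,
    )


# ---------------------------------------------------------------------------
# extreme poses


_OBJECTIVES = {
    "min_abad": (1, +1), "max_abad": (1, -1),
    "min_fe": (0, +1), "max_fe": (0, -1),
    "min_lar": (2, +1), "max_lar": (2, -1),
}


def extreme_pose(
    grid: PoseGrid,
    objective: str,
    constraints: dict[str, tuple[float, float]] | None = None,
) -> JointPose:
    """The viable pose optimising one angle under interval constraints.

    ``objective`` is one of min/max_fe|abad|lar; ``constraints`` maps
    axis names to closed intervals in degrees.  Ties are broken
    lexicographically by minimal |LAR|, then minimal |FE|, then by the
    signed values — fully deterministic.
    """
    if objective not in _OBJECTIVES:
        raise ValueError(f"objective must be one of {sorted(_OBJECTIVES)}")
    axes_vals = [grid.spec.fe_values, grid.spec.abad_values, grid.spec.lar_values]
    mask = grid.viable.copy()
    for axis, (lo, hi) in (constraints or {}).items():
        dim = _AXES.index(axis.upper())
        ok = (axes_vals[dim] >= lo - 1e-9) & (axes_vals[dim] <= hi + 1e-9)
        sl = [None, None, None]
        sl[dim] = slice(None)
        mask &= ok[tuple(sl)]
    cells = np.argwhere(mask)
    if cells.size == 0:
        raise ValueError("no viable pose satisfies the constraints")
    vals = np.column_stack([axes_vals[d][cells[:, d]] for d in range(3)])
    dim, sign = _OBJECTIVES[objective]
    order = np.lexsort((
        vals[:, 1], vals[:, 0], vals[:, 2],
        np.abs(vals[:, 0]), np.abs(vals[:, 2]),
        sign * vals[:, dim],
    ))
    fe, ab, la = vals[order[0]]
    return JointPose(float(fe), float(ab), float(la))


# ---------------------------------------------------------------------------
# joint spacing across configurations


PRIMITIVE_CODES = {"S": ("sphere", fit_sphere), "E": ("ellipsoid", fit_ellipsoid)}


def spacing_report(
    scene,
    pairings: tuple[str, ...] = ("SS", "SE", "ES", "EE"),
    cartilage_pcts: tuple[float, ...] = (0.0, 0.02),
    specimen_label: str = "SYNTH",
) -> pd.DataFrame:
    """Mean joint spacing for each primitive pairing × cartilage level.

    Pairing codes follow the simulation naming scheme: first letter =
    primitive fitted to the acetabulum, second = femoral head (S =
    sphere, E = ellipsoid).  For each configuration the femur's pinned
    point (head-fit centre) is placed on the pivot (socket-fit centre),
    displaced by the cartilage offset, and the mean signed clearance
    from the femoral-head patch to the acetabular patch is reported.
    """
    if not cartilage_pcts:
        raise ValueError("cartilage_pcts must be non-empty")
    fits = {}
    for code, (kind, fn) in PRIMITIVE_CODES.items():
        fits[("socket", code)] = fn(scene.socket_patch)
        fits[("head", code)] = fn(scene.femur_patch)
    rows = []
    for pairing in pairings:
        if len(pairing) != 2 or any(c not in PRIMITIVE_CODES for c in pairing):
            raise ValueError(f"bad pairing code {pairing!r}")
        socket_fit = fits[("socket", pairing[0])]
        head_fit = fits[("head", pairing[1])]
        centre = make_joint_centre(socket_fit, head_fit)
        for pct in cartilage_pcts:
            rule = CartilageRule(
                pct=pct,
                femur_length=scene.femur_truth.femur_length,
                offset_axis=scene.socket_truth.pole_axis,
            )
            shift = centre.position - centre.pinned_point + rule.offset_vector
            pose = RigidTransform(np.eye(3), shift)
            spacing = float(signed_clearance(
                scene.femur_patch, scene.socket_patch, pose,
                reference_centre=socket_fit.centre,
            ).mean())
            label = f"{specimen_label} {pairing}{int(round(pct * 100))}"
            rows.append({
                "label": label,
                "socket_primitive": pairing[0],
                "head_primitive": pairing[1],
                "cartilage_pct": pct,
                "mean_spacing_mm": spacing,
                "socket_fit_rms_mm": socket_fit.rms_residual,
                "head_fit_rms_mm": head_fit.rms_residual,
            })
    return pd.DataFrame(rows)
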