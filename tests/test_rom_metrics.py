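"""Tests for ROM volumes, sections, connectivity, locking and spacing."""

from __future__ import annotations

import numpy as np
import pytest

from osteorom.pose_search import GridSpec, PoseGrid
from osteorom.rom_metrics import (
    LockingReport, connected_components, cross_section, extreme_pose,
    label_lattice, locking_report, rom_volume, spacing_report, summarize,
)

SPEC45 = GridSpec(step=45.0)  # shape (9, 5, 9)


def _grid(mask) -> PoseGrid:
    return PoseGrid(SPEC45, np.asarray(mask, dtype=bool))


def _random_grid(rng, p=0.4) -> PoseGrid:
    return _grid(rng.random(SPEC45.shape) < p)


# ---------------------------------------------------------------------------
# volumes


def test_naive_volume_counts_cells(rng):
    grid = _random_grid(rng)
    n = int(grid.viable.sum())
    assert rom_volume(grid, "naive") == pytest.approx(n * 45.0**3, abs=1e-9)


def test_cosine_volume_hand_computed():
    mask = np.zeros(SPEC45.shape, dtype=bool)
    mask[0, 2, 0] = True  # ABAD = 0   -> weight 1
    mask[3, 1, 5] = True  # ABAD = -45 -> weight cos 45
    grid = _grid(mask)
    want = 45.0**3 * (1.0 + np.cos(np.radians(45.0)))
    assert rom_volume(grid) == pytest.approx(want, rel=1e-12)


def test_cosine_never_exceeds_naive(rng):
    for _ in range(5):
        grid = _random_grid(rng)
        assert rom_volume(grid, "cosine") <= rom_volume(grid, "naive") + 1e-9


def test_polar_cells_contribute_nothing():
    mask = np.zeros(SPEC45.shape, dtype=bool)
    mask[:, 0, :] = True  # ABAD = -90
    mask[:, 4, :] = True  # ABAD = +90
    grid = _grid(mask)
    assert rom_volume(grid, "cosine") == pytest.approx(0.0, abs=1e-6)
    assert rom_volume(grid, "naive") > 0


def test_unknown_volume_method_rejected(rng):
    with pytest.raises(ValueError, match="unknown volume method"):
        rom_volume(_random_grid(rng), "simpson")


# ---------------------------------------------------------------------------
# cross-sections


def test_cross_section_extracts_expected_slice(rng):
    grid = _random_grid(rng)
    sec = cross_section(grid, "abad", 0.0)
    assert sec.fixed_axis == "ABAD" and sec.fixed_value == 0.0
    assert sec.row_axis == "FE" and sec.col_axis == "LAR"
    assert np.array_equal(sec.map, grid.viable[:, 2, :])
    sec_fe = cross_section(grid, "FE", -90.0)
    assert np.array_equal(sec_fe.map, grid.viable[2, :, :])


def test_cross_section_off_lattice_reports_nearest(rng):
    grid = _random_grid(rng)
    with pytest.raises(ValueError, match="not on the lattice") as exc:
        cross_section(grid, "ABAD", 30.0)
    assert "0.0" in str(exc.value) and "45.0" in str(exc.value)
    with pytest.raises(ValueError, match="axis"):
        cross_section(grid, "ROLL", 0.0)


def test_cross_section_csv_round_trip(tmp_path, rng):
    import pandas as pd

    grid = _random_grid(rng)
    sec = cross_section(grid, "LAR", 45.0)
    path = sec.to_csv(tmp_path / "sec.csv")
    df = pd.read_csv(path, index_col=0)
    assert np.array_equal(df.to_numpy().astype(bool), sec.map)
    png = sec.to_png(tmp_path / "sec.png")
    assert png.stat().st_size > 0


# ---------------------------------------------------------------------------
# connectivity


def _bfs_components(mask, periodic):
    """Independent flood-fill oracle; periodic axes wrap modularly."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            cell = stack.pop()
            comp.append(cell)
            for d in range(len(shape)):
                for s in (-1, 1):
                    nb = list(cell)
                    nb[d] += s
                    if periodic[d]:
                        nb[d] %= shape[d]
                    elif not 0 <= nb[d] < shape[d]:
                        continue
                    nb = tuple(nb)
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
        comps.append(comp)
    return comps


def test_label_lattice_basic_and_periodic():
    mask = np.zeros((5, 4), dtype=bool)
    mask[0, 1] = mask[4, 1] = True  # opposite ends of axis 0
    labels = label_lattice(mask, (False, False))
    assert labels.max() == 2
    labels = label_lattice(mask, (True, False))
    assert labels.max() == 1
    with pytest.raises(ValueError, match="dimensionality"):
        label_lattice(mask, (True,))


def test_components_match_flood_fill_oracle(rng):
    for _ in range(10):
        grid = _random_grid(rng, p=0.35)
        for policy, periodic in (("endpoints-distinct", (False, False, False)),
                                 ("seam-merged", (True, False, True))):
            got = connected_components(grid, policy)
            want = _bfs_components(grid.viable, periodic)
            assert len(got) == len(want)
            # identical partition of the viable cells
            got_sets = {frozenset(map(tuple, c)) for c in got}
            want_sets = {frozenset(c) for c in want}
            assert got_sets == want_sets


def test_components_sorted_large_first(rng):
    grid = _random_grid(rng)
    comps = connected_components(grid)
    sizes = [len(c) for c in comps]
    assert sizes == sorted(sizes, reverse=True)
    assert sum(sizes) == int(grid.viable.sum())
    with pytest.raises(ValueError, match="seam_policy"):
        connected_components(grid, "wrap-everything")


def test_summary_consistency(rng):
    grid = _random_grid(rng)
    s = summarize(grid, "seam-merged")
    assert s.n_cells == SPEC45.n_cells == 405
    assert s.n_viable == int(grid.viable.sum())
    assert sum(s.component_sizes) == s.n_viable
    assert s.n_components == len(s.component_sizes)
    assert s.volume_naive_deg3 == pytest.approx(s.n_viable * 45.0**3)
    d = s.to_dict()
    assert d["seam_policy"] == "seam-merged"


# ---------------------------------------------------------------------------
# locking


def test_locking_report_on_constructed_lattice():
    mask = np.zeros(SPEC45.shape, dtype=bool)
    # ABAD = -45 (j=1): two FE clusters, both spanning all LAR -> locked
    mask[0:2, 1, :] = True
    mask[5:7, 1, :] = True
    # ABAD = 0 (j=2): everything viable -> free with full LAR circuit
    mask[:, 2, :] = True
    # ABAD = +45 (j=3): one cluster, partial LAR -> neither
    mask[3:5, 3, 2:5] = True
    rep = locking_report(_grid(mask))
    assert isinstance(rep, LockingReport)
    assert list(rep.n_components) == [0, 2, 1, 1, 0]
    assert list(rep.full_lar_circuit) == [False, True, True, False, False]
    assert rep.min_locked_abad == rep.max_locked_abad == -45.0
    assert rep.max_free_abad == 0.0


def test_locking_lar_seam_merged_within_slices():
    mask = np.zeros(SPEC45.shape, dtype=bool)
    # cells only at LAR = -180 and +180 (the same physical pose)
    mask[4, 2, 0] = mask[4, 2, 8] = True
    rep = locking_report(_grid(mask))
    assert rep.n_components[2] == 1  # seam duplicates are one cluster


def test_locking_empty_grid():
    rep = locking_report(_grid(np.zeros(SPEC45.shape, dtype=bool)))
    assert rep.min_locked_abad is None and rep.max_free_abad is None
    assert not rep.full_lar_circuit.any()


# ---------------------------------------------------------------------------
# extreme poses


def _extreme_fixture_grid():
    mask = np.zeros(SPEC45.shape, dtype=bool)
    mask[6, 2, 5] = True   # (FE  90, ABAD   0, LAR  45)
    mask[6, 2, 4] = True   # (FE  90, ABAD   0, LAR   0)
    mask[5, 1, 4] = True   # (FE  45, ABAD -45, LAR   0)
    return _grid(mask)


def test_extreme_pose_objectives():
    grid = _extreme_fixture_grid()
    assert extreme_pose(grid, "max_fe").as_tuple() == (90.0, 0.0, 0.0)
    assert extreme_pose(grid, "min_abad").as_tuple() == (45.0, -45.0, 0.0)
    assert extreme_pose(grid, "max_lar").as_tuple() == (90.0, 0.0, 45.0)


def test_extreme_pose_tie_break_prefers_small_lar():
    # both FE=90 cells tie on the objective; |LAR| breaks the tie
    grid = _extreme_fixture_grid()
    pose = extreme_pose(grid, "max_fe")
    assert pose.lar_deg == 0.0


def test_extreme_pose_constraints():
    grid = _extreme_fixture_grid()
    pose = extreme_pose(grid, "max_fe", constraints={"lar": (30.0, 60.0)})
    assert pose.as_tuple() == (90.0, 0.0, 45.0)
    with pytest.raises(ValueError, match="no viable pose"):
        extreme_pose(grid, "max_fe", constraints={"abad": (60.0, 90.0)})
    with pytest.raises(ValueError, match="objective"):
        extreme_pose(grid, "widest_fe")


# ---------------------------------------------------------------------------
# spacing across configurations


def test_spacing_report_structure_and_cartilage_effect(coarse_scene):
    df = spacing_report(coarse_scene, specimen_label="SYNTH")
    assert len(df) == 8  # 4 pairings x 2 cartilage levels
    assert set(df["label"]) == {
        f"SYNTH {p}{c}" for p in ("SS", "SE", "ES", "EE") for c in (0, 2)
    }
    for pairing, sub in df.groupby(["socket_primitive", "head_primitive"]):
        sub = sub.sort_values("cartilage_pct")
        spacings = sub["mean_spacing_mm"].to_numpy()
        assert (np.diff(spacings) > 0).all()  # cartilage opens the joint
    assert (df["mean_spacing_mm"] > 0).all()  # no reference interpenetration
    assert (df["socket_fit_rms_mm"] < 0.5).all()


def test_spacing_report_deterministic(coarse_scene):
    a = spacing_report(coarse_scene, pairings=("SS",), cartilage_pcts=(0.0,))
    b = spacing_report(coarse_scene, pairings=("SS",), cartilage_pcts=(0.0,))
    assert a["mean_spacing_mm"].iloc[0] == b["mean_spacing_mm"].iloc[0]


def test_spacing_report_rejects_bad_inputs(coarse_scene):
    with pytest.raises(ValueError, match="pairing"):
        spacing_report(coarse_scene, pairings=("SQ",))
    with pytest.raises(ValueError, match="non-empty"):
        spacing_report(coarse_scene, cartilage_pcts=())
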