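"""Thinning, centerline ordering, spline fitting, perpendicular sections."""

import numpy as np
import pytest

import stentmorph as sm
from stentmorph.reslice import (
    CrossSection,
    Centerline,
    detect_area_anomalies,
    extract_sections,
    fit_curve,
    order_skeleton,
    thin_to_skeleton,
)

from conftest import voxel_cylinder


def _mask(vox, spacing=(1.0, 1.0, 1.0)):
    return sm.BinaryMask(np.asarray(vox, dtype=bool), spacing)


def _degrees(vox_set):
    deg = {}
    for p in vox_set:
        deg[p] = sum(
            (p[0] + dx, p[1] + dy, p[2] + dz) in vox_set
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        )
    return deg


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------


def test_thin_line_is_fixed_point():
    vox = np.zeros((5, 5, 30), bool)
    vox[2, 2, 3:27] = True
    out = thin_to_skeleton(_mask(vox))
    np.testing.assert_array_equal(out.voxels, vox)


def test_thin_cylinder_gives_axial_simple_path():
    vox = voxel_cylinder(radius_px=3, length=40)
    skel = thin_to_skeleton(_mask(vox))
    v = np.argwhere(skel.voxels)
    c = vox.shape[0] // 2
    # every skeleton voxel within 1.5 voxels of the true axis
    assert np.hypot(v[:, 0] - c, v[:, 1] - c).max() <= 1.5
    # single simple path: two endpoints, everything else degree 2
    deg = _degrees({tuple(p) for p in v})
    counts = sorted(deg.values())
    assert counts[:2] == [1, 1] and all(d == 2 for d in counts[2:])
    # subset + component count preserved
    assert (skel.voxels & ~vox).sum() == 0
    assert sm.label_components(skel).n_components == 1


def test_thin_sphere_collapses_to_center():
    n = 24
    x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    sphere = (x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= 25
    skel = thin_to_skeleton(_mask(sphere))
    v = np.argwhere(skel.voxels)
    assert 1 <= len(v) <= 8
    assert np.abs(v - 12).max() <= 3
    assert sm.label_components(skel).n_components == 1


def test_thin_idempotent_and_preserves_components(distractor_case):
    _, vol, _ = distractor_case
    mask = sm.threshold_segment(vol, 300, 3000)
    skel = thin_to_skeleton(mask)
    again = thin_to_skeleton(skel)
    np.testing.assert_array_equal(skel.voxels, again.voxels)
    assert (
        sm.label_components(skel).n_components
        == sm.label_components(mask).n_components
    )


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------


def test_order_straight_line():
    vox = np.zeros((5, 5, 50), bool)
    vox[2, 2, 5:45] = True
    cl = order_skeleton(_mask(vox))
    assert len(cl) == 40
    pts = cl.points_mm
    assert pts[0, 2] > pts[-1, 2]  # superior end first
    np.testing.assert_allclose(pts[:, 0], 2.0)
    np.testing.assert_allclose(np.diff(pts[:, 2]), -1.0)


def test_order_l_shaped_path():
    vox = np.zeros((20, 5, 20), bool)
    vox[2, 2, 2:12] = True
    vox[2:12, 2, 11] = True
    cl = order_skeleton(_mask(vox))
    # the shortest simple path may cut the corner diagonally
    assert len(cl) in (18, 19)
    steps = np.linalg.norm(np.diff(cl.points_mm, axis=0), axis=1)
    assert steps.max() <= np.sqrt(3) + 1e-9


def test_order_prunes_short_spur():
    vox = np.zeros((10, 5, 30), bool)
    vox[2, 2, 2:25] = True  # main path, 23 voxels
    vox[3, 2, 10] = vox[4, 2, 10] = True  # 2-voxel spur
    cl = order_skeleton(_mask(vox), prune_len=3)
    assert len(cl) == 23
    assert not any((p[0] > 2.5) for p in cl.points_mm)


def test_order_keeps_main_path_over_long_side_branch():
    vox = np.zeros((30, 5, 40), bool)
    vox[2, 2, 2:38] = True  # main path, 36 voxels
    vox[3:15, 2, 20] = True  # 12-voxel side branch (stone-like)
    cl = order_skeleton(_mask(vox), prune_len=5)
    assert len(cl) == 36
    np.testing.assert_allclose(cl.points_mm[:, 0], 2.0)


def test_order_empty_skeleton_errors():
    with pytest.raises(ValueError, match="empty"):
        order_skeleton(_mask(np.zeros((4, 4, 4))))


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------


def _centerline_from_points(pts):
    return Centerline(points_mm=np.asarray(pts, float), source_voxels=np.zeros((0, 3), int))


def test_fit_line_reproduces_direction():
    t = np.linspace(0, 50, 60)
    pts = np.stack([2 + 0.3 * t, 1 + 0.1 * t, t], axis=1)
    curve = fit_curve(_centerline_from_points(pts), smoothing=0.5)
    tang = curve.unit_tangent(np.linspace(0.05, 0.95, 20))
    true_dir = np.array([0.3, 0.1, 1.0])
    true_dir /= np.linalg.norm(true_dir)
    cos = tang @ true_dir
    assert cos.min() > 0.999


def test_fit_helix_tangents_match_analytic():
    s = np.linspace(0, 4 * np.pi, 200)
    r, pitch = 8.0, 4.0
    pts = np.stack([r * np.cos(s), r * np.sin(s), pitch * s], axis=1)
    curve = fit_curve(_centerline_from_points(pts), smoothing=0.05)
    ts = np.linspace(0.1, 0.9, 30)
    tang = curve.unit_tangent(ts)
    # analytic tangent at the fitted point's azimuth
    pts_fit = curve.point(ts)
    phi = np.arctan2(pts_fit[:, 1], pts_fit[:, 0])
    analytic = np.stack([-r * np.sin(phi), r * np.cos(phi), np.full_like(phi, pitch)], axis=1)
    analytic /= np.linalg.norm(analytic, axis=1, keepdims=True)
    angles = np.degrees(np.arccos(np.clip((tang * analytic).sum(axis=1), -1, 1)))
    assert angles.max() < 5.0


def test_fit_interpolates_at_zero_smoothing():
    rng = np.random.default_rng(5)
    pts = np.cumsum(rng.normal(0, 1, (12, 3)) + [0, 0, 2], axis=0)
    curve = fit_curve(_centerline_from_points(pts), smoothing=0.0)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    np.testing.assert_allclose(curve.point(u), pts, atol=1e-6)


def test_fit_requires_enough_points():
    with pytest.raises(ValueError, match="at least"):
        fit_curve(_centerline_from_points([[0, 0, 0], [1, 1, 1]]), degree=3)


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------


def _analytic_cylinder_mask(direction, radius=5.0, length=60.0, spacing=(0.5, 0.5, 0.5), side=80.0):
    """Bright cylinder along an arbitrary direction, plus its axis points."""
    direction = np.asarray(direction, float)
    direction /= np.linalg.norm(direction)
    shape = tuple(int(round(side / s)) for s in spacing)
    centre = np.array([side / 2] * 3)
    grid = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"), axis=-1
    )
    rel = grid - centre
    along = rel @ direction
    radial = np.linalg.norm(rel - along[..., None] * direction, axis=-1)
    vox = (radial <= radius) & (np.abs(along) <= length / 2)
    axis_pts = centre + np.linspace(-length / 2, length / 2, 80)[:, None] * direction
    return sm.BinaryMask(vox, spacing), axis_pts


def _perpendicular_areas(mask, axis_pts, n_sections=40):
    curve = fit_curve(_centerline_from_points(axis_pts), smoothing=0.0)
    secs = extract_sections(mask, curve, n_sections=n_sections)
    middle = secs[n_sections // 4 : -n_sections // 4]
    return np.array([s.area_mm2 for s in middle])


def test_sections_straight_cylinder_area():
    mask, axis_pts = _analytic_cylinder_mask([0, 0, 1])
    areas = _perpendicular_areas(mask, axis_pts)
    np.testing.assert_allclose(areas, np.pi * 25, rtol=0.05)


def test_sections_tilted_cylinder_perpendicular_vs_axial():
    """Perpendicular re-slicing sees a circle where axial slices see an ellipse."""
    mask, axis_pts = _analytic_cylinder_mask([1, 0, 1])  # 45 deg about y
    areas = _perpendicular_areas(mask, axis_pts)
    np.testing.assert_allclose(areas, np.pi * 25, rtol=0.05)
    # axial (z) slices cut obliquely: area inflated by 1/cos(45 deg)
    sx, sy, _ = mask.spacing
    mid = mask.shape[2] // 2
    axial = [mask.voxels[:, :, z].sum() * sx * sy for z in range(mid - 2, mid + 3)]
    np.testing.assert_allclose(np.mean(axial), np.pi * 25 / np.cos(np.pi / 4), rtol=0.05)


def test_sections_empty_mask_zero_area():
    mask, axis_pts = _analytic_cylinder_mask([0, 0, 1])
    empty = sm.BinaryMask(np.zeros_like(mask.voxels), mask.spacing)
    curve = fit_curve(_centerline_from_points(axis_pts), smoothing=0.0)
    secs = extract_sections(empty, curve, n_sections=10)
    assert all(s.area_mm2 == 0.0 for s in secs)


def test_sections_basis_is_orthonormal(clean_case):
    _, vol, truth = clean_case
    mask = truth.stent_mask(vol.spacing)
    curve = fit_curve(_centerline_from_points(truth.centerline_mm[::8]), smoothing=0.2)
    secs = extract_sections(mask, curve, n_sections=25)
    for s in secs:
        for a, b in [(s.normal, s.u), (s.normal, s.v), (s.u, s.v)]:
            assert abs(np.dot(a, b)) < 1e-9
        for a in (s.normal, s.u, s.v):
            assert np.linalg.norm(a) == pytest.approx(1.0)


def test_sections_require_two():
    mask, axis_pts = _analytic_cylinder_mask([0, 0, 1])
    curve = fit_curve(_centerline_from_points(axis_pts), smoothing=0.0)
    with pytest.raises(ValueError):
        extract_sections(mask, curve, n_sections=1)


# ---------------------------------------------------------------------------
# area anomaly rule
# ---------------------------------------------------------------------------


def _sections_from_areas(areas):
    e = np.array([1.0, 0.0, 0.0])
    return [
        CrossSection(
            index=i, t=0.0, arc_mm=float(i), center_mm=np.zeros(3),
            normal=np.array([0.0, 0.0, 1.0]), u=e, v=np.array([0.0, 1.0, 0.0]),
            patch=np.zeros((2, 2), bool), pixel_mm=0.25, area_mm2=float(a),
        )
        for i, a in enumerate(areas)
    ]


def test_anomaly_constant_sequence_is_clean():
    assert detect_area_anomalies(_sections_from_areas(np.full(50, 12.6)), 0.3) == []


def test_anomaly_single_block():
    areas = np.ones(100)
    areas[40:50] = 1.8
    (seg,) = detect_area_anomalies(_sections_from_areas(areas), 0.3)
    assert (seg.start_index, seg.end_index) == (40, 49)
    assert seg.max_normalized_area == pytest.approx(1.8)


def test_anomaly_two_blocks():
    areas = np.ones(100)
    areas[10:15] = 1.7
    areas[60:70] = 2.1
    segs = detect_area_anomalies(_sections_from_areas(areas), 0.3)
    assert [(s.start_index, s.end_index) for s in segs] == [(10, 14), (60, 69)]


def test_anomaly_scale_invariant():
    areas = np.ones(80)
    areas[30:35] = 1.9
    for scale in (0.01, 1.0, 250.0):
        segs = detect_area_anomalies(_sections_from_areas(areas * scale), 0.3)
        assert [(s.start_index, s.end_index) for s in segs] == [(30, 34)]


def test_anomaly_small_end_sections_do_not_define_boundary():
    """Shrunken tip areas (end caps) must not make normal sections anomalous."""
    areas = np.ones(80)
    areas[:2] = 0.4
    areas[-2:] = 0.5
    assert detect_area_anomalies(_sections_from_areas(areas), 0.3) == []
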