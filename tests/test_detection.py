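"""Polar transform, elevation features, stone/encrustation classifier."""

import numpy as np
import pytest

from stentmorph.detection import (
    ConfigThresholds,
    EmptySectionError,
    RadiusProfile,
    classify_anomaly,
    decide_case,
    polar_transform,
    profile_features,
)
from stentmorph.report import AnomalySegment
from stentmorph.reslice import CrossSection

PIX = 0.25


def _section(patch, index=0):
    e1 = np.array([1.0, 0.0, 0.0])
    return CrossSection(
        index=index, t=0.0, arc_mm=float(index), center_mm=np.zeros(3),
        normal=np.array([0.0, 0.0, 1.0]), u=e1, v=np.array([0.0, 1.0, 0.0]),
        patch=np.asarray(patch, bool), pixel_mm=PIX,
        area_mm2=float(np.sum(patch)) * PIX**2,
    )


def _disk(n=64, r=10.0, cx=None, cy=None):
    cx = (n - 1) / 2 if cx is None else cx
    cy = (n - 1) / 2 if cy is None else cy
    y, x = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (x - cx) ** 2 + (y - cy) ** 2 <= r**2


def test_polar_disk_constant_profile():
    prof = polar_transform(_section(_disk(r=16.0)), n_bins=64)
    assert not prof.empty_bins.any()
    np.testing.assert_allclose(prof.radii, 16 * PIX, atol=PIX)


def test_polar_annulus_matches_disk():
    """Only the outer boundary governs the radius profile."""
    disk = _disk(r=10.0)
    annulus = disk & ~_disk(r=6.0)
    p_disk = polar_transform(_section(disk), 64)
    p_ring = polar_transform(_section(annulus), 64)
    np.testing.assert_allclose(p_ring.radii, p_disk.radii, atol=PIX)


def test_polar_bump_confined_to_analytic_window():
    n = 64
    c = (n - 1) / 2
    base = _disk(n, r=10.0)
    bump = _disk(n, r=4.0, cx=c + 9.0, cy=c)  # fused bump at angle 0
    prof_b = polar_transform(_section(base | bump), 64)
    prof_0 = polar_transform(_section(base), 64)
    # analytic half-angle subtended by the bump circle, from the disk centre,
    # padded for the centroid shift the bump itself induces plus one bin
    half = np.degrees(np.arcsin(4.0 / 9.0)) + 12.0
    centres = (np.arange(64) + 0.5) * 360.0 / 64
    ang_dist = np.minimum(centres, 360 - centres)  # distance from angle 0
    outside = ang_dist > half + 360.0 / 64
    np.testing.assert_allclose(prof_b.radii[outside], prof_0.radii[outside], atol=2 * PIX)
    inside = ang_dist < np.degrees(np.arcsin(4.0 / 9.0))
    assert (prof_b.radii[inside] > prof_0.radii[inside] + PIX).any()


def test_polar_rotation_equivariance():
    rng = np.random.default_rng(0)
    patch = _disk(r=10.0) | _disk(r=4.0, cx=40.0, cy=31.5)
    p0 = polar_transform(_section(patch), 64)
    p90 = polar_transform(_section(np.rot90(patch).copy()), 64)
    # rot90 of (row, col) shifts every angle by +90 deg = 16 bins
    shifted = np.roll(p0.radii, 16)
    close = np.abs(p90.radii - shifted) <= 2 * PIX
    assert close.mean() > 0.9  # within one bin / one pixel everywhere but bin edges


def test_polar_translation_invariance():
    patch = _disk(n=64, r=8.0)
    big = np.zeros((96, 96), bool)
    big[20 : 20 + 64, 9 : 9 + 64] = patch
    p0 = polar_transform(_section(patch), 32)
    p1 = polar_transform(_section(big), 32)
    np.testing.assert_allclose(p0.radii, p1.radii, atol=PIX)


def test_polar_empty_section_raises():
    with pytest.raises(EmptySectionError):
        polar_transform(_section(np.zeros((8, 8), bool)))


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def _profiles(elevated_at, n_sections=100, n_bins=64, base=2.0, factor=2.0, bins_elevated=12):
    out = []
    for i in range(n_sections):
        radii = np.full(n_bins, base)
        if i in elevated_at:
            radii[:bins_elevated] = base * factor
        out.append(RadiusProfile(i, radii, np.zeros(n_bins, bool)))
    return out


def test_features_flat_profiles_have_no_runs():
    f = profile_features(_profiles(set()))
    assert f.n_runs == 0 and not f.elevated_sections.any()


def test_features_contiguous_block_is_one_run():
    f = profile_features(_profiles(set(range(40, 50))))
    assert f.runs == ((40, 49),)
    assert f.longest_run == 10


def test_features_scattered_sections_are_separate_runs():
    f = profile_features(_profiles({10, 22, 37, 51, 70}))
    assert f.n_runs == 5 and f.longest_run == 1


def test_features_single_noisy_bin_not_elevated():
    """One quantization-noise bin must not make a section elevated."""
    f = profile_features(_profiles({50}, bins_elevated=1))
    assert not f.elevated_sections.any()


def test_features_baseline_excludes_anomalous_sections():
    profs = _profiles(set(range(0, 60)), n_sections=100, factor=3.0, bins_elevated=64)
    f = profile_features(profs, anomalous_indices=set(range(0, 60)))
    assert f.baseline_radius_mm == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


def test_classify_clean():
    f = profile_features(_profiles(set()))
    assert classify_anomaly(f) == "clean"


def test_classify_residual_stone_pattern():
    # one contiguous run over 12% of the stent with a large excursion
    f = profile_features(_profiles(set(range(44, 56)), factor=1.8))
    assert classify_anomaly(f) == "residual_stone"


def test_classify_encrustation_pattern():
    # six short runs scattered along the stent
    elevated = {10, 11, 25, 26, 40, 55, 56, 70, 84, 97}
    f = profile_features(_profiles(elevated, factor=1.6))
    assert classify_anomaly(f) == "encrustation"


def test_classify_ambiguous_defaults_to_encrustation():
    # one long run but too weak for the stone branch
    f = profile_features(_profiles(set(range(40, 60)), factor=1.45))
    assert classify_anomaly(f) == "encrustation"


def test_classify_monotone_in_elevation_delta():
    """Raising elevation_delta can only move verdicts toward clean."""
    elevated = set(range(44, 56))
    profs = _profiles(elevated, factor=1.5)
    lo = ConfigThresholds(elevation_delta=0.35)
    hi = ConfigThresholds(elevation_delta=0.6)
    if classify_anomaly(profile_features(profs, lo), lo) == "clean":
        assert classify_anomaly(profile_features(profs, hi), hi) == "clean"
    # factor 1.5 < 1+0.6: strictly above the lo cutoff, below the hi cutoff
    assert classify_anomaly(profile_features(profs, hi), hi) == "clean"
    assert classify_anomaly(profile_features(profs, lo), lo) != "clean"


# ---------------------------------------------------------------------------
# case aggregation
# ---------------------------------------------------------------------------


def _seg(a, b):
    return AnomalySegment(a, b, 1.5, 2.0)


def test_decide_no_segments_is_negative():
    rep = decide_case([], [])
    assert rep.verdict == "negative" and rep.segments == ()


def test_decide_encrustation_dominates():
    rep = decide_case([_seg(1, 3), _seg(10, 12)], ["residual_stone", "encrustation"])
    assert rep.verdict == "encrustation"


def test_decide_residual_stone_alone():
    rep = decide_case([_seg(5, 9)], ["residual_stone"])
    assert rep.verdict == "residual_stone"
    assert rep.segments[0].classification == "residual_stone"


def test_decide_all_clean_segments_is_negative():
    rep = decide_case([_seg(5, 9)], ["clean"])
    assert rep.verdict == "negative" and rep.segments == ()


def test_decide_length_mismatch():
    with pytest.raises(ValueError):
        decide_case([_seg(0, 1)], [])
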