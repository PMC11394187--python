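# Methods

This note records the model behind each pipeline stage, the parameters
that matter, the numerical choices, and what the synthetic phantoms do
and do not establish.

## Coordinate model

All geometry runs in physical millimetres on rectilinear grids: voxel
centre of index `(i, j, k)` sits at `origin + index · spacing`, index
order `(x, y, z)` with z the axial (slice) direction. Oblique DICOM
orientations are resampled (trilinear) to an axis-aligned grid at load
time; nothing downstream handles rotation matrices. Anisotropic spacing
is the normal case — the default phantom grid is (0.7, 0.7, 1.25) mm —
so no stage may assume cubic voxels.

## Segmentation boundary

The pipeline deliberately does not own a segmentation model. Stent
polymer, calcified deposits, and bone overlap in Hounsfield units, so
no window isolates the stent; any per-voxel foreground source (a
trained network, a manual contour, the built-in 300–3000 HU window)
satisfies the provider contract `CTVolume → BinaryMask` on the same
grid. The built-in window intentionally over-segments: removing what it
wrongly includes is the job of the 3D stage, and the tests exercise
exactly that division of labour.

## Connected-domain filtering

`label_components` is a literal two-pass raster scan: the first pass
assigns each foreground voxel the minimum provisional label among its
already-visited neighbours (or a fresh label) and records label
equivalences; the second resolves every voxel to its equivalence-class
minimum. The equivalence table is a union-find with path compression in
which the class representative is always the minimum label — the same
result as an explicit equality list, in near-linear time. The kernel is
numba-compiled; an independent pure-Python BFS flood fill in the test
suite checks partition equality exactly, over all three adjacency
systems. Default adjacency is 26: a thin tilted tube frequently
connects between slices only through voxel corners, and 6-adjacency
would shatter it.

`fill_gaps` repairs short axial dropouts a per-slice segmenter leaves:
components whose z-ranges are separated by at most `max_gap_slices`
(default 5) empty slices, with facing in-plane centroids within
`gap_centroid_mm` (default 10 mm), are bridged by disks whose centres
interpolate linearly and whose radius is the mean flanking
equivalent-disk radius. The operation is extensive and idempotent.

`select_stent_component` keeps the single component with the largest
axial extent among those with `z_extent ≥ 100 mm` and
`elongation = z_extent / max(x_extent, y_extent) ≥ 3`. A double-J stent
spans kidney to bladder; stones and bone fragments are compact. Both
thresholds are configurable; ties break to the larger component, then
the smaller label, for determinism.

## Thinning and centerline

`thin_to_skeleton` is an in-package 3×3×3 template thinning: six
directional subiterations (up/down/north/south/east/west border layers)
in which boundary voxels are deleted when they are *simple points* —
the foreground 26-neighbours form one 26-connected component and the
background 6-neighbours one 6-connected component within the
18-neighbourhood — and not curve endpoints (a voxel with exactly one
foreground 26-neighbour is kept). Candidates are marked per directional
pass and deleted sequentially with a recheck against the current image,
so one pass peels at most one voxel layer (keeping the skeleton
centred) and topology preservation holds unconditionally (every
deletion is verified in place). On a solid cylinder of radius 3 voxels
the result is a single simple path on the axis; the residual axis error
is below one voxel even when the tube axis falls exactly between voxel
columns.

The skeleton is a tree with occasional short side branches: thinning
grows small spurs from surface irregularities, and a wall deposit large
enough leaves a genuine side branch (a sphere of radius r thins to a
branch of roughly 2r/voxel). `order_skeleton` first prunes spurs
shorter than `prune_len` voxels (default 5), then orders the **tree
diameter** — the path between the two mutually farthest voxels, found
by double BFS with deterministic tie-breaks. The diameter is
threshold-free: no prune length can separate a stone branch (~15–18
voxels) from a genuine stent tip that sits a similar distance from the
nearest deposit junction, but the kidney-to-bladder path is always the
longest. Voxels bypassed by diagonal corner-cuts remain available in
`source_voxels`. The path starts at the superior (greater z) end by
convention.

`fit_curve` fits a cubic smoothing B-spline over normalized
chord-length parameterization. Two smoothing controls exist because
voxel paths are staircases: a 5-point moving average over the ordered
path (`presmooth_window`; bias ≤ 0.25 mm at the tightest curl radius
rendered, 9 mm) removes the sub-voxel jitter that otherwise leaks into
the tangent and tilts the section planes, and the spline tolerance
`smoothing` (RMS mm per point, default 0.5) absorbs the rest.
`smoothing = 0` is an exact interpolant through the raw points and
skips pre-smoothing, preserving the interpolation contract for
analytic inputs.

## Perpendicular re-slicing

Sections are sampled at uniform arc length (default 1 mm) via a dense
arc-length table. The in-plane basis is `u = normalize(t × ẑ)` (falling
back to the x axis when the tangent is axial within 1e-6), `v = t × u`;
a degenerate tangent reuses the previous section's direction. Patches
are square (default 28 mm at 0.25 mm pixels) but cropped to the
inscribed disk so the radial field of view is isotropic — square
corners would reach √2 farther and could capture the opposite limb of a
J-curl. The 28 mm default is sized so a residual fragment tangent to a
2 mm-radius stent (outer reach `r_tube + 2·r_stone ≈ 13 mm`) stays
inside the 14 mm field of view.

The **area** of a section is the integral of the trilinearly
interpolated occupancy over the field of view. Thresholding the
resampled mask at 0.5 and counting pixels inflates the boundary by
roughly a quarter of the source voxel — +5% area for a 5 mm cylinder on
a 0.5 mm grid — while the occupancy integral is unbiased; the boolean
patch used for polar profiling still thresholds at 0.5.

`detect_area_anomalies` implements the sorted-jump rule: normalize the
area sequence by its median, sort it, find the first adjacent pair
whose difference exceeds `jump_threshold`, and flag every section at or
above that boundary value, merging contiguous indices into segments.
Two refinements: the jump search is restricted to above-median values
(sections at the stent tips legitimately shrink — end caps — and must
not define a boundary from below), and the pipeline excludes
`end_trim_sections` (default 5) sections at each end entirely, because
spline end wobble at a curled tip can tilt the plane tens of degrees
and the tube support there is one-sided. `jump_threshold` defaults to
0.07, calibrated on the phantom families: the largest sorted gap a
clean stent produces (worst case: J-curl curvature) measured 0.056
across 20 seeds, while deposit populations open gaps of 0.085 and up.

## Polar profiling and classification

Each section maps to 64 angular bins; a bin's radius is the distance
from the foreground centroid to its outermost foreground pixel. The
transform is translation-invariant by construction and
rotation-equivariant up to one bin. Sixty-four bins resolve deposits
subtending ≥ ~6°; at a 2 mm stent radius a bin's arc is about one
pixel, so individual bin radii quantize coarsely — the classifier
absorbs this (below) rather than the transform.

`profile_features` reduces profiles to an elevation pattern. The
baseline radius is the median over all bins of the sections *outside*
the area-anomaly segments (global median as fallback), a bin is
elevated above `baseline · (1 + elevation_delta)`, and a section is
elevated when at least `elevated_min_fraction` of its bins are. Two
defaults come from measured quantization bounds, not from the deposits:
`elevation_delta = 0.35`, because the max/median bin-radius ratio of a
perfectly clean section is already ~1.27 (sparse bins plus half-voxel
boundary error) while true deposits elevate by 0.8 and more; and
`elevated_min_fraction = 0.08` (≥ 6 of 64 bins), because quantization
touches one or two bins while the narrowest rendered deposit spans 12.

`classify_anomaly` encodes the morphological contrast:

* no elevated section → `clean`;
* at most 2 runs, the longest ≥ `stone_run_fraction` (default 0.05) of
  the stent, with max relative elevation ≥ `stone_magnitude` (0.5) →
  `residual_stone` — one compact fragment;
* ≥ `encrust_min_runs` (3) runs, each ≤ `encrust_run_max_fraction`
  (0.04) of the stent → `encrustation` — intermittent growth;
* anything ambiguous → `encrustation`. The costly clinical error is
  attempting outpatient removal of an encrusted stent, so the ambiguous
  branch flags for review.

The run-fraction pair (0.05 / 0.04) is set by geometry: at 1 mm section
spacing on a ~150 mm stent, a 4.5–5.5 mm fragment elevates ~9–11
consecutive sections (6–7%), while individual encrustation deposits a
few mm long elevate 3–5 (≤ 4%). All six thresholds are configurable and
serialized into every report.

`decide_case` aggregates: encrustation anywhere wins, else residual
stone, else negative; a negative report carries no segments.

## Synthetic phantoms

`render_phantom` rasterizes an analytic centerline (straight, tilted up
to 8°, 1.2-turn helix of radius 8 mm, or a J with a 9 mm curl) as a
tube of radius 2 mm at 900 HU over a 20 HU background, with optional
wall-fused bumps (stone HU 700, radial height 1.6–2.4 mm, angular width
70–110°, length 2–3 mm), a spherical fragment pressed 0.7–1.5 mm into
the wall (a point tangency does not survive voxelization, and a real
fragment leaning on a stent shares an areal contact patch), loose
fragments clear of the tube, a bone-like ellipsoid (1100 HU), and an
axial gap. Gaussian noise (σ = 15 HU) is added last; spec plus seed
fully determine the volume. Truth masks are exact and pairwise
disjoint.

The deliberate difficulty is the attenuation overlap: deposits (700 HU)
and bone (1100 HU) sit inside the same threshold window as the stent
(900 HU), so only the 3D morphology separates them — as in real CT.

What the phantoms do **not** emulate: partial-volume blur at the tube
boundary (the rendered edge is a hard indicator plus noise), beam
hardening and streak artefacts, anatomy, contact between the stent and
bladder-wall calcifications, and encrustation growing *inside* the
lumen. Passing the phantom suite therefore demonstrates the geometry
and the decision logic, not clinical performance; the clinical accuracy
of this method class was established on hospital data that is not
redistributable, and those published confusion tables ship in
`stentmorph/data/` for the evaluation example only.

## Problem sizes and determinism

Default phantom grids are 64×64×120 voxels (≈ 45×45×150 mm), large
enough for 100-mm-scale stent filters and small enough that the full
end-to-end suite (150 phantoms) runs in about two minutes on one CPU.
Every random draw flows from an explicit seed (`numpy` Generator; preset
names are mixed in via CRC32, never Python's randomized `hash`), so all
volumes, reports, and acceptance numbers are bit-reproducible.

## Known limitations

* The sorted-jump area rule detects a deposit population only when the
  sorted area sequence opens a gap; many deposits with smoothly varying
  partial coverage can, on rare draws, fill the gap and be missed — the
  observed failure mode on dense helical phantom configurations before
  calibration, and the expected failure mode on real stents with
  near-continuous encrustation. A rank-based outlier rule would be more
  robust but is a different algorithm.
* Run-fraction thresholds are relative to stent length, so the same
  deposit classifies differently on stents of very different lengths;
  absolute-length thresholds would need a different calibration.
* The centerline model assumes one stent per volume; two stents (or a
  stent crossing a similarly bright catheter) would need instance
  separation upstream.
* Verdicts say nothing about severity; grading encrustation burden is
  out of scope.
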