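"""Centerline extraction and perpendicular re-slicing of the stent.

A stent tilts and curves freely inside the body, so fixed axial CT slices
cut it obliquely and its cross-section appears as a stretched irregular
ellipse.  Re-slicing fixes this: the filtered stent mask is thinned to a
curve-skeleton, the skeleton is ordered end-to-end and fitted with a
smoothing B-spline, and the volume is resampled on planes perpendicular
to the fitted tangent.  On those planes a clean stent is a near-perfect
disk of constant area, so any stone fused to or touching the wall shows
up as a localized area excursion.

Stages
------
``thin_to_skeleton``  iterative template thinning (boundary peeling)
``order_skeleton``    spur pruning + endpoint-to-endpoint ordering
``fit_curve``         smoothing cubic B-spline with analytic tangents
``extract_sections``  arc-length-uniform perpendicular resampling
``detect_area_anomalies``  sorted-jump boundary rule on the area sequence
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from scipy.ndimage import map_coordinates

from ._thinning import thin
from .io_volumes import BinaryMask, CTVolume
from .report import AnomalySegment

__all__ = [
    "Centerline",
    "FittedCurve",
    "CrossSection",
    "AnomalySegment",
    "SkeletonBranchError",
    "thin_to_skeleton",
    "order_skeleton",
    "fit_curve",
    "extract_sections",
    "detect_area_anomalies",
]

_NBR26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


class SkeletonBranchError(ValueError):
    """The skeleton graph cannot be ordered into an end-to-end path."""


@dataclass(frozen=True)
class Centerline:
    """Ordered stent centerline in mm, superior (high z) end first."""

    points_mm: np.ndarray  # (n, 3)
    source_voxels: np.ndarray  # (m, 3) int voxel indices of the full skeleton

    def __len__(self) -> int:
        return len(self.points_mm)


@dataclass(frozen=True)
class FittedCurve:
    """A smoothing B-spline C(t), t in [0, 1], with analytic derivative."""

    tck: tuple

    def point(self, t) -> np.ndarray:
        return np.stack(interpolate.splev(np.asarray(t, dtype=float), self.tck), axis=-1)

    def derivative(self, t) -> np.ndarray:
        return np.stack(interpolate.splev(np.asarray(t, dtype=float), self.tck, der=1), axis=-1)

    def unit_tangent(self, t) -> np.ndarray:
        d = self.derivative(t)
        n = np.linalg.norm(d, axis=-1, keepdims=True)
        return np.divide(d, n, out=np.zeros_like(d), where=n > 0)

    def arc_length_table(self, n_dense: int = 2048) -> tuple[np.ndarray, np.ndarray]:
        """Dense (t, cumulative arc length) table for arc-length sampling."""
        t = np.linspace(0.0, 1.0, n_dense)
        pts = self.point(t)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return t, cum


@dataclass(frozen=True)
class CrossSection:
    """One perpendicular resampled slice through the stent."""

    index: int
    t: float
    arc_mm: float
    center_mm: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray
    patch: np.ndarray  # 2D bool, circular field of view
    pixel_mm: float
    area_mm2: float
    out_of_bounds: bool = False
    hu_patch: np.ndarray | None = None


def thin_to_skeleton(mask: BinaryMask) -> BinaryMask:
    """Peel the stent mask down to a one-voxel-wide curve-skeleton.

    Iterative 3x3x3-template thinning: in six directional subiterations,
    boundary voxels that are simple points (removal preserves local
    foreground and background topology) and not curve endpoints are
    deleted, layer by layer, until no voxel can be removed.  The
    skeleton is a subset of the input and preserves the 26-connected
    component count.
    """
    if not mask.voxels.any():
        return mask
    return BinaryMask(thin(mask.voxels), mask.spacing, mask.origin)


def _skeleton_graph(voxels: np.ndarray) -> dict[tuple, list[tuple]]:
    vox = {tuple(v) for v in voxels}
    adj: dict[tuple, list[tuple]] = {}
    for p in vox:
        nbrs = []
        for d in _NBR26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if q in vox:
                nbrs.append(q)
        adj[p] = nbrs
    return adj


def _prune_spurs(adj: dict[tuple, list[tuple]], prune_len: int) -> dict[tuple, list[tuple]]:
    """Remove side branches shorter than prune_len voxels, iteratively."""
    adj = {p: list(n) for p, n in adj.items()}
    changed = True
    while changed:
        changed = False
        endpoints = [p for p, n in adj.items() if len(n) == 1]
        for ep in endpoints:
            if ep not in adj or len(adj[ep]) != 1:
                continue
            chain = [ep]
            prev, cur = ep, adj[ep][0]
            while len(adj[cur]) == 2 and len(chain) < prune_len:
                chain.append(cur)
                nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
                prev, cur = cur, nxt
            # a spur ends at a junction; a main branch ends at an endpoint
            if len(adj[cur]) >= 3 and len(chain) < prune_len:
                for p in chain:
                    for q in adj.pop(p):
                        if q in adj and p in adj[q]:
                            adj[q].remove(p)
                changed = True
    return adj


def _bfs_farthest(adj: dict[tuple, list[tuple]], start: tuple) -> tuple[tuple, dict[tuple, tuple | None]]:
    """Farthest voxel from start (deterministic tie-break) and BFS parents."""
    from collections import deque

    prev: dict[tuple, tuple | None] = {start: None}
    dist = {start: 0}
    queue = deque([start])
    far, far_d = start, 0
    while queue:
        p = queue.popleft()
        for q in sorted(adj[p]):
            if q not in prev:
                prev[q] = p
                dist[q] = dist[p] + 1
                if dist[q] > far_d or (dist[q] == far_d and q < far):
                    far, far_d = q, dist[q]
                queue.append(q)
    return far, prev


def order_skeleton(skeleton: BinaryMask, prune_len: int = 5) -> Centerline:
    """Order the skeleton voxels into a single end-to-end path.

    Short spurs (< ``prune_len`` voxels) left by thinning are pruned;
    the ordered sequence is then the longest path of the remaining
    skeleton tree (its diameter, found by double BFS), which is the
    kidney-to-bladder curve regardless of any residual side branch a
    wall deposit may have produced.  The path starts at the superior
    (greater z) end.
    """
    vox = np.argwhere(skeleton.voxels)
    if len(vox) == 0:
        raise ValueError("skeleton is empty")
    if len(vox) == 1:
        pts = skeleton.world(vox.astype(float))
        return Centerline(points_mm=pts, source_voxels=vox)
    adj = _prune_spurs(_skeleton_graph(vox), prune_len)
    if not any(len(n) <= 1 for n in adj.values()):
        raise SkeletonBranchError("skeleton has no endpoints (cyclic); cannot order a centerline")
    # tree diameter: farthest voxel from an arbitrary start, then farthest
    # from that — the path between them is the main stent curve
    seed = min(adj)
    a, _ = _bfs_farthest(adj, seed)
    b, prev = _bfs_farthest(adj, a)
    path = []
    node: tuple | None = b
    while node is not None:
        path.append(node)
        node = prev[node]
    spacing = np.asarray(skeleton.spacing)
    if path[0][2] * spacing[2] < path[-1][2] * spacing[2]:
        path.reverse()
    idx = np.array(path, dtype=float)
    return Centerline(points_mm=skeleton.world(idx), source_voxels=vox)


def fit_curve(
    centerline: Centerline,
    smoothing: float = 0.5,
    degree: int = 3,
    presmooth_window: int = 5,
) -> FittedCurve:
    """Fit a smoothing B-spline through the ordered centerline points.

    ``smoothing`` is the tolerated RMS residual per point in mm (0 gives
    an interpolating spline through the raw points); the
    parameterization is normalized chord length.  A short moving average
    (``presmooth_window`` points) is applied to the ordered path first:
    voxel paths are staircases whose jitter otherwise leaks into the
    tangent, tilting the section planes.  Pre-smoothing is skipped in
    interpolation mode (``smoothing=0``).  Needs at least ``degree + 1``
    points.
    """
    pts = np.asarray(centerline.points_mm, dtype=float)
    if smoothing > 0 and presmooth_window > 1 and len(pts) > presmooth_window:
        kernel = np.ones(presmooth_window) / presmooth_window
        pts = np.stack([np.convolve(pts[:, i], kernel, mode="valid") for i in range(3)], axis=1)
    n = len(pts)
    if n < degree + 1:
        raise ValueError(f"need at least {degree + 1} points to fit a degree-{degree} spline, got {n}")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    if u[-1] <= 0:
        raise ValueError("centerline has zero length")
    u /= u[-1]
    s = n * float(smoothing) ** 2
    tck, _ = interpolate.splprep(pts.T, u=u, k=degree, s=s)
    return FittedCurve(tck=tuple(tck))


def _section_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane orthonormal basis perpendicular to the tangent."""
    z_hat = np.array([0.0, 0.0, 1.0])
    c = np.cross(tangent, z_hat)
    if np.linalg.norm(c) < 1e-6:
        c = np.cross(tangent, np.array([1.0, 0.0, 0.0]))
    u = c / np.linalg.norm(c)
    v = np.cross(tangent, u)
    v /= np.linalg.norm(v)
    return u, v


def extract_sections(
    mask: BinaryMask,
    curve: FittedCurve,
    n_sections: int | None = None,
    section_spacing_mm: float = 1.0,
    patch_extent_mm: float = 28.0,
    pixel_mm: float = 0.25,
    hu_volume: CTVolume | None = None,
) -> list[CrossSection]:
    """Resample perpendicular cross-sections at uniform arc-length steps.

    Each section is a square patch of side ``patch_extent_mm`` sampled by
    trilinear interpolation (mask values thresholded at 0.5 for the
    boolean patch) and cropped to the inscribed disk, so the radial
    field of view is isotropic.  The area integrates the interpolated
    occupancy over the field of view (partial-volume weighting), which
    is unbiased where a hard threshold would inflate the boundary by a
    fraction of a voxel.  Planes that leave the volume are padded with
    background and flagged.
    """
    t_dense, cum = curve.arc_length_table()
    total = float(cum[-1])
    if n_sections is None:
        n_sections = max(int(np.ceil(total / section_spacing_mm)) + 1, 2)
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    arcs = np.linspace(0.0, total, n_sections)
    ts = np.interp(arcs, cum, t_dense)

    half = patch_extent_mm / 2.0
    n_pix = int(np.floor(patch_extent_mm / pixel_mm)) + 1
    ax = (np.arange(n_pix) - (n_pix - 1) / 2.0) * pixel_mm
    pa, pb = np.meshgrid(ax, ax, indexing="ij")
    fov = pa**2 + pb**2 <= half**2
    pix_area = pixel_mm**2

    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    vol_f = mask.voxels.astype(np.float32)
    shape = np.asarray(mask.shape)

    sections: list[CrossSection] = []
    prev_tangent: np.ndarray | None = None
    for i, (t, arc) in enumerate(zip(ts, arcs)):
        center = curve.point(t)
        d = curve.derivative(t)
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            if prev_tangent is None:
                raise ValueError("degenerate tangent at the first section")
            tangent = prev_tangent  # reuse previous frame direction
        else:
            tangent = d / norm
        prev_tangent = tangent
        u, v = _section_basis(tangent)

        world = center[None, None, :] + pa[..., None] * u + pb[..., None] * v
        idx = (world - origin) / spacing
        oob = bool((idx < 0).any() or (idx > shape - 1).any())
        flat = idx.reshape(-1, 3).T
        samp = map_coordinates(vol_f, flat, order=1, mode="constant", cval=0.0)
        occupancy = np.clip(samp.reshape(n_pix, n_pix), 0.0, 1.0) * fov
        patch = (occupancy >= 0.5) & fov
        hu_patch = None
        if hu_volume is not None:
            hu = map_coordinates(hu_volume.voxels.astype(np.float32), flat, order=1, mode="constant", cval=float(hu_volume.voxels.min()))
            hu_patch = hu.reshape(n_pix, n_pix)
        sections.append(
            CrossSection(
                index=i,
                t=float(t),
                arc_mm=float(arc),
                center_mm=center,
                normal=tangent,
                u=u,
                v=v,
                patch=patch,
                pixel_mm=pixel_mm,
                area_mm2=float(occupancy.sum()) * pix_area,
                out_of_bounds=oob,
                hu_patch=hu_patch,
            )
        )
    return sections


def detect_area_anomalies(sections: list[CrossSection], jump_threshold: float = 0.07) -> list[AnomalySegment]:
    """Find runs of sections whose area jumps above the normal band.

    The area sequence is normalized by its median and sorted; the first
    adjacent pair among the above-median values whose difference exceeds
    ``jump_threshold`` sets the boundary value, and every section at or
    above the boundary is anomalous (contiguous index runs are merged
    into segments).  No qualifying jump means no anomalies.  The search
    is restricted to the above-median side because sections at the stent
    tips legitimately shrink (end caps) and must not define a boundary.
    """
    if len(sections) < 2:
        raise ValueError("need at least 2 sections")
    areas = np.array([s.area_mm2 for s in sections], dtype=float)
    med = float(np.median(areas))
    if med <= 0:
        return []
    norm = areas / med
    svals = np.sort(norm)
    upper = svals[svals >= 1.0]
    boundary = None
    for i in range(len(upper) - 1):
        if upper[i + 1] - upper[i] > jump_threshold:
            boundary = upper[i + 1]
            break
    if boundary is None:
        return []
    anomalous = norm >= boundary
    segments: list[AnomalySegment] = []
    i = 0
    while i < len(anomalous):
        if anomalous[i]:
            j = i
            while j + 1 < len(anomalous) and anomalous[j + 1]:
                j += 1
            segments.append(
                AnomalySegment(
                    start_index=i,
                    end_index=j,
                    mean_normalized_area=float(norm[i : j + 1].mean()),
                    max_normalized_area=float(norm[i : j + 1].max()),
                )
            )
            i = j + 1
        else:
            i += 1
    return segments
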