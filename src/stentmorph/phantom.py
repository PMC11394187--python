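"""Synthetic CT phantoms with exact ground truth.

Clinical stent CTs cannot be redistributed, so every stage of the
pipeline is exercised against rendered phantoms instead: a curved bright
tube of known analytic centerline and radius plays the stent, with
optional wall-fused radial bumps (encrustation), a compact sphere
touching the wall (residual stone), scattered bright blobs away from the
tube (loose fragments), a bulky bone-like ellipsoid, and an axial gap
emulating slices a per-slice segmenter missed.

HU palette defaults place stones and encrustation (700 HU) inside the
same threshold window as the stent (900 HU), exactly the attenuation
overlap that makes plain thresholding insufficient and forces the 3D
connected-domain filtering to do real work.  The default grid is
anisotropic (0.7, 0.7, 1.25 mm) so physical-unit handling is always
exercised.  A spec plus its seed fully determines the rendered volume.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .io_volumes import BinaryMask, CTVolume

__all__ = [
    "Bump",
    "SphereStone",
    "PhantomSpec",
    "PhantomTruth",
    "render_phantom",
    "preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("clean", "encrusted", "residual", "distractors", "gapped")

_FAMILIES = ("straight", "tilted", "helix", "j")


@dataclass(frozen=True)
class Bump:
    """A wall-fused encrustation deposit: a radial thickening of the tube
    over an arc window (mm along the centerline) and an angular window."""

    arc_mm: float
    angle_deg: float
    angular_width_deg: float
    radial_mm: float
    length_mm: float


@dataclass(frozen=True)
class SphereStone:
    """A compact residual fragment: a sphere at the outer tube wall.

    ``offset_mm`` is the gap between sphere surface and tube wall: 0 is
    exact point tangency, positive values leave a gap, and negative
    values press the stone into the wall (areal contact — a point
    tangency rarely survives voxelization, while a real fragment leaning
    on the stent always shares a contact patch).  The sphere centre must
    stay outside the tube (``offset_mm > -radius_mm``)."""

    arc_mm: float
    radius_mm: float
    offset_mm: float
    angle_deg: float


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 120)
    spacing: tuple[float, float, float] = (0.7, 0.7, 1.25)
    family: str = "straight"
    tilt_deg: float = 0.0
    tilt_azimuth_deg: float = 0.0
    helix_radius_mm: float = 8.0
    helix_turns: float = 1.2
    helix_phase_deg: float = 0.0
    j_curl_radius_mm: float = 9.0
    j_curl_azimuth_deg: float = 0.0
    xy_offset_mm: tuple[float, float] = (0.0, 0.0)
    z_margin_mm: float = 5.0
    tube_radius_mm: float = 2.0
    tube_hu: float = 900.0
    background_hu: float = 20.0
    stone_hu: float = 700.0
    bone_hu: float = 1100.0
    noise_sigma_hu: float = 15.0
    encrustations: tuple[Bump, ...] = ()
    residual_stone: SphereStone | None = None
    loose_stones: tuple[tuple[tuple[float, float, float], float], ...] = ()
    bone_blob: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    gap: tuple[float, int] | None = None  # (arc position mm, gap length in z slices)
    seed: int = 0

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown centerline family {self.family!r}")
        if self.tube_radius_mm <= 0:
            raise ValueError("tube_radius_mm must be positive")
        for b in self.encrustations:
            if b.radial_mm <= 0 or b.length_mm <= 0 or b.angular_width_deg <= 0:
                raise ValueError(f"bump extents must be positive: {b}")
        s = self.residual_stone
        if s is not None:
            if s.radius_mm <= 0:
                raise ValueError("stone radius must be positive")
            # centre sits at r_tube + offset + r_stone from the axis
            if s.offset_mm + s.radius_mm <= 0:
                raise ValueError("residual stone centre would lie inside the tube")
        if self.gap is not None and self.gap[1] < 1:
            raise ValueError("gap length must be >= 1 slice")


@dataclass(frozen=True)
class PhantomTruth:
    centerline_mm: np.ndarray  # dense analytic samples (n, 3)
    arc_mm: np.ndarray  # cumulative arc length per sample
    tube: np.ndarray
    encrustation: np.ndarray
    residual_stone: np.ndarray
    loose_stones: np.ndarray
    bone: np.ndarray
    label: str  # clean / residual_stone / encrustation
    anomaly_arcs_mm: tuple[tuple[float, float], ...]

    def stent_mask(self, spacing, origin=(0.0, 0.0, 0.0)) -> BinaryMask:
        """Tube plus fused deposits: the connected stent structure."""
        return BinaryMask(self.tube | self.encrustation, spacing, origin)


# ---------------------------------------------------------------------------
# analytic centerlines
# ---------------------------------------------------------------------------


def dense_centerline(spec: PhantomSpec, step_mm: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Analytic centerline samples and cumulative arc length (mm)."""
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    cx = (nx - 1) * sx / 2 + spec.xy_offset_mm[0]
    cy = (ny - 1) * sy / 2 + spec.xy_offset_mm[1]
    z_lo, z_hi = spec.z_margin_mm, (nz - 1) * sz - spec.z_margin_mm
    n = 2048
    if spec.family == "straight":
        z = np.linspace(z_lo, z_hi, n)
        pts = np.stack([np.full(n, cx), np.full(n, cy), z], axis=1)
    elif spec.family == "tilted":
        th = np.deg2rad(spec.tilt_deg)
        ph = np.deg2rad(spec.tilt_azimuth_deg)
        z = np.linspace(z_lo, z_hi, n)
        zmid = (z_lo + z_hi) / 2
        dxy = np.tan(th) * (z - zmid)
        pts = np.stack([cx + dxy * np.cos(ph), cy + dxy * np.sin(ph), z], axis=1)
    elif spec.family == "helix":
        z = np.linspace(z_lo, z_hi, n)
        a = np.deg2rad(spec.helix_phase_deg) + 2 * np.pi * spec.helix_turns * (z - z_lo) / (z_hi - z_lo)
        pts = np.stack([cx + spec.helix_radius_mm * np.cos(a), cy + spec.helix_radius_mm * np.sin(a), z], axis=1)
    elif spec.family == "j":
        r = spec.j_curl_radius_mm
        e = np.array([np.cos(np.deg2rad(spec.j_curl_azimuth_deg)), np.sin(np.deg2rad(spec.j_curl_azimuth_deg))])
        z_top = z_hi - r
        n1 = int(n * 0.75)
        z = np.linspace(z_lo, z_top, n1)
        straight = np.stack([np.full(n1, cx), np.full(n1, cy), z], axis=1)
        alpha = np.linspace(0.0, np.pi, n - n1)
        centre = np.array([cx + r * e[0], cy + r * e[1], z_top])
        curl = (
            centre[None, :]
            + np.outer(-np.cos(alpha), np.array([r * e[0], r * e[1], 0.0]))
            + np.outer(np.sin(alpha), np.array([0.0, 0.0, r]))
        )
        pts = np.concatenate([straight, curl[1:]], axis=0)
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(spec.family)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    # resample uniformly in arc length at the requested step
    arcs = np.arange(0.0, cum[-1], step_mm)
    out = np.stack([np.interp(arcs, cum, pts[:, i]) for i in range(3)], axis=1)
    return out, arcs


def _frames(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit tangent and deterministic in-plane (u, v) basis per sample."""
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    z_hat = np.array([0.0, 0.0, 1.0])
    c = np.cross(tang, z_hat)
    bad = np.linalg.norm(c, axis=1) < 1e-6
    if bad.any():
        c[bad] = np.cross(tang[bad], np.array([1.0, 0.0, 0.0]))
    u = c / np.linalg.norm(c, axis=1, keepdims=True)
    v = np.cross(tang, u)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return tang, u, v


def _ang_diff_deg(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs((a - b + 180.0) % 360.0 - 180.0)
    return d


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render a phantom volume and its exact truth.

    A voxel is tube foreground iff its distance to the analytic
    centerline is at most the tube radius (plus the bump height inside an
    encrustation's arc/angular window); the residual stone is a sphere
    whose centre sits ``r_tube + offset + r_stone`` off the axis.
    Gaussian HU noise (seeded) is added last.
    """
    spec.validate()
    pts, arcs = dense_centerline(spec)
    tang, u_b, v_b = _frames(pts)
    tree = cKDTree(pts)

    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    grid = np.stack(
        np.meshgrid(
            np.arange(nx) * sx, np.arange(ny) * sy, np.arange(nz) * sz, indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)

    dist, idx = tree.query(grid, workers=-1)
    rel = grid - pts[idx]
    t_n = tang[idx]
    perp = rel - (rel * t_n).sum(axis=1, keepdims=True) * t_n
    rho = np.linalg.norm(perp, axis=1)
    ang = np.degrees(np.arctan2((perp * v_b[idx]).sum(axis=1), (perp * u_b[idx]).sum(axis=1))) % 360.0
    varc = arcs[idx]

    tube = dist <= spec.tube_radius_mm

    encrust = np.zeros(grid.shape[0], dtype=bool)
    for b in spec.encrustations:
        sel = (
            (np.abs(varc - b.arc_mm) <= b.length_mm / 2)
            & (_ang_diff_deg(ang, b.angle_deg) <= b.angular_width_deg / 2)
            & (rho <= spec.tube_radius_mm + b.radial_mm)
        )
        encrust |= sel
    encrust &= ~tube

    stone = np.zeros(grid.shape[0], dtype=bool)
    if spec.residual_stone is not None:
        s = spec.residual_stone
        i = int(np.argmin(np.abs(arcs - s.arc_mm)))
        direction = u_b[i] * np.cos(np.deg2rad(s.angle_deg)) + v_b[i] * np.sin(np.deg2rad(s.angle_deg))
        centre = pts[i] + (spec.tube_radius_mm + s.offset_mm + s.radius_mm) * direction
        stone = np.linalg.norm(grid - centre, axis=1) <= s.radius_mm
        stone &= ~tube

    loose = np.zeros(grid.shape[0], dtype=bool)
    for centre, radius in spec.loose_stones:
        c = np.asarray(centre, dtype=float)
        axis_clear = tree.query(c[None, :])[0][0]
        if axis_clear <= spec.tube_radius_mm + radius:
            raise ValueError(f"loose stone at {centre} touches the tube; move it or shrink it")
        loose |= np.linalg.norm(grid - c, axis=1) <= radius

    bone = np.zeros(grid.shape[0], dtype=bool)
    if spec.bone_blob is not None:
        centre, semi = spec.bone_blob
        d = (grid - np.asarray(centre)) / np.asarray(semi)
        bone = (d**2).sum(axis=1) <= 1.0

    if spec.gap is not None:
        arc_pos, n_slices = spec.gap
        i = int(np.argmin(np.abs(arcs - arc_pos)))
        z0 = int(round(pts[i, 2] / sz))
        zsel = (grid[:, 2] >= (z0 - 0.01) * sz) & (grid[:, 2] <= (z0 + n_slices - 1 + 0.01) * sz)
        tube &= ~zsel
        encrust &= ~zsel

    # disjoint truth masks with tube > encrustation > stone > loose > bone
    encrust &= ~tube
    stone &= ~(tube | encrust)
    loose &= ~(tube | encrust | stone)
    bone &= ~(tube | encrust | stone | loose)

    vol = np.full(grid.shape[0], spec.background_hu)
    vol[bone] = spec.bone_hu
    vol[loose] = spec.stone_hu
    vol[stone] = spec.stone_hu
    vol[encrust] = spec.stone_hu
    vol[tube] = spec.tube_hu
    rng = np.random.default_rng(spec.seed)
    vol = vol + rng.normal(0.0, spec.noise_sigma_hu, size=vol.shape)

    shape = spec.shape
    truth = PhantomTruth(
        centerline_mm=pts,
        arc_mm=arcs,
        tube=tube.reshape(shape),
        encrustation=encrust.reshape(shape),
        residual_stone=stone.reshape(shape),
        loose_stones=loose.reshape(shape),
        bone=bone.reshape(shape),
        label=(
            "encrustation"
            if spec.encrustations
            else ("residual_stone" if spec.residual_stone is not None else "clean")
        ),
        anomaly_arcs_mm=tuple(
            [(b.arc_mm - b.length_mm / 2, b.arc_mm + b.length_mm / 2) for b in spec.encrustations]
            + (
                [(spec.residual_stone.arc_mm - spec.residual_stone.radius_mm,
                  spec.residual_stone.arc_mm + spec.residual_stone.radius_mm)]
                if spec.residual_stone is not None
                else []
            )
        ),
    )
    return CTVolume(vol.reshape(shape), spec.spacing), truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _random_family(rng: np.random.Generator) -> dict:
    family = str(rng.choice(_FAMILIES))
    kw: dict = {"family": family, "xy_offset_mm": tuple(rng.uniform(-2.0, 2.0, size=2))}
    if family == "tilted":
        kw["tilt_deg"] = float(rng.uniform(3.0, 8.0))
        kw["tilt_azimuth_deg"] = float(rng.uniform(0.0, 360.0))
    elif family == "helix":
        kw["helix_phase_deg"] = float(rng.uniform(0.0, 360.0))
    elif family == "j":
        kw["j_curl_azimuth_deg"] = float(rng.uniform(0.0, 360.0))
    return kw


def preset(name: str, seed: int = 0) -> PhantomSpec:
    """Named reproducible phantom configurations.

    ``clean``       a stent with no deposits (random centerline family);
    ``encrusted``   4–6 short wall-fused bumps scattered along the stent;
    ``residual``    one 4.5–5.5 mm sphere touching the outer wall;
    ``distractors`` clean stent plus 5 loose fragments and a bone blob;
    ``gapped``      straight stent with one 3-slice axial gap.

    The seed draws the geometry (family, tilt, bump/stone placement) and
    the rendering noise, so the same (name, seed) is bit-identical.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    rng = np.random.default_rng([zlib.crc32(name.encode()), seed])
    base = PhantomSpec(seed=seed)

    if name == "gapped":
        spec = replace(base, family="straight", xy_offset_mm=tuple(rng.uniform(-2, 2, size=2)))
        _, arcs = dense_centerline(spec)
        return replace(spec, gap=(float(arcs[-1] / 2), 3))

    spec = replace(base, **_random_family(rng))
    _, arcs = dense_centerline(spec)
    total = float(arcs[-1])

    if name == "clean":
        return spec

    if name == "encrusted":
        n_bumps = int(rng.integers(4, 7))
        # jittered stratified placement: one bump per equal arc slot keeps
        # deposits separated and always terminates
        lo, hi = 15.0, total - 15.0
        width = (hi - lo) / n_bumps
        positions = [lo + width * (i + float(rng.uniform(0.25, 0.75))) for i in range(n_bumps)]
        bumps = tuple(
            Bump(
                arc_mm=p,
                angle_deg=float(rng.uniform(0.0, 360.0)),
                angular_width_deg=float(rng.uniform(70.0, 110.0)),
                radial_mm=float(rng.uniform(1.6, 2.4)),
                length_mm=float(rng.uniform(2.0, 3.0)),
            )
            for p in sorted(positions)
        )
        return replace(spec, encrustations=bumps)

    if name == "residual":
        stone = SphereStone(
            arc_mm=float(rng.uniform(0.25 * total, 0.75 * total)),
            radius_mm=float(rng.uniform(4.5, 5.5)),
            offset_mm=float(rng.uniform(-1.5, -0.7)),
            angle_deg=float(rng.uniform(0.0, 360.0)),
        )
        return replace(spec, residual_stone=stone)

    # distractors: loose fragments + a bone-like blob, none touching the tube
    pts, _ = dense_centerline(spec)
    tree = cKDTree(pts)
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    stones = []
    while len(stones) < 5:
        radius = float(rng.uniform(2.0, 3.5))
        c = np.array(
            [
                rng.uniform(radius + 2, (nx - 1) * sx - radius - 2),
                rng.uniform(radius + 2, (ny - 1) * sy - radius - 2),
                rng.uniform(radius + 2, (nz - 1) * sz - radius - 2),
            ]
        )
        if tree.query(c[None, :])[0][0] > spec.tube_radius_mm + radius + 1.5:
            stones.append((tuple(float(v) for v in c), radius))
    # bone blob: bulky ellipsoid in whichever xy corner clears the tube
    semi = np.array([6.0, 8.0, 18.0])
    margin = spec.tube_radius_mm + 1.5
    zmid = 0.5 * (nz - 1) * sz
    candidates = [
        np.array([x, y, zmid])
        for x in (semi[0] + 2.0, (nx - 1) * sx - semi[0] - 2.0)
        for y in (semi[1] + 2.0, (ny - 1) * sy - semi[1] - 2.0)
    ]

    def clearance(c: np.ndarray) -> float:
        # >1 means the tube (dilated by margin) misses the ellipsoid
        scaled = (pts - c) / (semi + margin)
        return float(np.min((scaled**2).sum(axis=1)))

    corner = max(candidates, key=clearance)
    if clearance(corner) <= 1.0:
        raise RuntimeError("could not place the bone blob clear of the stent")
    blob = (tuple(float(v) for v in corner), tuple(float(v) for v in semi))
    return replace(spec, loose_stones=tuple(stones), bone_blob=blob)
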