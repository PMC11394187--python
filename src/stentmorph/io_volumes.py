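"""Volume and mask I/O with a single coordinate convention.

All downstream geometry runs in physical millimetres.  A :class:`CTVolume`
is a rectilinear grid: 0-based voxel indices, index order ``(x, y, z)``,
voxel centre at ``origin + index * spacing``.  Oblique DICOM orientations
are resampled to an axis-aligned grid at load time, so nothing downstream
ever sees a rotation matrix.

NIfTI (via nibabel) is the canonical interchange format for both HU
volumes and binary masks; DICOM series directories are read-only input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "CTVolume",
    "BinaryMask",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "CaseReport",
    "write_report",
    "read_report",
]


class GridMismatchError(ValueError):
    """Raised when a mask's grid does not match its reference volume."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT scalar field in Hounsfield units on a rectilinear grid.

    Parameters
    ----------
    voxels
        3D float array indexed ``[x, y, z]``.
    spacing
        Physical voxel size ``(sx, sy, sz)`` in mm; strictly positive.
    origin
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def world(self, index: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to world coordinates in mm."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def index(self, world: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to (fractional) voxel indices."""
        return (np.asarray(world) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass(frozen=True)
class BinaryMask:
    """A boolean foreground mask on the same grid as its source CTVolume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxels.dtype != bool:
            object.__setattr__(self, "voxels", self.voxels.astype(bool))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def world(self, index: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def count(self) -> int:
        return int(self.voxels.sum())

    def same_grid(self, other, tol_mm: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol_mm)
            and np.allclose(self.origin, other.origin, atol=tol_mm)
        )


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def _affine_from_grid(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> tuple[np.ndarray | None, tuple, tuple]:
    """Extract spacing/origin from an axis-aligned affine.

    Returns ``(resample_matrix, spacing, origin)``; the matrix is None when
    the affine is already axis-aligned with positive steps.
    """
    lin = aff[:3, :3]
    spacing = np.sqrt((lin**2).sum(axis=0))
    if np.any(spacing <= 0):
        raise ValueError("NIfTI header has non-positive voxel spacing")
    # axis-aligned and positive iff lin is exactly diag(spacing)
    if np.allclose(lin, np.diag(spacing), atol=1e-6 * spacing.max()):
        return None, tuple(float(s) for s in spacing), tuple(float(o) for o in aff[:3, 3])
    return lin, tuple(float(s) for s in spacing), tuple(float(o) for o in aff[:3, 3])


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {img.shape}")
    # Bring to closest canonical (RAS) orientation: handles flips/permutations.
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    lin, spacing, origin = _grid_from_affine(img.affine, img.shape)
    if lin is not None:
        data, spacing, origin = _resample_oblique(data, img.affine)
    return np.ascontiguousarray(data), spacing, origin


def _resample_oblique(data: np.ndarray, affine: np.ndarray):
    """Trilinearly resample an oblique grid onto an axis-aligned one."""
    from scipy.ndimage import affine_transform

    lin = affine[:3, :3]
    spacing = np.sqrt((lin**2).sum(axis=0))
    # world-space bounding box of all 8 corners
    corners = np.array(
        [[i, j, k] for i in (0, data.shape[0] - 1) for j in (0, data.shape[1] - 1) for k in (0, data.shape[2] - 1)],
        dtype=float,
    )
    world = corners @ lin.T + affine[:3, 3]
    lo, hi = world.min(axis=0), world.max(axis=0)
    new_shape = np.maximum(np.round((hi - lo) / spacing).astype(int) + 1, 1)
    # map output index -> world -> input index
    inv = np.linalg.inv(lin)
    matrix = inv * spacing  # composed: world step per output index, then to input index
    offset = inv @ (lo - affine[:3, 3])
    out = affine_transform(
        data.astype(float), matrix, offset=offset, output_shape=tuple(new_shape), order=1, mode="constant", cval=float(np.min(data))
    )
    return out, tuple(float(s) for s in spacing), tuple(float(v) for v in lo)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------


def _load_dicom_dir(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f), stop_before_pixels=False)
        except Exception:
            continue  # skip non-DICOM files (DICOMDIR, reports, ...)
        if not hasattr(ds, "PixelData"):
            continue
        slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {path}")

    uids = sorted({str(getattr(ds, "SeriesInstanceUID", "?")) for ds in slices})
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} DICOM series: {', '.join(uids)}")

    first = slices[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("DICOM series has no PixelSpacing; refusing to assume 1 mm")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)

    # slice normal from ImageOrientationPatient; sort by projection of position
    if hasattr(first, "ImageOrientationPatient"):
        iop = np.array([float(v) for v in first.ImageOrientationPatient])
        normal = np.cross(iop[:3], iop[3:])
    else:
        normal = np.array([0.0, 0.0, 1.0])

    def slice_pos(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(np.dot(normal, [float(v) for v in ds.ImagePositionPatient]))
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=slice_pos)
    positions = np.array([slice_pos(ds) for ds in slices])
    if len(slices) > 1:
        dz = np.diff(positions)
        if np.any(dz <= 0):
            raise ValueError("DICOM slices have non-monotone positions after sorting")
        slice_mm = float(np.median(dz))
    elif hasattr(first, "SliceThickness"):
        slice_mm = float(first.SliceThickness)
    else:
        raise ValueError("single-slice series with no SliceThickness; spacing unknown")

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array is (row, col) = (y, x); build (x, y, z)
    vol = np.stack(planes, axis=-1).transpose(1, 0, 2)

    if hasattr(first, "ImagePositionPatient"):
        ox, oy, _ = (float(v) for v in first.ImagePositionPatient)
        oz = positions[0]
    else:
        ox = oy = oz = 0.0
    return np.ascontiguousarray(vol), (col_mm, row_mm, slice_mm), (ox, oy, float(oz))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def read_volume(path, fmt: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    ``fmt`` is one of ``{"nifti", "dicom_dir"}``; inferred from the path when
    omitted (directory -> DICOM, file -> NIfTI).  Voxel values are rescaled
    to Hounsfield units where rescale slope/intercept are present; DICOM
    slices are sorted by position along the slice normal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "dicom_dir" if path.is_dir() else "nifti"
    if fmt == "nifti":
        data, spacing, origin = _load_nifti(path)
    elif fmt == "dicom_dir":
        data, spacing, origin = _load_dicom_dir(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return CTVolume(data.astype(np.float64), spacing, origin)


def write_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI (float32, axis-aligned affine)."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine_from_grid(volume.spacing, volume.origin))
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    """Write a BinaryMask as uint8 0/1 NIfTI."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_from_grid(mask.spacing, mask.origin))
    nib.save(img, str(path))


def read_mask(path, reference: CTVolume | None = None, tol_mm: float = 1e-3) -> BinaryMask:
    """Read a boolean mask from NIfTI, checking its grid against ``reference``.

    Raises :class:`GridMismatchError` when shape/spacing/origin differ from
    the reference grid by more than ``tol_mm``.
    """
    data, spacing, origin = _load_nifti(Path(path))
    mask = BinaryMask(data > 0.5, spacing, origin)
    if reference is not None and not mask.same_grid(reference, tol_mm=tol_mm):
        raise GridMismatchError(
            "mask grid does not match reference: "
            f"mask shape={mask.shape} spacing={mask.spacing} origin={mask.origin}; "
            f"reference shape={reference.shape} spacing={reference.spacing} origin={reference.origin}"
        )
    return mask


# CaseReport plumbing lives in report.py; re-exported here for a single
# import surface.
from .report import CaseReport, read_report, write_report  # noqa: E402,F401
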