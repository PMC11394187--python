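"""Stent foreground segmentation providers.

The pipeline is agnostic about where the per-voxel stent foreground comes
from: any model that maps a CT volume to a boolean mask on the same grid
can plug in.  Two providers ship in-package:

* ``threshold`` — an HU-window baseline.  Stent polymer and calcified
  deposits overlap in attenuation with stones and bone, so a window alone
  over-segments by design; the 3D connected-domain filtering downstream is
  what isolates the stent.
* ``external`` — imports a mask produced by any external segmentation
  model (e.g. a trained neural network) from NIfTI, with a strict grid
  check against the reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .io_volumes import BinaryMask, CTVolume, read_mask

__all__ = [
    "threshold_segment",
    "import_mask",
    "SegmentationProvider",
    "get_provider",
]

DEFAULT_HU_LOW = 300.0
DEFAULT_HU_HIGH = 3000.0


def threshold_segment(volume: CTVolume, hu_low: float = DEFAULT_HU_LOW, hu_high: float = DEFAULT_HU_HIGH) -> BinaryMask:
    """Binary mask of voxels with ``hu_low <= HU <= hu_high``.

    Deterministic and idempotent; the default window (300–3000 HU)
    brackets typical stent and stone attenuation while excluding soft
    tissue and air.
    """
    if not hu_low < hu_high:
        raise ValueError(f"require hu_low < hu_high, got [{hu_low}, {hu_high}]")
    fg = (volume.voxels >= hu_low) & (volume.voxels <= hu_high)
    return BinaryMask(fg, volume.spacing, volume.origin)


def import_mask(path, reference: CTVolume) -> BinaryMask:
    """Load an externally produced stent mask, enforcing the grid contract."""
    return read_mask(path, reference=reference)


@dataclass(frozen=True)
class SegmentationProvider:
    """A named CTVolume -> BinaryMask contract with opaque parameters."""

    name: str
    parameters: dict = field(default_factory=dict)
    _fn: Callable[[CTVolume], BinaryMask] | None = None

    def __call__(self, volume: CTVolume) -> BinaryMask:
        if self._fn is None:
            raise RuntimeError(f"provider {self.name!r} has no callable bound")
        mask = self._fn(volume)
        if mask.shape != volume.shape:
            raise ValueError(f"provider {self.name!r} returned grid {mask.shape}, expected {volume.shape}")
        return mask


def get_provider(name: str, **parameters) -> SegmentationProvider:
    """Resolve a provider by name.

    ``threshold`` accepts ``hu_low``/``hu_high``; ``external`` requires
    ``mask_path`` pointing at a NIfTI mask on the volume's grid.
    """
    if name == "threshold":
        lo = float(parameters.get("hu_low", DEFAULT_HU_LOW))
        hi = float(parameters.get("hu_high", DEFAULT_HU_HIGH))
        return SegmentationProvider(
            name="threshold",
            parameters={"hu_low": lo, "hu_high": hi},
            _fn=lambda vol: threshold_segment(vol, lo, hi),
        )
    if name == "external":
        if "mask_path" not in parameters or parameters["mask_path"] in (None, ""):
            raise ValueError("provider 'external' requires parameter 'mask_path'")
        mask_path = parameters["mask_path"]
        return SegmentationProvider(
            name="external",
            parameters={"mask_path": str(mask_path)},
            _fn=lambda vol: import_mask(mask_path, vol),
        )
    raise ValueError(f"unknown segmentation provider {name!r} (expected 'threshold' or 'external')")
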