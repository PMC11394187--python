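"""Diagnostic plots: area sequence and polar feature map.

Matplotlib figures for quick visual review; nothing in the pipeline
depends on them.
"""

from __future__ import annotations

import numpy as np

from .detection import RadiusProfile
from .report import AnomalySegment
from .reslice import CrossSection


def plot_area_sequence(sections: list[CrossSection], segments: list[AnomalySegment] = (), ax=None):
    """Cross-sectional area along the stent, with anomaly segments shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    arcs = [s.arc_mm for s in sections]
    areas = [s.area_mm2 for s in sections]
    ax.plot(arcs, areas, lw=1.0, color="tab:blue")
    for seg in segments:
        ax.axvspan(sections[seg.start_index].arc_mm, sections[seg.end_index].arc_mm, color="tab:red", alpha=0.25)
    ax.set_xlabel("arc length along stent (mm)")
    ax.set_ylabel("section area (mm²)")
    return ax


def plot_polar_map(profiles: list[RadiusProfile], ax=None):
    """Angle x section-index map of radii: defects appear as bright streaks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    profiles = sorted(profiles, key=lambda p: p.section_index)
    img = np.stack([p.radii for p in profiles], axis=1)
    im = ax.imshow(img, aspect="auto", origin="lower", cmap="magma",
                   extent=(0, img.shape[1], 0, 360))
    ax.set_xlabel("section index along stent")
    ax.set_ylabel("angle (deg)")
    plt.colorbar(im, ax=ax, label="radius (mm)")
    return ax
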