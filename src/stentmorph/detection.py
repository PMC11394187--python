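"""Polar radius profiling and stone/encrustation classification.

A perpendicular cross-section of a clean stent is a near-circular disk,
so its polar transform — outermost foreground radius per angular bin
around the section centroid — is a flat profile.  The two pathologies
deform that profile in characteristically different ways:

* a **residual stone** is a single compact fragment touching the stent:
  one *contiguous* block of sections shows a *large* radius excursion;
* **encrustation** is mineral growth along the indwelling stent:
  *intermittent* moderate radius elevations scattered along the whole
  stent.

``classify_anomaly`` encodes this contrast with configurable thresholds
(the rules are qualitative in origin; every number used is recorded in
the case report for provenance), and ``decide_case`` aggregates segment
classes into the per-case verdict, with encrustation taking precedence
because it is the finding that changes clinical management.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .report import AnomalySegment, CaseReport
from .reslice import CrossSection

__all__ = [
    "RadiusProfile",
    "ProfileFeatures",
    "ConfigThresholds",
    "EmptySectionError",
    "polar_transform",
    "profile_features",
    "classify_anomaly",
    "decide_case",
]


class EmptySectionError(ValueError):
    """polar_transform was given a section with no foreground pixels."""


@dataclass(frozen=True)
class ConfigThresholds:
    """Decision thresholds for the stone/encrustation classifier.

    elevation_delta
        Relative radius increase over baseline that makes a bin "elevated".
    stone_run_fraction
        Minimum fraction of all sections a single contiguous elevated run
        must span to look like a compact stone.
    stone_magnitude
        Minimum max relative elevation for the stone branch.
    encrust_min_runs
        Minimum number of separate elevated runs for the intermittent
        (encrustation) pattern.
    encrust_run_max_fraction
        Maximum length of each run, as a fraction of all sections, for
        the encrustation pattern.
    elevated_min_fraction
        Minimum fraction of a section's angular bins that must be
        elevated before the section counts as elevated (a genuine
        deposit spans many bins; quantization noise touches one or two).
    n_bins
        Angular bins of the polar transform.
    """

    elevation_delta: float = 0.35
    stone_run_fraction: float = 0.05
    stone_magnitude: float = 0.5
    encrust_min_runs: int = 3
    encrust_run_max_fraction: float = 0.04
    elevated_min_fraction: float = 0.08
    n_bins: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.elevation_delta:
            raise ValueError("elevation_delta must be positive")
        for name in ("stone_run_fraction", "encrust_run_max_fraction", "elevated_min_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.encrust_min_runs < 1:
            raise ValueError("encrust_min_runs must be >= 1")
        if self.n_bins < 4:
            raise ValueError("n_bins must be >= 4")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RadiusProfile:
    """Outermost-foreground radius (mm) per angular bin of one section."""

    section_index: int
    radii: np.ndarray  # (n_bins,) mm
    empty_bins: np.ndarray  # (n_bins,) bool, True where no pixel fell in the bin

    @property
    def n_bins(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class ProfileFeatures:
    """Across-section elevation pattern feeding the classifier."""

    baseline_radius_mm: float
    elevated_fraction: np.ndarray  # per-section fraction of elevated bins
    elevated_sections: np.ndarray  # bool per section
    runs: tuple[tuple[int, int], ...]  # (start, end) inclusive, in section order
    n_sections: int
    max_relative_elevation: float

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def longest_run(self) -> int:
        return max((e - s + 1 for s, e in self.runs), default=0)


def polar_transform(section: CrossSection, n_bins: int = 64) -> RadiusProfile:
    """Map a cross-section to its radius-vs-angle profile.

    The radius of an angular bin is the distance (mm) from the foreground
    centroid to the outermost foreground pixel whose angle falls in the
    bin; bins with no pixels get radius 0 and are flagged.  Mapping the
    circular boundary to a 1D sequence turns wall defects into profile
    excursions.
    """
    ys, xs = np.nonzero(section.patch)
    if len(xs) == 0:
        raise EmptySectionError(f"section {section.index} has no foreground pixels")
    cy, cx = ys.mean(), xs.mean()
    dy = (ys - cy) * section.pixel_mm
    dx = (xs - cx) * section.pixel_mm
    ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    dist = np.hypot(dx, dy)
    bins = np.minimum((ang / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    radii = np.zeros(n_bins)
    np.maximum.at(radii, bins, dist)
    counts = np.bincount(bins, minlength=n_bins)
    return RadiusProfile(section_index=section.index, radii=radii, empty_bins=counts == 0)


def profile_features(
    profiles: list[RadiusProfile],
    thresholds: ConfigThresholds = ConfigThresholds(),
    anomalous_indices: set[int] | None = None,
) -> ProfileFeatures:
    """Reduce per-section radius profiles to the elevation pattern.

    The baseline radius is the median over all bins of the non-anomalous
    sections (falling back to the global median when every section is
    anomalous); a bin is elevated when its radius exceeds
    ``baseline * (1 + elevation_delta)``, a section when at least
    ``elevated_min_fraction`` of its bins are, and runs are maximal
    consecutive stretches of elevated sections.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    profiles = sorted(profiles, key=lambda p: p.section_index)
    anomalous_indices = anomalous_indices or set()
    clean_radii = [
        p.radii[~p.empty_bins] for p in profiles if p.section_index not in anomalous_indices
    ]
    pool = np.concatenate(clean_radii) if clean_radii else np.concatenate([p.radii[~p.empty_bins] for p in profiles])
    if pool.size == 0:
        raise ValueError("all angular bins are empty")
    baseline = float(np.median(pool))
    cutoff = baseline * (1.0 + thresholds.elevation_delta)

    frac = np.empty(len(profiles))
    max_rel = 0.0
    for i, p in enumerate(profiles):
        valid = ~p.empty_bins
        elevated = valid & (p.radii > cutoff)
        frac[i] = elevated.sum() / max(valid.sum(), 1)
        if baseline > 0 and valid.any():
            max_rel = max(max_rel, float(p.radii[valid].max() / baseline - 1.0))
    elevated_sections = frac >= thresholds.elevated_min_fraction

    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(elevated_sections):
        if elevated_sections[i]:
            j = i
            while j + 1 < len(elevated_sections) and elevated_sections[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return ProfileFeatures(
        baseline_radius_mm=baseline,
        elevated_fraction=frac,
        elevated_sections=elevated_sections,
        runs=tuple(runs),
        n_sections=len(profiles),
        max_relative_elevation=max_rel,
    )


def classify_anomaly(features: ProfileFeatures, thresholds: ConfigThresholds = ConfigThresholds()) -> str:
    """Classify the elevation pattern: clean / residual_stone / encrustation.

    Decision rule:

    * no elevated section → ``clean``;
    * one (or two) contiguous runs, the longest spanning at least
      ``stone_run_fraction`` of the stent with a relative elevation of at
      least ``stone_magnitude`` → ``residual_stone`` (a compact fragment
      leaning on the stent);
    * at least ``encrust_min_runs`` separate short runs (each at most
      ``encrust_run_max_fraction`` of the stent) → ``encrustation``
      (intermittent growth along the wall);
    * anything ambiguous → ``encrustation``: flagging a possibly encrusted
      stent for review is the safe error.
    """
    if not features.elevated_sections.any():
        return "clean"
    n = features.n_sections
    if (
        features.longest_run / n >= thresholds.stone_run_fraction
        and features.max_relative_elevation >= thresholds.stone_magnitude
        and features.n_runs <= 2
    ):
        return "residual_stone"
    if features.n_runs >= thresholds.encrust_min_runs and all(
        (e - s + 1) / n <= thresholds.encrust_run_max_fraction for s, e in features.runs
    ):
        return "encrustation"
    return "encrustation"


def decide_case(
    segments: list[AnomalySegment],
    per_segment_class: list[str],
    case_id: str = "case",
    provenance: dict | None = None,
    features: dict | None = None,
) -> CaseReport:
    """Aggregate classified segments into the per-case verdict.

    Encrustation anywhere makes the case positive; otherwise any residual
    stone yields ``residual_stone``; no segments (or only clean ones)
    yield ``negative``.
    """
    if len(segments) != len(per_segment_class):
        raise ValueError("segments and classes differ in length")
    classified = tuple(
        AnomalySegment(
            start_index=s.start_index,
            end_index=s.end_index,
            mean_normalized_area=s.mean_normalized_area,
            max_normalized_area=s.max_normalized_area,
            classification=c,
        )
        for s, c in zip(segments, per_segment_class)
    )
    kept = tuple(s for s in classified if s.classification != "clean")
    if any(s.classification == "encrustation" for s in kept):
        verdict = "encrustation"
    elif any(s.classification == "residual_stone" for s in kept):
        verdict = "residual_stone"
    else:
        verdict = "negative"
        kept = ()
    return CaseReport(
        case_id=case_id,
        verdict=verdict,
        segments=kept,
        provenance=provenance or {},
        features=features or {},
    )
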