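"""Per-case result reports.

A :class:`CaseReport` carries the verdict for one CT study — ``negative``,
``residual_stone``, ``encrustation`` or ``indeterminate`` — together with
the anomalous centerline segments that drove it and full provenance
(segmentation source and every parameter used), serialized as JSON with a
schema version and stable key order so re-writing a report is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field  # noqa: F401
from pathlib import Path

SCHEMA_VERSION = 1

VERDICTS = ("negative", "residual_stone", "encrustation", "indeterminate")


@dataclass(frozen=True)
class AnomalySegment:
    """A contiguous run of cross-sections with anomalous area.

    Indices refer to the ordered perpendicular section sequence along the
    fitted centerline; areas are normalized by the case's median section
    area.
    """

    start_index: int
    end_index: int
    mean_normalized_area: float
    max_normalized_area: float
    classification: str | None = None

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError(f"segment start {self.start_index} > end {self.end_index}")

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class CaseReport:
    case_id: str
    verdict: str
    segments: tuple[AnomalySegment, ...] = ()
    provenance: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"verdict must be one of {VERDICTS}, got {self.verdict!r}")
        if self.verdict == "negative" and self.segments:
            raise ValueError("a negative verdict cannot carry anomaly segments")
        object.__setattr__(self, "segments", tuple(self.segments))

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "case_id": self.case_id,
            "verdict": self.verdict,
            "segments": [asdict(s) for s in self.segments],
            "provenance": self.provenance,
            "features": self.features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseReport":
        segs = tuple(AnomalySegment(**s) for s in d.get("segments", []))
        return cls(
            case_id=d["case_id"],
            verdict=d["verdict"],
            segments=segs,
            provenance=d.get("provenance", {}),
            features=d.get("features", {}),
        )


def write_report(report: CaseReport, path) -> None:
    """Serialize a CaseReport as JSON (sorted keys, 2-space indent)."""
    Path(path).write_text(json.dumps(report.to_dict(), sort_keys=True, indent=2) + "\n")


def read_report(path) -> CaseReport:
    return CaseReport.from_dict(json.loads(Path(path).read_text()))
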