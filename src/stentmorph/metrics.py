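"""Evaluation statistics: 2x2 confusion matrices and accuracy.

Two reference confusion matrices from the clinical validation of this
detection approach ship as packaged CSVs (rows = predictions, columns =
truth): a 186-site stone vs residual-stone discrimination and a 222-case
positive/negative (encrustation) judgment, whose cohort marginals are 67
positive and 155 negative cases.  They feed the evaluation worked
example and the self-consistency checks; nothing in the pipeline reads
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ConfusionMatrix2x2",
    "confusion",
    "accuracy",
    "accuracy_pct",
    "load_reference_confusions",
    "evaluate_csv",
]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts of a binary cross-tabulation (positive = encrustation)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def actual_positive(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negative(self) -> int:
        return self.fp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


def confusion(pred, truth, positive_label) -> ConfusionMatrix2x2:
    """Cross-tabulate predicted vs true binary labels."""
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValueError(f"pred has {len(pred)} labels but truth has {len(truth)}")
    tp = fn = fp = tn = 0
    for p, t in zip(pred, truth):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix2x2(tp=tp, fn=fn, fp=fp, tn=tn)


def accuracy(cm: ConfusionMatrix2x2) -> float:
    """Exact accuracy percentage, 100 * (tp + tn) / total."""
    if cm.total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def accuracy_pct(cm: ConfusionMatrix2x2) -> float:
    """Accuracy rounded to one decimal place, half up (reporting style)."""
    return float(Decimal(accuracy(cm)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _read_confusion_csv(text_source) -> ConfusionMatrix2x2:
    df = pd.read_csv(text_source, index_col=0)
    pos_col, neg_col = df.columns[0], df.columns[1]
    pos_row, neg_row = df.index[0], df.index[1]
    return ConfusionMatrix2x2(
        tp=int(df.loc[pos_row, pos_col]),
        fn=int(df.loc[neg_row, pos_col]),
        fp=int(df.loc[pos_row, neg_col]),
        tn=int(df.loc[neg_row, neg_col]),
    )


def load_reference_confusions() -> dict[str, ConfusionMatrix2x2]:
    """The packaged clinical reference matrices.

    ``stone_site``: 186 stent-adjacent stone sites classified stone
    (= encrustation, positive) vs residual stone.  ``case_judgment``:
    222 cases judged encrustation-positive vs negative.
    """
    out = {}
    for key in ("stone_site", "case_judgment"):
        with resources.files("stentmorph.data").joinpath(f"{key}_confusion.csv").open() as fh:
            out[key] = _read_confusion_csv(fh)
    return out


def evaluate_csv(pred_csv, truth_csv, positive_label: str = "encrustation") -> dict:
    """Score a prediction table against a truth table.

    Both CSVs have columns ``case_id,label``; rows are joined on
    ``case_id`` and every truth case must be predicted.  Labels other
    than ``positive_label`` count as negative.
    """
    pred = pd.read_csv(Path(pred_csv)).set_index("case_id")["label"]
    truth = pd.read_csv(Path(truth_csv)).set_index("case_id")["label"]
    missing = truth.index.difference(pred.index)
    if len(missing):
        raise ValueError(f"predictions missing for cases: {', '.join(map(str, missing))}")
    joined = pd.DataFrame({"pred": pred.reindex(truth.index), "truth": truth})
    cm = confusion(joined["pred"], joined["truth"], positive_label)
    return {**cm.to_dict(), "accuracy": accuracy_pct(cm)}
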