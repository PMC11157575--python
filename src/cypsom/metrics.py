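"""Confusion-count metrics and SOM-weighted (micro) aggregation.

The headline metric throughout is the Jaccard score J = TP/(TP+FP+FN); for
pooled counts it relates to F1 by F1 = 2J/(1+J).  Weighted averages across
the nine isoforms use each isoform's SOM count as weight.  Ratios with a zero
denominator are defined as 0 (logged), which only touches degenerate
evaluation slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

METRIC_NAMES = ("jaccard", "precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.debug("0/0 in %s; defined as 0", what)
        return 0.0
    return num / den


def site_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Jaccard, precision, recall and F1 from one confusion-count block."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    j = _ratio(tp, tp + fp + fn, "jaccard")
    p = _ratio(tp, tp + fp, "precision")
    r = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * p * r, p + r, "f1")
    return {"jaccard": j, "precision": p, "recall": r, "f1": f1}


def confusion_from_calls(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(bool)
    yp = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        tp=int((yt & yp).sum()),
        fp=int((~yt & yp).sum()),
        fn=int((yt & ~yp).sum()),
        tn=int((~yt & ~yp).sum()),
    )


def jaccard_score_from_calls(y_true, y_pred) -> float:
    return site_metrics(confusion_from_calls(y_true, y_pred))["jaccard"]


def weighted_average(values: Sequence[float], weights: Sequence[float]) -> float:
    """SOM-count-weighted (micro) average across isoforms."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must align")
    total = weights.sum()
    if total == 0:
        raise ValueError("zero total weight")
    return float((values * weights).sum() / total)


def metabolite_metrics(
    predicted: Iterable[str], reference: Iterable[str]
) -> dict[str, float]:
    """Set-overlap metrics over canonical product SMILES."""
    pred, ref = set(predicted), set(reference)
    tp = len(pred & ref)
    return site_metrics(
        ConfusionCounts(tp=tp, fp=len(pred) - tp, fn=len(ref) - tp)
    )


def round_for_report(x: float, ndigits: int = 3) -> float:
    """Half-up rounding to the table precision used in reports."""
    q = 10 ** ndigits
    return np.floor(x * q + 0.5) / q


def metrics_table(
    per_isoform: Mapping[str, Mapping[str, float]],
    weights: Mapping[str, float],
):
    """Assemble a report table (metric x isoform + WAvg column)."""
    import pandas as pd

    isoforms = list(per_isoform)
    df = pd.DataFrame(per_isoform).reindex(index=list(METRIC_NAMES))
    w = [weights[i] for i in isoforms]
    df["WAvg"] = [
        weighted_average([per_isoform[i][m] for i in isoforms], w)
        for m in METRIC_NAMES
    ]
    return df.map(round_for_report)
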