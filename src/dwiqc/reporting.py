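"""Slice-wise and volume-wise QC reports, metrics and the workload estimator.

Evaluation uses the standard detection metrics over slice or volume
decisions::

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)

A *volume* here is one 3D gradient image. A volume is flagged in a view when
it contains at least T artifactual slices in that view; sweeping T trades
precision against recall (larger T can only unflag volumes, so recall is
non-increasing in T). The workload estimator converts a detector's operating
point into the fraction of volumes an analyst no longer has to open: at
precision p and recall r over a corpus with ``n_artifactual`` bad volumes,
the expected flagged count is ``r * n_artifactual / p`` and the inspection
reduction is ``100 * (1 - flagged / n_total)`` percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .io_slicing import LABEL_ARTIFACTUAL

__all__ = [
    "ConfusionCounts", "Metrics", "VolumeReport", "WorkloadEstimate",
    "compute_metrics", "slice_report", "volume_flags", "sweep_thresholds",
    "estimate_inspection_reduction", "volume_truth",
]

DEFAULT_THRESHOLDS = (1, 3, 5, 7, 10)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN over binary artifact decisions (positive = artifactual)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label and prediction vectors differ in length")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class Metrics:
    """Precision/recall/accuracy; ``None`` marks an undefined ratio
    (zero denominator), which is reported as such rather than as 0 or 1."""

    precision: float | None
    recall: float | None
    accuracy: float


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Exact rational evaluation of precision, recall and accuracy.

    Zero-denominator cases (no predicted positives / no true positives)
    yield the undefined marker ``None`` instead of raising.
    """
    if c.total < 1:
        raise ValueError("metrics need at least one decision")
    precision = (
        float(Fraction(c.tp, c.tp + c.fp)) if c.tp + c.fp > 0 else None
    )
    recall = float(Fraction(c.tp, c.tp + c.fn)) if c.tp + c.fn > 0 else None
    accuracy = float(Fraction(c.tp + c.tn, c.total))
    return Metrics(precision=precision, recall=recall, accuracy=accuracy)


REPORT_KEYS = ["volume_id", "view", "gradient_index", "slice_index"]


def slice_report(predictions: pd.DataFrame,
                 manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """The slice-wise QC report: one row per evaluated slice.

    ``predictions`` must carry the keys (volume_id, view, gradient_index,
    slice_index) plus ``probability`` and ``predicted_label``. If a manifest
    with ground-truth labels is given, a ``label`` column is joined in. Rows
    are ordered by volume, view, gradient, slice; duplicate keys are an
    error.
    """
    df = predictions.copy()
    missing = set(REPORT_KEYS + ["probability", "predicted_label"]) - set(df.columns)
    if missing:
        raise ValueError(f"predictions missing columns: {sorted(missing)}")
    if df.duplicated(subset=REPORT_KEYS).any():
        dupes = df[df.duplicated(subset=REPORT_KEYS)][REPORT_KEYS].head()
        raise ValueError(f"duplicate prediction keys, e.g.\n{dupes}")
    if manifest is not None:
        truth = manifest[REPORT_KEYS + ["label"]]
        df = df.merge(truth, on=REPORT_KEYS, how="left", validate="one_to_one")
    return df.sort_values(REPORT_KEYS, kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class VolumeReport:
    """Per-(volume, gradient) artifactual-slice counts and flag status in one view."""

    view: str
    threshold: int
    table: pd.DataFrame  # volume_id, gradient_index, artifactual_slices, flagged, slice_indices

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]

    def summary(self) -> dict:
        """JSON-ready summary: counts and the flagged volume list."""
        return {
            "view": self.view,
            "threshold": self.threshold,
            "n_volumes": int(len(self.table)),
            "n_flagged": int(self.table["flagged"].sum()),
            "flagged": [
                {"volume_id": r.volume_id, "gradient_index": int(r.gradient_index),
                 "artifactual_slices": int(r.artifactual_slices)}
                for r in self.flagged.itertuples()
            ],
        }


def volume_flags(report: pd.DataFrame, threshold: int, view: str) -> VolumeReport:
    """Flag each 3D gradient volume whose artifactual-slice count in ``view``
    reaches the slice-count threshold (count >= T)."""
    if threshold < 1:
        raise ValueError("slice-count threshold must be >= 1")
    sub = report[report["view"] == view]
    rows = []
    for (vol, g), grp in sub.groupby(["volume_id", "gradient_index"], sort=True):
        hits = grp[grp["predicted_label"] == 1]["slice_index"].tolist()
        rows.append(
            {
                "volume_id": vol,
                "gradient_index": g,
                "artifactual_slices": len(hits),
                "flagged": len(hits) >= threshold,
                "slice_indices": sorted(hits),
            }
        )
    table = pd.DataFrame(
        rows, columns=["volume_id", "gradient_index", "artifactual_slices",
                       "flagged", "slice_indices"],
    )
    return VolumeReport(view=view, threshold=threshold, table=table)


def volume_truth(manifest: pd.DataFrame, view: str) -> pd.DataFrame:
    """Ground-truth volume labels: a gradient volume is truly artifactual in a
    view iff any of its slices in that view is labeled artifactual."""
    sub = manifest[manifest["view"] == view]
    truth = (
        sub.assign(artifactual=sub["label"] == LABEL_ARTIFACTUAL)
        .groupby(["volume_id", "gradient_index"], sort=True)["artifactual"]
        .any()
        .reset_index()
    )
    return truth


def sweep_thresholds(
    report: pd.DataFrame,
    manifest: pd.DataFrame,
    view: str,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Volume-level metrics at each slice-count threshold.

    Returns a table with columns Threshold, Accuracy, Precision, Recall (one
    row per T). Because raising T can only unflag volumes, recall is
    non-increasing down the table.
    """
    truth = volume_truth(manifest, view)
    rows = []
    for t in thresholds:
        vr = volume_flags(report, t, view)
        merged = truth.merge(
            vr.table[["volume_id", "gradient_index", "flagged"]],
            on=["volume_id", "gradient_index"], how="left",
        )
        merged["flagged"] = (
            merged["flagged"].astype("boolean").fillna(False).astype(bool)
        )
        c = ConfusionCounts.from_predictions(
            merged["artifactual"].astype(int), merged["flagged"].astype(int)
        )
        m = compute_metrics(c)
        rows.append(
            {"Threshold": t, "Accuracy": m.accuracy,
             "Precision": m.precision, "Recall": m.recall}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WorkloadEstimate:
    """Expected inspection workload after automated flagging."""

    n_total: int
    n_artifactual: int
    precision: float
    recall: float
    expected_flagged: float
    reduction_percent: float  # rounded to 2 decimals for display


def estimate_inspection_reduction(
    n_total: int, n_artifactual: int, precision: float, recall: float
) -> WorkloadEstimate:
    """Percent reduction in volumes an analyst must inspect.

    Of ``n_artifactual`` truly bad volumes the detector recovers
    ``recall * n_artifactual`` true positives; at the given precision the
    flagged list containing them has ``recall * n_artifactual / precision``
    entries. Inspecting only that list instead of all ``n_total`` volumes is
    a ``100 * (1 - flagged / n_total)`` percent reduction.
    """
    if not 0 < precision <= 1:
        raise ValueError("precision must lie in (0, 1]")
    if not 0 <= recall <= 1:
        raise ValueError("recall must lie in [0, 1]")
    if n_artifactual > n_total:
        raise ValueError("n_artifactual cannot exceed n_total")
    flagged = recall * n_artifactual / precision
    reduction = 100.0 * (1.0 - flagged / n_total)
    reduction = min(max(reduction, 0.0), 100.0)
    return WorkloadEstimate(
        n_total=n_total,
        n_artifactual=n_artifactual,
        precision=precision,
        recall=recall,
        expected_flagged=flagged,
        reduction_percent=round(reduction, 2),
    )
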