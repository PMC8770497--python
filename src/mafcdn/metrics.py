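"""Six-metric semantic-segmentation evaluation from per-class pixel counts.

All metrics derive from the 2x2 confusion table ``p[i][j]`` = number of
pixels of true class ``i`` predicted as class ``j`` (class 0 = background,
class 1 = MA):

* PA    — overall pixel accuracy, ``sum_i p_ii / sum_ij p_ij``;
* MPA   — mean of per-class accuracies ``p_ii / sum_j p_ij``;
* Pre   — precision ``TP / (TP + FP)`` with MA positive;
* Re    — recall ``TP / (TP + FN)``;
* F1    — ``2 Pre Re / (Pre + Re)``;
* MIoU  — mean over classes of ``p_ii / (sum_j p_ij + sum_j p_ji - p_ii)``.

Undefined ratios use a fixed convention (see :func:`compute_metrics`).
Aggregation across a test set is per-image mean +/- sample standard
deviation; a pooled mode (sum the tables, then compute) is also available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ShapeError, ValidationError
from .image_core import MaskImage

__all__ = [
    "ConfusionTable",
    "MetricsReport",
    "AggregateReport",
    "confusion",
    "compute_metrics",
    "aggregate",
    "pooled_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = ("PA", "MPA", "Pre", "Re", "F1", "MIoU")


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 pixel-count table; ``p[i, j]`` = true class i predicted as class j."""

    p: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=np.int64)
        if arr.shape != (2, 2):
            raise ValidationError(f"expected a 2x2 table; got shape {arr.shape}")
        if (arr < 0).any():
            raise ValidationError("confusion counts must be nonnegative")
        object.__setattr__(self, "p", arr)

    @property
    def total(self) -> int:
        return int(self.p.sum())

    @property
    def tp(self) -> int:
        return int(self.p[1, 1])

    @property
    def fp(self) -> int:
        return int(self.p[0, 1])

    @property
    def fn(self) -> int:
        return int(self.p[1, 0])

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.p + other.p)


@dataclass(frozen=True)
class MetricsReport:
    """The six metrics for one image (or one pooled table), each in [0, 1]."""

    PA: float
    MPA: float
    Pre: float
    Re: float
    F1: float
    MIoU: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def as_percent_strings(self) -> dict[str, str]:
        """Table-style formatting: percentages at 2 decimal places."""
        return {k: f"{100.0 * v:.2f}" for k, v in self.as_dict().items()}


@dataclass(frozen=True)
class AggregateReport:
    """Per-metric mean and sample standard deviation across a set of images."""

    mean: MetricsReport
    std: MetricsReport
    n: int

    def as_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean.as_dict(), "std": self.std.as_dict()}

    def format_row(self) -> dict[str, str]:
        """One table row: ``mean +/- std`` as percentages, 2 decimals each."""
        m, s = self.mean.as_dict(), self.std.as_dict()
        return {k: f"{100 * m[k]:.2f} ± {100 * s[k]:.2f}" for k in METRIC_NAMES}


def confusion(pred: MaskImage, truth: MaskImage) -> ConfusionTable:
    """Exact per-class pixel counts; TP = p[1,1], FP = p[0,1], FN = p[1,0]."""
    if (pred.height, pred.width) != (truth.height, truth.width):
        raise ShapeError(
            f"prediction {pred.height}x{pred.width} does not match ground truth "
            f"{truth.height}x{truth.width}"
        )
    idx = truth.labels.astype(np.int64) * 2 + pred.labels.astype(np.int64)
    counts = np.bincount(idx.ravel(), minlength=4)
    return ConfusionTable(counts.reshape(2, 2))


def _safe_ratio(num: float, den: float, both_empty: bool) -> float:
    """num/den with the degenerate convention: 1 if the class is absent
    everywhere (nothing to get wrong), else 0 when the denominator is 0."""
    if den > 0:
        return num / den
    return 1.0 if both_empty else 0.0


def compute_metrics(t: ConfusionTable) -> MetricsReport:
    """Evaluate the six metrics on one confusion table.

    Degenerate-ratio convention: if ``TP + FP = 0``, precision is 1 when
    ``TP + FN = 0`` too (no MA anywhere) and 0 otherwise; symmetrically for
    recall; F1 is 0 when ``Pre + Re = 0``; a class absent from both
    prediction and truth contributes 1 to the MPA and MIoU means.
    """
    p = t.p.astype(np.float64)
    total = p.sum()
    if total <= 0:
        raise ValidationError("confusion table is empty")
    pa = np.trace(p) / total

    row = p.sum(axis=1)  # truth counts per class
    col = p.sum(axis=0)  # prediction counts per class
    class_acc = [_safe_ratio(p[i, i], row[i], row[i] == 0 and col[i] == 0) for i in (0, 1)]
    mpa = float(np.mean(class_acc))

    tp, fp, fn = t.tp, t.fp, t.fn
    pre = _safe_ratio(tp, tp + fp, tp + fn == 0)
    re = _safe_ratio(tp, tp + fn, tp + fp == 0)
    f1 = 0.0 if pre + re == 0 else 2.0 * pre * re / (pre + re)

    iou = [
        _safe_ratio(p[i, i], row[i] + col[i] - p[i, i], row[i] == 0 and col[i] == 0)
        for i in (0, 1)
    ]
    miou = float(np.mean(iou))
    return MetricsReport(PA=float(pa), MPA=mpa, Pre=float(pre), Re=float(re), F1=float(f1), MIoU=miou)


def aggregate(reports: list[MetricsReport]) -> AggregateReport:
    """Per-metric arithmetic mean and sample std (ddof=1; 0 when n=1)."""
    if not reports:
        raise ValidationError("cannot aggregate an empty list of reports")
    arr = np.array([[getattr(r, k) for k in METRIC_NAMES] for r in reports], dtype=np.float64)
    mean = arr.mean(axis=0)
    std = arr.std(axis=0, ddof=1) if len(reports) > 1 else np.zeros(len(METRIC_NAMES))
    return AggregateReport(
        mean=MetricsReport(**dict(zip(METRIC_NAMES, mean.tolist()))),
        std=MetricsReport(**dict(zip(METRIC_NAMES, std.tolist()))),
        n=len(reports),
    )


def pooled_metrics(tables: list[ConfusionTable]) -> MetricsReport:
    """Alternative aggregation: sum the tables over images, then evaluate once."""
    if not tables:
        raise ValidationError("cannot pool an empty list of tables")
    total = tables[0]
    for t in tables[1:]:
        total = total + t
    return compute_metrics(total)


def write_reports(
    per_image: dict[str, MetricsReport], agg: AggregateReport, out_dir: str | Path
) -> tuple[Path, Path]:
    """Persist per-image + aggregate metrics as JSON and CSV (full precision)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    js = {
        "per_image": {k: v.as_dict() for k, v in sorted(per_image.items())},
        "aggregate": agg.as_dict(),
    }
    json_path = out_dir / "metrics.json"
    json_path.write_text(json.dumps(js, indent=2, sort_keys=True))

    rows = [{"image": k, **v.as_dict()} for k, v in sorted(per_image.items())]
    rows.append({"image": "mean", **agg.mean.as_dict()})
    rows.append({"image": "std", **agg.std.as_dict()})
    csv_path = out_dir / "metrics.csv"
    pd.DataFrame(rows, columns=["image", *METRIC_NAMES]).to_csv(csv_path, index=False)
    return json_path, csv_path
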