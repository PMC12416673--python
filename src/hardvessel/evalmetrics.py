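"""FOV-restricted pixel-wise segmentation metrics.

Predictions are compared against the gold standard only inside the
field-of-view disc (the DRIVE convention): Se = TP/(TP+FN),
Sp = TN/(TN+FP), precision = TP/(TP+FP), F1 = 2·P·R/(P+R),
ACC = (TP+TN)/N, and the threshold-free area under the ROC curve.  Degenerate
confusion tables (an empty positive or negative class) yield NaN for the
affected ratios together with a flag, never an exception.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "f1_macro_squared",
    "roc_auc",
    "aggregate_over_dataset",
    "write_reports",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricsReport:
    se: float
    sp: float
    precision: float
    f1: float
    acc: float
    auc: float = float("nan")
    n_pixels: int = 0
    threshold: float = 0.5
    undefined: tuple[str, ...] = field(default_factory=tuple)


def _restrict(S: np.ndarray, G: np.ndarray, fov: np.ndarray | None
              ) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(S, dtype=np.float64)
    G = np.asarray(G)
    if S.shape != G.shape:
        raise ValueError(f"prediction shape {S.shape} != mask shape {G.shape}")
    if fov is None:
        return S.ravel(), G.ravel().astype(bool)
    fov = np.asarray(fov).astype(bool)
    if fov.shape != G.shape:
        raise ValueError(f"FOV shape {fov.shape} != mask shape {G.shape}")
    return S[fov], G[fov].astype(bool)


def confusion(S: np.ndarray, G: np.ndarray, fov: np.ndarray | None = None,
              threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/FP/FN/TN for prediction S ≥ threshold inside the FOV."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    s, g = _restrict(S, G, fov)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & g)),
        fp=int(np.count_nonzero(pred & ~g)),
        fn=int(np.count_nonzero(~pred & g)),
        tn=int(np.count_nonzero(~pred & ~g)),
    )


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def metrics_from_confusion(c: ConfusionCounts,
                           threshold: float = 0.5) -> MetricsReport:
    undefined: list[str] = []
    se = _ratio(c.tp, c.tp + c.fn, "se", undefined)
    sp = _ratio(c.tn, c.tn + c.fp, "sp", undefined)
    precision = _ratio(c.tp, c.tp + c.fp, "precision", undefined)
    if math.isnan(se) or math.isnan(precision) or precision + se == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * se / (precision + se)
    acc = _ratio(c.tp + c.tn, c.total, "acc", undefined)
    return MetricsReport(se=se, sp=sp, precision=precision, f1=f1, acc=acc,
                         n_pixels=c.total, threshold=threshold,
                         undefined=tuple(undefined))


def f1_macro_squared(counts: list[ConfusionCounts]) -> float:
    """Squared macro-averaged F1, ((1/n)·Σ 2·P_k·R_k/(P_k+R_k))².

    An alternative F1 aggregation (squared mean of per-image F1) that is
    kept for completeness; the default report uses the standard binary
    2PR/(P+R).
    """
    per = []
    for c in counts:
        r = metrics_from_confusion(c)
        if not math.isnan(r.f1):
            per.append(r.f1)
    if not per:
        return float("nan")
    return float(np.mean(per)) ** 2


def roc_auc(S: np.ndarray, G: np.ndarray, fov: np.ndarray | None = None
            ) -> tuple[float, np.ndarray]:
    """Trapezoidal AUC from a sweep over all distinct prediction values.

    Returns ``(auc, curve)`` with the curve as an array of (fpr, tpr) rows.
    Equivalent to the pairwise ranking probability
    P(S_pos > S_neg) + ½·P(tie).
    """
    s, g = _restrict(S, G, fov)
    n_pos = int(g.sum())
    if n_pos == 0 or n_pos == g.size:
        raise ValueError(
            "roc_auc needs at least one positive and one negative pixel "
            "inside the FOV")
    fpr, tpr, _ = roc_curve(g.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def aggregate_over_dataset(per_image: list[dict]) -> dict:
    """Pooled and per-image-mean summaries of a dataset evaluation.

    ``per_image`` entries carry at least ``counts`` (:class:`ConfusionCounts`)
    and optionally ``auc`` and ``id``.  Pooled mode sums the confusion counts
    before computing metrics; mean mode averages the per-image metrics and
    reports their standard deviation.  Both are returned.
    """
    if not per_image:
        raise ValueError("aggregate_over_dataset: no images")
    pooled_counts = ConfusionCounts()
    rows = []
    for entry in per_image:
        c = entry["counts"]
        pooled_counts = pooled_counts + c
        r = metrics_from_confusion(c)
        row = {"id": entry.get("id", ""), **asdict(r)}
        row.pop("undefined")
        if "auc" in entry:
            row["auc"] = entry["auc"]
        rows.append(row)
    pooled = metrics_from_confusion(pooled_counts)
    pooled_dict = asdict(pooled)
    pooled_dict.pop("undefined")
    aucs = [r["auc"] for r in rows if not math.isnan(r.get("auc", float("nan")))]
    if aucs:
        pooled_dict["auc"] = float(np.mean(aucs))
    mean, std = {}, {}
    for key in ("se", "sp", "precision", "f1", "acc", "auc"):
        vals = np.array([r[key] for r in rows], dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        mean[key] = float(vals.mean()) if vals.size else float("nan")
        std[key] = float(vals.std()) if vals.size else float("nan")
    return {
        "pooled": pooled_dict,
        "per_image_mean": mean,
        "per_image_std": std,
        "per_image": rows,
        "f1_macro_squared": f1_macro_squared(
            [e["counts"] for e in per_image]),
    }


def write_reports(summary: dict, out_dir) -> dict[str, Path]:
    """Write the per-image CSV and the JSON summary next to each other."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "per_image_metrics.csv"
    rows = summary["per_image"]
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    json_path = out / "summary.json"
    payload = {k: v for k, v in summary.items() if k != "per_image"}
    json_path.write_text(json.dumps(payload, indent=2))
    return {"csv": csv_path, "json": json_path}
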