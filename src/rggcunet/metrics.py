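"""Pixel-overlap evaluation: DSC, Jaccard, precision, recall.

All four scores are functions of the pixel confusion counts::

    DSC       = 2TP / (FP + 2TP + FN)
    Jaccard   =  TP / (FP +  TP + FN)
    Precision =  TP / (FP +  TP)
    Recall    =  TP / (TP + FN)

Degenerate denominators follow explicit conventions (documented on
:func:`compute_metrics`) so that evaluating an empty mask against an empty
prediction scores 1.0 across the board.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

METRIC_NAMES = ("dsc", "jaccard", "precision", "recall")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.dtype == bool:
        return a
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return a.astype(bool)


def confusion_counts(pred_mask, true_mask) -> ConfusionCounts:
    """Exhaustive per-pixel TP/FP/FN/TN tally of two binary masks."""
    p = _as_binary(pred_mask, "pred_mask")
    t = _as_binary(true_mask, "true_mask")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """DSC, Jaccard, precision and recall from confusion counts.

    Conventions for empty denominators: with ``TP = FP = FN = 0`` (both
    masks empty) every metric is 1.  An undefined precision (no predicted
    positives) is 1 when there are also no missed positives, else 0; and
    symmetrically for recall.
    """
    tp, fp, fn = c.tp, c.fp, c.fn
    if tp + fp + fn == 0:
        return dict.fromkeys(METRIC_NAMES, 1.0)
    dsc = 2 * tp / (fp + 2 * tp + fn)
    jaccard = tp / (fp + tp + fn)
    precision = tp / (fp + tp) if (fp + tp) else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else (1.0 if fp == 0 else 0.0)
    return {"dsc": dsc, "jaccard": jaccard, "precision": precision,
            "recall": recall}


def evaluate_pairs(pairs, names=None) -> dict:
    """Score a sequence of (pred_mask, true_mask) pairs.

    Returns per-image rows plus a micro-average (confusion counts pooled
    over all pixels) and a macro-average (mean of per-image scores).
    """
    rows, pooled = [], ConfusionCounts()
    for i, (pred, true) in enumerate(pairs):
        c = confusion_counts(pred, true)
        pooled = pooled + c
        name = names[i] if names is not None else f"image_{i}"
        rows.append({"name": name, **compute_metrics(c),
                     "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn})
    micro = compute_metrics(pooled)
    macro = {m: float(np.mean([r[m] for r in rows])) for m in METRIC_NAMES} \
        if rows else dict.fromkeys(METRIC_NAMES, float("nan"))
    return {"rows": rows, "micro": micro, "macro": macro, "pooled": pooled}


def write_report(report: dict, path: str | Path) -> None:
    """Write the per-image + aggregate evaluation table as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fields = ["name", *METRIC_NAMES, "tp", "fp", "fn", "tn"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for row in report["rows"]:
            w.writerow({k: row[k] for k in fields})
        p = report["pooled"]
        w.writerow({"name": "micro_average", **report["micro"],
                    "tp": p.tp, "fp": p.fp, "fn": p.fn, "tn": p.tn})
        w.writerow({"name": "macro_average", **report["macro"],
                    "tp": "", "fp": "", "fn": "", "tn": ""})
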