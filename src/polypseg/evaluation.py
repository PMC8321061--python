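"""Segmentation metrics and stratified analysis.

Per-frame metrics are the overlap measures precision, recall, Dice and
Jaccard computed from pixel confusion counts —

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    Dice      = 2 TP / (2 TP + FP + FN)
    Jaccard   = TP / (TP + FP + FN) = Dice / (2 - Dice)

— and the symmetric Hausdorff distance between the predicted and true
boundaries, ``H(G, S) = max(sup_g inf_s d(g, s), sup_s inf_g d(s, g))``,
zero when the contours coincide and unbounded otherwise (infinite when one
mask is empty; such frames are excluded from means and their count
reported).

Frames are stratified into Small/Normal/Large groups by ground-truth polyp
area and, independently, by circularity (4*pi*area/perimeter^2), using the
25th and 75th percentiles of the *training* distribution as cut points, so
validation difficulty can be read off as a function of polyp size and shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff
from skimage import measure as skmeasure


@dataclass
class MetricsRecord:
    frame_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    dice: float
    precision: float
    recall: float
    jaccard: float
    hausdorff: float
    gt_area: float
    gt_circularity: float
    size_group: str | None = None
    circularity_group: str | None = None


# ---------------------------------------------------------------------------
# Confusion counts and overlap measures


def confusion_counts(predicted: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) pixel counts for two binary masks of equal shape."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("mask shapes differ")
    p = predicted.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return tp, fp, fn, tn


def _ratio(num: float, den: float, both_empty: bool) -> float:
    # zero-denominator convention: 1 when both masks empty, 0 when one is
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def dice(counts) -> float:
    tp, fp, fn = counts[0], counts[1], counts[2]
    return _ratio(2.0 * tp, 2.0 * tp + fp + fn, fp == 0 and fn == 0)


def precision(counts) -> float:
    tp, fp, fn = counts[0], counts[1], counts[2]
    return _ratio(tp, tp + fp, fn == 0)


def recall(counts) -> float:
    tp, fp, fn = counts[0], counts[1], counts[2]
    return _ratio(tp, tp + fn, fp == 0)


def jaccard(counts) -> float:
    tp, fp, fn = counts[0], counts[1], counts[2]
    return _ratio(float(tp), float(tp + fp + fn), fp == 0 and fn == 0)


# ---------------------------------------------------------------------------
# Hausdorff distance between mask boundaries


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (or the image border)."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.empty((0, 2))
    pad = np.pad(m, 1)
    interior = (pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:])
    edge = m & ~interior
    return np.argwhere(edge).astype(float)


def hausdorff(g: np.ndarray, s: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two (N, 2) boundary point sets.

    Euclidean, in pixel units; inf when either set is empty.
    """
    g = np.asarray(g, dtype=float).reshape(-1, 2)
    s = np.asarray(s, dtype=float).reshape(-1, 2)
    if len(g) == 0 or len(s) == 0:
        return math.inf
    return float(max(directed_hausdorff(g, s)[0], directed_hausdorff(s, g)[0]))


def hausdorff_masks(predicted: np.ndarray, truth: np.ndarray) -> float:
    return hausdorff(boundary_points(predicted), boundary_points(truth))


# ---------------------------------------------------------------------------
# Circularity


def mask_circularity(mask: np.ndarray, resample_step: int = 5) -> float:
    """4*pi*area / perimeter^2 in [0, 1]; perimeter from the traced boundary.

    The perimeter is the length of the subpixel iso-contour at level 0.5,
    resampled every ``resample_step`` vertices before summing chord lengths.
    The raw staircase contour overestimates a smooth boundary's length by
    ~5% (a rasterized disc would score ~0.89); chord resampling removes that
    bias while leaving polygonal shapes essentially untouched (a square of
    side >= 100 px scores within 1% of pi/4).
    """
    m = np.asarray(mask).astype(float)
    if not m.any():
        raise ValueError("circularity of an empty mask is undefined")
    area = float(m.sum())
    perim = 0.0
    for c in skmeasure.find_contours(np.pad(m, 1), 0.5):
        idx = list(range(0, len(c), max(1, resample_step)))
        if idx[-1] != len(c) - 1:
            idx.append(len(c) - 1)
        pts = c[idx]
        perim += float(np.hypot(*np.diff(pts, axis=0).T).sum())
    if perim == 0:
        return 1.0
    return float(min(4.0 * math.pi * area / perim ** 2, 1.0))


# ---------------------------------------------------------------------------
# Per-frame record and stratification


def evaluate_frame(frame_id: str, predicted: np.ndarray, truth: np.ndarray) -> MetricsRecord:
    counts = confusion_counts(predicted, truth)
    t_any = np.asarray(truth).astype(bool).any()
    return MetricsRecord(
        frame_id=frame_id,
        tp=counts[0], fp=counts[1], fn=counts[2], tn=counts[3],
        dice=dice(counts), precision=precision(counts), recall=recall(counts),
        jaccard=jaccard(counts),
        hausdorff=hausdorff_masks(predicted, truth),
        gt_area=float(np.asarray(truth).astype(bool).sum()),
        gt_circularity=mask_circularity(truth) if t_any else float("nan"),
    )


GROUPS = ("Small", "Normal", "Large")


def _assign(value: float, q25: float, q75: float) -> str:
    if value < q25:
        return "Small"
    if value > q75:
        return "Large"
    return "Normal"


def stratify(records, train_areas, train_circularities) -> list[MetricsRecord]:
    """Assign Small/Normal/Large groups by area and circularity in place.

    Cut points are the 25th/75th percentiles (linear interpolation between
    order statistics) of the training-corpus distributions.
    """
    areas = np.asarray(list(train_areas), dtype=float)
    circs = np.asarray(list(train_circularities), dtype=float)
    if areas.size == 0 or circs.size == 0:
        raise ValueError("reference distributions must be non-empty")
    a25, a75 = np.percentile(areas, [25, 75])
    c25, c75 = np.percentile(circs, [25, 75])
    for r in records:
        r.size_group = _assign(r.gt_area, a25, a75)
        r.circularity_group = _assign(r.gt_circularity, c25, c75)
    return list(records)


# ---------------------------------------------------------------------------
# Summaries


METRIC_COLUMNS = ("dice", "precision", "recall", "jaccard", "hausdorff")


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class StratifiedSummary:
    """Per-group statistics plus the joint scatter tables."""

    group_key: str
    table: pd.DataFrame                 # (group, metric) -> median/mean/std/q25/q75
    outliers: dict[tuple[str, str], list[str]]
    excluded_hausdorff: int             # frames with infinite Hausdorff
    scatter: pd.DataFrame               # frame_id, dice, hausdorff, recall, precision, group


def summarize(records, group_key: str = "size_group") -> StratifiedSummary:
    """Per-group median/mean/std/quartiles and 1.5*IQR outliers.

    Frames with infinite Hausdorff (an empty boundary) are excluded from the
    Hausdorff statistics; their count is reported.
    """
    df = records_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    if group_key not in df.columns or df[group_key].isna().all():
        df = df.assign(**{group_key: "All"})
    rows = []
    outliers: dict[tuple[str, str], list[str]] = {}
    excluded = int(np.isinf(df["hausdorff"]).sum())
    for group, sub in df.groupby(group_key, sort=True):
        for metric in METRIC_COLUMNS:
            vals = sub[metric].replace([np.inf, -np.inf], np.nan).dropna()
            if vals.empty:
                continue
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            iqr = q75 - q25
            out_mask = (vals < q25 - 1.5 * iqr) | (vals > q75 + 1.5 * iqr)
            outliers[(str(group), metric)] = sub.loc[vals.index[out_mask], "frame_id"].tolist()
            rows.append({"group": group, "metric": metric, "n": len(vals),
                         "median": med, "mean": vals.mean(),
                         "std": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                         "q25": q25, "q75": q75,
                         "n_outliers": int(out_mask.sum())})
    table = pd.DataFrame(rows)
    scatter = df[["frame_id", "dice", "hausdorff", "recall", "precision", group_key]].copy()
    return StratifiedSummary(group_key=group_key, table=table, outliers=outliers,
                             excluded_hausdorff=excluded, scatter=scatter)


# ---------------------------------------------------------------------------
# Report plots (boxplots per group, joint scatters)


def write_report(records, out_dir, group_keys=("size_group", "circularity_group")):
    """Write per-frame CSV, per-group summary CSVs and plots; returns paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = records_frame(records)
    paths = {"frames": out_dir / "frame_metrics.csv"}
    df.to_csv(paths["frames"], index=False)
    for key in group_keys:
        summary = summarize(records, key)
        p = out_dir / f"summary_{key}.csv"
        summary.table.to_csv(p, index=False)
        paths[f"summary_{key}"] = p
        fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
        for ax, metric in zip(axes, ("dice", "precision", "recall")):
            data = [df.loc[df[key] == g, metric].dropna() for g in GROUPS
                    if (df[key] == g).any()]
            labels = [g for g in GROUPS if (df[key] == g).any()]
            if data:
                ax.boxplot(data, tick_labels=labels)
            ax.set_title(metric)
        fig.suptitle(f"Metrics by {key}")
        fig.tight_layout()
        fp = out_dir / f"boxplot_{key}.png"
        fig.savefig(fp, dpi=110)
        plt.close(fig)
        paths[f"boxplot_{key}"] = fp
    finite = df[np.isfinite(df["hausdorff"])]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter(finite["dice"], finite["hausdorff"], s=12)
    axes[0].set_xlabel("Dice")
    axes[0].set_ylabel("Hausdorff [px]")
    axes[1].scatter(df["recall"], df["precision"], s=12)
    axes[1].set_xlabel("recall")
    axes[1].set_ylabel("precision")
    fig.tight_layout()
    sp = out_dir / "scatter.png"
    fig.savefig(sp, dpi=110)
    plt.close(fig)
    paths["scatter"] = sp
    return paths
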