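"""Edge- and region-level evaluation.

Region level: the dew-area accuracy Ap, the mean over droplets of
1 - |S_MAN - S_ALM| / S_MAN (clamped to [0, 1]), where S_MAN is the
annotated area of a droplet and S_ALM the matched detected area.

Edge level: precision/recall of thresholded probability maps against
consensus ground truth with distance-tolerant one-to-one pixel matching,
summarised as the area under the PR curve (Ap of edge) and the ODS / OIS
F-measures (best F at one dataset-wide threshold vs. the mean of per-image
best F).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.spatial import cKDTree


@dataclass
class MetricsReport:
    ap_edge: float
    ap_dew_area: float
    ods: float
    ois: float
    per_droplet_errors: list[int]
    n_droplets: int


def default_thresholds(n: int = 33) -> np.ndarray:
    """n evenly spaced binarisation thresholds strictly inside (0, 1)."""
    return np.linspace(0.0, 1.0, n + 2)[1:-1]


def default_tolerance(shape: tuple[int, int], frac: float = 0.0075) -> float:
    """Edge-match tolerance: a fraction of the image diagonal (BSDS style)."""
    return frac * float(np.hypot(*shape))


def ap_dew_area(s_man: list[float], s_alm: list[float]) -> float:
    """Mean per-droplet area accuracy, clamp(1 - |S_MAN - S_ALM|/S_MAN, 0, 1).

    Unmatched (missed) ground-truth droplets enter with s_alm = 0 and score
    zero.  Raises on empty input (the mean over zero droplets is undefined).
    """
    s_man = np.asarray(s_man, dtype=np.float64)
    s_alm = np.asarray(s_alm, dtype=np.float64)
    if s_man.size == 0:
        raise ValueError("ap_dew_area is undefined for zero droplets")
    if s_man.size != s_alm.size:
        raise ValueError("s_man and s_alm must have equal length")
    if np.any(s_man <= 0):
        raise ValueError("annotated droplet areas must be positive")
    acc = np.clip(1.0 - np.abs(s_man - s_alm) / s_man, 0.0, 1.0)
    return float(acc.mean())


def match_edge_pixels(
    pred: np.ndarray, gt: np.ndarray, tol_px: float
) -> tuple[int, int, int]:
    """One-to-one matching of predicted to ground-truth edge pixels.

    A predicted pixel may match any ground-truth pixel within Euclidean
    distance ``tol_px``; the pairing is a maximum-cardinality bipartite
    matching, so the true-positive count is the largest achievable and
    each ground-truth pixel is used at most once.  Returns
    (n_true_pos, n_pred, n_gt).
    """
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth must share a shape")
    p_coords = np.argwhere(pred)
    g_coords = np.argwhere(gt)
    n_pred, n_gt = len(p_coords), len(g_coords)
    if n_pred == 0 or n_gt == 0:
        return 0, n_pred, n_gt
    tree = cKDTree(g_coords)
    neighbours = tree.query_ball_point(p_coords, r=tol_px + 1e-9)
    rows, cols = [], []
    for i, nbrs in enumerate(neighbours):
        rows.extend([i] * len(nbrs))
        cols.extend(nbrs)
    if not rows:
        return 0, n_pred, n_gt
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n_pred, n_gt)
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    tp = int((match >= 0).sum())
    return tp, n_pred, n_gt


def pr_at_threshold(
    prob: np.ndarray,
    gt_consensus: np.ndarray,
    t: float,
    eta: float = 0.5,
    tol_px: float | None = None,
) -> tuple[float, float, float]:
    """Precision, recall and F-measure of ``prob >= t`` against consensus.

    Ground-truth positives are consensus >= eta; controversial pixels
    (0 < consensus < eta) are excluded from both sides of the match, so a
    prediction there neither helps nor hurts.
    """
    tp, n_pred, n_gt = _counts_at_threshold(prob, gt_consensus, t, eta, tol_px)
    return _prf(tp, n_pred, n_gt)


def _counts_at_threshold(prob, gt_consensus, t, eta, tol_px):
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    prob = np.asarray(prob, dtype=np.float64)
    cons = np.asarray(gt_consensus, dtype=np.float64)
    if tol_px is None:
        tol_px = default_tolerance(prob.shape)
    controversial = (cons > 0) & (cons < eta)
    pred = (prob >= t) & ~controversial
    gt_pos = cons >= eta
    return match_edge_pixels(pred, gt_pos, tol_px)


def _prf(tp: int, n_pred: int, n_gt: int) -> tuple[float, float, float]:
    if n_pred == 0:
        precision = 1.0 if n_gt == 0 else 0.0
    else:
        precision = tp / n_pred
    if n_gt == 0:
        recall = 1.0
    else:
        recall = tp / n_gt
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return float(precision), float(recall), float(f)


def ods_ois(
    dataset: list[tuple[np.ndarray, np.ndarray]],
    thresholds: np.ndarray | None = None,
    eta: float = 0.5,
    tol_px: float | None = None,
) -> tuple[float, float]:
    """ODS and OIS F-measures over (probability map, consensus) pairs.

    ODS: best F over thresholds, computed from match counts pooled over
    the dataset at each threshold.  OIS: mean over images of the best
    per-image F.  On a single-image dataset the two coincide.
    """
    if not dataset:
        raise ValueError("ods_ois requires at least one image")
    if thresholds is None:
        thresholds = default_thresholds()
    n_t = len(thresholds)
    pooled = np.zeros((n_t, 3), dtype=np.int64)
    best_per_image = []
    for prob, cons in dataset:
        per_image_f = []
        for j, t in enumerate(thresholds):
            tp, n_pred, n_gt = _counts_at_threshold(prob, cons, t, eta, tol_px)
            pooled[j] += (tp, n_pred, n_gt)
            per_image_f.append(_prf(tp, n_pred, n_gt)[2])
        best_per_image.append(max(per_image_f))
    ods = max(_prf(*pooled[j])[2] for j in range(n_t))
    ois = float(np.mean(best_per_image))
    return float(ods), ois


def ap_edge(
    prob: np.ndarray,
    consensus: np.ndarray,
    eta: float = 0.5,
    tol_px: float | None = None,
    thresholds: np.ndarray | None = None,
) -> float:
    """Area under the precision-recall curve of the edge probability map.

    PR points are traced over the threshold grid, sorted by recall, and
    integrated with the trapezoidal rule after anchoring the curve at
    recall 0 with the precision of its lowest-recall point.
    """
    if thresholds is None:
        thresholds = default_thresholds()
    points = [
        pr_at_threshold(prob, consensus, t, eta, tol_px)[:2] for t in thresholds
    ]
    pr = np.array(points)  # columns: precision, recall
    order = np.argsort(pr[:, 1], kind="stable")
    precision = pr[order, 0]
    recall = pr[order, 1]
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(precision, recall))


def area_error_report(
    pairs: list[tuple[int, int]], n_bins: int = 6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-droplet area errors and an accuracy-vs-area curve.

    ``pairs`` holds (s_man, s_alm) per ground-truth droplet.  The report
    lists the signed error s_alm - s_man and the accuracy
    1 - |error| / s_man (clamped at 0); the curve bins accuracy by
    annotated area.
    """
    rows = []
    for s_man, s_alm in pairs:
        error = s_alm - s_man
        accuracy = max(1.0 - abs(error) / s_man, 0.0) if s_man > 0 else 0.0
        rows.append(
            {"s_man": s_man, "s_alm": s_alm, "error": error, "accuracy": accuracy}
        )
    report = pd.DataFrame(rows, columns=["s_man", "s_alm", "error", "accuracy"])
    if len(report):
        edges = np.linspace(
            report["s_man"].min(), report["s_man"].max() + 1, n_bins + 1
        )
        which = np.clip(
            np.digitize(report["s_man"], edges) - 1, 0, n_bins - 1
        )
        curve = (
            report.assign(bin=which)
            .groupby("bin")
            .agg(
                area_lo=("s_man", "min"),
                area_hi=("s_man", "max"),
                mean_accuracy=("accuracy", "mean"),
                n=("accuracy", "size"),
            )
            .reset_index(drop=True)
        )
    else:
        curve = pd.DataFrame(
            columns=["area_lo", "area_hi", "mean_accuracy", "n"]
        )
    return report, curve
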