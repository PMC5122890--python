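"""Knee-point selection on Pareto fronts and reconstruction scoring.

Selection pipeline: prune the high-error tail of the front, normalize both
objectives by their front maxima, smooth the curve with a B-spline and
resample it evenly along arc length, locate the knee by the four-angle
criterion, then map the knee back to the nearest original front member.

The four-angle criterion assigns to every interior resampled point the
largest of the four vertex angles formed with its two left and two right
neighbors (pairs (L1,R1), (L1,R2), (L2,R1), (L2,R2)).  On a locally straight
stretch of the curve all four angles equal pi; the sharper the bend at a
point, the smaller they get, so the knee — the bend where improving one
objective starts to cost the other dearly — is the point whose assigned
angle is furthest below pi.  Taking the max over four neighbor pairs makes
the sharpness estimate robust to single-point wobble in the resampled front.

Scoring covers the weighted reconstruction error RE, thresholded
classification rates (TPR/FPR/Precision) and threshold-free ranking areas
(AUROC/AUPR) over all unordered node pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splev, splprep
from sklearn.metrics import average_precision_score, roc_auc_score

from .moea_core import ParetoFront

__all__ = [
    "KneeSelection",
    "MetricsReport",
    "prune_front",
    "normalize_front",
    "smooth_and_resample",
    "knee_point",
    "map_back",
    "select_knee",
    "reconstruction_error",
    "local_reconstruction_error",
    "confusion_rates",
    "auroc",
    "aupr",
    "pair_scores",
    "evaluate_matrices",
]

logger = logging.getLogger(__name__)


@dataclass
class KneeSelection:
    """Outcome of knee detection on one front.

    ``chosen`` indexes into ``front`` (the pruned, surviving front);
    ``angles`` holds the per-resampled-point assigned angle (NaN at
    boundary points excluded from candidacy).
    """

    front: ParetoFront
    chosen: int
    angles: np.ndarray
    pruned: np.ndarray
    normalization: tuple[float, float]

    @property
    def solution(self):
        return self.front.solutions[self.chosen]


@dataclass
class MetricsReport:
    re: float
    tpr: float
    fpr: float
    precision: float
    auroc: float
    aupr: float
    threshold: float

    def to_dict(self) -> dict[str, float]:
        return {
            "TPR": self.tpr,
            "FPR": self.fpr,
            "Precision": self.precision,
            "RE": self.re,
            "AUROC": self.auroc,
            "AUPR": self.aupr,
        }


# ---------------------------------------------------------------------------
# knee detection


def _prune_indices(objectives: np.ndarray, k: int) -> np.ndarray:
    """Indices to *remove*: the min(k, size-1) members with largest f1."""
    n = objectives.shape[0]
    n_drop = min(max(k, 0), n - 1)
    if n_drop == 0:
        return np.empty(0, dtype=int)
    order = np.argsort(-objectives[:, 0], kind="stable")
    return np.sort(order[:n_drop])


def prune_front(front: ParetoFront, k: int = 10) -> ParetoFront:
    """Drop the k highest-error members; the front never empties.

    High-f1 solutions are overly sparse near-zero vectors whose angles can
    masquerade as knees; full recovery lives where the error term is small.
    """
    if len(front) == 0:
        raise ValueError("front must be nonempty")
    drop = set(_prune_indices(front.objectives, k).tolist())
    survivors = [s for i, s in enumerate(front.solutions) if i not in drop]
    return ParetoFront(solutions=survivors)


def normalize_front(front) -> np.ndarray:
    """Scale each objective by its maximum over the front into [0, 1].

    The two objectives usually live on very different scales, which would
    otherwise distort every angle.  A degenerate axis (max 0) passes through
    unscaled.
    """
    F = front.objectives if isinstance(front, ParetoFront) else np.asarray(front, dtype=float)
    if F.shape[0] == 0:
        raise ValueError("front must be nonempty")
    maxes = F.max(axis=0)
    scale = maxes.copy()
    for k in range(scale.size):
        if scale[k] <= 0:
            logger.warning("degenerate objective axis %d (max <= 0); left unscaled", k)
            scale[k] = 1.0
    return F / scale


def smooth_and_resample(points: np.ndarray, n_samples: int = 100,
                        spline_degree: int = 3, smoothing: float = 0.0) -> np.ndarray:
    """Fit a B-spline through the f1-sorted points and resample it at
    ``n_samples`` arc-length-uniform locations.

    Fewer points than ``spline_degree + 1`` reduce the degree to fit; the
    curve is kept monotone decreasing by sorting on f1 and dropping any f2
    violations before fitting.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    keep = [0]
    for i in range(1, pts.shape[0]):
        if pts[i, 1] < pts[keep[-1], 1] and pts[i, 0] > pts[keep[-1], 0]:
            keep.append(i)
    pts = pts[keep]
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 distinct points to resample")
    k = int(min(spline_degree, pts.shape[0] - 1))
    tck, _ = splprep([pts[:, 0], pts[:, 1]], s=smoothing, k=k)
    u_dense = np.linspace(0.0, 1.0, max(20 * n_samples, 1000))
    xd, yd = splev(u_dense, tck)
    seg = np.hypot(np.diff(xd), np.diff(yd))
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arclen[-1], n_samples)
    u_even = np.interp(targets, arclen, u_dense)
    xs, ys = splev(u_even, tck)
    return np.column_stack([xs, ys])


def _assigned_angles(points: np.ndarray, step: int | None = None) -> np.ndarray:
    """Per-point assigned angle: max of the four vertex angles with the two
    left and two right neighbors; NaN where a side lacks two neighbors.

    Neighbors sit ``step`` and ``2 * step`` resampled points away on each
    side; by default ``step`` is 5% of the curve so that the angle probes a
    fixed arc fraction and a spline-rounded corner still reads as a bend no
    matter how densely the curve was resampled.
    """
    Q = np.asarray(points, dtype=float)
    n = Q.shape[0]
    if step is None:
        step = max(1, n // 20)
    angles = np.full(n, np.nan)
    for i in range(2 * step, n - 2 * step):
        best = 0.0
        for dl in (step, 2 * step):
            for dr in (step, 2 * step):
                va = Q[i - dl] - Q[i]
                vb = Q[i + dr] - Q[i]
                na, nb = np.linalg.norm(va), np.linalg.norm(vb)
                if na == 0 or nb == 0:
                    continue
                cosang = np.clip(va @ vb / (na * nb), -1.0, 1.0)
                best = max(best, float(np.arccos(cosang)))
        angles[i] = best
    return angles


def knee_point(resampled: np.ndarray, step: int | None = None) -> tuple[int, np.ndarray]:
    """Locate the knee on a resampled front: the interior point whose
    assigned angle drops furthest below pi (the sharpest bend).

    Ties (a perfectly straight front has every assigned angle equal to pi)
    resolve to the smallest-f1 point.  Boundary points, with fewer than two
    neighbors on a side, are excluded from candidacy.
    """
    Q = np.asarray(resampled, dtype=float)
    if Q.shape[0] < 5:
        raise ValueError("knee detection needs at least 5 resampled points")
    angles = _assigned_angles(Q, step=step)
    valid = ~np.isnan(angles)
    min_angle = np.min(angles[valid])
    candidates = np.flatnonzero(valid & (angles <= min_angle + 1e-9))
    # points are sorted by ascending f1, so the first candidate has smallest f1
    return int(candidates[0]), angles


def map_back(resampled: np.ndarray, knee_idx: int, normalized_points: np.ndarray) -> int:
    """Original front member closest (Euclidean, normalized space) to the knee."""
    d = np.linalg.norm(normalized_points - resampled[knee_idx], axis=1)
    return int(np.argmin(d))


def select_knee(front: ParetoFront, prune_k: int = 10, n_samples: int = 100,
                spline_degree: int = 3, smoothing: float = 0.005,
                min_turn: float = 0.35) -> KneeSelection:
    """Full selection pipeline: prune, normalize, smooth/resample, four-angle
    knee detection, map back to a surviving front member.

    ``min_turn`` (radians) is the sharpness gate: an interior bend counts as
    a knee only if its assigned angle drops at least that far below pi.  On
    fronts whose normalized curvature is weak — typical when the evolved
    front terminates at the noise floor instead of bending there — every
    interior angle stays near pi and the selection degenerates, per the
    straight-front tie-break, to the smallest-f1 (lowest measurement error)
    member.  Degenerate fronts (fewer than 2 survivors, or too few distinct
    points to fit a curve) fall back the same way.
    """
    if len(front) == 0:
        raise ValueError("front must be nonempty")
    pruned_idx = _prune_indices(front.objectives, prune_k)
    survivors = prune_front(front, prune_k)
    P = normalize_front(survivors)
    maxes = front.objectives[np.setdiff1d(np.arange(len(front)), pruned_idx)].max(axis=0) \
        if len(survivors) else (0.0, 0.0)
    fallback = KneeSelection(
        front=survivors,
        chosen=int(np.argmin(survivors.objectives[:, 0])),
        angles=np.empty(0),
        pruned=pruned_idx,
        normalization=(float(maxes[0]), float(maxes[1])),
    )
    if len(survivors) < 2:
        logger.warning("front too small for knee detection; choosing smallest-f1 member")
        return fallback
    try:
        resampled = smooth_and_resample(P, n_samples=n_samples, spline_degree=spline_degree,
                                        smoothing=smoothing)
        knee_idx, angles = knee_point(resampled)
    except ValueError:
        logger.warning("knee detection degenerate; choosing smallest-f1 member")
        return fallback
    if np.pi - angles[knee_idx] < min_turn:
        # no sharp bend anywhere: straight-front tie-break, smallest f1
        fallback.angles = angles
        return fallback
    chosen = map_back(resampled, knee_idx, P)
    return KneeSelection(front=survivors, chosen=chosen, angles=angles,
                         pruned=pruned_idx,
                         normalization=(float(maxes[0]), float(maxes[1])))


# ---------------------------------------------------------------------------
# reconstruction metrics


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def reconstruction_error(X_est: np.ndarray, X_true: np.ndarray) -> float:
    """RE = sum_{i != j} |xhat_ij - x_ij| / sum_{i != j} x_ij.

    Zero exactly at perfect weighted recovery; an all-zero estimate of a
    nonempty network scores 1.
    """
    X_est = np.asarray(X_est, dtype=float)
    X_true = np.asarray(X_true, dtype=float)
    if X_est.shape != X_true.shape:
        raise ValueError("estimate and truth must have the same shape")
    mask = _offdiag_mask(X_true.shape[0])
    denom = X_true[mask].sum()
    if denom == 0:
        raise ValueError("reconstruction error undefined for an all-zero truth")
    return float(np.abs(X_est - X_true)[mask].sum() / denom)


def local_reconstruction_error(x_est: np.ndarray, x_true: np.ndarray) -> float:
    """Per-node RE over one neighbor-weight vector (same normalization)."""
    x_est = np.asarray(x_est, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    denom = x_true.sum()
    if denom == 0:
        raise ValueError("local reconstruction error undefined for an all-zero truth row")
    return float(np.abs(x_est - x_true).sum() / denom)


def confusion_rates(X_est: np.ndarray, X_true: np.ndarray,
                    threshold: float = 0.5) -> tuple[float, float, float]:
    """(TPR, FPR, Precision) after binarizing at ``threshold``.

    An unordered pair i < j counts as a predicted edge iff xhat_ij >=
    threshold; true weights are 0 or >= 1, so the default 0.5 is the
    maximum-margin cut.  Precision is 1 when nothing is predicted.
    """
    X_est = np.asarray(X_est, dtype=float)
    X_true = np.asarray(X_true, dtype=float)
    if X_est.shape != X_true.shape:
        raise ValueError("estimate and truth must have the same shape")
    iu = np.triu_indices(X_true.shape[0], k=1)
    pred = X_est[iu] >= threshold
    actual = X_true[iu] > 0
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    fn = int(np.sum(~pred & actual))
    tn = int(np.sum(~pred & ~actual))
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return tpr, fpr, precision


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic, tie-corrected)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (average-precision convention)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUPR undefined: labels contain a single class")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def pair_scores(X_est: np.ndarray, X_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (scores, labels) over all unordered node pairs for AUROC/AUPR."""
    iu = np.triu_indices(np.asarray(X_true).shape[0], k=1)
    return np.asarray(X_est, dtype=float)[iu], (np.asarray(X_true, dtype=float)[iu] > 0).astype(int)


def evaluate_matrices(X_est: np.ndarray, X_true: np.ndarray,
                      threshold: float = 0.5) -> MetricsReport:
    """All six metrics of a whole-network estimate against the truth."""
    tpr, fpr, precision = confusion_rates(X_est, X_true, threshold)
    scores, labels = pair_scores(X_est, X_true)
    return MetricsReport(
        re=reconstruction_error(X_est, X_true),
        tpr=tpr,
        fpr=fpr,
        precision=precision,
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        threshold=threshold,
    )
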