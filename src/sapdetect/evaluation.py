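"""Agreement statistics between detector output and human rater panels.

Human raters score each second of video 0/1 for stretch-attend posture; a
majority-vote consensus serves as ground truth.  The detector's per-second
flags are compared with the consensus through a 2x2 confusion matrix, from
which accuracy, sensitivity and specificity (with Wald binomial intervals),
the F-score and the Matthews correlation coefficient (MCC) follow.  MCC is
the headline measure because SAP seconds are rare relative to non-SAP
seconds, which inflates accuracy and makes the F-score precision-heavy.

Threshold selection is supported by scanning an (eccentricity, speed)
threshold grid: each pair is re-gated against the consensus, giving an MCC
surface and an ROC point cloud with trapezoidal AUC.  Inter-rater
reliability of the panel itself is the two-way, absolute-agreement,
average-measures intraclass correlation ICC(A,k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .posture import DetectionParams, FrameTrack, frames_to_seconds, gate_frames

__all__ = [
    "ConfusionCounts",
    "BasicMetrics",
    "BinomialCI",
    "RocCurve",
    "ThresholdScan",
    "IccResult",
    "consensus",
    "counts_from_rates",
    "confusion",
    "basic_metrics",
    "wald_ci",
    "f_score",
    "mcc",
    "auc_trapezoid",
    "roc_over_grid",
    "optimize_thresholds",
    "icc_two_way_average",
]


def _validate_panel(scores: np.ndarray, binary: bool = True) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 1 or scores.shape[1] < 1:
        raise ValueError("panel must be a non-empty 2-D (raters x seconds) array")
    if np.isnan(scores).any():
        raise ValueError("panel contains missing values")
    if binary and not np.isin(scores, (0, 1)).all():
        raise ValueError("panel entries must be 0 or 1")
    return scores


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 agreement counts against a binary ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def positives(self) -> int:
        """Seconds the ground truth calls SAP (P = tp + fn)."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Seconds the ground truth calls non-SAP (N = fp + tn)."""
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class BasicMetrics:
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class BinomialCI:
    """Wald (normal-approximation) binomial proportion interval, clamped to [0, 1]."""

    estimate: float
    lower: float
    upper: float
    level: float
    n: int


@dataclass(frozen=True)
class RocCurve:
    """(fpr, tpr) points with their threshold pairs and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    threshold_pairs: tuple
    auc: float


@dataclass(frozen=True)
class ThresholdScan:
    """MCC / sensitivity / specificity over an (eccentricity, speed) grid."""

    ecc_grid: np.ndarray
    speed_grid: np.ndarray
    mcc: np.ndarray  # (n_ecc, n_speed)
    tpr: np.ndarray
    fpr: np.ndarray
    roc: RocCurve


@dataclass(frozen=True)
class IccResult:
    icc: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def counts_from_rates(
    positives: int, negatives: int, sensitivity: float, specificity: float
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from class totals and rates.

    Useful for re-deriving a full 2x2 table from a report that prints only
    P, N, sensitivity and specificity; tp and tn are rounded to the
    nearest integer.
    """
    tp = round(positives * sensitivity)
    tn = round(negatives * specificity)
    return ConfusionCounts(tp=tp, fp=negatives - tn, fn=positives - tp, tn=tn)


def consensus(panel: np.ndarray) -> np.ndarray:
    """Majority-vote consensus across raters, per second.

    A second is scored 1 iff strictly more than half the raters scored 1;
    with an even rater count an exact tie resolves to 0 (conservative with
    respect to calling SAP).
    """
    scores = _validate_panel(panel)
    r = scores.shape[0]
    return (2 * scores.sum(axis=0) > r).astype(np.int8)


def confusion(pred, truth) -> ConfusionCounts:
    """Count tp/fp/fn/tn between two equal-length binary score vectors."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("unequal score lengths")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
    )


def basic_metrics(c: ConfusionCounts) -> BasicMetrics:
    """Accuracy, sensitivity (recall on P) and specificity (recall on N).

    A class with zero ground-truth members leaves its rate undefined (NaN).
    """
    p, n = c.positives, c.negatives
    accuracy = (c.tp + c.tn) / (p + n) if p + n else float("nan")
    sensitivity = c.tp / p if p else float("nan")
    specificity = c.tn / n if n else float("nan")
    return BasicMetrics(accuracy=accuracy, sensitivity=sensitivity, specificity=specificity)


def wald_ci(successes: int, n: int, level: float = 0.95) -> BinomialCI:
    """Wald binomial interval ``p +- z * sqrt(p(1-p)/n)``, clamped to [0, 1].

    Appropriate when n is large (> 30) and p is not near 0 or 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    p = successes / n
    z = stats.norm.ppf((1 + level) / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return BinomialCI(
        estimate=p,
        lower=float(max(0.0, p - half)),
        upper=float(min(1.0, p + half)),
        level=level,
        n=n,
    )


def f_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall (F1)."""
    if c.tp + c.fp == 0 or c.positives == 0:
        warnings.warn("F-score undefined (no predicted or true positives); returning 0")
        return 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / c.positives
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    A zero factor in the denominator (a degenerate margin) is treated as
    no correlation and returns 0.
    """
    tp, fp, fn, tn = (float(x) for x in (c.tp, c.fp, c.fn, c.tn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def auc_trapezoid(points: Sequence[tuple]) -> float:
    """Trapezoidal area under a (fpr, tpr) curve.

    Points must be sorted by fpr (non-decreasing) and include the (0, 0)
    and (1, 1) anchors.
    """
    pts = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least the two anchor points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(x) < 0):
        raise ValueError("points must be sorted by fpr")
    if not (x[0] == 0 and y[0] == 0 and x[-1] == 1 and y[-1] == 1):
        raise ValueError("curve must include the (0,0) and (1,1) anchors")
    return float(np.sum(np.diff(x) * (y[:-1] + y[1:]) / 2.0))


def roc_over_grid(
    tracks: Sequence[FrameTrack],
    truths: Sequence[np.ndarray],
    ecc_grid,
    speed_grid,
    fps: float,
) -> ThresholdScan:
    """Re-gate frame traces at every (eccentricity, speed) threshold pair.

    For each grid pair the full SAP gate (eccentricity, speed veto, bout
    filter, second aggregation) is applied to every track and compared
    with the per-second ground truth, recording sensitivity, 1-specificity
    and MCC.  The pooled (fpr, tpr) points, with (0,0) and (1,1) anchors
    appended and sorted by fpr then tpr, form the ROC whose AUC is the
    trapezoidal sum.
    """
    ecc_grid = np.asarray(list(ecc_grid), dtype=float)
    speed_grid = np.asarray(list(speed_grid), dtype=float)
    if ecc_grid.size == 0 or speed_grid.size == 0:
        raise ValueError("threshold grids must be non-empty")
    if len(tracks) != len(truths):
        raise ValueError("one truth vector is required per track")
    truths = [np.asarray(t, dtype=int) for t in truths]

    mcc_surface = np.zeros((len(ecc_grid), len(speed_grid)))
    tpr_surface = np.zeros_like(mcc_surface)
    fpr_surface = np.zeros_like(mcc_surface)
    points = []
    for i, e in enumerate(ecc_grid):
        for j, s in enumerate(speed_grid):
            params = DetectionParams(ecc_threshold=e, speed_threshold_cms=s, fps=fps)
            preds = []
            for track, truth in zip(tracks, truths):
                flags = gate_frames(track.eccentricity, track.speed_cms, track.valid, params)
                sec = frames_to_seconds(flags, fps)
                if len(sec) != len(truth):
                    raise ValueError(
                        f"track yields {len(sec)} seconds but truth has {len(truth)}"
                    )
                preds.append(sec)
            c = confusion(np.concatenate(preds), np.concatenate(truths))
            m = basic_metrics(c)
            tpr_surface[i, j] = m.sensitivity
            fpr_surface[i, j] = 1.0 - m.specificity
            mcc_surface[i, j] = mcc(c)
            points.append((fpr_surface[i, j], tpr_surface[i, j], (e, s)))

    points.append((0.0, 0.0, None))
    points.append((1.0, 1.0, None))
    points.sort(key=lambda p: (p[0], p[1]))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    roc = RocCurve(
        fpr=fpr,
        tpr=tpr,
        threshold_pairs=tuple(p[2] for p in points),
        auc=auc_trapezoid(list(zip(fpr, tpr))),
    )
    return ThresholdScan(
        ecc_grid=ecc_grid,
        speed_grid=speed_grid,
        mcc=mcc_surface,
        tpr=tpr_surface,
        fpr=fpr_surface,
        roc=roc,
    )


def optimize_thresholds(scan: ThresholdScan) -> tuple[float, float]:
    """Threshold pair maximising MCC over the scanned grid.

    Ties are broken towards the higher eccentricity threshold, then the
    higher speed threshold (prefer specificity), deterministically.
    """
    surface = scan.mcc
    if surface.size == 0 or np.isnan(surface).all():
        raise ValueError("MCC surface is empty or undefined everywhere")
    best = np.nanmax(surface)
    ties = np.argwhere(surface == best)
    # highest ecc index, then highest speed index
    i, j = max(ties, key=lambda ij: (scan.ecc_grid[ij[0]], scan.speed_grid[ij[1]]))
    return float(scan.ecc_grid[i]), float(scan.speed_grid[j])


def icc_two_way_average(panel: np.ndarray) -> IccResult:
    """Two-way, absolute-agreement, average-measures intraclass correlation.

    This is ICC(A,k) in the McGraw & Wong taxonomy (ICC2k): subjects
    (seconds) and raters are both random effects, agreement is absolute,
    and the reliability refers to the mean of the k raters.  With mean
    squares from the two-way layout — MSR between subjects, MSC between
    raters, MSE residual, n subjects —

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    Binary scores are treated as numeric, as is conventional when rating
    panels are analysed with a continuous-model ICC.
    """
    scores = _validate_panel(panel, binary=False)
    r, s = scores.shape
    if r < 2 or s < 2:
        raise ValueError("need at least 2 raters and 2 subjects")
    grand = scores.mean()
    subj_means = scores.mean(axis=0)
    rater_means = scores.mean(axis=1)
    msr = r * np.sum((subj_means - grand) ** 2) / (s - 1)
    msc = s * np.sum((rater_means - grand) ** 2) / (r - 1)
    resid = scores - subj_means[None, :] - rater_means[:, None] + grand
    mse = np.sum(resid**2) / ((r - 1) * (s - 1))
    denom = msr + (msc - mse) / s
    if denom == 0:
        if msr == 0 and mse == 0:
            # all-constant panel: agreement is vacuous
            return IccResult(icc=float("nan"), n_subjects=s, n_raters=r, degenerate=True)
        return IccResult(icc=float("nan"), n_subjects=s, n_raters=r, degenerate=True)
    return IccResult(icc=float((msr - mse) / denom), n_subjects=s, n_raters=r)
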