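"""Evaluation statistics for the anomaly-detection pipeline.

Classification: ROC AUC, precision-recall AUC, confusion-matrix metrics,
Cohen's kappa, exam-level percentile-bootstrap confidence intervals and
DeLong's paired test for correlated AUCs. Segmentation: Dice similarity
coefficient and normalised surface Dice with an anisotropic-spacing
distance tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import norm
from sklearn.metrics import average_precision_score, cohen_kappa_score, roc_auc_score

__all__ = [
    "MetricReport",
    "SegScore",
    "roc_auc",
    "pr_auc",
    "confusion_counts",
    "confusion_metrics",
    "cohens_kappa",
    "bootstrap_ci",
    "delong_test",
    "dice",
    "nsd",
    "classification_report",
]


@dataclass
class MetricReport:
    """Point estimates with percentile-bootstrap confidence intervals."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    n: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "n": self.n,
        }
        for k, (lo, hi) in self.ci.items():
            out[f"{k}_ci"] = [lo, hi]
        return out


@dataclass
class SegScore:
    dsc: float
    nsd: float
    tolerance_mm: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney concordance)."""
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise ValueError("ROC AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (average-precision summation)."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise ValueError("PR AUC undefined without positives")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def confusion_counts(pred: Sequence[int], labels: Sequence[int]) -> dict[str, int]:
    pred, labels = _check_binary(pred), _check_binary(labels)
    return {
        "tp": int(((pred == 1) & (labels == 1)).sum()),
        "fn": int(((pred == 0) & (labels == 1)).sum()),
        "fp": int(((pred == 1) & (labels == 0)).sum()),
        "tn": int(((pred == 0) & (labels == 0)).sum()),
    }


def confusion_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1 at a decision threshold.

    ``score >= threshold`` is positive. F1 = 2TP/(2TP+FP+FN), defined as 0
    when the denominator is 0; sensitivity/specificity are NaN when their
    class is absent.
    """
    labels = _check_binary(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    c = confusion_counts(pred, labels)
    tp, fn, fp, tn = c["tp"], c["fn"], c["fp"], c["tn"]
    n = tp + fn + fp + tn
    return {
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
    }


def cohens_kappa(ratings_a: Sequence[int], ratings_b: Sequence[int]) -> float:
    """Chance-corrected agreement between two binary raters.

    Returns 1.0 in the degenerate all-agree single-class case where the
    chance term saturates.
    """
    a, b = _check_binary(ratings_a), _check_binary(ratings_b)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    p_o = float((a == b).mean())
    p_e = float(a.mean() * b.mean() + (1 - a.mean()) * (1 - b.mean()))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float(cohen_kappa_score(a, b))


def bootstrap_ci(
    statistic_fn: Callable[[np.ndarray], float],
    data: Sequence,
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of exam-level data.

    Resamples ``data`` rows with replacement ``B`` times and returns the
    ``alpha/2`` and ``1-alpha/2`` percentiles. Resamples on which the
    statistic is undefined (raises or returns NaN) are redrawn so exactly
    ``B`` values enter the percentiles; the redraw count is tracked on the
    function attribute ``bootstrap_ci.last_redraws``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    data = np.asarray(data)
    rng = np.random.default_rng(seed)
    n = len(data)
    stats = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                v = statistic_fn(data[idx])
            except ValueError:
                v = float("nan")
            if np.isfinite(v):
                stats[b] = v
                break
            redraws += 1
            if redraws > 100 * B:
                raise RuntimeError("statistic undefined on almost all resamples")
    bootstrap_ci.last_redraws = redraws
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _midrank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def delong_test(
    scores_model1: Sequence[float],
    scores_model2: Sequence[float],
    labels: Sequence[int],
) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated ROC AUCs on paired scores.

    Uses the structural components (placement values) of each model's AUC to
    estimate the variance of the paired AUC difference; returns
    ``(auc1, auc2, z, p)`` with a two-sided normal p-value. A degenerate
    zero-variance difference with equal AUCs yields p = 1.
    """
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise ValueError("DeLong test undefined with a single class")
    scores = np.vstack(
        [np.asarray(scores_model1, float), np.asarray(scores_model2, float)]
    )
    pos = scores[:, labels == 1]
    neg = scores[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    aucs = np.empty(2)
    v_pos = np.empty((2, m))
    v_neg = np.empty((2, n))
    for k in range(2):
        all_ranks = _midrank(np.concatenate([pos[k], neg[k]]))
        pos_ranks = _midrank(pos[k])
        neg_ranks = _midrank(neg[k])
        aucs[k] = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
        # placement of each positive among negatives, and vice versa
        v_pos[k] = (all_ranks[:m] - pos_ranks) / n
        v_neg[k] = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s_pos = np.cov(v_pos)
    s_neg = np.cov(v_neg)
    var = (s_pos[0, 0] + s_pos[1, 1] - 2 * s_pos[0, 1]) / m + (
        s_neg[0, 0] + s_neg[1, 1] - 2 * s_neg[0, 1]
    ) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0 if diff == 0 else float("inf") * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = 2 * norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(z), float(p)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); both empty -> 1.0."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _boundary(mask: np.ndarray) -> np.ndarray:
    # face-connected boundary; voxels on the array edge count as boundary
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(mask.ndim, 1), border_value=0
    )
    return mask & ~eroded


def nsd(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    tolerance_mm: float = 1.0,
    spacing_mm: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """Normalised surface Dice at a distance tolerance.

    The fraction of boundary voxels of each mask lying within
    ``tolerance_mm`` of the other mask's boundary, symmetrised:
    ``(|S_a near S_b| + |S_b near S_a|) / (|S_a| + |S_b|)``. Distances use
    an exact Euclidean distance transform with anisotropic voxel spacing.
    Both masks empty -> 1.0; exactly one empty -> 0.0.
    """
    if tolerance_mm < 0:
        raise ValueError("tolerance must be >= 0")
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() and not b.any():
        return 1.0
    if not a.any() or not b.any():
        return 0.0
    sa, sb = _boundary(a), _boundary(b)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing_mm)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing_mm)
    close_a = (dist_to_b[sa] <= tolerance_mm).sum()
    close_b = (dist_to_a[sb] <= tolerance_mm).sum()
    return float((close_a + close_b) / (sa.sum() + sb.sum()))


def seg_scores(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    tolerance_mm: float = 1.0,
    spacing_mm: Sequence[float] = (1.0, 1.0, 1.0),
) -> SegScore:
    return SegScore(
        dsc=dice(mask_a, mask_b),
        nsd=nsd(mask_a, mask_b, tolerance_mm, spacing_mm),
        tolerance_mm=tolerance_mm,
    )


def classification_report(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    B: int = 1000,
    seed: int | None = None,
) -> MetricReport:
    """Point metrics at a threshold with 1000-resample percentile CIs."""
    scores = np.asarray(scores, float)
    labels = _check_binary(labels)
    point = confusion_metrics(scores, labels, threshold)
    auc = roc_auc(scores, labels)
    data = np.column_stack([scores, labels])

    def stat(name: str) -> Callable[[np.ndarray], float]:
        if name == "auc":
            return lambda d: roc_auc(d[:, 0], d[:, 1].astype(int))
        return lambda d: confusion_metrics(d[:, 0], d[:, 1].astype(int), threshold)[name]

    ci = {}
    rng = np.random.default_rng(seed)
    for name in ("auc", "accuracy", "sensitivity", "specificity", "f1"):
        ci[name] = bootstrap_ci(
            stat(name), data, B=B, seed=int(rng.integers(2**31))
        )
    return MetricReport(
        auc=auc,
        accuracy=point["accuracy"],
        sensitivity=point["sensitivity"],
        specificity=point["specificity"],
        f1=point["f1"],
        n=len(labels),
        ci=ci,
    )
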