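"""Training and inference protocol around the slice-bag classifier.

Patient-grouped 5-fold cross-validation (all exams of a patient share a
fold, so no identity leaks between training and validation), per-fold
selection of the epoch with the highest validation AUC, a 5-model
ensemble whose category probabilities are averaged at inference, and a
decision threshold set to the median of the per-fold thresholds that
maximise validation F1. Also implements the dataset-size / label-source
experiment: train the full protocol on increasing numbers of exams with
either report-derived (noisy) or reference (clean) labels and compare
held-out AUCs with DeLong's paired test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import bootstrap_ci, delong_test, roc_auc
from .mil import MILBagClassifier

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "EnsembleModel",
    "make_folds",
    "train_fold",
    "best_f1_threshold",
    "select_threshold",
    "train_ensemble",
    "ensemble_predict",
    "run_scaling_experiment",
]


class SplitError(ValueError):
    pass


@dataclass
class FoldSplit:
    k: int
    assignments: dict[str, int]  # patient_id -> fold
    seed: int

    def fold_of(self, patient_id: str) -> int:
        return self.assignments[patient_id]


@dataclass
class TrainConfig:
    """Optimisation settings: AdamW, cosine annealing, 12 epochs by default."""

    epochs: int = 12
    lr: float = 2.3e-4
    weight_decay: float = 1e-2
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class EnsembleModel:
    fold_models: list[MILBagClassifier]
    threshold: float
    organ: str = ""
    fold_thresholds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def make_folds(
    patient_of_exam: Mapping[str, str], k: int = 5, seed: int = 0
) -> FoldSplit:
    """Assign patients (not exams) to k folds of near-equal patient counts."""
    patients = sorted(set(patient_of_exam.values()))
    if len(patients) < k:
        raise SplitError(f"need at least {k} distinct patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    assignments: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            assignments[patients[idx]] = fold
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def train_fold(
    train_X: Sequence,
    train_y: np.ndarray,
    val_X: Sequence,
    val_y: np.ndarray,
    model_params: Mapping | None = None,
    train_config: TrainConfig | None = None,
) -> MILBagClassifier:
    """Fit one fold; the returned model carries the best-val-AUC epoch weights
    and a ``val_auc_trace_`` with exactly ``epochs`` entries."""
    tc = train_config or TrainConfig()
    clf = MILBagClassifier(
        **(dict(model_params) if model_params else {}),
        lr=tc.lr,
        weight_decay=tc.weight_decay,
        epochs=tc.epochs,
        batch_size=tc.batch_size,
        seed=tc.seed,
    )
    return clf.fit(train_X, train_y, X_val=val_X, y_val=val_y)


def best_f1_threshold(val_scores: Sequence[float], val_labels: Sequence[int]) -> float:
    """Threshold maximising F1 on validation scores.

    Candidates are midpoints between consecutive sorted unique scores plus
    {0, 1}; ``score >= t`` predicts positive; ties go to the smallest
    threshold.
    """
    scores = np.asarray(val_scores, dtype=float)
    labels = np.asarray(val_labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("F1 threshold undefined with single-class labels")
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    best_t, best_f1 = 0.0, -1.0
    for t in candidates:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = int((~pred & (labels == 1)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


def select_threshold(per_fold_thresholds: Sequence[float]) -> float:
    """Median of the per-fold best-F1 thresholds (mean of middle two if even)."""
    if len(per_fold_thresholds) == 0:
        raise ValueError("no thresholds to select from")
    return float(np.median(per_fold_thresholds))


def train_ensemble(
    X: Sequence,
    y: np.ndarray,
    patient_of_exam: Sequence[str],
    k: int = 5,
    seed: int = 0,
    model_params: Mapping | None = None,
    train_config: TrainConfig | None = None,
    organ: str = "",
) -> EnsembleModel:
    """Full protocol: k patient-grouped folds -> k best-epoch models ->
    median-of-best-F1 decision threshold."""
    y = np.asarray(y, dtype=int)
    if y.ndim == 1:
        y = y[:, None]
    patient_of_exam = list(patient_of_exam)
    abn = (y.max(axis=1) > 0).astype(int)
    # refold deterministically until every validation fold holds both classes
    fold_of = None
    for attempt in range(20):
        split = make_folds(
            {str(i): p for i, p in enumerate(patient_of_exam)},
            k=k,
            seed=seed + 7919 * attempt,
        )
        candidate = np.array([split.fold_of(p) for p in patient_of_exam])
        if all(
            len(np.unique(abn[candidate == fold])) == 2 for fold in range(k)
        ):
            fold_of = candidate
            break
    if fold_of is None:
        raise SplitError(
            "could not build folds with two-class validation sets; "
            "stratify or enlarge the cohort"
        )
    models, thresholds = [], []
    for fold in range(k):
        val_idx = np.where(fold_of == fold)[0]
        train_idx = np.where(fold_of != fold)[0]
        tc = train_config or TrainConfig()
        tc_fold = TrainConfig(
            epochs=tc.epochs,
            lr=tc.lr,
            weight_decay=tc.weight_decay,
            batch_size=tc.batch_size,
            seed=int(np.random.SeedSequence([tc.seed, fold]).generate_state(1)[0] % (2**31)),
        )
        clf = train_fold(
            [X[i] for i in train_idx],
            y[train_idx],
            [X[i] for i in val_idx],
            y[val_idx],
            model_params=model_params,
            train_config=tc_fold,
        )
        val_scores = clf.anomaly_score([X[i] for i in val_idx])
        val_abn = (y[val_idx].max(axis=1) > 0).astype(int)
        thresholds.append(best_f1_threshold(val_scores, val_abn))
        models.append(clf)
    return EnsembleModel(
        fold_models=models,
        threshold=select_threshold(thresholds),
        organ=organ,
        fold_thresholds=thresholds,
    )


def ensemble_predict(ensemble: EnsembleModel, X: Sequence):
    """Average category probabilities over fold models; anomaly score is the
    max averaged probability; decision is ``score >= threshold``."""
    probs = np.mean([m.predict_proba(X) for m in ensemble.fold_models], axis=0)
    scores = probs.max(axis=1)
    decisions = (scores >= ensemble.threshold).astype(int)
    return probs, scores, decisions


def run_scaling_experiment(
    train_X: Sequence,
    train_patients: Sequence[str],
    labels_by_source: Mapping[str, np.ndarray],
    test_X: Sequence,
    test_y_abnormal: Sequence[int],
    sizes: Sequence[int] = (30, 100, 200, 600, 1200),
    seeds: Sequence[int] = (0, 1, 2),
    k: int = 5,
    model_params: Mapping | None = None,
    train_config: TrainConfig | None = None,
    baseline: tuple[str, int] | None = None,
    bootstrap_B: int = 200,
    sizes_by_source: Mapping[str, Sequence[int]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Dataset-size / label-source experiment on a fixed held-out test set.

    For every (size, label source, seed) the full k-fold ensemble protocol
    is trained on a random subsample of the training pool and evaluated by
    organ-abnormal AUC (with a percentile-bootstrap CI) on the test set.
    Each arm's test scores are compared against the baseline arm (default:
    the cleanest source at the smallest size) with DeLong's paired test.
    Matched subsamples are used across label sources within a seed.
    """
    n_pool = len(train_X)
    if max(sizes) > n_pool:
        raise SplitError(
            f"training pool has {n_pool} exams; largest requested size is {max(sizes)}"
        )
    test_y = np.asarray(test_y_abnormal, dtype=int)
    sources = sorted(labels_by_source)
    if baseline is None:
        base_source = "expert" if "expert" in sources else sources[0]
        baseline = (base_source, min(sizes))
    rows = []
    scores_by_arm: dict[tuple[str, int, int], np.ndarray] = {}
    for seed in seeds:
        rng = np.random.default_rng(seed)
        subsample = rng.permutation(n_pool)
        for size in sizes:
            idx = subsample[:size]
            for source in sources:
                if sizes_by_source is not None and size not in sizes_by_source.get(
                    source, sizes
                ):
                    continue
                y = np.asarray(labels_by_source[source])[idx]
                if (y.max(axis=1) > 0).astype(int).min() == (
                    y.max(axis=1) > 0
                ).astype(int).max():
                    raise SplitError(
                        f"subsample of size {size} is single-class for {source}"
                    )
                # small subsamples can land a single-class validation fold;
                # refold deterministically until every fold is two-class
                ens = None
                for attempt in range(10):
                    try:
                        ens = train_ensemble(
                            [train_X[i] for i in idx],
                            y,
                            [train_patients[i] for i in idx],
                            k=k,
                            seed=seed * 101 + attempt,
                            model_params=model_params,
                            train_config=train_config,
                        )
                        break
                    except ValueError as err:
                        if "single-class" not in str(err):
                            raise
                if ens is None:
                    raise SplitError(
                        f"could not stratify folds for size {size} ({source})"
                    )
                _, scores, _ = ensemble_predict(ens, test_X)
                scores_by_arm[(source, size, seed)] = scores
                auc = roc_auc(scores, test_y)
                data = np.column_stack([scores, test_y])
                lo, hi = bootstrap_ci(
                    lambda d: roc_auc(d[:, 0], d[:, 1].astype(int)),
                    data,
                    B=bootstrap_B,
                    seed=seed,
                )
                rows.append(
                    {
                        "size": size,
                        "source": source,
                        "seed": seed,
                        "auc": auc,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
    table = pd.DataFrame(rows)
    comparisons = {}
    base_src, base_size = baseline
    for seed in seeds:
        base_scores = scores_by_arm[(base_src, base_size, seed)]
        for source in sources:
            for size in sizes:
                if (source, size) == (base_src, base_size) or (
                    source,
                    size,
                    seed,
                ) not in scores_by_arm:
                    continue
                a1, a2, z, p = delong_test(
                    scores_by_arm[(source, size, seed)], base_scores, test_y
                )
                comparisons[f"{source}_n{size}_vs_{base_src}_n{base_size}_seed{seed}"] = {
                    "auc": a1,
                    "auc_baseline": a2,
                    "z": z,
                    "p": p,
                }
    return table, comparisons
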