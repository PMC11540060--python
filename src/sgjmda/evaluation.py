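"""Cross-validation protocol and ranking/classification metrics.

The known positive associations are shuffled and split into n roughly
equal folds (sizes differ by at most one).  Per fold the test positives
are zeroed out of the training association matrix — so they can influence
neither the heterogeneous graph nor the positive training set — the model
is fit, and the held-out positives are scored against an equally sized set
of sampled test negatives that is disjoint from the training negatives and
from every known positive.  Six indicators are reported per fold: AUC,
AUPR, and accuracy / precision / recall / F1 at a fixed threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import RunConfig
from .matrices import AssociationMatrix
from .training import fit, predict, sample_negatives_random, sample_training_negatives

__all__ = ["FoldResult", "CVSummary", "make_folds", "compute_metrics", "cross_validate"]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("AUC", "AUPR", "ACC", "Pre", "Recall", "F1")


@dataclass
class FoldResult:
    fold: int
    seed: int
    metrics: dict[str, float]
    train_positives: np.ndarray
    test_positives: np.ndarray
    train_negatives: np.ndarray
    test_negatives: np.ndarray


@dataclass
class CVSummary:
    folds: list[FoldResult]
    mean: dict[str, float] = field(init=False)
    std: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean = {
            m: float(np.mean([f.metrics[m] for f in self.folds])) for m in METRIC_NAMES
        }
        self.std = {
            m: float(np.std([f.metrics[m] for f in self.folds])) for m in METRIC_NAMES
        }


def make_folds(A, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition the positive pairs into train/test splits.

    Positives are shuffled by ``seed`` and cut into ``n_folds`` parts whose
    sizes differ by at most one; fold i uses part i as test positives and
    the rest as training positives.  Returns ``[(train_pos, test_pos), ...]``
    with (n, 2) index arrays.
    """
    A_vals = A.values if isinstance(A, AssociationMatrix) else np.asarray(A, float)
    positives = np.argwhere(A_vals == 1.0)
    if n_folds < 2 or n_folds > len(positives):
        raise ValueError(
            f"n_folds must be in [2, {len(positives)}], got {n_folds}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    parts = np.array_split(order, n_folds)
    folds = []
    for i in range(n_folds):
        test_idx = parts[i]
        train_idx = np.concatenate([parts[j] for j in range(n_folds) if j != i])
        folds.append((positives[np.sort(train_idx)], positives[np.sort(test_idx)]))
    return folds


def compute_metrics(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """Six-metric bundle on one labeled score vector.

    AUC is the rank-based ROC area (midrank tie handling); AUPR is the
    step-interpolated precision-recall area.  The remaining four are
    confusion-matrix metrics at ``threshold``; precision, recall and F1
    fall back to 0 when their denominators are empty.
    """
    labels = np.asarray(labels, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC/AUPR need both classes present")
    pred = (scores >= threshold).astype(float)
    tp = float(np.sum((pred == 1) & (labels == 1)))
    fp = float(np.sum((pred == 1) & (labels == 0)))
    fn = float(np.sum((pred == 0) & (labels == 1)))
    tn = float(np.sum((pred == 0) & (labels == 0)))
    pre = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec > 0 else 0.0
    return {
        "AUC": float(roc_auc_score(labels, scores)),
        "AUPR": float(average_precision_score(labels, scores)),
        "ACC": (tp + tn) / len(labels),
        "Pre": pre,
        "Recall": rec,
        "F1": f1,
    }


def _sample_test_negatives(
    A_vals: np.ndarray,
    n: int,
    seed: int,
    train_negatives: np.ndarray,
) -> np.ndarray:
    """Test negatives: unlabeled pairs disjoint from the training negatives."""
    return sample_negatives_random(A_vals, n, seed, exclude=train_negatives)


def cross_validate(A, SMpp, SDpp, cfg: RunConfig, n_folds: int = 5) -> CVSummary:
    """Full cross-validation of the fit/predict pipeline.

    The fused similarities are taken as fixed inputs across folds (they
    derive from precomputed similarity sources, not from the association
    labels); only the association matrix is re-masked per fold.
    """
    if not isinstance(A, AssociationMatrix):
        A = AssociationMatrix(
            [f"m{i}" for i in range(np.asarray(A).shape[0])],
            [f"d{j}" for j in range(np.asarray(A).shape[1])],
            np.asarray(A, float),
        )
    folds = make_folds(A, n_folds, cfg.seed)
    results = []
    for i, (train_pos, test_pos) in enumerate(folds):
        fold_seed = cfg.seed + 1000 * (i + 1)
        fold_cfg = cfg.replace(seed=fold_seed)
        A_train = A.values.copy()
        A_train[test_pos[:, 0], test_pos[:, 1]] = 0.0
        # training negatives come from the unlabeled pairs of the ORIGINAL
        # matrix: a held-out positive is a known association whose label is
        # hidden, not a legitimate negative candidate
        train_neg = sample_training_negatives(
            A.values, len(train_pos), fold_cfg, SMpp, SDpp
        )
        result = fit(
            A_train, SMpp, SDpp, fold_cfg,
            positives=train_pos, negatives=train_neg,
        )
        scores = predict(
            result.params, A_train, SMpp, SDpp, fold_cfg,
            microbe_ids=A.microbe_ids, disease_ids=A.disease_ids,
        )
        # test negatives never overlap training negatives nor any positive:
        # the pool is zeros of the *original* A minus the training negatives
        test_neg = _sample_test_negatives(
            A.values, len(test_pos), fold_seed + 1, result.negatives
        )
        eval_pairs = np.vstack([test_pos, test_neg])
        labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
        values = scores.values[eval_pairs[:, 0], eval_pairs[:, 1]]
        metrics = compute_metrics(labels, values, cfg.threshold)
        logger.info(
            "fold %d/%d: %s", i + 1, n_folds,
            " ".join(f"{k}={v:.4f}" for k, v in metrics.items()),
        )
        results.append(
            FoldResult(
                fold=i,
                seed=fold_seed,
                metrics=metrics,
                train_positives=train_pos,
                test_positives=test_pos,
                train_negatives=result.negatives,
                test_negatives=test_neg,
            )
        )
    return CVSummary(results)
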