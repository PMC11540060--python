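"""Negative sampling and the end-to-end fit/predict procedure.

Only positive microbe-disease associations are experimentally verified;
training "negatives" are drawn from the unlabeled pairs, either uniformly
at random or by the k-means strategy: unlabeled pairs are clustered on
their concatenated entity feature vectors and the negative quota is spread
proportionally across clusters, which samples a more representative
cross-section of the unlabeled space than a uniform draw.

Training minimizes the pair-wise binary cross-entropy with Adam plus
decoupled weight decay for a fixed number of epochs (no early stopping).
Negatives are drawn once per fit, not per epoch, so a fold is fully
reproducible from its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._autodiff import AdamW
from .config import RunConfig
from .matrices import AssociationMatrix, ScoreMatrix
from .model import SGJMDAParams, forward, init_params, pair_loss, prepare_operators

__all__ = [
    "sample_negatives_random",
    "sample_negatives_kmeans",
    "sample_training_negatives",
    "fit",
    "predict",
    "TrainResult",
]

logger = logging.getLogger(__name__)


def _assoc_values(A) -> np.ndarray:
    return A.values if isinstance(A, AssociationMatrix) else np.asarray(A, float)


def _zero_pairs(A_vals: np.ndarray, exclude: np.ndarray | None = None) -> np.ndarray:
    zeros = np.argwhere(A_vals == 0.0)
    if exclude is not None and len(exclude):
        excl = set(map(tuple, np.asarray(exclude, int)))
        zeros = np.array([p for p in zeros if tuple(p) not in excl], int).reshape(-1, 2)
    return zeros


def sample_negatives_random(A, n: int, seed: int, exclude=None) -> np.ndarray:
    """Uniform sample of ``n`` unlabeled pairs, without replacement.

    ``exclude`` removes extra pairs (e.g. held-out test positives that were
    zeroed in the training matrix) from the candidate pool.
    """
    A_vals = _assoc_values(A)
    pool = _zero_pairs(A_vals, exclude)
    if n > len(pool):
        raise ValueError(f"requested {n} negatives but only {len(pool)} unlabeled pairs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool[np.sort(idx)]


def sample_negatives_kmeans(
    A,
    microbe_feats: np.ndarray,
    disease_feats: np.ndarray,
    n: int,
    n_clusters: int = 10,
    seed: int = 0,
    exclude=None,
) -> np.ndarray:
    """k-means-guided negative sampling over the unlabeled pairs.

    Each unlabeled pair is represented by the concatenation of its microbe
    and disease feature vectors; pairs are partitioned into ``n_clusters``
    groups and the quota of ``n`` negatives is allocated proportionally to
    cluster size (largest-remainder rounding), then drawn uniformly within
    each cluster.  Empty allocations are redistributed to the remaining
    clusters.
    """
    A_vals = _assoc_values(A)
    pool = _zero_pairs(A_vals, exclude)
    if n > len(pool):
        raise ValueError(f"requested {n} negatives but only {len(pool)} unlabeled pairs")
    microbe_feats = np.asarray(microbe_feats, float)
    disease_feats = np.asarray(disease_feats, float)
    X = np.hstack([microbe_feats[pool[:, 0]], disease_feats[pool[:, 1]]])
    k = min(n_clusters, len(pool))
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    rng = np.random.default_rng(seed)
    sizes = np.bincount(labels, minlength=k)
    # largest-remainder proportional allocation, capped by cluster size
    raw = n * sizes / sizes.sum()
    quota = np.minimum(np.floor(raw).astype(int), sizes)
    remainders = raw - np.floor(raw)
    while quota.sum() < n:
        room = sizes - quota
        order = np.argsort(-(remainders + (room > 0)))  # prefer clusters with room
        gave = False
        for c in order:
            if room[c] > 0:
                quota[c] += 1
                gave = True
                break
        if not gave:  # every cluster exhausted (cannot happen if n <= |pool|)
            break
    chosen: list[np.ndarray] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if quota[c] == 0 or len(members) == 0:
            continue
        pick = rng.choice(members, size=quota[c], replace=False)
        chosen.append(pool[pick])
    out = np.vstack(chosen)
    return out[np.lexsort((out[:, 1], out[:, 0]))]


def sample_training_negatives(
    A_pool,
    n: int,
    cfg: RunConfig,
    SMpp=None,
    SDpp=None,
    exclude=None,
) -> np.ndarray:
    """Draw ``n`` training negatives by the configured strategy.

    ``A_pool`` defines the unlabeled candidate pool (its zero entries);
    during cross-validation this is the *original* association matrix, so
    held-out test positives — known associations whose label is merely
    hidden from training — are never drawn as negatives.
    """
    A_vals = _assoc_values(A_pool)
    if cfg.neg_strategy == "kmeans":
        if SMpp is None or SDpp is None:
            raise ValueError("kmeans negative sampling needs entity features")
        sm = SMpp.values if hasattr(SMpp, "values") else np.asarray(SMpp, float)
        sd = SDpp.values if hasattr(SDpp, "values") else np.asarray(SDpp, float)
        return sample_negatives_kmeans(
            A_vals, sm, sd, n,
            n_clusters=cfg.n_neg_clusters, seed=cfg.seed, exclude=exclude,
        )
    return sample_negatives_random(A_vals, n, cfg.seed, exclude=exclude)


@dataclass
class TrainResult:
    params: SGJMDAParams
    loss_trace: list[float] = field(default_factory=list)
    positives: np.ndarray | None = None
    negatives: np.ndarray | None = None
    config: RunConfig | None = None


def _flat(pairs: np.ndarray, n_cols: int) -> np.ndarray:
    pairs = np.asarray(pairs, int).reshape(-1, 2)
    return pairs[:, 0] * n_cols + pairs[:, 1]


def fit(
    A_train,
    SMpp,
    SDpp,
    cfg: RunConfig,
    positives: np.ndarray | None = None,
    negatives: np.ndarray | None = None,
) -> TrainResult:
    """Train the model on one association matrix.

    ``positives`` defaults to every 1-entry of ``A_train``; ``negatives``
    are sampled 1:1 with the positives by ``cfg.neg_strategy`` when not
    given.  Every source of randomness (weight init, negative sampling)
    derives from ``cfg.seed``.  Returns the trained parameters and the
    per-epoch loss trace; with ``epochs=0`` the initialized parameters are
    returned untouched with an empty trace.
    """
    A_vals = _assoc_values(A_train)
    n_m, n_d = A_vals.shape
    if positives is None:
        positives = np.argwhere(A_vals == 1.0)
    positives = np.asarray(positives, int).reshape(-1, 2)
    if negatives is None:
        negatives = sample_training_negatives(A_vals, len(positives), cfg, SMpp, SDpp)
    negatives = np.asarray(negatives, int).reshape(-1, 2)
    if len(positives) and len(negatives):
        overlap = set(map(tuple, positives)) & set(map(tuple, negatives))
        if overlap:
            raise ValueError("positive and negative training pairs overlap")

    rng = np.random.default_rng(cfg.seed)
    params = init_params(n_m, n_d, cfg, rng)
    ops = prepare_operators(A_vals, SMpp, SDpp, cfg)
    optimizer = AdamW(params.trainable(cfg), lr=cfg.lr, weight_decay=cfg.wd)
    pos_flat, neg_flat = _flat(positives, n_d), _flat(negatives, n_d)

    trace: list[float] = []
    for epoch in range(cfg.epochs):
        optimizer.zero_grad()
        out = forward(params, ops, cfg)
        loss = pair_loss(out["scores"], pos_flat, neg_flat, cfg.loss_reduction)
        value = float(loss.value)
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        loss.backward()
        optimizer.step()
        trace.append(value)
        if epoch % 100 == 0:
            logger.debug("epoch %d loss %.6f", epoch, value)
    return TrainResult(params, trace, positives, negatives, cfg)


def predict(
    params: SGJMDAParams,
    A_train,
    SMpp,
    SDpp,
    cfg: RunConfig,
    microbe_ids=None,
    disease_ids=None,
) -> ScoreMatrix:
    """Score every microbe-disease pair with trained parameters.

    The training associations enter only through the heterogeneous graph
    structure; known positives are scored like any other pair, never
    overwritten.
    """
    A_vals = _assoc_values(A_train)
    ops = prepare_operators(A_vals, SMpp, SDpp, cfg)
    out = forward(params, ops, cfg)
    if isinstance(A_train, AssociationMatrix):
        microbe_ids = microbe_ids or A_train.microbe_ids
        disease_ids = disease_ids or A_train.disease_ids
    microbe_ids = microbe_ids or [f"m{i}" for i in range(A_vals.shape[0])]
    disease_ids = disease_ids or [f"d{j}" for j in range(A_vals.shape[1])]
    return ScoreMatrix(list(microbe_ids), list(disease_ids), out["scores"].value)
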