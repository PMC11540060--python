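"""Correlation decoder and binary cross-entropy loss.

A microbe-disease pair is scored by the Pearson correlation between the
two entities' concatenated embedding vectors (homogeneous block stacked
with the heterogeneous block), squashed through a sigmoid:

    A_hat[i, j] = sigmoid(Corr(lambda_i, lambda_j))

Because correlations live in [-1, 1], scores are confined to
(sigmoid(-1), sigmoid(1)) ~ (0.2689, 0.7311).  This bounds the per-positive
cross-entropy from below at -ln(sigmoid(1)) ~ 0.3133; the loss therefore
cannot approach zero even on a perfectly ranked training set.  That is a
property of the decoder, not a defect: ranking, not calibration, drives the
prediction task.
"""

from __future__ import annotations

import logging

import numpy as np

from .matrices import AssociationMatrix, ScoreMatrix

__all__ = [
    "pair_features",
    "correlation",
    "correlation_matrix",
    "sigmoid",
    "reconstruct",
    "bce_loss",
    "SCORE_CLIP",
]

logger = logging.getLogger(__name__)

SCORE_CLIP = 1e-7  # defensive clip before logs; sigmoid bounds make it inert


def pair_features(SM3, SMt, SD3, SDt):
    """Concatenate homogeneous and heterogeneous embeddings per entity.

    ``lambda`` for microbe i is the concatenation of its ``SM'''`` row and
    its ``SM~`` row (same for diseases).  Passing ``None`` for both
    heterogeneous blocks (the "Het" ablation) uses the homogeneous rows
    alone; a lone ``None`` is a contract violation.
    """
    if (SMt is None) != (SDt is None):
        raise ValueError("heterogeneous blocks must be both present or both absent")
    SM3, SD3 = np.asarray(SM3, float), np.asarray(SD3, float)
    if SMt is None:
        return SM3, SD3
    SMt, SDt = np.asarray(SMt, float), np.asarray(SDt, float)
    if SM3.shape[0] != SMt.shape[0] or SD3.shape[0] != SDt.shape[0]:
        raise ValueError("row counts of the two embedding blocks disagree")
    return np.hstack([SM3, SMt]), np.hstack([SD3, SDt])


def correlation(u, v) -> float:
    """Pearson correlation of two feature vectors.

    A constant (zero-variance) vector has no defined correlation; it is
    mapped to 0.0 — a neutral score of 1/2 after the sigmoid — with a
    warning, which keeps early training finite when an embedding collapses.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size or u.size < 2:
        raise ValueError("vectors must share a length of at least 2")
    uc, vc = u - u.mean(), v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        logger.warning("zero-variance embedding vector; correlation set to 0")
        return 0.0
    return float(np.clip(uc @ vc / (nu * nv), -1.0, 1.0))


def _center_normalize(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    dead = norms[:, 0] == 0.0
    if dead.any():
        logger.warning(
            "%d zero-variance embedding rows; their correlations set to 0",
            int(dead.sum()),
        )
        norms[dead] = 1.0
    return Xc / norms


def correlation_matrix(lam_m: np.ndarray, lam_d: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation between microbe and disease features."""
    lam_m, lam_d = np.asarray(lam_m, float), np.asarray(lam_d, float)
    if lam_m.shape[1] != lam_d.shape[1]:
        raise ValueError("feature dimensions disagree")
    return np.clip(_center_normalize(lam_m) @ _center_normalize(lam_d).T, -1.0, 1.0)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def reconstruct(lam_m, lam_d, microbe_ids=None, disease_ids=None) -> ScoreMatrix:
    """Score every pair: sigmoid of the correlation matrix."""
    lam_m, lam_d = np.asarray(lam_m, float), np.asarray(lam_d, float)
    if lam_m.size == 0 or lam_d.size == 0:
        raise ValueError("empty feature matrices")
    scores = sigmoid(correlation_matrix(lam_m, lam_d))
    microbe_ids = microbe_ids or [f"m{i}" for i in range(lam_m.shape[0])]
    disease_ids = disease_ids or [f"d{j}" for j in range(lam_d.shape[0])]
    return ScoreMatrix(list(microbe_ids), list(disease_ids), scores)


def bce_loss(
    A,
    A_hat,
    positives: np.ndarray,
    negatives: np.ndarray,
    reduction: str = "sum",
) -> float:
    """Binary cross-entropy over the selected positive and negative pairs.

    ``L = - sum_{(i,j)} [ A_ij ln A_hat_ij + (1 - A_ij) ln(1 - A_hat_ij) ]``
    summed (not averaged) over ``positives`` union ``negatives`` by
    default.  The index sets are (n, 2) arrays of (microbe, disease)
    indices and must be disjoint.
    """
    A_vals = A.values if isinstance(A, AssociationMatrix) else np.asarray(A, float)
    S = A_hat.values if isinstance(A_hat, ScoreMatrix) else np.asarray(A_hat, float)
    pos = np.asarray(positives, dtype=int).reshape(-1, 2)
    neg = np.asarray(negatives, dtype=int).reshape(-1, 2)
    if pos.size + neg.size == 0:
        return 0.0
    sel = np.vstack([p for p in (pos, neg) if p.size])
    if (sel < 0).any() or (sel[:, 0] >= S.shape[0]).any() or (sel[:, 1] >= S.shape[1]).any():
        raise IndexError("pair index outside the score matrix")
    if pos.size and neg.size:
        common = set(map(tuple, pos)) & set(map(tuple, neg))
        if common:
            raise ValueError(f"positive and negative sets overlap: {sorted(common)[:3]}")
    s = np.clip(S[sel[:, 0], sel[:, 1]], SCORE_CLIP, 1.0 - SCORE_CLIP)
    y = A_vals[sel[:, 0], sel[:, 1]]
    terms = y * np.log(s) + (1.0 - y) * np.log(1.0 - s)
    loss = -terms.sum()
    if reduction == "mean":
        loss /= len(sel)
    elif reduction != "sum":
        raise ValueError("reduction must be 'sum' or 'mean'")
    return float(loss)
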