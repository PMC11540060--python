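"""Nonlinear fusion of similarity views by KNN-guided cross-diffusion.

Three similarity views per entity side (cosine, Gaussian interaction
profile, sigmoid kernel) are fused into one consensus matrix:

1. each view is row-normalized so the diagonal is exactly 1/2 and every
   row sums to 1;
2. a sparse KNN affinity is built per view, keeping each row's strongest
   floor(N / 10) neighbors (self excluded) renormalized to sum 1;
3. the three normalized views are cross-diffused: at each iteration every
   view is replaced by its own KNN affinity applied to the average of the
   *other* views from the previous iteration, until the relative Frobenius
   change of every view falls below tolerance;
4. the elementwise mean of the converged views is symmetrized and merged
   convexly with the functional (microbe) or semantic (disease) similarity:
   SM'' = alpha * SM' + (1 - alpha) * FS.

All updates within an iteration are simultaneous: view k at step t sees the
other views at step t-1 only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .matrices import SimilarityMatrix

__all__ = [
    "normalize_full",
    "knn_count",
    "knn_affinity",
    "cross_diffuse",
    "symmetrize",
    "merge_with_functional",
    "fuse_side",
    "FusionResult",
]

logger = logging.getLogger(__name__)


def _values(S) -> np.ndarray:
    return S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)


def normalize_full(S, uniform_row_fallback: bool = False) -> np.ndarray:
    """Row-normalize a similarity matrix with diagonal pinned to 1/2.

    Off-diagonal entries become ``S[i, j] / (2 * sum_{k != i} S[i, k])`` so
    each row sums to exactly 1.  A row with all-zero off-diagonal has no
    neighbors to distribute mass over: this is an error by default, or a
    uniform off-diagonal row when ``uniform_row_fallback`` is set.
    """
    v = _values(S)
    n = v.shape[0]
    off = v.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    dead = row_sums <= 0
    if dead.any():
        idx = int(np.flatnonzero(dead)[0])
        label = S.ids[idx] if isinstance(S, SimilarityMatrix) else idx
        if not uniform_row_fallback:
            raise ValueError(
                f"entity {label!r} has zero similarity to every other entity; "
                "cannot row-normalize (pass uniform_row_fallback=True to "
                "substitute a uniform row)"
            )
        off[dead] = 1.0
        off[dead, np.flatnonzero(dead)] = 0.0  # keep diagonal out of the mass
        row_sums = off.sum(axis=1)
    out = off / (2.0 * row_sums[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def knn_count(n_entities: int, divisor: int = 10) -> int:
    """Neighbors retained per row: floor(N / divisor), at least 1."""
    return max(1, n_entities // divisor)


def knn_affinity(S, n_neighbors: int) -> np.ndarray:
    """Sparse row-stochastic affinity keeping each row's top neighbors.

    Per row the ``n_neighbors`` largest off-diagonal similarities are kept
    (ties broken toward the lower column index) and renormalized to sum 1;
    all other entries, including the diagonal, are zero.  Rows whose kept
    neighbors are all zero-valued stay all-zero.
    """
    v = _values(S)
    n = v.shape[0]
    if not 1 <= n_neighbors < n:
        raise ValueError(
            f"n_neighbors must be in [1, {n - 1}] for {n} entities, "
            f"got {n_neighbors}"
        )
    masked = v.copy()
    np.fill_diagonal(masked, -np.inf)  # self never a neighbor
    # stable argsort on negated values => ties resolved toward lower index
    order = np.argsort(-masked, axis=1, kind="stable")[:, :n_neighbors]
    out = np.zeros_like(v)
    rows = np.repeat(np.arange(n), n_neighbors)
    cols = order.ravel()
    out[rows, cols] = v[rows, cols]
    sums = out.sum(axis=1)
    alive = sums > 0
    out[alive] /= sums[alive, None]
    return out


@dataclass
class FusionResult:
    fused: np.ndarray                 # mean of the converged views
    views: list[np.ndarray]           # per-view converged matrices
    n_iterations: int
    residuals: list[np.ndarray] = field(default_factory=list)
    converged: bool = True


def cross_diffuse(
    views: list[np.ndarray],
    affinities: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 1000,
    renormalize: bool = False,
) -> FusionResult:
    """Simultaneously cross-diffuse similarity views through KNN affinities.

    At iteration t, view k becomes ``SKNN_k @ mean(other views at t-1) @
    SKNN_k.T``.  Iteration stops once every view's relative Frobenius
    change drops below ``tol``, or at ``max_iter`` with a warning.  Returns
    the elementwise mean of the final views along with convergence
    diagnostics.

    ``renormalize`` re-applies the diagonal-1/2 row normalization after
    each sweep, as classic similarity-network fusion does.  Without it the
    double-smoothing update is a strict contraction toward a constant
    matrix: the iteration "converges", but to a structureless fixed point
    that carries no similarity signal.  Renormalization is therefore the
    default; the plain update remains available for comparison.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    m = len(views)
    if m < 2 or len(affinities) != m:
        raise ValueError("need >= 2 views with one affinity each")
    current = [np.asarray(v, dtype=float) for v in views]
    residual_trace: list[np.ndarray] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        total = np.add.reduce(current)
        updated = []
        for k in range(m):
            others_mean = (total - current[k]) / (m - 1)
            new = affinities[k] @ others_mean @ affinities[k].T
            if renormalize:
                new = normalize_full(new, uniform_row_fallback=True)
            updated.append(new)
        if not all(np.all(np.isfinite(u)) for u in updated):
            raise FloatingPointError(
                f"non-finite values in cross-diffusion at iteration {it}"
            )
        res = np.array(
            [
                np.linalg.norm(updated[k] - current[k])
                / max(np.linalg.norm(current[k]), np.finfo(float).tiny)
                for k in range(m)
            ]
        )
        residual_trace.append(res)
        current = updated
        if np.all(res < tol):
            converged = True
            break
    if not converged:
        logger.warning(
            "cross-diffusion did not converge in %d iterations "
            "(last residuals %s)", max_iter, residual_trace[-1],
        )
    fused = np.add.reduce(current) / m
    return FusionResult(fused, current, it, residual_trace, converged)


def symmetrize(SM: np.ndarray) -> np.ndarray:
    """(SM + SM.T) / 2 — exactly symmetric, idempotent."""
    SM = np.asarray(SM, dtype=float)
    return (SM + SM.T) / 2.0


def merge_with_functional(SMp: np.ndarray, FS, alpha: float) -> np.ndarray:
    """Convex combination ``alpha * SM' + (1 - alpha) * FS``."""
    fs = _values(FS)
    SMp = np.asarray(SMp, dtype=float)
    if SMp.shape != fs.shape:
        raise ValueError(f"shape mismatch {SMp.shape} vs {fs.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * SMp + (1.0 - alpha) * fs


def fuse_side(
    cos: SimilarityMatrix,
    gip: SimilarityMatrix,
    sig: SimilarityMatrix,
    fs: SimilarityMatrix,
    cfg: RunConfig,
) -> SimilarityMatrix:
    """Full fusion pipeline for one entity side (microbes or diseases).

    Under the "SF" ablation the nonlinear fusion is replaced by the plain
    elementwise mean of the four input matrices.
    """
    ids = cos.ids
    for other in (gip, sig, fs):
        if other.ids != ids:
            raise ValueError("all similarity views must share the same IDs")
    if cfg.ablation == "SF":
        merged = (cos.values + gip.values + sig.values + fs.values) / 4.0
        return SimilarityMatrix(ids, merged)
    views = [normalize_full(v) for v in (cos, gip, sig)]
    k = knn_count(len(ids), cfg.knn_divisor)
    affinities = [knn_affinity(v, k) for v in (cos, gip, sig)]
    result = cross_diffuse(
        views,
        affinities,
        tol=cfg.fusion_tol,
        max_iter=cfg.fusion_max_iter,
        renormalize=cfg.renormalize_views,
    )
    merged = merge_with_functional(symmetrize(result.fused), fs, cfg.alpha)
    return SimilarityMatrix(ids, merged)
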