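"""The full differentiable model: encoders plus correlation decoder.

The forward pass composes, on the autodiff tape:

* per side, one homogeneous GCN layer over the fused similarity graph
  (or a dense feature map under the "Hom" ablation);
* ``n_hetero_layers`` multi-neighborhood layers over the bipartite
  association graph, each a concatenation of propagations through powers
  0..k of the normalized adjacency followed by a ReLU;
* jumping-knowledge aggregation of the layer outputs (weighted sum; a
  selector of the last layer under the "JK" ablation; skipped entirely
  under "Het");
* row-wise centering and normalization of the concatenated embeddings, so
  the pair-score matrix is the Pearson correlation matrix passed through a
  sigmoid ("Dec" swaps the correlation for a plain inner product).

Everything trainable — the two homogeneous weight matrices, the per-power
weight blocks of every heterogeneous layer, and (optionally) the
jumping-knowledge coefficients — is optimized jointly against the
binary cross-entropy of the sampled positive/negative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .config import RunConfig
from .decoder import SCORE_CLIP
from .encoders import (
    block_widths,
    build_hetero,
    glorot_uniform,
    normalized_operator,
)
from .matrices import SimilarityMatrix

__all__ = ["SGJMDAParams", "init_params", "prepare_operators", "forward", "pair_loss"]

_NORM_EPS = 1e-12  # inside sqrt of the row norms; exact 0 for collapsed rows


@dataclass
class SGJMDAParams:
    """Trainable parameter set."""

    w_microbe: Tensor
    w_disease: Tensor
    hetero: list[list[Tensor]]  # [layer][power] weight blocks
    omegas: list[Tensor]        # jumping-knowledge coefficients, one per layer

    def trainable(self, cfg: RunConfig) -> list[Tensor]:
        params = [self.w_microbe, self.w_disease]
        if cfg.ablation != "Het":
            for layer in self.hetero:
                params.extend(layer)
            if cfg.ablation != "JK" and cfg.jk_learnable:
                params.extend(self.omegas)
        return params

    def snapshot(self) -> dict:
        return {
            "w_microbe": self.w_microbe.value.copy(),
            "w_disease": self.w_disease.value.copy(),
            "hetero": [[w.value.copy() for w in layer] for layer in self.hetero],
            "omegas": [w.value.copy() for w in self.omegas],
        }


def init_params(
    n_microbes: int, n_diseases: int, cfg: RunConfig, rng: np.random.Generator
) -> SGJMDAParams:
    """Glorot-uniform initialization of every weight, driven by ``rng``.

    Jumping-knowledge coefficients start uniform at ``1/l`` whether or not
    they are trained further.
    """
    d = cfg.layer_size
    w_m = Tensor(glorot_uniform(rng, (n_microbes, d)), requires_grad=True)
    w_d = Tensor(glorot_uniform(rng, (n_diseases, d)), requires_grad=True)
    widths = block_widths(d, cfg.k_neighborhood)
    hetero = [
        [Tensor(glorot_uniform(rng, (d, w)), requires_grad=True) for w in widths]
        for _ in range(cfg.n_hetero_layers)
    ]
    omegas = [
        Tensor(np.asarray(1.0 / cfg.n_hetero_layers), requires_grad=cfg.jk_learnable)
        for _ in range(cfg.n_hetero_layers)
    ]
    return SGJMDAParams(w_m, w_d, hetero, omegas)


def _sim_values(S) -> np.ndarray:
    return S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, float)


def prepare_operators(A_train: np.ndarray, SMpp, SDpp, cfg: RunConfig) -> dict:
    """Precompute every constant matrix the forward pass multiplies by.

    The homogeneous stage needs ``P G`` per side (the graph doubles as the
    feature matrix, so this product is fixed); the heterogeneous stage
    needs the normalized bipartite operator rebuilt from the *training*
    associations.  Under "Hom" the propagation is dropped and the raw
    fused similarity is the feature matrix.
    """
    sm = _sim_values(SMpp)
    sd = _sim_values(SDpp)
    A_train = np.asarray(A_train, dtype=float)
    if cfg.ablation == "Hom":
        z_m, z_d = sm, sd
    else:
        z_m = normalized_operator(sm, literal=cfg.literal_normalization) @ sm
        z_d = normalized_operator(sd, literal=cfg.literal_normalization) @ sd
    hetero = build_hetero(
        A_train,
        self_loops=cfg.hetero_self_loops,
        literal=cfg.literal_normalization,
    )
    return {
        "Z_m": z_m,
        "Z_d": z_d,
        "P_tilde": hetero.operator,
        "n_microbes": A_train.shape[0],
        "n_diseases": A_train.shape[1],
    }


def _row_normalize(lam: Tensor) -> Tensor:
    """Center each row and divide by its norm (Pearson preprocessing)."""
    centered = lam - lam.mean(axis=1, keepdims=True)
    ss = (centered * centered).sum(axis=1, keepdims=True)
    return centered / ad.sqrt(ss + _NORM_EPS)


def forward(params: SGJMDAParams, ops: dict, cfg: RunConfig) -> dict:
    """Differentiable forward pass; returns the tape's named intermediates."""
    n_m = ops["n_microbes"]
    h_m = ad.relu(ad.matmul(Tensor(ops["Z_m"]), params.w_microbe))
    h_d = ad.relu(ad.matmul(Tensor(ops["Z_d"]), params.w_disease))
    out = {"H_m": h_m, "H_d": h_d}

    if cfg.ablation == "Het":
        lam_m, lam_d = h_m, h_d
    else:
        h = ad.concat([h_m, h_d], axis=0)  # stack microbes over diseases
        layers = []
        p_tilde = ops["P_tilde"]
        for layer_weights in params.hetero:
            h = ad.relu(
                _multi_neighborhood(p_tilde, h, layer_weights, cfg.k_neighborhood)
            )
            layers.append(h)
        if cfg.ablation == "JK":
            h_agg = layers[-1]
        else:
            h_agg = layers[0] * params.omegas[0]
            for layer, w in zip(layers[1:], params.omegas[1:]):
                h_agg = h_agg + layer * w
        sm_t = h_agg.rows(0, n_m)
        sd_t = h_agg.rows(n_m, n_m + ops["n_diseases"])
        out["SM_tilde"], out["SD_tilde"] = sm_t, sd_t
        lam_m = ad.concat([h_m, sm_t], axis=1)
        lam_d = ad.concat([h_d, sd_t], axis=1)

    out["lam_m"], out["lam_d"] = lam_m, lam_d
    if cfg.ablation == "Dec":
        logits = ad.matmul(lam_m, lam_d.T)
    else:
        logits = ad.matmul(_row_normalize(lam_m), _row_normalize(lam_d).T)
    out["scores"] = ad.sigmoid(logits)
    return out


def _multi_neighborhood(P: np.ndarray, H: Tensor, weights, k_max: int) -> Tensor:
    blocks = []
    propagated = H
    for i in range(k_max + 1):
        if i > 0:
            propagated = ad.matmul(Tensor(P), propagated)
        blocks.append(ad.matmul(propagated, weights[i]))
    return ad.concat(blocks, axis=1)


def pair_loss(
    scores: Tensor,
    pos_flat: np.ndarray,
    neg_flat: np.ndarray,
    reduction: str = "sum",
) -> Tensor:
    """BCE over the sampled pairs, on the tape.

    Scores are clipped away from {0, 1} before the logs; with the
    correlation decoder the sigmoid bounds already guarantee this, but the
    inner-product ("Dec") variant can saturate.
    """
    s = scores.take_flat(np.concatenate([pos_flat, neg_flat]))
    clipped = _clip(s, SCORE_CLIP, 1.0 - SCORE_CLIP)
    n_pos = len(pos_flat)
    s_pos = clipped.rows(0, n_pos)
    s_neg = clipped.rows(n_pos, n_pos + len(neg_flat))
    loss = -(ad.log(s_pos).sum() + ad.log(1.0 - s_neg).sum())
    if reduction == "mean":
        loss = loss * (1.0 / max(n_pos + len(neg_flat), 1))
    return loss


def _clip(t: Tensor, lo: float, hi: float) -> Tensor:
    clipped = np.clip(t.value, lo, hi)
    mask = (t.value > lo) & (t.value < hi)
    return Tensor(
        clipped,
        _parents=(t,),
        _backward=lambda g: t._accumulate(g * mask),
    )
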