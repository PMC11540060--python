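"""Graph convolutional encoders over the fused similarity and association graphs.

Two encoder stages produce the node embeddings:

* a single-layer homogeneous GCN per entity side, propagating the fused
  similarity matrix over itself: ``SM''' = relu(P SM'' W)`` with
  ``P = D^{-1/2} SM'' D^{-1/2}``;
* a multi-neighborhood GCN over the bipartite microbe-disease graph
  ``G~ = [[0, A], [A^T, 0]]`` (plus self-loops), whose layer output
  concatenates propagations through powers 0..k of the normalized
  adjacency, followed by jumping-knowledge aggregation (a weighted sum of
  all layer outputs).

The degree normalization is the standard symmetric ``D^{-1/2} G D^{-1/2}``;
a config flag restores the variant with a positive right exponent for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .config import RunConfig
from .matrices import AssociationMatrix, SimilarityMatrix

__all__ = [
    "normalized_operator",
    "gcn_homogeneous",
    "HeteroGraph",
    "build_hetero",
    "block_widths",
    "multi_neighborhood_layer",
    "jk_aggregate",
    "glorot_uniform",
    "encode",
]


def normalized_operator(G: np.ndarray, literal: bool = False) -> np.ndarray:
    """Degree-normalized propagation operator for a nonnegative graph matrix.

    Symmetric normalization ``D^{-1/2} G D^{-1/2}`` by default, the
    right-positive-exponent variant ``D^{-1/2} G D^{+1/2}`` when
    ``literal`` is set.  Rows/columns of isolated nodes (zero degree)
    come out all-zero.
    """
    G = np.asarray(G, dtype=float)
    if (G < 0).any():
        raise ValueError("graph matrix must be nonnegative")
    deg = G.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, deg**-0.5, 0.0)
        d_pos_sqrt = np.where(deg > 0, deg**0.5, 0.0)
    right = d_pos_sqrt if literal else d_inv_sqrt
    return d_inv_sqrt[:, None] * G * right[None, :]


def _activation(name: str):
    if name == "relu":
        return ad.relu
    if name in ("linear", "identity", None):
        return lambda t: t
    raise ValueError(f"unknown activation {name!r}")


def gcn_homogeneous(
    G,
    W,
    activation: str = "relu",
    literal: bool = False,
) -> Tensor:
    """One GCN layer on a homogeneous similarity graph.

    The graph matrix doubles as the input feature matrix, so the output is
    ``act(P G W)`` with ``P`` the normalized operator of ``G``.  ``W`` maps
    the N-dimensional similarity profile to the embedding dimension.
    """
    G_vals = G.values if isinstance(G, SimilarityMatrix) else np.asarray(G, float)
    P = normalized_operator(G_vals, literal=literal)
    W = W if isinstance(W, Tensor) else Tensor(W)
    return _activation(activation)(ad.matmul(Tensor(P @ G_vals), W))


@dataclass
class HeteroGraph:
    """Bipartite microbe-disease block graph and its propagation operator."""

    n_microbes: int
    n_diseases: int
    adjacency: np.ndarray   # (N_m+N_d)^2 block matrix, zero diagonal blocks
    operator: np.ndarray    # normalized propagation operator (self-loops opt.)

    @property
    def n_nodes(self) -> int:
        return self.n_microbes + self.n_diseases


def build_hetero(
    A,
    self_loops: bool = True,
    literal: bool = False,
) -> HeteroGraph:
    """Build ``G~ = [[0, A], [A^T, 0]]`` and its normalized operator.

    Self-loops (identity added before normalization) give isolated
    entities — microbes or diseases with no training association — a
    defined degree, so their embedding reduces to a transform of their own
    input features.
    """
    A_vals = A.values if isinstance(A, AssociationMatrix) else np.asarray(A, float)
    n_m, n_d = A_vals.shape
    n = n_m + n_d
    G = np.zeros((n, n))
    G[:n_m, n_m:] = A_vals
    G[n_m:, :n_m] = A_vals.T
    G_for_norm = G + np.eye(n) if self_loops else G
    P = normalized_operator(G_for_norm, literal=literal)
    return HeteroGraph(n_m, n_d, G, P)


def block_widths(layer_size: int, k_max: int) -> list[int]:
    """Column widths of the per-power weight blocks.

    The concatenation over powers 0..k must return ``layer_size`` columns so
    layers stack; each block gets ``layer_size // (k+1)`` columns with the
    remainder assigned to the power-0 block.
    """
    n_blocks = k_max + 1
    if layer_size < n_blocks:
        raise ValueError(
            f"layer_size {layer_size} cannot be split into {n_blocks} blocks"
        )
    base = layer_size // n_blocks
    widths = [base] * n_blocks
    widths[0] += layer_size - base * n_blocks
    return widths


def multi_neighborhood_layer(
    P: np.ndarray,
    H,
    weights: list,
    k_max: int,
) -> Tensor:
    """Concatenate propagations through powers 0..k of the operator.

    ``output = [ P^0 H W_0 | P^1 H W_1 | ... | P^k H W_k ]`` (linear; the
    caller applies any nonlinearity).  Powers are accumulated by repeated
    multiplication, never by forming ``P^i`` explicitly.
    """
    if len(weights) != k_max + 1:
        raise ValueError(f"need {k_max + 1} weight blocks, got {len(weights)}")
    H = H if isinstance(H, Tensor) else Tensor(H)
    weights = [w if isinstance(w, Tensor) else Tensor(w) for w in weights]
    blocks = []
    propagated = H
    for i in range(k_max + 1):
        if i > 0:
            propagated = ad.matmul(Tensor(P), propagated)
        blocks.append(ad.matmul(propagated, weights[i]))
    return ad.concat(blocks, axis=1)


def jk_aggregate(layers: list, omegas) -> Tensor:
    """Jumping-knowledge aggregation: weighted sum of layer outputs."""
    if len(layers) == 0:
        raise ValueError("need at least one layer")
    if len(omegas) != len(layers):
        raise ValueError(f"need {len(layers)} weights, got {len(omegas)}")
    layers = [h if isinstance(h, Tensor) else Tensor(h) for h in layers]
    shape = layers[0].shape
    for h in layers[1:]:
        if h.shape != shape:
            raise ValueError("all layers must share the same shape")
    out = layers[0] * omegas[0]
    for h, w in zip(layers[1:], omegas[1:]):
        out = out + h * w
    return out


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def encode(A, SMpp, SDpp, cfg: RunConfig, params=None):
    """Run both encoder stages and return the four embedding matrices.

    Returns ``(SM''', SD''', SM~, SD~)`` as numpy arrays: homogeneous
    embeddings per side, then the microbe/disease row blocks of the
    jumping-knowledge aggregate over the heterogeneous layers.  Under the
    "Het" ablation the last two are ``None``.  With ``params=None`` fresh
    weights are initialized from ``cfg.seed``.
    """
    from .model import forward, init_params, prepare_operators  # cycle-free at call

    A_vals = A.values if isinstance(A, AssociationMatrix) else np.asarray(A, float)
    if params is None:
        rng = np.random.default_rng(cfg.seed)
        params = init_params(A_vals.shape[0], A_vals.shape[1], cfg, rng)
    ops = prepare_operators(A_vals, SMpp, SDpp, cfg)
    out = forward(params, ops, cfg)
    sm3, sd3 = out["H_m"].value, out["H_d"].value
    if cfg.ablation == "Het":
        return sm3, sd3, None, None
    return sm3, sd3, out["SM_tilde"].value, out["SD_tilde"].value
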