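"""Neighborhood view: multi-head graph attention over neighbor embeddings.

Per head ``k`` with weight matrix ``W_k`` and attention vector ``q_k``, the
raw coefficient for neighbor ``j`` of node ``i`` is

    c_ij = LeakyReLU(q_k^T [W_k h_i ⊕ W_k h_j])

softmax-normalized over the neighborhood.  The layer output is the smooth
nonlinearity of the head-averaged attention-weighted neighbor sum,

    h'_i = σ((1/K) Σ_k Σ_j α_ij^k W_k h_j),

stacked for a configurable number of layers (default two).  Nodes without
neighbors pass through a self-loop.  The per-pair interaction vector is
``h2 = |z - z'| ⊕ [l2(z, z')]``, keeping the scalar l2 aggregation of the
view as the last coordinate while giving the feature gates coordinates to
weight.

A degree-normalized mean aggregator (``aggregator="mean"``) replaces the
attention weights for the GCN-style ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .pathing import neighbors
from .termbase import TermbaseError, TerminologyBase

__all__ = [
    "GATConfig",
    "GATParams",
    "softmax",
    "attention_coefficients",
    "gat_forward",
    "neighborhood_interaction",
]


@dataclass(frozen=True)
class GATConfig:
    dim: int = 300
    heads: int = 2
    layers: int = 2
    leaky_slope: float = 0.2
    neighbor_cap: int = 25
    aggregator: Literal["gat", "mean"] = "gat"

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise TermbaseError(f"heads must be >= 1, got {self.heads}")
        if self.layers < 1:
            raise TermbaseError(f"layers must be >= 1, got {self.layers}")


@dataclass
class GATParams:
    """Per-layer, per-head weight matrices W and attention vectors q."""

    config: GATConfig
    weights: list[np.ndarray]  # layer -> (K, d, d)
    attn: list[np.ndarray]  # layer -> (K, 2d)

    @classmethod
    def init(cls, config: GATConfig, rng: np.random.Generator | None = None) -> "GATParams":
        rng = rng or np.random.default_rng(0)
        d, K = config.dim, config.heads
        weights = [
            rng.normal(0.0, 1.0 / np.sqrt(d), size=(K, d, d)) for _ in range(config.layers)
        ]
        attn = [rng.normal(0.0, 1.0 / np.sqrt(d), size=(K, 2 * d)) for _ in range(config.layers)]
        return cls(config=config, weights=weights, attn=attn)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def softmax(c: np.ndarray, axis: int = -1) -> np.ndarray:
    z = c - c.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_coefficients(
    params: GATParams,
    h_i: np.ndarray,
    neighbor_vectors: np.ndarray,
    layer: int = 0,
) -> np.ndarray:
    """Per-head softmax-normalized attention weights, shape (K, m)."""
    nbrs = np.atleast_2d(np.asarray(neighbor_vectors, dtype=np.float64))
    if nbrs.shape[0] == 0:
        raise TermbaseError("attention over an empty neighborhood")
    if nbrs.shape[1] != h_i.shape[0]:
        raise TermbaseError(
            f"dimension mismatch: center {h_i.shape[0]}, neighbors {nbrs.shape[1]}"
        )
    W = params.weights[layer]  # (K, d, d)
    q = params.attn[layer]  # (K, 2d)
    d = h_i.shape[0]
    Whi = W @ h_i  # (K, d)
    Whj = np.einsum("kde,me->kmd", W, nbrs)  # (K, m, d)
    c = np.einsum("kd,kd->k", q[:, :d], Whi)[:, None] + np.einsum(
        "kd,kmd->km", q[:, d:], Whj
    )
    c = _leaky_relu(c, params.config.leaky_slope)
    return softmax(c, axis=1)


def gat_forward(
    params: GATParams,
    tb: TerminologyBase,
    node_embeddings: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Stacked multi-head attention aggregation over every node's neighborhood.

    ``node_embeddings`` must cover all concept ids.  Nodes with an empty
    neighbor set aggregate over a self-loop only.
    """
    cfg = params.config
    ids = tb.ids()
    missing = [i for i in ids if i not in node_embeddings]
    if missing:
        raise TermbaseError(f"missing embeddings for {missing[:3]!r}...")
    index = {cid: i for i, cid in enumerate(ids)}
    H = np.stack([np.asarray(node_embeddings[cid], dtype=np.float64) for cid in ids])
    if H.shape[1] != cfg.dim:
        raise TermbaseError(f"embedding dim {H.shape[1]} != configured dim {cfg.dim}")
    nbr_idx = []
    for cid in ids:
        ns = neighbors(tb, cid, cap=cfg.neighbor_cap).neighbor_ids
        nbr_idx.append([index[n] for n in ns] if ns else [index[cid]])  # self-loop

    for layer in range(cfg.layers):
        W = params.weights[layer]  # (K, d, d)
        WH = np.einsum("kde,ne->nkd", W, H)  # (n, K, d)
        out = np.empty_like(H)
        for i in range(len(ids)):
            js = nbr_idx[i]
            Whj = WH[js]  # (m, K, d)
            if cfg.aggregator == "mean":
                agg = Whj.mean(axis=0).mean(axis=0)  # degree-normalized, head-averaged
            else:
                alpha = attention_coefficients(params, H[i], H[js], layer=layer)  # (K, m)
                agg = np.einsum("km,mkd->d", alpha, Whj) / cfg.heads
            out[i] = agg
        H = _elu(out)
    return {cid: H[index[cid]] for cid in ids}


def neighborhood_interaction(z: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """Feature vector h2 = |z - z'| concatenated with the scalar l2 distance."""
    if z.shape != z2.shape:
        raise TermbaseError(f"dimension mismatch: {z.shape} vs {z2.shape}")
    diff = np.abs(z - z2)
    return np.concatenate([diff, [float(np.linalg.norm(z - z2))]])
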