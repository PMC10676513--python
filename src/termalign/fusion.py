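"""Gated multi-view fusion and the alignment scorer.

Each view produces an interaction feature vector per candidate pair:
``h1`` (semantic), ``h2`` (neighborhood), ``h3`` (path).  A feature gate
``g_i = σ(W_i h_i)`` reweights each vector elementwise (``h'_i = g_i ⊙ h_i``)
before the concatenation ``[h'_1, h'_2, h'_3]`` enters a small MLP that
yields one real alignment score per pair (higher = more likely aligned).

This module also hosts the :class:`AlignmentModel` container (encoder,
projection, GAT parameters, kernel bank, gates, scorer, ablation flags), the
per-base entity cache, and the batched forward/backward passes the trainer
drives.  Ablations run through the same interfaces: dropped views simply
contribute nothing to the concatenation, ``use_gates=False`` is the identity
gate, and the GCN-style aggregator / max pooling swap in behind the
neighborhood and path caches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import numpy as np

from . import pathing
from .encoder import Projection, TextEncoder, get_encoder
from .neighborhood import (
    GATConfig,
    GATParams,
    gat_forward,
    neighborhood_interaction,
)
from .pathview import (
    KernelBank,
    PoolingMode,
    path_feature_dim,
    path_features,
    path_similarity_matrix,
)
from .semantic import semantic_interaction
from .termbase import DanglingIdError, TermbaseError, TerminologyBase

__all__ = [
    "VIEWS",
    "GateParams",
    "ScorerParams",
    "AlignmentModel",
    "EntityCache",
    "gate",
    "score",
    "pair_features",
    "precompute_cache",
    "feature_blocks",
    "forward_scores",
    "backward_scores",
    "save_model",
    "load_model",
]

VIEWS = ("semantic", "neighborhood", "path")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GateParams:
    """Learnable gate matrix for one view's interaction vector."""

    weight: np.ndarray  # (d, d)

    @classmethod
    def init(cls, dim: int, rng: np.random.Generator) -> "GateParams":
        return cls(weight=rng.normal(0.0, 1.0 / np.sqrt(dim), size=(dim, dim)))


@dataclass
class ScorerParams:
    """Two-layer MLP (tanh hidden layer, linear output) over gated features."""

    w1: np.ndarray  # (hidden, D)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float

    @classmethod
    def init(cls, in_dim: int, hidden: int, rng: np.random.Generator) -> "ScorerParams":
        return cls(
            w1=rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(hidden, in_dim)),
            b1=np.zeros(hidden),
            w2=rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden),
            b2=0.0,
        )


def gate(params: GateParams, h: np.ndarray) -> np.ndarray:
    """Gate-aware embedding: σ(W h) ⊙ h (batched over leading axis if 2-D)."""
    if h.shape[-1] != params.weight.shape[1]:
        raise TermbaseError(
            f"gate shape mismatch: features {h.shape[-1]}, gate {params.weight.shape[1]}"
        )
    return _sigmoid(h @ params.weight.T) * h


def score(scorer: ScorerParams, *hs: np.ndarray) -> float:
    """Alignment score of one pair from its (already gated) view vectors."""
    x = np.concatenate(hs)
    if x.shape[0] != scorer.w1.shape[1]:
        raise TermbaseError(
            f"scorer input dim {x.shape[0]} != expected {scorer.w1.shape[1]}"
        )
    return float(scorer.w2 @ np.tanh(scorer.w1 @ x + scorer.b1) + scorer.b2)


@dataclass
class AlignmentModel:
    """All learnable parameters and configuration of the aligner."""

    encoder: TextEncoder
    encoder_backend: str
    projection: Projection
    gat: GATParams
    bank: KernelBank
    gates: dict[str, GateParams]
    scorer: ScorerParams
    views: tuple[str, ...] = VIEWS
    use_gates: bool = True
    pooling: PoolingMode = "kernel"
    path_n: int = 5
    path_k: int = 2
    max_paths: int = 4
    hidden: int = 64
    rng_seed: int = 0

    def feature_dim(self, view: str) -> int:
        d = self.projection.d_proj
        if view in ("semantic", "neighborhood"):
            return d + 1
        if view == "path":
            return path_feature_dim(self.bank, self.pooling)
        raise TermbaseError(f"unknown view {view!r}")

    @property
    def scorer_in_dim(self) -> int:
        return sum(self.feature_dim(v) for v in self.views)

    @classmethod
    def build(
        cls,
        rng_seed: int = 0,
        encoder_backend: str = "test",
        d_enc: int = 768,
        d_proj: int = 300,
        heads: int = 2,
        gat_layers: int = 2,
        leaky_slope: float = 0.2,
        neighbor_cap: int = 25,
        bank: KernelBank | None = None,
        views: Sequence[str] = VIEWS,
        use_gates: bool = True,
        pooling: PoolingMode = "kernel",
        path_n: int = 5,
        path_k: int = 2,
        max_paths: int = 4,
        hidden: int = 64,
        aggregator: str = "gat",
        max_tokens: int = 128,
    ) -> "AlignmentModel":
        views = tuple(v for v in VIEWS if v in views)
        if not views:
            raise TermbaseError("at least one view must be active")
        enc = get_encoder(encoder_backend, dim=d_enc, rng_seed=rng_seed, max_tokens=max_tokens)
        bank = bank or KernelBank.default()
        rng = np.random.default_rng(rng_seed)
        proj = Projection.init(enc.dim, d_proj, rng)
        gat_cfg = GATConfig(
            dim=d_proj,
            heads=heads,
            layers=gat_layers,
            leaky_slope=leaky_slope,
            neighbor_cap=neighbor_cap,
            aggregator=aggregator,  # type: ignore[arg-type]
        )
        gat = GATParams.init(gat_cfg, rng)
        model = cls(
            encoder=enc,
            encoder_backend=encoder_backend,
            projection=proj,
            gat=gat,
            bank=bank,
            gates={},
            scorer=ScorerParams.init(1, hidden, rng),  # placeholder, rebuilt below
            views=views,
            use_gates=use_gates,
            pooling=pooling,
            path_n=path_n,
            path_k=path_k,
            max_paths=max_paths,
            hidden=hidden,
            rng_seed=rng_seed,
        )
        model.gates = {v: GateParams.init(model.feature_dim(v), rng) for v in views}
        model.scorer = ScorerParams.init(model.scorer_in_dim, hidden, rng)
        return model


@dataclass
class EntityCache:
    """Per-base precomputed vectors: raw/projected names, GAT output, paths."""

    ids: list[str]
    index: dict[str, int]
    name_raw: np.ndarray  # (N, d_enc) encoder outputs
    name_vecs: np.ndarray  # (N, d_proj) projected name embeddings
    gat_vecs: np.ndarray  # (N, d_proj)
    path_raw: list[np.ndarray | None]  # per entity (m_i, d_enc) or None
    path_vecs: list[np.ndarray | None]  # per entity (m_i, d_proj) or None


def _encode_names_raw(model: AlignmentModel, tb: TerminologyBase) -> tuple[list[str], np.ndarray]:
    ids = tb.ids()
    raw = np.stack([model.encoder.encode(tb.concepts[i].name) for i in ids])
    return ids, raw


def _encode_paths_raw(model: AlignmentModel, tb: TerminologyBase) -> list[np.ndarray | None]:
    out: list[np.ndarray | None] = []
    for cid in tb.ids():
        paths = pathing.extract_paths(
            tb, cid, n=model.path_n, k=model.path_k, max_paths=model.max_paths
        )
        # Singleton paths carry no hierarchy context beyond the name itself;
        # entities with no hierarchy edges are treated as pathless.
        paths = [p for p in paths if p.n > 1]
        if not paths:
            out.append(None)
            continue
        seqs = [pathing.path_to_sequence(p, tb) for p in paths]
        out.append(np.stack([model.encoder.encode(s.text) for s in seqs]))
    return out


def precompute_cache(model: AlignmentModel, tb: TerminologyBase) -> EntityCache:
    """Encode names, run the GAT, and embed hierarchical paths for one base."""
    ids, name_raw = _encode_names_raw(model, tb)
    name_vecs = model.projection.apply(name_raw)
    node_embs = {cid: name_vecs[i] for i, cid in enumerate(ids)}
    if "neighborhood" in model.views:
        gat_vecs_map = gat_forward(model.gat, tb, node_embs)
        gat_vecs = np.stack([gat_vecs_map[cid] for cid in ids])
    else:
        gat_vecs = name_vecs
    if "path" in model.views:
        path_raw = _encode_paths_raw(model, tb)
        path_vecs = [None if r is None else model.projection.apply(r) for r in path_raw]
    else:
        path_raw = [None] * len(ids)
        path_vecs = [None] * len(ids)
    return EntityCache(
        ids=ids,
        index={cid: i for i, cid in enumerate(ids)},
        name_raw=name_raw,
        name_vecs=name_vecs,
        gat_vecs=gat_vecs,
        path_raw=path_raw,
        path_vecs=path_vecs,
    )


def refresh_cache(model: AlignmentModel, tb: TerminologyBase, cache: EntityCache) -> EntityCache:
    """Re-project and re-aggregate a cache after the projection changed."""
    name_vecs = model.projection.apply(cache.name_raw)
    node_embs = {cid: name_vecs[i] for i, cid in enumerate(cache.ids)}
    if "neighborhood" in model.views:
        gat_map = gat_forward(model.gat, tb, node_embs)
        gat_vecs = np.stack([gat_map[cid] for cid in cache.ids])
    else:
        gat_vecs = name_vecs
    path_vecs = [None if r is None else model.projection.apply(r) for r in cache.path_raw]
    return replace(cache, name_vecs=name_vecs, gat_vecs=gat_vecs, path_vecs=path_vecs)


def _abs_diff_with_tail(A: np.ndarray, B: np.ndarray, tail: np.ndarray) -> np.ndarray:
    return np.concatenate([np.abs(A - B), tail[:, None]], axis=1)


def feature_blocks(
    model: AlignmentModel,
    cache_s: EntityCache,
    cache_t: EntityCache,
    idx_pairs: Sequence[tuple[int, int]],
) -> dict[str, np.ndarray]:
    """Per-view interaction feature matrices for a batch of (i, j) index pairs."""
    si = np.fromiter((i for i, _ in idx_pairs), dtype=np.intp, count=len(idx_pairs))
    ti = np.fromiter((j for _, j in idx_pairs), dtype=np.intp, count=len(idx_pairs))
    blocks: dict[str, np.ndarray] = {}
    if "semantic" in model.views:
        A = cache_s.name_vecs[si]
        B = cache_t.name_vecs[ti]
        cos = np.einsum("nd,nd->n", A, B) / (
            np.linalg.norm(A, axis=1) * np.linalg.norm(B, axis=1)
        )
        blocks["semantic"] = _abs_diff_with_tail(A, B, np.clip(cos, -1.0, 1.0))
    if "neighborhood" in model.views:
        A = cache_s.gat_vecs[si]
        B = cache_t.gat_vecs[ti]
        l2 = np.linalg.norm(A - B, axis=1)
        blocks["neighborhood"] = _abs_diff_with_tail(A, B, l2)
    if "path" in model.views:
        d3 = model.feature_dim("path")
        H3 = np.zeros((len(idx_pairs), d3))
        for row, (i, j) in enumerate(idx_pairs):
            Pi = cache_s.path_vecs[i]
            Pj = cache_t.path_vecs[j]
            S = None if Pi is None or Pj is None else path_similarity_matrix(Pi, Pj)
            H3[row] = path_features(S, model.bank, model.pooling)
        blocks["path"] = H3
    return blocks


def pair_features(
    model: AlignmentModel,
    tb_s: TerminologyBase,
    tb_t: TerminologyBase,
    e: str,
    e2: str,
    cache_s: EntityCache | None = None,
    cache_t: EntityCache | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(h1, h2, h3) for a single candidate pair, via the three views."""
    if e not in tb_s:
        raise DanglingIdError(f"unknown source id {e!r}")
    if e2 not in tb_t:
        raise DanglingIdError(f"unknown target id {e2!r}")
    cache_s = cache_s or precompute_cache(model, tb_s)
    cache_t = cache_t or precompute_cache(model, tb_t)
    i, j = cache_s.index[e], cache_t.index[e2]
    h1 = semantic_interaction(cache_s.name_vecs[i], cache_t.name_vecs[j])
    h2 = neighborhood_interaction(cache_s.gat_vecs[i], cache_t.gat_vecs[j])
    Pi, Pj = cache_s.path_vecs[i], cache_t.path_vecs[j]
    S = None if Pi is None or Pj is None else path_similarity_matrix(Pi, Pj)
    h3 = path_features(S, model.bank, model.pooling)
    return h1, h2, h3


def forward_scores(
    model: AlignmentModel, blocks: Mapping[str, np.ndarray], want_aux: bool = False
):
    """Batched gate + scorer forward pass over per-view feature matrices."""
    gated = []
    gates_cache: dict[str, np.ndarray] = {}
    for v in model.views:
        H = blocks[v]
        if model.use_gates:
            G = _sigmoid(H @ model.gates[v].weight.T)
            gates_cache[v] = G
            gated.append(G * H)
        else:
            gated.append(H)
    X = np.concatenate(gated, axis=1)
    Z = X @ model.scorer.w1.T + model.scorer.b1
    T = np.tanh(Z)
    s = T @ model.scorer.w2 + model.scorer.b2
    if not want_aux:
        return s
    return s, {"gates": gates_cache, "X": X, "T": T}


def backward_scores(
    model: AlignmentModel,
    blocks: Mapping[str, np.ndarray],
    aux: Mapping,
    ds: np.ndarray,
) -> dict[str, np.ndarray | float]:
    """Gradients of Σ_n ds_n · score_n w.r.t. gate and scorer parameters."""
    T = aux["T"]
    X = aux["X"]
    grads: dict[str, np.ndarray | float] = {}
    grads["b2"] = float(ds.sum())
    grads["w2"] = T.T @ ds
    dZ = (ds[:, None] * model.scorer.w2[None, :]) * (1.0 - T**2)
    grads["w1"] = dZ.T @ X
    grads["b1"] = dZ.sum(axis=0)
    dX = dZ @ model.scorer.w1
    offset = 0
    for v in model.views:
        H = blocks[v]
        d_v = H.shape[1]
        dXp = dX[:, offset : offset + d_v]
        offset += d_v
        if model.use_gates:
            G = aux["gates"][v]
            dG = dXp * H
            grads[f"gate_{v}"] = (dG * G * (1.0 - G)).T @ H
    return grads


def save_model(model: AlignmentModel, path: str | Path) -> None:
    """Serialize parameters + configuration to an .npz archive."""
    path = Path(path)
    meta = {
        "encoder_backend": model.encoder_backend,
        "d_enc": model.encoder.dim,
        "views": list(model.views),
        "use_gates": model.use_gates,
        "pooling": model.pooling,
        "path_n": model.path_n,
        "path_k": model.path_k,
        "max_paths": model.max_paths,
        "hidden": model.hidden,
        "rng_seed": model.rng_seed,
        "gat": {
            "heads": model.gat.config.heads,
            "layers": model.gat.config.layers,
            "leaky_slope": model.gat.config.leaky_slope,
            "neighbor_cap": model.gat.config.neighbor_cap,
            "aggregator": model.gat.config.aggregator,
        },
        "bank": {"mus": list(model.bank.mus), "sigmas": list(model.bank.sigmas)},
    }
    arrays: dict[str, np.ndarray] = {
        "proj_weight": model.projection.weight,
        "proj_bias": model.projection.bias,
        "scorer_w1": model.scorer.w1,
        "scorer_b1": model.scorer.b1,
        "scorer_w2": model.scorer.w2,
        "scorer_b2": np.array(model.scorer.b2),
    }
    for l, (W, q) in enumerate(zip(model.gat.weights, model.gat.attn)):
        arrays[f"gat_W{l}"] = W
        arrays[f"gat_q{l}"] = q
    for v, g in model.gates.items():
        arrays[f"gate_{v}"] = g.weight
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> AlignmentModel:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    model = AlignmentModel.build(
        rng_seed=meta["rng_seed"],
        encoder_backend=meta["encoder_backend"],
        d_enc=meta["d_enc"],
        d_proj=data["proj_weight"].shape[0],
        heads=meta["gat"]["heads"],
        gat_layers=meta["gat"]["layers"],
        leaky_slope=meta["gat"]["leaky_slope"],
        neighbor_cap=meta["gat"]["neighbor_cap"],
        aggregator=meta["gat"]["aggregator"],
        bank=KernelBank(mus=tuple(meta["bank"]["mus"]), sigmas=tuple(meta["bank"]["sigmas"])),
        views=tuple(meta["views"]),
        use_gates=meta["use_gates"],
        pooling=meta["pooling"],
        path_n=meta["path_n"],
        path_k=meta["path_k"],
        max_paths=meta["max_paths"],
        hidden=meta["hidden"],
    )
    model.projection = Projection(weight=data["proj_weight"], bias=data["proj_bias"])
    model.scorer = ScorerParams(
        w1=data["scorer_w1"],
        b1=data["scorer_b1"],
        w2=data["scorer_w2"],
        b2=float(data["scorer_b2"]),
    )
    model.gat.weights = [data[f"gat_W{l}"] for l in range(meta["gat"]["layers"])]
    model.gat.attn = [data[f"gat_q{l}"] for l in range(meta["gat"]["layers"])]
    model.gates = {v: GateParams(weight=data[f"gate_{v}"]) for v in meta["views"] if f"gate_{v}" in data}
    return model
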