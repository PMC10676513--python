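"""Pairwise margin training with k-NN hard-negative sampling.

The ranking objective is the hinge loss

    L = Σ_(e, e'+, e'-)  max{0, γ + d(e, e'+) − d(e, e'-)},

summed over training positives and their sampled negatives.  Negatives are
drawn per positive from a fixed pool of the ``candidate_pool`` target
entities nearest to the query in a rough (name-only) embedding space, with
the gold counterpart excluded; ``negatives_per_positive`` of them are
resampled uniformly each epoch.

Training runs in two stages:

1. *Representation stage* — the encoder projection is fit with ``d`` the
   l1 distance between projected name embeddings (fine-tuning the shared
   text representation on the prealigned seeds).
2. *Interaction stage* — gates and scorer are fit with ``d = −score(e, e')``
   over precomputed view features, so the fusion MLP is trained as a
   ranker under the same pairwise objective.

All updates use a small deterministic Adam optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import fusion as fu
from .encoder import Projection, TextEncoder, encode_name
from .termbase import AlignmentSeeds, TermbaseError, TerminologyBase, split_seeds

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "Adam",
    "margin_loss",
    "rough_embeddings",
    "negative_pool",
    "sample_negatives",
    "train",
]


@dataclass(frozen=True)
class TrainingConfig:
    margin: float = 1.0
    negatives_per_positive: int = 5
    candidate_pool: int = 50
    epochs: int = 20
    learning_rate: float = 0.01
    rng_seed: int = 0
    train_fraction: float = 0.3
    seed_cap: int = 15_000
    eval_every: int = 0  # 0: validation metrics only after the final epoch

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise TermbaseError(f"margin must be positive, got {self.margin}")
        if self.negatives_per_positive > self.candidate_pool:
            raise TermbaseError("negatives_per_positive cannot exceed candidate_pool")


@dataclass
class TrainedModel:
    model: fu.AlignmentModel
    config: TrainingConfig
    log: list[dict]
    cache_s: fu.EntityCache | None = None
    cache_t: fu.EntityCache | None = None


def margin_loss(d_pos: float, d_negs: Sequence[float], gamma: float) -> float:
    """Σ over negatives of max{0, γ + d_pos − d_neg}."""
    if gamma <= 0:
        raise TermbaseError(f"margin must be positive, got {gamma}")
    return float(sum(max(0.0, gamma + d_pos - d) for d in d_negs))


def rough_embeddings(
    tb: TerminologyBase, enc: TextEncoder, proj: Projection
) -> dict[str, np.ndarray]:
    """Name-only projected embeddings for every concept (pre-interaction)."""
    return {cid: encode_name(enc, proj, tb.concepts[cid]) for cid in tb.ids()}


def negative_pool(
    query_vec: np.ndarray,
    target_ids: Sequence[str],
    target_mat: np.ndarray,
    gold_id: str,
    p: int,
) -> list[str]:
    """The p target entities nearest to the query (l2), gold excluded.

    Ties in distance break lexicographically by id for determinism.
    """
    d = np.linalg.norm(target_mat - query_vec[None, :], axis=1)
    order = sorted(range(len(target_ids)), key=lambda i: (d[i], target_ids[i]))
    out = [target_ids[i] for i in order if target_ids[i] != gold_id]
    return out[:p]


def sample_negatives(
    e: str,
    pool: Mapping[str, np.ndarray],
    m: int,
    p: int,
    rng: np.random.Generator,
    gold_id: str,
    query_vec: np.ndarray,
) -> list[str]:
    """Sample m negatives for query ``e`` from its p-nearest rough-embedding pool."""
    ids = sorted(pool)
    mat = np.stack([pool[i] for i in ids])
    cands = negative_pool(query_vec, ids, mat, gold_id, p)
    if len(cands) < m:
        raise TermbaseError(
            f"only {len(cands)} negative candidates available for {e!r}, need {m}"
        )
    pick = rng.choice(len(cands), size=m, replace=False)
    return [cands[i] for i in pick]


class Adam:
    """Minimal deterministic Adam over a dict of named parameter arrays."""

    def __init__(self, lr: float = 0.01, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        for name, g in grads.items():
            g = np.asarray(g, dtype=np.float64)
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g**2
            mhat = self.m[name] / (1 - self.beta1**self.t)
            vhat = self.v[name] / (1 - self.beta2**self.t)
            params[name] = params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _hinge_terms(gamma: float, d_pos: np.ndarray, d_neg: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, gamma + d_pos - d_neg)


def _stage1_train(
    model: fu.AlignmentModel,
    cache_s: fu.EntityCache,
    cache_t: fu.EntityCache,
    train_pairs: Sequence[tuple[str, str]],
    pools: Sequence[Sequence[str]],
    cfg: TrainingConfig,
    rng: np.random.Generator,
    log: list[dict],
) -> None:
    """Fit the projection with d = l1 distance between projected name vectors."""
    Xs = cache_s.name_raw
    Xt = cache_t.name_raw
    qi = np.array([cache_s.index[e] for e, _ in train_pairs])
    gi = np.array([cache_t.index[g] for _, g in train_pairs])
    U_pos = Xs[qi] - Xt[gi]  # (P, d_enc)
    pool_idx = [np.array([cache_t.index[c] for c in pl]) for pl in pools]

    params = {"A": model.projection.weight.copy()}
    opt = Adam(lr=cfg.learning_rate)
    m = cfg.negatives_per_positive
    for epoch in range(cfg.epochs):
        neg_rows = np.stack(
            [pl[rng.choice(len(pl), size=m, replace=False)] for pl in pool_idx]
        )  # (P, m) target indices
        U_neg = Xs[qi][:, None, :] - Xt[neg_rows]  # (P, m, d_enc)
        A = params["A"]
        Ppos = U_pos @ A.T  # (P, d_proj)
        Pneg = U_neg @ A.T  # (P, m, d_proj)
        d_pos = np.abs(Ppos).sum(axis=1)
        d_neg = np.abs(Pneg).sum(axis=2)
        terms = _hinge_terms(cfg.margin, d_pos[:, None], d_neg)
        active = terms > 0
        loss = float(terms.sum())
        grad = np.einsum("pm,pd,pe->de", active.astype(np.float64), np.sign(Ppos), U_pos)
        grad -= np.einsum("pmd,pme->de", np.sign(Pneg) * active[:, :, None], U_neg)
        opt.step(params, {"A": grad})
        log.append({"stage": 1, "epoch": epoch + 1, "loss": loss})
    model.projection.weight = params["A"]


def _stage2_train(
    model: fu.AlignmentModel,
    blocks: Mapping[str, np.ndarray],
    pos_rows: np.ndarray,
    pool_rows: Sequence[np.ndarray],
    cfg: TrainingConfig,
    rng: np.random.Generator,
    log: list[dict],
) -> None:
    """Fit gates + scorer with d = −score over precomputed pair features."""
    m = cfg.negatives_per_positive
    params: dict[str, np.ndarray] = {
        "w1": model.scorer.w1,
        "b1": model.scorer.b1,
        "w2": model.scorer.w2,
        "b2": np.array(model.scorer.b2),
    }
    if model.use_gates:
        for v in model.views:
            params[f"gate_{v}"] = model.gates[v].weight
    opt = Adam(lr=cfg.learning_rate)
    n_rows = next(iter(blocks.values())).shape[0]
    for epoch in range(cfg.epochs):
        neg_rows = np.stack(
            [pr[rng.choice(len(pr), size=m, replace=False)] for pr in pool_rows]
        )  # (P, m) feature-row indices
        s, aux = fu.forward_scores(model, blocks, want_aux=True)
        d_pos = -s[pos_rows]
        d_neg = -s[neg_rows]
        terms = _hinge_terms(cfg.margin, d_pos[:, None], d_neg)
        active = terms > 0
        loss = float(terms.sum())
        ds = np.zeros(n_rows)
        np.add.at(ds, np.repeat(pos_rows, m), -active.ravel().astype(np.float64))
        np.add.at(ds, neg_rows.ravel(), active.ravel().astype(np.float64))
        grads = fu.backward_scores(model, blocks, aux, ds)
        opt.step(params, grads)
        model.scorer.w1 = params["w1"]
        model.scorer.b1 = params["b1"]
        model.scorer.w2 = params["w2"]
        model.scorer.b2 = float(params["b2"])
        if model.use_gates:
            for v in model.views:
                model.gates[v].weight = params[f"gate_{v}"]
        log.append({"stage": 2, "epoch": epoch + 1, "loss": loss})


def _build_pools(
    model: fu.AlignmentModel,
    cache_s: fu.EntityCache,
    cache_t: fu.EntityCache,
    train_pairs: Sequence[tuple[str, str]],
    p: int,
    m: int,
) -> list[list[str]]:
    pools = []
    for e, gold in train_pairs:
        pool = negative_pool(
            cache_s.name_vecs[cache_s.index[e]], cache_t.ids, cache_t.name_vecs, gold, p
        )
        if len(pool) < m:
            raise TermbaseError(
                f"only {len(pool)} negative candidates for {e!r}, need {m}"
            )
        pools.append(pool)
    return pools


def train(
    tb_s: TerminologyBase,
    tb_t: TerminologyBase,
    seeds: AlignmentSeeds,
    config: TrainingConfig | None = None,
    model: fu.AlignmentModel | None = None,
) -> TrainedModel:
    """Two-stage pairwise margin training; returns the model and epoch log.

    Unsplit seeds are split with the configured train fraction and cap.
    Validation Hits@1/Hits@10 are logged after the final epoch (and every
    ``eval_every`` interaction epochs when set).
    """
    from . import evaluation  # local import: evaluation also imports training

    cfg = config or TrainingConfig()
    if seeds.labels is None:
        seeds = split_seeds(seeds, cfg.train_fraction, cfg.seed_cap, cfg.rng_seed)
    train_pairs = seeds.train
    if not train_pairs:
        raise TermbaseError("empty training split")
    model = model or fu.AlignmentModel.build(rng_seed=cfg.rng_seed)
    rng = np.random.default_rng(cfg.rng_seed)
    log: list[dict] = []

    # Stage 1: fit the projection on name representations.
    cache_s = fu.precompute_cache(model, tb_s)
    cache_t = fu.precompute_cache(model, tb_t)
    pools1 = _build_pools(
        model, cache_s, cache_t, train_pairs, cfg.candidate_pool, cfg.negatives_per_positive
    )
    _stage1_train(model, cache_s, cache_t, train_pairs, pools1, cfg, rng, log)

    # Re-project caches under the trained projection; rebuild pools once from
    # the updated rough embeddings.
    cache_s = fu.refresh_cache(model, tb_s, cache_s)
    cache_t = fu.refresh_cache(model, tb_t, cache_t)
    pools2 = _build_pools(
        model, cache_s, cache_t, train_pairs, cfg.candidate_pool, cfg.negatives_per_positive
    )

    # Stage 2: features for positives and every pool candidate, then fit
    # gates + scorer as a ranker.
    idx_pairs: list[tuple[int, int]] = []
    pos_rows = []
    pool_rows: list[np.ndarray] = []
    for (e, gold), pool in zip(train_pairs, pools2):
        pos_rows.append(len(idx_pairs))
        idx_pairs.append((cache_s.index[e], cache_t.index[gold]))
        rows = []
        for c in pool:
            rows.append(len(idx_pairs))
            idx_pairs.append((cache_s.index[e], cache_t.index[c]))
        pool_rows.append(np.array(rows))
    blocks = fu.feature_blocks(model, cache_s, cache_t, idx_pairs)
    _stage2_train(model, blocks, np.array(pos_rows), pool_rows, cfg, rng, log)

    # Validation metrics on the held-out split.
    val = seeds.validation
    if val:
        result = evaluation.rank_all(
            model,
            tb_s,
            tb_t,
            queries=[s for s, _ in val],
            candidates=cache_t.ids,
            cache_s=cache_s,
            cache_t=cache_t,
        )
        gold = AlignmentSeeds(pairs=list(val))
        log.append(
            {
                "stage": 2,
                "epoch": cfg.epochs,
                "validation_hits_at_1": evaluation.hits_at_k(result, gold, 1),
                "validation_hits_at_10": evaluation.hits_at_k(result, gold, 10),
            }
        )
    return TrainedModel(model=model, config=cfg, log=log, cache_s=cache_s, cache_t=cache_t)
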