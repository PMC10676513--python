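"""Candidate ranking, Hits@k metrics, ablation runs, and training-fraction sweeps.

For each query entity of the source base the aligner scores every candidate
of the target base and sorts descending (ties broken lexicographically by
candidate id).  Hits@k is the fraction of queries whose gold counterpart
appears within the top k.  The ablation driver retrains the interaction
stage per variant (view removal, gate removal, GCN-style mean aggregation,
max pooling) while sharing the representation stage and entity caches; the
sweep driver retrains on nested subsets of the training split with the
validation split held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from . import fusion as fu
from .semantic import semantic_similarity
from .termbase import AlignmentSeeds, DanglingIdError, TermbaseError, TerminologyBase, split_seeds

__all__ = [
    "RankingResult",
    "rank_all",
    "hits_at_k",
    "sweep",
    "ablate",
    "DEFAULT_VARIANTS",
]


@dataclass
class RankingResult:
    """Per-query candidate orderings (descending score)."""

    queries: list[str]
    ranked: dict[str, list[str]]

    def rank_of(self, query: str, target: str) -> int:
        """1-based rank of ``target`` among the query's candidates."""
        try:
            return self.ranked[query].index(target) + 1
        except ValueError:
            raise TermbaseError(
                f"gold target {target!r} not among candidates for query {query!r}"
            ) from None


def rank_all(
    model: fu.AlignmentModel,
    tb_s: TerminologyBase,
    tb_t: TerminologyBase,
    queries: Sequence[str],
    candidates: Sequence[str],
    cache_s: fu.EntityCache | None = None,
    cache_t: fu.EntityCache | None = None,
    scorer: str | Callable[[str, str], float] = "model",
) -> RankingResult:
    """Score every query against every candidate and sort descending.

    ``scorer`` selects the trained fusion model (``"model"``), the plain
    cosine of projected name embeddings (``"semantic_cosine"``), or an
    arbitrary callable ``f(query_id, candidate_id) -> float``.
    """
    if not queries or not candidates:
        raise TermbaseError("queries and candidates must be non-empty")
    for q in queries:
        if q not in tb_s:
            raise DanglingIdError(f"unknown query id {q!r}")
    for c in candidates:
        if c not in tb_t:
            raise DanglingIdError(f"unknown candidate id {c!r}")
    cand_list = list(candidates)
    ranked: dict[str, list[str]] = {}
    if callable(scorer):
        for q in queries:
            s = np.array([scorer(q, c) for c in cand_list])
            order = sorted(range(len(cand_list)), key=lambda i: (-s[i], cand_list[i]))
            ranked[q] = [cand_list[i] for i in order]
        return RankingResult(queries=list(queries), ranked=ranked)

    cache_s = cache_s or fu.precompute_cache(model, tb_s)
    cache_t = cache_t or fu.precompute_cache(model, tb_t)
    ci = [cache_t.index[c] for c in cand_list]
    for q in queries:
        qi = cache_s.index[q]
        if scorer == "semantic_cosine":
            v = cache_s.name_vecs[qi]
            M = cache_t.name_vecs[ci]
            s = M @ v / (np.linalg.norm(M, axis=1) * np.linalg.norm(v))
        elif scorer == "model":
            blocks = fu.feature_blocks(model, cache_s, cache_t, [(qi, j) for j in ci])
            s = fu.forward_scores(model, blocks)
        else:
            raise TermbaseError(f"unknown scorer {scorer!r}")
        order = sorted(range(len(cand_list)), key=lambda i: (-s[i], cand_list[i]))
        ranked[q] = [cand_list[i] for i in order]
    return RankingResult(queries=list(queries), ranked=ranked)


def hits_at_k(
    result: RankingResult, gold: AlignmentSeeds | Mapping[str, str], k: int
) -> float:
    """Fraction of queries whose gold target ranks within the top k."""
    if k < 1:
        raise TermbaseError(f"k must be >= 1, got {k}")
    gold_map = gold.as_dict() if isinstance(gold, AlignmentSeeds) else dict(gold)
    hits = 0
    for q in result.queries:
        if q not in gold_map:
            raise TermbaseError(f"query {q!r} has no gold target")
        if result.rank_of(q, gold_map[q]) <= k:
            hits += 1
    return hits / len(result.queries)


# Ablation variants mirroring the usual removal/replacement experiments.
DEFAULT_VARIANTS: dict[str, dict] = {
    "full": {},
    "no_semantic": {"views": ("neighborhood", "path")},
    "no_neighborhood": {"views": ("semantic", "path")},
    "no_path": {"views": ("semantic", "neighborhood")},
    "semantic_only": {"views": ("semantic",)},
    "no_gates": {"use_gates": False},
    "mean_aggregation": {"aggregator": "mean"},
    "max_pooling": {"pooling": "max"},
    "kernel_plus_max_pooling": {"pooling": "kernel+max"},
}


def _variant_model(base: fu.AlignmentModel, overrides: Mapping) -> fu.AlignmentModel:
    model = fu.AlignmentModel.build(
        rng_seed=base.rng_seed,
        encoder_backend=base.encoder_backend,
        d_enc=base.encoder.dim,
        d_proj=base.projection.d_proj,
        heads=base.gat.config.heads,
        gat_layers=base.gat.config.layers,
        leaky_slope=base.gat.config.leaky_slope,
        neighbor_cap=base.gat.config.neighbor_cap,
        bank=base.bank,
        views=overrides.get("views", base.views),
        use_gates=overrides.get("use_gates", base.use_gates),
        pooling=overrides.get("pooling", base.pooling),
        path_n=base.path_n,
        path_k=base.path_k,
        max_paths=base.max_paths,
        hidden=base.hidden,
        aggregator=overrides.get("aggregator", base.gat.config.aggregator),
    )
    model.projection = base.projection  # share the stage-1-trained projection
    return model


def ablate(
    tb_s: TerminologyBase,
    tb_t: TerminologyBase,
    seeds: AlignmentSeeds,
    config=None,
    variants: Mapping[str, Mapping] | None = None,
    model: fu.AlignmentModel | None = None,
) -> dict[str, dict[str, float]]:
    """Train and evaluate ablation variants, sharing the representation stage.

    The projection is fit once on the full model; each variant then retrains
    its own gates and scorer (interaction stage) with identical negative
    draws and reports validation Hits@1/Hits@10.
    """
    from . import training as tr

    cfg = config or tr.TrainingConfig()
    variants = dict(variants or DEFAULT_VARIANTS)
    if seeds.labels is None:
        seeds = split_seeds(seeds, cfg.train_fraction, cfg.seed_cap, cfg.rng_seed)
    base = model or fu.AlignmentModel.build(rng_seed=cfg.rng_seed)
    train_pairs = seeds.train
    if not train_pairs:
        raise TermbaseError("empty training split")

    # Stage 1 once, on the full model.
    rng = np.random.default_rng(cfg.rng_seed)
    log: list[dict] = []
    cache_s = fu.precompute_cache(base, tb_s)
    cache_t = fu.precompute_cache(base, tb_t)
    pools1 = tr._build_pools(
        base, cache_s, cache_t, train_pairs, cfg.candidate_pool, cfg.negatives_per_positive
    )
    tr._stage1_train(base, cache_s, cache_t, train_pairs, pools1, cfg, rng, log)
    cache_s = fu.refresh_cache(base, tb_s, cache_s)
    cache_t = fu.refresh_cache(base, tb_t, cache_t)
    pools2 = tr._build_pools(
        base, cache_s, cache_t, train_pairs, cfg.candidate_pool, cfg.negatives_per_positive
    )

    idx_pairs: list[tuple[int, int]] = []
    pos_rows: list[int] = []
    pool_rows: list[np.ndarray] = []
    for (e, gold), pool in zip(train_pairs, pools2):
        pos_rows.append(len(idx_pairs))
        idx_pairs.append((cache_s.index[e], cache_t.index[gold]))
        rows = []
        for c in pool:
            rows.append(len(idx_pairs))
            idx_pairs.append((cache_s.index[e], cache_t.index[c]))
        pool_rows.append(np.array(rows))
    pos_arr = np.array(pos_rows)

    val = seeds.validation
    gold_map = dict(val)
    results: dict[str, dict[str, float]] = {}
    for name, overrides in variants.items():
        vm = _variant_model(base, overrides)
        vcs, vct = cache_s, cache_t
        if vm.gat.config.aggregator != base.gat.config.aggregator and "neighborhood" in vm.views:
            vcs = fu.refresh_cache(vm, tb_s, cache_s)
            vct = fu.refresh_cache(vm, tb_t, cache_t)
        blocks = fu.feature_blocks(vm, vcs, vct, idx_pairs)
        vrng = np.random.default_rng(cfg.rng_seed + 1)
        vlog: list[dict] = []
        tr._stage2_train(vm, blocks, pos_arr, pool_rows, cfg, vrng, vlog)
        metrics: dict[str, float] = {"final_loss": vlog[-1]["loss"]}
        if val:
            result = rank_all(
                vm,
                tb_s,
                tb_t,
                queries=[s for s, _ in val],
                candidates=vct.ids,
                cache_s=vcs,
                cache_t=vct,
            )
            metrics["hits_at_1"] = hits_at_k(result, gold_map, 1)
            metrics["hits_at_10"] = hits_at_k(result, gold_map, 10)
        results[name] = metrics
    return results


def sweep(
    tb_s: TerminologyBase,
    tb_t: TerminologyBase,
    seeds: AlignmentSeeds,
    config=None,
    fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.5, 0.7, 1.0),
    model_builder: Callable[[int], fu.AlignmentModel] | None = None,
) -> list[dict[str, float]]:
    """Retrain on nested fractions of the training split; validation fixed.

    Subsets are nested (the 5% subset is contained in the 10% subset, etc.)
    by taking prefixes of one fixed shuffle of the training pairs.
    """
    from . import training as tr

    cfg = config or tr.TrainingConfig()
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise TermbaseError(f"fractions must lie in (0, 1], got {f}")
    if seeds.labels is None:
        seeds = split_seeds(seeds, cfg.train_fraction, cfg.seed_cap, cfg.rng_seed)
    train_pairs = list(seeds.train)
    val_pairs = list(seeds.validation)
    rng = np.random.default_rng(cfg.rng_seed)
    order = rng.permutation(len(train_pairs))
    rows: list[dict[str, float]] = []
    for f in fractions:
        n_sub = int(round(f * len(train_pairs)))
        if n_sub < 1:
            raise TermbaseError(f"fraction {f} yields an empty training set")
        chosen = set(order[:n_sub].tolist())
        # membership from the shuffle prefix, original order preserved, so
        # fraction 1.0 reproduces a plain training run exactly
        sub = [p for i, p in enumerate(train_pairs) if i in chosen]
        labeled = AlignmentSeeds(
            pairs=sub + val_pairs, labels=["train"] * len(sub) + ["validation"] * len(val_pairs)
        )
        model = model_builder(cfg.rng_seed) if model_builder else None
        trained = tr.train(tb_s, tb_t, labeled, cfg, model=model)
        final = trained.log[-1]
        rows.append(
            {
                "fraction": f,
                "n_train": n_sub,
                "train_sources": [s for s, _ in sub],
                "hits_at_1": final.get("validation_hits_at_1", float("nan")),
                "hits_at_10": final.get("validation_hits_at_10", float("nan")),
            }
        )
    return rows
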