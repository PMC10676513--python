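"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately written in a different style from the
library (explicit Python loops, full-chain enumeration) so they can serve
as independent cross-checks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from termalign import Concept, TerminologyBase, make_test_encoder
from termalign.pathing import neighbors


@pytest.fixture
def chain_tb() -> TerminologyBase:
    """Three-concept chain: A's parent is B, B's parent is C."""
    tb = TerminologyBase(
        concepts={
            "A": Concept("A", "abdominal pain"),
            "B": Concept("B", "abdominal and pelvic pain"),
            "C": Concept("C", "symptoms and signs"),
        },
        hierarchy={("A", "B"), ("B", "C")},
    )
    return tb.validate()


@pytest.fixture
def diamond_tb() -> TerminologyBase:
    """E has two parents (P1, P2) and one child (D)."""
    tb = TerminologyBase(
        concepts={
            "P1": Concept("P1", "digestive findings"),
            "P2": Concept("P2", "abdominal findings"),
            "E": Concept("E", "abdominal pain"),
            "D": Concept("D", "upper abdominal pain"),
        },
        hierarchy={("E", "P1"), ("E", "P2"), ("D", "E")},
    )
    return tb.validate()


@pytest.fixture
def enc64():
    return make_test_encoder(dim=64, rng_seed=0)


# ---------------------------------------------------------------------------
# Random-structure generators
# ---------------------------------------------------------------------------


def random_dag(rng: np.random.Generator, max_nodes: int = 20, p: float = 0.3) -> TerminologyBase:
    """Random DAG: edges only from later to earlier ids (child -> parent)."""
    n = int(rng.integers(2, max_nodes + 1))
    ids = [f"N{i:02d}" for i in range(n)]
    hierarchy = set()
    for j in range(1, n):
        for i in range(j):
            if rng.random() < p:
                hierarchy.add((ids[j], ids[i]))
    concepts = {cid: Concept(cid, f"term {cid.lower()}") for cid in ids}
    return TerminologyBase(concepts=concepts, hierarchy=hierarchy)


def random_digraph_edges(rng: np.random.Generator, max_nodes: int = 30, p: float = 0.1):
    """Arbitrary random digraph (may contain cycles)."""
    n = int(rng.integers(2, max_nodes + 1))
    ids = [f"N{i:02d}" for i in range(n)]
    edges = {
        (ids[a], ids[b])
        for a in range(n)
        for b in range(n)
        if a != b and rng.random() < p
    }
    return ids, edges


def kahn_is_acyclic(node_ids, edges) -> bool:
    """Independent acyclicity oracle: Kahn's topological sort."""
    out_deg = {i: 0 for i in node_ids}
    preds: dict[str, list[str]] = {i: [] for i in node_ids}
    for child, parent in edges:
        out_deg[child] += 1
        preds[parent].append(child)
    queue = [i for i in node_ids if out_deg[i] == 0]
    seen = 0
    while queue:
        node = queue.pop()
        seen += 1
        for c in preds[node]:
            out_deg[c] -= 1
            if out_deg[c] == 0:
                queue.append(c)
    return seen == len(node_ids)


# ---------------------------------------------------------------------------
# Path-window oracle: enumerate full root-to-leaf chains, then window.
# ---------------------------------------------------------------------------


def _maximal_up_chains(tb: TerminologyBase, e: str) -> list[list[str]]:
    chains = []
    stack = [[e]]
    while stack:
        chain = stack.pop()
        ps = tb.parents(chain[-1])
        if not ps:
            chains.append(chain)
        else:
            for parent in ps:
                stack.append(chain + [parent])
    return chains


def _maximal_down_chains(tb: TerminologyBase, e: str) -> list[list[str]]:
    chains = []
    stack = [[e]]
    while stack:
        chain = stack.pop()
        cs = tb.children(chain[-1])
        if not cs:
            chains.append(chain)
        else:
            for child in cs:
                stack.append(chain + [child])
    return chains


def window_oracle(tb: TerminologyBase, e: str, n: int, k: int) -> set[tuple[tuple[str, ...], int]]:
    """All (path ids, seed index) windows with <= n-k ancestors, <= k-1 children."""
    up, down = n - k, k - 1
    out = set()
    for uc in _maximal_up_chains(tb, e):
        ancestors_near_to_far = uc[1:]
        for dc in _maximal_down_chains(tb, e):
            descendants = dc[1:]
            anc = ancestors_near_to_far[:up]
            desc = descendants[:down]
            ids = tuple(reversed(anc)) + (e,) + tuple(desc)
            out.add((ids, len(anc)))
    return out


# ---------------------------------------------------------------------------
# Kernel-pooling oracle: explicit double loops over the similarity matrix.
# ---------------------------------------------------------------------------


def kernel_pooling_oracle(S: np.ndarray, mus, sigmas, eps: float = 1e-10) -> np.ndarray:
    rows, cols = S.shape
    row_part = []
    for kk in range(len(mus)):
        total = 0.0
        for i in range(rows):
            soft = sum(
                math.exp(-((S[i, j] - mus[kk]) ** 2) / (2 * sigmas[kk] ** 2))
                for j in range(cols)
            )
            total += math.log(max(soft, eps))
        row_part.append(total)
    col_part = []
    for kk in range(len(mus)):
        total = 0.0
        for j in range(cols):
            soft = sum(
                math.exp(-((S[i, j] - mus[kk]) ** 2) / (2 * sigmas[kk] ** 2))
                for i in range(rows)
            )
            total += math.log(max(soft, eps))
        col_part.append(total)
    return np.array(row_part + col_part)


# ---------------------------------------------------------------------------
# Dense GAT oracle: explicit per-node, per-head loops with a masked alpha.
# ---------------------------------------------------------------------------


def dense_gat_oracle(params, tb: TerminologyBase, node_embeddings) -> dict[str, np.ndarray]:
    cfg = params.config
    ids = tb.ids()
    H = np.stack([np.asarray(node_embeddings[i], dtype=float) for i in ids])
    index = {cid: i for i, cid in enumerate(ids)}

    def leaky(x):
        return x if x > 0 else cfg.leaky_slope * x

    def elu(x):
        return np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1)

    for layer in range(cfg.layers):
        W = params.weights[layer]
        q = params.attn[layer]
        d = H.shape[1]
        out = np.zeros_like(H)
        for i, cid in enumerate(ids):
            nbr = list(neighbors(tb, cid, cap=cfg.neighbor_cap).neighbor_ids)
            js = [index[x] for x in nbr] if nbr else [i]
            acc = np.zeros(d)
            for kk in range(cfg.heads):
                c = np.array(
                    [
                        leaky(
                            float(
                                q[kk] @ np.concatenate([W[kk] @ H[i], W[kk] @ H[j]])
                            )
                        )
                        for j in js
                    ]
                )
                alpha = np.exp(c - c.max())
                alpha = alpha / alpha.sum()
                for a, j in zip(alpha, js):
                    acc += a * (W[kk] @ H[j])
            out[i] = acc / cfg.heads
        H = elu(out)
    return {cid: H[index[cid]] for cid in ids}
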