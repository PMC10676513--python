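"""Neighbor sets and hierarchical-path extraction/serialization.

A hierarchical path for a concept ``e`` is a top-down chain
``ancestors → e → descendants`` drawn from the hierarchy DAG.  Two
parameters shape it: the total target length ``n`` and the 1-based seed
position ``k``, giving up to ``n - k`` ancestors above the seed and up to
``k - 1`` descendants below it (e.g. n=5, k=2 → 3 ancestors, 1 child).
Near roots or leaves the window truncates — shorter paths are allowed,
never padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .termbase import DanglingIdError, TermbaseError, TerminologyBase

__all__ = [
    "NeighborSet",
    "HierarchicalPath",
    "PathTokenSequence",
    "CLS",
    "SEP",
    "neighbors",
    "extract_paths",
    "path_to_sequence",
]

CLS = "[CLS]"
SEP = "[SEP]"


@dataclass(frozen=True)
class NeighborSet:
    """Deterministically ordered neighbors of a concept.

    Order: hierarchy parents, then hierarchy children, then attribute
    neighbors; lexicographic within each category; duplicates dropped
    keeping the earliest category.
    """

    center_id: str
    neighbor_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.neighbor_ids)


@dataclass(frozen=True)
class HierarchicalPath:
    """Ordered top-down concept chain with the seed at 1-based position k."""

    concept_ids: tuple[str, ...]
    seed_index: int  # 0-based position of the seed within concept_ids

    @property
    def n(self) -> int:
        return len(self.concept_ids)

    @property
    def k(self) -> int:
        """1-based seed position counted from the bottom of the window.

        ``k - 1`` concepts lie below the seed, ``n - k`` above it.
        """
        return self.n - self.seed_index

    @property
    def seed_id(self) -> str:
        return self.concept_ids[self.seed_index]

    @property
    def ancestors(self) -> tuple[str, ...]:
        return self.concept_ids[: self.seed_index]

    @property
    def descendants(self) -> tuple[str, ...]:
        return self.concept_ids[self.seed_index + 1 :]


@dataclass(frozen=True)
class PathTokenSequence:
    """Serialized path: CLS, ancestor block, SEP, seed, SEP, child block, SEP.

    Empty blocks are omitted from ``tokens`` but every separator is kept, so
    a singleton path serializes as ``[CLS, SEP, name, SEP, SEP]``.
    """

    tokens: tuple[str, ...]

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def neighbors(tb: TerminologyBase, e: str, cap: int = 25) -> NeighborSet:
    """All hierarchy- and attribute-adjacent concepts of ``e``, capped.

    Truncation keeps the first ``cap`` ids in the deterministic category /
    lexicographic order.
    """
    if e not in tb:
        raise DanglingIdError(f"unknown concept id {e!r}")
    if cap < 1:
        raise TermbaseError(f"neighbor cap must be >= 1, got {cap}")
    ordered: list[str] = []
    seen: set[str] = set()
    for group in (tb.parents(e), tb.children(e), tb.attribute_neighbors(e)):
        for nid in group:
            if nid not in seen and nid != e:
                seen.add(nid)
                ordered.append(nid)
    return NeighborSet(center_id=e, neighbor_ids=tuple(ordered[:cap]))


def _chains(next_of, start: str, limit: int) -> list[tuple[str, ...]]:
    """Maximal near-to-far chains from ``start`` of length <= limit.

    A chain stops only when the limit is reached or the DAG runs out;
    branches are explored depth-first in lexicographic order.
    """
    if limit == 0:
        return [()]
    steps = next_of(start)
    if not steps:
        return [()]
    out: list[tuple[str, ...]] = []
    for nxt in steps:  # next_of returns sorted ids
        for tail in _chains(next_of, nxt, limit - 1):
            out.append((nxt,) + tail)
    return out


def extract_paths(
    tb: TerminologyBase,
    e: str,
    n: int = 5,
    k: int = 2,
    max_paths: int = 4,
) -> list[HierarchicalPath]:
    """Enumerate hierarchical paths of ``e`` as windows over root-to-leaf chains.

    Each path carries up to ``n - k`` ancestors and ``k - 1`` descendants,
    truncated where the DAG runs out.  Enumeration is depth-first with
    lexicographic tie-breaking (ancestor chains outer, descendant chains
    inner); at most ``max_paths`` paths are returned.
    """
    if e not in tb:
        raise DanglingIdError(f"unknown concept id {e!r}")
    if n < 1:
        raise TermbaseError(f"path length n must be >= 1, got {n}")
    if not 1 <= k <= n:
        raise TermbaseError(f"seed position k={k} must satisfy 1 <= k <= n={n}")
    if max_paths < 1:
        raise TermbaseError(f"max_paths must be >= 1, got {max_paths}")
    up = _chains(tb.parents, e, n - k)  # near-to-far ancestor chains
    down = _chains(tb.children, e, k - 1)  # near-to-far descendant chains
    paths: list[HierarchicalPath] = []
    for anc in up:
        for desc in down:
            ids = tuple(reversed(anc)) + (e,) + desc
            paths.append(HierarchicalPath(concept_ids=ids, seed_index=len(anc)))
            if len(paths) >= max_paths:
                return paths
    return paths


def path_to_sequence(path: HierarchicalPath, tb: TerminologyBase) -> PathTokenSequence:
    """Serialize a path into the CLS/SEP token layout with concept names.

    The ancestor block lists names top-down, the descendant block near-to-far,
    space-joined within each block.
    """
    for cid in path.concept_ids:
        if cid not in tb:
            raise DanglingIdError(f"path references unknown id {cid!r}")
        if not tb.concepts[cid].name:
            raise TermbaseError(f"concept {cid!r} has no name to serialize")
    anc_block = " ".join(tb.name(c) for c in path.ancestors)
    child_block = " ".join(tb.name(c) for c in path.descendants)
    tokens: list[str] = [CLS]
    if anc_block:
        tokens.append(anc_block)
    tokens += [SEP, tb.name(path.seed_id), SEP]
    if child_block:
        tokens.append(child_block)
    tokens.append(SEP)
    return PathTokenSequence(tokens=tuple(tokens))
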