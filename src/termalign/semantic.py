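"""Semantic view: name-embedding interaction.

The semantic interaction between two concepts is the cosine similarity of
their projected name embeddings; for feature-level gating the view also
exposes the elementwise absolute difference with the cosine appended as the
final coordinate (``h1 = |v - v'| ⊕ [cos]``).
"""

from __future__ import annotations

import numpy as np

from .termbase import TermbaseError

__all__ = ["semantic_similarity", "semantic_interaction"]


def semantic_similarity(v: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity of two name vectors."""
    n1 = np.linalg.norm(v)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise TermbaseError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(v, v2) / (n1 * n2))


def semantic_interaction(v: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Feature vector h1 = |v - v'| concatenated with the cosine similarity."""
    if v.shape != v2.shape:
        raise TermbaseError(f"dimension mismatch: {v.shape} vs {v2.shape}")
    return np.concatenate([np.abs(v - v2), [semantic_similarity(v, v2)]])
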