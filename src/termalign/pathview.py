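"""Path view: path-set cosine similarity matrix and RBF kernel pooling.

Given the path-embedding sets of two concepts, the view builds the full
pairwise cosine matrix ``S`` and summarizes it with a bank of Gaussian
kernels: each kernel with mean μ_k and width σ_k soft-counts how many
entries of a row (or column) sit near μ_k,

    K_k(S_i) = Σ_j exp(-(S_ij - μ_k)² / (2 σ_k²)),

and the interaction vector concatenates row-wise and column-wise sums of
log kernel features (a 2K-vector).  The default bank follows the usual
kernel-pooling convention: one exact-match kernel (μ=1, σ=0.001) plus ten
kernels with μ from -0.9 to 0.9 in steps of 0.2, σ=0.1.  Concepts without
paths contribute an all-zero vector so the fusion input keeps a fixed
dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .termbase import TermbaseError

__all__ = [
    "KernelBank",
    "SimilarityMatrix",
    "path_similarity_matrix",
    "kernel_row_features",
    "path_interaction",
    "max_pool_interaction",
    "path_features",
    "path_feature_dim",
]

LOG_EPS = 1e-10

SimilarityMatrix = np.ndarray  # rows: paths of e, columns: paths of e'

PoolingMode = Literal["kernel", "max", "kernel+max"]


@dataclass(frozen=True)
class KernelBank:
    """RBF kernel means and widths used to pool similarity matrices."""

    mus: tuple[float, ...]
    sigmas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mus) != len(self.sigmas) or not self.mus:
            raise TermbaseError("kernel bank needs matching, non-empty mus/sigmas")
        if any(s <= 0 for s in self.sigmas):
            raise TermbaseError("kernel widths must be positive")

    @property
    def K(self) -> int:
        return len(self.mus)

    @classmethod
    def default(cls, n_soft: int = 10, exact_sigma: float = 1e-3, sigma: float = 0.1) -> "KernelBank":
        """Exact-match kernel plus ``n_soft`` evenly spaced soft kernels."""
        step = 2.0 / n_soft
        mus = [1.0] + [round(-1.0 + step / 2 + i * step, 10) for i in range(n_soft)]
        sigmas = [exact_sigma] + [sigma] * n_soft
        return cls(mus=tuple(mus), sigmas=tuple(sigmas))


def path_similarity_matrix(paths_e: np.ndarray, paths_e2: np.ndarray) -> SimilarityMatrix:
    """Pairwise cosine matrix between two path-embedding lists (m, d) x (p, d)."""
    A = np.atleast_2d(np.asarray(paths_e, dtype=np.float64))
    B = np.atleast_2d(np.asarray(paths_e2, dtype=np.float64))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise TermbaseError("path similarity requires non-empty path sets")
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise TermbaseError("zero-norm path embedding")
    S = (A / na[:, None]) @ (B / nb[:, None]).T
    return np.clip(S, -1.0, 1.0)


def kernel_row_features(row: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Per-kernel Gaussian soft-count over one row of the similarity matrix."""
    row = np.asarray(row, dtype=np.float64)
    if row.size == 0:
        raise TermbaseError("kernel features of an empty row")
    mus = np.asarray(bank.mus)[:, None]
    sigmas = np.asarray(bank.sigmas)[:, None]
    return np.exp(-((row[None, :] - mus) ** 2) / (2.0 * sigmas**2)).sum(axis=1)


def _log_kernel_sum(S: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Σ_i log K_row(S_i) over the rows of S, shape (K,)."""
    mus = np.asarray(bank.mus)[None, None, :]
    sigmas = np.asarray(bank.sigmas)[None, None, :]
    k = np.exp(-((S[:, :, None] - mus) ** 2) / (2.0 * sigmas**2)).sum(axis=1)  # (rows, K)
    return np.log(np.maximum(k, LOG_EPS)).sum(axis=0)


def path_interaction(S: SimilarityMatrix | None, bank: KernelBank) -> np.ndarray:
    """h3: row-wise ⊕ column-wise log-kernel sums (2K-vector).

    ``S=None`` (either concept has no paths) yields the all-zero vector.
    """
    if S is None or S.size == 0:
        return np.zeros(2 * bank.K)
    S = np.atleast_2d(np.asarray(S, dtype=np.float64))
    return np.concatenate([_log_kernel_sum(S, bank), _log_kernel_sum(S.T, bank)])


def max_pool_interaction(S: SimilarityMatrix | None) -> np.ndarray:
    """Ablation pooling: the single maximum entry of S (zero when pathless)."""
    if S is None or S.size == 0:
        return np.zeros(1)
    return np.array([float(np.max(S))])


def path_feature_dim(bank: KernelBank, pooling: PoolingMode = "kernel") -> int:
    return {"kernel": 2 * bank.K, "max": 1, "kernel+max": 2 * bank.K + 1}[pooling]


def path_features(
    S: SimilarityMatrix | None, bank: KernelBank, pooling: PoolingMode = "kernel"
) -> np.ndarray:
    """h3 under the configured pooling mode (kernel, max, or both)."""
    if pooling == "kernel":
        return path_interaction(S, bank)
    if pooling == "max":
        return max_pool_interaction(S)
    if pooling == "kernel+max":
        return np.concatenate([path_interaction(S, bank), max_pool_interaction(S)])
    raise TermbaseError(f"unknown pooling mode {pooling!r}")
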