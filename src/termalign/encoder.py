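"""Text-encoder contract, the deterministic trigram test encoder, and the
learnable projection that maps encoder vectors to the interaction dimension.

The pipeline treats the encoder as an opaque backend producing a fixed-size
vector per input string (the sequence-level CLS reading of a transformer, or
the hashed character-trigram vector of the built-in test encoder).  A single
shared encoder serves concept names and serialized hierarchical paths; the
projection (a fully connected layer, default 768 → 300) is the only
trainable piece at this level.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .termbase import Concept, TermbaseError
from .pathing import PathTokenSequence

__all__ = [
    "TextEncoder",
    "TrigramHashEncoder",
    "PretrainedEncoder",
    "Projection",
    "make_test_encoder",
    "get_encoder",
    "encode_name",
    "encode_path",
]


@runtime_checkable
class TextEncoder(Protocol):
    """Deterministic map from a raw string to a fixed-dimension vector."""

    dim: int

    def encode(self, text: str) -> np.ndarray: ...


@dataclass(frozen=True)
class TrigramHashEncoder:
    """Seeded character-trigram hashing encoder (desk-scale text encoder).

    Each trigram of the lowercased, space-padded input hashes (keyed BLAKE2b,
    so stable across processes) to an index and a sign in a ``dim``-vector;
    the result is L2-normalized.  Near-identical strings share most trigrams
    and therefore have high cosine similarity.
    """

    dim: int = 768
    rng_seed: int = 0

    def encode(self, text: str) -> np.ndarray:
        if not text:
            raise TermbaseError("cannot encode an empty string")
        key = int(self.rng_seed).to_bytes(8, "little", signed=False)
        s = f" {text.lower()} "
        v = np.zeros(self.dim, dtype=np.float64)
        for i in range(len(s) - 2):
            h = int.from_bytes(
                hashlib.blake2b(s[i : i + 3].encode("utf-8"), key=key, digest_size=8).digest(),
                "little",
            )
            idx = h % self.dim
            sign = 1.0 if (h >> 60) & 1 else -1.0
            v[idx] += sign
        norm = np.linalg.norm(v)
        if norm == 0.0:  # pathological cancellation; keep output well defined
            v[0] = 1.0
            norm = 1.0
        return v / norm


class PretrainedEncoder:
    """Transformer CLS encoder behind the same contract (optional backend).

    Requires the ``transformers``/``torch`` extra; imported lazily so the
    rest of the library works without them.
    """

    def __init__(self, model_name: str, max_tokens: int = 128):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional backend
            raise ImportError(
                "the pretrained encoder backend requires the 'torch' and "
                "'transformers' packages (install the [pretrained] extra)"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()
        self.max_tokens = max_tokens
        self.dim = int(self._model.config.hidden_size)

    def encode(self, text: str) -> np.ndarray:  # pragma: no cover - optional backend
        import torch

        if not text:
            raise TermbaseError("cannot encode an empty string")
        toks = self._tokenizer(
            text, return_tensors="pt", truncation=True, max_length=self.max_tokens
        )
        with torch.no_grad():
            out = self._model(**toks)
        return out.last_hidden_state[0, 0].numpy().astype(np.float64)


def make_test_encoder(dim: int = 768, rng_seed: int = 0) -> TrigramHashEncoder:
    """Build the deterministic trigram test encoder (dim >= 8)."""
    if dim < 8:
        raise TermbaseError(f"encoder dim must be >= 8, got {dim}")
    return TrigramHashEncoder(dim=dim, rng_seed=rng_seed)


def get_encoder(backend: str, dim: int = 768, rng_seed: int = 0, max_tokens: int = 128) -> TextEncoder:
    """Resolve a config string: ``test`` or ``pretrained:<model-name>``."""
    if backend == "test":
        return make_test_encoder(dim=dim, rng_seed=rng_seed)
    if backend.startswith("pretrained:"):
        return PretrainedEncoder(backend.split(":", 1)[1], max_tokens=max_tokens)
    raise TermbaseError(f"unknown encoder backend {backend!r}")


@dataclass
class Projection:
    """Trainable affine map from encoder space to the interaction dimension."""

    weight: np.ndarray  # (d_proj, d_enc)
    bias: np.ndarray  # (d_proj,)

    @classmethod
    def init(cls, d_enc: int, d_proj: int = 300, rng: np.random.Generator | None = None) -> "Projection":
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, 1.0 / np.sqrt(d_enc), size=(d_proj, d_enc))
        return cls(weight=w, bias=np.zeros(d_proj))

    @property
    def d_proj(self) -> int:
        return self.weight.shape[0]

    @property
    def d_enc(self) -> int:
        return self.weight.shape[1]

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Project one vector (d_enc,) or a batch (n, d_enc)."""
        if x.ndim == 1:
            return self.weight @ x + self.bias
        return x @ self.weight.T + self.bias


def encode_name(enc: TextEncoder, proj: Projection, concept: Concept) -> np.ndarray:
    """Projected CLS-style vector of a concept's preferred name."""
    if not concept.name:
        raise TermbaseError(f"concept {concept.id!r} has an empty name")
    return proj.apply(enc.encode(concept.name))


def encode_path(enc: TextEncoder, proj: Projection, seq: PathTokenSequence) -> np.ndarray:
    """Projected CLS-style vector of a serialized hierarchical path."""
    return proj.apply(enc.encode(seq.text))
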