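"""Span representations for node text attributes.

Each node's free-text attribute is embedded as the concatenation
``[first sub-word vector ; mean of all sub-word vectors ; last sub-word
vector]`` (width ``3h``) — the span pooling used by modern biomedical event
extractors. Sub-word vectors come from a pluggable backend: a pre-trained
transformer if one is registered, or the default deterministic
hashed-character-n-gram embedder that needs no model download and gives
controllable surface-form similarity (shared stems -> high cosine).
"""

from __future__ import annotations

import base64
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .errors import BackendUnavailable, EmptySpan, InvalidWidth, ShapeMismatch

__all__ = [
    "TokenizedSpan", "SpanEmbedding", "span_representation",
    "fallback_embed", "pretrained_embed", "register_backend",
    "EmbeddingCache", "embed_texts",
]


@dataclass
class TokenizedSpan:
    """Ordered words, each an ``(s_i, h)`` array of sub-word vectors."""

    words: list[np.ndarray]

    def __post_init__(self):
        if not self.words:
            raise EmptySpan("span has no words")
        widths = {w.shape[1] for w in self.words}
        if len(widths) != 1:
            raise ShapeMismatch(f"inconsistent sub-word widths: {widths}")
        if any(w.shape[0] < 1 for w in self.words):
            raise EmptySpan("a word has no sub-word vectors")

    @property
    def width(self) -> int:
        return self.words[0].shape[1]


@dataclass
class SpanEmbedding:
    vector: np.ndarray  # width 3h


def span_representation(span: TokenizedSpan) -> SpanEmbedding:
    """[v_{f,1} ; mean over all sub-word vectors ; v_{l,s_l}]."""
    first = span.words[0][0]
    last = span.words[-1][-1]
    stacked = np.vstack(span.words)
    mean = stacked.sum(axis=0) / stacked.shape[0]
    return SpanEmbedding(np.concatenate([first, mean, last]))


def _ngram_vector(word: str, h: int, seed: int) -> np.ndarray:
    """Hash boundary-padded character 3-grams into a signed h-dim vector."""
    padded = f"#{word}#"
    grams = [padded[i:i + 3] for i in range(max(1, len(padded) - 2))]
    v = np.zeros(h)
    for gram in grams:
        digest = hashlib.blake2b(f"{seed}|{gram}".encode(), digest_size=8).digest()
        idx = int.from_bytes(digest[:4], "big") % h
        sign = 1.0 if digest[4] % 2 == 0 else -1.0
        v[idx] += sign
    norm = np.linalg.norm(v)
    if norm == 0.0:  # only possible if signs cancel exactly
        v[int.from_bytes(hashlib.blake2b(word.encode(), digest_size=2).digest(), "big") % h] = 1.0
        norm = 1.0
    return v / norm


def fallback_embed(text: str, h: int = 16, seed: int = 0) -> TokenizedSpan:
    """Deterministic download-free backend: one unit-norm sub-word vector per
    whitespace word, built from hashed character 3-grams."""
    if not text or not text.strip():
        raise EmptySpan("cannot embed empty text")
    if h < 2:
        raise InvalidWidth(f"h={h} < 2")
    words = text.split()
    return TokenizedSpan([_ngram_vector(w, h, seed)[None, :] for w in words])


_BACKENDS: dict[str, object] = {}


def register_backend(name: str, fn) -> None:
    """Register a callable ``fn(text) -> TokenizedSpan`` (e.g. a transformer
    wrapper grouping sub-word hidden states by word)."""
    _BACKENDS[name] = fn


def pretrained_embed(text: str, backend: str = "scibert") -> TokenizedSpan:
    if not text or not text.strip():
        raise EmptySpan("cannot embed empty text")
    fn = _BACKENDS.get(backend)
    if fn is None:
        raise BackendUnavailable(
            f"no backend {backend!r} registered; register one with "
            "register_backend() or use fallback_embed()")
    return fn(text)


def embed_texts(texts, h: int = 16, seed: int = 0) -> dict[str, np.ndarray]:
    """Span representation (width 3h) for each unique text, fallback backend."""
    return {t: span_representation(fallback_embed(t, h, seed)).vector
            for t in dict.fromkeys(texts)}


class EmbeddingCache:
    """On-disk cache of span vectors: JSON header line + TSV of
    (text, base64 float64 vector)."""

    def __init__(self, backend: str, h: int):
        self.backend = backend
        self.h = h
        self.vectors: dict[str, np.ndarray] = {}

    def put(self, text: str, vector: np.ndarray) -> None:
        self.vectors[text] = np.asarray(vector, dtype=np.float64)

    def get(self, text: str) -> np.ndarray | None:
        return self.vectors.get(text)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"backend": self.backend, "h": self.h}) + "\n")
            for text, vec in sorted(self.vectors.items()):
                b64 = base64.b64encode(vec.tobytes()).decode()
                fh.write(f"{text}\t{b64}\n")

    @classmethod
    def load(cls, path) -> "EmbeddingCache":
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            cache = cls(header["backend"], header["h"])
            for line in fh:
                text, b64 = line.rstrip("\n").split("\t")
                cache.vectors[text] = np.frombuffer(
                    base64.b64decode(b64), dtype=np.float64).copy()
        return cache
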